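"""Fan-experiment stimulus designs and their conversion to training pairs.

A fan design is a set of 24 short study sentences of the form
``De <person> is in <de/het> <location>`` in which one category (person or
location) is manipulated between fan 2 and fan 4 — the *fan* of a concept
being the number of study sentences it (classic mode) or its semantic group
(semantic mode) participates in — while the other category is held at fan 2.
The fixed letter template is: 4 varied-category fan-2 groups contributing 2
sentences each, 4 varied-category fan-4 groups contributing 4 each, and 12
fixed-category groups contributing 2 each (8 + 16 = 24 sentences).

Recognition foils re-pair person and location words that both occur among the
targets but never co-occur in any target sentence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embedding_space import SimilarityGroup

CATEGORIES = ("person", "location")
ARTICLES = ("de", "het")

#: letter template shared by classic and semantic modes: for the varied
#: category, groups 0-3 are fan 2 and groups 4-7 are fan 4; the fixed
#: category has 12 fan-2 groups.  Each entry is (varied_group, fixed_group).
_FAN2_BLOCK = [(v, f) for v in range(4) for f in (v, (v + 1) % 4)]
_FAN4_BLOCK = [
    (4, 4), (4, 5), (4, 6), (4, 7),
    (5, 4), (5, 5), (5, 8), (5, 9),
    (6, 6), (6, 7), (6, 10), (6, 11),
    (7, 8), (7, 9), (7, 10), (7, 11),
]
PATTERN: list[tuple[int, int]] = _FAN2_BLOCK + _FAN4_BLOCK
N_VARIED_GROUPS = 8        # 4 at fan 2 + 4 at fan 4
N_FIXED_GROUPS = 12        # all at fan 2
VARIED_GROUP_FANS = (2, 2, 2, 2, 4, 4, 4, 4)


class LexiconError(ValueError):
    """Raised when a lexicon cannot support the requested design."""


@dataclass(frozen=True)
class Concept:
    """A single lexical item with its design bookkeeping."""

    word: str
    category: str            # "person" | "location"
    group_id: str
    item_index: int = 1      # ordinal within the group, >= 1
    determiner: str = "de"   # article used before this word

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.determiner not in ARTICLES:
            raise ValueError(f"unknown determiner {self.determiner!r}")
        if self.category == "person" and self.determiner != "de":
            raise ValueError("person words always take the article 'de'")
        if self.item_index < 1:
            raise ValueError("item_index must be >= 1")


@dataclass(frozen=True)
class FanSentence:
    person: Concept
    location: Concept
    kind: str                # "target" | "foil"
    person_fan: int
    location_fan: int

    def __post_init__(self) -> None:
        if self.kind not in ("target", "foil"):
            raise ValueError(f"unknown sentence kind {self.kind!r}")
        if min(self.person_fan, self.location_fan) < 1:
            raise ValueError("fan values must be positive")
        if self.person_fan == 4 and self.location_fan == 4:
            raise ValueError("at most one category may be at fan 4")

    @property
    def sentence_text(self) -> str:
        return (f"De {self.person.word} is in "
                f"{self.location.determiner} {self.location.word}")

    def fan_of(self, category: str) -> int:
        return self.person_fan if category == "person" else self.location_fan

    def concept(self, category: str) -> Concept:
        return self.person if category == "person" else self.location


@dataclass
class FanDesign:
    """24 target sentences plus 24 re-paired foils."""

    targets: list[FanSentence]
    foils: list[FanSentence]
    varied_category: str     # "person" | "location"
    design_mode: str         # "classic" | "semantic"
    determiner_tolerance: int = 2

    @property
    def fixed_category(self) -> str:
        return "location" if self.varied_category == "person" else "person"

    def sentences(self) -> list[tuple[str, FanSentence]]:
        """All sentences with their stable ids (t00..t23, f00..f23)."""
        out = [(f"t{i:02d}", s) for i, s in enumerate(self.targets)]
        out += [(f"f{i:02d}", s) for i, s in enumerate(self.foils)]
        return out

    def group_fans(self, category: str) -> dict[str, int]:
        """Fan of every group in `category`, recomputed from the targets."""
        fans: dict[str, int] = {}
        for s in self.targets:
            gid = s.concept(category).group_id
            fans[gid] = fans.get(gid, 0) + 1
        return fans

    def validate(self) -> None:
        """Check every structural invariant; raise ValueError on violation."""
        if len(self.targets) != 24:
            raise ValueError(f"expected 24 targets, got {len(self.targets)}")
        n22 = sum(1 for s in self.targets
                  if s.person_fan == 2 and s.location_fan == 2)
        n4 = sum(1 for s in self.targets
                 if s.fan_of(self.varied_category) == 4)
        if n22 != 8 or n4 != 16:
            raise ValueError(
                f"fan pattern violated: {n22} sentences at 2-2, {n4} at fan 4")
        varied_fans = self.group_fans(self.varied_category)
        for s in self.targets:
            gid = s.concept(self.varied_category).group_id
            if varied_fans[gid] != s.fan_of(self.varied_category):
                raise ValueError(
                    f"group {gid} appears in {varied_fans[gid]} sentences but "
                    f"is labelled fan {s.fan_of(self.varied_category)}")
        if sorted(varied_fans.values()) != [2, 2, 2, 2, 4, 4, 4, 4]:
            raise ValueError("varied-category groups must be 4x fan2 + 4x fan4")
        fixed_fans = self.group_fans(self.fixed_category)
        if sorted(fixed_fans.values()) != [2] * 12:
            raise ValueError("fixed-category groups must each contribute 2")
        for cat in CATEGORIES:
            words = [s.concept(cat).word for s in self.targets]
            if self.design_mode == "semantic":
                if len(set(words)) != 24:
                    raise ValueError(
                        f"semantic mode requires 24 distinct {cat} words")
            else:
                by_group: dict[str, set[str]] = {}
                for s in self.targets:
                    c = s.concept(cat)
                    by_group.setdefault(c.group_id, set()).add(c.word)
                for gid, ws in by_group.items():
                    if len(ws) != 1:
                        raise ValueError(
                            f"classic mode: group {gid} uses several words {ws}")
        target_pairs = {(s.person.word, s.location.word) for s in self.targets}
        if self.foils:
            if len(self.foils) != 24:
                raise ValueError(f"expected 24 foils, got {len(self.foils)}")
            seen: set[tuple[str, str]] = set()
            target_words = {c: {s.concept(c).word for s in self.targets}
                            for c in CATEGORIES}
            for s in self.foils:
                pair = (s.person.word, s.location.word)
                if pair in target_pairs:
                    raise ValueError(f"foil {pair} duplicates a target pair")
                if pair in seen:
                    raise ValueError(f"duplicate foil pair {pair}")
                seen.add(pair)
                for cat in CATEGORIES:
                    if s.concept(cat).word not in target_words[cat]:
                        raise ValueError(
                            f"foil word {s.concept(cat).word!r} not in targets")
        dets = [s.location.determiner for s in self.targets]
        imbalance = abs(dets.count("de") - dets.count("het"))
        if imbalance > self.determiner_tolerance:
            raise ValueError(
                f"determiner imbalance {imbalance} exceeds tolerance "
                f"{self.determiner_tolerance}")


@dataclass(frozen=True)
class TrainingPair:
    """One skip-gram training item: the varied-category word as target, the
    other-category word plus the article preceding the target as contexts."""

    target_token: str
    context_tokens: frozenset[str]
    sentence_ref: int

    def __post_init__(self) -> None:
        if len(self.context_tokens) != 2:
            raise ValueError("a training pair carries exactly 2 context tokens")


# ---------------------------------------------------------------------------
# classic designs
# ---------------------------------------------------------------------------

def _normalize_location_lexicon(
        location_lexicon: Iterable) -> list[tuple[str, str]]:
    """Accept [(word, det), ...] or {word: det}."""
    if isinstance(location_lexicon, Mapping):
        return list(location_lexicon.items())
    out = []
    for entry in location_lexicon:
        if isinstance(entry, str):
            out.append((entry, "de"))
        else:
            word, det = entry
            out.append((word, det))
    return out


def _pick_balanced_locations(lexicon: list[tuple[str, str]],
                             weights: Sequence[int], tolerance: int,
                             rng: np.random.Generator) -> list[tuple[str, str]]:
    """Choose len(weights) location words so that the determiner counts of the
    resulting target sentences (word i used weights[i] times) are balanced to
    within `tolerance`.  Words are drawn at random within the best feasible
    split between the 'de' and 'het' sub-pools."""
    de_pool = [w for w in lexicon if w[1] == "de"]
    het_pool = [w for w in lexicon if w[1] == "het"]
    rng.shuffle(de_pool)
    rng.shuffle(het_pool)
    classes = sorted(set(weights), reverse=True)
    counts = [weights.count(c) for c in classes]  # slots per weight class
    best = None
    for split in itertools.product(*(range(n + 1) for n in counts)):
        n_de = sum(split)
        n_het = sum(counts) - n_de
        if n_de > len(de_pool) or n_het > len(het_pool):
            continue
        de_uses = sum(c * s for c, s in zip(classes, split))
        imbalance = abs(2 * de_uses - sum(w for w in weights))
        if best is None or imbalance < best[0]:
            best = (imbalance, split)
    if best is None or best[0] > tolerance:
        raise LexiconError(
            "location lexicon cannot satisfy the determiner balance "
            f"tolerance of {tolerance}; supply more 'de'/'het' words")
    _, split = best
    de_iter, het_iter = iter(de_pool), iter(het_pool)
    chosen: list[tuple[str, str]] = []
    for cls, n_slots, n_de in zip(classes, counts, split):
        picks = [next(de_iter) for _ in range(n_de)]
        picks += [next(het_iter) for _ in range(n_slots - n_de)]
        rng.shuffle(picks)
        for w in picks:
            chosen.append(w)
    # reorder back into the weight sequence
    out: list[tuple[str, str] | None] = [None] * len(weights)
    pos_by_class = {c: [i for i, w in enumerate(weights) if w == c]
                    for c in classes}
    it = iter(chosen)
    for cls, n_slots, _ in zip(classes, counts, split):
        for i in pos_by_class[cls]:
            out[i] = next(it)
    return out  # type: ignore[return-value]


def _assemble_targets(varied_concepts: list[list[Concept]],
                      fixed_concepts: list[list[Concept]],
                      varied_category: str) -> list[FanSentence]:
    """Combine per-group concept lists according to the letter template.
    varied_concepts[g] holds the concepts group g contributes, consumed in
    order of appearance; same for fixed_concepts."""
    v_iters = [iter(c) for c in varied_concepts]
    f_iters = [iter(c) for c in fixed_concepts]
    sentences = []
    for v, f in PATTERN:
        vc = next(v_iters[v])
        fc = next(f_iters[f])
        person, location = ((vc, fc) if varied_category == "person"
                            else (fc, vc))
        fan = VARIED_GROUP_FANS[v]
        sentences.append(FanSentence(
            person=person, location=location, kind="target",
            person_fan=fan if varied_category == "person" else 2,
            location_fan=fan if varied_category == "location" else 2))
    return sentences


def build_classic_design(person_lexicon: Sequence[str],
                         location_lexicon: Iterable,
                         varied_category: str = "location",
                         rng_seed: int = 0,
                         determiner_tolerance: int = 2) -> FanDesign:
    """Build a classic design: every group is a single repeated word.

    Needs 8 words in the varied category (4 fan-2 + 4 fan-4 groups) and 12 in
    the fixed one.  Lexical items are assigned to the letter template at
    random, driven solely by `rng_seed`; location words must come with their
    determiner (``(word, "de"|"het")`` pairs or a mapping).
    """
    if varied_category not in CATEGORIES:
        raise ValueError(f"unknown category {varied_category!r}")
    rng = np.random.default_rng(rng_seed)
    persons = list(person_lexicon)
    locations = _normalize_location_lexicon(location_lexicon)
    n_person = N_VARIED_GROUPS if varied_category == "person" else N_FIXED_GROUPS
    n_location = N_VARIED_GROUPS if varied_category == "location" else N_FIXED_GROUPS
    if len(persons) < n_person:
        raise LexiconError(
            f"person lexicon too small: need {n_person}, got {len(persons)}")
    if len(locations) < n_location:
        raise LexiconError(
            f"location lexicon too small: need {n_location}, got {len(locations)}")
    person_words = [persons[i] for i in
                    rng.choice(len(persons), size=n_person, replace=False)]
    if varied_category == "location":
        loc_weights = list(VARIED_GROUP_FANS)
    else:
        loc_weights = [2] * N_FIXED_GROUPS
    loc_words = _pick_balanced_locations(
        locations, loc_weights, determiner_tolerance, rng)

    def group_concepts(words, category, fans, dets=None):
        out = []
        for g, (word, fan) in enumerate(zip(words, fans)):
            det = dets[g] if dets else "de"
            prefix = "p" if category == "person" else "l"
            c = Concept(word=word, category=category,
                        group_id=f"{prefix}{g + 1}", determiner=det)
            out.append([c] * fan)
        return out

    if varied_category == "person":
        varied = group_concepts(person_words, "person", VARIED_GROUP_FANS)
        fixed = group_concepts([w for w, _ in loc_words], "location",
                               [2] * N_FIXED_GROUPS,
                               dets=[d for _, d in loc_words])
    else:
        varied = group_concepts([w for w, _ in loc_words], "location",
                                VARIED_GROUP_FANS,
                                dets=[d for _, d in loc_words])
        fixed = group_concepts(person_words, "person", [2] * N_FIXED_GROUPS)
    targets = _assemble_targets(varied, fixed, varied_category)
    design = FanDesign(targets=targets, foils=[],
                       varied_category=varied_category, design_mode="classic",
                       determiner_tolerance=determiner_tolerance)
    design.foils = make_foils(design, rng_seed=int(rng.integers(2 ** 31)))
    design.validate()
    return design


# ---------------------------------------------------------------------------
# semantic designs
# ---------------------------------------------------------------------------

def _group_determiner(group: SimilarityGroup, idx: int) -> str:
    if group.category == "person":
        return "de"
    if group.determiners is not None:
        return group.determiners[idx]
    return "de"


def build_semantic_design(groups_person: Sequence[SimilarityGroup],
                          groups_location: Sequence[SimilarityGroup],
                          varied_category: str = "person",
                          rng_seed: int = 0,
                          determiner_tolerance: int = 2,
                          max_retries: int = 200) -> FanDesign:
    """Build a semantic design: each letter of the template is a semantic
    group, and each of its sentences uses a *distinct* member of that group,
    so all 24 person words and all 24 location words are pairwise distinct.

    Group order within a category and member order within a group are
    shuffled per seed; fan-4 letters are assigned to groups with >= 4
    members.  Location determiner balance is met by redrawing (bounded by
    `max_retries`) since single-use words leave no room for local swaps.
    """
    if varied_category not in CATEGORIES:
        raise ValueError(f"unknown category {varied_category!r}")
    for groups, cat in ((groups_person, "person"),
                        (groups_location, "location")):
        if not groups:
            raise ValueError(f"no {cat} groups supplied")
        for g in groups:
            if len(g.members) < 2:
                raise ValueError(
                    f"{cat} group {list(g.members)} has fewer than 2 members")
    varied_groups = (groups_person if varied_category == "person"
                     else groups_location)
    fixed_groups = (groups_location if varied_category == "person"
                    else groups_person)
    big = [g for g in varied_groups if len(g.members) >= 4]
    if len(big) < 4:
        raise ValueError(
            "need at least 4 varied-category groups with >= 4 members for the "
            f"fan-4 letters; got {len(big)}")
    if len(varied_groups) < N_VARIED_GROUPS:
        raise ValueError(
            f"need {N_VARIED_GROUPS} varied-category groups, "
            f"got {len(varied_groups)}")
    if len(fixed_groups) < N_FIXED_GROUPS:
        raise ValueError(
            f"need {N_FIXED_GROUPS} fixed-category groups, "
            f"got {len(fixed_groups)}")
    rng = np.random.default_rng(rng_seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            targets = _draw_semantic_targets(
                varied_groups, fixed_groups, varied_category, rng)
            design = FanDesign(targets=targets, foils=[],
                               varied_category=varied_category,
                               design_mode="semantic",
                               determiner_tolerance=determiner_tolerance)
            design.foils = make_foils(
                design, rng_seed=int(rng.integers(2 ** 31)))
            design.validate()
            return design
        except ValueError as err:  # determiner imbalance: redraw
            if "determiner imbalance" not in str(err):
                raise
            last_err = err
    raise ValueError(
        f"could not balance location determiners in {max_retries} draws; "
        f"last error: {last_err}")


def _draw_semantic_targets(varied_groups, fixed_groups, varied_category, rng):
    varied_cat = varied_category
    fixed_cat = "location" if varied_cat == "person" else "person"
    big_idx = [i for i, g in enumerate(varied_groups) if len(g.members) >= 4]
    fan4_sel = rng.choice(big_idx, size=4, replace=False)
    remaining = [i for i in range(len(varied_groups)) if i not in set(fan4_sel)]
    fan2_sel = rng.choice(remaining, size=4, replace=False)
    ordered = [varied_groups[i] for i in fan2_sel] + \
              [varied_groups[i] for i in fan4_sel]
    fixed_sel = rng.choice(len(fixed_groups), size=N_FIXED_GROUPS,
                           replace=False)
    fixed_ordered = [fixed_groups[i] for i in fixed_sel]

    def draw_members(group: SimilarityGroup, n: int, category: str,
                     group_id: str) -> list[Concept]:
        order = rng.permutation(len(group.members))[:n]
        return [Concept(word=group.members[j], category=category,
                        group_id=group_id, item_index=rank + 1,
                        determiner=_group_determiner(group, j))
                for rank, j in enumerate(order)]

    varied_concepts = [
        draw_members(g, fan, varied_cat,
                     f"{'p' if varied_cat == 'person' else 'l'}{i + 1}")
        for i, (g, fan) in enumerate(zip(ordered, VARIED_GROUP_FANS))]
    fixed_concepts = [
        draw_members(g, 2, fixed_cat,
                     f"{'p' if fixed_cat == 'person' else 'l'}{i + 1}")
        for i, g in enumerate(fixed_ordered)]
    return _assemble_targets(varied_concepts, fixed_concepts, varied_cat)


# ---------------------------------------------------------------------------
# foils
# ---------------------------------------------------------------------------

def make_foils(design: FanDesign, rng_seed: int = 0,
               max_retries: int = 1000) -> list[FanSentence]:
    """Re-pair the target person and location words into 24 foils.

    Each target word keeps its multiplicity (a word studied in four sentences
    also appears in four foils); no foil pair may equal a target pair or
    another foil.  Rejection sampling over shuffled pools, then deterministic
    backtracking if the retry budget is exhausted.  A foil inherits the fan
    labels of its constituent words' groups.
    """
    if len(design.targets) == 0:
        raise ValueError("design has no targets to re-pair")
    rng = np.random.default_rng(rng_seed)
    persons = [s.person for s in design.targets]
    locations = [s.location for s in design.targets]
    forbidden = {(s.person.word, s.location.word) for s in design.targets}
    person_fans = design.group_fans("person")
    location_fans = design.group_fans("location")

    def pairing_ok(order: Sequence[Concept]) -> bool:
        seen = set()
        for p, l in zip(persons, order):
            pair = (p.word, l.word)
            if pair in forbidden or pair in seen:
                return False
            seen.add(pair)
        return True

    assignment: list[Concept] | None = None
    for _ in range(max_retries):
        order = list(locations)
        rng.shuffle(order)
        if pairing_ok(order):
            assignment = order
            break
    if assignment is None:
        assignment = _backtrack_pairing(persons, locations, forbidden)
    if assignment is None:
        raise ValueError("no valid foil re-pairing exists for this design")
    return [FanSentence(person=p, location=l, kind="foil",
                        person_fan=person_fans[p.group_id],
                        location_fan=location_fans[l.group_id])
            for p, l in zip(persons, assignment)]


def _backtrack_pairing(persons, locations, forbidden):
    """Depth-first search for a duplicate-free re-pairing (most-constrained
    slots are equivalent here, so plain left-to-right order suffices)."""
    n = len(persons)
    used = [False] * n
    out: list = [None] * n
    seen: set[tuple[str, str]] = set()

    def rec(i: int) -> bool:
        if i == n:
            return True
        for j in range(n):
            if used[j]:
                continue
            pair = (persons[i].word, locations[j].word)
            if pair in forbidden or pair in seen:
                continue
            used[j] = True
            seen.add(pair)
            out[i] = locations[j]
            if rec(i + 1):
                return True
            used[j] = False
            seen.discard(pair)
        return False

    return out if rec(0) else None


# ---------------------------------------------------------------------------
# training pairs
# ---------------------------------------------------------------------------

def to_training_pairs(design: FanDesign) -> list[TrainingPair]:
    """One pair per target sentence: the varied-category word is the target
    token; the other-category word and the article immediately preceding the
    target word are its two context tokens.  When the person is the target
    that article is the sentence-initial ``De`` (lower-cased), constant
    across sentences."""
    pairs = []
    for i, s in enumerate(design.targets):
        target = s.concept(design.varied_category)
        other = s.concept(design.fixed_category)
        article = (s.location.determiner
                   if design.varied_category == "location" else "de")
        pairs.append(TrainingPair(
            target_token=target.word,
            context_tokens=frozenset({other.word, article}),
            sentence_ref=i))
    return pairs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def design_to_tsv(design: FanDesign, path) -> None:
    import pandas as pd

    rows = []
    for sid, s in design.sentences():
        rows.append(dict(
            sentence_id=sid, kind=s.kind, person=s.person.word,
            location=s.location.word, determiner=s.location.determiner,
            person_fan=s.person_fan, location_fan=s.location_fan,
            group_person=s.person.group_id, group_location=s.location.group_id,
            text=s.sentence_text))
    with open(path, "w") as fh:
        fh.write(f"# varied_category={design.varied_category}\t"
                 f"design_mode={design.design_mode}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def design_from_tsv(path) -> FanDesign:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(item.split("=", 1)
                    for item in header.lstrip("# ").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    sentences: dict[str, list[FanSentence]] = {"target": [], "foil": []}
    for _, r in df.iterrows():
        s = FanSentence(
            person=Concept(word=r.person, category="person",
                           group_id=r.group_person),
            location=Concept(word=r.location, category="location",
                             group_id=r.group_location,
                             determiner=r.determiner),
            kind=r.kind, person_fan=int(r.person_fan),
            location_fan=int(r.location_fan))
        sentences[r.kind].append(s)
    return FanDesign(targets=sentences["target"], foils=sentences["foil"],
                     varied_category=meta["varied_category"],
                     design_mode=meta["design_mode"])


# ---------------------------------------------------------------------------
# example lexicons (Dutch occupations and locations, as in the original
# person-in-location paradigm; the classic simulation is insensitive to the
# particular words, which act as memory placeholders)
# ---------------------------------------------------------------------------

DEFAULT_PERSON_LEXICON = [
    "kapitein", "verkoper", "soldaat", "schilder", "cowboy", "rechter",
    "dokter", "advocaat", "monteur", "zanger", "jager", "notaris",
    "artiest", "muzikant", "loodgieter", "denker",
]

DEFAULT_LOCATION_LEXICON = [
    ("toren", "de"), ("zwembad", "het"), ("grot", "de"), ("dorp", "het"),
    ("schuur", "de"), ("ravijn", "het"), ("fabriek", "de"), ("kasteel", "het"),
    ("woning", "de"), ("fort", "het"), ("tempel", "de"), ("bos", "het"),
    ("hut", "de"), ("warenhuis", "het"), ("kerk", "de"), ("plein", "het"),
]
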