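"""Word-vector spaces: cosine utilities, semantic-group validation, synthetic
clustered spaces, and word2vec text-format I/O.

The semantic fan manipulation needs word lists ("similarity groups") whose
in-group cosine similarity always exceeds their similarity to members of
other groups of the same category.  `synth_clustered_space` generates such
spaces deterministically so the whole pipeline can run without pretrained
embeddings: group centroids are drawn isotropically at unit norm and members
scatter around them with a controlled relative spread.  Like pretrained
word2vec vectors, the synthetic vectors are not normalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class WordVectorStore:
    """token -> d-dimensional vector map."""

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {tok!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)")
            self.vectors[tok] = vec

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self.vectors[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vector store") from None

    def __len__(self) -> int:
        return len(self.vectors)

    def tokens(self) -> list[str]:
        return list(self.vectors)


@dataclass(frozen=True)
class SimilarityGroup:
    """2-4 tokens forming one semantic fan group.  Location groups may carry
    the article of each member (parallel to `members`)."""

    members: tuple[str, ...]
    category: str  # "person" | "location"
    determiners: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if self.determiners is not None:
            dets = tuple(self.determiners)
            if len(dets) != len(self.members):
                raise ValueError("determiners must parallel members")
            object.__setattr__(self, "determiners", dets)


class GroupViolation(NamedTuple):
    word: str
    in_group_min: float
    out_group_max: float


def cosine(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity; raises on zero vectors or length mismatch."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine is undefined for the zero vector")
    return float(np.dot(u, v) / (nu * nv))


def nearest_neighbors(store: WordVectorStore, query: str,
                      n: int) -> list[tuple[str, float]]:
    """The n tokens most cosine-similar to `query`, query excluded,
    descending similarity with lexicographic tie-break."""
    if query not in store:
        raise KeyError(f"token {query!r} not in vector store")
    if n >= len(store):
        raise ValueError("n must be smaller than the vocabulary size")
    q = store[query]
    scored = [(tok, cosine(q, vec)) for tok, vec in store.vectors.items()
              if tok != query]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:n]


def validate_groups(groups: Sequence[SimilarityGroup],
                    store: WordVectorStore) -> list[GroupViolation]:
    """Check the in-group > out-group cosine constraint.

    For every group member, its minimum cosine to the rest of its group must
    exceed its maximum cosine to any member of a *different group of the same
    category*.  Returns one violation triple per failing word; an empty list
    means every group is valid.  Single groups are vacuously valid.
    """
    violations: list[GroupViolation] = []
    for gi, group in enumerate(groups):
        others = [tok for gj, g in enumerate(groups)
                  if gj != gi and g.category == group.category
                  for tok in g.members]
        if not others:
            continue
        for word in group.members:
            mates = [m for m in group.members if m != word]
            if not mates:
                continue
            in_min = min(cosine(store[word], store[m]) for m in mates)
            out_max = max(cosine(store[word], store[o]) for o in others)
            if in_min <= out_max:
                violations.append(GroupViolation(word, in_min, out_max))
    return violations


def synth_clustered_space(n_groups_person: int = 8,
                          n_groups_location: int = 12,
                          group_size: int = 4,
                          dimension: int = 100,
                          within_spread: float = 0.05,
                          rng_seed: int = 0,
                          max_retries: int = 50,
                          ) -> tuple[WordVectorStore, list[SimilarityGroup]]:
    """Generate a clustered vector space emulating pretrained embeddings.

    Each group gets a unit-norm centroid drawn isotropically; members are the
    centroid plus isotropic Gaussian noise with expected norm
    ``within_spread`` (so the spread is relative to the centroid norm).
    Location members carry alternating de/het determiners, which keeps
    designs built from them balanced.  The space is regenerated until
    `validate_groups` passes; a seed never yields a different space twice.
    """
    if within_spread <= 0:
        raise ValueError("within_spread must be positive")
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        vectors: dict[str, np.ndarray] = {}
        groups: list[SimilarityGroup] = []
        for category, n_groups in (("person", n_groups_person),
                                   ("location", n_groups_location)):
            for g in range(n_groups):
                centroid = rng.normal(size=dimension)
                centroid /= np.linalg.norm(centroid)
                members = []
                for m in range(group_size):
                    tok = f"{category}_g{g + 1}_m{m + 1}"
                    noise = rng.normal(size=dimension) * (
                        within_spread / np.sqrt(dimension))
                    vectors[tok] = centroid + noise
                    members.append(tok)
                dets = (tuple("de" if m % 2 == 0 else "het"
                              for m in range(group_size))
                        if category == "location" else None)
                groups.append(SimilarityGroup(
                    members=tuple(members), category=category,
                    determiners=dets))
        store = WordVectorStore(dimension=dimension, vectors=vectors)
        if not validate_groups(groups, store):
            return store, groups
    raise RuntimeError(
        f"could not satisfy the in-group > out-group constraint in "
        f"{max_retries} attempts; try a smaller within_spread than "
        f"{within_spread}")


# ---------------------------------------------------------------------------
# word2vec text format
# ---------------------------------------------------------------------------

def read_word2vec_text(path) -> WordVectorStore:
    """Read vectors in word2vec text format (header ``vocab_size dim``, then
    one ``token v1 ... vd`` line each).  Duplicate tokens keep the first
    occurrence with a warning; a row of the wrong width is an error naming
    the line number."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header}")
        declared_vocab, dimension = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            token, values = parts[0], parts[1:]
            if values and values[-1] == "":  # trailing space convention
                values = values[:-1]
            if len(values) != dimension:
                raise ValueError(
                    f"{path}:{lineno}: expected {dimension} values for "
                    f"{token!r}, got {len(values)}")
            if token in vectors:
                warnings.warn(
                    f"{path}:{lineno}: duplicate token {token!r}; "
                    "keeping the first occurrence")
                continue
            vectors[token] = np.array(values, dtype=float)
    if declared_vocab != len(vectors):
        logger.info("header declared %d tokens, read %d",
                    declared_vocab, len(vectors))
    return WordVectorStore(dimension=dimension, vectors=vectors)


def write_word2vec_text(store: WordVectorStore, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(store)} {store.dimension}\n")
        for token, vec in store.vectors.items():
            values = " ".join(repr(float(x)) for x in vec)
            fh.write(f"{token} {values}\n")


def groups_to_json(groups: Sequence[SimilarityGroup], path) -> None:
    import json

    payload = [dict(category=g.category, members=list(g.members),
                    determiners=(list(g.determiners)
                                 if g.determiners else None))
               for g in groups]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def groups_from_json(path) -> list[SimilarityGroup]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return [SimilarityGroup(members=tuple(g["members"]),
                            category=g["category"],
                            determiners=(tuple(g["determiners"])
                                         if g.get("determiners") else None))
            for g in payload]
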