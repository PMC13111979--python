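"""From embeddings to spreading activation and predicted behavior.

The rational analysis of memory puts the spreading activation a cue j sends
to a memory chunk i at log P(i|j)/P(i) — pointwise mutual information.  A
skip-gram model trained with k negative samples approximates the same
quantity as t.c + log k, the shifted dot product of the target and context
vectors.  Activation maps to behavior through the standard declarative
retrieval linking functions: latency F*exp(-A) and retrieval probability
1/(1 + exp(-(A - T)/s)).

A sign-binarized comparison model treats every embedding dimension as a
discrete retrieval cue and applies the classic fan formula S - log(fan_j)
per cue; it captures the fan-2/fan-4 ordering but discards the magnitude
information the dot product carries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .embedding_space import WordVectorStore
from .fan_design import ARTICLES, FanDesign
from .sgns_core import TrainedSGNS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# activation as (shifted) pmi
# ---------------------------------------------------------------------------

def shifted_dot(t_vec: Sequence[float], c_vec: Sequence[float],
                k: int) -> float:
    """t.c + log k, the skip-gram estimate of pmi(t, c)."""
    t_vec = np.asarray(t_vec, dtype=float)
    c_vec = np.asarray(c_vec, dtype=float)
    if t_vec.shape != c_vec.shape:
        raise ValueError(
            f"length mismatch: {t_vec.shape} vs {c_vec.shape}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(t_vec @ c_vec) + math.log(k)


def pmi_activation(p_i_given_j: float, p_i: float) -> float:
    """Spreading activation log(P(i|j) / P(i)).

    With P(i|j) = 1/fan and P(i) = 1/memory_size this reduces to the classic
    fan formula log(memory_size) - log(fan).
    """
    for name, p in (("p_i_given_j", p_i_given_j), ("p_i", p_i)):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return math.log(p_i_given_j / p_i)


# ---------------------------------------------------------------------------
# linking functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkingParams:
    """ACT-R declarative retrieval linking parameters.

    F: latency scale (same time unit as the predicted retrieval time);
    T: retrieval threshold (activation units); s: activation noise scale.
    """

    F: float = 3000.0   # ms, calibrated so fan-experiment RTs land ~1-2 s
    T: float = 0.5
    s: float = 0.4

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be positive")
        if self.s <= 0:
            raise ValueError("s must be positive")


def retrieval_time(A, params: LinkingParams):
    """Predicted retrieval latency F * exp(-A); decreasing in A."""
    return params.F * np.exp(-np.asarray(A, dtype=float))


def retrieval_prob(A, params: LinkingParams):
    """Probability of successful retrieval 1/(1 + exp(-(A - T)/s))."""
    return expit((np.asarray(A, dtype=float) - params.T) / params.s)


# ---------------------------------------------------------------------------
# activation tables
# ---------------------------------------------------------------------------

ACTIVATION_COLUMNS = ["sentence_id", "target", "context", "dot",
                      "shifted_dot", "fan_condition", "kind", "list_id",
                      "seed"]


def build_activation_table(models: Sequence[TrainedSGNS],
                           design: FanDesign,
                           list_id: int = 0,
                           include_foils: bool = True) -> pd.DataFrame:
    """Per-pair activation estimates, dot products averaged across seeds.

    One row per target sentence's (target word, content context word) pair;
    articles are excluded (the reported pair means are over person-location
    pairs).  A foil has no trained pair of its own, so its activation is the
    mean of the trained pair dots of all target sentences sharing either of
    its constituent words.
    """
    if not models:
        raise ValueError("no models given")
    k = models[0].config.k_negatives
    shift = math.log(k)
    seed_label = ",".join(str(m.seed) for m in models)
    rows = []
    for sid, s in design.sentences():
        if s.kind != "target":
            continue
        t = s.concept(design.varied_category).word
        c = s.concept(design.fixed_category).word
        for m in models:
            if t not in m.target_index or c not in m.context_index:
                raise KeyError(
                    f"pair ({t!r}, {c!r}) missing from model vocabulary")
        dot = float(np.mean([m.dot(t, c) for m in models]))
        rows.append(dict(
            sentence_id=sid, target=t, context=c, dot=dot,
            shifted_dot=dot + shift,
            fan_condition=s.fan_of(design.varied_category),
            kind="target", list_id=list_id, seed=seed_label))
    table = pd.DataFrame(rows)
    if include_foils and design.foils:
        by_word: dict[str, list[float]] = {}
        for r in rows:
            by_word.setdefault(r["target"], []).append(r["dot"])
            by_word.setdefault(r["context"], []).append(r["dot"])
        foil_rows = []
        for sid, s in design.sentences():
            if s.kind != "foil":
                continue
            t = s.concept(design.varied_category).word
            c = s.concept(design.fixed_category).word
            dot = float(np.mean(by_word[t] + by_word[c]))
            foil_rows.append(dict(
                sentence_id=sid, target=t, context=c, dot=dot,
                shifted_dot=dot + shift,
                fan_condition=s.fan_of(design.varied_category),
                kind="foil", list_id=list_id, seed=seed_label))
        table = pd.concat([table, pd.DataFrame(foil_rows)],
                          ignore_index=True)
    return table[ACTIVATION_COLUMNS]


def condition_means(table: pd.DataFrame,
                    column: str = "shifted_dot") -> dict[int, float]:
    """Mean of `column` over target rows per fan condition."""
    targets = table[table["kind"] == "target"]
    return {int(fan): float(g[column].mean())
            for fan, g in targets.groupby("fan_condition")}


def pretraining_dots(design: FanDesign, store: WordVectorStore,
                     rng_seed: int, init_low: float = -1.0,
                     init_high: float = 1.0) -> pd.DataFrame:
    """Dot products of pretrained target vectors with freshly initialized
    (untrained) context vectors — the before-training null check that the
    stimulus lists carry no built-in fan contrast."""
    rng = np.random.default_rng([rng_seed, 0])
    contexts = sorted({s.concept(design.fixed_category).word
                       for s in design.targets})
    ctx_vecs = {c: rng.uniform(init_low, init_high, size=store.dimension)
                for c in contexts}
    rows = []
    for sid, s in design.sentences():
        if s.kind != "target":
            continue
        t = s.concept(design.varied_category).word
        c = s.concept(design.fixed_category).word
        dot = float(store[t] @ ctx_vecs[c])
        rows.append(dict(sentence_id=sid, target=t, context=c, dot=dot,
                         fan_condition=s.fan_of(design.varied_category)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binarized-cue ACT-R comparison model
# ---------------------------------------------------------------------------

@dataclass
class CueSpace:
    """Discrete-cue view of an embedding space for the classic fan formula.

    Every embedding dimension becomes one retrieval cue per word: its sign
    (+1 for positive values, -1 otherwise).  `chunks` are the studied
    person-location facts, represented by the binarized vectors of their
    words per category.  S is the log memory size; cue weights are uniform,
    W/d per cue with total weight W.
    """

    binarized: dict[str, np.ndarray]
    chunk_words: dict[str, list[str]]     # category -> word per study chunk
    S: float
    total_weight: float = 100.0

    @property
    def dimension(self) -> int:
        return next(iter(self.binarized.values())).shape[0]


def binarize(store: WordVectorStore) -> dict[str, np.ndarray]:
    """Sign-binarize every vector: +1 where the value is positive, else -1
    (zeros fall in the -1 branch)."""
    if not len(store):
        raise ValueError("empty vector store")
    return {tok: np.where(vec > 0, 1, -1).astype(np.int8)
            for tok, vec in store.vectors.items()}


def make_cue_space(store: WordVectorStore, design: FanDesign,
                   S: float | None = None,
                   total_weight: float = 100.0) -> CueSpace:
    """Build the cue space of a design's study set.  S defaults to
    log(number of study chunks), the log memory size under a uniform need
    distribution; it is exposed because the framework usually treats it as a
    free parameter."""
    chunk_words = {
        "person": [s.person.word for s in design.targets],
        "location": [s.location.word for s in design.targets],
    }
    needed = set(chunk_words["person"]) | set(chunk_words["location"])
    missing = sorted(t for t in needed if t not in store)
    if missing:
        raise KeyError(f"vector store lacks tokens {missing}")
    sub = WordVectorStore(
        dimension=store.dimension,
        vectors={t: store[t] for t in sorted(needed)})
    if S is None:
        S = math.log(len(design.targets))
    return CueSpace(binarized=binarize(sub), chunk_words=chunk_words,
                    S=S, total_weight=total_weight)


def actr_fan_activation(probe: str, cue_space: CueSpace,
                        probe_category: str) -> float:
    """Spreading activation of a probe word under the binarized-cue model.

    Each of the probe's d cues is a (dimension, sign) feature; its fan is
    the number of study chunks whose word of the probe's category carries
    the same sign in that dimension.  The activation is the cue-weighted sum
    of S - log(fan_j) with uniform weights W/d.  A cue matched by no chunk
    is guarded to fan 1 (log 0) with a warning.
    """
    if probe not in cue_space.binarized:
        raise KeyError(f"probe {probe!r} not binarized in this cue space")
    probe_vec = cue_space.binarized[probe]
    chunk_mat = np.stack([cue_space.binarized[w]
                          for w in cue_space.chunk_words[probe_category]])
    fan = (chunk_mat == probe_vec).sum(axis=0)
    if (fan == 0).any():
        logger.warning("%d cue(s) of %r matched no chunk; using fan 1",
                       int((fan == 0).sum()), probe)
        fan = np.maximum(fan, 1)
    d = cue_space.dimension
    w_j = cue_space.total_weight / d
    return float(np.sum(w_j * (cue_space.S - np.log(fan))))


def actr_activation_table(store: WordVectorStore, design: FanDesign,
                          S: float | None = None,
                          total_weight: float = 100.0) -> pd.DataFrame:
    """Binarized-cue activation of every varied-category target word."""
    space = make_cue_space(store, design, S=S, total_weight=total_weight)
    cat = design.varied_category
    rows = []
    for sid, s in design.sentences():
        if s.kind != "target":
            continue
        word = s.concept(cat).word
        rows.append(dict(
            sentence_id=sid, target=word,
            activation=actr_fan_activation(word, space, cat),
            fan_condition=s.fan_of(cat)))
    return pd.DataFrame(rows)
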