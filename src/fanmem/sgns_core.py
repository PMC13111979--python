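"""Skip-gram with negative sampling (SGNS), trained on fan-design pairs.

This is the model whose target-context dot products approximate pointwise
mutual information shifted by -log k, and therefore spreading activation in
the rational analysis of memory.  The trainer is deliberately minimal: the
vocabulary is the handful of content words and articles of one fan design,
every epoch visits each (target, context-token) edge once in a per-epoch
shuffled order, and each visit takes one Adam step on the binary logistic
objective

    L(t, c) = -log sigma(t.c) - sum_{c' ~ Pn} log sigma(-t.c')

with k noise contexts c' drawn from the unigram edge distribution raised to
the ``noise_exponent`` (3/4 by default).  Training can update both matrices
(classic simulation: both initialized uniform(-1, 1)) or freeze the target
matrix at pretrained vectors (semantic simulation).

Averaging "over models" for multiple seeds happens downstream on per-pair
dot products, not on vectors (see `activation_link.build_activation_table`).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .embedding_space import WordVectorStore, read_word2vec_text, \
    write_word2vec_text
from .fan_design import ARTICLES, TrainingPair


@dataclass(frozen=True)
class SGNSConfig:
    dimension: int = 100
    k_negatives: int = 5
    noise_exponent: float = 0.75
    learning_rate: float = 3e-3          # Adam step size
    init_low: float = -1.0
    init_high: float = 1.0
    epochs: int = 24                     # 24 classic; semantic runs use 65
    freeze_targets: bool = False
    seeds: tuple[int, ...] = (1, 2, 3)
    recall_stop_threshold: float | None = None
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    #: visit each *distinct* (target, context) pair once per epoch.  A fan-f
    #: target repeats its article pair in f sentences; collapsing those
    #: repeats makes its observed-pair count f+1 versus f+1 for fan 2 vs 3,
    #: which is what places the converged fan-2/fan-4 dot gap at log(5/3)
    #: rather than log 2.
    dedupe_edges: bool = True
    #: redraw noise contexts that collide with the observed context of the
    #: current pair.  Off by default: a collision then simply contributes
    #: its negative gradient, as in implementations that do not special-case
    #: the draw.
    resample_collisions: bool = False

    def __post_init__(self) -> None:
        if self.k_negatives < 1:
            raise ValueError("k_negatives must be >= 1")
        if not 0 < self.noise_exponent <= 1:
            raise ValueError("noise_exponent must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedSGNS:
    target_matrix: np.ndarray            # |T| x d
    context_matrix: np.ndarray           # |C| x d
    target_index: dict[str, int]
    context_index: dict[str, int]
    config: SGNSConfig
    seed: int
    epoch_log: list[dict] = field(default_factory=list)

    def dot(self, target_token: str, context_token: str) -> float:
        t = self.target_matrix[self.target_index[target_token]]
        c = self.context_matrix[self.context_index[context_token]]
        return float(t @ c)


def noise_distribution(context_counts: Mapping[str, int],
                       exponent: float = 0.75) -> dict[str, float]:
    """Unigram noise distribution p_c proportional to count_c**exponent."""
    if not context_counts:
        raise ValueError("empty context counts")
    if any(c <= 0 for c in context_counts.values()):
        raise ValueError("context counts must be positive")
    weights = {tok: cnt ** exponent for tok, cnt in context_counts.items()}
    total = sum(weights.values())
    return {tok: w / total for tok, w in weights.items()}


def _edges(pairs: Sequence[TrainingPair]) -> list[tuple[str, str]]:
    """The (target, context-token) edge corpus, in deterministic order."""
    return [(p.target_token, c) for p in pairs
            for c in sorted(p.context_tokens)]


def init_model(pairs: Sequence[TrainingPair], config: SGNSConfig,
               seed: int,
               pretrained_targets: WordVectorStore | None = None,
               ) -> TrainedSGNS:
    """Build an untrained model over the vocabulary of `pairs`.

    Target rows are uniform(init_low, init_high) draws, or exact copies of
    the pretrained vectors when given; context rows are always uniform draws.
    Bit-deterministic under `seed` (target rows drawn before context rows).
    """
    targets = sorted({p.target_token for p in pairs})
    contexts = sorted({c for p in pairs for c in p.context_tokens})
    if not targets:
        raise ValueError("no training pairs given")
    rng = np.random.default_rng([seed, 0])
    d = config.dimension
    if pretrained_targets is not None:
        if pretrained_targets.dimension != d:
            raise ValueError(
                f"pretrained dimension {pretrained_targets.dimension} != "
                f"configured dimension {d}")
        missing = [t for t in targets if t not in pretrained_targets]
        if missing:
            raise KeyError(
                f"pretrained vectors missing for target tokens: {missing}")
        target_matrix = np.stack([pretrained_targets[t] for t in targets])
    else:
        target_matrix = rng.uniform(config.init_low, config.init_high,
                                    size=(len(targets), d))
    context_matrix = rng.uniform(config.init_low, config.init_high,
                                 size=(len(contexts), d))
    return TrainedSGNS(
        target_matrix=target_matrix, context_matrix=context_matrix,
        target_index={t: i for i, t in enumerate(targets)},
        context_index={c: i for i, c in enumerate(contexts)},
        config=config, seed=seed, epoch_log=[])


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return -np.logaddexp(0.0, -x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def edge_loss(t_vec: np.ndarray, c_vec: np.ndarray,
              neg_vecs: np.ndarray) -> float:
    """The per-edge negative-sampling loss (used by the gradient tests)."""
    return float(-_log_sigmoid(t_vec @ c_vec)
                 - np.sum(_log_sigmoid(-(neg_vecs @ t_vec))))


def edge_gradients(t_vec: np.ndarray, c_vec: np.ndarray,
                   neg_vecs: np.ndarray):
    """Analytic gradients of `edge_loss` w.r.t. t, c and each noise row."""
    g_pos = _sigmoid(t_vec @ c_vec) - 1.0         # scalar
    s_neg = _sigmoid(neg_vecs @ t_vec)            # (k,)
    grad_t = g_pos * c_vec + s_neg @ neg_vecs
    grad_c = g_pos * t_vec
    grad_neg = np.outer(s_neg, t_vec)
    return grad_t, grad_c, grad_neg


class _AdamState:
    """Row-sparse Adam: moments exist for every row but only rows touched by
    a step are advanced, with bias correction from the global step count."""

    def __init__(self, shape, config: SGNSConfig):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.cfg = config

    def update_rows(self, matrix, rows, grads, step: int) -> None:
        cfg = self.cfg
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        self.m[rows] = b1 * self.m[rows] + (1 - b1) * grads
        self.v[rows] = b2 * self.v[rows] + (1 - b2) * grads * grads
        m_hat = self.m[rows] / (1 - b1 ** step)
        v_hat = self.v[rows] / (1 - b2 ** step)
        matrix[rows] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat)
                                                     + cfg.adam_eps)


def train(model: TrainedSGNS, pairs: Sequence[TrainingPair],
          config: SGNSConfig | None = None,
          seed: int | None = None) -> TrainedSGNS:
    """Train a copy of `model` on the edge corpus of `pairs`.

    Runs ``config.epochs`` full passes (or stops early at the first epoch
    whose recall error drops to ``recall_stop_threshold``, when set).  Each
    pass visits every distinct (target, context-token) pair once in a
    per-epoch shuffled order (set ``dedupe_edges=False`` to visit repeated
    pairs at their sentence multiplicity instead).  Noise contexts are drawn
    from the p**exponent unigram distribution of the sentence-level edge
    corpus, articles included.  Context rows always update; target rows only
    when ``freeze_targets`` is false.
    """
    config = config or model.config
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng([seed, 1])
    corpus = _edges(pairs)
    for t, c in corpus:
        if t not in model.target_index or c not in model.context_index:
            raise KeyError(f"edge ({t!r}, {c!r}) not in model vocabulary")
    if config.dedupe_edges:
        edges = sorted(set(corpus))
    else:
        edges = corpus
    counts: dict[str, int] = {}
    for _, c in corpus:
        counts[c] = counts.get(c, 0) + 1
    noise = noise_distribution(counts, config.noise_exponent)
    context_tokens = sorted(model.context_index,
                            key=model.context_index.__getitem__)
    probs = np.array([noise.get(tok, 0.0) for tok in context_tokens])
    probs = probs / probs.sum()
    cum = np.cumsum(probs)
    edge_rows = np.array([[model.target_index[t], model.context_index[c]]
                          for t, c in edges])

    out = TrainedSGNS(
        target_matrix=model.target_matrix.copy(),
        context_matrix=model.context_matrix.copy(),
        target_index=dict(model.target_index),
        context_index=dict(model.context_index),
        config=config, seed=seed, epoch_log=list(model.epoch_log))
    T, C = out.target_matrix, out.context_matrix
    adam_t = _AdamState(T.shape, config)
    adam_c = _AdamState(C.shape, config)
    k = config.k_negatives
    step = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(edges))
        total_loss = 0.0
        for idx in order:
            ti, ci = edge_rows[idx]
            negs = np.searchsorted(cum, rng.random(k))
            if config.resample_collisions:
                while (negs == ci).any():
                    clash = negs == ci
                    negs[clash] = np.searchsorted(cum, rng.random(clash.sum()))
            t_vec = T[ti]
            total_loss += edge_loss(t_vec, C[ci], C[negs])
            grad_t, grad_c, grad_neg = edge_gradients(t_vec, C[ci], C[negs])
            step += 1
            # negatives can repeat within a draw: accumulate per row
            uniq, inv = np.unique(negs, return_inverse=True)
            acc = np.zeros((len(uniq), C.shape[1]))
            np.add.at(acc, inv, grad_neg)
            c_rows = np.concatenate(([ci], uniq))
            c_grads = np.vstack((grad_c, acc))
            adam_c.update_rows(C, c_rows, c_grads, step)
            if not config.freeze_targets:
                adam_t.update_rows(T, np.array([ti]), grad_t[None, :], step)
        mean_loss = total_loss / len(edges)
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}; the learning rate "
                f"({config.learning_rate}) is likely too large for this "
                "corpus")
        err = recall_error(out, pairs)
        out.epoch_log.append(
            dict(epoch=epoch, mean_loss=mean_loss, recall_error=err))
        if (config.recall_stop_threshold is not None
                and err <= config.recall_stop_threshold):
            break
    return out


def recall_error(model: TrainedSGNS, pairs: Sequence[TrainingPair],
                 exclude_tokens: Sequence[str] = ARTICLES,
                 scorer: Callable[[np.ndarray, np.ndarray], np.ndarray]
                 | None = None) -> float:
    """Fraction of observed content edges the model fails to recall.

    A target with f observed content-word contexts (its fan) recalls
    correctly when those f contexts are exactly its top-f content contexts
    by score (dot product by default; `scorer(t_vec, C_content)` may replace
    it).  Articles are excluded from the ranking since a single article
    co-occurs with up to half the targets.  Ties break lexicographically.
    """
    observed: dict[str, set[str]] = {}
    for p in pairs:
        content = {c for c in p.context_tokens if c not in exclude_tokens}
        observed.setdefault(p.target_token, set()).update(content)
    content_tokens = sorted(c for c in model.context_index
                            if c not in exclude_tokens)
    if not content_tokens:
        return 0.0
    rows = [model.context_index[c] for c in content_tokens]
    C = model.context_matrix[rows]
    mistakes = 0
    n_edges = 0
    for t, ctxs in observed.items():
        f = len(ctxs)
        n_edges += f
        if f == 0:
            continue
        t_vec = model.target_matrix[model.target_index[t]]
        scores = scorer(t_vec, C) if scorer else C @ t_vec
        ranked = sorted(zip(-scores, content_tokens))
        top = {tok for _, tok in ranked[:f]}
        mistakes += len(ctxs - top)
    return mistakes / n_edges if n_edges else 0.0


def train_ensemble(pairs: Sequence[TrainingPair], config: SGNSConfig,
                   pretrained_targets: WordVectorStore | None = None,
                   ) -> list[TrainedSGNS]:
    """Initialize and train one model per configured seed."""
    models = []
    for seed in config.seeds:
        model = init_model(pairs, config, seed, pretrained_targets)
        models.append(train(model, pairs))
    return models


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedSGNS, directory) -> None:
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, matrix, index in (
            ("target", model.target_matrix, model.target_index),
            ("context", model.context_matrix, model.context_index)):
        tokens = sorted(index, key=index.__getitem__)
        store = WordVectorStore(
            dimension=matrix.shape[1],
            vectors={tok: matrix[i] for tok, i in zip(tokens,
                                                      range(len(tokens)))})
        write_word2vec_text(store, directory / f"{name}.txt")
    meta = dict(config=asdict(model.config), seed=model.seed,
                epoch_log=model.epoch_log)
    meta["config"]["seeds"] = list(model.config.seeds)
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(directory) -> TrainedSGNS:
    directory = pathlib.Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    meta["config"]["seeds"] = tuple(meta["config"]["seeds"])
    config = SGNSConfig(**meta["config"])
    stores = {name: read_word2vec_text(directory / f"{name}.txt")
              for name in ("target", "context")}
    out = {}
    for name, store in stores.items():
        tokens = store.tokens()
        out[name] = (np.stack([store[t] for t in tokens]),
                     {t: i for i, t in enumerate(tokens)})
    return TrainedSGNS(
        target_matrix=out["target"][0], context_matrix=out["context"][0],
        target_index=out["target"][1], context_index=out["context"][1],
        config=config, seed=meta["seed"], epoch_log=meta["epoch_log"])
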