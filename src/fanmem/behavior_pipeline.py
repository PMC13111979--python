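"""Synthetic recognition-test behavior and the analysis-side pipeline.

The generator mirrors the statistical assumptions of the fan experiments'
analyses: reaction times are shifted log-normal around the activation-derived
retrieval latency, accuracy is Bernoulli around the activation-derived
retrieval probability, and participants and items contribute random effects
(log scale for RT, logit scale for accuracy).  The analysis side implements
the experiments' cleaning rules (absolute RT bounds, +-3 sd trim,
participant-accuracy exclusion), sum-contrast coding of the fan conditions,
condition summaries, the dot-product median split, and a bootstrap
fan-effect estimator used for parameter recovery.

Trial tables are plain DataFrames with the column contract
``participant_id, sentence_id, kind, fan_condition, varied_category, round,
rt_ms, correct`` so that deposited experimental CSVs and synthetic tables
flow through the same functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .activation_link import LinkingParams, retrieval_prob, retrieval_time
from .fan_design import FanDesign

TRIAL_COLUMNS = ["participant_id", "sentence_id", "kind", "fan_condition",
                 "varied_category", "round", "rt_ms", "correct"]


@dataclass(frozen=True)
class ContrastCodes:
    """Sum contrasts nesting the fan manipulation in targets and foils."""

    fan_target: int    # -1 fan-2 target, +1 fan-4 target, 0 for foils
    fan_foil: int      # -1 fan-2 foil, +1 fan-4 foil, 0 for targets
    stimulus_type: int  # +1 target, -1 foil


@dataclass(frozen=True)
class CleaningConfig:
    rt_floor_ms: float = 200.0
    rt_ceiling_ms: float = 90_000.0
    sd_multiplier: float = 3.0
    accuracy_threshold: float = 0.6   # 0.65 for the semantic experiment

    def __post_init__(self) -> None:
        if self.rt_floor_ms >= self.rt_ceiling_ms:
            raise ValueError("rt_floor_ms must be below rt_ceiling_ms")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")


@dataclass(frozen=True)
class GeneratorParams:
    """Generative settings for synthetic testing-phase data.

    RT for a sentence with activation A is
    ``shift_ms + exp(log(F e^-A) + u_p + w_i + eps)`` with participant/item
    effects and residual eps on the log scale; correctness is Bernoulli with
    success logit ``(A - T)/s + u'_p + w'_i``.  Defaults put mean RTs in the
    1-2 s range observed in fan experiments with three testing rounds of
    the 48 sentences.
    """

    linking: LinkingParams = field(default_factory=LinkingParams)
    shift_ms: float = 500.0
    sigma_log: float = 0.25
    participant_sd: float = 0.15
    item_sd: float = 0.05
    n_participants: int = 100
    n_rounds: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:  # 0 allowed: degenerate noise-free generation
            raise ValueError("sigma_log must be non-negative")
        if min(self.participant_sd, self.item_sd) < 0:
            raise ValueError("random-effect sds must be non-negative")
        if self.shift_ms < 0:
            raise ValueError("shift_ms must be non-negative")


def generate_trials(design: FanDesign, activations: pd.DataFrame,
                    params: GeneratorParams) -> pd.DataFrame:
    """Simulate the testing phase of a fan experiment.

    Every participant responds to all 24 targets and 24 foils in each round.
    Each sentence's activation (its `shifted_dot` in `activations`) drives
    both latency and accuracy through the linking functions.
    """
    act = activations.set_index("sentence_id")["shifted_dot"]
    sids, kinds, fans = [], [], []
    for sid, s in design.sentences():
        if sid not in act.index:
            raise KeyError(f"no activation for sentence {sid!r}")
        sids.append(sid)
        kinds.append(s.kind)
        fans.append(s.fan_of(design.varied_category))
    A = act.loc[sids].to_numpy(dtype=float)
    n_items = len(sids)
    P, R = params.n_participants, params.n_rounds
    rng = np.random.default_rng(params.rng_seed)
    u_rt = rng.normal(0.0, params.participant_sd, size=P)
    u_acc = rng.normal(0.0, params.participant_sd, size=P)
    w_rt = rng.normal(0.0, params.item_sd, size=n_items)
    w_acc = rng.normal(0.0, params.item_sd, size=n_items)
    base_log_rt = np.log(retrieval_time(A, params.linking))
    base_logit = (A - params.linking.T) / params.linking.s
    eps = rng.normal(0.0, params.sigma_log, size=(P, R, n_items))
    log_rt = (base_log_rt[None, None, :] + u_rt[:, None, None]
              + w_rt[None, None, :] + eps)
    rt = params.shift_ms + np.exp(log_rt)
    logit = base_logit[None, None, :] + u_acc[:, None, None] + w_acc
    correct = rng.random((P, R, n_items)) < 1.0 / (1.0 + np.exp(-logit))
    pid = [f"pp{p + 1:03d}" for p in range(P)]
    return pd.DataFrame(dict(
        participant_id=np.repeat(pid, R * n_items),
        sentence_id=np.tile(sids, P * R),
        kind=np.tile(kinds, P * R),
        fan_condition=np.tile(fans, P * R),
        varied_category=design.varied_category,
        round=np.tile(np.repeat(np.arange(1, R + 1), n_items), P),
        rt_ms=rt.ravel(), correct=correct.ravel()))[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# cleaning and exclusion
# ---------------------------------------------------------------------------

def clean_rts(trials: pd.DataFrame,
              config: CleaningConfig = CleaningConfig(),
              per_participant: bool = False,
              ) -> tuple[pd.DataFrame, dict]:
    """Two-stage RT cleaning: absolute bounds, then a +-sd_multiplier trim
    around the mean of the survivors (computed once, globally, unless
    `per_participant`).  Returns the kept trials and a per-stage report."""
    if trials.empty:
        raise ValueError("no trials to clean")
    n0 = len(trials)
    rt = trials["rt_ms"]
    keep1 = (rt >= config.rt_floor_ms) & (rt <= config.rt_ceiling_ms)
    stage1 = trials[keep1]
    if stage1.empty:
        raise ValueError("all trials removed by the absolute RT bounds")

    def sd_mask(df: pd.DataFrame) -> pd.Series:
        mu, sd = df["rt_ms"].mean(), df["rt_ms"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(True, index=df.index)
        lo, hi = mu - config.sd_multiplier * sd, mu + config.sd_multiplier * sd
        return df["rt_ms"].between(lo, hi)

    if per_participant:
        keep2 = stage1.groupby("participant_id", group_keys=False).apply(
            sd_mask, include_groups=False)
        keep2 = keep2.reindex(stage1.index)
    else:
        keep2 = sd_mask(stage1)
    cleaned = stage1[keep2]
    if cleaned.empty:
        raise ValueError("all trials removed by the sd trim")
    n1, n2 = int((~keep1).sum()), int((~keep2).sum())
    report = dict(
        n_input=n0,
        stage1_removed=n1, stage1_pct=100.0 * n1 / n0,
        stage2_removed=n2, stage2_pct=100.0 * n2 / n0,
        n_output=len(cleaned))
    return cleaned.copy(), report


def exclude_participants(trials: pd.DataFrame, threshold: float = 0.6,
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants whose mean testing-phase accuracy is strictly below
    `threshold` (run before RT cleaning, on all their trials)."""
    acc = trials.groupby("participant_id")["correct"].mean()
    excluded = sorted(acc.index[acc < threshold])
    kept = trials[~trials["participant_id"].isin(excluded)].copy()
    return kept, excluded


# ---------------------------------------------------------------------------
# contrast coding
# ---------------------------------------------------------------------------

def code_contrasts(trial) -> ContrastCodes:
    """Contrast codes for one trial (any mapping with kind/fan_condition)."""
    kind, fan = trial["kind"], int(trial["fan_condition"])
    if kind not in ("target", "foil"):
        raise ValueError(f"unknown stimulus kind {kind!r}")
    if fan not in (2, 4):
        raise ValueError(f"fan must be 2 or 4, got {fan}")
    sign = -1 if fan == 2 else 1
    if kind == "target":
        return ContrastCodes(fan_target=sign, fan_foil=0, stimulus_type=1)
    return ContrastCodes(fan_target=0, fan_foil=sign, stimulus_type=-1)


def add_contrast_codes(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorized `code_contrasts` over a trial table."""
    out = trials.copy()
    sign = np.where(out["fan_condition"] == 2, -1, 1)
    is_target = out["kind"] == "target"
    out["fan_target"] = np.where(is_target, sign, 0)
    out["fan_foil"] = np.where(is_target, 0, sign)
    out["stimulus_type"] = np.where(is_target, 1, -1)
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _stats(df: pd.DataFrame) -> dict:
    n = len(df)
    if n == 0:
        return dict(mean_rt=np.nan, se_rt=np.nan, mean_accuracy=np.nan,
                    se_accuracy=np.nan, n=0)
    rt = df["rt_ms"]
    acc = df["correct"].astype(float)
    return dict(
        mean_rt=rt.mean(), se_rt=rt.std(ddof=1) / math.sqrt(n) if n > 1
        else np.nan,
        mean_accuracy=acc.mean(),
        se_accuracy=acc.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan,
        n=n)


def summarize_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Condition table mirroring the experiments' descriptive summaries.

    Rows: person/location/combined x fan 2/4.  The fan-2 cell pools every
    fan-2 trial and is by design identical across the three condition
    labels (fan 2 means both categories at fan 2); the fan-4 cells subset
    by which category was varied, "combined" pooling both.  SEs are over
    trials; pass an aggregated table for by-participant SEs.
    """
    rows = []
    fan2 = trials[trials["fan_condition"] == 2]
    fan4 = trials[trials["fan_condition"] == 4]
    for condition in ("person", "location", "combined"):
        rows.append(dict(condition=condition, fan=2, **_stats(fan2)))
        sub = (fan4 if condition == "combined"
               else fan4[fan4["varied_category"] == condition])
        rows.append(dict(condition=condition, fan=4, **_stats(sub)))
    return pd.DataFrame(rows)


def split_by_dot_product(trials: pd.DataFrame, activations: pd.DataFrame,
                         quantile: float = 0.5) -> dict:
    """Split target trials by their item's dot product and summarize RTs.

    Items at or above the dot-product quantile form the "above" group, the
    rest "below" (so 5 distinct dots at the median give a 2/3 item split).
    Returns per-group mean/SE RT plus the threshold and rule metadata.
    """
    targets = trials[trials["kind"] == "target"]
    dots = (activations[activations["kind"] == "target"]
            .set_index("sentence_id")["dot"])
    item_dots = dots.loc[targets["sentence_id"].unique()]
    threshold = float(item_dots.quantile(quantile))
    if item_dots.nunique() == 1:
        warnings.warn("all item dot products are identical; single group")
        return dict(threshold=threshold,
                    rule="below: dot < threshold; above: dot >= threshold",
                    groups={"all": _stats(targets)})
    trial_dots = targets["sentence_id"].map(dots)
    below = targets[trial_dots < threshold]
    above = targets[trial_dots >= threshold]
    return dict(
        threshold=threshold,
        rule="below: dot < threshold; above: dot >= threshold",
        n_items_below=int((item_dots < threshold).sum()),
        n_items_above=int((item_dots >= threshold).sum()),
        groups={"below": _stats(below), "above": _stats(above)})


# ---------------------------------------------------------------------------
# fan-effect recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FanEffect:
    estimate: float      # mean by-participant log-RT difference (fan4 - fan2)
    ci_low: float
    ci_high: float
    n_participants: int
    n_bootstrap: int


def recover_fan_effect(trials: pd.DataFrame, n_bootstrap: int = 2000,
                       rng_seed: int = 0, ci_level: float = 0.95,
                       resample_items: bool = True) -> FanEffect:
    """Estimate the target fan effect on log RT with a cluster bootstrap.

    The statistic is the across-participant mean of each participant's
    (mean log RT, fan-4 targets) - (mean log RT, fan-2 targets); positive
    values mean slower retrieval at higher fan.  The seeded percentile
    bootstrap resamples participants and, by default, also the fan-2 and
    fan-4 item sets: with by-item variability in the data (experimental or
    generated), a participant-only bootstrap treats the particular item
    draw as fixed and its intervals undercover.  Set
    ``resample_items=False`` for the participant-only interval.
    """
    targets = trials[trials["kind"] == "target"].copy()
    targets["log_rt"] = np.log(targets["rt_ms"])
    cell = (targets.groupby(["participant_id", "sentence_id"])
            .agg(log_rt=("log_rt", "mean"), fan=("fan_condition", "first"))
            .reset_index())
    M = cell.pivot(index="participant_id", columns="sentence_id",
                   values="log_rt")
    fan_of = cell.drop_duplicates("sentence_id").set_index(
        "sentence_id")["fan"]
    items2 = [c for c in M.columns if fan_of[c] == 2]
    items4 = [c for c in M.columns if fan_of[c] == 4]
    M = M.dropna(axis=0, how="any")
    n = len(M)
    if n < 2:
        raise ValueError(
            f"need at least 2 participants with both conditions, got {n}")
    A2 = M[items2].to_numpy()
    A4 = M[items4].to_numpy()
    estimate = float(A4.mean(axis=1).mean() - A2.mean(axis=1).mean())
    rng = np.random.default_rng(rng_seed)
    boot = np.empty(n_bootstrap)
    # n-out-of-n resampling of a small cluster margin understates its
    # variance by (n-1)/n; inflate the resampled deviations accordingly
    infl2 = np.sqrt(A2.shape[1] / (A2.shape[1] - 1)) if A2.shape[1] > 1 else 1
    infl4 = np.sqrt(A4.shape[1] / (A4.shape[1] - 1)) if A4.shape[1] > 1 else 1
    for b in range(n_bootstrap):
        rows = rng.integers(0, n, size=n)
        m2 = A2[rows].mean(axis=0)
        m4 = A4[rows].mean(axis=0)
        t2, t4 = m2.mean(), m4.mean()
        if resample_items:
            s2 = m2[rng.integers(0, len(m2), size=len(m2))].mean()
            s4 = m4[rng.integers(0, len(m4), size=len(m4))].mean()
            t2 = t2 + (s2 - t2) * infl2
            t4 = t4 + (s4 - t4) * infl4
        boot[b] = t4 - t2
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return FanEffect(estimate=estimate, ci_low=float(lo),
                     ci_high=float(hi), n_participants=n,
                     n_bootstrap=n_bootstrap)
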