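"""Synthetic behavior generation and the cleaning/coding/summary pipeline."""

import numpy as np
import pandas as pd
import pytest

from fanmem import (
    CleaningConfig,
    GeneratorParams,
    LinkingParams,
    add_contrast_codes,
    clean_rts,
    code_contrasts,
    exclude_participants,
    generate_trials,
    recover_fan_effect,
    split_by_dot_product,
    summarize_conditions,
)
from fanmem.behavior_pipeline import TRIAL_COLUMNS


def trial_row(participant="pp1", sid="t00", kind="target", fan=2,
              rt=1000.0, correct=True, rnd=1, varied="location"):
    return dict(participant_id=participant, sentence_id=sid, kind=kind,
                fan_condition=fan, varied_category=varied, round=rnd,
                rt_ms=rt, correct=correct)


def table(rows):
    return pd.DataFrame(rows)[TRIAL_COLUMNS]


class TestGenerateTrials:
    def test_trial_count(self, classic_design, classic_activations):
        params = GeneratorParams(n_participants=10, n_rounds=3, rng_seed=0)
        trials = generate_trials(classic_design, classic_activations, params)
        assert len(trials) == 10 * 3 * 48
        assert list(trials.columns) == TRIAL_COLUMNS
        assert (trials["rt_ms"] > 0).all()

    def test_degenerate_noise_gives_equal_rts(self, classic_design,
                                              classic_activations):
        act = classic_activations.assign(shifted_dot=1.0)
        params = GeneratorParams(sigma_log=0.0, participant_sd=0.0,
                                 item_sd=0.0, n_participants=3, rng_seed=0)
        trials = generate_trials(classic_design, act, params)
        assert trials["rt_ms"].nunique() == 1

    def test_monotone_in_activation_without_noise(self, classic_design,
                                                  classic_activations):
        act = classic_activations.assign(
            shifted_dot=np.where(
                classic_activations["fan_condition"] == 2, 2.0, 1.0))
        params = GeneratorParams(sigma_log=0.0, participant_sd=0.0,
                                 item_sd=0.0, n_participants=2, rng_seed=0)
        trials = generate_trials(classic_design, act, params)
        targets = trials[trials["kind"] == "target"]
        by_fan = targets.groupby("fan_condition")["rt_ms"]
        assert by_fan.max()[2] < by_fan.min()[4]

    def test_seed_determinism(self, classic_design, classic_activations):
        params = GeneratorParams(n_participants=2, rng_seed=9)
        t1 = generate_trials(classic_design, classic_activations, params)
        t2 = generate_trials(classic_design, classic_activations, params)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_activation_names_sentence(self, classic_design,
                                               classic_activations):
        act = classic_activations[
            classic_activations["sentence_id"] != "t05"]
        with pytest.raises(KeyError, match="t05"):
            generate_trials(classic_design, act,
                            GeneratorParams(n_participants=1, rng_seed=0))


class TestCleanRts:
    def test_absolute_bounds_remove_planted_extremes(self):
        rows = [trial_row(rt=rt) for rt in (100.0, 100_000.0, 900, 1100,
                                            1000, 950, 1050, 980)]
        cleaned, report = clean_rts(table(rows))
        assert report["stage1_removed"] == 2
        assert 100.0 not in cleaned["rt_ms"].values
        assert 100_000.0 not in cleaned["rt_ms"].values

    def test_identical_rts_trim_nothing(self):
        rows = [trial_row(rt=1000.0) for _ in range(10)]
        cleaned, report = clean_rts(table(rows))
        assert report["stage2_removed"] == 0
        assert len(cleaned) == 10

    def test_sd_trim_removes_exactly_planted_outlier(self):
        rng = np.random.default_rng(0)
        base = 1000 + 50 * rng.standard_normal(200)
        rows = [trial_row(rt=r) for r in base]
        mu, sd = np.mean(base), np.std(base, ddof=1)
        outlier = mu + 3.5 * sd
        rows.append(trial_row(rt=outlier))
        df = table(rows)
        # adding one point barely moves mean/sd: only the outlier exceeds 3 sd
        cleaned, report = clean_rts(df)
        assert report["stage2_removed"] == 1
        assert outlier not in cleaned["rt_ms"].values

    def test_report_counts_sum(self):
        rows = [trial_row(rt=rt) for rt in (50.0, 1000, 1010, 990, 995)]
        cleaned, report = clean_rts(table(rows))
        assert (report["n_input"] - report["stage1_removed"]
                - report["stage2_removed"]) == report["n_output"]
        assert report["stage1_pct"] == pytest.approx(100 / 5)

    def test_all_removed_raises(self):
        rows = [trial_row(rt=10.0), trial_row(rt=5.0)]
        with pytest.raises(ValueError):
            clean_rts(table(rows))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CleaningConfig(rt_floor_ms=500, rt_ceiling_ms=400)


class TestExcludeParticipants:
    def cohort(self):
        rows = []
        for pid, acc in (("pp1", 0.55), ("pp2", 0.6), ("pp3", 0.9)):
            for i in range(20):
                rows.append(trial_row(participant=pid, sid=f"t{i:02d}",
                                      correct=i < acc * 20))
        return table(rows)

    def test_below_threshold_excluded(self):
        kept, excluded = exclude_participants(self.cohort(), 0.6)
        assert excluded == ["pp1"]
        assert set(kept["participant_id"]) == {"pp2", "pp3"}

    def test_exact_threshold_retained(self):
        kept, excluded = exclude_participants(self.cohort(), 0.6)
        assert "pp2" not in excluded  # strict < comparison


class TestContrastCodes:
    @pytest.mark.parametrize("kind, fan, expected", [
        ("foil", 4, (0, 1, -1)),
        ("foil", 2, (0, -1, -1)),
        ("target", 2, (-1, 0, 1)),
        ("target", 4, (1, 0, 1)),
    ])
    def test_coding_rules(self, kind, fan, expected):
        codes = code_contrasts(trial_row(kind=kind, fan=fan))
        assert (codes.fan_target, codes.fan_foil,
                codes.stimulus_type) == expected

    def test_codes_ignore_rt_and_correct(self):
        a = code_contrasts(trial_row(kind="target", fan=4, rt=1.0,
                                     correct=False))
        b = code_contrasts(trial_row(kind="target", fan=4, rt=9e4,
                                     correct=True))
        assert a == b

    def test_vectorized_matches_rowwise(self):
        rows = [trial_row(kind=k, fan=f)
                for k in ("target", "foil") for f in (2, 4)]
        df = add_contrast_codes(table(rows))
        for _, row in df.iterrows():
            codes = code_contrasts(row)
            assert row["fan_target"] == codes.fan_target
            assert row["fan_foil"] == codes.fan_foil
            assert row["stimulus_type"] == codes.stimulus_type

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            code_contrasts(trial_row(kind="probe"))


class TestSummaries:
    def six_trials(self):
        return table([
            trial_row(sid="a", fan=2, rt=1000, correct=True),
            trial_row(sid="b", fan=2, rt=1200, correct=False),
            trial_row(sid="c", fan=4, rt=1500, correct=True,
                      varied="location"),
            trial_row(sid="d", fan=4, rt=1700, correct=True,
                      varied="location"),
            trial_row(sid="e", fan=4, rt=2000, correct=False,
                      varied="person"),
            trial_row(sid="f", fan=4, rt=1800, correct=True,
                      varied="person"),
        ])

    def test_hand_computed_means_and_ses(self):
        summary = summarize_conditions(self.six_trials()).set_index(
            ["condition", "fan"])
        fan2 = summary.loc[("combined", 2)]
        assert fan2["mean_rt"] == pytest.approx(1100)
        assert fan2["se_rt"] == pytest.approx(
            np.std([1000, 1200], ddof=1) / np.sqrt(2))
        assert fan2["mean_accuracy"] == pytest.approx(0.5)
        loc4 = summary.loc[("location", 4)]
        assert loc4["mean_rt"] == pytest.approx(1600)
        assert loc4["n"] == 2

    def test_combined_fan4_pools_both_categories(self):
        summary = summarize_conditions(self.six_trials()).set_index(
            ["condition", "fan"])
        assert summary.loc[("combined", 4)]["n"] == 4
        assert summary.loc[("combined", 4)]["mean_rt"] == pytest.approx(
            np.mean([1500, 1700, 2000, 1800]))

    def test_fan2_rows_identical_across_conditions(self):
        summary = summarize_conditions(self.six_trials())
        fan2 = summary[summary["fan"] == 2]
        assert fan2["mean_rt"].nunique() == 1
        assert fan2["n"].nunique() == 1

    def test_empty_condition_has_null_stats(self):
        trials = self.six_trials()
        summary = summarize_conditions(
            trials[trials["varied_category"] == "location"])
        row = summary.set_index(["condition", "fan"]).loc[("person", 4)]
        assert row["n"] == 0
        assert np.isnan(row["mean_rt"])


class TestDotProductSplit:
    def activations(self, dots):
        return pd.DataFrame(dict(
            sentence_id=[f"t{i:02d}" for i in range(len(dots))],
            dot=dots, kind="target"))

    def test_median_split_rule_two_three(self):
        act = self.activations([1.0, 2.0, 3.0, 4.0, 5.0])
        rows = [trial_row(sid=f"t{i:02d}", rt=1000 + i) for i in range(5)]
        out = split_by_dot_product(table(rows), act)
        assert out["n_items_below"] == 2
        assert out["n_items_above"] == 3

    def test_all_equal_dots_warns_single_group(self):
        act = self.activations([2.0, 2.0, 2.0])
        rows = [trial_row(sid=f"t{i:02d}") for i in range(3)]
        with pytest.warns(UserWarning, match="identical"):
            out = split_by_dot_product(table(rows), act)
        assert "all" in out["groups"]

    def test_generated_rts_decrease_with_dot(self, classic_design,
                                             classic_activations):
        params = GeneratorParams(n_participants=30, rng_seed=4)
        trials = generate_trials(classic_design, classic_activations, params)
        out = split_by_dot_product(trials, classic_activations)
        assert (out["groups"]["below"]["mean_rt"]
                > out["groups"]["above"]["mean_rt"])


class TestRecoverFanEffect:
    def test_sign_flips_when_activations_swapped(self, classic_design,
                                                 classic_activations):
        params = GeneratorParams(n_participants=30, rng_seed=5)
        trials = generate_trials(classic_design, classic_activations, params)
        eff = recover_fan_effect(trials, n_bootstrap=200, rng_seed=0)
        swapped = classic_activations.copy()
        m = swapped["kind"] == "target"
        f2 = m & (swapped["fan_condition"] == 2)
        f4 = m & (swapped["fan_condition"] == 4)
        mean2 = swapped.loc[f2, "shifted_dot"].mean()
        mean4 = swapped.loc[f4, "shifted_dot"].mean()
        swapped.loc[f2, "shifted_dot"] += mean4 - mean2
        swapped.loc[f4, "shifted_dot"] += mean2 - mean4
        trials_swapped = generate_trials(classic_design, swapped, params)
        eff_swapped = recover_fan_effect(trials_swapped, n_bootstrap=200,
                                         rng_seed=0)
        assert eff.estimate > 0 > eff_swapped.estimate

    def test_positive_contrast_detected(self, classic_design,
                                        classic_activations):
        params = GeneratorParams(n_participants=50, rng_seed=6)
        trials = generate_trials(classic_design, classic_activations, params)
        eff = recover_fan_effect(trials, n_bootstrap=500, rng_seed=1)
        assert eff.ci_low > 0

    def test_too_few_participants(self):
        rows = [trial_row(participant="pp1", sid="a", fan=2),
                trial_row(participant="pp1", sid="b", fan=4)]
        with pytest.raises(ValueError, match="participants"):
            recover_fan_effect(table(rows))


def test_osf_like_schema_flows_through_pipeline():
    """A CSV with the deposited-data column contract runs the whole
    analysis path unchanged."""
    rng = np.random.default_rng(0)
    rows = []
    for p in range(4):
        for i in range(12):
            rows.append(trial_row(
                participant=f"s{p}", sid=f"t{i:02d}",
                kind="target" if i % 2 == 0 else "foil",
                fan=2 if i < 6 else 4,
                rt=float(rng.uniform(600, 2500)),
                correct=bool(rng.random() < 0.9), rnd=1 + i % 3))
    df = table(rows)
    df, _ = exclude_participants(df, 0.6)
    df, report = clean_rts(df)
    df = add_contrast_codes(df)
    summary = summarize_conditions(df)
    assert report["n_output"] == len(df)
    assert len(summary) == 6
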