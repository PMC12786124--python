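"""Wilcoxon signed-rank, Bonferroni, confidence intervals, importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegfuse.fusion import FusionTrace
from eegfuse.stats import (bonferroni, demographic_importance,
                           difference_ci, evidence_tier, group_comparison,
                           paired_wilcoxon, summarize_fusion_weights)


def brute_force_wilcoxon(diffs):
    """Full sign-assignment enumeration with average ranks — the oracle."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [np.sum([r for r, s in zip(ranks, signs) if s > 0])
             for signs in itertools.product([-1, 1], repeat=n)]
    w_all = np.array(w_all)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    p_le = np.mean(w_all <= w_obs + 1e-9)
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_zero_degenerate(self):
        res = paired_wilcoxon([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_three_positive_differences(self):
        # W+ = 6 is one of 8 equally likely sign patterns; doubled tail
        assert paired_wilcoxon([1.0, 2.0, 3.0]).p_value == pytest.approx(0.25)

    def test_tied_opposite_pair(self):
        assert paired_wilcoxon([1.0, -1.0]).p_value == pytest.approx(1.0)

    def test_matches_enumeration_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            d = rng.integers(-4, 5, size=n).astype(float)  # ties and zeros
            if (d == 0).all():
                continue
            assert paired_wilcoxon(d).p_value == pytest.approx(
                brute_force_wilcoxon(d), abs=1e-12)

    def test_large_n_approximation_close_to_scipy(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(40) + 0.3
        ours = paired_wilcoxon(d).p_value
        ref = sps.wilcoxon(d, correction=False, mode="approx").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([])


class TestBonferroni:
    def test_identity_family(self):
        np.testing.assert_allclose(bonferroni([0.2, 0.04], m=1), [0.2, 0.04])

    def test_multiplication(self):
        assert bonferroni([0.03], m=4)[0] == pytest.approx(0.12)

    def test_cap_at_one(self):
        assert bonferroni([0.5], m=3)[0] == 1.0


class TestDifferenceCI:
    def test_constant_vector_degenerate_interval(self):
        lo, hi = difference_ci([0.4, 0.4, 0.4])
        assert lo == hi == pytest.approx(0.4)

    def test_hand_computed_three_values(self):
        # mean 2, SD 1, t_{2,0.975} = 4.3027 -> 2 -+ 2.4841
        lo, hi = difference_ci([1.0, 2.0, 3.0])
        assert lo == pytest.approx(-0.484, abs=1e-3)
        assert hi == pytest.approx(4.484, abs=1e-3)

    def test_interval_nesting_in_level(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal(15)
        lo90, hi90 = difference_ci(d, level=0.90)
        lo95, hi95 = difference_ci(d, level=0.95)
        assert lo95 < lo90 < hi90 < hi95

    def test_bootstrap_close_to_t(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(60) * 0.1 + 0.05
        lo_t, hi_t = difference_ci(d)
        lo_b, hi_b = difference_ci(d, method="bootstrap", seed=0)
        assert lo_b == pytest.approx(lo_t, abs=0.01)
        assert hi_b == pytest.approx(hi_t, abs=0.01)


def diffs_frame():
    rng = np.random.default_rng(4)
    rows = []
    for i in range(12):
        nat = ["Chinese", "French", "German"][i % 3]
        rows.append({
            "subject_id": f"S{i}", "nationality": nat,
            "sex": "M" if i % 2 else "F", "age": 20 + i % 8,
            "negative": rng.normal(0.05, 0.05),
            "neutral": rng.normal(0.0, 0.05),
            "positive": rng.normal(0.05, 0.05),
            "overall": rng.normal(0.03, 0.04),
        })
    return pd.DataFrame(rows)


class TestGroupComparison:
    def test_family_size_nationality(self):
        report = group_comparison(diffs_frame(), "nationality")
        assert len(report) == 12                       # 3 groups x 4 outcomes
        assert (report["m"] == 12).all()

    def test_single_subject_group_flagged(self):
        df = diffs_frame()
        df.loc[df["sex"] == "F", "sex"] = "M"
        df.loc[0, "sex"] = "F"
        report = group_comparison(df, "sex")
        f_rows = report[report["group"] == "F"]
        assert (f_rows["flag"] == "insufficient-n").all()
        assert f_rows["p_raw"].isna().all()
        assert (report["m"] == 4).all()                # only the M cells tested

    def test_age_dichotomy_at_23(self):
        report = group_comparison(diffs_frame(), "age")
        assert set(report["group"]) == {"age<=23", "age>23"}

    def test_injected_effect_is_family_minimum(self):
        df = diffs_frame()
        # symmetric alternating noise: signed-rank sees no signal
        for col in ("negative", "neutral", "positive", "overall"):
            df[col] = 0.001 * np.where(np.arange(len(df)) % 2 == 0, 1, -1)
        mask = df["nationality"] == "French"
        df.loc[mask, "overall"] = [0.30, 0.31, 0.32, 0.33]
        report = group_comparison(df, "nationality")
        tested = report[report["tested"]]
        best = tested.loc[tested["p_raw"].idxmin()]
        assert best["group"] == "French" and best["outcome"] == "overall"
        # its adjusted p is (possibly jointly) the family minimum
        assert best["p_adjusted"] == tested["p_adjusted"].min()

    def test_evidence_tiers(self):
        assert evidence_tier(0.005) == "strong"
        assert evidence_tier(0.03) == "moderate"
        assert evidence_tier(0.07) == "weak"
        assert evidence_tier(0.5) == "none"


def make_trace(omega2, L, labels, subjects=None):
    omega2 = np.asarray(omega2, dtype=float)
    n, d16 = omega2.shape
    return FusionTrace(
        omega1=1.0 - omega2, omega2=omega2, L=np.asarray(L, dtype=float),
        subject_ids=np.asarray(subjects if subjects is not None else ["s"] * n),
        true_labels=np.asarray(labels), predicted_labels=np.asarray(labels),
        demo_columns=tuple(f"v{i}" for i in range(np.asarray(L).shape[0])))


class TestFusionWeightSummary:
    def test_single_sample_means_equal_sample(self):
        t = make_trace(np.full((1, 16), 0.3), np.ones((4, 16)), [0])
        table = summarize_fusion_weights([t])
        np.testing.assert_allclose(table["mean_omega2"], 0.3)
        np.testing.assert_allclose(table["mean_omega1"], 0.7)

    def test_means_sum_to_one(self):
        rng = np.random.default_rng(5)
        traces = [make_trace(rng.random((7, 16)), np.ones((4, 16)),
                             rng.integers(0, 3, 7)) for _ in range(3)]
        table = summarize_fusion_weights(traces)
        np.testing.assert_allclose(
            table["mean_omega1"] + table["mean_omega2"], 1.0, atol=1e-12)

    def test_hand_computed_two_traces(self):
        t1 = make_trace(np.array([[0.2] * 16]), np.ones((4, 16)), [0])
        t2 = make_trace(np.array([[0.6] * 16]), np.ones((4, 16)), [0])
        table = summarize_fusion_weights([t1, t2])
        np.testing.assert_allclose(table["mean_omega2"], 0.4)


def importance_oracle(omega2_bar, L):
    """Explicit double loop over variables i and fused dimensions j."""
    d, k = L.shape
    v = np.zeros(d)
    for i in range(d):
        acc = 0.0
        for j in range(k):
            acc += abs(omega2_bar[j] * L[i, j])
        v[i] = acc / k
    return v / v.sum()


class TestDemographicImportance:
    def test_toy_two_by_two(self):
        # L = I2, omega2 = (0.5, 0.25): row means (0.25, 0.125) -> (2/3, 1/3)
        t = make_trace(np.array([[0.5, 0.25]]), np.eye(2), [0])
        summary = demographic_importance([t])
        np.testing.assert_allclose(summary.per_emotion.loc["negative"],
                                   [2 / 3, 1 / 3])

    def test_zero_row_gets_zero_importance(self):
        L = np.ones((4, 16))
        L[2] = 0.0
        t = make_trace(np.full((3, 16), 0.5), L, [0, 1, 2])
        summary = demographic_importance([t])
        np.testing.assert_allclose(summary.per_emotion["v2"], 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        L = rng.standard_normal((4, 16))
        om = rng.random((6, 16))
        labels = [0, 0, 1, 1, 2, 2]
        a = demographic_importance([make_trace(om, L, labels)])
        b = demographic_importance([make_trace(om, 7.3 * L, labels)])
        np.testing.assert_allclose(a.per_emotion.to_numpy(),
                                   b.per_emotion.to_numpy(), atol=1e-12)

    def test_matches_loop_oracle_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = rng.standard_normal((4, 16))
            om = rng.random((5, 16))
            t = make_trace(om, L, [1] * 5)
            summary = demographic_importance([t])
            expect = importance_oracle(om.mean(axis=0), L)
            np.testing.assert_allclose(
                summary.per_emotion.loc["neutral"].to_numpy(), expect,
                atol=1e-12)

    def test_normalized_and_nonnegative(self):
        rng = np.random.default_rng(8)
        t = make_trace(rng.random((9, 16)), rng.standard_normal((4, 16)),
                       rng.integers(0, 3, 9),
                       subjects=["a"] * 5 + ["b"] * 4)
        summary = demographic_importance([t])
        vals = summary.per_subject[[c for c in summary.per_subject.columns
                                    if c.startswith("v")]].to_numpy()
        assert (vals >= 0).all()
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-12)

    def test_condition_on_predicted(self):
        t = make_trace(np.array([[0.5, 0.5], [0.2, 0.2]]), np.eye(2), [0, 0])
        t.predicted_labels = np.array([0, 1])
        by_true = demographic_importance([t], condition_on="true")
        by_pred = demographic_importance([t], condition_on="predicted")
        assert by_true.per_subject.shape[0] == 1
        assert by_pred.per_subject.shape[0] == 2
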