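"""ROI extraction, normalization, and perfusion statistics."""

import numpy as np
import pandas as pd
import pytest

from ssopkit import (
    extract_roi_means,
    normalize_to_reference,
    pearson_correlation,
    roc_threshold,
    simulate_ischemia_timecourse,
)
from ssopkit.chromophores import StO2Map


def make_map(values, qc=None):
    values = np.asarray(values, dtype=float)
    qc = np.zeros(values.shape, np.uint8) if qc is None else qc
    c = values / 100.0
    return StO2Map(c_hbo2=c, c_hb=1 - c, sto2=values, qc=qc)


class TestExtractRoiMeans:
    def test_constant_map(self):
        m = make_map(np.full((6, 6), 70.0))
        masks = {"A": np.zeros((6, 6), bool), "R": np.zeros((6, 6), bool)}
        masks["A"][:3] = True
        masks["R"][3:] = True
        df = extract_roi_means(m, masks)
        assert set(df["roi"]) == {"A", "R"}
        assert (df["sto2_mean"] == 70.0).all()
        assert (df["sto2_sem"] == 0.0).all()

    def test_flagged_pixels_excluded(self):
        vals = np.full((4, 4), 60.0)
        vals[0, 0] = 999.0
        qc = np.zeros((4, 4), np.uint8)
        qc[0, 0] = 2
        df = extract_roi_means(make_map(vals, qc), {"A": np.ones((4, 4), bool)})
        assert df["sto2_mean"].iloc[0] == 60.0
        assert df["n_pixels"].iloc[0] == 15

    def test_fully_flagged_roi_errors_with_name(self):
        qc = np.full((3, 3), 2, np.uint8)
        with pytest.raises(ValueError, match="'bad'"):
            extract_roi_means(make_map(np.ones((3, 3)), qc),
                              {"bad": np.ones((3, 3), bool)})

    def test_mask_shape_checked(self):
        with pytest.raises(ValueError):
            extract_roi_means(make_map(np.ones((3, 3))),
                              {"A": np.ones((4, 4), bool)})


def example_series():
    rows = []
    for subject, scale in [("s1", 1.0), ("s2", 2.0)]:
        for roi, v0 in [("A", 70.0), ("C", 73.0)]:
            for tp, drift in [("T0", 0.0), ("T15", -5.0)]:
                rows.append(dict(subject=subject, roi=roi, timepoint=tp,
                                 sto2_mean=scale * (v0 + drift),
                                 sto2_sem=scale * 1.0))
    return pd.DataFrame(rows)


class TestNormalization:
    def test_reference_row_maps_to_one(self):
        norm = normalize_to_reference(example_series())
        ref = norm[(norm.roi == "A") & (norm.timepoint == "T0")]
        assert (ref["sto2_mean"] == 1.0).all()

    def test_hand_computed_ratios(self):
        norm = normalize_to_reference(example_series())
        row = norm[(norm.subject == "s1") & (norm.roi == "C") & (norm.timepoint == "T15")]
        assert row["sto2_mean"].iloc[0] == pytest.approx(68.0 / 70.0)

    def test_scale_invariance_per_subject(self):
        norm = normalize_to_reference(example_series())
        s1 = norm[norm.subject == "s1"].drop(columns="subject").reset_index(drop=True)
        s2 = norm[norm.subject == "s2"].drop(columns="subject").reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)

    def test_idempotent(self):
        once = normalize_to_reference(example_series())
        twice = normalize_to_reference(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_or_nonpositive_reference(self):
        df = example_series()
        with pytest.raises(ValueError, match="reference"):
            normalize_to_reference(df[df.roi != "A"])
        bad = df.copy()
        bad.loc[(bad.roi == "A") & (bad.timepoint == "T0"), "sto2_mean"] = 0.0
        with pytest.raises(ValueError, match="<= 0"):
            normalize_to_reference(bad)

    def test_lactate_standardized_when_requested(self):
        df = simulate_ischemia_timecourse(seed=2)
        norm = normalize_to_reference(df, include_lactate=True)
        ref = norm[(norm.roi == "A") & (norm.timepoint == "T0")]
        np.testing.assert_allclose(ref["sto2"], 1.0)
        np.testing.assert_allclose(ref["lactate"], 1.0)


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_five_pair_hand_computed_value(self):
        # x=[1..5], y=[2,1,4,3,6]: Sxy=10, Sxx=10, Syy=14.8 -> r=10/sqrt(148)
        res = pearson_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert res.r == pytest.approx(10.0 / np.sqrt(148.0), rel=1e-12)

    def test_fisher_ci_brackets_r_and_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = -x + rng.normal(scale=0.5, size=200)
        small = pearson_correlation(x[:20], y[:20])
        large = pearson_correlation(x, y)
        for res in (small, large):
            assert res.ci_low < res.r < res.ci_high
        assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_simulated_ischemia_matches_reported_sign_and_class(self):
        """Pooled StO2-lactate pairs from the default simulation give a
        strong negative correlation with CI excluding zero."""
        df = simulate_ischemia_timecourse(seed=1)
        res = pearson_correlation(df["sto2"], df["lactate"])
        assert res.r < -0.7
        assert res.ci_high < 0


def brute_force_auc(neg, pos):
    """Exhaustive Mann-Whitney pair counting with half-weight ties."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocThreshold:
    def test_fully_separated_groups(self):
        res = roc_threshold([1, 2, 3], [10, 11, 12])
        assert res.auc == 1.0
        assert 3 < res.threshold <= 10

    def test_identical_groups_auc_half(self):
        res = roc_threshold([5, 5, 5], [5, 5, 5])
        assert res.auc == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 21, size=2)
        g1 = rng.integers(0, 8, size=n1).astype(float)  # many ties
        g2 = rng.integers(2, 10, size=n2).astype(float)
        res = roc_threshold(g1, g2)
        assert res.auc == pytest.approx(brute_force_auc(g1, g2), abs=1e-12)

    def test_ci_within_unit_interval_and_brackets_auc(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(1, 1, 30)
        res = roc_threshold(g1, g2)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
        assert res.ci_high - res.ci_low > 0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold([1.0], [2.0, 3.0])

    def test_youden_threshold_separates_simulated_rois(self):
        df = simulate_ischemia_timecourse(seed=1)
        perfused = df.loc[df.roi != "R", "sto2"].to_numpy()
        resected = df.loc[df.roi == "R", "sto2"].to_numpy()
        res = roc_threshold(resected, perfused)
        assert res.auc > 0.9
        assert resected.min() < res.threshold < perfused.max()
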