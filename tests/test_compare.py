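"""Pointwise/plaque/cohort difference statistics and paired tests."""

import numpy as np
import pytest

from capquant import (
    NoCapPointsError,
    PairedSliceMeasurement,
    PlaqueSet,
    RadialProfile,
    cohort_mean_diff,
    load_fixture,
    min_cap_thickness,
    paired_tests,
    plaque_mean_diff,
    pointwise_diff,
    relative_error,
    slice_mean_diff,
    table1_stats,
)


def make_profile(cap_values, modality="OCT", slice_id="s", start=0):
    """A 100-point profile with the given cap values placed from ``start``."""
    n = 100
    cap = np.full(n, np.nan)
    for k, v in enumerate(cap_values):
        cap[start + k] = v
    is_cap = np.isfinite(cap)
    pts = np.column_stack([np.cos(2 * np.pi * np.arange(n) / n),
                           np.sin(2 * np.pi * np.arange(n) / n)])
    return RadialProfile(
        slice_id=slice_id,
        modality=modality,
        lumen_pts=pts,
        wall_pts=2 * pts,
        quarter=np.repeat([1, 2, 3, 4], 25).astype(np.int8),
        wall_thickness=np.full(n, 1.0),
        cap_thickness=cap,
        is_cap_point=is_cap,
    )


def make_pair(oct_caps, ivus_caps, slice_id="s", ivus_start=0):
    return PairedSliceMeasurement(
        slice_id=slice_id,
        oct=make_profile(oct_caps, "OCT", slice_id),
        ivus=make_profile(ivus_caps, "IVUS", slice_id, start=ivus_start),
    )


class TestPointwise:
    def test_absolute_difference(self):
        pair = make_pair([0.30], [0.25])
        assert pointwise_diff(pair) == pytest.approx([0.05])
        assert slice_mean_diff(pair) == pytest.approx(0.05)

    def test_identical_profiles_give_zero(self):
        pair = make_pair([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert pointwise_diff(pair) == pytest.approx([0, 0, 0])

    def test_only_matched_indices_enter(self):
        # IVUS caps shifted by 2 indices: only 3 of 5 overlap
        pair = make_pair([0.2] * 5, [0.5] * 5, ivus_start=2)
        assert pair.n_matched == 3
        assert pointwise_diff(pair) == pytest.approx([0.3] * 3)

    def test_random_profiles_match_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 0.5, 40), rng.uniform(0.1, 0.5, 40)
        pair = make_pair(a, b)
        assert pointwise_diff(pair) == pytest.approx(np.abs(a - b))
        assert slice_mean_diff(pair) == pytest.approx(np.abs(a - b).mean())

    def test_no_matched_points_raises(self):
        pair = make_pair([0.2] * 5, [0.5] * 5, ivus_start=50)
        with pytest.raises(NoCapPointsError):
            slice_mean_diff(pair)


class TestPooling:
    def test_plaque_mean_is_pooled_not_averaged(self):
        plaque = PlaqueSet(
            "P1", "T1",
            [
                make_pair([0.1, 0.2], [0.2, 0.4], "s1"),  # diffs 0.1, 0.2
                make_pair([0.1], [0.5], "s2"),            # diff 0.4
            ],
        )
        assert plaque_mean_diff(plaque) == pytest.approx(0.7 / 3)
        slice_means = [slice_mean_diff(s) for s in plaque.slices]
        assert np.mean(slice_means) == pytest.approx(0.275)
        assert plaque_mean_diff(plaque) != pytest.approx(np.mean(slice_means))

    def test_single_slice_plaque_equals_slice_mean(self):
        pair = make_pair([0.1, 0.4, 0.2], [0.15, 0.1, 0.25])
        plaque = PlaqueSet("P1", "T1", [pair])
        assert plaque_mean_diff(plaque) == pytest.approx(slice_mean_diff(pair))

    def test_pooled_equals_count_weighted_mean_of_slice_means(self):
        rng = np.random.default_rng(7)
        slices = [
            make_pair(rng.uniform(0.1, 0.5, n), rng.uniform(0.1, 0.5, n), f"s{n}")
            for n in (3, 11, 25)
        ]
        plaque = PlaqueSet("P1", "T1", slices)
        weights = np.array(plaque.n_j, dtype=float)
        means = np.array([slice_mean_diff(s) for s in slices])
        assert plaque_mean_diff(plaque) == pytest.approx(
            float((weights * means).sum() / weights.sum())
        )

    def test_cohort_pooling_matches_flat_oracle(self):
        rng = np.random.default_rng(9)
        plaques, all_diffs = [], []
        for p in range(3):
            slices = []
            for s in range(rng.integers(1, 4)):
                n = int(rng.integers(2, 12))
                a, b = rng.uniform(0.1, 0.5, n), rng.uniform(0.1, 0.5, n)
                slices.append(make_pair(a, b, f"p{p}s{s}"))
                all_diffs.extend(np.abs(a - b))
            plaques.append(PlaqueSet(f"P{p}", "T1", slices))
        assert cohort_mean_diff(plaques) == pytest.approx(np.mean(all_diffs))
        single = PlaqueSet("only", "T1", plaques[0].slices)
        assert cohort_mean_diff([single]) == pytest.approx(plaque_mean_diff(single))

    def test_equal_count_plaques_average(self):
        p1 = PlaqueSet("P1", "T1", [make_pair([0.2, 0.2], [0.1, 0.1])])  # mean 0.1
        p2 = PlaqueSet("P2", "T1", [make_pair([0.4, 0.4], [0.1, 0.1])])  # mean 0.3
        assert cohort_mean_diff([p1, p2]) == pytest.approx(0.2)


class TestRelativeErrorAndMin:
    def test_published_mean_level_example(self):
        # cohort averages 0.382 vs 0.375 differ by 1.83%
        assert 100 * relative_error(0.382 - 0.375, 0.382) == pytest.approx(1.83, abs=0.005)

    def test_published_min_level_example(self):
        # first plaque: min caps 0.128 (OCT) vs 0.193 (IVUS)
        assert 100 * relative_error(0.128 - 0.193, 0.128) == pytest.approx(50.78, abs=0.005)

    def test_equal_means_give_zero(self):
        assert relative_error(0.0, 0.3) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            relative_error(0.1, 0.0)

    def test_unit_scale_invariance(self):
        # relative errors are dimensionless: mm and um inputs agree
        assert relative_error(0.05, 0.4) == pytest.approx(relative_error(50.0, 400.0))

    def test_min_cap_associativity(self):
        profs = [make_profile([0.21, 0.14, 0.33], slice_id="a"),
                 make_profile([0.18, 0.40], slice_id="b")]
        assert min_cap_thickness([profs[0]]) == pytest.approx(0.14)
        per_slice = [min_cap_thickness([p]) for p in profs]
        assert min_cap_thickness(profs) == pytest.approx(min(per_slice))

    def test_no_cap_points_raises(self):
        with pytest.raises(NoCapPointsError):
            min_cap_thickness([make_profile([])])


class TestPrintedTableReproduction:
    def test_per_plaque_min_errors_match_printed_column(self):
        df = load_fixture("table1")
        recomputed = 100 * (df["min_capt_oct_mm"] - df["min_capt_ivus_mm"]).abs() / df[
            "min_capt_oct_mm"
        ]
        assert np.allclose(recomputed, df["min_rel_err_pct"], atol=0.01)

    def test_cohort_statistics(self):
        stats = table1_stats(load_fixture("table1"))
        assert stats["cohort_mean_capt_oct_mm"] == pytest.approx(0.382, abs=5e-4)
        assert stats["cohort_min_capt_ivus_mm"] == pytest.approx(0.141, abs=5e-4)
        assert stats["avg_mean_rel_err_pct"] == pytest.approx(1.83, abs=0.005)
        assert stats["avg_min_rel_err_pct"] == pytest.approx(27.32, abs=0.005)
        assert stats["mean_plaque_min_rel_err_pct"] == pytest.approx(44.46, abs=0.005)
        assert stats["cohort_mean_capt_oct_sd_mm"] == pytest.approx(0.100, abs=5e-4)
        assert stats["sd_plaque_min_rel_err_pct"] == pytest.approx(24.50, abs=5e-3)

    def test_identical_modalities_give_zero_errors(self):
        df = load_fixture("table1").copy()
        df["mean_capt_ivus_mm"] = df["mean_capt_oct_mm"]
        df["min_capt_ivus_mm"] = df["min_capt_oct_mm"]
        stats = table1_stats(df.drop(columns=["mean_rel_err_pct", "min_rel_err_pct"]))
        assert stats["avg_mean_rel_err_pct"] == 0.0
        assert stats["mean_plaque_min_rel_err_pct"] == 0.0


class TestPairedTests:
    def test_identical_samples_flagged_degenerate(self):
        res = paired_tests([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert res["degenerate"] and res["paired_p"] == 1.0
        assert not res["significant"]

    def test_shifted_pairs_significant_and_match_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 50)
        b = a + 1.0 + rng.normal(0.0, 0.3, 50)
        res = paired_tests(a, b)
        assert res["paired_p"] < 0.05 and res["significant"]
        # sign-flip permutation oracle on the differences
        d = a - b
        t_obs = abs(d.mean())
        flips = rng.choice([-1.0, 1.0], size=(2000, 50))
        t_perm = np.abs((flips * d).mean(axis=1))
        assert (t_perm >= t_obs).mean() < 0.05

    def test_iid_pairs_not_spuriously_tiny(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.3, 0.05, 50)
        b = rng.normal(0.3, 0.05, 50)
        res = paired_tests(a, b)
        assert res["paired_p"] > 0.001
        assert all(p > 0.001 for p in res["normality_p"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_tests([1, 2, 3], [1, 2])
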