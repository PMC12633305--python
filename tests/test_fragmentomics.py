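import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fatefrag as ff
from fatefrag.fragments import FragmentSet
from fatefrag.fragmentomics import (
    FDDProfile,
    FragmentomicsConfig,
    compute_bin_metrics,
    ecdf,
    fdd,
    fdd_features,
    global_length_fdd,
    kl_global,
)
from fatefrag.intervals import GenomicInterval, RegionSet


def brute_force_fdd(a, b, grid):
    """Independent oracle: direct count of values <= x on each side."""
    a, b = list(a), list(b)
    return np.array(
        [sum(v <= x for v in a) / len(a) - sum(v <= x for v in b) / len(b) for x in grid]
    )


class TestEcdf:
    def test_fraction_at_interior_point(self):
        assert ecdf([1, 2, 3])(2) == pytest.approx(2 / 3)

    def test_single_value_step(self):
        f = ecdf([5])
        assert f(5) == 1.0 and f(4.9) == 0.0

    def test_ties_accumulate(self):
        assert ecdf([2, 2])(2) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ecdf([])


class TestFdd:
    def test_identical_sides_give_zero_profile(self):
        prof = fdd([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert np.all(prof.values == 0)

    def test_hand_computed_subtraction(self):
        prof = fdd([1, 2], [3, 4], [1, 2, 3, 4])
        assert np.allclose(prof.values, [0.5, 1.0, 0.5, 0.0])

    def test_swap_negates(self):
        grid = [1, 2, 3, 4]
        a, b = [1, 2], [3, 4]
        assert np.allclose(fdd(a, b, grid).values, -fdd(b, a, grid).values)

    def test_empty_side_raises(self):
        with pytest.raises(ValueError, match="empty contrast set"):
            fdd([], [1], [1])

    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            na, nb = rng.integers(1, 51, size=2)
            a = rng.integers(0, 20, size=na).astype(float)
            b = rng.integers(0, 20, size=nb).astype(float)
            grid = np.unique(np.concatenate([a, b]))
            assert np.array_equal(fdd(a, b, grid).values, brute_force_fdd(a, b, grid))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 30), min_size=1, max_size=30),
        b=st.lists(st.integers(0, 30), min_size=1, max_size=30),
    )
    def test_bounded_and_antisymmetric(self, a, b):
        grid = np.unique(np.concatenate([a, b]).astype(float))
        prof = fdd(a, b, grid)
        assert np.all(np.abs(prof.values) <= 1.0)
        assert np.allclose(prof.values, -fdd(b, a, grid).values)


class TestFddFeatures:
    def test_zero_profile(self):
        prof = FDDProfile("m", [1, 2, 3], [0, 0, 0])
        assert fdd_features(prof) == (0.0, 0.0)

    def test_hand_computed_tv_and_sd(self):
        prof = FDDProfile("m", [1, 2, 3, 4], [0.5, 1.0, 0.5, 0.0])
        tv, sd = fdd_features(prof)
        assert tv == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(0.375 - 0.25))  # 0.353553...

    def test_constant_profile_degenerate_variance(self):
        prof = FDDProfile("m", [1, 2, 3], [0.4, 0.4, 0.4])
        tv, sd = fdd_features(prof)
        assert tv == pytest.approx(1.2)
        assert sd == 0.0


class TestBinMetrics:
    def test_hand_arithmetic(self):
        bm = compute_bin_metrics(np.array([145, 145, 200]), pseudocount=0.5)
        assert bm.mean_len == pytest.approx(490 / 3)
        assert bm.coverage == 3
        assert bm.core_cov == 2
        assert bm.chromatosome_cov == 0
        assert bm.nucleosome_cov == 1
        assert bm.ratio_core_nuc == pytest.approx(2.5 / 1.5)

    def test_inclusive_window_boundaries(self):
        bm = compute_bin_metrics(np.array([160, 170]))
        assert bm.chromatosome_cov == 2 and bm.core_cov == 0
        assert compute_bin_metrics(np.array([159])).core_cov == 1
        assert compute_bin_metrics(np.array([160])).chromatosome_cov == 1

    def test_empty_bin_flagged(self):
        bm = compute_bin_metrics(np.array([]))
        assert bm.coverage == 0 and np.isnan(bm.mean_len)

    def test_window_counts_never_exceed_coverage(self):
        rng = np.random.default_rng(1)
        lens = rng.integers(90, 500, size=200)
        bm = compute_bin_metrics(lens)
        assert bm.core_cov + bm.chromatosome_cov + bm.nucleosome_cov <= bm.coverage


class TestKl:
    def test_identical_multisets_give_zero(self):
        assert kl_global([145, 197, 330], [145, 197, 330]) == pytest.approx(0.0)

    def test_disjoint_supports_increase_as_pseudocount_shrinks(self):
        a, b = [145] * 50, [197] * 50
        kls = [kl_global(a, b, pseudocount=ps) for ps in (1.0, 0.1, 0.01)]
        assert all(k > 0 for k in kls)
        assert kls[0] < kls[1] < kls[2]

    def test_two_cell_closed_form(self):
        # P=[0.75,0.25], Q=[0.25,0.75]: KL = 0.75 ln3 + 0.25 ln(1/3) = 0.5 ln 3
        p = np.array([0.75, 0.25])
        q = np.array([0.25, 0.75])
        expected = float(np.sum(p * np.log(p / q)))
        assert expected == pytest.approx(0.5 * np.log(3))
        # realize those cell masses with counts and a folded-in pseudocount:
        # cells {145, 146}, pseudocount 1: P=(2+1, 0+1)/4, Q=(0+1, 2+1)/4
        got = kl_global([145, 145], [146, 146], pseudocount=1.0, length_min=145, length_max=146)
        assert got == pytest.approx(expected)


def two_bin_regions():
    egcr = RegionSet("eGCR", [GenomicInterval("c1", 0, 1000)])
    elcr = RegionSet("eLCR", [GenomicInterval("c1", 1000, 2000)])
    return egcr, elcr


def frags_with_lengths(lengths_egcr, lengths_elcr):
    chroms, starts, ends = [], [], []
    for L in lengths_egcr:
        chroms.append("c1"); starts.append(100); ends.append(100 + L)
    for L in lengths_elcr:
        chroms.append("c1"); starts.append(1100); ends.append(1100 + L)
    return FragmentSet(chroms, starts, ends)


class TestGlobalLengthFdd:
    def test_identical_lengths_zero_profile(self):
        egcr, elcr = two_bin_regions()
        frags = frags_with_lengths([150] * 5, [150] * 5)
        prof = global_length_fdd(frags, egcr, elcr)
        assert np.all(prof.values == 0)

    def test_step_function_subtraction(self):
        egcr, elcr = two_bin_regions()
        frags = frags_with_lengths([145] * 4, [197] * 4)
        prof = global_length_fdd(frags, egcr, elcr)
        grid = prof.grid.astype(int)
        expected = np.where((grid >= 145) & (grid <= 196), 1.0, 0.0)
        assert np.array_equal(prof.values, expected)

    def test_cancer_like_sample_lobe_positions(self):
        # tumor sample at default depth: positive lobe in the core range,
        # negative minimum in the chromatosome/linker range
        design = ff.CohortDesign(n_healthy=0, n_tumor=1, tf_per_tumor=(0.3,), seed=11)
        egcr, elcr = design.truth_regions()
        frags, _ = ff.simulate_fragments(design, 0)
        prof = global_length_fdd(frags, egcr, elcr)
        peak = prof.grid[np.argmax(prof.values)]
        trough = prof.grid[np.argmin(prof.values)]
        assert 130 <= peak <= 150
        assert 160 <= trough <= 200
        assert prof.values.max() > 0 > prof.values.min()


class TestExtractFragmentomics:
    def test_feature_schema_is_stable_across_samples(self, small_design):
        egcr, elcr = small_design.truth_regions()
        rows = []
        for i in (0, small_design.n_healthy):
            frags, _ = ff.simulate_fragments(small_design, i)
            rows.append(ff.extract_fragmentomics(frags, egcr, elcr))
        assert list(rows[0].values) == list(rows[1].values)
        assert list(rows[0].values) == ff.FragmentomicsFeatures.feature_names()

    def test_healthy_sample_tv_below_cancer_sample(self, small_design):
        egcr, elcr = small_design.truth_regions()
        healthy, _ = ff.simulate_fragments(small_design, 0)
        cancer, _ = ff.simulate_fragments(small_design, small_design.n_healthy + 2)
        f_h = ff.extract_fragmentomics(healthy, egcr, elcr)
        f_c = ff.extract_fragmentomics(cancer, egcr, elcr)
        assert f_c.values["tv_global_length"] > f_h.values["tv_global_length"]
        assert f_c.values["kl_global"] > f_h.values["kl_global"]

    def test_doubling_weights_leaves_ecdf_features_unchanged(self, small_design):
        egcr, elcr = small_design.truth_regions()
        frags, _ = ff.simulate_fragments(small_design, small_design.n_healthy)
        doubled = FragmentSet(frags.chrom, frags.start, frags.end, frags.weight * 2)
        config = FragmentomicsConfig(min_bin_coverage=50)
        a = ff.extract_fragmentomics(frags, egcr, elcr, config)
        b = ff.extract_fragmentomics(doubled, egcr, elcr, config)
        # ECDF/KL features depend only on the length multiset, not the scale
        for name in ("tv_global_length", "sd_global_length", "kl_global",
                     "tv_mean_len", "sd_mean_len"):
            assert a.values[name] == pytest.approx(b.values[name])

    def test_insufficient_bins_raises(self):
        egcr, elcr = two_bin_regions()
        frags = frags_with_lengths([150] * 10, [150] * 10)
        with pytest.raises(ValueError, match="insufficient bins"):
            ff.extract_fragmentomics(frags, egcr, elcr)  # 1 bin/side < min_bins

    def test_all_features_nonnegative(self, small_design):
        egcr, elcr = small_design.truth_regions()
        frags, _ = ff.simulate_fragments(small_design, 1)
        feats = ff.extract_fragmentomics(frags, egcr, elcr)
        assert all(v >= 0 for v in feats.values.values())


class TestTitrationMonotonicity:
    def test_median_global_tv_strictly_increases_with_tf(self, titration_features):
        medians = [
            np.median([f.values["tv_global_length"] for f in feats])
            for tf, feats in sorted(titration_features.items())
        ]
        assert all(a < b for a, b in zip(medians, medians[1:]))
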