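import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import norm

from rsnec import entropy as ent
from rsnec.io import NetworkMap
from rsnec.wavelets import equivalent_filter_support, swt


def brute_force_sample_entropy(pm, pm1, r):
    """Independent O(N^2) oracle using scipy's Chebyshev distances."""
    counts = []
    for p in (pm, pm1):
        d = cdist(p, p, metric="chebyshev")
        np.fill_diagonal(d, np.inf)
        counts.append((d < r).sum() / (len(p) * (len(p) - 1)))
    cm, cm1 = counts
    if cm == 0 or cm1 == 0:
        return None, cm, cm1
    return -np.log(cm1 / cm), cm, cm1


class TestNoiseSigma:
    def test_all_zero(self):
        assert ent.estimate_noise_sigma(np.zeros(100)) == 0.0

    def test_normal_recovery_within_5pct(self, rng):
        c = rng.normal(0, 2.0, 4096)
        assert abs(ent.estimate_noise_sigma(c) - 2.0) / 2.0 < 0.05

    def test_robust_to_outliers(self, rng):
        # 5% gross outliers shift the |c| median to its 0.526 quantile,
        # a ~6% bias; a variance-based estimator would be off by ~7x
        c = rng.normal(0, 2.0, 4096)
        c[:205] += rng.choice([-50, 50], 205)
        assert abs(ent.estimate_noise_sigma(c) - 2.0) / 2.0 < 0.10
        assert abs(c.std() - 2.0) / 2.0 > 1.0


class TestBayesShrink:
    def test_zero_noise_gives_zero(self, rng):
        assert ent.bayes_shrink_threshold(rng.standard_normal(100), 0.0) == 0.0

    def test_closed_form_at_double_variance(self):
        # var(coeffs) == 2 sigma_n^2  =>  sigma_signal == sigma_n => t == sigma_n
        sigma_n = 1.3
        c = np.array([1.0, -1.0] * 500) * np.sqrt(2) * sigma_n
        assert ent.bayes_shrink_threshold(c, sigma_n) == pytest.approx(sigma_n)

    def test_all_noise_branch(self, rng):
        c = rng.normal(0, 1.0, 1000)
        t = ent.bayes_shrink_threshold(c, sigma_noise=5.0)
        assert t == np.abs(c).max()


class TestBuildPatterns:
    def test_count_formula(self):
        p = ent.build_patterns(np.arange(10.0), m=2, delta=3)
        assert len(p) == 7  # 10 - (2-1)*3
        np.testing.assert_array_equal(p[0], [0.0, 3.0])

    def test_contamination_matches_enumeration(self, rng):
        x = rng.standard_normal(30)
        contaminated = {0, 7, 19}
        p = ent.build_patterns(x, m=2, delta=4, contaminated=contaminated)
        expected = [
            (x[i], x[i + 4])
            for i in range(26)
            if i not in contaminated and i + 4 not in contaminated
        ]
        np.testing.assert_array_equal(p, np.array(expected))

    def test_m1_counts_exclude_contaminated_points(self, rng):
        x = rng.standard_normal(50)
        p = ent.build_patterns(x, m=1, delta=1, contaminated={1, 2, 3})
        assert len(p) == 47


class TestContaminateIndices:
    def test_no_flags_empty(self):
        out = ent.contaminate_indices(np.zeros(128), 3)
        assert all(len(o) == 0 for o in out)

    def test_all_flags_everything(self):
        out = ent.contaminate_indices(np.ones(128), 3)
        for o in out:
            assert len(o) == 128

    @pytest.mark.parametrize("wavelet", ["sym8", "db4"])
    def test_single_flag_window_equals_filter_support(self, wavelet):
        n = 1024
        flags = np.zeros(n)
        flags[500] = 1.0
        out = ent.contaminate_indices(flags, 3, wavelet)
        for j in (1, 2, 3):
            width = len(out[j - 1])
            assert width == equivalent_filter_support(wavelet, j)


class TestSampleEntropy:
    def test_alternating_series_exact(self):
        # series 1,2,1,2,...: every equal-valued pair matches at m=1 with
        # r=0.5; every 2-pattern is (1,2) or (2,1)
        x = np.array([1.0, 2.0] * 50)
        pm = ent.build_patterns(x, 1, 1)
        pm1 = ent.build_patterns(x, 2, 1)
        res = ent.sample_entropy(pm, pm1, r=0.5)
        n = 100
        cm_expected = (2 * 2 * (50 * 49 / 2)) / (n * (n - 1))
        n1 = 99  # 50 patterns (1,2), 49 patterns (2,1)
        cm1_expected = (2 * (50 * 49 / 2) + 2 * (49 * 48 / 2)) / (n1 * (n1 - 1))
        assert res.cm == pytest.approx(cm_expected, abs=1e-15)
        assert res.cm1 == pytest.approx(cm1_expected, abs=1e-15)
        assert res.h == pytest.approx(-np.log(cm1_expected / cm_expected),
                                      abs=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(60, 400))
            x = rng.standard_normal(n)
            delta = int(rng.integers(1, 4))
            r = float(rng.uniform(0.1, 0.6))
            pm = ent.build_patterns(x, 1, delta)
            pm1 = ent.build_patterns(x, 2, delta)
            res = ent.sample_entropy(pm, pm1, r)
            h, cm, cm1 = brute_force_sample_entropy(pm, pm1, r)
            assert res.cm == pytest.approx(cm, abs=1e-15)
            assert res.cm1 == pytest.approx(cm1, abs=1e-15)
            if h is not None:
                assert res.h == pytest.approx(h, abs=1e-12)

    def test_iid_normal_closed_form(self, rng):
        # t = 0, m = 1, r = 0.2 sigma: H -> -ln(2 Phi(0.2/sqrt(2)) - 1)
        expected = -np.log(2 * norm.cdf(0.2 / np.sqrt(2)) - 1)
        reps = 12
        hs = []
        for _ in range(reps):
            x = rng.standard_normal(4096)
            r = 0.2 * x.std()
            res = ent.sample_entropy(
                ent.build_patterns(x, 1, 1), ent.build_patterns(x, 2, 1), r
            )
            hs.append(res.h)
        se = np.std(hs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(hs) - expected) < 3 * se + 0.01
        assert ent.normal_iid_entropy(0.2) == pytest.approx(expected)

    def test_h_nonnegative_and_nonincreasing_in_r(self, rng):
        x = rng.standard_normal(300)
        pm = ent.build_patterns(x, 1, 1)
        pm1 = ent.build_patterns(x, 2, 1)
        prev = np.inf
        for r in np.linspace(0.1, 2.0, 12):
            res = ent.sample_entropy(pm, pm1, r)
            if res.h is None:
                continue
            assert res.h >= 0
            assert res.h <= prev + 1e-12
            prev = res.h

    def test_too_few_patterns_unreliable(self, rng):
        x = rng.standard_normal(40)
        res = ent.sample_entropy(
            ent.build_patterns(x, 1, 1), ent.build_patterns(x, 2, 1), 0.5
        )
        assert not res.reliable and res.h is None

    def test_zero_matches_undefined_not_sentinel(self):
        x = np.linspace(0, 100, 60)  # no pair within tiny r
        res = ent.sample_entropy(
            ent.build_patterns(x, 1, 1), ent.build_patterns(x, 2, 1), 1e-6
        )
        assert res.h is None and res.reliable


class TestSelectScales:
    def test_tr2_selects_levels_2_and_3(self):
        out = ent.select_scales(2.0, (0.01, 0.10))
        assert [j for j, _ in out] == [2, 3]
        (lo2, hi2), (lo3, hi3) = out[0][1], out[1][1]
        assert (lo2, hi2) == (0.0625, 0.125)
        assert (lo3, hi3) == (0.03125, 0.0625)

    def test_tr3_overlap_rule_oracle(self):
        # independent recomputation of the >= 50% overlap rule at TR = 3 s
        tr, band = 3.0, (0.01, 0.10)
        f_nyq = 1 / (2 * tr)
        expected = []
        for j in range(1, 20):
            lo, hi = f_nyq / 2**j, f_nyq / 2 ** (j - 1)
            overlap = max(0.0, min(hi, band[1]) - max(lo, band[0]))
            if overlap >= 0.5 * (hi - lo):
                expected.append(j)
        out = ent.select_scales(tr, band, n_scales=None)
        assert [j for j, _ in out] == expected
        assert [j for j, _ in ent.select_scales(tr, band)] == expected[:2]

    def test_band_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="no dyadic level"):
            ent.select_scales(2.0, (0.4, 0.8))


class TestRoiEntropy:
    def test_deterministic(self, rng):
        x = rng.standard_normal(300)
        a = ent.roi_entropy(x, None, 2.0)
        b = ent.roi_entropy(x.copy(), None, 2.0)
        assert a.h == b.h

    def test_constant_series_missing(self):
        out = ent.roi_entropy(np.full(256, 2.0), None, 2.0)
        assert out.h is None

    def test_definedness_matches_pattern_count(self, rng):
        # heavy random flags contaminate nearly everything: definedness must
        # agree with the N_m >= 50 reliability rule, level by level
        x = rng.standard_normal(256)
        flags = (rng.random(256) < 0.5).astype(float)
        out = ent.roi_entropy(x, flags, 2.0)
        contaminated = ent.contaminate_indices(flags, 3, "sym8")
        dec = swt(x, 3, "sym8")
        for j, res in out.per_level.items():
            pm = ent.build_patterns(dec.details[j - 1], 1, 2**j,
                                    contaminated[j - 1])
            pm1 = ent.build_patterns(dec.details[j - 1], 2, 2**j,
                                     contaminated[j - 1])
            if len(pm) < 50 or len(pm1) < 50:
                assert not res.reliable
            else:
                assert res.reliable

    def test_masking_not_imputation(self, rng):
        # flagged frames only remove patterns; surviving admissible patterns
        # yield the same counts as direct exclusion
        x = rng.standard_normal(512)
        flags = np.zeros(512)
        flags[100] = 1.0
        out_flagged = ent.roi_entropy(x, flags, 2.0)
        contaminated = ent.contaminate_indices(flags, 3, "sym8")
        dec = swt(x, 3, "sym8")
        sigma_noise = ent.estimate_noise_sigma(dec.details[0])
        for j, res in out_flagged.per_level.items():
            c = dec.details[j - 1]
            r = 0.2 * np.std(c) + ent.bayes_shrink_threshold(c, sigma_noise)
            manual = ent.sample_entropy(
                ent.build_patterns(c, 1, 2**j, contaminated[j - 1]),
                ent.build_patterns(c, 2, 2**j, contaminated[j - 1]),
                r,
            )
            assert res.h == manual.h


class TestRsnEntropy:
    def _map(self):
        return NetworkMap(np.arange(4), np.array(["VIS", "VIS", "DMN", "DMN"]))

    def test_uniform_roi_entropy(self, rng, monkeypatch):
        x = rng.standard_normal((256, 4))
        monkeypatch.setattr(
            ent, "roi_entropy",
            lambda *a, **k: ent.ROIEntropy(h=1.7),
        )
        prof = ent.rsn_entropy(x, None, self._map(), 2.0)
        np.testing.assert_allclose(prof.values, 1.7)

    def test_hand_set_means(self, rng, monkeypatch):
        x = rng.standard_normal((256, 4))
        hs = iter([1.0, 2.0, 3.0, 5.0])
        monkeypatch.setattr(
            ent, "roi_entropy",
            lambda *a, **k: ent.ROIEntropy(h=next(hs)),
        )
        prof = ent.rsn_entropy(x, None, self._map(), 2.0)
        np.testing.assert_allclose(prof.values, [1.5, 4.0])

    def test_missing_network_flagged(self, rng, monkeypatch):
        x = rng.standard_normal((256, 4))
        hs = iter([1.0, 2.0, None, None])
        monkeypatch.setattr(
            ent, "roi_entropy",
            lambda *a, **k: ent.ROIEntropy(h=next(hs)),
        )
        prof = ent.rsn_entropy(x, None, self._map(), 2.0)
        assert prof.values[0] == pytest.approx(1.5)
        assert np.isnan(prof.values[1])
        assert not prof.complete


class TestSelectR0:
    def test_largest_range_wins(self):
        grid = {0.1: np.array([[1.0, 2.0]]), 0.2: np.array([[0.0, 5.0]])}
        assert ent.select_r0(grid) == 0.2

    def test_tie_goes_to_default(self):
        grid = {r0: np.array([[0.0, 1.0]]) for r0 in ent.R0_GRID}
        assert ent.select_r0(grid) == 0.2

    def test_nan_ignored(self):
        grid = {
            0.15: np.array([[np.nan, 1.0, 3.0]]),
            0.25: np.array([[0.0, 1.0, np.nan]]),
        }
        assert ent.select_r0(grid) == 0.15
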