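"""Spacing laws, empirical P(s), and KS testing."""

import numpy as np
import pytest
import scipy.integrate

from rmtnet.spectral import Segment, trim_and_segment, Spectrum
from rmtnet.spacing_stats import (
    WignerBeta, PoissonLaw, WIGNER, POISSON,
    empirical_P_of_s, ks_statistic, ks_test, classify_segments,
)


def _segment_from_spacings(spacings, index=1):
    lam = np.concatenate([[0.0], np.cumsum(spacings)])
    return Segment(index=index, raw=lam, unfolded=lam,
                   spacings=np.asarray(spacings, float))


class TestSpacingLaws:
    def test_beta1_constants_match_closed_form(self):
        law = WignerBeta(1)
        assert law.a == pytest.approx(np.pi / 2, abs=1e-12)
        assert law.b == pytest.approx(np.pi / 4, abs=1e-12)
        s = np.linspace(0, 6, 601)
        closed = (np.pi * s / 2) * np.exp(-np.pi * s**2 / 4)
        assert np.max(np.abs(law.pdf(s) - closed)) < 1e-12

    def test_level_repulsion_and_poisson_at_zero(self):
        assert WIGNER.pdf(0.0) == 0.0
        assert POISSON.pdf(0.0) == 1.0

    def test_wigner_peak_location(self):
        # maximum of (pi s/2) exp(-pi s^2/4) is at s = sqrt(2/pi);
        # dense grid search as the independent check
        s = np.linspace(0.5, 1.1, 600001)
        grid_peak = s[np.argmax(WIGNER.pdf(s))]
        assert grid_peak == pytest.approx(np.sqrt(2 / np.pi), abs=1e-5)

    @pytest.mark.parametrize("law", [WignerBeta(1), WignerBeta(2),
                                     WignerBeta(4), PoissonLaw()],
                             ids=["goe", "gue", "gse", "poisson"])
    def test_unit_norm_and_unit_mean(self, law):
        norm, _ = scipy.integrate.quad(law.pdf, 0, np.inf)
        mean, _ = scipy.integrate.quad(lambda s: s * law.pdf(s), 0, np.inf)
        assert norm == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("law", [WignerBeta(1), WignerBeta(2),
                                     WignerBeta(4), PoissonLaw()],
                             ids=["goe", "gue", "gse", "poisson"])
    def test_cdf_matches_quadrature_of_pdf(self, law):
        for s in np.linspace(0.0, 4.0, 17):
            num, _ = scipy.integrate.quad(law.pdf, 0, s, limit=200)
            assert law.cdf(s) == pytest.approx(num, abs=1e-8)

    def test_cdf_limits(self):
        assert WIGNER.cdf(0.0) == 0.0
        assert WIGNER.cdf(50.0) == pytest.approx(1.0)
        assert POISSON.cdf(np.log(2)) == pytest.approx(0.5)

    def test_invalid_beta(self):
        with pytest.raises(ValueError, match="beta"):
            WignerBeta(3)


class TestEmpiricalPofS:
    def test_single_bin_mass(self):
        seg = _segment_from_spacings([1.0] * 50)
        hist = empirical_P_of_s([seg], bin_width=0.2)
        nonzero = np.nonzero(hist.density)[0]
        assert len(nonzero) == 1
        b = nonzero[0]
        assert hist.bin_edges[b] == pytest.approx(1.0)
        assert hist.density[b] == pytest.approx(5.0)

    def test_averaging_identical_segments_is_idempotent(self):
        rng = np.random.default_rng(0)
        sp = rng.exponential(size=100)
        one = empirical_P_of_s([_segment_from_spacings(sp)], 0.2)
        two = empirical_P_of_s([_segment_from_spacings(sp, i) for i in (1, 2)], 0.2)
        assert two.density == pytest.approx(one.density)
        assert two.n_segments_averaged == 2

    def test_per_segment_density_normalized(self):
        rng = np.random.default_rng(3)
        segs = [_segment_from_spacings(rng.exponential(size=199), i)
                for i in range(1, 39)]
        hist = empirical_P_of_s(segs, 0.2)
        assert np.sum(hist.density * np.diff(hist.bin_edges)) == pytest.approx(1.0)

    def test_recovers_exponential_within_3_standard_errors(self):
        # 38 segments x 199 spacings from exp(-s), seeded
        rng = np.random.default_rng(42)
        segs = [_segment_from_spacings(rng.exponential(size=199), i)
                for i in range(1, 39)]
        hist = empirical_P_of_s(segs, 0.2)
        centers = hist.bin_centers
        expected = np.exp(-centers)
        total = 38 * 199
        se = np.sqrt(np.maximum(expected * 0.2, 1e-12) / total) / 0.2
        mask = expected > 0.01  # skip far-tail bins with ~no counts
        assert np.all(np.abs(hist.density - expected)[mask] < 3 * se[mask] + 0.02)

    def test_all_degenerate_errors(self):
        seg = Segment(index=1, raw=np.array([1.0, 1.0]), unfolded=None,
                      spacings=None, degenerate=True)
        with pytest.raises(ValueError, match="degenerate"):
            empirical_P_of_s([seg])


class TestKSTest:
    def test_exact_quantile_sample_gives_D_half_over_m(self):
        # points at the (i-1/2)/m null quantiles: D = 1/(2m) by construction
        m = 99
        q = (np.arange(1, m + 1) - 0.5) / m
        sample = -np.log1p(-q)  # exponential quantile function
        assert ks_statistic(sample, POISSON) == pytest.approx(0.5 / m, abs=1e-12)
        res = ks_test(sample, POISSON)
        assert res.p_value > 0.999
        assert res.sample_size == m

    def test_statistic_matches_sup_distance_formula(self):
        rng = np.random.default_rng(8)
        sample = rng.exponential(size=60)
        x = np.sort(sample)
        i = np.arange(1, 61)
        f = POISSON.cdf(x)
        d_manual = np.max(np.maximum(i / 60 - f, f - (i - 1) / 60))
        res = ks_test(sample, POISSON)
        assert res.statistic == pytest.approx(d_manual, abs=1e-14)

    def test_degenerate_sample_rejected_hard(self):
        res = ks_test(np.zeros(50), WIGNER)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match="at least 5"):
            ks_test(np.ones(3), POISSON)

    def test_wrong_law_rejected_with_power(self):
        rng = np.random.default_rng(12)
        rejected = sum(
            ks_test(rng.exponential(size=199), WIGNER).p_value < 0.05
            for _ in range(50))
        assert rejected == 50  # gross mismatch near s = 0


class TestClassifySegments:
    def _segments(self, rng, n_seg=10, m=99, law="exp"):
        draw = rng.exponential if law == "exp" else rng.uniform
        return [_segment_from_spacings(draw(size=m), i)
                for i in range(1, n_seg + 1)]

    def test_all_pass_and_all_fail(self):
        rng = np.random.default_rng(5)
        segs = self._segments(rng)
        passing, summary = classify_segments(segs, POISSON, alpha=0.0)
        assert summary.n_passing == len(passing) == 10  # p > 0 always
        passing, summary = classify_segments(segs, POISSON, alpha=1.0)
        assert summary.n_passing == 0 and passing == []

    def test_goe_segments_pass_wigner(self, goe_spectrum):
        segments, _ = trim_and_segment(goe_spectrum, n=100, coverage=0.95)
        passing, summary = classify_segments(segments, WIGNER, alpha=0.05)
        assert summary.n_tested == 9
        assert summary.n_passing >= 7  # expectation 0.95 * 9
        assert summary.table[0][0] == segments[0].index

    def test_degenerate_segments_skipped(self):
        rng = np.random.default_rng(6)
        segs = self._segments(rng, n_seg=3)
        segs.append(Segment(index=99, raw=np.ones(5), unfolded=None,
                            spacings=None, degenerate=True))
        _, summary = classify_segments(segs, POISSON)
        assert summary.n_tested == 3
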