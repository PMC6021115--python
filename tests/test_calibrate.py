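"""Spectrum binning, four-Gaussian decomposition and threshold derivation."""

import itertools

import numpy as np
import pytest

from rbcshape import (MixtureFit, SearchGrid, ShapeClass, ThresholdSet,
                      adapt_thresholds, default_search_grid,
                      fit_four_gaussians, score_histogram,
                      thresholds_from_sigma)
from rbcshape.calibrate import GaussianComponent, _gauss4

# population layout mimicking a calibrated recording: slipper / sheared /
# croissant peaks plus a broad background of indefinite shapes
TRUE = dict(slipper=(-117.0, 12.0, 0.35), sheared=(40.0, 15.0, 0.15),
            croissant=(115.0, 13.0, 0.35), background=(0.0, 80.0, 0.15))


def sample_spectrum(n, seed):
    rng = np.random.default_rng(seed)
    parts = []
    for mu, sig, w in TRUE.values():
        parts.append(rng.normal(mu, sig, int(round(w * n))))
    return np.concatenate(parts)


class TestScoreHistogram:
    def test_single_score_occupies_one_bin(self):
        centers, counts = score_histogram([42.0], bin_width=5)
        assert counts.sum() == 1
        assert np.count_nonzero(counts) == 1

    def test_counts_conserved(self, rng):
        s = rng.normal(0, 50, 1000)
        _, counts = score_histogram(s, bin_width=3.3)
        assert counts.sum() == 1000

    def test_two_point_masses_two_bins(self):
        s = np.array([-100.0] * 10 + [100.0] * 10)
        centers, counts = score_histogram(s, bin_width=5)
        assert np.count_nonzero(counts) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_histogram([], 5)


class TestFitFourGaussians:
    def test_exact_mixture_recovered_to_optimizer_tolerance(self):
        centers = np.arange(-150, 151, 5.0)
        p = [-117, 12, 300, 40, 15, 120, 115, 13, 280, 0, 80, 40]
        counts = _gauss4(centers, *p)
        fit = fit_four_gaussians((centers, counts))
        assert fit.fit_residual < 1e-3
        assert fit["slipper"].center == pytest.approx(-117, abs=0.1)
        assert fit["sheared_croissant"].center == pytest.approx(40, abs=0.1)
        assert fit["croissant"].center == pytest.approx(115, abs=0.1)
        assert fit["background"].width == pytest.approx(80, rel=0.02)

    def test_sampled_spectrum_centers_and_widths_recovered(self):
        scores = sample_spectrum(10_000, seed=11)
        fit = fit_four_gaussians(score_histogram(scores, 5.0))
        for role, key in (("slipper", "slipper"), ("croissant", "croissant"),
                          ("sheared_croissant", "sheared")):
            mu, sig, _ = TRUE[key]
            assert fit[role].center == pytest.approx(mu, abs=3.0)
            assert fit[role].width == pytest.approx(sig, rel=0.15)

    def test_center_bias_below_bin_width_over_replicates(self):
        """Mixture-fit calibration property: mean center error across 20
        independent 10,000-score spectra stays below the bin width."""
        errs = {r: [] for r in ("slipper", "sheared_croissant", "croissant")}
        for rep in range(20):
            fit = fit_four_gaussians(
                score_histogram(sample_spectrum(10_000, seed=100 + rep), 5.0))
            errs["slipper"].append(fit["slipper"].center - TRUE["slipper"][0])
            errs["sheared_croissant"].append(
                fit["sheared_croissant"].center - TRUE["sheared"][0])
            errs["croissant"].append(fit["croissant"].center - TRUE["croissant"][0])
        for role, e in errs.items():
            assert abs(np.mean(e)) < 5.0, (role, np.mean(e))

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError, match="occupied bins"):
            fit_four_gaussians(score_histogram([1.0] * 100, 5.0))

    def test_role_ordering_invariant(self):
        scores = sample_spectrum(5000, seed=3)
        fit = fit_four_gaussians(score_histogram(scores, 5.0))
        assert (fit["slipper"].center < fit["sheared_croissant"].center
                < fit["croissant"].center)


class TestSigmaThresholds:
    def fit(self):
        comps = [GaussianComponent(-117, 10, 1, "slipper"),
                 GaussianComponent(40, 15, 1, "sheared_croissant"),
                 GaussianComponent(115, 13, 1, "croissant"),
                 GaussianComponent(0, 80, 1, "background")]
        return MixtureFit(comps, (-150, 150), 0.0)

    def test_one_sigma_interval_arithmetic(self):
        th = thresholds_from_sigma(self.fit(), 1.0)
        assert th.slipper == (-117, 10)      # interval [-127, -107]
        assert th.croissant == (115, 13)

    def test_k2_doubles_half_widths(self):
        t1 = thresholds_from_sigma(self.fit(), 1.0)
        t2 = thresholds_from_sigma(self.fit(), 2.0)
        assert t2.slipper[1] == 2 * t1.slipper[1]
        assert t2.croissant[1] == 2 * t1.croissant[1]

    def test_monotone_class_counts_in_k(self, rng):
        scores = rng.normal(0, 90, 2000)
        from rbcshape.report import classify
        counts = []
        for k in (0.5, 1.0, 2.0, 3.0):
            th = thresholds_from_sigma(self.fit(), k)
            pred = [classify(s, th) for s in scores]
            counts.append((pred.count("slipper"), pred.count("croissant")))
        for (s1, c1), (s2, c2) in zip(counts, counts[1:]):
            assert s2 >= s1 and c2 >= c1


def brute_force_adapt(scores, labels, grid: SearchGrid):
    """Independent exhaustive oracle: plain nested loops over the grid."""
    out = {}
    for cls, centers, widths in (
            (ShapeClass.SLIPPER, grid.slipper_centers, grid.slipper_half_widths),
            (ShapeClass.CROISSANT, grid.croissant_centers, grid.croissant_half_widths)):
        best = None
        for c, h in itertools.product(sorted(centers), sorted(widths)):
            fp = fn = 0
            for s, lab in zip(scores, labels):
                inside = abs(s - c) <= h
                if inside and lab is not cls:
                    fp += 1
                if not inside and lab is cls:
                    fn += 1
            key = (fp + fn, h, c)
            if best is None or key < best:
                best = key
        out[cls] = best
    return out


class TestAdaptThresholds:
    def _clusters(self, rng, n=200):
        half = n // 2
        scores = np.concatenate([rng.normal(-117, 5, half),
                                 rng.normal(115, 5, n - half)])
        labels = ([ShapeClass.SLIPPER] * half
                  + [ShapeClass.CROISSANT] * (n - half))
        return scores, labels

    def test_separated_clusters_reach_zero_cost(self, rng):
        scores, labels = self._clusters(rng)
        grid = SearchGrid(np.arange(-125, -109, 1.0), np.arange(2, 40, 1.0),
                          np.arange(107, 123, 1.0), np.arange(2, 40, 1.0))
        th, costs = adapt_thresholds(scores, labels, grid)
        assert costs == {"slipper_cost": 0, "croissant_cost": 0}
        # tie-break: narrowest covering interval
        oracle = brute_force_adapt(scores, labels, grid)
        assert th.slipper == (oracle[ShapeClass.SLIPPER][2],
                              oracle[ShapeClass.SLIPPER][1])

    def test_matches_exhaustive_oracle_on_noisy_overlap(self, rng):
        scores = np.concatenate([rng.normal(-100, 30, 80),
                                 rng.normal(90, 40, 80),
                                 rng.uniform(-150, 150, 40)])
        labels = ([ShapeClass.SLIPPER] * 80 + [ShapeClass.CROISSANT] * 80
                  + [ShapeClass.OTHER] * 40)
        grid = SearchGrid(np.linspace(-130, -70, 25), np.linspace(5, 80, 20),
                          np.linspace(60, 120, 25), np.linspace(5, 80, 20))
        th, costs = adapt_thresholds(scores, labels, grid)
        oracle = brute_force_adapt(scores, labels, grid)
        assert (costs["slipper_cost"], th.slipper[1], th.slipper[0]) \
            == oracle[ShapeClass.SLIPPER]
        assert (costs["croissant_cost"], th.croissant[1], th.croissant[0]) \
            == oracle[ShapeClass.CROISSANT]

    def test_sheared_reference_counts_against_both_intervals(self):
        scores = np.array([-117.0, 115.0, 64.0])
        labels = [ShapeClass.SLIPPER, ShapeClass.CROISSANT,
                  ShapeClass.SHEARED_CROISSANT]
        grid = SearchGrid(np.array([-117.0]), np.array([10.0]),
                          np.array([115.0]), np.array([40.0, 60.0]))
        th, costs = adapt_thresholds(scores, labels, grid)
        # width 60 would swallow the sheared cell at 64 -> cost 1; width 40 wins
        assert th.croissant[1] == 40.0
        assert costs["croissant_cost"] == 0

    def test_missing_class_rejected(self):
        grid = SearchGrid(np.zeros(1) - 100, np.ones(1), np.zeros(1) + 100,
                          np.ones(1))
        with pytest.raises(ValueError):
            adapt_thresholds([0.0], [ShapeClass.CROISSANT], grid)

    def test_default_grid_spans_fit(self):
        comps = [GaussianComponent(-117, 10, 1, "slipper"),
                 GaussianComponent(40, 15, 1, "sheared_croissant"),
                 GaussianComponent(115, 13, 1, "croissant"),
                 GaussianComponent(0, 80, 1, "background")]
        grid = default_search_grid(MixtureFit(comps, (-150, 150), 0.0))
        assert grid.slipper_centers.min() == pytest.approx(-127)
        assert grid.slipper_half_widths.max() == pytest.approx(40)
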