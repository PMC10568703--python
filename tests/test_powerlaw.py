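"""Exponent-fit recovery on ensembles with known ground truth."""

import numpy as np
import pytest

from flexibcd import (fit_backbone_scaling, fit_fractal_dimension,
                      fit_size_distribution_exponent)
from flexibcd.fixtures import make_fractal_ensemble, random_lattice_tree, sample_power_law_masses
from flexibcd.topology import backbone_chemical_distance


class TestFractalDimension:
    def test_straight_chains_are_one_dimensional(self):
        m, rg = make_fractal_ensemble(1, [4, 8, 16, 32, 64, 128, 256])
        fit = fit_fractal_dimension(m, rg, fit_range=(1, np.inf))
        assert fit.exponent == pytest.approx(1.0, abs=0.05)

    def test_compact_blobs_are_three_dimensional(self):
        m, rg = make_fractal_ensemble(3, [2, 2.5, 3, 3.5, 4, 5, 6, 7])
        fit = fit_fractal_dimension(m, rg, fit_range=(1, np.inf))
        assert fit.exponent == pytest.approx(3.0, abs=0.1)

    def test_hierarchical_doubling_gives_two(self):
        # pair doubling with Rg growth 2^(1/2) forces m ~ Rg^2
        m, rg = make_fractal_ensemble(2.0, [10])
        fit = fit_fractal_dimension(m, rg, fit_range=(1, np.inf))
        assert fit.exponent == pytest.approx(2.0, abs=0.05)

    def test_unreliable_flag_on_narrow_range(self):
        fit = fit_fractal_dimension([10, 12, 14], [1.0, 1.1, 1.2],
                                    fit_range=(1, np.inf))
        assert not fit.reliable


class TestSizeDistributionExponent:
    @pytest.mark.parametrize("tau", [1.5, 2.2])
    def test_recovers_known_exponent(self, tau):
        masses = sample_power_law_masses(tau, 1000.0, 100_000, seed=42)
        fit = fit_size_distribution_exponent(masses)
        assert fit.exponent == pytest.approx(tau, abs=0.1)
        assert fit.reliable

    @pytest.mark.parametrize("tau", [1.2, 1.8, 2.5, 3.0])
    def test_recovery_across_range(self, tau):
        """Exponents in [1, 3] recovered within +-0.1 at 10^4+ samples."""
        masses = sample_power_law_masses(tau, 3000.0, 50_000, seed=7)
        fit = fit_size_distribution_exponent(masses)
        assert fit.exponent == pytest.approx(tau, abs=0.1)

    def test_monodisperse_rejected(self):
        fit = fit_size_distribution_exponent([8] * 100)
        assert not fit.reliable

    def test_tiny_cutoff_mostly_monomers(self):
        masses = sample_power_law_masses(1.5, 1.0, 10_000, seed=1)
        assert np.mean(masses == 1) > 0.8


class TestBackboneScaling:
    def test_pure_chains_slope_one(self):
        ls = np.array([15, 31, 63, 127, 255, 511, 1023])
        ms = ls + 1  # a chain of l bonds has l+1 monomers
        fit = fit_backbone_scaling(ms, ls)
        assert fit.exponent == pytest.approx(1.0, abs=0.05)

    def test_random_trees_recovered_within_tolerance(self):
        """Slope of log m vs log l on random lattice trees agrees with an
        exact per-tree (m, l) oracle computed by exhaustive BFS."""
        ms, ls = [], []
        rng = np.random.default_rng(0)
        for k, n in enumerate(np.unique(np.geomspace(8, 400, 40).astype(int))):
            for rep in range(3):
                fix = random_lattice_tree(int(n), seed=1000 + 10 * k + rep)
                res = backbone_chemical_distance(np.arange(n), fix.bonds)
                ms.append(n)
                ls.append(res.chemical_distance)
        fit = fit_backbone_scaling(ms, ls)
        # oracle: direct OLS on the raw exact pairs
        slope = np.polyfit(np.log10(ls), np.log10(ms), 1)[0]
        assert fit.exponent == pytest.approx(slope, abs=0.1)


class TestBinnedEstimator:
    """The histogram-slope variant: correct tool for pooled mixtures,
    known mild cutoff bias on homogeneous samples."""

    @pytest.mark.parametrize("tau", [1.5, 2.2])
    def test_recovers_within_bias_band(self, tau):
        masses = sample_power_law_masses(tau, 300.0, 20_000, seed=3)
        fit = fit_size_distribution_exponent(masses, method="binned")
        assert fit.exponent == pytest.approx(tau, abs=0.25)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit_size_distribution_exponent([5, 6, 7] * 10, method="nope")
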