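"""The qSIP enrichment chain: WADs, bootstrap, GC/mass conversion, APE."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qsippy as q
from qsippy.enrichment import LabelOnlyTaxon

BACKGROUND = 0.01111233


class TestWad:
    @pytest.mark.parametrize(
        "y, rho, expected",
        [
            ([0.2, 0.5, 0.3], [1.67, 1.72, 1.77], 1.7250),
            ([0.0, 5.0, 0.0], [1.67, 1.70, 1.77], 1.70),
            ([1.0, 1.0], [1.70, 1.75], 1.725),
        ],
    )
    def test_examples(self, y, rho, expected):
        assert q.compute_wad(y, rho) == pytest.approx(expected)

    def test_all_zero_is_nan(self):
        assert np.isnan(q.compute_wad([0, 0], [1.7, 1.75]))

    @given(st.integers(0, 999))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 8)
        y = rng.uniform(0.01, 10, size=n)
        rho = rng.uniform(1.65, 1.80, size=n)
        brute = sum(yi * ri for yi, ri in zip(y, rho)) / sum(y)
        assert q.compute_wad(y, rho) == pytest.approx(brute, rel=1e-12)


class TestBootstrap:
    def test_degenerate(self):
        est = q.bootstrap_mean([1.7, 1.7, 1.7], n_draws=100, seed=0)
        assert est.mean == pytest.approx(1.7)
        assert est.ci_high - est.ci_low == pytest.approx(0.0)

    def test_enumeration_mean_exact(self):
        # all 4 equally likely resamples of {1.70, 1.72}
        est = q.bootstrap_mean([1.70, 1.72], enumerate_all=True)
        assert est.mean == pytest.approx(1.71, abs=1e-15)
        assert est.n_draws == 4

    def test_sampled_matches_enumeration(self):
        exact = q.bootstrap_mean([1.70, 1.72], enumerate_all=True)
        sampled = q.bootstrap_mean([1.70, 1.72], n_draws=1000, seed=42)
        # Monte-Carlo tolerance: SE of the mean of 1000 draws
        se = np.std([1.70, 1.71, 1.71, 1.72]) / np.sqrt(1000)
        assert sampled.mean == pytest.approx(exact.mean, abs=4 * se)

    def test_seed_reproducible(self):
        a = q.bootstrap_mean([1.1, 1.4, 1.3], seed=7)
        b = q.bootstrap_mean([1.1, 1.4, 1.3], seed=7)
        assert a == b

    def test_empty_errors_single_warns(self):
        with pytest.raises(ValueError):
            q.bootstrap_mean([])
        with pytest.warns(UserWarning):
            q.bootstrap_mean([1.7], n_draws=10, seed=0)


class TestWadDifference:
    def test_no_shift(self):
        est = q.wad_difference([1.7, 1.7], [1.7, 1.7], seed=0)
        assert est.mean == pytest.approx(0.0)
        assert est.ci_low <= 0 <= est.ci_high

    def test_degenerate_replicates(self):
        est = q.wad_difference([1.75, 1.75], [1.70, 1.70], seed=0)
        assert est.mean == pytest.approx(0.05)
        assert est.ci_high - est.ci_low == pytest.approx(0.0)

    def test_enumeration(self):
        est = q.wad_difference([1.74, 1.76], [1.70], enumerate_all=True)
        assert est.mean == pytest.approx(0.05, abs=1e-15)

    def test_label_only_signalled(self):
        with pytest.raises(LabelOnlyTaxon):
            q.wad_difference([1.74], [], seed=0)


class TestGcAndMasses:
    @pytest.mark.parametrize(
        "w_light, g",
        [(1.646057, 0.0), (1.729563, 1.0), (1.700, 0.6459775)],
    )
    def test_gc_from_wad(self, w_light, g):
        assert q.gc_from_wad(w_light) == pytest.approx(g, abs=1e-6)

    def test_gc_out_of_range_warns(self):
        with pytest.warns(UserWarning, match="GC"):
            q.gc_from_wad(1.62)

    @pytest.mark.parametrize("g, m", [(0.0, 307.691), (1.0, 308.187)])
    def test_molecular_weight_light(self, g, m):
        assert q.molecular_weight_light(g) == pytest.approx(m)

    def test_mw_monotone_in_gc(self):
        gs = np.linspace(0, 1, 11)
        ms = q.molecular_weight_light(gs)
        assert (np.diff(ms) > 0).all()

    @pytest.mark.parametrize(
        "g, increment",
        [(0.0, 9.9220539), (1.0, 9.4259512)],  # N_C(g)*(1-background)*1.003355
    )
    def test_heavy_max_increment(self, g, increment):
        assert q.heavy_max_mass(g, 0.0) == pytest.approx(increment, abs=1e-6)

    def test_heavy_max_increment_decreases_with_gc(self):
        incs = q.heavy_max_mass(np.linspace(0, 1, 5), 0.0)
        assert (np.diff(incs) < 0).all()

    @pytest.mark.parametrize(
        "z, expected",
        [(0.0, 308.011), (0.05, 317.0701471), (-0.01, 306.1992)],
    )
    def test_labeled_mass(self, z, expected):
        got = q.labeled_mass(z, 1.7, 308.011)
        assert got == pytest.approx(expected, abs=1e-3)
        if z < 0:
            assert got < 308.011


class TestAtomFractionExcess:
    def test_zero_shift(self):
        assert q.atom_fraction_excess(308.0, 308.0, 318.0) == 0.0

    def test_full_substitution(self):
        a = q.atom_fraction_excess(318.0, 308.0, 318.0)
        assert a == pytest.approx(1 - BACKGROUND, abs=1e-12)

    def test_linear_midpoint(self):
        a = q.atom_fraction_excess(313.0, 308.0, 318.0)
        assert a == pytest.approx((1 - BACKGROUND) / 2, abs=1e-12)

    def test_negative_not_clipped(self):
        assert q.atom_fraction_excess(307.0, 308.0, 318.0) < 0


class TestForwardModel:
    def test_paper_benchmark_density(self):
        # DNA at 99 atom % 13C from an unlabeled WAD of 1.700 g/mL
        assert round(q.forward_density_shift(1.700, 0.99), 2) == 1.75

    def test_background_is_identity(self):
        for w in (1.66, 1.70, 1.73):
            assert q.forward_density_shift(w, BACKGROUND) == pytest.approx(w, abs=1e-12)

    @pytest.mark.parametrize("gc", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("excess", [0.0, 0.01, 0.1, 0.3, 0.97888767])
    def test_round_trip(self, gc, excess):
        w_light = 1.646057 + 0.083506 * gc
        w_lab = q.forward_density_shift(w_light, BACKGROUND + excess)
        recovered = q.excess_from_shift(w_light, w_lab - w_light)
        assert recovered == pytest.approx(excess, abs=1e-10)

    def test_ape_monotone_in_z(self):
        zs = np.linspace(-0.01, 0.05, 25)
        apes = q.excess_from_shift(1.70, zs)
        assert (np.diff(apes) > 0).all()


class TestActiveCalls:
    @pytest.mark.parametrize(
        "mean, lo, hi, expected",
        [
            (0.05, 0.02, 0.08, True),
            (0.05, -0.01, 0.11, False),
            (-0.02, -0.04, -0.01, False),
        ],
    )
    def test_ci_rule(self, mean, lo, hi, expected):
        est = q.BootstrapEstimate(mean, lo, hi, 1000)
        assert q.call_active(est) is expected

    @pytest.mark.parametrize(
        "taxon_ci, treatment_ci, expected",
        [((1.76, 1.78), (1.70, 1.75), True), ((1.73, 1.76), (1.70, 1.75), False)],
    )
    def test_label_only_rule(self, taxon_ci, treatment_ci, expected):
        taxon = q.BootstrapEstimate(np.mean(taxon_ci), *taxon_ci, 1000)
        treatment = q.BootstrapEstimate(np.mean(treatment_ci), *treatment_ci, 1000)
        assert q.call_active_label_only(taxon, treatment) is expected

    def test_label_only_rejects_taxa_with_unlabeled_data(self):
        est = q.BootstrapEstimate(1.76, 1.75, 1.77, 1000)
        with pytest.raises(ValueError, match="CI rule"):
            q.call_active_label_only(est, est, has_unlabeled_data=True)
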