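"""Unit and property tests for the equilibrium occupancy model and Kd fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irbind import (
    NoiseModel,
    PromoterBindingModel,
    SiteModel,
    TitrationDesign,
    apparent_hill_coefficient,
    band_distribution,
    band_table_to_saturation,
    configuration_distribution,
    fit_multisite,
    fit_single_site,
    fractional_saturation,
    simulate_emsa,
)
from irbind.errors import DomainError, InvalidModelError, NonIdentifiableError

from conftest import PAPER_KDS_UM, poisson_binomial


def coupled(kds, omega):
    model = PromoterBindingModel.from_kds(kds)
    coupling = {
        frozenset((a, b)): omega
        for i, a in enumerate(model.site_ids)
        for b in model.site_ids[i + 1 :]
    }
    return PromoterBindingModel(sites=model.sites, coupling=coupling)


class TestConfigurationDistribution:
    def test_zero_ligand_all_mass_on_empty(self, four_site_model):
        dist = configuration_distribution(four_site_model, 0.0)
        assert dist.prob_of([]) == 1.0
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_site_at_kd_is_half_bound(self):
        model = PromoterBindingModel.from_kds([1.0])
        dist = configuration_distribution(model, 1.0)
        assert dist.prob_of([]) == pytest.approx(0.5, abs=1e-12)
        assert dist.prob_of(["S1"]) == pytest.approx(0.5, abs=1e-12)

    def test_empty_configuration_matches_closed_form(self, four_site_model):
        # independent sites: P(empty) is the product of per-site vacancies
        conc = 0.121
        expected = np.prod([1 - conc / (conc + kd) for kd in PAPER_KDS_UM])
        dist = configuration_distribution(four_site_model, conc)
        assert dist.prob_of([]) == pytest.approx(expected, rel=1e-12)
        assert dist.prob_of([]) == pytest.approx(0.0628, abs=5e-4)

    def test_invalid_inputs(self, four_site_model):
        with pytest.raises(InvalidModelError):
            SiteModel("bad", kd=-1.0)
        with pytest.raises(DomainError):
            configuration_distribution(four_site_model, -0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        kds=st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=6),
        omega=st.floats(1e-3, 1e3),
        conc=st.floats(0.0, 1e4),
    )
    def test_normalization_property(self, kds, omega, conc):
        model = coupled(kds, omega)
        cfg = configuration_distribution(model, conc)
        assert np.all(cfg.probs >= 0)
        assert abs(cfg.probs.sum() - 1.0) < 1e-12
        band = band_distribution(model, conc)
        assert abs(band.probs.sum() - 1.0) < 1e-12


class TestBandDistribution:
    def test_zero_ligand(self, four_site_model):
        probs = band_distribution(four_site_model, 0.0).probs
        assert probs[0] == 1.0 and np.all(probs[1:] == 0.0)

    def test_two_identical_sites_at_kd_binomial(self):
        model = PromoterBindingModel.from_kds([1.0, 1.0])
        probs = band_distribution(model, 1.0).probs
        assert probs == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)

    @pytest.mark.parametrize("conc", [0.003, 0.0205, 0.3, 2.0, 50.0])
    def test_independent_sites_match_poisson_binomial(self, four_site_model, conc):
        probs = band_distribution(four_site_model, conc).probs
        ps = [conc / (conc + kd) for kd in PAPER_KDS_UM]
        assert np.max(np.abs(probs - poisson_binomial(ps))) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        kds=st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=6),
        conc=st.floats(1e-4, 1e4),
    )
    def test_oracle_equivalence_property(self, kds, conc):
        model = PromoterBindingModel.from_kds(kds)
        probs = band_distribution(model, conc).probs
        oracle = poisson_binomial([conc / (conc + kd) for kd in kds])
        assert np.max(np.abs(probs - oracle)) < 1e-12


class TestFractionalSaturation:
    def test_limits(self, four_site_model):
        assert fractional_saturation(four_site_model, 0.0) == 0.0
        assert fractional_saturation(four_site_model, 1e9) > 0.999

    def test_single_site_half_at_kd(self):
        model = PromoterBindingModel.from_kds([0.862])
        assert fractional_saturation(model, 0.862) == pytest.approx(0.5, abs=1e-12)

    def test_four_site_closed_form(self, four_site_model):
        conc = 0.0205
        expected = np.mean([conc / (conc + kd) for kd in PAPER_KDS_UM])
        assert fractional_saturation(four_site_model, conc) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.167, abs=5e-4)

    def test_strictly_increasing(self, four_site_model):
        concs = np.logspace(-4, 3, 40)
        ys = [fractional_saturation(four_site_model, c) for c in concs]
        assert np.all(np.diff(ys) > 0)


class TestApparentHillCoefficient:
    @pytest.mark.parametrize("kd", [0.0205, 1.0, 11.0])
    def test_single_site_is_one(self, kd):
        model = PromoterBindingModel.from_kds([kd])
        assert apparent_hill_coefficient(model) == pytest.approx(1.0, abs=1e-6)

    def test_strong_positive_coupling_approaches_two(self):
        assert apparent_hill_coefficient(coupled([1.0, 1.0], 1e6)) >= 1.99

    def test_heterogeneous_independent_sites_below_one(self, four_site_model):
        assert apparent_hill_coefficient(four_site_model) < 1.0

    def test_n_h_decreases_with_affinity_spread(self):
        # three-point ladder at fixed geometric mean 1 µM
        n_hs = []
        for spread in (0.5, 1.5, 2.5):  # log10 half-spread
            model = PromoterBindingModel.from_kds(10.0 ** np.linspace(-spread, spread, 3))
            n_hs.append(apparent_hill_coefficient(model))
        assert n_hs[0] > n_hs[1] > n_hs[2]
        assert all(0 < n < 1 for n in n_hs)

    def test_identical_sites_within_bounds(self):
        for n in (2, 3, 4):
            model = PromoterBindingModel.from_kds([1.0] * n)
            n_h = apparent_hill_coefficient(model)
            assert 0 < n_h <= n + 1e-9


class TestFitSingleSite:
    @pytest.mark.parametrize("kd", [1.0, 0.0205])
    def test_noiseless_round_trip(self, kd, noiseless_single_site_table):
        curve = band_table_to_saturation(noiseless_single_site_table(kd))
        fit = fit_single_site(curve)
        assert fit.kds[0] == pytest.approx(kd, rel=1e-6)
        assert fit.residual < 1e-12

    def test_all_zero_curve_not_identifiable(self):
        from irbind.hill_analysis import SaturationCurve, SaturationPoint

        curve = SaturationCurve(
            points=tuple(SaturationPoint(c, 0.0) for c in (0.0, 0.1, 1.0, 10.0))
        )
        with pytest.raises(NonIdentifiableError):
            fit_single_site(curve)

    def test_noisy_median_error_within_ten_percent(self):
        # 5% multiplicative band noise, triplicates, 200 seeded simulations
        kd = 0.5
        model = PromoterBindingModel.from_kds([kd])
        design = TitrationDesign.log_spaced(kd, replicates=3)
        errors = []
        for seed in range(200):
            table = simulate_emsa(model, design, NoiseModel(multiplicative_sigma=0.05, seed=seed))
            fit = fit_single_site(band_table_to_saturation(table))
            errors.append(abs(fit.kds[0] - kd) / kd)
        assert np.median(errors) <= 0.10


class TestFitMultisite:
    def test_recovers_four_paper_kds(self, four_site_model):
        concs = (0.0, *np.logspace(math.log10(0.0205) - 2, math.log10(11.0) + 2, 16))
        design = TitrationDesign(concentrations=concs, replicates=1)
        table = simulate_emsa(four_site_model, design, NoiseModel(multiplicative_sigma=0.0))
        fit = fit_multisite(table, 4)
        for got, want in zip(fit.kds, sorted(PAPER_KDS_UM)):
            assert got == pytest.approx(want, rel=0.01)

    def test_two_equal_sites(self):
        model = PromoterBindingModel.from_kds([1.0, 1.0])
        design = TitrationDesign.log_spaced(1.0, n_lanes=12, replicates=1)
        table = simulate_emsa(model, design, NoiseModel(multiplicative_sigma=0.0))
        fit = fit_multisite(table, 2)
        assert fit.kds[0] == pytest.approx(1.0, rel=0.01)
        assert fit.kds[1] == pytest.approx(1.0, rel=0.01)

    def test_model_mismatch_raises_residual(self, four_site_model):
        concs = (0.0, *np.logspace(math.log10(0.0205) - 2, math.log10(11.0) + 2, 16))
        design = TitrationDesign(concentrations=concs, replicates=1)
        table4 = simulate_emsa(four_site_model, design, NoiseModel(multiplicative_sigma=0.0))
        good = fit_multisite(table4, 4).residual
        # collapse species 2..4 into one bound class to mimic a 2-site reading
        from irbind.hill_analysis import BandTable, Lane

        lanes2 = tuple(
            Lane(
                concentration=ln.concentration,
                intensities=(ln.intensities[0], ln.intensities[1], sum(ln.intensities[2:])),
                replicate_id=ln.replicate_id,
            )
            for ln in table4.lanes
        )
        bad = fit_multisite(BandTable(lanes=lanes2), 2).residual
        assert good < 1e-12
        assert bad > 1e-4

    def test_too_few_concentrations(self, four_site_model):
        design = TitrationDesign(concentrations=(0.0, 0.1, 1.0, 10.0), replicates=1)
        table = simulate_emsa(four_site_model, design, NoiseModel(multiplicative_sigma=0.0))
        with pytest.raises(NonIdentifiableError):
            fit_multisite(table, 4)
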