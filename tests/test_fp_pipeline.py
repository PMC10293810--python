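"""Plate-reader FPCD analysis: normalization, decay fits, model selection,
isotherm and stoichiometry regression."""

import numpy as np
import pandas as pd
import pytest

from dtkin.fp_pipeline import (
    CompetitionFitResult,
    DegenerateDataError,
    ExponentialFit,
    KoffProfile,
    NormalizedDecay,
    PlateTimeCourseSet,
    analyze_plate,
    bic,
    build_koff_profile,
    fit_competition_models,
    fit_exponential_decay,
    fit_kd,
    fit_stoichiometry,
    koff_obs_from_fit,
    normalize_polarization,
)
from dtkin.synthetic_data import FpPlateDesign, generate_fpcd_dataset, get_preset


def make_plate(pol_by_condition, times=None):
    times = np.arange(90, 290, 10.0) if times is None else times
    rows = []
    for (conc, rep), pol in pol_by_condition.items():
        for t, p in zip(times, pol):
            rows.append({"condition_id": f"c{conc}", "competitor_M": conc,
                         "replicate": rep, "time_s": t, "polarization_mP": p})
    return PlateTimeCourseSet(data=pd.DataFrame(rows))


class TestNormalization:
    def test_anchor_mapping_extremes_to_unit_interval(self):
        t = np.arange(90, 290, 10.0)
        plate = make_plate({
            (0.0, 1): np.full(t.size, 200.0),
            (1e-6, 1): np.linspace(200, 60, t.size),
        })
        decays = normalize_polarization(plate)
        allvals = np.concatenate([d.fraction for d in decays])
        assert allvals.max() == pytest.approx(1.0)
        assert allvals.min() == pytest.approx(0.0)

    def test_flat_signal_raises_degenerate_error(self):
        t = np.arange(90, 290, 10.0)
        plate = make_plate({(0.0, 1): np.full(t.size, 120.0),
                            (1e-6, 1): np.full(t.size, 121.0)})
        with pytest.raises(DegenerateDataError):
            normalize_polarization(plate)

    def test_recovers_generating_fractions_with_linear_mp_mapping(self, rng):
        """Known bound fractions spanning the full range, mapped linearly to
        polarization with noise: normalization inverts the mapping to within
        the noise SD."""
        t = np.arange(90, 590, 10.0)
        noise_sd = 1.0
        frac_true = {
            (0.0, 1): np.ones(t.size),
            (1e-6, 1): np.exp(-0.01 * (t - 90)),
            (1e-5, 1): np.exp(-0.05 * (t - 90)),
        }
        plate = make_plate(
            {key: 60 + 140 * f + rng.normal(0, noise_sd, t.size)
             for key, f in frac_true.items()},
            times=t,
        )
        decays = normalize_polarization(plate, robust=True)
        for d in decays:
            resid = d.fraction - frac_true[(d.competitor_M, 1)]
            assert np.abs(np.median(resid)) < 4 * noise_sd / 140

    def test_strictly_increasing_times_enforced(self):
        rows = [
            {"condition_id": "c", "competitor_M": 0.0, "replicate": 1,
             "time_s": t, "polarization_mP": 100.0}
            for t in [90.0, 100.0, 100.0]
        ]
        with pytest.raises(ValueError, match="strictly increasing"):
            PlateTimeCourseSet(data=pd.DataFrame(rows))


class TestExponentialDecay:
    def test_noiseless_parameters_recovered_exactly(self):
        t = np.arange(0, 600, 10.0)
        d = NormalizedDecay(t, 0.8 * np.exp(-0.01 * t) + 0.2, 1e-6, 1, (0, 1))
        fit = fit_exponential_decay(d)
        assert fit.k == pytest.approx(0.01, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-9)
        assert fit.plateau == pytest.approx(0.2, abs=1e-9)

    def test_constant_signal_gives_zero_rate_amplitude_product(self):
        t = np.arange(0, 600, 10.0)
        fit = fit_exponential_decay(NormalizedDecay(t, np.ones(t.size), 0.0, 1, (0, 1)))
        assert fit.converged
        assert fit.k * fit.amplitude == pytest.approx(0.0, abs=1e-6)

    def test_median_rate_recovery_under_noise(self, rng):
        """Noisy decays at the 4 C dissociation rate: median fitted rate
        within 3% of truth."""
        k_true = 6.8e-3
        t = np.arange(90, 1800, 10.0)
        ks = []
        for _ in range(200):
            y = np.exp(-k_true * t) + rng.normal(0, 0.02, t.size)
            fit = fit_exponential_decay(NormalizedDecay(t, y, 1e-6, 1, (0, 1)))
            ks.append(fit.k)
        assert np.median(ks) == pytest.approx(k_true, rel=0.03)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(
                NormalizedDecay(np.arange(4.0), np.ones(4), 0.0, 1, (0, 1))
            )

    def test_partial_flag_for_small_amplitude(self):
        t = np.arange(0, 600, 10.0)
        y = 0.1 * np.exp(-0.01 * t) + 0.9
        fit = fit_exponential_decay(NormalizedDecay(t, y, 0.0, 1, (0, 1)))
        assert fit.partial


class TestKoffConvention:
    def test_initial_slope_is_rate_times_amplitude(self):
        fit = ExponentialFit(k=0.01, amplitude=0.8, plateau=0.2, rss=0.0,
                             n_points=50, converged=True)
        assert koff_obs_from_fit(fit) == pytest.approx(0.008)
        assert koff_obs_from_fit(fit, "rate") == pytest.approx(0.01)

    def test_conventions_agree_for_complete_decay(self):
        fit = ExponentialFit(k=0.02, amplitude=1.0, plateau=0.0, rss=0.0,
                             n_points=50, converged=True)
        assert koff_obs_from_fit(fit) == koff_obs_from_fit(fit, "rate")

    def test_end_to_end_saturating_chase_recovers_intrinsic_rate(self):
        """Classic-only kinetics at saturating competitor: the initial-slope
        estimate lands within 5% of the intrinsic dissociation rate."""
        preset = get_preset("TREX1_ssDNA_25C")
        from dtkin.kinetics_core import RateConstants
        rates = RateConstants.self_competition(7e-3 / 8.9e-9, 7e-3, 0.0)
        from dtkin.kinetics_core import (ReactionTotals, SpeciesState,
                                         equilibrium_state, simulate_scheme)
        eq = equilibrium_state(rates, ReactionTotals(100e-9, 5e-9, 0.0))
        D = 50e-6
        y0 = SpeciesState(E=eq.E, P=eq.P, D=D, EP=eq.EP, ED=0.0)
        times = np.arange(0.0, 1200.0, 10.0)
        tc = simulate_scheme(rates, ReactionTotals(100e-9, 5e-9, D), times, y0=y0)
        frac = tc["EP"] / eq.EP
        fit = fit_exponential_decay(NormalizedDecay(times, frac, D, 1, (0, 1)))
        assert koff_obs_from_fit(fit) == pytest.approx(7e-3, rel=0.05)


class TestCompetitionModels:
    def test_pure_transfer_profile_returns_generating_slope(self):
        D = np.array([0.0, 1e-6, 2e-6, 5e-6, 1e-5, 2e-5])
        y = 1500.0 * D
        profile = KoffProfile(D, y, np.zeros_like(D), np.ones(D.size, int))
        res = fit_competition_models(profile)
        assert res.selected == "direct_transfer"
        assert res.direct_transfer.params["k_thetaD"] == pytest.approx(1500, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        D = np.array([1e-6, 2e-6, 5e-6])
        with pytest.raises(DegenerateDataError):
            fit_competition_models(
                KoffProfile(D, D * 100, np.zeros(3), np.ones(3, int))
            )

    def test_classic_data_selects_classic(self, rng):
        """Saturating-plateau profile (fast-dissociating dsDNA ligand) at 5%
        noise selects the 2-parameter classic model."""
        D = np.array([0, 1e-7, 3e-7, 1e-6, 2e-6, 4e-6, 8e-6, 1.4e-5, 2e-5])
        y = 1.9e-2 * D / (D + 2e-7)
        hits = 0
        for _ in range(50):
            yn = y * (1 + 0.05 * rng.standard_normal(D.size))
            p = KoffProfile(D, yn, np.where(y > 0, 0.05 * y, 1e-4),
                            np.full(D.size, 4))
            if fit_competition_models(p).selected != "direct_transfer":
                hits += 1
        assert hits >= 45

    def test_transfer_data_selects_transfer_and_recovers_slope(self, rng):
        D = np.array([0, 1e-7, 3e-7, 1e-6, 2e-6, 4e-6, 8e-6, 1.4e-5, 2e-5])
        y = 7e-3 * D / (D + 2e-7) + 1500.0 * D
        hits = 0
        for _ in range(50):
            yn = y * (1 + 0.05 * rng.standard_normal(D.size))
            p = KoffProfile(D, yn, np.where(y > 0, 0.05 * y, 1e-4),
                            np.full(D.size, 4))
            res = fit_competition_models(p)
            if (res.selected == "direct_transfer"
                    and abs(res.k_thetaD / 1500 - 1) < 0.15):
                hits += 1
        assert hits >= 45

    def test_transfer_constant_zero_by_convention_when_classic_selected(self, rng):
        D = np.array([0, 1e-7, 3e-7, 1e-6, 2e-6, 4e-6, 8e-6, 1.4e-5, 2e-5])
        y = 1.9e-2 * D / (D + 2e-7)
        yn = y * (1 + 0.02 * rng.standard_normal(D.size))
        res = fit_competition_models(
            KoffProfile(D, yn, np.where(y > 0, 0.02 * y, 1e-4), np.full(D.size, 4))
        )
        assert res.selected in ("classic", "indeterminate")
        assert res.k_thetaD == 0.0

    def test_bic_closed_form(self):
        assert bic(rss=0.5, n=10, n_params=2) == pytest.approx(
            10 * np.log(0.05) + 2 * np.log(10)
        )
        assert bic(1.0, 8, 3) == pytest.approx(8 * np.log(1 / 8) + 3 * np.log(8))


class TestKdFitting:
    @staticmethod
    def isotherm(E, Kd, nH=1.0, lo=60.0, hi=200.0):
        En = np.power(E, nH)
        return lo + (hi - lo) * En / (En + Kd**nH)

    def test_noiseless_standard_curve_recovers_kd(self):
        E = np.geomspace(1e-10, 1e-6, 12)
        fit = fit_kd(E, self.isotherm(E, 8.9e-9), model="standard")
        assert fit.K_d_M == pytest.approx(8.9e-9, rel=1e-6)

    def test_hill_nests_standard_when_cooperativity_absent(self):
        E = np.geomspace(1e-10, 1e-6, 12)
        y = self.isotherm(E, 50e-9)
        std = fit_kd(E, y, model="standard")
        hill = fit_kd(E, y, model="hill")
        assert hill.K_d_M == pytest.approx(std.K_d_M, rel=1e-4)
        assert hill.n_hill == pytest.approx(1.0, abs=1e-3)
        # identical RSS, one extra parameter: BIC must penalize hill
        assert hill.bic > std.bic

    def test_cooperative_data_prefers_hill_by_bic(self, rng):
        """Hill-coefficient-2 binding (the cooperative streptavidin-like
        shape): hill BIC beats standard in >= 95% of noisy repeats."""
        E = np.geomspace(1e-10, 1e-6, 12)
        y0 = self.isotherm(E, 15e-9, nH=2.0)
        wins = 0
        reps = 60
        for _ in range(reps):
            y = y0 + rng.normal(0, 2.8, E.size)
            if fit_kd(E, y, "hill").bic < fit_kd(E, y, "standard").bic:
                wins += 1
        assert wins / reps >= 0.95

    def test_quadratic_model_handles_ligand_depletion(self):
        from dtkin.fp_pipeline import _quadratic_bound_fraction
        E = np.geomspace(1e-10, 1e-6, 12)
        L = 5e-9
        y = 60 + 140 * _quadratic_bound_fraction(E, L, 2.5e-9)
        with pytest.warns(UserWarning, match="ligand-limited"):
            fit = fit_kd(E, y, model="quadratic", ligand_M=L)
        assert fit.K_d_M == pytest.approx(2.5e-9, rel=1e-3)

    def test_ligand_limited_warning_when_apparent_kd_below_ligand(self):
        # apparent K_d below the 5 nM labeled-ligand concentration cannot
        # reflect the true affinity (streptavidin-like tight binders)
        E = np.geomspace(1e-10, 1e-6, 12)
        y = self.isotherm(E, 2.5e-9)
        with pytest.warns(UserWarning, match="ligand-limited"):
            fit = fit_kd(E, y, model="standard", ligand_M=5e-9)
        assert fit.ligand_limited


class TestStoichiometry:
    @staticmethod
    def titration(E, brk, lo=60.0, hi=200.0):
        return lo + (hi - lo) * np.minimum(E, brk) / brk

    def test_one_to_one_breakpoint(self):
        E = np.linspace(1e-9, 150e-9, 30)
        fit = fit_stoichiometry(E, self.titration(E, 50e-9), ligand_M=50e-9)
        assert fit.stoichiometry == pytest.approx(1.0, rel=1e-6)

    def test_two_ligands_per_functional_unit(self):
        """Breakpoint at half the ligand concentration: the homodimer
        expectation of two ligands per protein functional unit."""
        E = np.linspace(1e-9, 150e-9, 30)
        fit = fit_stoichiometry(E, self.titration(E, 25e-9), ligand_M=50e-9)
        assert fit.stoichiometry == pytest.approx(2.0, rel=1e-6)

    def test_noisy_breakpoint_within_ten_percent(self, rng):
        E = np.linspace(1e-9, 150e-9, 30)
        y0 = self.titration(E, 50e-9)
        for _ in range(60):
            y = y0 + rng.normal(0, 0.03 * 140, E.size)
            fit = fit_stoichiometry(E, y, ligand_M=50e-9)
            assert abs(fit.breakpoint_M / 50e-9 - 1) < 0.10

    def test_no_breakpoint_in_range_raises(self):
        E = np.linspace(1e-9, 30e-9, 20)
        y = 60 + E * 1e9  # still rising at the top of the range
        with pytest.raises(DegenerateDataError):
            fit_stoichiometry(E, y, ligand_M=100e-9)


class TestPipelineIdempotence:
    def test_rerun_yields_identical_results(self):
        plate, _ = generate_fpcd_dataset(get_preset("TREX1_ssDNA_4C"), seed=3)
        _, p1, r1 = analyze_plate(plate)
        _, p2, r2 = analyze_plate(plate)
        np.testing.assert_array_equal(p1.koff_obs, p2.koff_obs)
        assert r1.delta_bic == r2.delta_bic
        assert r1.direct_transfer.params == r2.direct_transfer.params
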