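"""Stepwise MWC fitting: anchor fit, activation fit, mutant multipliers."""

import numpy as np
import pytest

from mwcgate.allosteric import MWCParameters, SensorOptics, apparent_hill, fluorescence_values
from mwcgate.mwcfit import (
    FitConfig,
    IdentifiabilityError,
    PanelRoster,
    SensorModel,
    fit_mutant_multipliers,
    fit_panel,
    modality_separation,
    sensitivity_scan,
    single_site_separation_scan,
    step1_anchor_fit,
    step1_fit_lpa,
    step2_activation_fit,
)
from mwcgate.reference import ANCHOR_L_PA, PUBLISHED_FACTORS, study_truth_parameters
from mwcgate.synth import (
    NON_FUNCTIONAL,
    GeneratorSpec,
    generate_current_panel,
    generate_fluorescence_panel,
    generate_mutant_panel,
)

PH11 = np.linspace(8.0, 3.0, 11)


def noise_free_fluor(params, optics, construct="X"):
    spec = GeneratorSpec(truth="mwc", params=params, optics=optics,
                         sigma=0.0, replicates=1, seed=0)
    return generate_fluorescence_panel(spec, construct)


class TestStep1:
    def test_noise_free_affinities_recovered(self, bim136_optics):
        truth = MWCParameters.two_state(3.6e-6, 1.0e-6, 100.0)
        fl = noise_free_fluor(truth, bim136_optics, "H235F")
        k_r, k_pa = step1_anchor_fit(fl, bim136_optics, FitConfig(), anchor_L_pA=100.0)
        assert k_r == pytest.approx(3.6e-6, rel=1e-4)
        assert k_pa == pytest.approx(1.0e-6, rel=1e-4)
        assert k_r >= k_pa

    def test_noisy_affinities_within_a_quarter(self, bim136_optics):
        truth = MWCParameters.two_state(3.6e-6, 1.0e-6, 100.0)
        spec = GeneratorSpec(truth="mwc", params=truth, optics=bim136_optics,
                             sigma=0.01, replicates=3, seed=1)
        fl = generate_fluorescence_panel(spec, "H235F")
        k_r, k_pa = step1_anchor_fit(fl, bim136_optics, FitConfig(), anchor_L_pA=100.0)
        assert abs(k_r / 3.6e-6 - 1) < 0.25
        assert abs(k_pa / 1.0e-6 - 1) < 0.25

    def test_direction_mismatch_rejected(self, bim136_optics):
        # a rising curve cannot come from a quenching sensor (F_R > F_pA)
        dequench = SensorOptics(F_R=0.30, F_pA=0.70, F_A=0.70)
        truth = MWCParameters.two_state(3.6e-6, 1.0e-6, 100.0)
        fl = noise_free_fluor(truth, dequench, "X")
        with pytest.raises(ValueError, match="direction mismatch"):
            step1_anchor_fit(fl, bim136_optics, FitConfig(), anchor_L_pA=100.0)

    def test_flat_series_rejected(self, bim136_optics):
        flat = MWCParameters.two_state(1.001e-6, 1.0e-6, 1.0)  # no drive
        fl = noise_free_fluor(flat, bim136_optics, "X")
        with pytest.raises(ValueError, match="flat series"):
            step1_anchor_fit(fl, bim136_optics, FitConfig(), anchor_L_pA=100.0)

    def test_unanchored_joint_fit_refused_as_under_determined(self, bim136_optics):
        truth = MWCParameters.two_state(3.6e-6, 1.0e-6, 100.0)
        fl = noise_free_fluor(truth, bim136_optics, "H235F")
        with pytest.raises(IdentifiabilityError, match="under-determined"):
            step1_anchor_fit(fl, bim136_optics, FitConfig(), anchor_L_pA=None)

    def test_isomerization_constant_recovery_and_monotonicity(self, bim136_optics):
        cfg = FitConfig()
        for l_true in (100.0, 1e4):
            truth = MWCParameters.two_state(3.6e-6, 1.0e-6, l_true)
            fl = noise_free_fluor(truth, bim136_optics)
            l_fit = step1_fit_lpa(fl, bim136_optics, 3.6e-6, 1.0e-6, cfg)
            assert l_fit == pytest.approx(l_true, rel=0.01)
        # larger L_pA stabilizes R: midpoint moves to higher [H+] (lower pH);
        # it must stay below (K_R/K_pA)^n ~ 605 for the midpoint to exist
        lo = MWCParameters.two_state(3.6e-6, 1.0e-6, 100.0)
        hi = MWCParameters.two_state(3.6e-6, 1.0e-6, 500.0)
        from mwcgate.allosteric import half_transition_ph

        assert half_transition_ph(hi, "pa") < half_transition_ph(lo, "pa")

    def test_noisy_isomerization_constant_within_factor_two(self, bim136_optics):
        truth = MWCParameters.two_state(3.6e-6, 1.0e-6, 1000.0)
        spec = GeneratorSpec(truth="mwc", params=truth, optics=bim136_optics,
                             sigma=0.01, replicates=3, seed=2)
        fl = generate_fluorescence_panel(spec)
        l_fit = step1_fit_lpa(fl, bim136_optics, 3.6e-6, 1.0e-6, FitConfig())
        assert 500.0 < l_fit < 2000.0


class TestStep2:
    def test_noise_free_activation_branch_recovered(self, sensor_truth, bim136_optics):
        fl = noise_free_fluor(sensor_truth, bim136_optics, "sensor")
        spec = GeneratorSpec(truth="mwc", params=sensor_truth, optics=bim136_optics,
                             sigma=0.0, replicates=1, seed=0)
        cur = generate_current_panel(spec, "sensor")
        cfg = FitConfig(K_pAp_fixed=None, K_Ap_fixed=None, refine_L_pA=False)
        params, rss = step2_activation_fit(
            fl, cur, sensor_truth.K_R, sensor_truth.K_pA, sensor_truth.L_pA,
            bim136_optics, cfg,
        )
        assert params.K_pAp == pytest.approx(sensor_truth.K_pAp, rel=1e-3)
        assert params.K_Ap == pytest.approx(sensor_truth.K_Ap, rel=1e-3)
        assert params.L_A == pytest.approx(sensor_truth.L_A, rel=1e-3)
        assert params.K_pAp > params.K_Ap
        assert params.K_Rp == params.K_pAp
        assert rss < 1e-10

    def test_fitted_model_reproduces_both_midpoints(self, sensor_truth, bim136_optics):
        from mwcgate.allosteric import half_transition_ph

        fl = noise_free_fluor(sensor_truth, bim136_optics, "sensor")
        spec = GeneratorSpec(truth="mwc", params=sensor_truth, optics=bim136_optics,
                             sigma=0.0, replicates=1, seed=0)
        cur = generate_current_panel(spec, "sensor")
        params, _ = step2_activation_fit(
            fl, cur, sensor_truth.K_R, sensor_truth.K_pA, sensor_truth.L_pA,
            bim136_optics, FitConfig(),
        )
        for which, optics in (("fluorescence-amplitude", bim136_optics), ("a", None)):
            assert half_transition_ph(params, which, optics) == pytest.approx(
                half_transition_ph(sensor_truth, which, optics), abs=0.1
            )

    def test_fluorescence_less_steep_than_current(self, sensor_truth, bim136_optics):
        # the pre-activation transition shows lower apparent cooperativity
        nh_fluor = apparent_hill(sensor_truth, "fluorescence-amplitude", bim136_optics)
        nh_current = apparent_hill(sensor_truth, "a")
        assert nh_fluor < nh_current


@pytest.fixture()
def sensor_model(sensor_truth, bim136_optics):
    return SensorModel("sensor", sensor_truth, bim136_optics, rss_per_point=1e-12)


class TestMutantMultipliers:
    def test_unit_multipliers_recovered_noise_free(self, sensor_model, sensor_truth, bim136_optics):
        spec = GeneratorSpec(truth="mwc", params=sensor_truth, optics=bim136_optics,
                             sigma=0.0, replicates=1, seed=0)
        fl = generate_fluorescence_panel(spec, "twin")
        cur = generate_current_panel(spec, "twin")
        ph = fit_mutant_multipliers(fl, cur, sensor_model, FitConfig(), construct="twin")
        assert ph.f_L_pA == pytest.approx(1.0, abs=0.02)
        assert ph.f_L_A == pytest.approx(1.0, abs=0.02)
        assert ph.quality == "ok"

    def test_published_style_factors_recovered_with_noise(self, sensor_model, sensor_truth, bim136_optics):
        truth = sensor_truth.with_multipliers(15.0, 10.0)
        spec = GeneratorSpec(truth="mwc", params=truth, optics=bim136_optics,
                             sigma=0.01, replicates=3, seed=1)
        panel = generate_mutant_panel(sensor_truth, bim136_optics, {"E26Q-like": (15.0, 10.0)},
                                      spec, sensor_name="unused")
        fl = [s for s in panel["E26Q-like"] if s.modality == "fluorescence"]
        cur = [s for s in panel["E26Q-like"] if s.modality == "current"]
        ph = fit_mutant_multipliers(fl, cur, sensor_model, FitConfig(), construct="E26Q-like")
        assert abs(ph.f_L_pA / 15.0 - 1) < 0.30
        assert abs(ph.f_L_A / 10.0 - 1) < 0.30

    def test_pre_activation_only_mutant_equalizes_midpoints(self, sensor_model, sensor_truth, bim136_optics):
        # strong R-stabilization: fluorescence change rides on A appearance
        truth = sensor_truth.with_multipliers(2000.0, 1.0)
        spec = GeneratorSpec(truth="mwc", params=truth, optics=bim136_optics,
                             sigma=0.005, replicates=3, seed=3)
        fl = generate_fluorescence_panel(spec, "Y28F-like")
        cur = generate_current_panel(spec, "Y28F-like")
        ph = fit_mutant_multipliers(fl, cur, sensor_model, FitConfig(), construct="Y28F-like")
        fitted = sensor_model.params.with_multipliers(ph.f_L_pA, ph.f_L_A)
        sep = modality_separation(fitted, bim136_optics)
        assert abs(sep) < 0.25
        assert modality_separation(sensor_model.params, bim136_optics) > 0.3

    def test_two_state_only_mode_reports_no_activation_factor(self, sensor_model, sensor_truth, bim136_optics):
        from dataclasses import replace

        from mwcgate.allosteric import TWO_STATE_LA

        truth = replace(sensor_truth, L_pA=sensor_truth.L_pA * 6.67, L_A=TWO_STATE_LA)
        spec = GeneratorSpec(truth="mwc", params=truth, optics=bim136_optics,
                             sigma=0.01, replicates=3, seed=2)
        fl = generate_fluorescence_panel(spec, "H235F-like")
        ph = fit_mutant_multipliers(fl, None, sensor_model, FitConfig(), construct="H235F-like")
        assert ph.f_L_A is None
        assert ph.quality == "two-state-only"
        assert ph.f_L_pA == pytest.approx(6.67, rel=0.25)

    def test_missing_fluorescence_rejected(self, sensor_model):
        with pytest.raises(ValueError, match="fluorescence"):
            fit_mutant_multipliers(None, None, sensor_model, FitConfig())

    def test_misfit_flagged_poor(self, sensor_truth, bim136_optics):
        # a demanding sensor reference: data from an incompatible (steep Hill)
        # truth cannot be matched by adjusting the two L's alone
        from mwcgate.synth import HillTruth

        sensor = SensorModel("sensor", sensor_truth, bim136_optics, rss_per_point=1e-6)
        spec = GeneratorSpec(
            truth="hill", hill=HillTruth(pH50=5.0, nH=6.0, F0=0.70, dF_signed=-0.20),
            sigma=0.0, replicates=1, seed=0,
        )
        fl = generate_fluorescence_panel(spec, "odd")
        ph = fit_mutant_multipliers(fl, None, sensor, FitConfig(), construct="odd")
        assert ph.quality == "poor"


class TestPanelAndScan:
    def test_full_chain_recovers_panel_factors(self, study_panel, bim136_optics):
        roster = PanelRoster(sensor="sensor", anchor_mutant="H235F",
                             mutants=list(PUBLISHED_FACTORS), optics=bim136_optics)
        pf = fit_panel(study_panel, roster, FitConfig(), anchor_L_pA=100.0)
        assert not pf.errors
        for name, (f_lpa, f_la) in PUBLISHED_FACTORS.items():
            ph = pf.phenotypes[name]
            assert abs(ph.f_L_pA / f_lpa - 1) < 0.30, name
            assert abs(ph.f_L_A / f_la - 1) < 0.30, name

    def test_anchor_scan_preserves_mutant_ranking(self, study_panel, bim136_optics):
        roster = PanelRoster(sensor="sensor", anchor_mutant="H235F",
                             mutants=list(PUBLISHED_FACTORS), optics=bim136_optics)
        cfg = FitConfig(anchor_L_pA=100.0, alternates=(1000.0,))
        table, correlations = sensitivity_scan(study_panel, roster, cfg)
        assert set(table["anchor"].unique()) == {100.0, 1000.0}
        assert correlations["f_L_pA[100 vs 1000]"] == pytest.approx(1.0)
        assert correlations["f_L_A[100 vs 1000]"] == pytest.approx(1.0)

    def test_nonpositive_anchor_rejected(self, study_panel, bim136_optics):
        roster = PanelRoster(sensor="sensor", anchor_mutant="H235F",
                             mutants=list(PUBLISHED_FACTORS), optics=bim136_optics)
        with pytest.raises(ValueError):
            fit_panel(study_panel, roster, FitConfig(), anchor_L_pA=-5.0)
        with pytest.raises(ValueError):
            FitConfig(anchor_L_pA=0.0)


class TestSiteClassSeparation:
    def test_single_site_cannot_separate_the_two_modalities(self):
        res = single_site_separation_scan(n_per_axis=8)
        assert res["n_combos"] == 8**5
        assert res["n_valid"] > 0
        assert res["max_separation_ph"] < 1.0

    def test_two_site_sensor_model_exceeds_tenfold_separation(self, bim250_optics):
        p250 = study_truth_parameters("Bim250-Y197")
        sep = modality_separation(p250, bim250_optics)
        assert sep > 1.0  # > 10-fold in proton concentration
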