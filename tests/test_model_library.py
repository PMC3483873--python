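"""Model-construction tests: normal model, NSCLC rules, PTEN loss, erlotinib."""

import numpy as np
import pytest

from egfrsim import (
    Scenario,
    SolverOptions,
    apply_erlotinib,
    apply_pten_loss,
    build_normal_model,
    build_nsclc_model,
    build_scenario,
    egf_dose_to_concentration,
    simulate,
    validate_network,
)
from egfrsim.errors import EgfrSimError, ValidationError
from egfrsim.model_library import (
    DOWNSTREAM_OVEREXPRESSION_FOLD,
    EGFR_OVEREXPRESSION_FOLD,
    MUTANT_INTERNALIZATION_FACTOR,
    erlotinib_dose_to_concentration,
)
from egfrsim.reaction_network import compile_rhs


class TestEgfDoseConversion:
    @pytest.mark.parametrize(
        "dose, expected",
        [
            (0.0, 0.0),
            (6.045, 1.0),          # inverse of the MW bridge
            (50.0, 8.271),         # the study stimulus
        ],
    )
    def test_known_conversions(self, dose, expected):
        assert egf_dose_to_concentration(dose) == pytest.approx(expected, rel=1e-3)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            egf_dose_to_concentration(-1.0)

    def test_erlotinib_umol_to_nM(self):
        assert erlotinib_dose_to_concentration(10.0) == 10_000.0


class TestNormalModel:
    def test_validates_with_no_violations(self):
        report = validate_network(build_normal_model())
        assert report.ok
        assert report.n_species > 30 and report.n_reactions > 40

    def test_pten_present_and_active(self):
        net = build_normal_model()
        assert net.species["PTEN"].initial_amount > 0

    def test_has_both_sos_recruitment_routes(self):
        net = build_normal_model()
        assert "sos_binding_direct" in net.reactions       # Grb2 route
        assert "sos_binding_shc" in net.reactions          # Shc-dependent route

    def test_unknown_constant_rejected(self):
        with pytest.raises(ValidationError):
            build_normal_model(constants={"k_warp": 1.0})


class TestNsclcConstruction:
    def test_egfr_scaled_threefold(self):
        base = build_normal_model()
        nsclc = build_nsclc_model(base)
        ratio = nsclc.species["EGFR"].initial_amount / base.species["EGFR"].initial_amount
        assert ratio == pytest.approx(EGFR_OVEREXPRESSION_FOLD)

    def test_downstream_factors_scaled_at_least_twofold(self):
        base = build_normal_model()
        nsclc = build_nsclc_model(base)
        for sid in ("Ras_GDP", "PI3K", "Akt", "STAT3c"):
            ratio = nsclc.species[sid].initial_amount / base.species[sid].initial_amount
            assert ratio >= DOWNSTREAM_OVEREXPRESSION_FOLD

    def test_internalization_constants_halved(self):
        base = build_normal_model()
        nsclc = build_nsclc_model(base)
        for rid, rxn in base.reactions.items():
            if rid.startswith("internalization_"):
                assert rxn.rate_law.k1 / nsclc.reactions[rid].rate_law.k1 == pytest.approx(
                    1.0 / MUTANT_INTERNALIZATION_FACTOR
                )

    def test_parameter_count_exceeds_normal_by_one(self):
        base = build_normal_model()
        nsclc = build_nsclc_model(base)
        assert nsclc.counts()[2] == base.counts()[2] + 1

    def test_double_application_raises(self):
        nsclc = build_nsclc_model(build_normal_model())
        with pytest.raises(EgfrSimError, match="double"):
            build_nsclc_model(nsclc)

    def test_missing_target_species_reported(self):
        base = build_normal_model()
        del base.species["PI3K"]
        with pytest.raises(EgfrSimError, match="PI3K"):
            build_nsclc_model(base)

    def test_modifications_recorded_in_metadata(self):
        nsclc = build_nsclc_model(build_normal_model())
        mods = nsclc.metadata["modifications"]
        assert {"kind": "scale_initial", "target": "EGFR",
                "factor": EGFR_OVEREXPRESSION_FOLD} in mods


class TestPtenLoss:
    def test_pten_catalyzed_flux_is_null_at_any_state(self):
        net = apply_pten_loss(build_nsclc_model(build_normal_model()))
        assert net.species["PTEN"].initial_amount == 0.0
        rhs = compile_rhs(net)
        rng = np.random.default_rng(11)
        j = list(net.reactions).index("pten_hydrolysis")
        for _ in range(10):
            state = rng.uniform(0, 100, size=len(net.species))
            state[net.species_index("PTEN")] = 0.0
            assert rhs.rates(state)[j] == 0.0

    def test_missing_pten_raises(self):
        net = build_normal_model()
        del net.species["PTEN"]
        with pytest.raises(EgfrSimError):
            apply_pten_loss(net)


class TestErlotinib:
    def test_dose_zero_is_dynamic_noop(self):
        opts = SolverOptions(t_end=400.0)
        treated = simulate(build_scenario(Scenario("nsclc_erlotinib", erlotinib_dose=0.0)), opts)
        untreated = simulate(build_scenario("nsclc"), opts)
        for sid in untreated.species_ids:
            assert np.allclose(treated.series(sid), untreated.series(sid), atol=1e-5)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            apply_erlotinib(build_normal_model(), -1.0)

    def test_drug_bath_is_constant_species(self):
        net = apply_erlotinib(build_nsclc_model(build_normal_model()), 10.0)
        assert net.species["erlotinib"].is_constant
        assert net.species["erlotinib"].initial_amount == 10_000.0


class TestScenario:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            Scenario("metastatic")

    def test_drug_scenarios_default_to_ic50_dose(self):
        assert Scenario("nsclc_erlotinib").erlotinib_dose == 10.0
        assert Scenario("nsclc").erlotinib_dose == 0.0

    def test_override_unknown_id_rejected(self):
        with pytest.raises(ValidationError, match="GHOST"):
            build_scenario(Scenario("normal", overrides={"GHOST": 1.0}))

    def test_override_changes_initial_amount(self):
        net = build_scenario(Scenario("normal", overrides={"PTEN": 75.0}))
        assert net.species["PTEN"].initial_amount == 75.0

    def test_egf_initial_set_from_dose(self):
        net = build_scenario(Scenario("normal", egf_dose=6.045))
        assert net.species["EGF"].initial_amount == pytest.approx(1.0)

    def test_clamp_egf_flag(self):
        net = build_scenario(Scenario("normal", clamp_egf=True))
        assert net.species["EGF"].is_constant


class TestDiseaseOrderings:
    """Qualitative orderings between the normal and NSCLC runs."""

    def test_receptor_phosphorylation_peak_delayed_in_nsclc(
        self, features_by_scenario
    ):
        assert (features_by_scenario["nsclc"]["pEGFR_total"].peak_time
                > features_by_scenario["normal"]["pEGFR_total"].peak_time)

    @pytest.mark.parametrize("name", ["RasGTP", "Raf1active"])
    def test_ras_raf_later_peak_and_shallower_decay_in_nsclc(
        self, name, scenario_trajectories, observables, features_by_scenario
    ):
        f_n = features_by_scenario["normal"][name]
        f_c = features_by_scenario["nsclc"][name]
        assert f_c.peak_time > f_n.peak_time
        # beyond the normal peak the disease curve stays above the normal one
        # (5% amplitude tolerance absorbs the brief crossover at the peak itself)
        traj_n = scenario_trajectories["normal"]
        traj_c = scenario_trajectories["nsclc"]
        sel = traj_n.times > f_n.peak_time
        a = traj_c.observable(observables[name])[sel]
        b = traj_n.observable(observables[name])[sel]
        assert np.all(a >= b - 0.05 * b.max())

    def test_nsclc_nuclear_stat3_dimer_still_high_at_800s(
        self, scenario_trajectories, observables
    ):
        traj = scenario_trajectories["nsclc"]
        series = traj.observable(observables["STAT3n_dimer"])
        i800 = int(np.searchsorted(traj.times, 800.0))
        assert series[i800] >= 0.5 * series.max()

    def test_wt_surface_receptor_decays_faster_over_100s(self, receptor_trajectories):
        from egfrsim.kinetics_features import standard_observables_for

        wt = receptor_trajectories["wt"]
        mut = receptor_trajectories["mutant"]
        sel = wt.times <= 100.0
        s_wt = wt.observable(standard_observables_for(wt))
        s_mut = mut.observable(standard_observables_for(mut))
        assert s_wt[sel][-1] / s_wt[0] < s_mut[sel][-1] / s_mut[0]

    def test_frozen_internalization_keeps_downstream_near_normal(
        self, features_by_scenario, observables, solver_options
    ):
        """With internalization held at wild-type rates, the other disease
        edits leave pAkt and ppMEK peak amplitudes within ~25% of normal and
        the remaining observables within a factor of two — in contrast to the
        full disease model, whose ppERK peak is ~30x normal."""
        from egfrsim import simulate
        from egfrsim.kinetics_features import extract_features
        from egfrsim.model_library import set_egf

        net = build_nsclc_model(build_normal_model())
        for rid, rxn in net.reactions.items():
            if rid.startswith("internalization_"):
                rxn.rate_law.k1 /= MUTANT_INTERNALIZATION_FACTOR
        net.touch()
        set_egf(net, 50.0)
        traj = simulate(net, solver_options)
        for name, bound in (("pAkt", 1.25), ("ppMEK", 1.35), ("ppERK", 2.0),
                            ("STAT3n_dimer", 2.0)):
            amp = extract_features(traj.observable(observables[name]), traj.times).peak_amplitude
            ratio = amp / features_by_scenario["normal"][name].peak_amplitude
            assert 1.0 / bound <= ratio <= bound, (name, ratio)
        full_fold = (features_by_scenario["nsclc"]["ppERK"].peak_amplitude
                     / features_by_scenario["normal"]["ppERK"].peak_amplitude)
        assert full_fold > 10.0
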