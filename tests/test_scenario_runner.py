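import numpy as np
import pytest

from circgenome.model_core import make_default_parameters
from circgenome.scenario_runner import (InoculationEvent, Intervention,
                                        PRESET_NAMES, ScenarioConfig,
                                        StopRule, preset, run, scale_config)
from circgenome.species_classifier import reverse_complement
from circgenome.observers_io import (config_from_dict, config_to_dict,
                                     write_timeseries)


class TestPresets:
    def test_one_gene_inoculation(self):
        cfg = preset("fig2a")
        (ev,) = cfg.inoculations
        assert ev.step == 10_000 and ev.interval == 0
        assert (cfg.parameters.CS_REP, "linear", 50) in ev.molecules
        assert (cfg.parameters.CS_CT, "linear", 50) in ev.molecules

    def test_intermittent_inoculation_and_stop_rule(self):
        cfg = preset("fig2b")
        (ev,) = cfg.inoculations
        assert ev.interval == 10_000
        assert [m[2] for m in ev.molecules] == [1, 1]
        assert cfg.stop_rule is not None
        assert cfg.stop_rule.category == "cir_rep"

    def test_role_analysis_interventions(self):
        cfg = preset("fig3")
        steps = [(iv.step, iv.parameter) for iv in cfg.interventions]
        assert (2_500_000, "F_LT") in steps
        assert (5_000_000, "P_TLR") in steps
        flt_iv = cfg.interventions[0]
        assert flt_iv.scope is not None
        # templating is switched off for REP and its complement
        assert set(flt_iv.scope.contains_any) == {
            "GAGUCUCU", reverse_complement("GAGUCUCU")}

    def test_template_capability_scope_excludes_complement(self):
        cfg = preset("fig4a")
        values = []
        for iv in cfg.interventions:
            assert iv.parameter == "F_LT"
            assert iv.scope.contains_any == ("GAGUCUCU",)
            assert reverse_complement("GAGUCUCU") not in iv.scope.contains_any
            values.append(iv.value)
        assert values == [0.2, 0.1, 0.0]

    def test_no_circularization_variant(self):
        assert preset("fig4b").parameters.P_EL == 0.0
        assert preset("fig4a").parameters.P_EL > 0.0

    def test_two_gene_inoculation(self):
        cfg = preset("fig7a")
        (ev,) = cfg.inoculations
        seqs = {m[0] for m in ev.molecules}
        assert "GAGUCUCU" + "UGAUGCAG" in seqs
        assert "ACGAACUG" + "AACGCUCG" in seqs
        assert all(m[1] == "circular" and m[2] == 100 for m in ev.molecules)

    def test_noncoding_variant_overrides(self):
        cfg = preset("fig7b")
        p = cfg.parameters
        assert (p.T_NPB, p.P_BB, p.P_FP, p.P_NDE, p.P_NF) == \
            (200_000, 2e-5, 0.01, 0.002, 0.001)
        seqs = {m[0] for m in cfg.inoculations[0].molecules}
        assert "GAGUCUCU" + "UGACGCAG" in seqs
        assert "ACUGACGU" + "UGACGCAG" in seqs

    def test_duplication_variant_uses_near_rep_second_gene(self):
        cfg = preset("s2")
        p = cfg.parameters
        # the second characteristic sequence is one substitution from REP
        diffs = sum(a != b for a, b in zip(p.CS_NR, p.CS_REP))
        assert diffs == 1
        assert "GAGUCUCU" * 2 in {m[0] for m in
                                  cfg.inoculations[0].molecules}

    def test_seed_variants_differ_only_by_seed(self):
        a, b = preset("fig2a"), preset("fig5a")
        assert a.seed != b.seed
        assert a.inoculations[0].molecules == b.inoculations[0].molecules

    def test_scaled_variant_shrinks_proportionally(self):
        full, scaled = preset("fig2a"), preset("fig2a_scaled")
        assert scaled.parameters.N == full.parameters.N // 2
        assert scaled.parameters.T_NPB == full.parameters.T_NPB // 4
        assert scaled.steps == full.steps // 10
        assert scaled.inoculations[0].step == full.inoculations[0].step // 10

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="fig2a"):
            preset("fig99")

    def test_all_presets_construct_and_validate(self):
        for name in PRESET_NAMES:
            preset(name).validate()


class TestConfigValidation:
    def test_zero_steps_rejected(self):
        cfg = ScenarioConfig(steps=0)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_topology_rejected(self):
        cfg = ScenarioConfig(inoculations=[
            InoculationEvent(0, [("GAGU", "helix", 1)])])
        with pytest.raises(ValueError, match="topology"):
            cfg.validate()

    def test_unknown_intervention_parameter_rejected(self):
        cfg = ScenarioConfig(interventions=[Intervention(0, "P_XX", 0.5)])
        with pytest.raises(ValueError, match="P_XX"):
            cfg.validate()

    def test_out_of_range_intervention_value_rejected(self):
        cfg = ScenarioConfig(interventions=[Intervention(0, "P_TLR", 1.5)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_scoped_intervention_limited_to_flt(self):
        from circgenome.event_engine import SpeciesScope
        cfg = ScenarioConfig(interventions=[
            Intervention(0, "P_TLR", 0.0, SpeciesScope("linear"))])
        with pytest.raises(ValueError, match="F_LT"):
            cfg.validate()

    def test_config_yaml_round_trip(self):
        cfg = preset("fig3")
        d = config_to_dict(cfg)
        cfg2 = config_from_dict(d)
        assert config_to_dict(cfg2) == d


class TestRun:
    def test_minimal_run_returns_one_census_of_zeros(self):
        cfg = ScenarioConfig(
            parameters=make_default_parameters().replace(N=2, T_NPB=0),
            steps=1, observe_every=1)
        res = run(cfg)
        assert len(res.censuses) == 1
        assert all(v == 0 for v in res.censuses[0].counts.values())

    def test_run_is_deterministic_and_byte_identical(self, tmp_path):
        cfg = ScenarioConfig(
            parameters=make_default_parameters().replace(N=3, T_NPB=400),
            steps=400, observe_every=100, seed=5,
            inoculations=[InoculationEvent(10, [("GAGUCUCU", "linear", 5)])])
        blobs = []
        for i in range(2):
            res = run(cfg)
            out = tmp_path / f"ts{i}.tsv"
            write_timeseries(res.censuses, out)
            blobs.append(out.read_bytes())
        assert blobs[0] == blobs[1]

    def test_mass_accounting_includes_inoculations(self):
        cfg = ScenarioConfig(
            parameters=make_default_parameters().replace(N=3, T_NPB=300),
            steps=300, observe_every=100, seed=2,
            inoculations=[InoculationEvent(
                50, [("GAGUCUCU", "linear", 4)], interval=100)])
        res = run(cfg)
        st = res.state
        assert st.total_mass() == st.target_mass()
        assert st.inoculated_mass >= 3 * 4 * 8

    def test_intervention_prefix_identity(self):
        base = ScenarioConfig(
            parameters=make_default_parameters().replace(N=3, T_NPB=600),
            steps=600, observe_every=100, seed=8,
            inoculations=[InoculationEvent(10, [("GAGUCUCU", "linear", 6)])])
        with_iv = ScenarioConfig(
            parameters=base.parameters, steps=base.steps,
            observe_every=100, seed=8,
            inoculations=list(base.inoculations),
            interventions=[Intervention(300, "P_TLR", 0.0)])
        a = run(base).censuses
        b = run(with_iv).censuses
        for ca, cb in zip(a, b):
            if ca.step < 300:
                assert ca.counts == cb.counts

    def test_no_rings_ever_without_end_to_end_ligation(self):
        cfg = ScenarioConfig(
            parameters=make_default_parameters().replace(
                N=3, T_NPB=800, P_EL=0.0),
            steps=1500, observe_every=100, seed=4,
            inoculations=[InoculationEvent(10, [("GAGUCUCU", "linear", 8)])])
        res = run(cfg)
        for c in res.censuses:
            for cat in ("cir_rep", "cir_repcom", "cir_ct", "cir_ctcom",
                        "cir_repnr", "cir_nr"):
                assert c.counts[cat] == 0

    def test_reference_engine_agrees_on_contract(self):
        cfg = ScenarioConfig(
            parameters=make_default_parameters().replace(N=3, T_NPB=200),
            steps=50, observe_every=10, seed=1)
        res = run(cfg, engine="reference")
        assert len(res.censuses) == 5
        from circgenome.model_core import total_mass
        assert total_mass(res.state) == res.state.target_mass()
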