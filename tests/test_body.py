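"""Structural assembly and interleg / contralateral pathway rules."""

import json

import pytest

import hexawalk as hw
from hexawalk.body import ipsilateral_inhibition, contralateral_drive
from hexawalk.gates import compute_sensory
from hexawalk.params import ModelParams, InterlegParams, ContralateralConfig


class TestAssemblyCounts:
    def test_full_model_counts(self):
        c = hw.assemble().counts
        assert c["cpgs"] == 18
        assert c["motoneurons"] == 72
        assert c["interneurons"] == 108
        assert c["neuronal_first_order_odes"] == 648
        assert c["muscle_second_order_odes"] == 18

    def test_single_side_has_nine_units(self):
        c = hw.assemble(legs=["L1", "L2", "L3"]).counts
        assert c["neuromuscular_units"] == 9

    def test_per_leg_tally(self):
        c = hw.assemble(legs=["L2"]).counts
        assert (c["cpgs"], c["motoneurons"], c["interneurons"]) == (3, 12, 18)
        assert c["neuronal_first_order_odes"] == 108  # 36 neurons x 3

    def test_counts_invariant_under_slow_muscle_toggle(self):
        assert (hw.assemble(enable_slow=True).counts
                == hw.assemble(enable_slow=False).counts)

    def test_summary_json_and_synapse_signs(self):
        asm = hw.assemble()
        summary = json.loads(asm.summary_json())
        assert summary["counts"]["neurons"] == 216
        syns = summary["synapses"]
        # premotor INs inhibit their MNs; CPG -> IN is excitatory
        assert all(s["E"] < -40 for s in syns if "in->mn" in s["label"])
        assert all(s["E"] > -40 for s in syns if "cpg->in" in s["label"])
        # CPG half-centers are mutually inhibitory
        assert all(s["E"] < -40 for s in syns if " cpg " in s["label"])

    def test_unknown_leg_rejected(self):
        with pytest.raises(ValueError):
            hw.assemble(legs=["L4"])

    def test_variant_without_left_legs_rejected(self):
        p = ModelParams()
        p.contralateral.l2_to_r2_inhibition = True
        with pytest.raises(ValueError):
            hw.assemble(p, legs=["R1", "R2", "R3"])


class TestIpsilateralRule:
    P = InterlegParams()

    def g(self, beta, dbeta):
        return ipsilateral_inhibition(beta, dbeta, self.P.g_inh9, self.P)

    def test_quadrant_table(self):
        full = self.P.g_inh9
        tonic = self.P.tonic_fraction * full
        # (beta, dbeta) -> expected level
        table = [
            (31.0, 0.0, tonic),      # grounded, stationary: tonic hold
            (31.0, 0.2, full),       # lifting off
            (45.0, 0.3, full),       # rising in swing
            (55.0, -0.1, full),      # falling but still high
            (38.0, -0.2, 0.0),       # descending below release angle
            (31.0, -0.05, 0.0),      # settling into contact
        ]
        for beta, dbeta, expected in table:
            assert self.g(beta, dbeta) == pytest.approx(expected), \
                (beta, dbeta)

    def test_bounded_by_maximum(self):
        for beta in (30.0, 40.0, 50.0, 60.0):
            for dbeta in (-0.5, 0.0, 0.5):
                assert 0.0 <= self.g(beta, dbeta) <= self.P.g_inh9

    def test_periodic_input_gives_periodic_inhibition(self):
        import numpy as np
        t = np.arange(0, 4000)
        beta = 45.0 + 15.0 * np.sin(2 * np.pi * t / 1000.0)
        dbeta = np.gradient(beta)
        g = np.array([self.g(b, d) for b, d in zip(beta, dbeta)])
        assert np.array_equal(g[:1000], g[1000:2000])


class TestContralateralDrive:
    CFG = ContralateralConfig()

    def sensors(self, l2=31.0, l3=31.0):
        return {"L2": compute_sensory(l2, 0.0, 75.0),
                "L3": compute_sensory(l3, 0.0, 75.0)}

    def test_normal_walking_pair_pathways_silent(self):
        out = contralateral_drive(self.sensors(l2=55.0), "normal", self.CFG)
        assert not out["front_pair_active"]
        assert not out["hind_pair_active"]

    def test_transition_excites_r3_when_l2_lifted(self):
        out = contralateral_drive(self.sensors(l2=55.0),
                                  "tripod_transition", self.CFG)
        assert out["R3_levator_exc"] > self.CFG.g_l2r3_rest

    def test_active_hind_pair_suppresses_front_pair(self):
        out = contralateral_drive(self.sensors(), "tripod_transition",
                                  self.CFG, active_pair_segment=3)
        assert out["hind_pair_active"] and not out["front_pair_active"]

    def test_all_grounded_no_currents(self):
        out = contralateral_drive(self.sensors(), "normal", self.CFG)
        assert out["R2_levator_inh"] == 0.0
        assert out["R3_levator_inh"] == 0.0
        assert out["R3_levator_exc"] == self.CFG.g_l2r3_rest


def test_yaml_parameter_overrides(tmp_path):
    cfg = tmp_path / "params.yaml"
    cfg.write_text(
        "interleg:\n  g_inh3: 0.1\n"
        "gates:\n  beta_crit: 34.0\n"
        "drives:\n  tripod:\n    ld: [0.25, 0.33]\n")
    p = ModelParams.from_yaml(cfg)
    assert p.interleg.g_inh3 == 0.1
    assert p.gates.beta_crit == 34.0
    assert p.drives["tripod"].ld == (0.25, 0.33)
    with pytest.raises(KeyError):
        bad = tmp_path / "bad.yaml"
        bad.write_text("nonsense:\n  x: 1\n")
        ModelParams.from_yaml(bad)
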