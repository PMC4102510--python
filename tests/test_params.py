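"""Parameter defaults, interspecies scaling rules and parameter-file IO."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bapkin import params as P


class TestScalingOps:
    def test_morimoto_skin_factor_value(self):
        # frozen from evaluating the printed expression in 64-bit floats
        expected = ((1.17e-7 * 6.19**0.751 + 2.73e-8)
                    / (14.78e-7 * 6.19**0.589 + 8.33e-8))
        assert P.morimoto_skin_factor() == pytest.approx(expected, rel=1e-12)
        assert P.morimoto_skin_factor() == pytest.approx(0.1105, abs=5e-5)
        assert 0.0 < P.morimoto_skin_factor() < 1.0

    def test_skin_factor_preserves_zero(self):
        assert P.scale_skin_permeability(0.0) == 0.0

    @pytest.mark.parametrize("fn, rat, expected", [
        (P.scale_rate_by_gfr, 0.0, 0.0),
        (P.scale_rate_by_gfr, 1.0, 125.0 / 1.31),
        (P.scale_rate_by_gfr, 1.31, 125.0),
        (P.scale_rate_by_bileflow, 0.0, 0.0),
        (P.scale_rate_by_bileflow, 1.0, 350.0 / 22.5),
        (P.scale_rate_by_bileflow, 22.5, 350.0),
    ])
    def test_rate_scaling(self, fn, rat, expected):
        assert fn(rat) == pytest.approx(expected, rel=1e-12)

    def test_rate_scaling_rejects_negative(self):
        with pytest.raises(ValueError):
            P.scale_rate_by_gfr(-1.0)
        with pytest.raises(ValueError):
            P.scale_rate_by_bileflow(-0.5)

    def test_metabolic_clearance_scaling(self):
        assert P.scale_metabolic_clearance(5.0, 1.0) == 5.0
        # rat value back-computed from the human default and the fitted constant
        rat = 951.69e3 / 1020.03
        assert P.scale_metabolic_clearance(rat, 1020.03) == pytest.approx(
            951.69e3, rel=1e-12)
        assert rat == pytest.approx(933.0, rel=1e-3)
        with pytest.raises(ValueError):
            P.scale_metabolic_clearance(0.0, 1020.03)

    @given(st.floats(1e-6, 1e6), st.floats(1e-3, 1e4))
    def test_clearance_scaling_round_trips(self, rat, c):
        scaled = P.scale_metabolic_clearance(rat, c)
        assert scaled / c == pytest.approx(rat, rel=1e-12)

    @given(st.floats(1e-9, 1e6))
    def test_gfr_scaling_round_trips(self, rat):
        assert P.scale_rate_by_gfr(rat) / (125.0 / 1.31) == pytest.approx(
            rat, rel=1e-12)


class TestDefaults:
    def test_pbpk_defaults_match_published_table(self, params):
        bap, met = params.bap, params.ohbap
        assert bap.p_lung == 2670.00
        assert bap.pa_lung == 80.70
        assert bap.clearance == 951.69e3
        assert bap.f_metabolite == 0.185
        assert bap.k_bile == 0.338
        assert bap.k_feces == 0.334
        assert bap.k_p == 0.00132
        assert bap.p_vehicle == 1.0
        assert bap.p_blood_air == 2.04
        assert met.p_kidney == 40.40
        assert met.pa_adipose == 0.711
        assert met.pa_kidney == 12.90
        assert met.clearance == 37.13e3
        assert met.k_bile == 663.80
        assert met.k_kidney_bladder == 60.40
        assert met.k_bladder_urine == 0.102
        assert met.k_feces == 0.173
        assert met.k_gut_reabsorption == 0.00693

    def test_tk_defaults(self, tk):
        assert tk.k_b == 0.19826
        assert tk.ka_inh == 0.04835
        assert tk.ka_der == 0.06181
        assert tk.alpha_inh == 0.0399
        assert tk.alpha_der == 0.0164
        assert all(v > 0 for v in (tk.ka_inh, tk.ka_der, tk.k_b))

    def test_presence_pattern_enforced(self):
        with pytest.raises(ValueError, match="not part of this chemical"):
            P.ChemicalPBPKParams(
                chemical="bap", p_lung=1, p_adipose=1, p_skin=1, p_kidney=1,
                p_liver=1, p_rest=1, pa_lung=1, pa_adipose=1.0,  # bad for BaP
                clearance=1, f_metabolite=0.5, k_bile=1, k_feces=1,
                k_p=1, p_vehicle=1, p_blood_air=1)
        with pytest.raises(ValueError, match="must be present"):
            P.ChemicalPBPKParams(
                chemical="3ohbap", p_lung=1, p_adipose=1, p_skin=1,
                p_kidney=1, p_liver=1, p_rest=1, pa_lung=1)

    def test_physiology_flow_invariant(self):
        ph = P.human_physiology()
        total = ph.q_adipose + ph.q_skin + ph.q_kidney + ph.q_liver + ph.q_rest
        assert total <= ph.cardiac_output * (1 + 1e-9)
        with pytest.raises(ValueError, match="cardiac output"):
            P.SpeciesPhysiology(
                species="human", v_blood=1, v_lung=1, v_adipose=1, v_skin=1,
                v_kidney=1, v_liver=1, v_rest=1, cardiac_output=10.0,
                q_adipose=5, q_skin=5, q_kidney=5, q_liver=5, q_rest=5,
                alveolar_ventilation=1, skin_area_cm2=1, gfr_ml_min=1,
                bile_flow_ml_day=1)


class TestParamIO:
    def test_round_trip(self, params, tmp_path):
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            P.save_params(params, path)
            loaded = P.load_params(path)
            assert loaded.bap == params.bap
            assert loaded.ohbap == params.ohbap

    def test_kkbr_synonym_accepted(self, params, tmp_path):
        import yaml
        path = tmp_path / "p.yaml"
        P.save_params(params, path)
        doc = yaml.safe_load(path.read_text())
        doc["3-OHBaP"]["K_kbr"] = doc["3-OHBaP"].pop("K_kb")
        path.write_text(yaml.safe_dump(doc))
        assert P.load_params(path).ohbap.k_kidney_bladder == 60.40

    def test_unknown_symbol_rejected(self, params, tmp_path):
        import yaml
        path = tmp_path / "p.yaml"
        P.save_params(params, path)
        doc = yaml.safe_load(path.read_text())
        doc["BaP"]["K_xyz"] = 1.0
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValueError, match="K_xyz"):
            P.load_params(path)
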