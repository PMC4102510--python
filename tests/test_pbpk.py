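"""PBPK engine: vector field, exact propagation, mass balance, linearity."""

import numpy as np
import pytest

from bapkin.exposure import ExposureScenario, ExposureWindow
from bapkin.pbpk import (M_BLAD, N_STATES, PBPKModel, STATE_NAMES,
                         mass_balance_report, simulate)

from conftest import piecewise_ode_solution


class TestDerivatives:
    def test_zero_state_no_exposure_is_equilibrium(self, model):
        scen = ExposureScenario((), 24.0, "empty")
        rates = model.derivatives(0.0, np.zeros(N_STATES), scen)
        assert np.all(rates == 0.0)

    def test_bladder_only_state_excretes_at_kbu(self, model):
        scen = ExposureScenario((), 24.0)
        state = np.zeros(N_STATES)
        state[M_BLAD] = 5.0
        rates = model.derivatives(1.0, state, scen)
        i_urine = STATE_NAMES.index("ohbap_urine")
        assert rates[i_urine] == pytest.approx(0.102 * 5.0, rel=1e-12)
        assert rates[M_BLAD] == pytest.approx(-0.102 * 5.0, rel=1e-12)

    def test_vector_field_conserves_mass(self, model, rng_state=None):
        """Sum of compartment + sink rates equals input rates at random states."""
        rng = np.random.default_rng(7)
        scen = ExposureScenario(
            (ExposureWindow("inhalation", 0, 8, 100.0),
             ExposureWindow("dermal", 0, 8, 10.0)), 24.0)
        f = model.params.bap.f_metabolite
        for _ in range(10):
            state = rng.uniform(0, 10, N_STATES)
            r = model.derivatives(2.0, state, scen)
            names = STATE_NAMES
            bap_pool = sum(r[names.index(n)] for n in names[:9])
            m_pool = sum(r[names.index(n)] for n in names[9:20])
            sinks = (r[names.index("bap_exhaled")]
                     + (1 - f) * r[names.index("bap_metabolized")]
                     + r[names.index("ohbap_other_metabolites")])
            inputs = (r[names.index("absorbed_inhalation")]
                      + r[names.index("absorbed_dermal")]
                      + r[names.index("absorbed_oral")])
            assert bap_pool + m_pool + sinks == pytest.approx(
                inputs, rel=1e-9, abs=1e-9)

    def test_negative_state_guard(self, model):
        scen = ExposureScenario((), 24.0)
        state = np.zeros(N_STATES)
        state[0] = -1.0
        with pytest.raises(FloatingPointError):
            model.derivatives(0.0, state, scen)


class TestSimulate:
    def test_zero_exposure_stays_zero(self, model):
        scen = ExposureScenario((), 48.0, "null")
        traj = model.simulate(scen, dt=0.5)
        assert np.all(traj.states == 0.0)
        assert mass_balance_report(traj) == 0.0

    def test_matches_independent_ode_integration(self, model, inhalation_8h):
        """Exact propagator vs adaptive BDF on the same vector field."""
        t_eval = np.linspace(0.0, 48.0, 25)
        ode = piecewise_ode_solution(model, inhalation_8h, t_eval)
        traj = model.simulate(inhalation_8h, grid=t_eval)
        exact = np.vstack([traj.states[np.argmin(np.abs(traj.times - t))]
                           for t in t_eval])
        scale = np.max(np.abs(exact), axis=0, keepdims=True)
        scale[scale == 0] = 1.0
        assert np.max(np.abs(exact - ode) / scale) < 1e-7

    def test_dose_linearity(self, model, multiroute_week):
        base = model.simulate(multiroute_week, dt=1.0)
        for lam in (0.5, 2.0, 10.0):
            scaled = model.simulate(multiroute_week.scaled(lam), dt=1.0)
            ref = lam * base.states
            dev = np.abs(scaled.states - ref) / np.maximum(np.abs(ref), 1e-300)
            assert np.max(dev) < 1e-8

    def test_states_stay_nonnegative(self, model, multiroute_week):
        traj = model.simulate(multiroute_week, dt=0.25)
        assert traj.states.min() >= -1e-9

    def test_cumulative_outputs_nondecreasing(self, model, multiroute_week):
        traj = model.simulate(multiroute_week, dt=0.25)
        for name in ("ohbap_urine", "bap_feces", "ohbap_feces",
                     "bap_metabolized", "absorbed_dermal", "bap_exhaled"):
            assert np.all(np.diff(traj.series(name)) >= -1e-12)

    def test_urine_bounded_by_formed_metabolite(self, model, multiroute_week):
        traj = model.simulate(multiroute_week, dt=0.5)
        f = model.params.bap.f_metabolite
        assert traj.urine_cumulative()[-1] <= f * traj.series(
            "bap_metabolized")[-1] + 1e-15

    def test_grid_refinement_is_inert(self, model, inhalation_8h):
        """The propagator is exact: halving the step leaves urine unchanged."""
        u1 = model.simulate(inhalation_8h, dt=0.2).urine_cumulative()[-1]
        u2 = model.simulate(inhalation_8h, dt=0.1).urine_cumulative()[-1]
        assert u2 == pytest.approx(u1, rel=1e-9)

    def test_urinary_excretion_continues_after_exposure(self, model,
                                                        inhalation_8h):
        """Slow release from storage organs keeps urine flowing post-shift."""
        traj = model.simulate(inhalation_8h, dt=0.5)
        rate = traj.urinary_rate()
        after = rate[traj.times > 120.0]
        assert np.all(after > 0.0)

    def test_route_signature_dermal_peaks_later(self, model):
        """For equal absorbed amounts, dermal urinary peak lags inhalation."""
        inh = ExposureScenario(
            (ExposureWindow("inhalation", 0, 8, 1000.0),), 168.0)
        t_inh = model.simulate(inh, dt=0.05)
        absorbed = t_inh.series("absorbed_inhalation")[-1]
        bap = model.params.bap
        area = model.params.physiology.skin_area_cm2
        level = absorbed / (bap.k_p * area * bap.p_vehicle * 1e-6 * 8.0)
        der = ExposureScenario((ExposureWindow("dermal", 0, 8, level),), 168.0)
        t_der = model.simulate(der, dt=0.05)
        assert t_der.series("absorbed_dermal")[-1] == pytest.approx(
            absorbed, rel=1e-9)
        peak_inh = t_inh.times[np.argmax(t_inh.urinary_rate())]
        peak_der = t_der.times[np.argmax(t_der.urinary_rate())]
        assert peak_der > peak_inh


class TestMassBalance:
    def test_default_tolerance_met(self, model, multiroute_week):
        traj = model.simulate(multiroute_week, dt=0.5)
        assert mass_balance_report(traj) < 1e-6

    def test_corrupted_trajectory_flagged(self, model, inhalation_8h):
        from dataclasses import replace
        traj = model.simulate(inhalation_8h, dt=1.0)
        states = traj.states.copy()
        states[len(states) // 2:, 0] *= 1.5  # inject a bookkeeping error
        bad = replace(traj, states=states)
        assert mass_balance_report(bad) > 1e-6

    def test_oral_route_enters_balance(self, params):
        from dataclasses import replace as drep
        bap = drep(params.bap, k_oral=0.1)
        model = PBPKModel(drep(params, bap=bap))
        scen = ExposureScenario((ExposureWindow("oral", 2, 3, 50.0),), 96.0)
        traj = model.simulate(scen, dt=0.5)
        assert traj.series("absorbed_oral")[-1] == pytest.approx(50.0, rel=1e-9)
        assert mass_balance_report(traj) < 1e-6
        assert traj.series("bap_metabolized")[-1] > 0.0
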