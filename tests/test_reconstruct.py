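"""Chi-square statistic, candidate generation and exposure-dose recovery."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bapkin.exposure import worker_fixture
from bapkin.reconstruct import (candidate_levels, fit_exposure, pearson_chi2,
                                route_comparison)
from bapkin.synthetic import SyntheticSpec, generate_worker_dataset


@pytest.fixture(scope="module")
def dermal_template():
    fx = worker_fixture(1)
    return replace(fx.simulated, windows=fx.simulated.by_route("dermal"))


class TestChi2:
    def test_perfect_fit_is_zero(self):
        assert pearson_chi2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_value(self):
        assert pearson_chi2([2.0, 3.0], [1.0, 3.0]) == 1.0

    @given(st.floats(0.1, 100.0))
    def test_homogeneity_degree_one(self, lam):
        o = np.array([2.0, 5.0, 1.0])
        e = np.array([1.5, 4.0, 2.0])
        assert pearson_chi2(lam * o, lam * e) == pytest.approx(
            lam * pearson_chi2(o, e), rel=1e-12)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([1.0], [0.0])


class TestCandidates:
    def test_single_candidate_is_center(self):
        assert candidate_levels(5.0, n=1).tolist() == [5.0]

    @given(st.floats(1e-3, 1e3), st.integers(2, 200))
    def test_candidates_within_interval(self, center, n):
        levels = candidate_levels(center, n=n, spread=10.0,
                                  rng=np.random.default_rng(0))
        assert np.all(levels >= center / 10.0 * (1 - 1e-12))
        assert np.all(levels <= center * 10.0 * (1 + 1e-12))

    def test_seed_reproducibility(self):
        a = candidate_levels(1.0, 50, rng=np.random.default_rng(4))
        b = candidate_levels(1.0, 50, rng=np.random.default_rng(4))
        assert np.array_equal(a, b)


class TestFit:
    def test_noiseless_recovery_within_2_percent(self, dermal_template):
        """Single free dose, no noise: the thousand-candidate search lands
        within 2% of the generating level."""
        obs, _ = generate_worker_dataset(
            SyntheticSpec(scenario=dermal_template, model="tk", cv=0.0, seed=0))
        res = fit_exposure(obs, dermal_template, model="tk", free=[0],
                           n_iter=2000, seed=1)
        assert res.levels[0] == pytest.approx(
            dermal_template.windows[0].level, rel=0.02)

    def test_noisy_recovery_within_noise_scale(self, dermal_template):
        obs, _ = generate_worker_dataset(
            SyntheticSpec(scenario=dermal_template, model="tk", cv=0.15,
                          seed=3))
        res = fit_exposure(obs, dermal_template, model="tk", n_iter=1000,
                           seed=3)
        for i, w in enumerate(dermal_template.windows):
            assert res.levels[i] == pytest.approx(w.level, rel=0.30)

    def test_flat_background_flags_no_signal(self, dermal_template):
        voids = generate_worker_dataset(
            SyntheticSpec(scenario=dermal_template, model="tk", cv=0.0,
                          seed=0))[0]
        flat = voids.with_concentrations([0.5] * len(voids))
        res = fit_exposure(flat, dermal_template, model="tk", n_iter=400,
                           seed=2, background=0.5)
        assert res.no_signal

    def test_doubling_iterations_never_worsens_chi2(self, dermal_template):
        obs, _ = generate_worker_dataset(
            SyntheticSpec(scenario=dermal_template, model="tk", cv=0.15,
                          seed=9))
        short = fit_exposure(obs, dermal_template, model="tk", n_iter=250,
                             seed=7)
        long = fit_exposure(obs, dermal_template, model="tk", n_iter=500,
                            seed=7)
        assert long.chi2 <= short.chi2 + 1e-15
        assert np.array_equal(long.trace_chi2[:250], short.trace_chi2)

    def test_best_chi2_is_minimum_of_trace(self, dermal_template):
        obs, _ = generate_worker_dataset(
            SyntheticSpec(scenario=dermal_template, model="tk", cv=0.10,
                          seed=5))
        res = fit_exposure(obs, dermal_template, model="tk", n_iter=300,
                           seed=5)
        assert res.chi2 == res.trace_chi2[-1] == np.min(res.trace_chi2)

    def test_median_recovery_ratio_over_seeds(self, dermal_template):
        """10% noise, repeated seeds: median recovered/true within [0.9, 1.1]."""
        ratios = []
        for seed in range(10):
            obs, _ = generate_worker_dataset(
                SyntheticSpec(scenario=dermal_template, model="tk", cv=0.10,
                              seed=seed))
            res = fit_exposure(obs, dermal_template, model="tk", n_iter=600,
                               seed=seed + 100)
            ratios.extend(res.levels[i] / w.level
                          for i, w in enumerate(dermal_template.windows))
        assert 0.9 <= np.median(ratios) <= 1.1


class TestRouteComparison:
    def test_dermal_data_needs_inflated_inhalation(self, model,
                                                   dermal_template):
        """Dermally generated urine forces fitted air levels far above the
        measured ones; inhalation-generated data reproduces them."""
        fx = worker_fixture(1)
        abs_inh = model.simulate(fx.measured, dt=1.0).absorbed()[-1]
        unit = model.simulate(
            dermal_template.with_levels([1.0] * 2), dt=1.0).absorbed()[-1]
        gen = dermal_template.with_levels([10 * abs_inh / unit] * 2)
        obs, _ = generate_worker_dataset(
            SyntheticSpec(scenario=gen, model="pbpk", cv=0.15, seed=7))
        summary = route_comparison(obs, fx.measured, dermal_template,
                                   model="pbpk", n_iter=300, seed=11)
        assert summary["fitted_to_measured_ratio"] > 2.0
        assert summary["inhalation_insufficient"]
        assert summary["dermal_chi2"] < summary["inhalation_chi2"]

    def test_inhalation_data_at_measured_level_is_consistent(self, model):
        fx = worker_fixture(1)
        obs, _ = generate_worker_dataset(
            SyntheticSpec(scenario=fx.measured, model="pbpk", cv=0.0, seed=0))
        summary = route_comparison(obs, fx.measured, None, model="pbpk",
                                   n_iter=400, seed=3)
        assert summary["fitted_to_measured_ratio"] == pytest.approx(1.0,
                                                                    rel=0.10)
        assert not summary["inhalation_insufficient"]
        assert "dermal_chi2" not in summary
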