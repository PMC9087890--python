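import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from imsfs import (
    InferenceSettings,
    JointSFS,
    ModelParams,
    akaike_weights,
    composite_loglik,
    fit_model,
    generate_jsfs,
    max_obs_loglik,
    model_loglik,
    select_models,
)
from imsfs.inference import ExpectedJSFS, SpectrumMismatchError


def spectrum_1d(values, n_sites=None):
    """A JointSFS with one western sample of zero size: cells (0, 1..k)."""
    counts = np.zeros((1, len(values) + 2))
    counts[0, 1:-1] = values
    return JointSFS(counts, 0, len(values) + 1, n_sites=n_sites)


def expected_1d(probs, floor=1e-12):
    mat = np.zeros((1, len(probs) + 2))
    mat[0, 1:-1] = probs
    return ExpectedJSFS(probs=mat, n_sims=1, floor=floor, model="M1",
                        params=ModelParams(), mean_tree_length=1.0)


class TestCompositeLoglik:
    def test_direct_evaluation(self):
        obs = spectrum_1d([5, 3, 2])
        exp = expected_1d([0.5, 0.3, 0.2])
        want = 5 * math.log(0.5) + 3 * math.log(0.3) + 2 * math.log(0.2)
        assert composite_loglik(obs, exp) == pytest.approx(want, abs=1e-12)

    def test_point_mass_gives_zero(self):
        obs = spectrum_1d([7, 0, 0])
        exp = expected_1d([1.0, 0.0, 0.0])
        assert composite_loglik(obs, exp) == 0.0

    def test_saturated_observation_attains_bound(self):
        obs = spectrum_1d([5, 3, 2])
        exp = expected_1d([0.5, 0.3, 0.2])
        assert composite_loglik(obs, exp) == pytest.approx(max_obs_loglik(obs))

    def test_shape_mismatch_rejected(self):
        obs = spectrum_1d([5, 3])
        exp = expected_1d([0.5, 0.3, 0.2])
        with pytest.raises(SpectrumMismatchError):
            composite_loglik(obs, exp)

    def test_unfloored_zero_cell_with_mass_rejected(self):
        obs = spectrum_1d([5, 3, 2])
        exp = expected_1d([0.7, 0.3, 0.0])
        with pytest.raises(SpectrumMismatchError):
            composite_loglik(obs, exp)


class TestMaxObsLoglik:
    def test_point_mass_is_zero(self):
        assert max_obs_loglik(spectrum_1d([9, 0])) == 0.0

    def test_two_even_cells(self):
        assert max_obs_loglik(spectrum_1d([1, 1])) == pytest.approx(
            2 * math.log(0.5))

    def test_empty_spectrum_rejected(self):
        with pytest.raises(SpectrumMismatchError):
            max_obs_loglik(spectrum_1d([0, 0]))

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=8),
           st.lists(st.floats(0.01, 1.0), min_size=8, max_size=8))
    @hyp_settings(max_examples=100, deadline=None, derandomize=True)
    def test_saturated_bound_over_random_spectra(self, counts, raw_probs):
        if sum(counts) == 0:
            counts[0] = 1
        probs = np.array(raw_probs[:len(counts)])
        probs /= probs.sum()
        obs = spectrum_1d(counts)
        exp = expected_1d(probs)
        assert composite_loglik(obs, exp) <= max_obs_loglik(obs) + 1e-9


class TestScaleAnchor:
    def test_model_loglik_reduces_to_composite_without_site_count(self):
        obs = spectrum_1d([5, 3, 2])
        exp = expected_1d([0.5, 0.3, 0.2])
        assert model_loglik(obs, exp) == composite_loglik(obs, exp)

    def test_site_count_adds_binomial_term(self):
        obs = spectrum_1d([5, 3, 2], n_sites=1000)
        exp = expected_1d([0.5, 0.3, 0.2])
        exp.p_poly = 0.01
        extra = 10 * math.log(0.01) + 990 * math.log(0.99)
        assert model_loglik(obs, exp) == pytest.approx(
            composite_loglik(obs, exp) + extra)

    def test_saturated_bound_holds_with_anchor(self):
        obs = spectrum_1d([5, 3, 2], n_sites=1000)
        exp = expected_1d([0.5, 0.3, 0.2])
        exp.p_poly = 0.004
        assert model_loglik(obs, exp) <= max_obs_loglik(obs)


class TestAkaikeWeights:
    def test_single_model_gets_unit_weight(self):
        _, w = akaike_weights({"M1": 123.4})
        assert w["M1"] == 1.0

    def test_equal_fits_split_evenly(self):
        _, w = akaike_weights({"A": 10.0, "B": 10.0})
        assert w["A"] == pytest.approx(0.5)

    def test_two_unit_gap_closed_form(self):
        delta, w = akaike_weights({"A": 0.0, "B": 2.0})
        assert delta == {"A": 0.0, "B": 2.0}
        assert w["A"] == pytest.approx(1 / (1 + math.exp(-1)))
        assert w["B"] == pytest.approx(math.exp(-1) / (1 + math.exp(-1)))

    def test_invariant_to_constant_shift(self):
        a = {"A": 100.0, "B": 104.2, "C": 101.7}
        b = {k: v + 55.5 for k, v in a.items()}
        _, wa = akaike_weights(a)
        _, wb = akaike_weights(b)
        for k in a:
            assert wa[k] == pytest.approx(wb[k], abs=1e-12)


TRUTH_M1 = ModelParams(N_anc=20_000, N_west=100_000, N_east=50_000,
                       T_div=100_000)


@pytest.fixture(scope="module")
def obs_m1():
    settings = InferenceSettings(n_sims=2000, seed=0)
    return generate_jsfs("M1", TRUTH_M1, settings, 6, 6, 5000, rng=42,
                         n_sims=100_000)


class TestFitModel:

    def test_fit_is_reproducible(self, obs_m1):
        settings = InferenceSettings(n_sims=400, n_cycles=3, n_reps=2, seed=3)
        a = fit_model(obs_m1, "M1", settings, seed=7)
        b = fit_model(obs_m1, "M1", settings, seed=7)
        assert a.params == b.params
        assert a.lnL_est == b.lnL_est
        assert a.replicate == b.replicate

    def test_fit_respects_saturated_bound(self, obs_m1):
        settings = InferenceSettings(n_sims=400, n_cycles=3, n_reps=1, seed=1)
        fit = fit_model(obs_m1, "M1", settings, seed=1)
        assert fit.lnL_est <= fit.lnL_obs + 1e-6
        assert fit.delta >= -1e-6
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.lnL_est)

    def test_isolation_parameters_recovered(self, obs_m1):
        settings = InferenceSettings(n_sims=1500, n_cycles=10, n_reps=3, seed=5)
        fit = fit_model(obs_m1, "M1", settings, seed=5)
        assert fit.params.N_west == pytest.approx(TRUTH_M1.N_west, rel=0.35)
        assert fit.params.N_east == pytest.approx(TRUTH_M1.N_east, rel=0.35)
        assert fit.params.T_div == pytest.approx(TRUTH_M1.T_div, rel=0.35)

    def test_fixed_parameters_are_pinned(self, obs_m1):
        settings = InferenceSettings(n_sims=400, n_cycles=3, n_reps=1, seed=2)
        fit = fit_model(obs_m1, "M1", settings, seed=2,
                        fixed={"N_anc": 20_000.0, "T_div": 100_000.0})
        assert fit.k == 2
        assert fit.params.N_anc == 20_000.0
        assert fit.params.T_div == 100_000.0

    def test_empty_spectrum_rejected(self):
        settings = InferenceSettings(n_sims=100, n_cycles=1, n_reps=1)
        with pytest.raises(SpectrumMismatchError):
            fit_model(spectrum_1d([0, 0]), "M1", settings, seed=0)


class TestSelectModels:
    def test_single_candidate_gets_unit_weight(self):
        settings = InferenceSettings(n_sims=300, n_cycles=2, n_reps=1, seed=0)
        obs = generate_jsfs("M1", TRUTH_M1, settings, 4, 4, 800, rng=1,
                            n_sims=50_000)
        sel = select_models(obs, ["M1"], settings, seed=1)
        assert sel.weights["M1"] == 1.0
        assert sel.best_model == "M1"
        assert sel.delta_aic["M1"] == 0.0

    def test_weights_normalize_and_table_is_complete(self):
        settings = InferenceSettings(n_sims=300, n_cycles=2, n_reps=1, seed=0)
        obs = generate_jsfs("M1", TRUTH_M1, settings, 4, 4, 800, rng=1,
                            n_sims=50_000)
        sel = select_models(obs, ["M1", "M2", "M8"], settings, seed=1)
        assert sum(sel.weights.values()) == pytest.approx(1.0, abs=1e-12)
        frame = sel.to_frame()
        assert len(frame) == 3
        assert frame["delta_aic"].min() == 0.0

    def test_isolation_data_prefers_isolation_model(self):
        # parsimony: with no gene flow in the truth, the extra migration
        # parameter should not pay its AIC penalty
        settings = InferenceSettings(n_sims=2000, n_cycles=8, n_reps=2, seed=0)
        obs = generate_jsfs("M1", TRUTH_M1, settings, 6, 6, 10_000, rng=11,
                            n_sims=100_000)
        sel = select_models(obs, ["M1", "M2"], settings, seed=11)
        assert sel.best_model == "M1"

    def test_empty_candidate_list_rejected(self):
        settings = InferenceSettings(n_sims=100, n_cycles=1, n_reps=1)
        obs = spectrum_1d([3, 2, 1])
        with pytest.raises(ValueError):
            select_models(obs, [], settings, seed=0)
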