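import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_run
from rlconf import (
    LearnerState,
    MODEL_SPACE,
    apply_update,
    choice_prob_learning,
    choice_prob_transfer,
    counterfactual_x,
    imaginary_outcome,
    prediction_errors,
    run_model,
)
from rlconf.models import end_values, get_model
from rlconf.recovery import draw_params
from rlconf.simulate import AgentSpec, ConfParams, simulate_agent


def test_model_space_has_ten_models():
    assert len(MODEL_SPACE) == 10
    families = [spec.family for spec in MODEL_SPACE.values()]
    assert families.count("ABS") == 1 and families.count("ASYM") == 1
    assert families.count("REL") == 4 and families.count("RELASYM") == 4


def test_parameter_lists():
    assert MODEL_SPACE["abs"].param_names == ("alpha_c", "alpha_u", "beta")
    assert MODEL_SPACE["asym"].param_names == ("alpha_con", "alpha_dis", "beta")
    assert MODEL_SPACE["rel-qu"].param_names == (
        "alpha_c", "alpha_u", "alpha_v", "beta",
    )
    assert MODEL_SPACE["relasym-imag"].param_names == (
        "alpha_con", "alpha_dis", "alpha_v", "w", "beta",
    )


class TestPredictionErrors:
    def test_absolute_delta(self):
        spec = MODEL_SPACE["abs"]
        params = dict(alpha_c=0.5, alpha_u=0.5, beta=1.0)
        dc, du, dv = prediction_errors(
            spec, params, LearnerState(), "GP", True, 1.0, None
        )
        assert dc == 1.0 and math.isnan(du) and math.isnan(dv)

    def test_relative_delta_centers_on_context_value(self):
        spec = MODEL_SPACE["rel-zero"]
        params = dict(alpha_c=0.5, alpha_u=0.5, alpha_v=0.5, beta=1.0)
        state = LearnerState()
        state.V["GP"] = 0.4
        state.Q[("GP", True)] = 0.2
        dc, _, _ = prediction_errors(spec, params, state, "GP", True, 1.0, None)
        assert dc == pytest.approx(0.4)

    def test_complete_context_value_delta(self):
        spec = MODEL_SPACE["rel-zero"]
        params = dict(alpha_c=0.5, alpha_u=0.5, alpha_v=0.5, beta=1.0)
        _, _, dv = prediction_errors(
            spec, params, LearnerState(), "GC", True, 1.0, 0.1
        )
        assert dv == pytest.approx(0.55)

    def test_outcome_contract(self):
        spec = MODEL_SPACE["abs"]
        params = dict(alpha_c=0.5, alpha_u=0.5, beta=1.0)
        with pytest.raises(ValueError):
            prediction_errors(spec, params, LearnerState(), "GC", True, 1.0, None)
        with pytest.raises(ValueError):
            prediction_errors(spec, params, LearnerState(), "GP", True, 1.0, 0.1)


class TestImaginaryOutcome:
    @pytest.mark.parametrize(
        "r_c, v, expected",
        [
            (0.1, 0.3, 1.0),
            (-0.1, -0.2, -1.0),
            (1.0, 0.5, 0.1),
            (-1.0, -0.2, -0.1),
            (1.0, 0.0, 0.0),
        ],
    )
    def test_five_cases(self, r_c, v, expected):
        assert imaginary_outcome(r_c, v) == expected

    def test_unexpected_magnitude_raises(self):
        with pytest.raises(ValueError):
            imaginary_outcome(0.5, 0.2)


class TestCounterfactual:
    def _params(self, name):
        spec = MODEL_SPACE[name]
        return spec, {n: 0.5 for n in spec.param_names}

    def test_zero_variant(self):
        spec, params = self._params("rel-zero")
        assert counterfactual_x(spec, params, LearnerState(), "GP", True, 1.0) == 0.0

    def test_weighted_imaginary_scales(self):
        spec, params = self._params("relasym-imag")
        state = LearnerState()
        state.V["GP"] = 0.3
        assert counterfactual_x(spec, params, state, "GP", True, 0.1) == pytest.approx(0.5)

    def test_qu_variant_tracks_state(self, rng):
        spec, params = self._params("rel-qu")
        state = LearnerState()
        for _ in range(20):
            state.Q[("GP", False)] = rng.normal()
            x = counterfactual_x(spec, params, state, "GP", True, 1.0)
            assert x == state.Q[("GP", False)]

    def test_rejects_complete_context(self):
        spec, params = self._params("rel-zero")
        with pytest.raises(ValueError):
            counterfactual_x(spec, params, LearnerState(), "GC", True, 1.0)


class TestApplyUpdate:
    def test_zero_delta_keeps_state(self):
        spec = MODEL_SPACE["abs"]
        params = dict(alpha_c=0.5, alpha_u=0.5, beta=1.0)
        state = LearnerState()
        new = apply_update(spec, params, state, "GP", True, 0.0, None,
                           (0.0, float("nan"), float("nan")))
        assert new.Q[("GP", True)] == 0.0

    def test_asymmetric_rates(self):
        spec = MODEL_SPACE["asym"]
        params = dict(alpha_con=0.4, alpha_dis=0.1, beta=1.0)
        up = apply_update(spec, params, LearnerState(), "GP", True, 1.0, None,
                          (1.0, float("nan"), float("nan")))
        assert up.Q[("GP", True)] == pytest.approx(0.4)
        down = apply_update(spec, params, LearnerState(), "GP", True, -1.0, None,
                            (-1.0, float("nan"), float("nan")))
        assert down.Q[("GP", True)] == pytest.approx(-0.1)

    def test_unchosen_mirror(self):
        """Negative unchosen prediction errors are confirmatory."""
        spec = MODEL_SPACE["asym"]
        params = dict(alpha_con=0.4, alpha_dis=0.1, beta=1.0)
        new = apply_update(spec, params, LearnerState(), "GC", True, 1.0, 0.1,
                           (1.0, -1.0, float("nan")))
        assert new.Q[("GC", False)] == pytest.approx(-0.4)


class TestChoiceProbabilities:
    def test_symmetry_and_zero_beta(self):
        assert choice_prob_learning(0.3, 0.3, 5.0) == pytest.approx(0.5)
        assert choice_prob_learning(1.0, -1.0, 0.0) == pytest.approx(0.5)

    def test_closed_form(self):
        assert choice_prob_learning(0.3, 0.0, 5.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.5)), abs=1e-6
        )

    def test_transfer_equals_learning_on_grid(self):
        for qa in np.linspace(-1, 1, 7):
            for qb in np.linspace(-1, 1, 7):
                assert choice_prob_transfer(qa, qb, 3.0) == choice_prob_learning(
                    qa, qb, 3.0
                )
                assert choice_prob_transfer(qa, qb, 3.0) + choice_prob_transfer(
                    qb, qa, 3.0
                ) == pytest.approx(1.0)


class TestRunModel:
    def test_zero_beta_likelihood(self, tiny_dataset):
        params = dict(alpha_c=0.3, alpha_u=0.3, beta=0.0)
        _, ll = run_model("abs", params, tiny_dataset)
        assert ll == pytest.approx(len(tiny_dataset) * math.log(0.5))

    def test_one_trial_dataset(self, tiny_dataset):
        one = tiny_dataset[tiny_dataset["phase"] == "learning"].head(1)
        params = dict(alpha_c=0.3, alpha_u=0.3, beta=4.0)
        _, ll = run_model("abs", params, one)
        assert ll == pytest.approx(math.log(0.5))  # Q values start equal

    @pytest.mark.parametrize("name", list(MODEL_SPACE))
    def test_matches_naive_loop(self, name, tiny_dataset, rng):
        """The compiled likelihood pass equals a hand-written reference."""
        spec = get_model(name)
        for _ in range(3):
            params = draw_params(name, rng)
            latents, ll = run_model(name, params, tiny_dataset)
            ll_ref, lat_ref, q_ref, _ = naive_run(
                spec.family, spec.counterfactual_variant, params, tiny_dataset
            )
            assert ll == pytest.approx(ll_ref, abs=1e-10)
            got = latents[["Qc", "Qu", "V", "delta_c", "delta_u",
                           "delta_v", "choice_prob"]].to_numpy()
            ref = np.array([[r[c] for c in ("Qc", "Qu", "V", "delta_c",
                                            "delta_u", "delta_v", "choice_prob")]
                            for r in lat_ref])
            assert np.allclose(got, ref, atol=1e-10, equal_nan=True)
            q_end, _ = end_values(latents)
            from rlconf.task import CONTEXTS
            for i, ctx in enumerate(CONTEXTS):
                assert q_end[i, 1] == pytest.approx(q_ref[f"{ctx}_hi"], abs=1e-12)
                assert q_end[i, 0] == pytest.approx(q_ref[f"{ctx}_lo"], abs=1e-12)

    def test_family_nesting(self, tiny_dataset):
        """ABS with a shared rate coincides with ASYM; REL with alpha_v=0
        coincides with ABS."""
        a = 0.3
        lat_abs, ll_abs = run_model(
            "abs", dict(alpha_c=a, alpha_u=a, beta=4.0), tiny_dataset
        )
        lat_asym, ll_asym = run_model(
            "asym", dict(alpha_con=a, alpha_dis=a, beta=4.0), tiny_dataset
        )
        assert ll_abs == pytest.approx(ll_asym, abs=1e-12)
        lat_rel, ll_rel = run_model(
            "rel-zero", dict(alpha_c=a, alpha_u=a, alpha_v=0.0, beta=4.0),
            tiny_dataset,
        )
        assert ll_abs == pytest.approx(ll_rel, abs=1e-12)
        assert np.allclose(
            lat_abs[["Qc", "Qu"]].to_numpy(), lat_rel[["Qc", "Qu"]].to_numpy(),
            atol=1e-12,
        )

    def test_simulated_latents_are_reproduced(self, full_dataset, relasym_agent):
        """Refiltering an agent's own choices reproduces its stored latents."""
        latents, _ = run_model("relasym-imag", relasym_agent.params, full_dataset)
        cols = ["Qc", "Qu", "V", "delta_c", "delta_u", "delta_v", "choice_prob"]
        assert np.allclose(
            latents[cols].to_numpy(),
            full_dataset[cols].to_numpy(),
            atol=1e-12, equal_nan=True,
        )

    def test_unordered_dataset_raises(self, tiny_dataset):
        shuffled = tiny_dataset.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError):
            run_model("abs", dict(alpha_c=0.3, alpha_u=0.3, beta=1.0), shuffled)

    def test_loglik_is_smooth_in_parameters(self, tiny_dataset, rng):
        params = dict(alpha_c=0.4, alpha_u=0.3, beta=3.0)

        def ll(beta):
            return run_model("abs", {**params, "beta": beta}, tiny_dataset)[1]

        for h in (1e-3, 1e-4, 1e-5):
            grad = (ll(3.0 + h) - ll(3.0 - h)) / (2 * h)
            assert np.isfinite(grad)
        g1 = (ll(3.0 + 1e-4) - ll(3.0 - 1e-4)) / 2e-4
        g2 = (ll(3.0 + 1e-5) - ll(3.0 - 1e-5)) / 2e-5
        assert g1 == pytest.approx(g2, rel=1e-3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.05, 0.95),
    seed=st.integers(0, 10_000),
)
def test_q_values_stay_in_outcome_hull(alpha, seed):
    """Delta-rule trajectories remain inside the hull of 0 and the
    observed outcomes for learning rates in (0, 1)."""
    rng = np.random.default_rng(seed)
    spec = MODEL_SPACE["abs"]
    params = dict(alpha_c=alpha, alpha_u=alpha, beta=1.0)
    state = LearnerState()
    outcomes = rng.choice([1.0, 0.1], size=50)
    for r in outcomes:
        deltas = prediction_errors(spec, params, state, "GP", True, float(r), None)
        state = apply_update(spec, params, state, "GP", True, float(r), None, deltas)
        assert 0.0 <= state.Q[("GP", True)] <= 1.0


def test_high_beta_agent_exploits(tiny_config):
    """With a huge inverse temperature the agent ends up picking the
    higher-valued option on essentially every late trial."""
    agent = AgentSpec(
        model="abs",
        params=dict(alpha_c=0.8, alpha_u=0.8, beta=1000.0),
        conf_bias="none",
        conf_params=ConfParams(),
        conf_noise_sd=0.0,
    )
    cfg = type(tiny_config)(n_runs=3, trials_per_context_per_run=20, seed=5)
    df = simulate_agent(agent, cfg, subject=0, seed=5)
    late = df[(df["phase"] == "learning") & (df["run"] == 3) & (df["trial"] > 40)]
    # with beta -> inf the choice follows the running Q ranking deterministically
    assert (late["choice_prob"] > 0.999).mean() > 0.95
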