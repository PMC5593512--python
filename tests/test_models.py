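"""Unit and property tests for the belief updates, propensity terms,
softmax and sequence likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from banditfit.models import (MODEL_GRID, BeliefState, ModelSpec,
                              Propensities, RWState, action_propensities,
                              bayes_update, belief_variance, confidence,
                              expected_value, prob_greater,
                              relative_confidence, rw_forget, rw_update,
                              sequence_loglik, softmax_choice_prob,
                              validate_params)
from banditfit.task import TrialSequence, fig2_fixture, FIG2_PARAMS


def test_model_grid_matches_published_layout():
    assert len(MODEL_GRID) == 10
    ks = {name: spec.k for name, spec in MODEL_GRID.items()}
    assert ks == {"rw": 2, "rw_kernel": 3, "rw_kernel_forget": 4,
                  "bayes_single": 2, "bayes": 3, "bayes_kernel": 4,
                  "bayes_var_chosen": 4, "bayes_var_unchosen": 4,
                  "bayes_conf": 4, "bayes_full": 5}
    assert sum(s.family == "rw" for s in MODEL_GRID.values()) == 3


def test_spec_rejects_terms_outside_their_family():
    with pytest.raises(ValueError):
        ModelSpec("bad", "rw", variance="unchosen")
    with pytest.raises(ValueError):
        ModelSpec("bad", "bayes", forget=True)
    with pytest.raises(ValueError):
        validate_params("rw", {"beta": 1.0, "alpha": 0.5, "kappa": 0.1})


@pytest.mark.parametrize("q0, reward, alpha, expected", [
    (0.5, 1, 0.5, 0.75),    # midpoint step
    (0.5, 1, 0.0, 0.5),     # zero learning rate
    (0.75, 0, 0.3, 0.525),  # hand arithmetic
])
def test_rw_update_arithmetic(q0, reward, alpha, expected):
    state = RWState(q=np.array([q0, 0.4]))
    new = rw_update(state, 0, reward, alpha)
    assert new.q[0] == pytest.approx(expected, abs=1e-12)
    assert new.q[1] == 0.4
    assert new.delta == pytest.approx(reward - q0)


@pytest.mark.parametrize("q_unchosen, phi, expected", [
    (0.9, 1.0, 0.5),   # full relaxation
    (0.9, 0.0, 0.9),   # no forgetting
    (0.9, 0.2, 0.82),  # hand arithmetic
])
def test_rw_forget(q_unchosen, phi, expected):
    state = RWState(q=np.array([0.3, q_unchosen]))
    assert rw_forget(state, 1, phi).q[1] == pytest.approx(expected, abs=1e-12)


def test_bayes_update_single_step():
    new = bayes_update(BeliefState(), 0, 1, omega=0.72, lam=0.28)
    assert new.gamma[0] == pytest.approx(2.0)
    assert new.eps[0] == pytest.approx(1.0)
    assert new.gamma[1] == pytest.approx(1.0)
    assert new.eps[1] == pytest.approx(1.0)


def test_bayes_update_fixed_point():
    """Repeated rewarded choices drive gamma to its fixed point 1 + 1/omega."""
    omega = 0.3
    st_ = BeliefState()
    for _ in range(200):
        st_ = bayes_update(st_, 0, 1, omega, 0.1)
    assert st_.gamma[0] == pytest.approx(1.0 + 1.0 / omega, abs=1e-8)


def test_bayes_replay_of_worked_example_beliefs():
    """After the printed 20-trial sequence, bandit-2's belief is β(1.26, 1.74)."""
    seq = fig2_fixture()
    st_ = BeliefState()
    for c, r in zip(seq.choices, seq.rewards):
        st_ = bayes_update(st_, int(c), int(r), **{
            "omega": FIG2_PARAMS["omega"], "lam": FIG2_PARAMS["lambda"]})
    assert st_.gamma[1] == pytest.approx(1.26, abs=0.01)
    assert st_.eps[1] == pytest.approx(1.74, abs=0.01)
    # bandit 1 printed as (2.02, 1.08); reproduced within the legend rounding
    assert st_.gamma[0] == pytest.approx(2.02, abs=0.02)
    assert st_.eps[0] == pytest.approx(1.08, abs=0.02)


@pytest.mark.parametrize("gamma, eps, q", [
    (1.0, 1.0, 0.5),
    (2.02, 1.08, 0.65),   # worked-example value (printed precision)
    (1.26, 1.74, 0.42),
])
def test_expected_value(gamma, eps, q):
    assert expected_value(gamma, eps) == pytest.approx(q, abs=0.005)


@pytest.mark.parametrize("gamma, eps, v", [
    (1.0, 1.0, 1.0 / 12.0),
    (2.0, 2.0, 0.05),
])
def test_belief_variance(gamma, eps, v):
    assert belief_variance(gamma, eps) == pytest.approx(v, abs=1e-12)


def test_confidence_symmetry_and_extremes():
    pair = confidence((2.0, 3.0), (2.0, 3.0))
    assert pair.c0 == pytest.approx(0.5, abs=1e-9)
    assert prob_greater(100.0, 1.0, 1.0, 100.0) > 0.999


def test_confidence_matches_monte_carlo():
    """Quadrature agrees with a Monte-Carlo oracle within 3 standard errors."""
    rng = np.random.default_rng(4)
    n_mc = 200_000
    for _ in range(100):
        g0, e0, g1, e1 = rng.uniform(1.0, 25.0, size=4)
        draws0 = rng.beta(g0, e0, size=n_mc)
        draws1 = rng.beta(g1, e1, size=n_mc)
        p_mc = (draws1 > draws0).mean()
        se = math.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_mc)
        pair = confidence((g0, e0), (g1, e1))
        assert abs(pair.c1 - p_mc) <= 3.0 * se + 1e-4
        # the fast vectorised rule agrees with the adaptive quadrature
        assert prob_greater(g1, e1, g0, e0) == pytest.approx(pair.c1, abs=2e-4)


def test_relative_confidence():
    assert relative_confidence(confidence((1, 1), (1, 1)), 0) == pytest.approx(0.0)
    assert relative_confidence(ConfPair(0.56), 0) == pytest.approx(0.12, abs=1e-12)
    assert relative_confidence(ConfPair(1.0), 0) == 1.0
    assert relative_confidence(ConfPair(0.9), None) == 0.0


def ConfPair(c_for_bandit0):
    from banditfit.models import ConfidencePair

    return ConfidencePair(c0=c_for_bandit0, c1=1.0 - c_for_bandit0)


def test_propensity_assembly():
    base = action_propensities("bayes", {"beta": 1.0, "omega": 0.5,
                                         "lambda": 0.2}, q=[0.6, 0.4])
    assert np.allclose(base.m, [0.6, 0.4])
    withb = action_propensities(
        "rw_kernel", {"beta": 1.0, "alpha": 0.5, "b": 0.3},
        q=[0.6, 0.4], previous_choice=0)
    assert np.allclose(withb.m, [0.9, 0.4])
    # worked-example trial-21 assembly: previously unchosen bandit gets
    # upsilon*V_uc + kappa*Crel on top of its expected value
    full = action_propensities(
        "bayes_full",
        {"beta": 1.0, "omega": 0.72, "lambda": 0.28, "upsilon": -1.0,
         "kappa": 0.26},
        q=[0.65, 0.42], v=[0.04, 0.05], previous_choice=0, crel_prev=0.12)
    assert full.m[1] == pytest.approx(0.42 - 1.0 * 0.05 + 0.26 * 0.12)
    assert full.m[0] == pytest.approx(0.65)
    # components sum to the propensity
    assert np.allclose(full.base + full.kernel + full.variance +
                       full.confidence, full.m)


def test_propensity_addons_inactive_without_history():
    p = action_propensities(
        "bayes_full",
        {"beta": 1.0, "omega": 0.5, "lambda": 0.2, "upsilon": -2.0,
         "kappa": 1.0},
        q=[0.5, 0.5], v=[1 / 12, 1 / 12], previous_choice=None)
    assert np.allclose(p.m, [0.5, 0.5])


def test_softmax():
    assert np.allclose(softmax_choice_prob(np.array([0.3, 0.3]), 5.0), 0.5)
    assert np.allclose(softmax_choice_prob(np.array([2.0, -1.0]), 0.0), 0.5)
    p = softmax_choice_prob(np.array([0.65, 0.42]), 12.28)
    from scipy.special import expit

    assert p[0] == pytest.approx(expit(12.28 * 0.23), abs=1e-12)
    assert p.sum() == pytest.approx(1.0)
    # overflow safety
    p = softmax_choice_prob(np.array([1e4, -1e4]), 100.0)
    assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_softmax_normalisation_property(seed):
    rng = np.random.default_rng(seed)
    m = rng.normal(0, 1, size=2)
    beta = rng.uniform(0, 5)
    p = softmax_choice_prob(m, beta)
    assert p.sum() == pytest.approx(1.0)
    assert np.all(p > 0) and np.all(p < 1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.05, 0.95), st.floats(0.05, 0.95))
def test_pseudo_count_bounds_property(seed, omega, lam):
    """Counts stay in [1, 1 + 1/omega] for any choice/reward sequence.

    1 + 1/omega is the fixed point of the chosen-bandit update; forgetting
    only relaxes counts towards 1.
    """
    rng = np.random.default_rng(seed)
    st_ = BeliefState()
    hi = 1.0 + 1.0 / omega
    for _ in range(60):
        st_ = bayes_update(st_, int(rng.integers(2)), int(rng.integers(2)),
                           omega, lam)
        for arr in (st_.gamma, st_.eps):
            assert np.all(arr >= 1.0 - 1e-12)
            assert np.all(arr <= hi + 1e-9)


def test_forgetting_geometric_relaxation():
    """The unchosen belief decays to (1, 1) geometrically at rate 1 - lambda."""
    lam = 0.3
    st_ = bayes_update(BeliefState(), 1, 1, 0.5, lam)  # build up bandit 1
    for _ in range(5):
        prev_gap = st_.gamma[1] - 1.0
        st_ = bayes_update(st_, 0, 1, 0.5, lam)
        assert st_.gamma[1] - 1.0 == pytest.approx((1 - lam) * prev_gap)


def test_rw_q_stays_in_unit_interval():
    rng = np.random.default_rng(0)
    state = RWState()
    for _ in range(500):
        state = rw_update(state, int(rng.integers(2)), int(rng.integers(2)),
                          rng.uniform(0.01, 0.99))
        assert np.all((state.q >= 0) & (state.q <= 1))


# ---------------------------------------------------------------------------
# Sequence likelihood
# ---------------------------------------------------------------------------

def _oracle_loglik(seq, spec, params):
    """Step-by-step recomputation of the sequence log likelihood.

    Written directly from the update equations, independently of the
    vectorised implementation; only the beta-comparison integral
    (prob_greater) is shared, as a numerical primitive.
    """
    p = dict(params)
    fam = spec.family
    if fam == "bayes" and spec.single_rate:
        p["lambda"] = p["omega"]
    q = [0.5, 0.5]
    g = [1.0, 1.0]
    e = [1.0, 1.0]
    prev_choice = None
    prev_state = ([1.0, 1.0], [1.0, 1.0])  # counts at previous choice
    total = 0.0
    for c, r in zip(seq.choices, seq.rewards):
        if fam == "bayes":
            s0, s1 = g[0] + e[0], g[1] + e[1]
            q = [g[0] / s0, g[1] / s1]
            v_now = [g[0] * e[0] / (s0 ** 2 * (s0 + 1)),
                     g[1] * e[1] / (s1 ** 2 * (s1 + 1))]
        m = [q[0], q[1]]
        if prev_choice is not None:
            if spec.kernel:
                m[prev_choice] += p["b"]
            if spec.variance is not None or spec.confidence:
                if spec.variance_state == "previous":
                    pg, pe = prev_state
                    ps0, ps1 = pg[0] + pe[0], pg[1] + pe[1]
                    v_use = [pg[0] * pe[0] / (ps0 ** 2 * (ps0 + 1)),
                             pg[1] * pe[1] / (ps1 ** 2 * (ps1 + 1))]
                    cg, ce = pg, pe
                else:
                    v_use, cg, ce = v_now, g, e
            if spec.variance is not None:
                tgt = prev_choice if spec.variance == "chosen" else 1 - prev_choice
                m[tgt] += p["upsilon"] * v_use[tgt]
            if spec.confidence:
                c1 = prob_greater(cg[1], ce[1], cg[0], ce[0])
                c_chosen = c1 if prev_choice == 1 else 1.0 - c1
                m[1 - prev_choice] += p["kappa"] * (2 * c_chosen - 1)
        if c < 0:
            prev_choice = None  # a miss breaks the history terms
            continue
        z = [p["beta"] * m[0], p["beta"] * m[1]]
        zmax = max(z)
        logp = z[c] - zmax - math.log(math.exp(z[0] - zmax) + math.exp(z[1] - zmax))
        total += logp
        if fam == "bayes":
            prev_state = ([g[0], g[1]], [e[0], e[1]])
            u = 1 - c
            g[c] = (1 - p["omega"]) * g[c] + p["omega"] + r
            e[c] = (1 - p["omega"]) * e[c] + p["omega"] + (1 - r)
            g[u] = (1 - p["lambda"]) * g[u] + p["lambda"]
            e[u] = (1 - p["lambda"]) * e[u] + p["lambda"]
        else:
            q[c] += p["alpha"] * (r - q[c])
            if spec.forget:
                u = 1 - c
                q[u] += p["phi"] * (0.5 - q[u])
        prev_choice = c
    return total


_ORACLE_PARAMS = {
    "beta": 7.5, "alpha": 0.35, "b": 0.4, "phi": 0.15,
    "omega": 0.45, "lambda": 0.2, "upsilon": -1.2, "kappa": 0.3,
}


@pytest.mark.parametrize("name", sorted(MODEL_GRID))
def test_sequence_loglik_matches_stepwise_oracle(name):
    """The vectorised likelihood equals an independent trialwise recomputation."""
    spec = MODEL_GRID[name]
    params = {k: _ORACLE_PARAMS[k] for k in spec.param_names}
    choices = np.array([0, 0, 1, -1, 1, 0, 1, 1, -1, 0, 0, 1, 0, 1])
    rewards = np.array([1, 0, 1, -1, 0, 1, 1, 0, -1, 1, 0, 0, 1, 1])
    seq = TrialSequence("oracle", choices, rewards)
    got = sequence_loglik(seq, spec, params)
    want = _oracle_loglik(seq, spec, params)
    assert got == pytest.approx(want, abs=1e-12)


def test_sequence_loglik_beta_zero_is_chance(sim_subject):
    n = sim_subject.n_valid
    ll = sequence_loglik(sim_subject, "bayes_full",
                         {"beta": 0.0, "omega": 0.4, "lambda": 0.2,
                          "upsilon": -1.0, "kappa": 0.26})
    assert ll == pytest.approx(n * math.log(0.5), abs=1e-9)


def test_sequence_loglik_relabelling_symmetry(sim_subject):
    """Jointly flipping bandit labels leaves the likelihood unchanged."""
    params = {"beta": 10.0, "omega": 0.5, "lambda": 0.15, "upsilon": -0.8,
              "kappa": 0.2}
    flipped = TrialSequence(
        "flip",
        np.where(sim_subject.choices >= 0, 1 - sim_subject.choices, -1),
        sim_subject.rewards.copy(),
    )
    for name in ("rw_kernel", "bayes_full"):
        spec = MODEL_GRID[name]
        pars = {k: _ORACLE_PARAMS[k] for k in spec.param_names}
        a = sequence_loglik(sim_subject, spec, pars)
        b = sequence_loglik(flipped, spec, pars)
        assert a == pytest.approx(b, abs=1e-10)


NESTINGS = [
    # (rich spec, poor spec, parameter pinning that collapses rich -> poor)
    ("bayes", "bayes_single", {"lambda": "omega"}),
    ("rw_kernel", "rw", {"b": 0.0}),
    ("rw_kernel_forget", "rw_kernel", {"phi": 0.0}),
    ("bayes_kernel", "bayes", {"b": 0.0}),
    ("bayes_var_unchosen", "bayes", {"upsilon": 0.0}),
    ("bayes_var_chosen", "bayes", {"upsilon": 0.0}),
    ("bayes_conf", "bayes", {"kappa": 0.0}),
    ("bayes_full", "bayes", {"upsilon": 0.0, "kappa": 0.0}),
]


@pytest.mark.parametrize("rich, poor, pin", NESTINGS)
def test_model_nesting_likelihood_identities(rich, poor, pin, sim_subject):
    """Pinning the extra term of a richer model reproduces the nested one."""
    poor_params = {k: _ORACLE_PARAMS[k] for k in MODEL_GRID[poor].param_names}
    rich_params = dict(poor_params)
    for k, v in pin.items():
        rich_params[k] = poor_params[v] if isinstance(v, str) else v
    ll_rich = sequence_loglik(sim_subject, rich, rich_params)
    ll_poor = sequence_loglik(sim_subject, poor, poor_params)
    assert ll_rich == pytest.approx(ll_poor, abs=1e-10)


def test_variance_state_convention_changes_likelihood(sim_subject):
    """The previous- vs current-state convention is a real model difference."""
    prev = MODEL_GRID["bayes_full"]
    import dataclasses

    cur = dataclasses.replace(prev, name="cur", variance_state="current")
    params = {k: _ORACLE_PARAMS[k] for k in prev.param_names}
    assert (sequence_loglik(sim_subject, prev, params)
            != pytest.approx(sequence_loglik(sim_subject, cur, params)))


def test_empty_sequence_warns_and_returns_zero():
    seq = TrialSequence("none", np.array([-1, -1]), np.array([-1, -1]))
    with pytest.warns(UserWarning):
        assert sequence_loglik(seq, "rw", {"beta": 1.0, "alpha": 0.5}) == 0.0
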