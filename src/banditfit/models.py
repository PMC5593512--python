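"""Trial-by-trial choice models for the restless two-armed bandit task.

Two model families are implemented:

* **Rescorla-Wagner (RW)**: expected reward probabilities (Q-values) are
  learned through reward prediction errors with learning rate ``alpha``,
  optionally with a choice kernel ``b`` (perseveration) and a forgetting
  rate ``phi`` that relaxes the unchosen Q-value towards 0.5.

* **Bayesian observer**: each bandit's reward probability is tracked as a
  beta distribution whose pseudo-counts of wins (``gamma``) and win
  omissions (``epsilon``) are updated with learning rate ``omega`` for the
  chosen bandit and relaxed towards the uniform prior with forgetting rate
  ``lambda`` for the unchosen one.  Optional propensity terms use the
  belief variance (uncertainty aversion / exploration bonus, ``upsilon``)
  and the relative confidence that the previous choice was the better one
  (``kappa``).

All models map action propensities to choice probabilities through a
softmax with inverse temperature ``beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "ModelSpec",
    "MODEL_GRID",
    "get_spec",
    "RWState",
    "BeliefState",
    "ConfidencePair",
    "Propensities",
    "validate_params",
    "rw_update",
    "rw_forget",
    "bayes_update",
    "expected_value",
    "belief_variance",
    "confidence",
    "prob_greater",
    "relative_confidence",
    "action_propensities",
    "softmax_choice_prob",
    "sequence_loglik",
]

# Natural-scale parameter domains. b, upsilon and kappa are unbounded.
PARAM_DOMAINS: dict[str, tuple[float, float]] = {
    "beta": (0.0, math.inf),
    "alpha": (0.0, 1.0),
    "b": (-math.inf, math.inf),
    "phi": (0.0, 1.0),
    "omega": (0.0, 1.0),
    "lambda": (0.0, 1.0),
    "upsilon": (-math.inf, math.inf),
    "kappa": (-math.inf, math.inf),
}


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"bayes_full"``.
    family
        ``"rw"`` or ``"bayes"``.
    kernel
        Include the choice-kernel (perseveration) term ``b``.
    forget
        RW family only: include the forgetting rate ``phi`` for the
        unchosen option.
    single_rate
        Bayesian family only: tie the forgetting rate to the learning rate
        (``lambda = omega``), giving the two-parameter observer.
    variance
        ``None``, ``"chosen"`` or ``"unchosen"``: add ``upsilon * V`` to the
        propensity of the bandit that was (or was not) chosen on the
        previous trial.
    confidence
        Add ``kappa * Crel(t-1)`` to the propensity of the previously
        unchosen bandit.
    variance_state
        Which belief state feeds the variance and confidence terms on trial
        t: ``"previous"`` (state as of the trial t-1 choice, the default)
        or ``"current"`` (state as of the trial t choice, i.e. after the
        trial t-1 outcome).
    """

    name: str
    family: str
    kernel: bool = False
    forget: bool = False
    single_rate: bool = False
    variance: str | None = None
    confidence: bool = False
    variance_state: str = "previous"

    def __post_init__(self) -> None:
        if self.family not in ("rw", "bayes"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.variance not in (None, "chosen", "unchosen"):
            raise ValueError(f"invalid variance mode {self.variance!r}")
        if self.variance_state not in ("previous", "current"):
            raise ValueError(f"invalid variance_state {self.variance_state!r}")
        if self.family == "rw" and (
            self.variance or self.confidence or self.single_rate
        ):
            raise ValueError(
                "variance, confidence and single_rate terms require the "
                "Bayesian observer family"
            )
        if self.family == "bayes" and self.forget:
            raise ValueError("'forget' (phi) is an RW-family term; the "
                             "Bayesian family forgets through lambda")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family == "rw":
            names = ["beta", "alpha"]
            if self.kernel:
                names.append("b")
            if self.forget:
                names.append("phi")
        else:
            names = ["beta", "omega"]
            if not self.single_rate:
                names.append("lambda")
            if self.kernel:
                names.append("b")
            if self.variance is not None:
                names.append("upsilon")
            if self.confidence:
                names.append("kappa")
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of free subject-level parameters."""
        return len(self.param_names)


def _grid() -> dict[str, ModelSpec]:
    specs = [
        ModelSpec("rw", "rw"),
        ModelSpec("rw_kernel", "rw", kernel=True),
        ModelSpec("rw_kernel_forget", "rw", kernel=True, forget=True),
        ModelSpec("bayes_single", "bayes", single_rate=True),
        ModelSpec("bayes", "bayes"),
        ModelSpec("bayes_kernel", "bayes", kernel=True),
        ModelSpec("bayes_var_chosen", "bayes", variance="chosen"),
        ModelSpec("bayes_var_unchosen", "bayes", variance="unchosen"),
        ModelSpec("bayes_conf", "bayes", confidence=True),
        ModelSpec("bayes_full", "bayes", variance="unchosen", confidence=True),
    ]
    return {s.name: s for s in specs}


#: The ten-model comparison grid: three RW variants and seven Bayesian
#: observer variants, ordered as in the model-comparison table.
MODEL_GRID: dict[str, ModelSpec] = _grid()


def get_spec(spec: str | ModelSpec) -> ModelSpec:
    """Resolve a spec name to its :class:`ModelSpec`."""
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return MODEL_GRID[spec]
    except KeyError:
        raise ValueError(
            f"unknown model {spec!r}; choose from {sorted(MODEL_GRID)}"
        ) from None


def validate_params(spec: str | ModelSpec, params: Mapping[str, float]) -> dict:
    """Check that ``params`` exactly matches ``spec`` and obeys the domains.

    Returns the validated parameters as a plain dict (with ``lambda``
    filled in from ``omega`` for the single-rate observer).
    """
    spec = get_spec(spec)
    names = spec.param_names
    missing = set(names) - set(params)
    extra = set(params) - set(names)
    if missing or extra:
        raise ValueError(
            f"model {spec.name!r} takes parameters {list(names)}; "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )
    out = {}
    for name in names:
        val = float(params[name])
        lo, hi = PARAM_DOMAINS[name]
        if not (lo <= val <= hi) or not math.isfinite(val):
            raise ValueError(f"parameter {name}={val} outside [{lo}, {hi}]")
        out[name] = val
    if spec.family == "bayes" and spec.single_rate:
        out["lambda"] = out["omega"]
    return out


# ---------------------------------------------------------------------------
# Evolving internal states
# ---------------------------------------------------------------------------

@dataclass
class RWState:
    """Q-values of the RW learner; ``delta`` is the last prediction error."""

    q: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    delta: float = 0.0


@dataclass
class BeliefState:
    """Beta pseudo-counts for both bandits: wins ``gamma``, omissions ``eps``."""

    gamma: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    eps: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))


@dataclass(frozen=True)
class ConfidencePair:
    """Confidence that each bandit is the better one; c0 + c1 = 1."""

    c0: float
    c1: float


@dataclass(frozen=True)
class Propensities:
    """Per-bandit action propensities with their additive components."""

    m: np.ndarray
    base: np.ndarray
    kernel: np.ndarray
    variance: np.ndarray
    confidence: np.ndarray


# ---------------------------------------------------------------------------
# Update rules
# ---------------------------------------------------------------------------

def rw_update(state: RWState, choice: int, reward: int, alpha: float) -> RWState:
    """Prediction-error update of the chosen Q-value: Q += alpha*(R - Q)."""
    if choice not in (0, 1) or reward not in (0, 1):
        raise ValueError("choice and reward must be 0 or 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    q = state.q.copy()
    delta = reward - q[choice]
    q[choice] += alpha * delta
    return RWState(q=q, delta=delta)


def rw_forget(state: RWState, unchosen: int, phi: float) -> RWState:
    """Relax the unchosen Q-value towards the uninformed value 0.5."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    q = state.q.copy()
    q[unchosen] += phi * (0.5 - q[unchosen])
    return RWState(q=q, delta=state.delta)


def bayes_update(
    state: BeliefState, choice: int, reward: int, omega: float, lam: float
) -> BeliefState:
    """Leaky pseudo-count update of both beliefs after one outcome.

    The chosen bandit's counts decay towards 1 at rate ``omega`` and the
    observed outcome adds one full count to the matching side; the unchosen
    bandit's counts only decay, at rate ``lam``.
    """
    if choice not in (0, 1) or reward not in (0, 1):
        raise ValueError("choice and reward must be 0 or 1")
    g, e = state.gamma.copy(), state.eps.copy()
    c, u = choice, 1 - choice
    g[c] = (1 - omega) * g[c] + omega + reward
    e[c] = (1 - omega) * e[c] + omega + (1 - reward)
    g[u] = (1 - lam) * g[u] + lam
    e[u] = (1 - lam) * e[u] + lam
    return BeliefState(gamma=g, eps=e)


def expected_value(gamma: float, eps: float) -> float:
    """Mean of the beta belief: Q = gamma / (gamma + eps)."""
    if gamma <= 0 or eps <= 0:
        raise ValueError("pseudo-counts must be positive")
    return gamma / (gamma + eps)


def belief_variance(gamma: float, eps: float) -> float:
    """Variance of the beta belief."""
    if gamma <= 0 or eps <= 0:
        raise ValueError("pseudo-counts must be positive")
    s = gamma + eps
    return gamma * eps / (s * s * (s + 1.0))


# ---------------------------------------------------------------------------
# Confidence: P(theta_A > theta_B) for two beta beliefs
# ---------------------------------------------------------------------------

def _gl_rule(n):
    """Gauss-Legendre rule on [0, 1] plus a spectral antiderivative matrix.

    ``S @ f`` evaluated at the nodes approximates the running integral
    of f from 0 (Legendre interpolation of f, integrated exactly), which
    supplies the beta CDFs from the beta densities without incomplete-
    beta-function evaluations on the node grid.
    """
    from numpy.polynomial import legendre as L

    x, w = L.leggauss(n)
    P = np.stack([L.legval(x, [0.0] * i + [1.0]) for i in range(n)])
    coef = ((2.0 * np.arange(n) + 1.0) / 2.0)[:, None] * P * w[None, :]
    anti = np.empty((n, n))
    for i in range(n):
        if i == 0:
            anti[:, i] = x + 1.0
        else:
            anti[:, i] = (L.legval(x, [0.0] * (i + 1) + [1.0])
                          - L.legval(x, [0.0] * (i - 1) + [1.0])) / (2 * i + 1)
    S = 0.5 * (anti @ coef)
    y = 0.5 * (x + 1.0)
    return {
        "y": y[:, None],
        "log_y": np.log(y)[:, None],
        "log_1my": np.log1p(-y)[:, None],
        "w": 0.5 * w,
        "S": S,
    }


# The effective polynomial degree of the beta-density integrands is of the
# order of the total pseudo-counts, which the update rules bound by
# 1 + 1/rate; the rule order is chosen from the largest total in the batch.
_GL_RULES = {n: _gl_rule(n) for n in (48, 96)}

# Above this total pseudo-count the beta densities are too sharply peaked
# for a fixed global rule; both beliefs are then effectively Gaussian and a
# moment-matched normal approximation is accurate to ~1e-4.
_NORMAL_APPROX_TOTAL = 200.0


def prob_greater(ga, ea, gb, eb):
    """P(theta_A > theta_B) for independent beta(ga, ea) and beta(gb, eb).

    Vectorised over numpy arrays. Computed as the Gauss-Legendre quadrature
    of ``f_A(y) * F_B(y)`` on [0, 1], with a moment-matched normal
    approximation for very concentrated beliefs.
    """
    ga, ea, gb, eb = np.broadcast_arrays(
        np.asarray(ga, float), np.asarray(ea, float),
        np.asarray(gb, float), np.asarray(eb, float),
    )
    flat = [a.ravel() for a in (ga, ea, gb, eb)]
    fga, fea, fgb, feb = flat
    top = min(max((fga + fea).max(initial=0.0), (fgb + feb).max(initial=0.0)),
              _NORMAL_APPROX_TOTAL)
    rule = _GL_RULES[48 if top <= 18.0 else 96]
    # antisymmetrised form: P(A>B) = (1 + I)/2 with
    # I = integral of f_A F_B - f_B F_A, which integration by parts shows
    # equals 2P - 1; its quadrature is exactly antisymmetric under
    # swapping A and B, so P(A>B) + P(B>A) = 1 holds to machine precision
    # and the likelihood is exactly invariant to bandit relabelling.
    fa = np.exp((fga - 1.0) * rule["log_y"] + (fea - 1.0) * rule["log_1my"]
                - special.betaln(fga, fea))
    fb = np.exp((fgb - 1.0) * rule["log_y"] + (feb - 1.0) * rule["log_1my"]
                - special.betaln(fgb, feb))
    Fa = rule["S"] @ fa
    Fb = rule["S"] @ fb
    out = 0.5 * (1.0 + rule["w"] @ (fa * Fb - fb * Fa))

    big = (fga + fea > _NORMAL_APPROX_TOTAL) | (fgb + feb > _NORMAL_APPROX_TOTAL)
    if np.any(big):
        ma = fga / (fga + fea)
        mb = fgb / (fgb + feb)
        va = ma * (1 - ma) / (fga + fea + 1.0)
        vb = mb * (1 - mb) / (fgb + feb + 1.0)
        out = np.where(
            big, special.ndtr((ma - mb) / np.sqrt(va + vb)), out
        )
    out = np.clip(out, 0.0, 1.0)
    return out.reshape(ga.shape) if ga.shape else float(out[0])


def confidence(belief0: BeliefState | tuple, belief1: tuple | None = None,
               *, tol: float = 1e-6) -> ConfidencePair:
    """Confidence pair (C0, C1) with C1 = P(theta_1 > theta_0).

    Accepts either a :class:`BeliefState` or two ``(gamma, eps)`` tuples.
    Uses deterministic adaptive quadrature of ``f_1(y) * F_0(y)`` on [0, 1]
    to absolute tolerance ``tol``.
    """
    if isinstance(belief0, BeliefState):
        g0, e0 = belief0.gamma[0], belief0.eps[0]
        g1, e1 = belief0.gamma[1], belief0.eps[1]
    else:
        (g0, e0), (g1, e1) = belief0, belief1
    integrand = lambda y: stats.beta.pdf(y, g1, e1) * stats.beta.cdf(y, g0, e0)
    c1, err = integrate.quad(integrand, 0.0, 1.0, epsabs=tol, limit=200)
    if not math.isfinite(c1) or err > 100 * tol:
        raise ArithmeticError(
            f"confidence quadrature failed: value={c1}, err={err}, "
            f"beliefs=({g0},{e0})/({g1},{e1})"
        )
    c1 = min(max(c1, 0.0), 1.0)
    return ConfidencePair(c0=1.0 - c1, c1=c1)


def relative_confidence(pair: ConfidencePair, previous_choice: int | None) -> float:
    """Crel = C_chosen - C_unchosen = 2*C_chosen - 1; zero without a history."""
    if previous_choice is None:
        return 0.0
    c_chosen = pair.c1 if previous_choice == 1 else pair.c0
    return 2.0 * c_chosen - 1.0


# ---------------------------------------------------------------------------
# Propensities and choice probabilities
# ---------------------------------------------------------------------------

def action_propensities(
    spec: str | ModelSpec,
    params: Mapping[str, float],
    q: np.ndarray,
    v: np.ndarray | None = None,
    previous_choice: int | None = None,
    crel_prev: float = 0.0,
) -> Propensities:
    """Assemble per-bandit propensities from Q-values and add-on terms.

    ``q`` and ``v`` are the expected values and (Bayesian family) belief
    variances feeding this trial's choice; ``crel_prev`` is the relative
    confidence computed on the previous trial. All add-on terms are
    inactive when ``previous_choice`` is None (first trial, or first valid
    trial after a miss).
    """
    spec = get_spec(spec)
    p = validate_params(spec, params)
    base = np.asarray(q, float).copy()
    kern = np.zeros(2)
    var = np.zeros(2)
    conf = np.zeros(2)
    if previous_choice is not None:
        prev, other = previous_choice, 1 - previous_choice
        if spec.kernel:
            kern[prev] = p["b"]
        if spec.variance is not None:
            if v is None:
                raise ValueError("variance term requires belief variances")
            target = prev if spec.variance == "chosen" else other
            var[target] = p["upsilon"] * float(v[target])
        if spec.confidence:
            conf[other] = p["kappa"] * crel_prev
    m = base + kern + var + conf
    return Propensities(m=m, base=base, kernel=kern, variance=var, confidence=conf)


def softmax_choice_prob(m: np.ndarray | Propensities, beta: float) -> np.ndarray:
    """Softmax choice probabilities P(a) ∝ exp(beta * m_a), overflow-safe."""
    if isinstance(m, Propensities):
        m = m.m
    m = np.asarray(m, float)
    if not np.all(np.isfinite(m)):
        raise ArithmeticError(f"non-finite propensities {m}")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * (m - m.max())
    ez = np.exp(z)
    return ez / ez.sum()


# ---------------------------------------------------------------------------
# Sequence likelihood
# ---------------------------------------------------------------------------

def _forward_states(choices, rewards, valid, spec: ModelSpec, p: dict):
    """Propagate the internal state through a sequence.

    Returns per-trial arrays *at choice time* (i.e. before that trial's
    update): q (T,2), v (T,2) or None, and the RW prediction-error trace
    delta (T,) with NaN on missed trials.
    """
    T = len(choices)
    q = np.empty((T, 2))
    delta = np.full(T, np.nan)
    if spec.family == "rw":
        alpha, phi = p["alpha"], p.get("phi", 0.0)
        q0, q1 = 0.5, 0.5
        for t in range(T):
            q[t, 0], q[t, 1] = q0, q1
            if not valid[t]:
                continue
            c, r = choices[t], rewards[t]
            if c == 0:
                delta[t] = r - q0
                q0 += alpha * delta[t]
                if spec.forget:
                    q1 += phi * (0.5 - q1)
            else:
                delta[t] = r - q1
                q1 += alpha * delta[t]
                if spec.forget:
                    q0 += phi * (0.5 - q0)
        return q, None, delta, None

    omega = p["omega"]
    lam = p["lambda"] if not spec.single_rate else omega
    g = np.empty((T, 2))
    e = np.empty((T, 2))
    g0 = g1 = e0 = e1 = 1.0
    for t in range(T):
        g[t, 0], g[t, 1], e[t, 0], e[t, 1] = g0, g1, e0, e1
        if not valid[t]:
            continue
        c, r = choices[t], rewards[t]
        if c == 0:
            delta[t] = r - g0 / (g0 + e0)
            g0 = (1 - omega) * g0 + omega + r
            e0 = (1 - omega) * e0 + omega + (1 - r)
            g1 = (1 - lam) * g1 + lam
            e1 = (1 - lam) * e1 + lam
        else:
            delta[t] = r - g1 / (g1 + e1)
            g1 = (1 - omega) * g1 + omega + r
            e1 = (1 - omega) * e1 + omega + (1 - r)
            g0 = (1 - lam) * g0 + lam
            e0 = (1 - lam) * e0 + lam
    s = g + e
    q = g / s
    v = g * e / (s * s * (s + 1.0))
    return q, v, delta, (g, e)


# The belief/Q trajectory and the confidence vector depend only on the
# data and the update-rate parameters, not on beta or the propensity
# weights, so they are memoised across optimiser evaluations.
_TRAJ_CACHE: dict = {}
_TRAJ_CACHE_MAX = 128


def _trajectory(choices, rewards, valid, spec: ModelSpec, p: dict):
    """Per-trial state arrays (cached): q, v, delta, prev, crel, v_term.

    ``v_term`` is the variance feeding the trial's switching terms under
    the spec's state convention; ``crel`` is the relative confidence of
    the previous choice (zero when inactive or without history).
    """
    rates = ((p["alpha"], p.get("phi", 0.0)) if spec.family == "rw"
             else (p["omega"], p["lambda"]))
    key = (hash(choices.tobytes()), hash(rewards.tobytes()), spec.family,
           spec.forget, spec.single_rate, spec.variance, spec.confidence,
           spec.variance_state, rates)
    hit = _TRAJ_CACHE.get(key)
    if hit is not None:
        return hit

    T = len(choices)
    q, v, delta, counts = _forward_states(choices, rewards, valid, spec, p)
    prev = _previous_choice_vector(choices, valid)
    has_prev = prev >= 0

    # State feeding the variance/confidence add-ons of trial t: the belief
    # as of the previous trial's choice (default) or the current one.
    v_term = g_term = e_term = None
    if spec.family == "bayes" and (spec.variance is not None or spec.confidence):
        if spec.variance_state == "previous":
            idx = np.maximum(np.arange(T) - 1, 0)
            # has_prev gates trials whose predecessor was missed, so the
            # lagged state is always the previous valid choice's state
            v_term = v[idx]
            g_term = counts[0][idx]
            e_term = counts[1][idx]
        else:
            v_term = v
            g_term, e_term = counts

    crel = np.zeros(T)
    if spec.confidence and np.any(has_prev):
        sel = has_prev
        c1 = prob_greater(
            g_term[sel, 1], e_term[sel, 1], g_term[sel, 0], e_term[sel, 0]
        )
        c_chosen = np.where(prev[sel] == 1, c1, 1.0 - c1)
        crel[sel] = 2.0 * c_chosen - 1.0

    if len(_TRAJ_CACHE) >= _TRAJ_CACHE_MAX:
        _TRAJ_CACHE.clear()
    out = (q, v, delta, prev, crel, v_term)
    _TRAJ_CACHE[key] = out
    return out


def _previous_choice_vector(choices, valid):
    """prev[t] = choice on trial t-1 if that trial was valid, else -1.

    A miss breaks the history: add-on terms are inactive on the first
    valid trial after it.
    """
    T = len(choices)
    prev = np.full(T, -1, dtype=int)
    prev[1:] = np.where(valid[:-1], choices[:-1], -1)
    return prev


def sequence_loglik(
    trials,
    spec: str | ModelSpec,
    params: Mapping[str, float],
    return_trace: bool = False,
):
    """Total log likelihood of one subject's choices under a model.

    Missed trials contribute nothing and trigger no belief update. With
    ``return_trace=True`` also returns a dict of per-trial arrays (NaN on
    missed trials): expected values ``q0``/``q1``, belief variances
    ``v0``/``v1``, prediction error ``delta``, chosen value ``q_chosen``,
    relative confidence ``crel``, propensities ``m0``/``m1``, choice
    probabilities ``p0``/``p1``, and ``logp`` of the observed choice —
    the source of all model-derived regressors.
    """
    spec = get_spec(spec)
    p = validate_params(spec, params)
    choices = np.asarray(trials.choices)
    rewards = np.asarray(trials.rewards)
    valid = choices >= 0
    T = len(choices)
    if valid.sum() == 0:
        import warnings

        warnings.warn("sequence has no valid responses; log likelihood is 0")

    q, v, delta, prev, crel, v_term = _trajectory(
        choices, rewards, valid, spec, p)
    has_prev = prev >= 0

    m = q.copy()
    if spec.kernel:
        rows = np.nonzero(has_prev)[0]
        m[rows, prev[rows]] += p["b"]
    if spec.variance is not None:
        rows = np.nonzero(has_prev)[0]
        tgt = prev[rows] if spec.variance == "chosen" else 1 - prev[rows]
        m[rows, tgt] += p["upsilon"] * v_term[rows, tgt]
    if spec.confidence:
        rows = np.nonzero(has_prev)[0]
        tgt = 1 - prev[rows]
        m[rows, tgt] += p["kappa"] * crel[rows]

    beta = p["beta"]
    dm = beta * (m[:, 1] - m[:, 0])  # propensity difference scaled
    # log P(choice) via the logistic of the signed propensity difference
    signed = np.where(choices == 1, dm, -dm)
    logp = special.log_expit(np.where(valid, signed, 0.0))
    total = float(logp[valid].sum())
    if not return_trace:
        return total

    p1 = special.expit(dm)
    trace = {
        "q0": q[:, 0].copy(), "q1": q[:, 1].copy(),
        "v0": v[:, 0].copy() if v is not None else np.full(T, np.nan),
        "v1": v[:, 1].copy() if v is not None else np.full(T, np.nan),
        "delta": delta.copy(),
        "q_chosen": np.where(valid, np.take_along_axis(
            q, np.clip(choices, 0, 1)[:, None], axis=1).ravel(), np.nan),
        "crel": crel.copy(),
        "m0": m[:, 0], "m1": m[:, 1],
        "p0": 1.0 - p1, "p1": p1,
        "logp": np.where(valid, logp, np.nan),
    }
    return total, trace
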