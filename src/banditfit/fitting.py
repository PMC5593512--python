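"""Hierarchical model fitting: per-subject MAP under Gaussian group priors
on transformed parameters, wrapped in an expectation-maximisation loop with
a Laplace approximation of each subject's posterior.

Parameters are optimised on an unconstrained scale — log for the inverse
temperature, logit for rates in (0, 1), identity for the unbounded
weights — so that Gaussian group priors respect the natural bounds. The
E-step computes each subject's MAP estimate and inverse-Hessian (Laplace)
covariance; the M-step moment-matches the group prior to the posterior
means and variances. Iterating shrinks individual estimates towards the
group and prevents extreme values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .models import ModelSpec, get_spec, sequence_loglik

__all__ = [
    "TRANSFORMS",
    "transform_to",
    "transform_from",
    "GroupPrior",
    "flat_prior",
    "SubjectFit",
    "EMResult",
    "fit_map_subject",
    "laplace_evidence",
    "fit_em_group",
    "HierarchicalEM",
]

#: Transform applied to each parameter before Gaussian priors are placed.
TRANSFORMS: dict[str, str] = {
    "beta": "log",
    "alpha": "logit",
    "phi": "logit",
    "omega": "logit",
    "lambda": "logit",
    "b": "identity",
    "upsilon": "identity",
    "kappa": "identity",
}


def _fwd(name: str, value: float) -> float:
    kind = TRANSFORMS[name]
    if kind == "log":
        if value <= 0:
            raise ValueError(f"{name}={value} not in (0, inf)")
        return math.log(value)
    if kind == "logit":
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name}={value} not in (0, 1)")
        return math.log(value / (1.0 - value))
    return float(value)


def _inv(name: str, value: float) -> float:
    kind = TRANSFORMS[name]
    if kind == "log":
        # clamp so optimiser excursions cannot overflow; e^50 ~ 5e21 is
        # already an operationally greedy inverse temperature
        return math.exp(min(value, 50.0))
    if kind == "logit":
        return float(special.expit(value))
    return float(value)


def transform_to(params: Mapping[str, float], spec: str | ModelSpec) -> np.ndarray:
    """Natural-scale parameters -> unconstrained vector (spec order)."""
    spec = get_spec(spec)
    return np.array([_fwd(n, params[n]) for n in spec.param_names])


def transform_from(x: Mapping[str, float] | np.ndarray,
                   spec: str | ModelSpec) -> dict[str, float]:
    """Unconstrained vector or dict -> natural-scale parameter dict."""
    spec = get_spec(spec)
    names = spec.param_names
    if isinstance(x, Mapping):
        return {n: _inv(n, x[n]) for n in names}
    x = np.asarray(x, float)
    return {n: _inv(n, x[i]) for i, n in enumerate(names)}


@dataclass
class GroupPrior:
    """Independent Gaussian prior per parameter on the transformed scale."""

    param_names: tuple[str, ...]
    mean: np.ndarray
    var: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.var = np.asarray(self.var, float)
        if not (len(self.param_names) == len(self.mean) == len(self.var)):
            raise ValueError("prior dimensions do not match parameter names")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    def log_density(self, x: np.ndarray) -> float:
        z2 = (x - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z2 + np.log(2.0 * math.pi * self.var)))


def flat_prior(spec: str | ModelSpec, variance: float = 100.0) -> GroupPrior:
    """Effectively uninformative (but proper) initial prior: N(0, variance)."""
    spec = get_spec(spec)
    d = spec.k
    return GroupPrior(spec.param_names, np.zeros(d), np.full(d, variance))


@dataclass
class SubjectFit:
    """MAP estimate with Laplace covariance for one subject."""

    subject_id: str
    param_names: tuple[str, ...]
    x_map: np.ndarray                 # transformed scale
    params: dict[str, float]          # natural scale
    loglik: float                     # log likelihood at the MAP
    log_joint: float                  # loglik + log prior at the MAP
    cov: np.ndarray                   # inverse Hessian of -log joint
    hessian_regularised: bool = False
    converged: bool = True
    n_restarts_used: int = 0


def _neg_log_joint(x, seq, spec, prior):
    params = transform_from(x, spec)
    return -sequence_loglik(seq, spec, params) - prior.log_density(x)


def _finite_diff_hessian(f, x, step=1e-4):
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / step ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step ** 2)
    return H


def fit_map_subject(
    trials,
    spec: str | ModelSpec,
    prior: GroupPrior,
    n_restarts: int = 5,
    seed: int = 0,
    hessian_step: float = 1e-4,
    restart_sd_cap: float = 2.0,
    x0: np.ndarray | None = None,
) -> SubjectFit:
    """Maximum a posteriori fit of one subject from multiple restarts.

    Minimises the negative log joint (likelihood x prior) on the
    transformed scale with L-BFGS-B, starting from the prior mean, an
    optional warm start ``x0``, and ``n_restarts`` draws around the prior
    mean (draw sd capped at ``restart_sd_cap`` so a deliberately flat
    prior does not scatter starts into numerically absurd regions). The
    Laplace covariance is the inverse of a central-finite-difference
    Hessian at the optimum; a non-positive-definite Hessian is jittered to
    the nearest positive-definite matrix and flagged.
    """
    spec = get_spec(spec)
    if getattr(trials, "n_valid", 1) < 1:
        raise ValueError("subject has no valid responses")
    rng = np.random.default_rng(seed)
    d = spec.k
    f = lambda x: _neg_log_joint(x, trials, spec, prior)

    starts = [prior.mean.copy()]
    if x0 is not None:
        starts.append(np.asarray(x0, float))
    sd = np.minimum(np.sqrt(prior.var), restart_sd_cap)
    for _ in range(n_restarts):
        starts.append(prior.mean + rng.normal(0.0, sd, size=d))

    best = None
    any_success = False
    for s in starts:
        res = optimize.minimize(f, s, method="L-BFGS-B")
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"MAP optimisation failed for {trials.subject_id}")

    H = _finite_diff_hessian(f, best.x, step=hessian_step)
    H = 0.5 * (H + H.T)
    regularised = False
    jitter = 0.0
    eigs = np.linalg.eigvalsh(H)
    if eigs.min() <= 1e-10:
        jitter = abs(eigs.min()) + 1e-6
        H = H + jitter * np.eye(d)
        regularised = True
    cov = np.linalg.inv(H)

    params = transform_from(best.x, spec)
    ll = sequence_loglik(trials, spec, params)
    return SubjectFit(
        subject_id=getattr(trials, "subject_id", "?"),
        param_names=spec.param_names,
        x_map=best.x,
        params=params,
        loglik=float(ll),
        log_joint=float(-best.fun),
        cov=cov,
        hessian_regularised=regularised,
        converged=bool(any_success),
        n_restarts_used=len(starts),
    )


def laplace_evidence(fit: SubjectFit) -> float:
    """Laplace approximation of one subject's log marginal likelihood.

    log p(data) ~= log joint at MAP + (d/2) log 2*pi + (1/2) log det cov,
    where cov is the inverse Hessian of the negative log joint.
    """
    d = len(fit.x_map)
    sign, logdet = np.linalg.slogdet(fit.cov)
    if sign <= 0:
        raise ValueError("Laplace covariance is not positive-definite")
    return fit.log_joint + 0.5 * d * math.log(2.0 * math.pi) + 0.5 * logdet


@dataclass
class EMResult:
    """Outcome of the hierarchical EM fit."""

    spec: ModelSpec
    prior: GroupPrior
    subject_fits: list[SubjectFit]
    objective: list[float]            # -sum Laplace evidence per iteration
    n_iter: int
    converged: bool
    variance_floored: bool = False

    def params_frame(self):
        import pandas as pd

        rows = [{"subject_id": f.subject_id, **f.params}
                for f in self.subject_fits]
        return pd.DataFrame(rows)


def fit_em_group(
    dataset: Sequence,
    spec: str | ModelSpec,
    n_restarts: int = 5,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int = 0,
    hessian_step: float = 1e-4,
    init_prior_variance: float = 100.0,
    var_floor: float = 1e-8,
) -> EMResult:
    """Expectation-maximisation over a cohort.

    E-step: MAP + Laplace covariance per subject under the current prior
    (restarts in the first iteration, warm starts from the previous MAP
    thereafter). M-step: prior mean <- mean of subject MAPs; prior
    variance <- mean(MAP^2 + Laplace variance) - mean(MAP)^2, per
    parameter. Stops when the largest absolute change in the prior means
    falls below ``tol``.
    """
    spec = get_spec(spec)
    if len(dataset) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    prior = flat_prior(spec, init_prior_variance)
    seeds = np.random.SeedSequence(seed).generate_state(len(dataset))
    fits: list[SubjectFit] = []
    objective: list[float] = []
    converged = False
    floored = False

    for it in range(max_iter):
        new_fits = []
        for i, seq in enumerate(dataset):
            x0 = fits[i].x_map if fits else None
            restarts = n_restarts if it == 0 else 1
            new_fits.append(
                fit_map_subject(seq, spec, prior, n_restarts=restarts,
                                seed=int(seeds[i]) + it, x0=x0,
                                hessian_step=hessian_step)
            )
        fits = new_fits
        objective.append(-sum(laplace_evidence(f) for f in fits))

        X = np.stack([f.x_map for f in fits])
        V = np.stack([np.diag(f.cov) for f in fits])
        mu = X.mean(axis=0)
        var = (X ** 2 + V).mean(axis=0) - mu ** 2
        if np.any(var < var_floor):
            floored = True
            warnings.warn("group prior variance floored; the cohort may be "
                          "degenerate for some parameter")
            var = np.maximum(var, var_floor)
        shift = np.max(np.abs(mu - prior.mean))
        prior = GroupPrior(spec.param_names, mu, var, iteration=it + 1)
        if shift < tol:
            converged = True
            break

    return EMResult(spec=spec, prior=prior, subject_fits=fits,
                    objective=objective, n_iter=prior.iteration,
                    converged=converged, variance_floored=floored)


class HierarchicalEM(BaseEstimator):
    """Scikit-learn style estimator for the hierarchical EM fit.

    Parameters mirror :func:`fit_em_group`. ``fit(X)`` accepts a list of
    :class:`~banditfit.task.TrialSequence` or a tidy trial table
    (`pandas.DataFrame` in the format of :func:`banditfit.io.read_trials`).

    Attributes
    ----------
    prior_ : GroupPrior
        Fitted group-level prior (transformed scale).
    subject_fits_ : list of SubjectFit
        Per-subject MAP estimates with Laplace covariances.
    objective_ : list of float
        Penalised negative log evidence per EM iteration.
    n_iter_ : int
        Number of EM iterations performed.
    """

    def __init__(self, spec="bayes_full", n_restarts=5, max_iter=50,
                 tol=1e-3, hessian_step=1e-4, init_prior_variance=100.0,
                 random_state=0):
        self.spec = spec
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.hessian_step = hessian_step
        self.init_prior_variance = init_prior_variance
        self.random_state = random_state

    def fit(self, X, y=None):
        dataset = _as_dataset(X)
        result = fit_em_group(
            dataset, self.spec, n_restarts=self.n_restarts,
            max_iter=self.max_iter, tol=self.tol, seed=self.random_state,
            hessian_step=self.hessian_step,
            init_prior_variance=self.init_prior_variance,
        )
        self.result_ = result
        self.spec_ = result.spec
        self.prior_ = result.prior
        self.subject_fits_ = result.subject_fits
        self.objective_ = result.objective
        self.n_iter_ = result.n_iter
        return self

    def score(self, X, y=None):
        """Total MAP log likelihood of ``X`` under the per-subject fits."""
        dataset = _as_dataset(X)
        if len(dataset) != len(self.subject_fits_):
            raise ValueError("dataset size does not match the fit")
        return float(sum(
            sequence_loglik(seq, self.spec_, f.params)
            for seq, f in zip(dataset, self.subject_fits_)
        ))


def _as_dataset(X):
    """Coerce a DataFrame trial table or sequence list to TrialSequences."""
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        from .io import frame_to_dataset

        return frame_to_dataset(X)
    return list(X)
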