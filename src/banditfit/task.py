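"""Restless two-armed bandit task environment and synthetic cohorts.

The task presents two bandits whose hidden reward probabilities drift over
220 trials as independent Gaussian random walks reflected at configurable
bounds; each choice pays a binary 1-unit reward (1 SEK in the original
design) with the chosen bandit's current probability. Agents simulated
under any model in the grid provide synthetic cohorts for parameter- and
model-recovery studies, replacing undeposited human data.

Bandits are labelled 0/1 internally; published worked examples label them
1/2, and the reader in :mod:`banditfit.io` accepts that labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec, get_spec, validate_params

__all__ = [
    "WalkConfig",
    "TrialSequence",
    "CohortSpec",
    "generate_random_walks",
    "simulate_agent",
    "generate_cohort",
    "default_group_params",
    "fig2_fixture",
    "FIG2_CHOICES",
    "FIG2_REWARDS",
    "FIG2_PARAMS",
]


@dataclass(frozen=True)
class WalkConfig:
    """Gaussian random walk on reward probabilities, reflected at bounds.

    ``start`` fixes the initial probabilities; when None they are drawn
    uniformly within the bounds from the seed.
    """

    n_trials: int = 220
    step_sd: float = 0.05
    bounds: tuple[float, float] = (0.1, 0.9)
    start: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid bounds {self.bounds}")
        if self.step_sd < 0:
            raise ValueError("step_sd must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.start is not None:
            for s in self.start:
                if not (lo <= s <= hi):
                    raise ValueError(f"start {self.start} outside bounds")


@dataclass
class TrialSequence:
    """One subject's ordered trials.

    ``choices`` and ``rewards`` are integer arrays with -1 marking a missed
    trial (choice missing if and only if reward missing); ``p0``/``p1``
    hold the true hidden reward probabilities when known.
    """

    subject_id: str
    choices: np.ndarray
    rewards: np.ndarray
    p0: np.ndarray | None = None
    p1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=int)
        if self.choices.shape != self.rewards.shape or self.choices.ndim != 1:
            raise ValueError("choices and rewards must be equal-length 1-d")
        if np.any((self.choices < 0) != (self.rewards < 0)):
            raise ValueError("reward must be missing iff choice is missing")
        if np.any(self.choices > 1) or np.any(self.rewards > 1):
            raise ValueError("choices and rewards must be in {0, 1} or missing")
        for p in (self.p0, self.p1):
            if p is not None:
                p = np.asarray(p, float)
                if p.shape != self.choices.shape:
                    raise ValueError("probability trajectories must match length")
                if np.any((p < 0) | (p > 1)):
                    raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.choices)

    @property
    def n_valid(self) -> int:
        return int((self.choices >= 0).sum())

    @property
    def missed(self) -> np.ndarray:
        return self.choices < 0

    def to_frame(self) -> pd.DataFrame:
        T = len(self)
        df = pd.DataFrame({
            "subject_id": self.subject_id,
            "trial_index": np.arange(1, T + 1),
            "choice": [c if c >= 0 else pd.NA for c in self.choices],
            "reward": [r if r >= 0 else pd.NA for r in self.rewards],
            "missed": (self.choices < 0).astype(int),
        })
        if self.p0 is not None:
            df["p0"] = np.asarray(self.p0, float)
            df["p1"] = np.asarray(self.p1, float)
        return df


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold into [lo, hi]; terminates because each fold shrinks the excursion
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


def generate_random_walks(config: WalkConfig) -> np.ndarray:
    """Two independent reflected Gaussian random walks, shape (n_trials, 2)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    if config.start is None:
        start = rng.uniform(lo, hi, size=2)
    else:
        start = np.asarray(config.start, float)
    walks = np.empty((config.n_trials, 2))
    walks[0] = start
    steps = rng.normal(0.0, config.step_sd, size=(config.n_trials - 1, 2))
    for t in range(1, config.n_trials):
        for a in range(2):
            walks[t, a] = _reflect(walks[t - 1, a] + steps[t - 1, a], lo, hi)
    return walks


def simulate_agent(
    walks: np.ndarray,
    spec: str | ModelSpec,
    params: Mapping[str, float],
    seed: int,
    subject_id: str = "sim",
) -> TrialSequence:
    """Simulate one agent's choices and rewards on a given environment.

    On each trial the model's propensities are computed from the current
    internal state, a choice is drawn from the softmax probabilities, the
    reward is Bernoulli in the chosen bandit's true probability, and the
    state is updated. Fully reproducible given the seed.
    """
    from math import exp

    from .models import prob_greater

    spec = get_spec(spec)
    p = validate_params(spec, params)
    walks = np.asarray(walks, float)
    T = walks.shape[0]
    rng = np.random.default_rng(seed)
    choice_u = rng.random(T)
    reward_u = rng.random(T)

    beta = p["beta"]
    fam = spec.family
    q = [0.5, 0.5]
    g = [1.0, 1.0]
    e = [1.0, 1.0]
    prev_choice: int | None = None
    crel_prev = 0.0
    v_prev = [0.0, 0.0]   # variances at the previous trial's choice
    choices = np.empty(T, dtype=int)
    rewards = np.empty(T, dtype=int)
    for t in range(T):
        if fam == "bayes":
            s0, s1 = g[0] + e[0], g[1] + e[1]
            q = [g[0] / s0, g[1] / s1]
            v_now = [g[0] * e[0] / (s0 * s0 * (s0 + 1.0)),
                     g[1] * e[1] / (s1 * s1 * (s1 + 1.0))]
        m = [q[0], q[1]]
        if prev_choice is not None:
            other = 1 - prev_choice
            if spec.kernel:
                m[prev_choice] += p["b"]
            if spec.variance is not None:
                v_use = v_prev if spec.variance_state == "previous" else v_now
                tgt = prev_choice if spec.variance == "chosen" else other
                m[tgt] += p["upsilon"] * v_use[tgt]
            if spec.confidence:
                m[other] += p["kappa"] * crel_prev
        dm = beta * (m[1] - m[0])
        p1 = 1.0 / (1.0 + exp(-dm)) if abs(dm) < 500 else float(dm > 0)
        c = int(choice_u[t] < p1)
        r = int(reward_u[t] < walks[t, c])
        choices[t] = c
        rewards[t] = r
        # history terms for the next trial, from this trial's choice-time
        # state (default) or the post-outcome state
        if fam == "bayes":
            if spec.variance_state == "previous":
                v_prev = v_now
                if spec.confidence:
                    c1 = prob_greater(g[1], e[1], g[0], e[0])
                    crel_prev = 2.0 * (c1 if c == 1 else 1.0 - c1) - 1.0
            u = 1 - c
            g[c] = (1 - p["omega"]) * g[c] + p["omega"] + r
            e[c] = (1 - p["omega"]) * e[c] + p["omega"] + (1 - r)
            g[u] = (1 - p["lambda"]) * g[u] + p["lambda"]
            e[u] = (1 - p["lambda"]) * e[u] + p["lambda"]
            if spec.variance_state == "current" and spec.confidence:
                c1 = prob_greater(g[1], e[1], g[0], e[0])
                crel_prev = 2.0 * (c1 if c == 1 else 1.0 - c1) - 1.0
        else:
            q[c] += p["alpha"] * (r - q[c])
            if spec.forget:
                u = 1 - c
                q[u] += p["phi"] * (0.5 - q[u])
        prev_choice = c
    return TrialSequence(subject_id, choices, rewards,
                         p0=walks[:, 0].copy(), p1=walks[:, 1].copy())


# Transformed-scale group distributions calibrated so that untransformed
# quartiles bracket the fitted-parameter summary of the original cohort
# (log for beta, logit for the rates, identity for b/upsilon/kappa; the
# mean is the reported median, the sd is the half-interquartile range
# divided by the normal quartile 0.6745).
_DEFAULT_GROUP: dict[str, tuple[float, float]] = {
    "beta": (2.508, 0.687),
    "alpha": (-0.85, 0.80),
    "b": (0.20, 0.50),
    "phi": (-1.40, 0.60),
    "omega": (-0.372, 1.036),
    "lambda": (-1.374, 0.616),
    "upsilon": (-1.069, 0.865),
    "kappa": (0.260, 0.153),
}


def default_group_params(spec: str | ModelSpec) -> tuple[dict, dict]:
    """Default transformed-scale group means and sds for a model spec."""
    spec = get_spec(spec)
    means = {n: _DEFAULT_GROUP[n][0] for n in spec.param_names}
    sds = {n: _DEFAULT_GROUP[n][1] for n in spec.param_names}
    return means, sds


@dataclass
class CohortSpec:
    """A cohort of agents with parameters drawn from group Gaussians.

    Means and sds live on the transformed scale (log beta, logit rates,
    identity for the unbounded weights); defaults are calibrated to the
    fitted-parameter quartiles of the original study cohort.
    """

    n_subjects: int = 30
    model: str | ModelSpec = "bayes_full"
    group_means: Mapping[str, float] | None = None
    group_sds: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.model = get_spec(self.model)
        means, sds = default_group_params(self.model)
        if self.group_means is not None:
            means.update(self.group_means)
        if self.group_sds is not None:
            sds.update(self.group_sds)
        names = self.model.param_names
        if set(means) - set(names) or set(sds) - set(names):
            raise ValueError("group parameters do not match the model spec")
        if any(sds[n] < 0 for n in names):
            raise ValueError("group sds must be non-negative")
        self.group_means = {n: float(means[n]) for n in names}
        self.group_sds = {n: float(sds[n]) for n in names}
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


def generate_cohort(
    cohort: CohortSpec, walk: WalkConfig
) -> tuple[list[TrialSequence], pd.DataFrame]:
    """Simulate a cohort on a shared environment.

    All subjects face the same pair of random walks, as in the original
    design. Returns the trial sequences and a truth table with one row per
    subject and one column per natural-scale generative parameter.
    """
    from .fitting import transform_from  # deferred: avoid import cycle

    spec = get_spec(cohort.model)
    walks = generate_random_walks(walk)
    root = np.random.SeedSequence(cohort.seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    agent_seeds = root.generate_state(cohort.n_subjects)

    seqs: list[TrialSequence] = []
    rows = []
    for i in range(cohort.n_subjects):
        x = {
            n: draw_rng.normal(cohort.group_means[n], cohort.group_sds[n])
            for n in spec.param_names
        }
        params = transform_from(x, spec)
        sid = f"sub{i + 1:03d}"
        seqs.append(simulate_agent(walks, spec, params,
                                   seed=int(agent_seeds[i]), subject_id=sid))
        rows.append({"subject_id": sid, **params,
                     "agent_seed": int(agent_seeds[i])})
    truth = pd.DataFrame(rows)
    return seqs, truth


# ---------------------------------------------------------------------------
# Published worked example: 20 trials of one participant
# ---------------------------------------------------------------------------

#: Printed choice sequence of the worked example, relabelled 1/2 -> 0/1.
FIG2_CHOICES = np.array([1, 1, 1, 2, 1, 1, 1, 2, 2, 1,
                         2, 2, 1, 1, 1, 2, 2, 2, 2, 1]) - 1
#: Printed payout sequence of the worked example.
FIG2_REWARDS = np.array([1, 1, 0, 0, 1, 1, 0, 1, 0, 0,
                         0, 0, 1, 1, 0, 0, 1, 1, 0, 1])
#: The participant's individually fitted update rates.
FIG2_PARAMS = {"omega": 0.72, "lambda": 0.28}


def fig2_fixture() -> TrialSequence:
    """The published 20-trial worked-example sequence (bandits 1/2 -> 0/1)."""
    return TrialSequence("fig2", FIG2_CHOICES.copy(), FIG2_REWARDS.copy())
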