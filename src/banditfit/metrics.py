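"""Behavioural performance measures for bandit-task sequences.

Four per-subject summaries: total monetary gains (1 unit per rewarded
trial), proportion of efficient choices (the bandit whose true hidden
probability was higher), number of switches between bandits, and the
proportion of adaptive switches (switches to the bandit with the higher
model-derived expected value at the time of the switch). Ties in the true
probabilities or in the model values count one half. Misses are not
choices: consecutive valid choices are compared across them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .models import get_spec, sequence_loglik

__all__ = [
    "total_gains",
    "efficient_choice_rate",
    "count_switches",
    "adaptive_switch_rate",
    "performance_summary",
    "summarize_cohort",
]


def total_gains(trials) -> int:
    """Number of rewarded trials (monetary gain in reward units)."""
    return int((np.asarray(trials.rewards) == 1).sum())


def efficient_choice_rate(trials) -> float:
    """Fraction of valid trials choosing the truly better bandit.

    Requires the hidden probabilities; exact ties count 0.5.
    """
    if trials.p0 is None or trials.p1 is None:
        raise ValueError("efficient choices need the true reward probabilities")
    choices = np.asarray(trials.choices)
    valid = choices >= 0
    if valid.sum() == 0:
        return math.nan
    p0 = np.asarray(trials.p0, float)[valid]
    p1 = np.asarray(trials.p1, float)[valid]
    chosen = np.where(choices[valid] == 1, p1, p0)
    other = np.where(choices[valid] == 1, p0, p1)
    score = np.where(chosen > other, 1.0, np.where(chosen == other, 0.5, 0.0))
    return float(score.mean())


def _valid_pairs(choices):
    """Indices (i, j) of consecutive valid choices, skipping misses."""
    idx = np.nonzero(np.asarray(choices) >= 0)[0]
    return list(zip(idx[:-1], idx[1:]))


def count_switches(trials) -> int:
    """Number of consecutive valid-choice pairs with unequal choices."""
    choices = np.asarray(trials.choices)
    return sum(int(choices[i] != choices[j]) for i, j in _valid_pairs(choices))


def adaptive_switch_rate(trials, q_trace: np.ndarray) -> float:
    """Among switches, the fraction towards the subjectively better bandit.

    ``q_trace`` is the (T, 2) array of model expected values at choice
    time, e.g. columns ``q0``/``q1`` of the :func:`sequence_loglik` trace
    under the subject's fitted parameters. Q-ties count 0.5; with no
    switches the rate is undefined (NaN).
    """
    choices = np.asarray(trials.choices)
    q_trace = np.asarray(q_trace, float)
    if q_trace.shape != (len(choices), 2):
        raise ValueError("q_trace must have shape (n_trials, 2)")
    scores = []
    for i, j in _valid_pairs(choices):
        if choices[i] == choices[j]:
            continue
        new, old = choices[j], 1 - choices[j]
        qn, qo = q_trace[j, new], q_trace[j, old]
        scores.append(1.0 if qn > qo else 0.5 if qn == qo else 0.0)
    return float(np.mean(scores)) if scores else math.nan


def performance_summary(trials, spec=None, params=None) -> dict:
    """All four measures for one subject.

    The adaptive-switch rate needs a model: pass the (winning) spec and the
    subject's fitted parameters. Efficient choices need true probabilities;
    both are NaN when their inputs are absent.
    """
    out = {
        "subject_id": trials.subject_id,
        "total_gains": total_gains(trials),
        "n_valid": trials.n_valid,
        "n_switches": count_switches(trials),
    }
    out["efficient_choice_rate"] = (
        efficient_choice_rate(trials)
        if trials.p0 is not None and trials.p1 is not None else math.nan
    )
    if spec is not None and params is not None:
        _, trace = sequence_loglik(trials, get_spec(spec), params,
                                   return_trace=True)
        q = np.column_stack([trace["q0"], trace["q1"]])
        out["adaptive_switch_rate"] = adaptive_switch_rate(trials, q)
    else:
        out["adaptive_switch_rate"] = math.nan
    return out


def summarize_cohort(dataset, spec=None, params_by_subject=None) -> pd.DataFrame:
    """One summary row per subject; see :func:`performance_summary`."""
    rows = []
    for seq in dataset:
        params = None
        if params_by_subject is not None:
            params = params_by_subject.get(seq.subject_id)
        rows.append(performance_summary(
            seq, spec if params is not None else None, params))
    return pd.DataFrame(rows)
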