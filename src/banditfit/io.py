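"""Tab-separated file formats: trial tables, regressor tables, fit
summaries, and run configuration.

The trial table has one row per trial with columns ``subject_id``,
``trial_index`` (1-based, contiguous per subject), ``choice`` and
``reward`` (0/1 or the literal ``NA`` on missed trials), optional true
probabilities ``p0``/``p1``, and a ``missed`` flag. Bandits are 0/1
internally; a reader flag accepts 1/2 labels as used in published
figures. The regressor table carries the trial-wise model quantities used
as imaging parametric modulators: the chosen expected value Q at choice,
the outcome R, the prediction error R - Q, the unchosen-option variance,
relative confidence, and the model choice probabilities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import ModelSpec, get_spec, sequence_loglik
from .task import TrialSequence

__all__ = [
    "read_trials",
    "write_trials",
    "frame_to_dataset",
    "dataset_to_frame",
    "export_regressors",
    "regressor_frame",
    "RunConfig",
]

_NA = "NA"


class SchemaError(ValueError):
    """A trial table violated the format contract."""


def dataset_to_frame(dataset: Sequence[TrialSequence]) -> pd.DataFrame:
    return pd.concat([seq.to_frame() for seq in dataset], ignore_index=True)


def frame_to_dataset(df: pd.DataFrame, one_based_bandits: bool = False
                     ) -> list[TrialSequence]:
    """Validate a tidy trial table and split it into TrialSequences.

    With ``one_based_bandits=True`` choices labelled 1/2 are mapped to the
    internal 0/1.
    """
    required = {"subject_id", "trial_index", "choice", "reward"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.reset_index(drop=True)
        idx = grp["trial_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(grp) + 1)):
            raise SchemaError(
                f"subject {sid!r}: trial_index must be 1..T contiguous")
        choices = np.empty(len(grp), dtype=int)
        rewards = np.empty(len(grp), dtype=int)
        for k, row in grp.iterrows():
            c, r = row["choice"], row["reward"]
            c_na, r_na = pd.isna(c), pd.isna(r)
            if c_na != r_na:
                raise SchemaError(
                    f"subject {sid!r}, trial {row['trial_index']}: reward "
                    "must be missing exactly when choice is missing")
            if "missed" in grp.columns and not pd.isna(row["missed"]):
                if bool(int(row["missed"])) != c_na:
                    raise SchemaError(
                        f"subject {sid!r}, trial {row['trial_index']}: "
                        "missed flag inconsistent with NA choice")
            if c_na:
                choices[k] = rewards[k] = -1
            else:
                c = int(c) - (1 if one_based_bandits else 0)
                if c not in (0, 1) or int(r) not in (0, 1):
                    raise SchemaError(
                        f"subject {sid!r}, trial {row['trial_index']}: "
                        f"invalid choice/reward ({row['choice']}, {r})")
                choices[k] = c
                rewards[k] = int(r)
        p0 = grp["p0"].to_numpy(float) if "p0" in grp.columns else None
        p1 = grp["p1"].to_numpy(float) if "p1" in grp.columns else None
        if (p0 is None) != (p1 is None):
            raise SchemaError(f"subject {sid!r}: p0 and p1 must come together")
        out.append(TrialSequence(str(sid), choices, rewards, p0=p0, p1=p1))
    return out


def read_trials(path, one_based_bandits: bool = False) -> list[TrialSequence]:
    """Read a tab-separated trial table; see the module docstring."""
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    return frame_to_dataset(df, one_based_bandits=one_based_bandits)


def write_trials(dataset: Sequence[TrialSequence], path) -> None:
    """Write a dataset as a tab-separated trial table (NA for misses)."""
    df = dataset_to_frame(dataset)
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def regressor_frame(trials: TrialSequence, spec: str | ModelSpec,
                    params: Mapping[str, float]) -> pd.DataFrame:
    """Trial-wise model regressors from the likelihood trace.

    Columns: Q of the chosen bandit at choice, outcome R, prediction error
    RPE = R - Q_chosen at outcome, unchosen-option variance, relative
    confidence, and choice probabilities. Missed trials give NA rows.
    """
    spec = get_spec(spec)
    _, tr = sequence_loglik(trials, spec, params, return_trace=True)
    choices = np.asarray(trials.choices)
    valid = choices >= 0
    T = len(choices)
    v_unchosen = np.full(T, np.nan)
    if spec.family == "bayes":
        sel = valid
        v = np.column_stack([tr["v0"], tr["v1"]])
        v_unchosen[sel] = v[sel, 1 - np.clip(choices[sel], 0, 1)]
    rewards = np.where(valid, trials.rewards, np.nan).astype(float)
    df = pd.DataFrame({
        "subject_id": trials.subject_id,
        "trial_index": np.arange(1, T + 1),
        "q_chosen": tr["q_chosen"],
        "q0": np.where(valid, tr["q0"], np.nan),
        "q1": np.where(valid, tr["q1"], np.nan),
        "reward": rewards,
        "rpe": np.where(valid, tr["delta"], np.nan),
        "v_unchosen": v_unchosen,
        "crel": np.where(valid, tr["crel"], np.nan),
        "p_choice0": np.where(valid, tr["p0"], np.nan),
        "p_choice1": np.where(valid, tr["p1"], np.nan),
    })
    return df


def export_regressors(dataset: Sequence[TrialSequence],
                      spec: str | ModelSpec,
                      params_by_subject: Mapping[str, Mapping[str, float]],
                      outdir) -> list[Path]:
    """One regressor TSV per subject, from the fitted parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seq in dataset:
        if seq.subject_id not in params_by_subject:
            raise ValueError(f"no fitted parameters for {seq.subject_id!r}")
        df = regressor_frame(seq, spec, params_by_subject[seq.subject_id])
        p = outdir / f"regressors_{seq.subject_id}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep=_NA, float_format="%.10g")
        paths.append(p)
    return paths


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run, written next to outputs."""

    model: str = "bayes_full"
    n_trials: int = 220
    step_sd: float = 0.05
    bounds: tuple = (0.1, 0.9)
    n_subjects: int = 30
    n_restarts: int = 5
    max_em_iter: int = 50
    em_tol: float = 1e-3
    n_ibic_samples: int = 1000
    seed: int = 0
    outdir: str = "."

    _KNOWN = None  # populated below

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "bounds" in raw:
            raw["bounds"] = tuple(raw["bounds"])
        return cls(**raw)

    def write(self, path) -> None:
        from . import __version__

        payload = asdict(self)
        payload["bounds"] = list(payload["bounds"])
        payload["package_version"] = __version__
        payload["config_hash"] = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
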