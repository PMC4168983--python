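"""Delimited-text readers/writers and run configuration.

Sample streams are tab-delimited (time_s, pupil_mm or pupil_px, gaze_x_deg,
gaze_y_deg, valid); trial tables are CSV.  Round-trips preserve float
values to 1e-12.  No proprietary eyetracker formats: conversion to these
text forms is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .preprocess import PupilSamples

__all__ = [
    "RunConfig",
    "read_samples",
    "write_samples",
    "read_trials",
    "write_trials",
    "write_posterior",
    "read_posterior",
    "write_report",
]

_SAMPLE_COLS = ("time_s", "gaze_x_deg", "gaze_y_deg", "valid")
_TRIAL_REQUIRED = ("subject", "rt")


@dataclass
class RunConfig:
    seed: int = 0
    samples_path: str | None = None
    trials_path: str | None = None
    output_dir: str = "out"
    mm_per_px: float | None = None
    rt_floor: float = 0.1
    rt_deadline: float = 1.5
    baseline_window: float = 1.0
    low_frac: float = 0.4
    high_frac: float = 0.4
    variant: str = "primary"
    chains: int = 3
    iterations: int = 4000
    burnin: int = 2000
    sim_n_trials: int = 5000
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("rt_floor", "rt_deadline", "baseline_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.low_frac + self.high_frac > 1:
            raise ValueError("bin fractions must sum to <= 1")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw)
                 if k in cls.__dataclass_fields__}
        return cls(**known, extras=raw)

    def to_yaml(self, path):
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "extras"}
        d.update(self.extras)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _check_columns(df, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {', '.join(missing)}")


def read_samples(path) -> PupilSamples:
    """Read a tab-delimited sample stream (pupil_mm or pupil_px column)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed rows -- {e}") from e
    units = "mm" if "pupil_mm" in df.columns else "px"
    pupil_col = f"pupil_{units}"
    _check_columns(df, _SAMPLE_COLS + (pupil_col,), path)
    return PupilSamples(
        time=df["time_s"].to_numpy(float),
        diameter=df[pupil_col].to_numpy(float),
        gaze_x=df["gaze_x_deg"].to_numpy(float),
        gaze_y=df["gaze_y_deg"].to_numpy(float),
        valid=df["valid"].to_numpy() > 0.5,
        units=units,
        interpolated=(df["interpolated"].to_numpy() > 0.5
                      if "interpolated" in df.columns else None),
    )


def write_samples(samples: PupilSamples, path):
    df = pd.DataFrame({
        "time_s": samples.time,
        f"pupil_{samples.units}": samples.diameter,
        "gaze_x_deg": samples.gaze_x,
        "gaze_y_deg": samples.gaze_y,
        "valid": samples.valid.astype(int),
        "interpolated": samples.interpolated.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_trials(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed rows -- {e}") from e
    _check_columns(df, _TRIAL_REQUIRED, path)
    return df


def write_trials(trials: pd.DataFrame, path):
    trials.to_csv(path, index=False, float_format="%.12g")


def write_posterior(samples, path):
    """Export posterior draws: one row per (chain, iteration), one column
    per group-level parameter."""
    group = samples.group
    n_chains = samples.n_chains
    kept = samples.n_kept
    chain = np.repeat(np.arange(n_chains), kept)
    iteration = np.tile(np.arange(kept), n_chains)
    cols = {"chain": chain, "iteration": iteration}
    for name, arr in group.items():
        cols[name] = arr.reshape(-1)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_posterior(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ("chain", "iteration"), path)
    return df


def write_report(results: dict, path):
    """Write a (nested) results dict as YAML, converting numpy scalars."""

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        return x

    with open(path, "w") as fh:
        yaml.safe_dump(clean(results), fh, sort_keys=False)
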