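"""Reading and preprocessing of center-of-pressure (CoP) trials and covariate tables.

A trial is one subject's anterior--posterior CoP displacement recorded on a
force plate during 30 s of quiet stance under one of four conditions
(stable/unstable surface x eyes open/closed).  Preprocessing removes the
least-squares linear trend and applies a zero-phase Butterworth low-pass
filter (10 Hz cutoff by default), after which the signal is ready for
wavelet decomposition.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ParameterError, SwayWaveWarning, ValidationError

logger = logging.getLogger("swaywave")

#: The four quiet-stance test conditions: Stable/Unstable surface, Eyes Open/Closed.
CONDITIONS = ("SEO", "SEC", "UEO", "UEC")

#: Descriptive names and units of the sensorimotor / fall-related-concern covariates.
COVARIATE_NAMES = {
    "x1": "FES-I score",
    "x2": "Reaction time (ms)",
    "x3": "Eyesight",
    "x4": "Touch sensation left foot (g)",
    "x5": "Touch sensation right foot (g)",
    "x6": "Neck proprioception left (degree)",
    "x7": "Neck proprioception right (degree)",
    "x8": "Knee proprioception left (degree)",
    "x9": "Knee proprioception right (degree)",
    "x10": "Ankle proprioception left (degree)",
    "x11": "Ankle proprioception right (degree)",
    "x12": "Hip extension left (N.m)",
    "x13": "Hip extension right (N.m)",
    "x14": "Hip abduction left (N.m)",
    "x15": "Hip abduction right (N.m)",
    "x16": "Knee extension left (N.m)",
    "x17": "Knee extension right (N.m)",
    "x18": "Knee flexion left (N.m)",
    "x19": "Knee flexion right (N.m)",
    "x20": "Ankle dorsal flexion left (N.m)",
    "x21": "Ankle dorsal flexion right (N.m)",
    "x22": "Ankle plantar flexion left (N.m)",
    "x23": "Ankle plantar flexion right (N.m)",
    "x24": "Falls history (0/1)",
}

COVARIATE_COLUMNS = tuple(COVARIATE_NAMES)

#: Valid ranges used for validation and for truncating the synthetic generator.
#: FES-I totals are bounded by the instrument (16 items scored 1-4); the
#: physical measures are non-negative by construction.
VALID_RANGES = {"x1": (16.0, 64.0)}
VALID_RANGES.update({f"x{i}": (0.0, np.inf) for i in range(2, 24)})


@dataclass
class CoPTrial:
    """One subject's one-condition anterior--posterior CoP time series."""

    subject_id: str
    condition: str
    fs: float
    samples: np.ndarray
    duration_s: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError(
                f"trial needs at least 2 samples, got {self.samples.size}"
            )
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValidationError(
                f"non-finite sample at index {bad[0]} "
                f"({bad.size} non-finite values total)"
            )
        if self.duration_s is None:
            self.duration_s = self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size


def load_trial(path, fs: float = 3000.0, condition: str = "SEO",
               subject_id: str | None = None) -> CoPTrial:
    """Read a delimited trial file (columns ``time,cop_ap``; time optional).

    Comma- or tab-delimited with a header row.  The sampling rate argument is
    authoritative; any time column is ignored beyond parsing.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"trial file not found: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"trial file is empty: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValidationError(f"no data rows in {path}")
    if "cop_ap" in df.columns:
        col = df["cop_ap"]
    elif df.shape[1] == 1:
        col = df.iloc[:, 0]
    else:
        col = df.iloc[:, 1]  # (time, cop_ap) layout
    values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValidationError(
            f"{path}: non-numeric or non-finite value in data row {bad[0] + 1}"
        )
    nominal = 30.0
    if abs(values.size / fs - nominal) > 0.5:
        warnings.warn(
            f"{path.name}: duration {values.size / fs:.1f} s differs from the "
            f"nominal {nominal:.0f} s; using all provided samples",
            SwayWaveWarning,
            stacklevel=2,
        )
    return CoPTrial(
        subject_id=subject_id or path.stem,
        condition=condition,
        fs=fs,
        samples=values,
    )


def detrend(trial: CoPTrial, mode: str = "linear") -> CoPTrial:
    """Remove the least-squares linear trend (or just the mean, ``mode='mean'``)."""
    if mode not in ("linear", "mean"):
        raise ParameterError(f"detrend mode must be 'linear' or 'mean', got {mode!r}")
    kind = "linear" if mode == "linear" else "constant"
    return replace(trial, samples=sps.detrend(trial.samples, type=kind))


def lowpass_filter(trial: CoPTrial, cutoff: float = 10.0, order: int = 4) -> CoPTrial:
    """Zero-phase Butterworth low-pass (forward-backward, squared magnitude response)."""
    if not 0 < cutoff < trial.fs / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={trial.fs / 2:g}), got {cutoff}"
        )
    if order < 1:
        raise ParameterError(f"filter order must be >= 1, got {order}")
    sos = sps.butter(order, cutoff, btype="low", fs=trial.fs, output="sos")
    return replace(trial, samples=sps.sosfiltfilt(sos, trial.samples))


def preprocess(trial: CoPTrial, cutoff: float = 10.0, order: int = 4,
               detrend_mode: str = "linear") -> CoPTrial:
    """Detrend then zero-phase low-pass filter, in that order."""
    return lowpass_filter(detrend(trial, mode=detrend_mode), cutoff=cutoff, order=order)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a covariate table (one row per subject, columns subject_id,x1..x24)."""
    if "subject_id" not in df.columns:
        raise ValidationError("covariate table must have a subject_id column")
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing covariate columns: {', '.join(missing_cols)}")
    known = {"subject_id", "group", *COVARIATE_COLUMNS}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown covariate columns: %s", ", ".join(unknown))
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate subject_id: {dup.iloc[0]!r}")
    sub = df[list(COVARIATE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    na = sub.isna()
    if na.to_numpy().any():
        row, col = np.argwhere(na.to_numpy())[0]
        raise ValidationError(
            f"missing or non-numeric value for subject "
            f"{df['subject_id'].iloc[row]!r}, column {sub.columns[col]}"
        )
    for col, (lo, hi) in VALID_RANGES.items():
        out = sub[(sub[col] < lo) | (sub[col] > hi)]
        if not out.empty:
            i = out.index[0]
            raise ValidationError(
                f"{col} ({COVARIATE_NAMES[col]}) = {sub.loc[i, col]:g} outside "
                f"[{lo:g}, {hi:g}] for subject {df.loc[i, 'subject_id']!r}"
            )
    if not sub["x24"].isin([0.0, 1.0]).all():
        i = sub.index[~sub["x24"].isin([0.0, 1.0])][0]
        raise ValidationError(
            f"x24 (falls history) must be 0 or 1, got {sub.loc[i, 'x24']!r} "
            f"for subject {df.loc[i, 'subject_id']!r}"
        )
    result = df.copy()
    result[list(COVARIATE_COLUMNS)] = sub
    result.attrs["unknown_columns"] = unknown
    return result


def load_covariates(path) -> pd.DataFrame:
    """Read and validate a covariate CSV with columns ``subject_id,x1,...,x24``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"covariate file not found: {path}")
    return validate_covariates(pd.read_csv(path))
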