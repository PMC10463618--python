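"""Synthetic CoP signals and covariate tables for testing the full pipeline.

The study's raw recordings are not publicly available, so this module
generates stand-ins that reproduce the *structure* the method consumes:

* CoP trials whose relative wavelet energy follows a prescribed 17-component
  dyadic-band profile.  Synthesis is by band shaping: white noise is split
  into the ideal dyadic frequency bands with discrete-frequency masks, each
  band is rescaled to its (jittered) target energy share, and the bands are
  summed back into a real signal.  The masks are deliberately *not* the
  wavelet filters themselves, so the generator is independent of the analysis
  path; the residual mismatch between realized and target shares is wavelet
  filter leakage between adjacent bands (about 1-2 percent points).

* Covariate tables drawn from truncated normals with group-dependent
  moments.  The underlying normal parameters are moment-matched so that the
  *truncated* distribution has the configured mean/SD wherever that is
  feasible; for heavily skewed variables whose SD exceeds what a truncated
  normal can carry on [0, inf), the generator falls back to direct
  parameterisation and the realized moments shrink toward the bound.

Three archetype profiles mirror the balance-strategy groups (very-low-
frequency dominant, broadband, higher-frequency dominant) plus a 'young'
broadband preset.  Condition shifts move a fraction of the very-low-frequency
energy (components with nominal bands below 0.2 Hz) into D11-D12, emulating
the observed change toward higher-frequency strategies in challenging trials,
with the dominant level converging on D12.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ParameterError, ValidationError
from .io_preprocess import (
    CONDITIONS,
    COVARIATE_COLUMNS,
    VALID_RANGES,
    CoPTrial,
)
from .wavelet_features import component_names, nominal_bands

N_COMPONENTS = 17  # 16 details + approximation
_NAMES = component_names(16)
_IDX = {name: i for i, name in enumerate(_NAMES)}


def _profile_vector(named: dict) -> np.ndarray:
    """17-vector from a {component: percent} dict; the remainder up to 100 is
    spread uniformly over the unnamed components."""
    e = np.full(N_COMPONENTS, np.nan)
    for name, val in named.items():
        e[_IDX[name]] = float(val)
    unnamed = np.isnan(e)
    remainder = 100.0 - np.nansum(e)
    if remainder < -1e-9 or (remainder > 1e-9 and not unnamed.any()):
        raise ParameterError("named profile components must sum to <= 100")
    e[unnamed] = max(remainder, 0.0) / max(unnamed.sum(), 1)
    return e


#: Preset archetype targets (percent).  group1 piles energy into D15-D16,
#: group2 is broadband over D11-D16, group3 is dominant in D11-D12.
ARCHETYPE_TARGETS = {
    "group1": _profile_vector(
        {"D9": 1.5, "D10": 3, "D11": 8, "D12": 8, "D13": 15, "D14": 15,
         "D15": 24, "D16": 24}
    ),
    "group2": _profile_vector(
        {"D11": 15, "D12": 15, "D13": 15, "D14": 15, "D15": 15, "D16": 15}
    ),
    "group3": _profile_vector(
        {"D9": 5, "D10": 9, "D11": 24, "D12": 26, "D13": 9, "D14": 7,
         "D15": 5, "D16": 4}
    ),
    "young": _profile_vector(
        {"D10": 4, "D11": 17, "D12": 18, "D13": 16, "D14": 14, "D15": 13,
         "D16": 12}
    ),
}

#: Fraction of sub-0.2 Hz energy moved into D11-D12 per condition.  Groups 1-2
#: adapt strongly when vision is removed or the surface is unstable; group 3
#: barely changes strategy.
CONDITION_SHIFTS = {
    "group1": {"SEO": 0.0, "SEC": 0.3, "UEO": 0.3, "UEC": 0.5},
    "group2": {"SEO": 0.0, "SEC": 0.3, "UEO": 0.3, "UEC": 0.5},
    "group3": {"SEO": 0.0, "SEC": 0.05, "UEO": 0.05, "UEC": 0.05},
    "young": {"SEO": 0.0, "SEC": 0.3, "UEO": 0.3, "UEC": 0.5},
}

# Received energy is split 35/65 between D11 and D12 so that, after the
# ~2-4 percent-point down-level leakage of the analysis filters, strongly
# shifted profiles converge on D12 as the measured dominant level.
_SHIFT_SPLIT = (0.35, 0.65)


@dataclass
class ArchetypeProfile:
    """A named target energy profile with per-condition shift fractions."""

    name: str
    target_e: np.ndarray
    condition_shift: dict = field(default_factory=dict)

    def __post_init__(self):
        self.target_e = np.asarray(self.target_e, dtype=float)
        if self.target_e.size != N_COMPONENTS:
            raise ParameterError(f"target_e must have {N_COMPONENTS} components")
        if np.any(self.target_e < 0):
            raise ParameterError("target_e components must be >= 0")
        if abs(self.target_e.sum() - 100.0) > 1e-9:
            raise ParameterError("target_e must sum to 100")

    def for_condition(self, condition: str, fs: float = 3000.0) -> np.ndarray:
        frac = self.condition_shift.get(condition, 0.0)
        return shift_profile(self.target_e, frac, fs=fs)


def archetype_profile(name: str) -> ArchetypeProfile:
    """Preset profile for 'group1', 'group2', 'group3' or 'young'."""
    if name not in ARCHETYPE_TARGETS:
        raise ParameterError(
            f"unknown archetype {name!r}; presets: {sorted(ARCHETYPE_TARGETS)}"
        )
    return ArchetypeProfile(
        name=name,
        target_e=ARCHETYPE_TARGETS[name].copy(),
        condition_shift=dict(CONDITION_SHIFTS[name]),
    )


def shift_profile(target_e: np.ndarray, fraction: float, fs: float = 3000.0,
                  levels: int = 16) -> np.ndarray:
    """Move ``fraction`` of the very-low-frequency energy into D11-D12.

    'Very low frequency' means components whose nominal dyadic band lies
    entirely below 0.2 Hz (at fs=3000: D14, D15, D16 and the approximation).
    """
    if not 0 <= fraction <= 1:
        raise ParameterError(f"shift fraction must be in [0, 1], got {fraction}")
    e = np.asarray(target_e, dtype=float).copy()
    bands = nominal_bands(fs, levels)
    low = np.array([hi <= 0.2 for (_, hi) in bands])
    moved = fraction * e[low].sum()
    e[low] *= 1.0 - fraction
    e[_IDX["D11"]] += _SHIFT_SPLIT[0] * moved
    e[_IDX["D12"]] += _SHIFT_SPLIT[1] * moved
    return e


def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _jittered_target(target_e, jitter, rng, max_tries=100):
    """Per-subject perturbation of the target shares, renormalized to 100.

    ``jitter`` is the SD in percent points applied to a 10%-share component;
    smaller shares get proportionally smaller perturbations (sd_i =
    jitter * sqrt(e_i / 10)), so near-zero bands stay near zero.  Draws with
    a negative component are rejected and redrawn.
    """
    target_e = np.asarray(target_e, dtype=float)
    if jitter <= 0:
        return target_e
    sd = jitter * np.sqrt(target_e / 10.0)
    for _ in range(max_tries):
        e = target_e + rng.normal(0.0, 1.0, size=N_COMPONENTS) * sd
        if np.all(e >= 0):
            return 100.0 * e / e.sum()
    raise ValidationError(
        "could not draw a non-negative jittered profile; reduce jitter"
    )


def generate_cop(profile, fs: float = 3000.0, duration_s: float = 30.0,
                 seed=None, jitter: float = 1.0, subject_id: str = "synthetic",
                 condition: str = "SEO", target_e=None, rms: float = 5.0
                 ) -> CoPTrial:
    """One CoP trial whose relative wavelet energy approximates the profile.

    ``profile`` is an :class:`ArchetypeProfile` or preset name; ``target_e``
    overrides its 17-vector (used for condition-shifted profiles).  ``jitter``
    is the SD, in percent points, of per-subject perturbation of the target;
    negative draws are rejected and redrawn.  The output is scaled to the
    given RMS amplitude (relative energy is scale-invariant).
    """
    if isinstance(profile, str):
        profile = archetype_profile(profile)
    base = np.asarray(target_e if target_e is not None else profile.target_e,
                      dtype=float)
    rng = _as_rng(seed)
    e_target = _jittered_target(base, jitter, rng)
    n = int(round(duration_s * fs))
    if n < 2:
        raise ParameterError("duration_s * fs must be at least 2 samples")
    levels = N_COMPONENTS - 1
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # rfft bin weights so that sum(w * |X|^2) / n equals the time-domain energy
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    masks = []
    for i, (lo, hi) in enumerate(nominal_bands(fs, levels)):
        if i == 0:  # top detail band includes the Nyquist edge
            mask = (freqs >= lo) & (freqs <= hi)
        elif i == levels:  # approximation band includes DC
            mask = freqs < hi
        else:
            mask = (freqs >= lo) & (freqs < hi)
        if not mask.any() and e_target[i] > 1e-9:
            raise ParameterError(
                f"band {_NAMES[i]} has no frequency bins at n={n}; "
                "increase duration_s to realize its target energy"
            )
        masks.append(mask)

    # Alternate band rescaling with least-squares line removal so the output
    # is orthogonal to a linear trend: analysis-side detrending then leaves
    # the low-frequency band energies intact (residual ~1 percent point).
    design = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    qline, _ = np.linalg.qr(design)
    x = rng.standard_normal(n)
    for _ in range(8):
        X = np.fft.rfft(x)
        for i, mask in enumerate(masks):
            band_energy = float((w[mask] * np.abs(X[mask]) ** 2).sum())
            if band_energy > 0:
                X[mask] *= np.sqrt(e_target[i] / band_energy)
        x = np.fft.irfft(X, n)
        x -= qline @ (qline.T @ x)
    x *= rms / np.sqrt(np.mean(x**2))
    return CoPTrial(subject_id=subject_id, condition=condition, fs=fs, samples=x)


# ---------------------------------------------------------------------------
# Covariate generation
# ---------------------------------------------------------------------------

#: Group-wise (mean, sd) of x1..x23 and falls-history proportion for x24.
COVARIATE_MOMENTS = {
    "x1": {"group1": (21, 4), "group2": (19, 3), "group3": (24, 7)},
    "x2": {"group1": (387, 59), "group2": (361, 76), "group3": (416, 141)},
    "x3": {"group1": (0.78, 0.13), "group2": (0.72, 0.22), "group3": (0.74, 0.17)},
    "x4": {"group1": (3, 3.4), "group2": (3.4, 3), "group3": (3.25, 3.31)},
    "x5": {"group1": (3.73, 3.57), "group2": (3.4, 3.05), "group3": (4.6, 3.8)},
    "x6": {"group1": (4.6, 3.6), "group2": (3.15, 3.6), "group3": (3.75, 2.4)},
    "x7": {"group1": (4.54, 3.79), "group2": (3.28, 2.57), "group3": (3.7, 2.27)},
    "x8": {"group1": (7.25, 6.28), "group2": (5.42, 5.91), "group3": (6.48, 3.0)},
    "x9": {"group1": (6.47, 5.12), "group2": (5.08, 3.84), "group3": (6.9, 3.43)},
    "x10": {"group1": (4.73, 3.9), "group2": (4.05, 2.17), "group3": (4.67, 2.12)},
    "x11": {"group1": (5.79, 5.05), "group2": (4.39, 2.44), "group3": (5.81, 3.9)},
    "x12": {"group1": (45.33, 18.46), "group2": (49.43, 16.96), "group3": (48.88, 20.11)},
    "x13": {"group1": (50.62, 22.84), "group2": (53.14, 20.84), "group3": (51.10, 21.52)},
    "x14": {"group1": (48.22, 21.07), "group2": (54.36, 22.4), "group3": (51.36, 25.63)},
    "x15": {"group1": (54.38, 22.93), "group2": (58.06, 19.93), "group3": (52.79, 31.16)},
    "x16": {"group1": (86.18, 26.15), "group2": (89.5, 19.01), "group3": (87.05, 29.71)},
    "x17": {"group1": (79.94, 26.51), "group2": (87.88, 28.94), "group3": (87.38, 25.87)},
    "x18": {"group1": (66.08, 19.31), "group2": (73.37, 27.54), "group3": (67.86, 22.67)},
    "x19": {"group1": (69.45, 22.51), "group2": (76.46, 29.85), "group3": (69.58, 24.28)},
    "x20": {"group1": (21.66, 5.39), "group2": (26.15, 6.23), "group3": (20.74, 9.1)},
    "x21": {"group1": (23.59, 6.8), "group2": (24.24, 13.73), "group3": (22.43, 7.8)},
    "x22": {"group1": (83.89, 34.46), "group2": (88.41, 32.71), "group3": (83.34, 29.48)},
    "x23": {"group1": (82.20, 26.27), "group2": (86.75, 34.9), "group3": (77.86, 26.60)},
    "x24": {"group1": 0.333, "group2": 0.20, "group3": 0.43},
}

_truncnorm_cache: dict = {}


def _matched_truncnorm(lo, hi, mean, sd):
    """Truncated normal on [lo, hi] whose *truncated* mean/SD equal the targets.

    Returns (a, b, loc, scale, matched).  The underlying normal parameters
    are solved by bounded least squares; a solution is accepted when the
    residual moments are within 1% of the target SD.  When no underlying
    normal can carry the target moments on the truncated support (e.g.
    SD >= mean - lo on a half line), the generator falls back to direct
    (mean, sd) parameterisation and the realized moments shrink toward the
    bound.
    """
    key = (lo, hi, round(float(mean), 10), round(float(sd), 10))
    hit = _truncnorm_cache.get(key)
    if hit is not None:
        return hit

    def residual(params):
        mu, logsig = params
        sig = np.exp(np.clip(logsig, -20, 20))
        a, b = (lo - mu) / sig, (hi - mu) / sig
        d = stats.truncnorm(a, b, loc=mu, scale=sig)
        return np.array([d.mean() - mean, d.std() - sd])

    matched = False
    loc, scale = float(mean), float(sd)
    try:
        sol = optimize.least_squares(
            residual,
            x0=[mean, np.log(sd)],
            bounds=([mean - 60 * sd, np.log(sd) - 4],
                    [mean + 10 * sd, np.log(sd) + 4]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if np.max(np.abs(sol.fun)) < 0.01 * sd:
            loc, scale = float(sol.x[0]), float(np.exp(sol.x[1]))
            matched = True
    except Exception:
        pass
    a, b = (lo - loc) / scale, (hi - loc) / scale
    result = (a, b, loc, scale, matched)
    _truncnorm_cache[key] = result
    return result


def moment_matchable(column: str, group: str, moments=None) -> bool:
    """Whether the truncated-normal generator can carry the configured moments."""
    moments = moments or COVARIATE_MOMENTS
    mean, sd = moments[column][group]
    lo, hi = VALID_RANGES[column]
    return _matched_truncnorm(lo, hi, mean, sd)[4]


def generate_covariates(group: str, n: int, seed=None, moments=None
                        ) -> pd.DataFrame:
    """n covariate records drawn from the group's configured moments."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    moments = moments or COVARIATE_MOMENTS
    if group not in moments["x1"]:
        raise ParameterError(f"no covariate moments configured for {group!r}")
    rng = _as_rng(seed)
    data = {}
    for col in COVARIATE_COLUMNS:
        if col == "x24":
            prop = float(moments[col][group])
            if not 0 <= prop <= 1:
                raise ParameterError(f"x24 proportion must be in [0,1], got {prop}")
            data[col] = rng.binomial(1, prop, size=n).astype(float)
            continue
        mean, sd = moments[col][group]
        if sd < 0:
            raise ParameterError(f"{col}: sd must be >= 0, got {sd}")
        lo, hi = VALID_RANGES[col]
        if not lo <= mean <= hi:
            raise ParameterError(f"{col}: mean {mean} outside valid range")
        if sd == 0:
            data[col] = np.full(n, float(mean))
            continue
        a, b, loc, scale, _ = _matched_truncnorm(lo, hi, mean, sd)
        data[col] = stats.truncnorm(a, b, loc=loc, scale=scale).rvs(
            size=n, random_state=rng
        )
    df = pd.DataFrame(data)
    df.insert(0, "group", group)
    return df


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-scale generator settings (defaults mirror the study design:
    three groups, 30 s trials at 3000 Hz, four conditions)."""

    n_per_group: int = 15
    fs: float = 3000.0
    duration_s: float = 30.0
    seed: int = 7
    jitter: float = 1.0
    groups: tuple = ("group1", "group2", "group3")
    conditions: tuple = CONDITIONS
    covariate_moments: dict | None = None

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration_s must be positive")


@dataclass
class StudyData:
    """Generated trials, covariates and the generating (true) group labels."""

    trials: list
    covariates: pd.DataFrame
    labels: dict  # subject_id -> true group


def generate_study(config: SimulationConfig) -> StudyData:
    """Full synthetic study: per subject, four condition trials + covariates."""
    rng = np.random.default_rng(config.seed)
    trials = []
    labels = {}
    cov_frames = []
    sid = 0
    for group in config.groups:
        profile = archetype_profile(group)
        cov = generate_covariates(group, config.n_per_group, seed=rng,
                                  moments=config.covariate_moments)
        ids = []
        for _ in range(config.n_per_group):
            sid += 1
            subject = f"S{sid:03d}"
            ids.append(subject)
            labels[subject] = group
            # one jittered per-subject profile, shared across conditions
            subject_target = _jittered_target(profile.target_e, config.jitter, rng)
            for condition in config.conditions:
                frac = profile.condition_shift.get(condition, 0.0)
                target = shift_profile(subject_target, frac, fs=config.fs)
                trials.append(
                    generate_cop(
                        profile,
                        fs=config.fs,
                        duration_s=config.duration_s,
                        seed=rng,
                        jitter=0.0,  # per-subject jitter already applied
                        subject_id=subject,
                        condition=condition,
                        target_e=target,
                    )
                )
        cov.insert(0, "subject_id", ids)
        cov_frames.append(cov)
    covariates = pd.concat(cov_frames, ignore_index=True)
    return StudyData(trials=trials, covariates=covariates, labels=labels)
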