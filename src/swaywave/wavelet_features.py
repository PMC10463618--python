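"""Maximal-overlap wavelet decomposition and relative-energy spectra.

The preprocessed CoP signal x[n] is passed through an undecimated
(maximal-overlap) dyadic filter cascade: at level j the running approximation
is circularly convolved with the level-j upsampled low-pass filter h and
high-pass filter g, giving one same-length detail sequence D_j per level plus
a final approximation A_J.  With the filters rescaled by 1/sqrt(2) the
cascade is a tight frame, so coefficient energy equals signal energy exactly
under the circular boundary, and summing the per-level multiresolution
components reconstructs the input.

Each component's share of the total coefficient energy (details plus
approximation together) is its relative energy, expressed in percent; the
17-vector of shares (J = 16 details + approximation) is the subject's
feature spectrum used downstream for clustering.

The cascade is evaluated in the frequency domain: the level-j transfer
function is G(2^{j-1} f) * prod_{l<j} H(2^l f), applied via FFT.  This is
algebraically identical to circular time-domain convolution and O(N log N).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ParameterError, SwayWaveWarning, ValidationError, ZeroEnergyError
from .io_preprocess import CoPTrial

_SUPPORTED_FAMILIES = tuple(
    ["sym2", "sym3", "sym4", "sym5", "sym6", "sym7", "sym8"]
    + [f"db{i}" for i in range(2, 9)]
)


@dataclass(frozen=True)
class FilterPair:
    """Rescaled low/high-pass analysis filters of an orthonormal wavelet.

    ``g`` is the quadrature-mirror counterpart of ``h``:
    g[n] = (-1)^n h[L-1-n].  For the maximal-overlap variant both filters are
    divided by sqrt(2), so sum(h^2) + sum(g^2) = 1.
    """

    h: tuple
    g: tuple
    family_name: str

    def __post_init__(self):
        h = np.asarray(self.h)
        g = np.asarray(self.g)
        if h.size != g.size or h.size < 2:
            raise ParameterError("h and g must be equal-length filters (length >= 2)")
        qmf = np.array([(-1) ** n * h[h.size - 1 - n] for n in range(h.size)])
        if np.max(np.abs(qmf - g)) > 1e-12:
            raise ParameterError("g is not the quadrature-mirror counterpart of h")
        if abs((h**2).sum() + (g**2).sum() - 1.0) > 1e-10:
            raise ParameterError("filters are not maximal-overlap normalized")

    @classmethod
    def from_wavelet(cls, name: str = "sym4") -> "FilterPair":
        if name not in _SUPPORTED_FAMILIES:
            raise ParameterError(
                f"unsupported wavelet {name!r}; choose one of {_SUPPORTED_FAMILIES}"
            )
        h = np.asarray(pywt.Wavelet(name).dec_lo, dtype=float) / np.sqrt(2.0)
        g = np.array([(-1) ** n * h[h.size - 1 - n] for n in range(h.size)])
        return cls(h=tuple(h), g=tuple(g), family_name=name)

    @property
    def h_arr(self) -> np.ndarray:
        return np.asarray(self.h, dtype=float)

    @property
    def g_arr(self) -> np.ndarray:
        return np.asarray(self.g, dtype=float)


@dataclass
class WaveletDecomposition:
    """Undecimated decomposition: J same-length details plus approximation."""

    levels: int
    details: list  # J arrays, each of length n_samples
    approximation: np.ndarray
    fs: float
    n_samples: int
    wavelet: str

    def component_energies(self) -> np.ndarray:
        """Sum of squared coefficients per component (D_1..D_J, then approx)."""
        e = [float(np.sum(d**2)) for d in self.details]
        e.append(float(np.sum(self.approximation**2)))
        return np.array(e)


@dataclass
class EnergySpectrum:
    """Relative energies in percent: E_D1..E_DJ then E_approx; sums to 100."""

    subject_id: str
    condition: str
    e: np.ndarray

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        if np.any(self.e < 0):
            raise ValidationError("relative energies must be non-negative")
        if abs(self.e.sum() - 100.0) > 1e-6:
            raise ValidationError(
                f"relative energies must sum to 100, got {self.e.sum()!r}"
            )

    @property
    def levels(self) -> int:
        return self.e.size - 1


def component_names(levels: int = 16) -> list:
    """Component labels in spectrum order: D1..D<levels>, then 'approx'."""
    return [f"D{j}" for j in range(1, levels + 1)] + ["approx"]


_transfer_cache: dict = {}


def _transfer_functions(n: int, levels: int, filters: FilterPair):
    """rfft-domain transfer function of each detail level and the approximation."""
    key = (n, levels, filters.family_name, filters.h)
    hit = _transfer_cache.get(key)
    if hit is not None:
        return hit
    h, g = filters.h_arr, filters.g_arr
    k = np.arange(n // 2 + 1)
    taps = np.arange(h.size)
    detail_tf = []
    low = np.ones(n // 2 + 1, dtype=complex)
    for j in range(1, levels + 1):
        phase = np.exp(-2j * np.pi * np.outer(k, (2 ** (j - 1)) * taps) / n)
        detail_tf.append((phase @ g) * low)
        low = (phase @ h) * low
    if len(_transfer_cache) > 32:  # bound memory across many signal lengths
        _transfer_cache.clear()
    _transfer_cache[key] = (detail_tf, low)
    return detail_tf, low


def _as_signal(signal) -> tuple:
    if isinstance(signal, CoPTrial):
        return signal.samples, signal.fs
    return np.asarray(signal, dtype=float), None


def modwt(signal, levels: int = 16, wavelet="sym4", fs: float = 3000.0
          ) -> WaveletDecomposition:
    """Maximal-overlap decomposition into `levels` details plus approximation.

    ``signal`` may be a raw array or a :class:`CoPTrial` (whose own sampling
    rate then takes precedence over ``fs``).  Boundary handling is circular,
    which makes coefficient energy exactly equal to signal energy.
    """
    x, trial_fs = _as_signal(signal)
    if trial_fs is not None:
        fs = trial_fs
    if levels < 1:
        raise ParameterError(f"levels must be >= 1, got {levels}")
    filters = wavelet if isinstance(wavelet, FilterPair) else FilterPair.from_wavelet(wavelet)
    if x.ndim != 1 or x.size < len(filters.h):
        raise ParameterError(
            f"signal too short: length {x.size} < filter support {len(filters.h)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    if 2 ** levels > x.size // 2:
        warnings.warn(
            f"level-{levels} scale (2^{levels} samples) exceeds half the record "
            f"length ({x.size}); the deepest components are weakly localized",
            SwayWaveWarning,
            stacklevel=2,
        )
    n = x.size
    X = np.fft.rfft(x)
    detail_tf, low_tf = _transfer_functions(n, levels, filters)
    details = [np.fft.irfft(tf * X, n) for tf in detail_tf]
    approximation = np.fft.irfft(low_tf * X, n)
    return WaveletDecomposition(
        levels=levels,
        details=details,
        approximation=approximation,
        fs=fs,
        n_samples=n,
        wavelet=filters.family_name,
    )


def modwt_mra(signal, levels: int = 16, wavelet="sym4") -> tuple:
    """Additive multiresolution components: (detail components, smooth).

    Each returned array has the input's length and the components sum to the
    input exactly (tight-frame property under circular boundary).
    """
    x, _ = _as_signal(signal)
    filters = wavelet if isinstance(wavelet, FilterPair) else FilterPair.from_wavelet(wavelet)
    if levels < 1:
        raise ParameterError(f"levels must be >= 1, got {levels}")
    if x.size < len(filters.h):
        raise ParameterError("signal too short for the chosen filter")
    n = x.size
    X = np.fft.rfft(x)
    detail_tf, low_tf = _transfer_functions(n, levels, filters)
    detail_mra = [np.fft.irfft(np.abs(tf) ** 2 * X, n) for tf in detail_tf]
    smooth = np.fft.irfft(np.abs(low_tf) ** 2 * X, n)
    return detail_mra, smooth


def relative_energy(decomp: WaveletDecomposition, subject_id: str = "",
                    condition: str = "SEO") -> EnergySpectrum:
    """Per-component share of total coefficient energy, in percent.

    The denominator includes all components: the J details and the
    approximation together carry 100%.
    """
    energies = decomp.component_energies()
    total = energies.sum()
    if total <= 0:
        raise ZeroEnergyError(
            "total coefficient energy is zero; relative energy is undefined"
        )
    return EnergySpectrum(
        subject_id=subject_id, condition=condition, e=100.0 * energies / total
    )


def nominal_bands(fs: float, levels: int) -> list:
    """Ideal dyadic pass-bands, spectrum order: detail j -> [fs/2^(j+1), fs/2^j],
    approximation -> [0, fs/2^(levels+1)].  The bands tile [0, fs/2] exactly."""
    if not fs > 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if levels < 1:
        raise ParameterError(f"levels must be >= 1, got {levels}")
    bands = [(fs / 2 ** (j + 1), fs / 2**j) for j in range(1, levels + 1)]
    bands.append((0.0, fs / 2 ** (levels + 1)))
    return bands


def band_localization_check(freq: float, fs: float, levels: int = 16,
                            n_samples: int | None = None, wavelet="sym4") -> int:
    """Detail level (1..levels) capturing most energy of a pure sinusoid at
    ``freq``; returns 0 when the approximation dominates."""
    if not 0 < freq < fs / 2:
        raise ParameterError(
            f"freq must lie in (0, Nyquist={fs / 2:g}), got {freq}"
        )
    if n_samples is None:
        n_samples = 2 ** (levels + 2)
    t = np.arange(n_samples) / fs
    x = np.sin(2 * np.pi * freq * t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SwayWaveWarning)
        decomp = modwt(x, levels=levels, wavelet=wavelet, fs=fs)
    energies = decomp.component_energies()
    best = int(np.argmax(energies))
    return 0 if best == levels else best + 1
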