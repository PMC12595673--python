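"""Multitaper spectral estimation of spontaneous activity.

Power spectral density is estimated per trial on the pre-stimulus window
with Slepian (DPSS) tapers, eigenvalue-weighted, then averaged across
trials. Densities are one-sided and calibrated so that the integral over
[0, fs/2] recovers the sample variance of the analysed (demeaned) segments.

Band summaries follow the standard rodent ECoG band set with the mains
(AC) band 45–55 Hz excluded from high gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import windows

from .errors import DegenerateDataError, ParameterError
from .io import EpochsSet

#: Default frequency bands, Hz, half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (55.0, 90.0),
}

#: Variant with high gamma spanning 45–90 Hz; only meaningful together with
#: the AC exclusion, which removes the 45–55 Hz bins from it.
BANDS_WIDE_HIGH_GAMMA = dict(BANDS, high_gamma=(45.0, 90.0))

#: Mains interference band excluded from band averages, half-open.
AC_EXCLUSION: tuple[float, float] = (45.0, 55.0)

BAND_ORDER = tuple(BANDS)


@lru_cache(maxsize=32)
def _dpss_cached(n_samples: int, nw: float, k: int):
    return windows.dpss(n_samples, nw, Kmax=k, return_ratios=True)


@dataclass
class Spectrum:
    """One-sided power spectral density averaged across trials."""

    freqs_hz: np.ndarray
    psd: np.ndarray          # µV²/Hz
    n_epochs_averaged: int
    params: dict = field(default_factory=dict)


def dpss_tapers(n_samples: int, half_bandwidth_hz: float, fs_hz: float,
                n_tapers: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal Slepian tapers for a segment of n_samples at fs_hz.

    The time–half-bandwidth product is NW = half_bandwidth_hz * n_samples
    / fs_hz; at most floor(2 NW) - 1 tapers are well concentrated. Returns
    (tapers [n_tapers x n_samples], concentration ratios), each ratio ≥ 0.90.
    """
    if n_samples < 2:
        raise ParameterError("need at least 2 samples for tapering")
    nw = half_bandwidth_hz * n_samples / fs_hz
    if nw < 1:
        raise ParameterError(
            f"time-half-bandwidth NW={nw:.3f} < 1; widen the band or window"
        )
    k_max = int(np.floor(2 * nw)) - 1
    if n_tapers > k_max:
        raise ParameterError(
            f"{n_tapers} tapers infeasible at NW={nw:.2f}; maximum is {k_max}"
        )
    if n_tapers < 1:
        raise ParameterError("need at least one taper")
    tapers, ratios = _dpss_cached(n_samples, float(nw), n_tapers)
    if np.min(ratios) < 0.90:
        raise ParameterError(
            f"taper concentration dropped to {np.min(ratios):.3f} < 0.90; "
            "request fewer tapers"
        )
    return tapers, ratios


def psd_multitaper(epochs: EpochsSet,
                   window_s: tuple[float, float] = (-0.9, -0.2),
                   half_bandwidth_hz: float = 2.9,
                   n_tapers: int = 3) -> Spectrum:
    """Trial-averaged multitaper PSD of a within-epoch window.

    Each trial's segment is demeaned, tapered with every DPSS taper, and
    the eigenspectra are combined with concentration-ratio weights
    normalised to unit sum; the per-trial densities are then averaged.
    """
    if epochs.n_trials < 1:
        raise ParameterError("at least one trial required")
    sl = epochs.time_slice(*window_s)
    seg = epochs.data[:, sl]
    n = seg.shape[1]
    tapers, ratios = dpss_tapers(n, half_bandwidth_hz, epochs.fs_hz, n_tapers)
    weights = ratios / ratios.sum()

    seg = seg - seg.mean(axis=1, keepdims=True)
    # (trials, tapers, freqs)
    spectra = np.fft.rfft(seg[:, None, :] * tapers[None, :, :], axis=-1)
    eigen = (np.abs(spectra) ** 2) * (2.0 / epochs.fs_hz)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs_hz)
    eigen[..., 0] /= 2.0
    if n % 2 == 0:
        eigen[..., -1] /= 2.0
    psd = np.tensordot(weights, eigen.mean(axis=0), axes=(0, 0))
    return Spectrum(
        freqs_hz=freqs, psd=psd, n_epochs_averaged=epochs.n_trials,
        params={"window_s": tuple(window_s),
                "half_bandwidth_hz": half_bandwidth_hz,
                "n_tapers": n_tapers},
    )


def band_power(spectrum: Spectrum,
               bands: dict[str, tuple[float, float]] | None = None,
               exclusions: tuple[tuple[float, float], ...] = (AC_EXCLUSION,),
               ) -> dict[str, float]:
    """Mean spectral density (µV²/Hz) per band.

    Bands are half-open [low, high); bins falling inside any exclusion
    interval are removed before averaging. The mean (not the integral) keeps
    units of density so bands of different width stay comparable.
    """
    if bands is None:
        bands = BANDS
    f = spectrum.freqs_hz
    excluded = np.zeros_like(f, dtype=bool)
    for lo, hi in exclusions:
        excluded |= (f >= lo) & (f < hi)
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        if hi > f[-1] + 1e-9 or lo < f[0] - 1e-9:
            raise ParameterError(
                f"band {name} [{lo}, {hi}) outside spectral support"
            )
        sel = (f >= lo) & (f < hi) & ~excluded
        if not np.any(sel):
            raise DegenerateDataError(
                f"band {name} [{lo}, {hi}) has no bins after exclusions"
            )
        out[name] = float(spectrum.psd[sel].mean())
    return out
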