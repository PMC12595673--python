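"""Morlet-wavelet time–frequency analysis and ASSR entrainment metrics.

Three complementary measures of the steady-state response are computed from
the complex coefficients of an L2-normalised Morlet transform:

* phase-locking factor (PLF, inter-trial phase coherence): magnitude of the
  across-trial mean unit phase vector — amplitude-blind, 1 for perfect
  locking, ~sqrt(pi / (4 N)) for N trials with random phases;
* induced power ratio: per-trial stimulation-window power over pre-stimulus
  baseline power, averaged over trials — phase-blind;
* evoked power: power of the trial-averaged waveform — requires both a
  response and across-trial phase consistency to survive averaging.

Analysis frequency bands are realised as the integer-Hz grid bins inside
the printed range endpoints inclusive (e.g. 38–42 Hz -> bins 38..42).
Wavelet coefficients near the epoch edges are contaminated by the finite
wavelet support; such bins are flagged and excluded from window averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft

from .errors import DegenerateDataError, EpochWindowError, ParameterError
from .io import EpochsSet

#: Analysis bands per stimulation rate, Hz (inclusive endpoints on the grid).
RATE_BANDS: dict[float, tuple[float, float]] = {
    10.0: (8.0, 12.0),
    20.0: (18.0, 22.0),
    40.0: (38.0, 42.0),
    80.0: (78.0, 82.0),
}

STIM_WINDOW_S: tuple[float, float] = (0.2, 0.9)
BASE_WINDOW_S: tuple[float, float] = (-0.5, -0.1)

#: Bins closer than this many Gaussian SDs of the wavelet envelope to an
#: epoch edge are flagged as edge-contaminated.
EDGE_SDS = 2.5


@dataclass
class TFR:
    """Per-trial complex Morlet coefficients, (trial, frequency, time)."""

    coeffs: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    edge_mask: np.ndarray  # (frequency, time) True where edge-contaminated
    params: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]


def _morlet_wavelet(freq_hz: float, fs_hz: float, n_cycles: float
                    ) -> np.ndarray:
    """Discrete complex Morlet wavelet, unit L2 norm, support ±4 SD."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(4.0 * sigma_t * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    w = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2)) * np.exp(2j * np.pi * freq_hz * t)
    return w / np.linalg.norm(w)


def morlet_tfr(epochs: EpochsSet,
               freqs_hz: np.ndarray | None = None,
               n_cycles: float = 7.0) -> TFR:
    """Convolve every trial with L2-normalised complex Morlet wavelets.

    Coefficients retain phase. Time bins within EDGE_SDS Gaussian widths of
    either epoch edge are flagged in ``edge_mask`` per frequency.
    """
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, 101.0)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz <= 0):
        raise ParameterError("analysis frequencies must be positive")
    duration = epochs.n_samples / epochs.fs_hz
    if np.any(freqs_hz < 1.0 / duration):
        raise ParameterError(
            f"analysis frequency below 1/epoch-duration ({1.0 / duration:.3f} Hz)"
        )
    n = epochs.n_samples
    times = epochs.times_s
    max_half = int(np.ceil(4.0 * n_cycles / (2 * np.pi * freqs_hz.min())
                           * epochs.fs_hz))
    nfft = next_fast_len(n + 2 * max_half + 1)
    # real-input FFT of all trials once; per-frequency multiply in the
    # spectral domain using the wavelet's analytic (one-sided) spectrum
    trial_f = rfft(epochs.data, n=nfft, axis=1)

    coeffs = np.empty((epochs.n_trials, freqs_hz.size, n), dtype=np.complex128)
    edge = np.zeros((freqs_hz.size, n), dtype=bool)
    for i, f in enumerate(freqs_hz):
        w = _morlet_wavelet(f, epochs.fs_hz, n_cycles)
        half = (w.size - 1) // 2
        wf_full = np.fft.fft(w, n=nfft)
        # product of one-sided spectra: the complex wavelet has negligible
        # negative-frequency content, so zero-padding the ifft input over
        # the missing negative bins reconstructs the analytic convolution
        prod = trial_f * wf_full[: trial_f.shape[1]]
        conv = np.fft.ifft(prod, n=nfft, axis=1)
        coeffs[:, i, :] = conv[:, half:half + n]
        sigma_t = n_cycles / (2 * np.pi * f)
        guard = EDGE_SDS * sigma_t
        edge[i] = (times - times[0] < guard) | (times[-1] - times < guard)
    return TFR(coeffs=coeffs, freqs_hz=freqs_hz, times_s=times,
               edge_mask=edge,
               params={"n_cycles": n_cycles, "fs_hz": epochs.fs_hz})


def _band_window_sel(tfr: TFR, band_hz: tuple[float, float],
                     window_s: tuple[float, float]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = band_hz
    fsel = (tfr.freqs_hz >= lo - 1e-9) & (tfr.freqs_hz <= hi + 1e-9)
    t0, t1 = window_s
    tsel = (tfr.times_s >= t0 - 1e-12) & (tfr.times_s < t1 - 1e-12)
    if not np.any(fsel) or not np.any(tsel):
        raise ParameterError(
            f"band {band_hz} x window {window_s} empty on the TFR grid"
        )
    keep = ~tfr.edge_mask[np.ix_(fsel, tsel)]
    if not np.any(keep):
        raise EpochWindowError(
            f"all bins of band {band_hz} x window {window_s} are "
            "edge-contaminated; lengthen the epoch"
        )
    return fsel, tsel, keep


def plf(tfr: TFR, band_hz: tuple[float, float],
        window_s: tuple[float, float] = STIM_WINDOW_S) -> float:
    """Phase-locking factor averaged over band x window bins.

    Per bin, the magnitude of the across-trial mean of coeff/|coeff|; bins
    with a zero-magnitude coefficient contribute a zero unit vector.
    Edge-flagged bins are excluded from the average.
    """
    if tfr.n_trials < 2:
        raise ParameterError("PLF needs at least 2 trials")
    fsel, tsel, keep = _band_window_sel(tfr, band_hz, window_s)
    c = tfr.coeffs[np.ix_(np.arange(tfr.n_trials), np.flatnonzero(fsel),
                          np.flatnonzero(tsel))]
    mag = np.abs(c)
    zero = mag == 0
    unit = c / np.where(zero, 1.0, mag)
    if np.any(zero):
        unit[zero] = 0.0
    resultant = np.abs(unit.mean(axis=0))
    return float(resultant[keep].mean())


def induced_power_ratio(tfr: TFR, band_hz: tuple[float, float],
                        stim_window_s: tuple[float, float] = STIM_WINDOW_S,
                        base_window_s: tuple[float, float] = BASE_WINDOW_S,
                        ratio_of_means: bool = False) -> float:
    """Stimulation/baseline power ratio.

    Default: per-trial ratio of band-mean power in the stimulation window
    to the pre-stimulus baseline window, then averaged across trials.
    ``ratio_of_means=True`` instead forms the ratio of trial-averaged
    powers (sensitivity variant).
    """
    fsel_s, tsel_s, keep_s = _band_window_sel(tfr, band_hz, stim_window_s)
    fsel_b, tsel_b, keep_b = _band_window_sel(tfr, band_hz, base_window_s)
    trials = np.arange(tfr.n_trials)
    c_s = tfr.coeffs[np.ix_(trials, np.flatnonzero(fsel_s),
                            np.flatnonzero(tsel_s))]
    c_b = tfr.coeffs[np.ix_(trials, np.flatnonzero(fsel_b),
                            np.flatnonzero(tsel_b))]
    pow_stim = (c_s.real ** 2 + c_s.imag ** 2)[:, keep_s]
    pow_base = (c_b.real ** 2 + c_b.imag ** 2)[:, keep_b]
    stim = pow_stim.mean(axis=1)
    base = pow_base.mean(axis=1)
    zero = np.flatnonzero(base <= 0)
    if zero.size:
        raise DegenerateDataError(
            f"zero baseline power in trial(s) {zero.tolist()}"
        )
    if ratio_of_means:
        return float(stim.mean() / base.mean())
    return float((stim / base).mean())


def evoked_power(epochs: EpochsSet, band_hz: tuple[float, float],
                 stim_window_s: tuple[float, float] = STIM_WINDOW_S,
                 freqs_hz: np.ndarray | None = None,
                 n_cycles: float = 7.0) -> float:
    """Power of the trial-averaged waveform in band x stimulation window.

    Trials are averaged sample-wise in the time domain first, so only the
    phase-consistent response survives; no baseline normalisation (µV²).
    """
    if epochs.n_trials < 2:
        raise ParameterError("evoked power needs at least 2 trials")
    if freqs_hz is None:
        lo, hi = band_hz
        freqs_hz = np.arange(np.floor(lo), np.ceil(hi) + 1)
    avg = EpochsSet(data=epochs.data.mean(axis=0, keepdims=True),
                    fs_hz=epochs.fs_hz, t0_s=epochs.t0_s,
                    stim_rate_hz=epochs.stim_rate_hz, meta=dict(epochs.meta))
    tfr = morlet_tfr(avg, freqs_hz=freqs_hz, n_cycles=n_cycles)
    fsel, tsel, keep = _band_window_sel(tfr, band_hz, stim_window_s)
    power = (np.abs(tfr.coeffs[0, fsel][:, tsel]) ** 2)[keep]
    return float(power.mean())


def harmonic_response(source: TFR | EpochsSet, stim_rate_hz: float,
                      kind: str = "plf",
                      max_freq_hz: float = 100.0,
                      window_s: tuple[float, float] = STIM_WINDOW_S,
                      n_cycles: float = 7.0) -> float:
    """PLF or evoked power at the first harmonic band [2f-2, 2f+2] Hz."""
    f2 = 2.0 * stim_rate_hz
    if isinstance(source, TFR):
        max_freq_hz = float(source.freqs_hz.max())
    if f2 > max_freq_hz:
        raise ParameterError(
            f"first harmonic {f2:g} Hz exceeds the analysis ceiling "
            f"{max_freq_hz:g} Hz"
        )
    band = (f2 - 2.0, f2 + 2.0)
    if kind == "plf":
        if not isinstance(source, TFR):
            source = morlet_tfr(
                source, freqs_hz=np.arange(band[0], band[1] + 1),
                n_cycles=n_cycles)
        return plf(source, band, window_s)
    if kind == "evoked":
        if isinstance(source, TFR):
            raise ParameterError("evoked harmonic needs raw epochs, not a TFR")
        return evoked_power(source, band, window_s, n_cycles=n_cycles)
    raise ParameterError(f"kind must be 'plf' or 'evoked', got {kind!r}")
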