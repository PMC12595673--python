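"""Synthetic ECoG cohort generator with known ground truth.

Emulates awake-mouse auditory-cortex ECoG under the recording conditions the
analysis assumes: 2 kHz sampling, 1–1000 Hz passband with a 50 Hz notch,
1-s auditory click trains at 10/20/40/80 Hz separated by 1-s inter-stimulus
intervals, 100 trials per session, cohorts of males and females recorded on
consecutive days, and saline vs ketamine sessions.

Generative model
----------------
* Background activity is spectrally shaped Gaussian noise: random Fourier
  phases under a deterministic amplitude envelope equal to the square root
  of a target one-sided density (piecewise-constant at the per-band target
  densities, 1/f^chi elsewhere), inverse-transformed to the time domain.
* The steady-state response is an additive entrained sinusoid at the train
  rate f (plus a 2f harmonic at a configurable fraction), gated to the 1-s
  train with 10 ms raised-cosine ramps. Its per-trial phase is von Mises
  with concentration kappa, whose mean resultant length I1(k)/I0(k) is the
  large-trial limit of the phase-locking factor — giving every entrainment
  setting a closed-form PLF target.
* Animal, day, and session (residual) effects act multiplicatively
  (i.e. additively on the log) on band densities and entrainment amplitude,
  so the intended test–retest ICC of any log-scale session metric equals
  sigma_animal^2 / (sigma_animal^2 + sigma_day^2 + sigma_resid^2) exactly.
  Day effects are shared across animals (a true column effect, penalised by
  absolute-agreement ICC).
* Ketamine acts phenomenologically: per-band density multipliers (< 1 below
  30 Hz, > 1 in the gamma bands) and reduced 40 Hz entrainment amplitude
  and phase concentration.
* Mains interference is an additive 50 Hz sinusoid followed by the
  recording notch, so the AC-band (45–55 Hz) exclusion is exercised.

Every session derives its RNG stream from (seed, animal, day, rate,
condition), so any single session is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.signal import filtfilt, iirnotch
from scipy.special import i0e, i1e

from .errors import ParameterError
from .io import EpochsSet, write_bundle
from .spectral import BANDS

ALLOWED_RATES = (10.0, 20.0, 40.0, 80.0)

#: Baseline/saline spontaneous densities, µV²/Hz, typical of mouse A1 ECoG.
DEFAULT_BAND_DENSITY = {
    "delta": 62.0,
    "theta": 54.6,
    "alpha": 17.2,
    "beta": 2.76,
    "low_gamma": 0.185,
    "high_gamma": 0.075,
}

#: Ketamine-to-saline density ratios: low-frequency suppression, gamma boost.
DEFAULT_KET_BAND_MULT = {
    "delta": 0.64,
    "theta": 0.70,
    "alpha": 0.61,
    "beta": 0.72,
    "low_gamma": 1.57,
    "high_gamma": 1.87,
}

#: Baseline phase concentration per stimulation rate; 40 Hz is sex-split
#: (males entrain more strongly).
DEFAULT_KAPPA = {10.0: 0.65, 20.0: 1.1, 40.0: {"M": 1.6, "F": 1.2}, 80.0: 0.72}

#: Baseline entrained amplitude per rate, µV; 40 Hz sex-split. Calibrated
#: once against the analysis chain so baseline induced-power ratios land at
#: the reported scale (~1.5 at 20 Hz, ~2.4/2.0 male/female at 40 Hz, ~2.2
#: at 80 Hz); see docs/methods.md for the 10 Hz compromise.
DEFAULT_AMP = {10.0: 2.5, 20.0: 2.0, 40.0: {"M": 2.2, "F": 1.8}, 80.0: 1.8}

#: Ketamine multipliers on 40 Hz entrainment.
DEFAULT_KET_KAPPA_MULT = 0.7
DEFAULT_KET_AMP_MULT = 0.61


def _sex_split(table: dict, rate: float, sex: str) -> float:
    v = table[rate]
    return float(v[sex]) if isinstance(v, dict) else float(v)


def default_band_power_uv2() -> dict:
    """(sex, condition) -> band -> µV²/Hz."""
    out = {}
    for sex in ("M", "F"):
        for cond in ("baseline", "SAL"):
            out[(sex, cond)] = dict(DEFAULT_BAND_DENSITY)
        out[(sex, "KET")] = {
            b: DEFAULT_BAND_DENSITY[b] * DEFAULT_KET_BAND_MULT[b]
            for b in DEFAULT_BAND_DENSITY
        }
    return out


def default_entrain_amp_uv() -> dict:
    out = {}
    for sex in ("M", "F"):
        for cond in ("baseline", "SAL"):
            out[(sex, cond)] = {r: _sex_split(DEFAULT_AMP, r, sex)
                                for r in ALLOWED_RATES}
        out[(sex, "KET")] = {
            r: _sex_split(DEFAULT_AMP, r, sex)
            * (DEFAULT_KET_AMP_MULT if r == 40.0 else 1.0)
            for r in ALLOWED_RATES
        }
    return out


def default_kappa() -> dict:
    out = {}
    for sex in ("M", "F"):
        for cond in ("baseline", "SAL"):
            out[(sex, cond)] = {r: _sex_split(DEFAULT_KAPPA, r, sex)
                                for r in ALLOWED_RATES}
        out[(sex, "KET")] = {
            r: _sex_split(DEFAULT_KAPPA, r, sex)
            * (DEFAULT_KET_KAPPA_MULT if r == 40.0 else 1.0)
            for r in ALLOWED_RATES
        }
    return out


@dataclass
class CohortSpec:
    """Full generative description of a synthetic experiment."""

    n_males: int = 35
    n_females: int = 33
    n_days: int = 5
    stim_rates_hz: tuple[float, ...] = ALLOWED_RATES
    n_trials: int = 100
    fs_hz: float = 2000.0
    train_dur_s: float = 1.0
    isi_s: float = 1.0
    epoch_window_s: tuple[float, float] = (-1.0, 1.0)
    aperiodic_exponent: float = 2.0
    band_power_uv2: dict = field(default_factory=default_band_power_uv2)
    entrain_amp_uv: dict = field(default_factory=default_entrain_amp_uv)
    kappa: dict = field(default_factory=default_kappa)
    harmonic_amp_frac: float = 0.3
    sigma_animal: float = 0.45
    sigma_day: float = 0.05
    sigma_resid: float = 0.14
    mains_amp_uv: float = 2.0
    notch: bool = True
    conditions: tuple[str, ...] = ("baseline",)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_males", "n_females", "n_days", "n_trials"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.fs_hz <= 400.0:
            raise ParameterError("fs_hz must exceed twice the 200 Hz "
                                 "analysis ceiling")
        if not self.stim_rates_hz:
            raise ParameterError("stim_rates_hz must be non-empty")
        if not set(self.stim_rates_hz) <= set(ALLOWED_RATES):
            raise ParameterError(
                f"stimulation rates must be among {ALLOWED_RATES}"
            )
        if not self.conditions:
            raise ParameterError("conditions must be non-empty")
        if not set(self.conditions) <= {"baseline", "SAL", "KET"}:
            raise ParameterError("conditions must be baseline/SAL/KET")
        for s in (self.sigma_animal, self.sigma_day, self.sigma_resid):
            if s < 0:
                raise ParameterError("sigma_* must be >= 0")
        for key, table in self.kappa.items():
            if any(k < 0 for k in table.values()):
                raise ParameterError(f"kappa must be >= 0 ({key})")
        for key, table in self.entrain_amp_uv.items():
            if any(a < 0 for a in table.values()):
                raise ParameterError(f"amplitudes must be >= 0 ({key})")
        t0, t1 = self.epoch_window_s
        if t0 > 0 or t1 < self.train_dur_s:
            raise ParameterError("epoch window must cover the full train")

    def intended_icc(self) -> float:
        """Closed-form ICC target of any log-scale session metric."""
        a, d, r = self.sigma_animal, self.sigma_day, self.sigma_resid
        tot = a * a + d * d + r * r
        if tot == 0:
            raise ParameterError("all variance components are zero")
        return a * a / tot


def expected_plf(kappa: float) -> float:
    """Mean resultant length I1(k)/I0(k) of a von Mises distribution.

    This is the infinite-trial limit of the phase-locking factor for
    trials whose phases are von Mises with concentration kappa.
    """
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def _shaped_noise(density: np.ndarray, n_samples: int, fs_hz: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-like noise whose expected one-sided PSD equals ``density``.

    Deterministic spectral amplitudes sqrt(S(f)) with uniform random
    phases, so the realised total variance equals the integral of the
    target density (up to the randomness of phase interference only).
    """
    if np.any(~np.isfinite(density)) or np.any(density < 0):
        raise ParameterError("target densities must be finite and >= 0")
    n_bins = n_samples // 2 + 1
    if density.shape[-1] != n_bins:
        raise ParameterError("density grid does not match the rfft grid")
    amp = np.sqrt(density * fs_hz * n_samples / 2.0)
    phases = rng.uniform(-np.pi, np.pi, size=density.shape)
    spec = amp * np.exp(1j * phases)
    spec[..., 0] = 0.0
    if n_samples % 2 == 0:
        spec[..., -1] = 0.0
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _gaussian_bump(freqs: np.ndarray, center_hz: float, bandwidth_hz: float,
                   peak_density: float) -> np.ndarray:
    sigma = bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> SD
    return peak_density * np.exp(-((freqs - center_hz) ** 2) / (2 * sigma ** 2))


def simulate_background(duration_s: float, fs_hz: float,
                        exponent: float = 2.0,
                        band_components: tuple = (),
                        rng: np.random.Generator | None = None,
                        aperiodic_density_uv2: float = 0.0,
                        f_ref_hz: float = 1.0,
                        passband_hz: tuple[float, float] = (1.0, 1000.0),
                        ) -> np.ndarray:
    """Spontaneous-activity surrogate: 1/f^exponent background plus
    Gaussian spectral bumps.

    ``aperiodic_density_uv2`` is the one-sided density at ``f_ref_hz``
    (with exponent 0 the background is flat at this density);
    ``band_components`` is a list of (center_hz, bandwidth_fwhm_hz,
    peak_density_uv2) triples. Zero outside the passband.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if exponent < 0:
        raise ParameterError("exponent must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration_s * fs_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    density = np.zeros_like(freqs)
    inband = (freqs >= passband_hz[0]) & (freqs <= passband_hz[1])
    with np.errstate(divide="ignore"):
        ap = aperiodic_density_uv2 * (f_ref_hz / np.maximum(freqs, 1e-12)) ** exponent
    density[inband] = ap[inband]
    for center, bw, peak in band_components:
        if not np.isfinite(peak) or peak < 0:
            raise ParameterError("bump densities must be finite and >= 0")
        density += np.where(inband, _gaussian_bump(freqs, center, bw, peak), 0.0)
    return _shaped_noise(density, n, fs_hz, rng)


def _train_envelope(t: np.ndarray, train_dur_s: float,
                    ramp_s: float = 0.010) -> np.ndarray:
    """Gate: 1 inside [0, train_dur), raised-cosine 10 ms on/off ramps."""
    env = ((t >= 0) & (t < train_dur_s)).astype(float)
    rise = (t >= 0) & (t < ramp_s)
    env[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / ramp_s))
    fall = (t >= train_dur_s - ramp_s) & (t < train_dur_s)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (train_dur_s - t[fall]) / ramp_s))
    return env


def _draw_phases(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=size)
    return rng.vonmises(0.0, kappa, size=size)


def simulate_assr_trial(stim_rate_hz: float, amp_uv: float, kappa: float,
                        harmonic_amp_frac: float,
                        epoch_window_s: tuple[float, float],
                        fs_hz: float,
                        rng: np.random.Generator,
                        train_dur_s: float = 1.0,
                        background_density: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, float]:
    """One stimulus-locked epoch: background plus gated entrained sinusoid.

    The response is amp*sin(2*pi*f*t + phi) + harmonic_amp_frac*amp*
    sin(2*pi*2f*t + 2*phi) inside the train only, phi ~ von Mises(0, kappa),
    with 10 ms raised-cosine ramps. Returns (epoch µV, phi).

    ``background_density`` is a one-sided target PSD on the epoch's rfft
    grid (None -> no background).
    """
    t0, t1 = epoch_window_s
    if t0 > 0 or t1 < train_dur_s:
        raise ParameterError("epoch window must cover [0, train_dur_s]")
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    n = int(round((t1 - t0) * fs_hz))
    t = t0 + np.arange(n) / fs_hz
    phi = float(_draw_phases(rng, kappa, None))
    if background_density is not None:
        epoch_sig = _shaped_noise(background_density, n, fs_hz, rng)
    else:
        epoch_sig = np.zeros(n)
    if amp_uv > 0:
        env = _train_envelope(t, train_dur_s)
        wave = np.sin(2 * np.pi * stim_rate_hz * t + phi)
        wave += harmonic_amp_frac * np.sin(2 * np.pi * 2 * stim_rate_hz * t
                                           + 2 * phi)
        epoch_sig = epoch_sig + amp_uv * env * wave
    return epoch_sig, phi


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def cohort_density_grid(freqs: np.ndarray, band_density: dict[str, float],
                        exponent: float, mains_hz: float = 50.0
                        ) -> np.ndarray:
    """Piecewise one-sided target PSD from per-band densities.

    Flat at the target density inside each analysis band; the 45–55 Hz AC
    gap interpolates geometrically between the flanking gamma bands; above
    the last band the density decays as 1/f^exponent; zero outside the
    1–1000 Hz passband.
    """
    density = np.zeros_like(freqs)
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        density[sel] = band_density[name]
    gap = (freqs >= BANDS["low_gamma"][1]) & (freqs < BANDS["high_gamma"][0])
    density[gap] = np.sqrt(band_density["low_gamma"]
                           * band_density["high_gamma"])
    lead = (freqs >= 1.0) & (freqs < BANDS["delta"][0])
    density[lead] = band_density["delta"]
    hi_edge = BANDS["high_gamma"][1]
    tail = (freqs >= hi_edge) & (freqs <= 1000.0)
    with np.errstate(divide="ignore"):
        density[tail] = (band_density["high_gamma"]
                         * (hi_edge / freqs[tail]) ** exponent)
    return density


@dataclass
class GroundTruth:
    """Realised generative parameters of one simulated cohort."""

    spec_seed: int
    intended_icc: float
    animal_effects: dict      # animal_id -> {"power": a, "amp": a}
    day_effects: dict         # "cond/day" -> {"power": c, "amp": c}
    sessions: dict            # session_id -> realised parameters

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _animal_ids(spec: CohortSpec) -> list[tuple[str, str]]:
    males = [(f"M{i + 1:02d}", "M") for i in range(spec.n_males)]
    females = [(f"F{i + 1:02d}", "F") for i in range(spec.n_females)]
    return males + females


def _session_id(animal: str, day: int, condition: str, rate: float) -> str:
    return f"{animal}/day{day}/{condition}/r{rate:g}"


def _hierarchy(spec: CohortSpec) -> tuple[dict, dict, dict]:
    """Draw animal, day and residual effects for both multiplier chains."""
    rng = np.random.default_rng([spec.seed, 101])
    animals = _animal_ids(spec)
    a_eff = {aid: {"power": rng.normal(0, spec.sigma_animal),
                   "amp": rng.normal(0, spec.sigma_animal)}
             for aid, _ in animals}
    d_eff = {}
    for cond in spec.conditions:
        for day in range(1, spec.n_days + 1):
            d_eff[f"{cond}/day{day}"] = {
                "power": rng.normal(0, spec.sigma_day),
                "amp": rng.normal(0, spec.sigma_day),
            }
    r_eff = {}
    for aid, _ in animals:
        for cond in spec.conditions:
            for day in range(1, spec.n_days + 1):
                r_eff[f"{aid}/{cond}/day{day}"] = {
                    "power": rng.normal(0, spec.sigma_resid),
                    "amp": rng.normal(0, spec.sigma_resid),
                }
    return a_eff, d_eff, r_eff


def iter_cohort(spec: CohortSpec, ground_truth: GroundTruth | None = None
                ) -> Iterator[EpochsSet]:
    """Yield one EpochsSet per animal x day x condition x rate.

    Memory-light: sessions are generated on demand. Pass a GroundTruth from
    ``new_ground_truth`` to have realised session parameters (including
    per-trial phases) recorded as sessions are produced.
    """
    spec.validate()
    a_eff, d_eff, r_eff = _hierarchy(spec)
    n = int(round((spec.epoch_window_s[1] - spec.epoch_window_s[0])
                  * spec.fs_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs_hz)
    t = spec.epoch_window_s[0] + np.arange(n) / spec.fs_hz
    if spec.notch:
        b, a = iirnotch(50.0, Q=35.0, fs=spec.fs_hz)

    for ai, (aid, sex) in enumerate(_animal_ids(spec)):
        for day in range(1, spec.n_days + 1):
            for ci, cond in enumerate(spec.conditions):
                pow_mult = np.exp(a_eff[aid]["power"]
                                  + d_eff[f"{cond}/day{day}"]["power"]
                                  + r_eff[f"{aid}/{cond}/day{day}"]["power"])
                amp_mult = np.exp(a_eff[aid]["amp"]
                                  + d_eff[f"{cond}/day{day}"]["amp"]
                                  + r_eff[f"{aid}/{cond}/day{day}"]["amp"])
                band_density = {
                    bname: v * pow_mult
                    for bname, v in spec.band_power_uv2[(sex, cond)].items()
                }
                density = cohort_density_grid(freqs, band_density,
                                              spec.aperiodic_exponent)
                for rate in spec.stim_rates_hz:
                    rng = np.random.default_rng(
                        [spec.seed, ai, day, int(rate), ci, 7])
                    kappa = spec.kappa[(sex, cond)][rate]
                    amp = spec.entrain_amp_uv[(sex, cond)][rate] * amp_mult
                    phases = _draw_phases(rng, kappa, spec.n_trials)
                    noise = _shaped_noise(
                        np.broadcast_to(density, (spec.n_trials, freqs.size)),
                        n, spec.fs_hz, rng)
                    env = _train_envelope(t, spec.train_dur_s)
                    carrier = np.sin(2 * np.pi * rate * t[None, :]
                                     + phases[:, None])
                    carrier = carrier + spec.harmonic_amp_frac * np.sin(
                        2 * np.pi * 2 * rate * t[None, :]
                        + 2 * phases[:, None])
                    data = noise + amp * env[None, :] * carrier
                    if spec.mains_amp_uv > 0:
                        psi = rng.uniform(-np.pi, np.pi, size=spec.n_trials)
                        data = data + spec.mains_amp_uv * np.sin(
                            2 * np.pi * 50.0 * t[None, :] + psi[:, None])
                    if spec.notch:
                        data = filtfilt(b, a, data, axis=1)
                    sid = _session_id(aid, day, cond, rate)
                    if ground_truth is not None:
                        ground_truth.sessions[sid] = {
                            "kappa": float(kappa),
                            "amp_uv": float(amp),
                            "power_mult": float(pow_mult),
                            "amp_mult": float(amp_mult),
                            "expected_plf": expected_plf(kappa),
                            "phases": np.round(phases, 6).tolist(),
                        }
                    yield EpochsSet(
                        data=data, fs_hz=spec.fs_hz,
                        t0_s=spec.epoch_window_s[0], stim_rate_hz=rate,
                        meta={"animal_id": aid, "sex": sex, "day": day,
                              "condition": cond, "session_id": sid},
                    )


def new_ground_truth(spec: CohortSpec) -> GroundTruth:
    a_eff, d_eff, _ = _hierarchy(spec)
    return GroundTruth(
        spec_seed=spec.seed, intended_icc=spec.intended_icc(),
        animal_effects=a_eff, day_effects=d_eff, sessions={},
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[EpochsSet], GroundTruth]:
    """Materialise a full cohort in memory (desk-scale specs only)."""
    gt = new_ground_truth(spec)
    sessions = list(iter_cohort(spec, gt))
    return sessions, gt


def simulate_cohort_to_dir(spec: CohortSpec, out_dir: str | Path
                           ) -> GroundTruth:
    """Write a cohort as epoch bundles in animal/day/condition/rate dirs."""
    out = Path(out_dir)
    gt = new_ground_truth(spec)
    for es in iter_cohort(spec, gt):
        m = es.meta
        d = out / m["animal_id"] / f"day{m['day']}" / m["condition"] / \
            f"r{es.stim_rate_hz:g}"
        write_bundle(es, d)
    gt.to_json(out / "ground_truth.json")
    return gt
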