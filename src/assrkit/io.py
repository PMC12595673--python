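"""Recording and epoch I/O.

Continuous single-channel recordings are exchanged as EDF (European Data
Format) files plus a TSV event table of stimulus-train onsets; epoched data
live in a package-native *bundle*: ``meta.json`` describing the set and
``data.f32`` holding little-endian float32 samples, trial-major.

Conventions: time zero is stimulus-train onset, windows are half-open
``[t0, t1)`` with the sample at exactly t=0 on the post-stimulus side, and
amplitudes are microvolts throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChannelNotFoundError,
    DataIntegrityError,
    EpochWindowError,
    FormatError,
    ParameterError,
)

VALID_SEXES = ("M", "F")
VALID_CONDITIONS = ("baseline", "SAL", "KET")


@dataclass
class EpochsSet:
    """Stimulus-locked trials of one recording session.

    data : (n_trials, n_samples) array, µV
    fs_hz : sampling rate
    t0_s : time of the first sample relative to train onset (≤ 0 for ASSR)
    stim_rate_hz : stimulation train rate in Hz, or None for spontaneous-only
    meta : session descriptors (animal_id, sex, day, condition, session_id)
    """

    data: np.ndarray
    fs_hz: float
    t0_s: float
    stim_rate_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ParameterError("epochs data must be 2-D (trials x samples)")
        if self.fs_hz <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ParameterError("epoch samples must be finite")
        sex = self.meta.get("sex")
        if sex is not None and sex not in VALID_SEXES:
            raise ParameterError(f"sex must be one of {VALID_SEXES}, got {sex!r}")
        cond = self.meta.get("condition")
        if cond is not None and cond not in VALID_CONDITIONS:
            raise ParameterError(
                f"condition must be one of {VALID_CONDITIONS}, got {cond!r}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Sample times relative to train onset."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def time_slice(self, t_start: float, t_stop: float) -> slice:
        """Index slice for the half-open window [t_start, t_stop)."""
        if t_stop <= t_start:
            raise ParameterError("window must have t_stop > t_start")
        i0 = int(round((t_start - self.t0_s) * self.fs_hz))
        i1 = int(round((t_stop - self.t0_s) * self.fs_hz))
        if i0 < 0 or i1 > self.n_samples:
            raise EpochWindowError(
                f"window [{t_start}, {t_stop}) s outside epoch "
                f"[{self.t0_s}, {self.t0_s + self.n_samples / self.fs_hz}) s"
            )
        return slice(i0, i1)


def make_event_table(onsets_s: Sequence[float], stim_rates_hz: Sequence[float],
                     train_dur_s: float = 1.0, isi_s: float = 1.0) -> pd.DataFrame:
    """Build and validate an event table (columns onset_s, stim_rate_hz)."""
    df = pd.DataFrame({"onset_s": np.asarray(onsets_s, dtype=float),
                       "stim_rate_hz": np.asarray(stim_rates_hz, dtype=float)})
    if len(df) == 0:
        return df
    if not np.all(np.diff(df["onset_s"].to_numpy()) > 0):
        raise ParameterError("event onsets must be strictly increasing")
    gaps = np.diff(df["onset_s"].to_numpy())
    min_gap = train_dur_s + isi_s
    if np.any(gaps < min_gap - 1e-9):
        raise ParameterError(
            f"consecutive onsets closer than train_dur+isi={min_gap} s"
        )
    return df


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "stim_rate_hz"}
    if not required.issubset(df.columns):
        raise FormatError(f"event table needs columns {sorted(required)}")
    return make_event_table(df["onset_s"], df["stim_rate_hz"])


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit integer encoding with physical scaling.
# Minimal single-purpose implementation: continuous records, one or more
# channels, ASCII headers per the published EDF field layout.
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, signals: np.ndarray | Sequence[np.ndarray],
              fs_hz: float, channel_labels: Sequence[str] | None = None,
              phys_range_uv: float | None = None) -> None:
    """Write channels (µV) to an EDF file.

    Samples are quantized to 16 bits over ±phys_range_uv (default: tight
    symmetric range around the data). With integer fs the file uses 1-second
    data records and the signal length must be a whole number of seconds;
    otherwise a single record holds the full signal.
    """
    sig = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    n_chan, n_samp = sig.shape
    if n_samp == 0:
        raise ParameterError("cannot write an empty signal")
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_chan)]
    if len(channel_labels) != n_chan:
        raise ParameterError("one label per channel required")
    if phys_range_uv is None:
        peak = float(np.max(np.abs(sig))) if sig.size else 0.0
        phys_range_uv = peak if peak > 0 else 1.0
    if int(fs_hz) == fs_hz and n_samp % int(fs_hz) == 0:
        spr = int(fs_hz)
        n_records = n_samp // spr
        record_dur = 1.0
    else:
        spr = n_samp
        n_records = 1
        record_dur = n_samp / fs_hz

    dig_max, dig_min = 32767, -32767
    scale = dig_max / phys_range_uv
    digital = np.clip(np.round(sig * scale), dig_min, dig_max).astype("<i2")

    header_bytes = 256 * (1 + n_chan)
    hdr = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X assrkit synthetic", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(header_bytes, 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(f"{record_dur:g}", 8),
        _ascii(n_chan, 4),
    ])
    fields = [
        ("label", 16, list(channel_labels)),
        ("transducer", 80, [""] * n_chan),
        ("dim", 8, ["uV"] * n_chan),
        ("pmin", 8, [f"{-phys_range_uv:.6g}"] * n_chan),
        ("pmax", 8, [f"{phys_range_uv:.6g}"] * n_chan),
        ("dmin", 8, [dig_min] * n_chan),
        ("dmax", 8, [dig_max] * n_chan),
        ("prefilter", 80, ["BP 1-1000 Hz; N 50 Hz"] * n_chan),
        ("spr", 8, [spr] * n_chan),
        ("reserved", 32, [""] * n_chan),
    ]
    shdr = b"".join(
        b"".join(_ascii(v, width) for v in values) for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(hdr + shdr)
        for rec in range(n_records):
            for ch in range(n_chan):
                fh.write(digital[ch, rec * spr:(rec + 1) * spr].tobytes())


def read_edf(path: str | Path, channel: str | None = None
             ) -> tuple[np.ndarray, float, str]:
    """Read one channel from an EDF file.

    Returns (samples in µV after physical scaling, fs_hz, channel label).
    With ``channel=None`` the first channel is returned.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError("truncated EDF header")
        try:
            n_records = int(hdr[236:244].decode("ascii").strip())
            record_dur = float(hdr[244:252].decode("ascii").strip())
            n_chan = int(hdr[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"corrupt EDF header: {exc}") from exc
        if n_chan < 1 or n_records < 0 or record_dur <= 0:
            raise FormatError("implausible EDF header fields")
        shdr = fh.read(256 * n_chan)
        if len(shdr) < 256 * n_chan:
            raise FormatError("truncated EDF signal headers")

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_chan
            return [
                shdr[base + i * width: base + (i + 1) * width]
                .decode("ascii").strip()
                for i in range(n_chan)
            ]

        # per-channel field offsets: label 0, transducer 16, dim 96,
        # pmin 104, pmax 112, dmin 120, dmax 128, prefilter 136, spr 216
        labels = col(0, 16)
        pmin = [float(v) for v in col(104, 8)]
        pmax = [float(v) for v in col(112, 8)]
        dmin = [float(v) for v in col(120, 8)]
        dmax = [float(v) for v in col(128, 8)]
        spr = [int(v) for v in col(216, 8)]

        if channel is None:
            idx = 0
        else:
            try:
                idx = labels.index(channel)
            except ValueError:
                raise ChannelNotFoundError(
                    f"channel {channel!r} not in {labels}"
                ) from None

        record_words = sum(spr)
        raw = np.frombuffer(fh.read(2 * record_words * n_records), dtype="<i2")
        if raw.size != record_words * n_records:
            raise FormatError("EDF payload shorter than header promises")

    raw = raw.reshape(n_records, record_words)
    start = sum(spr[:idx])
    digital = raw[:, start:start + spr[idx]].ravel().astype(np.float64)
    gain = (pmax[idx] - pmin[idx]) / (dmax[idx] - dmin[idx])
    physical = (digital - dmin[idx]) * gain + pmin[idx]
    fs = spr[idx] / record_dur
    return physical, fs, labels[idx]


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(continuous: np.ndarray, fs_hz: float, events: pd.DataFrame,
          window_s: tuple[float, float] = (-1.0, 1.0),
          meta: dict | None = None) -> EpochsSet:
    """Cut a continuous signal into stimulus-locked trials.

    Each event contributes samples in the half-open window
    ``[onset + window_s[0], onset + window_s[1])``. No detrending or
    filtering is applied. All events must share one stimulation rate.
    """
    x = np.asarray(continuous, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("continuous signal must be 1-D")
    t0, t1 = window_s
    if t1 <= t0:
        raise ParameterError("window_s must be increasing")
    n_win = int(round((t1 - t0) * fs_hz))
    starts = np.round((events["onset_s"].to_numpy() + t0) * fs_hz).astype(int)
    bad = [
        float(on) for on, s in zip(events["onset_s"], starts)
        if s < 0 or s + n_win > x.size
    ]
    if bad:
        raise EpochWindowError(
            f"epoch window {window_s} overruns the recording for onsets {bad}"
        )
    rates = set(events["stim_rate_hz"])
    if len(rates) > 1:
        raise ParameterError(
            f"events mix stimulation rates {sorted(rates)}; epoch per rate"
        )
    rate = rates.pop() if rates else None
    data = np.stack([x[s:s + n_win] for s in starts]) if len(starts) else \
        np.empty((0, n_win))
    return EpochsSet(data=data, fs_hz=fs_hz, t0_s=t0, stim_rate_hz=rate,
                     meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Epoch bundles (meta.json + data.f32)
# ---------------------------------------------------------------------------

_BUNDLE_DTYPE = "<f4"


def write_bundle(epochs: EpochsSet, directory: str | Path) -> Path:
    """Write an EpochsSet as a bundle directory; lossless at float32."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_trials": epochs.n_trials,
        "n_samples": epochs.n_samples,
        "fs_hz": epochs.fs_hz,
        "t0_s": epochs.t0_s,
        "stim_rate_hz": epochs.stim_rate_hz,
        "units": "uV",
        "dtype": _BUNDLE_DTYPE,
        "order": "trial-major",
        "meta": epochs.meta,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    epochs.data.astype(_BUNDLE_DTYPE).tofile(d / "data.f32")
    return d


def read_bundle(directory: str | Path) -> EpochsSet:
    d = Path(directory)
    try:
        meta = json.loads((d / "meta.json").read_text())
    except FileNotFoundError:
        raise FormatError(f"{d} is not an epochs bundle (no meta.json)") from None
    raw = np.fromfile(d / "data.f32", dtype=meta.get("dtype", _BUNDLE_DTYPE))
    n_trials, n_samples = meta["n_trials"], meta["n_samples"]
    if raw.size != n_trials * n_samples:
        raise DataIntegrityError(
            f"{d}: data.f32 holds {raw.size} samples, meta.json promises "
            f"{n_trials}x{n_samples}"
        )
    return EpochsSet(
        data=raw.reshape(n_trials, n_samples).astype(np.float64),
        fs_hz=meta["fs_hz"], t0_s=meta["t0_s"],
        stim_rate_hz=meta["stim_rate_hz"], meta=meta.get("meta", {}),
    )
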