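"""Configuration-driven orchestration: simulate -> analyze -> report.

The pipeline turns a directory of epoch bundles (or an in-memory stream of
EpochsSet objects) into the study's report tables: spontaneous band power
per session, ASSR metrics per session x rate, per-sex ICC reliability
tables, last-vs-first-day paired contrasts, pooled sex comparisons, and
ketamine-vs-saline deltas with their group statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from . import assr, inference, reliability, spectral
from .errors import AssrkitError, ParameterError
from .io import EpochsSet, read_bundle, write_bundle
from .synth import CohortSpec, iter_cohort, new_ground_truth

log = logging.getLogger("assrkit.pipeline")

SPONT_METRICS = tuple(spectral.BAND_ORDER)
ASSR_METRICS = ("plf", "induced_ratio", "evoked_power")


@dataclass
class AnalysisConfig:
    psd_window_s: tuple[float, float] = (-0.9, -0.2)
    half_bandwidth_hz: float = 2.9
    n_tapers: int = 3
    wide_high_gamma: bool = False
    exclusions: tuple[tuple[float, float], ...] = (spectral.AC_EXCLUSION,)
    stim_window_s: tuple[float, float] = assr.STIM_WINDOW_S
    base_window_s: tuple[float, float] = assr.BASE_WINDOW_S
    n_cycles: float = 7.0
    max_freq_hz: float = 100.0
    compute_harmonics: bool = True
    compute_spont: bool = True

    @property
    def bands(self) -> dict[str, tuple[float, float]]:
        return (spectral.BANDS_WIDE_HIGH_GAMMA if self.wide_high_gamma
                else spectral.BANDS)


@dataclass
class StatsConfig:
    alpha_norm: float = 0.05
    alpha: float = 0.05
    icc_log10: bool = False
    icc_strict: bool = True


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cohort_kwargs = dict(raw.get("cohort", {}))
        for key in ("stim_rates_hz", "conditions", "epoch_window_s"):
            if key in cohort_kwargs:
                cohort_kwargs[key] = tuple(cohort_kwargs[key])
        cohort = CohortSpec(**cohort_kwargs)
        analysis_kwargs = dict(raw.get("analysis", {}))
        for key in ("psd_window_s", "stim_window_s", "base_window_s"):
            if key in analysis_kwargs:
                analysis_kwargs[key] = tuple(analysis_kwargs[key])
        if "exclusions" in analysis_kwargs:
            analysis_kwargs["exclusions"] = tuple(
                tuple(e) for e in analysis_kwargs["exclusions"])
        analysis = AnalysisConfig(**analysis_kwargs)
        stats = StatsConfig(**raw.get("stats", {}))
        seed = int(raw.get("seed", cohort.seed))
        cohort.seed = seed
        cohort.validate()
        return cls(cohort=cohort, analysis=analysis, stats=stats, seed=seed)

    def snapshot(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        d = dataclasses.asdict(self)
        d["cohort"]["band_power_uv2"] = {
            f"{s}:{c}": v for (s, c), v in d["cohort"]["band_power_uv2"].items()}
        d["cohort"]["entrain_amp_uv"] = {
            f"{s}:{c}": v for (s, c), v in d["cohort"]["entrain_amp_uv"].items()}
        d["cohort"]["kappa"] = {
            f"{s}:{c}": v for (s, c), v in d["cohort"]["kappa"].items()}
        return json.dumps(d, indent=1, sort_keys=True, default=enc)


# ---------------------------------------------------------------------------
# Per-session metric extraction
# ---------------------------------------------------------------------------

def session_metrics(epochs: EpochsSet, cfg: AnalysisConfig | None = None
                    ) -> dict:
    """All of one session's metrics: spontaneous band densities from the
    pre-stimulus window, plus ASSR metrics at the session's train rate."""
    if cfg is None:
        cfg = AnalysisConfig()
    row: dict = {
        "session_id": epochs.meta.get("session_id"),
        "animal_id": epochs.meta.get("animal_id"),
        "sex": epochs.meta.get("sex"),
        "day": epochs.meta.get("day"),
        "condition": epochs.meta.get("condition"),
        "stim_rate_hz": epochs.stim_rate_hz,
        "n_trials": epochs.n_trials,
    }
    if cfg.compute_spont:
        spec = spectral.psd_multitaper(
            epochs, window_s=cfg.psd_window_s,
            half_bandwidth_hz=cfg.half_bandwidth_hz, n_tapers=cfg.n_tapers)
        row.update(spectral.band_power(spec, bands=cfg.bands,
                                       exclusions=cfg.exclusions))
    rate = epochs.stim_rate_hz
    if rate is not None and rate in assr.RATE_BANDS:
        band = assr.RATE_BANDS[rate]
        freqs = np.arange(band[0], band[1] + 1.0)
        tfr = assr.morlet_tfr(epochs, freqs_hz=freqs, n_cycles=cfg.n_cycles)
        row["plf"] = assr.plf(tfr, band, cfg.stim_window_s)
        row["induced_ratio"] = assr.induced_power_ratio(
            tfr, band, cfg.stim_window_s, cfg.base_window_s)
        row["evoked_power"] = assr.evoked_power(
            epochs, band, cfg.stim_window_s, n_cycles=cfg.n_cycles)
        if cfg.compute_harmonics and 2 * rate <= cfg.max_freq_hz:
            row["harmonic_plf"] = assr.harmonic_response(
                epochs, rate, kind="plf", window_s=cfg.stim_window_s,
                n_cycles=cfg.n_cycles)
    return row


def analyze_sessions(sessions: Iterable[EpochsSet],
                     cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Session-metric table for an in-memory stream of sessions."""
    return pd.DataFrame([session_metrics(es, cfg) for es in sessions])


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _metric_list(df: pd.DataFrame) -> list[str]:
    return [m for m in (*SPONT_METRICS, *ASSR_METRICS, "harmonic_plf")
            if m in df.columns]


def icc_report(metrics: pd.DataFrame, stats: StatsConfig | None = None
               ) -> pd.DataFrame:
    """Per-sex ICC(A,1) across days, per metric and stimulation rate."""
    stats = stats or StatsConfig()
    base = metrics[metrics["condition"].isin(["baseline"])]
    rows = []
    for rate, sub in base.groupby("stim_rate_hz", sort=True):
        for m in _metric_list(sub):
            if sub[m].isna().all():
                continue
            tab = reliability.icc_table(
                sub.dropna(subset=[m]), m, strict=stats.icc_strict,
                log10=stats.icc_log10)
            tab.insert(1, "stim_rate_hz", rate)
            rows.append(tab)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

def day_contrast_report(metrics: pd.DataFrame,
                        stats: StatsConfig | None = None) -> pd.DataFrame:
    """Paired last-day vs first-day contrasts per sex, metric and rate."""
    stats = stats or StatsConfig()
    base = metrics[metrics["condition"] == "baseline"]
    if base.empty or base["day"].nunique() < 2:
        return pd.DataFrame()
    d0, d1 = base["day"].min(), base["day"].max()
    rows = []
    for (rate, sex), sub in base.groupby(["stim_rate_hz", "sex"], sort=True):
        for m in _metric_list(sub):
            wide = sub.pivot_table(index="animal_id", columns="day",
                                   values=m, aggfunc="mean")
            if d0 not in wide.columns or d1 not in wide.columns:
                continue
            wide = wide.dropna(subset=[d0, d1])
            if len(wide) < 3:
                continue
            try:
                res = inference.route_test(
                    wide[d1].to_numpy(), wide[d0].to_numpy(), paired=True,
                    alpha_norm=stats.alpha_norm)
            except AssrkitError as exc:
                log.warning("day contrast skipped (%s %s %s): %s",
                            rate, sex, m, exc)
                continue
            rows.append({
                "metric": m, "stim_rate_hz": rate, "sex": sex,
                "day_first": d0, "day_last": d1, "n": len(wide),
                "mean_first": wide[d0].mean(), "mean_last": wide[d1].mean(),
                "delta_mean": (wide[d1] - wide[d0]).mean(),
                "test_name": res.test_name, "statistic": res.statistic,
                "p_value": res.p_value,
            })
    return pd.DataFrame(rows)


def sex_comparison_report(metrics: pd.DataFrame,
                          stats: StatsConfig | None = None) -> pd.DataFrame:
    """Male-vs-female comparisons of baseline metrics pooled across days."""
    stats = stats or StatsConfig()
    base = metrics[metrics["condition"] == "baseline"]
    rows = []
    for rate, sub in base.groupby("stim_rate_hz", sort=True):
        for m in _metric_list(sub):
            data = sub.dropna(subset=[m]).rename(columns={m: "value"})
            if data.empty:
                continue
            try:
                res = inference.compare_sexes(
                    data, alpha_norm=stats.alpha_norm)
            except AssrkitError as exc:
                log.warning("sex comparison skipped (%s %s): %s", rate, m, exc)
                continue
            per = data.groupby(["animal_id", "sex"])["value"].mean() \
                .reset_index()
            rows.append({
                "metric": m, "stim_rate_hz": rate,
                "n_males": res.n[0], "n_females": res.n[1],
                "mean_males": per.loc[per.sex == "M", "value"].mean(),
                "mean_females": per.loc[per.sex == "F", "value"].mean(),
                "test_name": res.test_name, "statistic": res.statistic,
                "p_value": res.p_value, "direction": res.effect_direction,
            })
    return pd.DataFrame(rows)


def ket_delta_report(metrics: pd.DataFrame,
                     stats: StatsConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ketamine-vs-saline per-animal deltas and their group statistics.

    Returns (deltas, comparisons): per-animal KET-SAL deltas for every
    metric, then per-sex paired KET-vs-SAL tests and unpaired sex
    comparisons of each delta.
    """
    stats = stats or StatsConfig()
    drug = metrics[metrics["condition"].isin(["SAL", "KET"])]
    if drug.empty:
        return pd.DataFrame(), pd.DataFrame()
    delta_rows, comp_rows = [], []
    for (rate,), sub in drug.groupby(["stim_rate_hz"], sort=True):
        for m in _metric_list(sub):
            data = sub.dropna(subset=[m])[
                ["animal_id", "sex", "condition", m]].rename(
                columns={m: "value"})
            if data.empty:
                continue
            deltas = inference.delta_effect(data)
            deltas.insert(0, "metric", m)
            deltas.insert(1, "stim_rate_hz", rate)
            delta_rows.append(deltas)
            for sex, dsub in deltas.groupby("sex", sort=True):
                pair = data[data.sex == sex].pivot_table(
                    index="animal_id", columns="condition", values="value",
                    aggfunc="mean")
                if len(pair) < 3:
                    continue
                try:
                    res = inference.route_test(
                        pair["KET"].to_numpy(), pair["SAL"].to_numpy(),
                        paired=True, alpha_norm=stats.alpha_norm)
                except AssrkitError as exc:
                    log.warning("KET contrast skipped (%s %s %s): %s",
                                rate, sex, m, exc)
                    continue
                comp_rows.append({
                    "metric": m, "stim_rate_hz": rate, "comparison":
                    f"KET vs SAL ({sex})", "n": len(pair),
                    "mean_SAL": pair["SAL"].mean(),
                    "mean_KET": pair["KET"].mean(),
                    "delta_mean": dsub["delta"].mean(),
                    "test_name": res.test_name,
                    "statistic": res.statistic, "p_value": res.p_value,
                })
            try:
                res = inference.compare_sexes(
                    deltas.rename(columns={"delta": "value"}),
                    alpha_norm=stats.alpha_norm)
                comp_rows.append({
                    "metric": m, "stim_rate_hz": rate,
                    "comparison": "delta M vs F",
                    "n": sum(res.n),
                    "mean_SAL": np.nan, "mean_KET": np.nan,
                    "delta_mean": deltas["delta"].mean(),
                    "test_name": res.test_name,
                    "statistic": res.statistic, "p_value": res.p_value,
                })
            except AssrkitError as exc:
                log.warning("delta sex comparison skipped (%s %s): %s",
                            rate, m, exc)
    deltas = (pd.concat(delta_rows, ignore_index=True)
              if delta_rows else pd.DataFrame())
    return deltas, pd.DataFrame(comp_rows)


# ---------------------------------------------------------------------------
# Disk-facing runners
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Simulate the configured cohort to epoch bundles + ground truth."""
    out = Path(out_dir)
    config.cohort.validate()
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_snapshot.json").write_text(config.snapshot())
    gt = new_ground_truth(config.cohort)
    t0 = time.time()
    n = 0
    for es in iter_cohort(config.cohort, gt):
        m = es.meta
        d = (out / m["animal_id"] / f"day{m['day']}" / m["condition"]
             / f"r{es.stim_rate_hz:g}")
        write_bundle(es, d)
        n += 1
        log.info("simulated %s (%d trials)", m["session_id"], es.n_trials)
    gt.to_json(out / "ground_truth.json")
    log.info("simulated %d sessions in %.1f s", n, time.time() - t0)
    return out


def iter_bundles(data_dir: str | Path) -> Iterator[Path]:
    for meta in sorted(Path(data_dir).rglob("meta.json")):
        yield meta.parent


def run_analyze(config: PipelineConfig, data_dir: str | Path,
                out_dir: str | Path) -> dict:
    """Analyze a bundle directory into the report CSVs.

    Per-session metrics are cached in session_metrics.csv; sessions already
    present in the cache are skipped on re-runs. Unreadable bundles are
    recorded in failures.json; the returned summary lists them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_snapshot.json").write_text(config.snapshot())
    cache_path = out / "session_metrics.csv"
    cache = (pd.read_csv(cache_path, float_precision="round_trip")
             if cache_path.exists() else pd.DataFrame())
    done = set(cache["session_id"]) if "session_id" in cache.columns else set()
    rows, failures = [], []
    for bundle in iter_bundles(data_dir):
        try:
            es = read_bundle(bundle)
            sid = es.meta.get("session_id", str(bundle))
            if sid in done:
                continue
            t0 = time.time()
            row = session_metrics(es, config.analysis)
            row["session_id"] = sid
            rows.append(row)
            log.info("analyzed %s in %.2f s", sid, time.time() - t0)
        except (AssrkitError, OSError) as exc:
            failures.append({"bundle": str(bundle), "error": str(exc)})
            log.error("failed %s: %s", bundle, exc)
    metrics = pd.concat([cache, pd.DataFrame(rows)], ignore_index=True) \
        if rows or not cache.empty else pd.DataFrame()
    if metrics.empty:
        raise ParameterError(f"no analyzable sessions under {data_dir}")
    metrics.to_csv(cache_path, index=False)

    stats = config.stats
    if failures and stats.icc_strict:
        # failed sessions leave incomplete day series; degrade to lenient
        # reliability handling so the partial report can still be written
        stats = dataclasses.replace(stats, icc_strict=False)
    reports = build_reports(metrics, stats)
    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "failures.json").write_text(json.dumps(failures, indent=1))
    return {"n_sessions": len(metrics), "n_failures": len(failures),
            "out_dir": str(out), "failures": failures}


def build_reports(metrics: pd.DataFrame, stats: StatsConfig | None = None
                  ) -> dict[str, pd.DataFrame]:
    stats = stats or StatsConfig()
    spont_cols = ["session_id", "animal_id", "sex", "day", "condition",
                  "stim_rate_hz", *[b for b in SPONT_METRICS
                                    if b in metrics.columns]]
    assr_cols = [c for c in ("session_id", "animal_id", "sex", "day",
                             "condition", "stim_rate_hz", "plf",
                             "induced_ratio", "evoked_power",
                             "harmonic_plf") if c in metrics.columns]
    deltas, ket_comp = ket_delta_report(metrics, stats)
    icc = pd.DataFrame()
    base = metrics[metrics["condition"] == "baseline"]
    if not base.empty and base["day"].nunique() >= 2:
        icc = icc_report(metrics, stats)
    return {
        "spontaneous_band_power": metrics[
            [c for c in spont_cols if c in metrics.columns]],
        "assr_metrics": metrics[assr_cols],
        "icc_table": icc,
        "day_last_vs_first": day_contrast_report(metrics, stats),
        "sex_comparisons": sex_comparison_report(metrics, stats),
        "ket_deltas": deltas,
        "ket_comparisons": ket_comp,
    }
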