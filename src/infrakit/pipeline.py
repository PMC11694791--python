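"""End-to-end batch analysis: periodogram -> %ASD -> peaks -> exports.

`run_pipeline` applies the standard per-animal quantification sequence to
a batch of activity files and writes plain-CSV outputs plus a resolved
run log, so that a fixed configuration and input set reproduce
byte-identical results:

* Lomb-Scargle periodogram with the significance threshold (per animal);
* %ASD band partition and highest significant peak;
* wavelet ridge (when the record is long enough for the requested range);
* total activity (mean counts per 24 h over the analysis window);
* sleep summaries for PIR inputs;
* a composite normalized-periodogram matrix across animals.

Failures in any stage are logged per animal and do not abort the batch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .sleep import daily_sleep_fraction, label_days, pir_to_sleep, \
    select_cycling_window
from .spectral import composite_matrix, highest_peak, lomb_scargle, percent_asd
from .timeseries import ActivityRecord, TimeWindow, extract_window, \
    load_activity
from .wavelet import cwt_scalogram, extract_ridge

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved analysis configuration; written next to every run's outputs."""

    period_range: tuple = (20.0, 96.0)
    band_edges: tuple = (20.0, 27.0, 96.0)
    alpha: float = 1e-3
    oversample: float = 10.0
    wavelet: str = "morse"
    wavelet_gamma: float = 3.0
    wavelet_beta: float = 20.0
    window_start_hours: float | None = None   # None = full record
    window_duration_hours: float | None = None
    sleep_cycle_period: float = 48.0
    sleep_span_days: int = 4
    spatial_d_convention: str = "neg_slope"
    composite_points: int = 500
    seed: int = 0
    outdir: str = "infrakit_out"

    def validate(self) -> "PipelineConfig":
        lo, hi = self.period_range
        if not (0 < lo < hi):
            raise ValueError("invalid period_range")
        edges = tuple(self.band_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band_edges must be increasing")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha out of range")
        if self.wavelet not in ("morse", "morlet"):
            raise ValueError("wavelet must be morse or morlet")
        if self.spatial_d_convention not in ("neg_slope", "one_minus_slope"):
            raise ValueError("unknown spatial_d convention")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("period_range", "band_edges"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_range"] = list(self.period_range)
        d["band_edges"] = list(self.band_edges)
        return d


def _window(config: PipelineConfig, record: ActivityRecord) -> ActivityRecord:
    if config.window_start_hours is None and config.window_duration_hours is None:
        return record
    start = config.window_start_hours or 0.0
    dur = config.window_duration_hours or (record.duration_hours - start)
    return extract_window(record, TimeWindow(start, dur))


def run_pipeline(config: PipelineConfig, inputs, records=None) -> dict:
    """Run the quantification sequence over a batch of activity inputs.

    ``inputs`` is a list of activity CSV paths; alternatively pass
    in-memory ``records`` (list of ``(name, ActivityRecord)``).  Returns
    the report dict (also serialized under ``config.outdir``) with keys
    ``animals`` (per-animal results), ``errors``, and ``status`` in
    {"ok", "partial", "fatal"}.
    """
    config = config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    batch: list[tuple[str, object]] = [(str(p), p) for p in (inputs or [])]
    if records:
        batch += [(name, rec) for name, rec in records]

    animals, errors, pgs = [], {}, []
    for name, item in batch:
        try:
            rec = item if isinstance(item, ActivityRecord) else load_activity(item)
            rec = _window(config, rec)
            result = _analyze_one(config, name, rec, outdir)
            animals.append(result)
            pgs.append(result.pop("_pg"))
        except Exception as exc:  # noqa: BLE001 - per-animal isolation
            errors[name] = f"{type(exc).__name__}: {exc}"

    if pgs:
        grid, mat = composite_matrix(pgs, config.composite_points)
        _write_csv(outdir / "composite_periodograms.csv",
                   ["period_hours"] + [a["name"] for a in animals],
                   np.column_stack([grid, mat.T]))

    status = "ok" if not errors else ("partial" if animals else "fatal")
    if not batch:
        status = "ok"
    report = {"animals": animals, "errors": errors, "status": status,
              "version": __version__, "config": config.to_dict()}
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(
        {k: report[k] for k in ("status", "errors", "version", "config")},
        sort_keys=True))
    return report


def _analyze_one(config: PipelineConfig, name: str, rec: ActivityRecord,
                 outdir: Path) -> dict:
    stem = Path(name).stem or "record"
    pg = lomb_scargle(rec, config.period_range, config.oversample, config.alpha)
    part = percent_asd(pg, config.band_edges)
    peak = highest_peak(pg)
    total_per_day = float(rec.counts[~rec.gap_mask].sum()
                          / max(rec.duration_hours / 24.0, 1e-12))

    _write_csv(outdir / f"{stem}_periodogram.csv",
               ["period_hours", "power", "significant"],
               np.column_stack([pg.periods, pg.power,
                                pg.significant.astype(float)]))

    result = {
        "name": stem,
        "n_bins": rec.n_bins,
        "highest_peak_hours": peak,
        "asd_percent": [float(v) for v in part.asd_percent],
        "band_edges": list(part.band_edges),
        "total_activity_per_24h": total_per_day,
        "_pg": pg,
    }

    hi = config.period_range[1]
    if rec.duration_hours >= 2 * hi:
        scal = cwt_scalogram(rec, (config.period_range[0] * 0.9, hi),
                             wavelet=config.wavelet,
                             gamma=config.wavelet_gamma,
                             beta=config.wavelet_beta)
        ridge = extract_ridge(scal)
        _write_csv(outdir / f"{stem}_ridge.csv",
                   ["time_hours", "period_hours", "valid"],
                   np.column_stack([ridge.times, ridge.peak_period,
                                    ridge.valid.astype(float)]))
        good = ridge.peak_period[ridge.valid]
        result["ridge_median_period_hours"] = (
            float(np.median(good)) if good.size else float("nan"))

    if rec.channel == "pir" and abs(rec.bin_width - 1.0) < 1e-9:
        try:
            sel = select_cycling_window(rec, config.sleep_span_days)
            sleep = pir_to_sleep(rec)
            labeling = label_days(sleep, sel.window, config.sleep_cycle_period)
            summary = daily_sleep_fraction(sleep, labeling)
            rows = [[d["day"], 1.0 if d["label"] == "active" else 0.0,
                     d["sleep_minutes"], d["fraction"]]
                    for d in summary["per_day"]]
            _write_csv(outdir / f"{stem}_sleep.csv",
                       ["day", "active", "sleep_minutes", "fraction"],
                       np.asarray(rows, float))
            result["sleep"] = {
                "window_start_hours": sel.window.start_offset,
                "low_confidence": sel.low_confidence,
                "mean_fraction": summary["mean_fraction"],
            }
        except ValueError as exc:
            result["sleep"] = {"error": str(exc)}
    return result


def _write_csv(path: Path, header: list, data: np.ndarray) -> None:
    with path.open("w") as fh:
        fh.write(",".join(header) + "\n")
        for row in np.atleast_2d(data):
            fh.write(",".join(f"{v:.6f}" if np.isfinite(v) else ""
                              for v in row) + "\n")
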