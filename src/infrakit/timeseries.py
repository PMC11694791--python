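"""Core representation and I/O for binned locomotor count series.

Activity from running wheels (revolutions per 5-min bin) and passive
infrared sensors (counts per 1-min bin) is held in :class:`ActivityRecord`:
an evenly binned, possibly gapped count series.  Gaps (recording drop-outs)
are represented by an explicit boolean mask rather than by zeros, because a
zero count is meaningful data — it is the very definition of a sleep minute
in PIR scoring — whereas a masked bin must be ignored by every downstream
statistic.

Bins are left-closed, right-open intervals; a bin's timestamp is its left
edge.  Internally time is measured in floating-point hours from the record
start; the absolute start timestamp is retained for display only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ActivityRecord",
    "TimeWindow",
    "load_activity",
    "write_activity",
    "rebin",
    "extract_window",
]

#: default bin widths (minutes) per channel
DEFAULT_BIN_WIDTH = {"wheel": 5.0, "pir": 1.0}

#: tolerated relative jitter of the sampling interval in timestamped files
MAX_JITTER = 0.01


@dataclass(frozen=True)
class ActivityRecord:
    """Evenly binned locomotor count series with an explicit gap mask.

    Parameters
    ----------
    counts
        Non-negative counts per bin.  Values at masked bins are carried
        along but ignored by every operation in this package.
    bin_width
        Bin width in minutes (> 0).
    gap_mask
        Boolean per bin; ``True`` marks a missing/invalid bin.
    channel
        ``"wheel"`` or ``"pir"``.
    start_time
        Absolute timestamp of the first bin's left edge (display only).
    """

    counts: np.ndarray
    bin_width: float
    gap_mask: np.ndarray = None  # type: ignore[assignment]
    channel: str = "wheel"
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp(0))

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        mask = self.gap_mask
        if mask is None:
            mask = ~np.isfinite(counts) | (counts < 0)
        mask = np.asarray(mask, dtype=bool)
        if counts.shape != mask.shape or counts.ndim != 1:
            raise ValueError("counts and gap_mask must be 1-D and equal length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.channel not in ("wheel", "pir"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if np.any(counts[~mask] < 0) or not np.all(np.isfinite(counts[~mask])):
            raise ValueError("unmasked counts must be finite and non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gap_mask", mask)

    # -- derived views -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_width / 60.0

    @property
    def times_hours(self) -> np.ndarray:
        """Left bin edges in hours from record start."""
        return np.arange(self.n_bins) * (self.bin_width / 60.0)

    @property
    def n_unmasked(self) -> int:
        return int((~self.gap_mask).sum())

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        """(times_hours, counts) restricted to valid bins."""
        keep = ~self.gap_mask
        return self.times_hours[keep], self.counts[keep]

    def with_counts(self, counts, gap_mask=None) -> "ActivityRecord":
        return replace(
            self,
            counts=np.asarray(counts, dtype=float),
            gap_mask=self.gap_mask if gap_mask is None else np.asarray(gap_mask, bool),
        )


@dataclass(frozen=True)
class TimeWindow:
    """Analysis window: offset and duration in hours from record start."""

    start_offset: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("window duration must be positive")

    @property
    def end_offset(self) -> float:
        return self.start_offset + self.duration


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _format_count(v: float) -> str:
    # bit-exact round trip: integers as integers, floats via repr
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def load_activity(path, dialect: str = "auto", bin_width: float | None = None,
                  channel: str | None = None) -> ActivityRecord:
    """Read an activity record from plain tabular text.

    Two dialects are supported (auto-detected from the header):

    ``timestamped``
        CSV with columns ``timestamp,count``; timestamps ISO-8601 or
        elapsed minutes.  The sampling interval must be uniform to within
        1% relative jitter, otherwise the file is rejected.
    ``counts``
        Headerless single count column; metadata (bin width, channel,
        start) comes from a YAML sidecar ``<path>.yaml`` or from keyword
        arguments.

    Blank, unparseable or negative count fields become masked bins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if dialect == "auto":
        head = lines[0].lower().replace(" ", "") if lines else ""
        dialect = "timestamped" if "timestamp" in head else "counts"

    if dialect == "timestamped":
        sep = "\t" if "\t" in lines[0] else ","
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str,
                         keep_default_na=False)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if "timestamp" not in cols or "count" not in cols:
            raise ValueError(f"{path}: expected 'timestamp' and 'count' columns")
        ts_raw = df["timestamp"].astype(str)
        try:
            elapsed_min = ts_raw.astype(float).to_numpy()
            start = pd.Timestamp(0)
        except ValueError:
            stamps = pd.to_datetime(ts_raw, format="ISO8601")
            start = stamps.iloc[0]
            elapsed_min = ((stamps - start).dt.total_seconds() / 60.0).to_numpy()
        if len(elapsed_min) >= 2:
            dt = np.diff(elapsed_min)
            width = float(np.median(dt))
            if width <= 0 or np.any(np.abs(dt - width) > MAX_JITTER * width):
                raise ValueError(
                    f"{path}: inconsistent sampling interval (>1% jitter)")
        else:
            width = bin_width if bin_width is not None else 1.0
        counts, mask = _parse_counts(df["count"])
        if bin_width is not None:
            width = bin_width
    elif dialect == "counts":
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
        width = bin_width or float(meta.get("bin_width_minutes", 0)) or None
        channel = channel or meta.get("channel")
        start = pd.Timestamp(meta["start"]) if "start" in meta else pd.Timestamp(0)
        body = [ln for ln in lines if not ln.lstrip().startswith("#")]
        counts, mask = _parse_counts(pd.Series(body))
        if width is None:
            width = DEFAULT_BIN_WIDTH.get(channel or "wheel")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    channel = channel or ("pir" if abs(width - 1.0) < 1e-9 else "wheel")
    safe = np.where(mask, 0.0, counts)
    return ActivityRecord(counts=safe, bin_width=float(width),
                          gap_mask=mask, channel=channel, start_time=start)


def _parse_counts(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    # Python float() is correctly rounded, which makes repr-serialized
    # counts round-trip bit-exactly
    counts = np.empty(len(series))
    for i, s in enumerate(series.astype(str).str.strip()):
        try:
            counts[i] = float(s)
        except ValueError:
            counts[i] = np.nan
    mask = ~np.isfinite(counts) | (counts < 0)
    return counts, mask


def write_activity(record: ActivityRecord, path) -> None:
    """Write a record as ``timestamp,count`` CSV (elapsed minutes).

    Gap bins are serialized as empty count fields; numeric content
    round-trips bit-exactly through :func:`load_activity`.
    """
    path = Path(path)
    w = record.bin_width
    with path.open("w") as fh:
        fh.write("timestamp,count\n")
        for i, (c, m) in enumerate(zip(record.counts, record.gap_mask)):
            t = i * w
            tstr = _format_count(t)
            fh.write(f"{tstr},{'' if m else _format_count(c)}\n")


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def rebin(record: ActivityRecord, new_width: float) -> ActivityRecord:
    """Sum counts into coarser bins.

    ``new_width`` must be an integer multiple of the record's bin width.
    A coarse bin is masked iff any constituent fine bin is masked; total
    unmasked counts are conserved for gap-free records.
    """
    ratio = new_width / record.bin_width
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"new width {new_width} is not an integer multiple of "
            f"{record.bin_width}")
    k = int(round(ratio))
    if k == 1:
        return record
    n = (record.n_bins // k) * k
    counts = np.where(record.gap_mask, 0.0, record.counts)[:n].reshape(-1, k)
    mask = record.gap_mask[:n].reshape(-1, k)
    return replace(record, counts=counts.sum(axis=1), bin_width=float(new_width),
                   gap_mask=mask.any(axis=1))


def extract_window(record: ActivityRecord, window: TimeWindow) -> ActivityRecord:
    """Sub-record covering ``window``, preserving bin width and mask.

    The window must lie within the record span; bin membership follows the
    left-closed convention (a bin belongs to the window iff its left edge
    does).
    """
    bw_h = record.bin_width / 60.0
    if window.start_offset < -1e-9 or window.end_offset > record.duration_hours + 1e-9:
        raise ValueError("window outside record span")
    i0 = int(round(window.start_offset / bw_h))
    i1 = int(round(window.end_offset / bw_h))
    i0, i1 = max(i0, 0), min(i1, record.n_bins)
    if i1 <= i0:
        raise ValueError("window contains no bins")
    return replace(
        record,
        counts=record.counts[i0:i1].copy(),
        gap_mask=record.gap_mask[i0:i1].copy(),
        start_time=record.start_time + pd.Timedelta(hours=i0 * bw_h),
    )
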