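"""Open-field path metrics: distance traveled and spatial d.

Spatial d is a fractal-geometry measure of path tortuosity used to
quantify mania-like straight-path locomotion: the trajectory is reduced
to "microevents" — the first video frame at each successive 2-cm mark of
cumulative path length — and the total path length ``L_k`` is re-measured
through every k-th microevent for k in {1, 2, 4, 8}.  A straight path
keeps the same length at every resolution (slope 0); a tortuous path
shortens as k grows.  Spatial d is the negative slope of the least-squares
line through ``log2(L_k)`` vs ``log2(k)``.  Straighter movement gives a
lower spatial d.

Two reporting conventions exist in the literature: the plain negative
slope (default here) and ``1 - slope``, which places a straight line at
d = 1 as in the original fractal-dimension formulation.  Both are
computed; ``convention`` selects which is reported as ``spatial_d``.

Input traces are x-y positions in cm at a fixed frame rate (30 fps in a
50x50 cm arena for the standard 10-min test), as produced by video
trackers such as ezTrack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PathTrace",
    "SpatialDFit",
    "load_trace",
    "total_distance",
    "segment_microevents",
    "path_length_at_resolution",
    "spatial_d",
]

RESOLUTIONS = (1, 2, 4, 8)
SEGMENT_CM = 2.0


@dataclass(frozen=True)
class PathTrace:
    """Calibrated x-y trajectory sampled at a uniform frame rate."""

    xy: np.ndarray               # (n, 2) positions, cm
    fps: float = 30.0
    arena_cm: float = 50.0

    def __post_init__(self):
        xy = np.asarray(self.xy, float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        tol = 0.05 * self.arena_cm
        fin = xy[np.all(np.isfinite(xy), axis=1)]
        if fin.size and (fin.min() < -tol or fin.max() > self.arena_cm + tol):
            raise ValueError("positions outside arena bounds")
        object.__setattr__(self, "xy", xy)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class SpatialDFit:
    """Multi-resolution path-length fit underlying spatial d."""

    microevent_indices: np.ndarray
    L_k: dict                    # resolution -> path length (cm)
    slope: float
    spatial_d: float
    convention: str              # "neg_slope" | "one_minus_slope"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_trace(path, calibration_cm_per_px: float = 1.0, fps: float = 30.0,
               arena_cm: float = 50.0, max_gap_frames: int = 5) -> PathTrace:
    """Read a (frame, x, y) CSV trace; ezTrack location output dialect.

    Columns named ``X``/``Y`` (any case) are used; positions are
    multiplied by ``calibration_cm_per_px``.  Single missing frames are
    bridged by linear interpolation; runs longer than ``max_gap_frames``
    invalidate the trace.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: expected X and Y columns")
    xy = df[[cols["x"], cols["y"]]].to_numpy(float) * calibration_cm_per_px
    bad = ~np.all(np.isfinite(xy), axis=1)
    if bad.any():
        run = _longest_run(bad)
        if run > max_gap_frames:
            raise ValueError(f"{path}: gap of {run} frames exceeds "
                             f"{max_gap_frames}-frame tolerance")
        idx = np.arange(len(xy))
        for d in range(2):
            xy[bad, d] = np.interp(idx[bad], idx[~bad], xy[~bad, d])
    return PathTrace(xy=xy, fps=fps, arena_cm=arena_cm)


def _longest_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def total_distance(trace: PathTrace) -> float:
    """Total distance traveled: sum of frame-to-frame displacements (cm)."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames")
    steps = np.linalg.norm(np.diff(trace.xy, axis=0), axis=1)
    return float(steps.sum())


def segment_microevents(trace: PathTrace,
                        segment_cm: float = SEGMENT_CM) -> np.ndarray:
    """Frame indices at successive ``segment_cm`` marks of path length.

    Frame 0 is the first microevent; each subsequent microevent is the
    first frame at/after the cumulative path length crosses the next
    multiple of ``segment_cm``.  The trailing partial segment is dropped.
    At least 9 microevents are required downstream (so that L_8 exists).
    """
    steps = np.linalg.norm(np.diff(trace.xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    if total < 2 * segment_cm:
        raise ValueError("path too short to segment")
    eps = 1e-9 * max(total, 1.0)  # guard against accumulated round-off
    n_marks = int(np.floor((total + eps) / segment_cm))
    marks = segment_cm * np.arange(1, n_marks + 1)
    idx = np.minimum(np.searchsorted(cum, marks - eps, side="left"),
                     trace.n_frames - 1)
    indices = np.concatenate([[0], idx])
    if indices.size < max(RESOLUTIONS) + 1:
        raise ValueError(
            f"only {indices.size} microevents; need at least "
            f"{max(RESOLUTIONS) + 1} to evaluate k = {max(RESOLUTIONS)}")
    return indices


def path_length_at_resolution(positions: np.ndarray, k: int) -> float:
    """Path length through every k-th microevent position (cm).

    Sums straight-line distances between microevents taken ``k`` apart,
    starting at the first; microevents beyond the last full stride are
    dropped.
    """
    pos = np.asarray(positions, float)
    if pos.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} microevents for k = {k}")
    sub = pos[::k]
    return float(np.linalg.norm(np.diff(sub, axis=0), axis=1).sum())


def spatial_d(trace: PathTrace, segment_cm: float = SEGMENT_CM,
              convention: str = "neg_slope") -> SpatialDFit:
    """Spatial d of a trajectory via the multi-resolution length fit.

    Ordinary least squares of ``log2(L_k)`` on ``log2(k)`` over
    k in {1, 2, 4, 8}; ``spatial_d`` is ``-slope`` (default) or
    ``1 - slope`` under the ``one_minus_slope`` convention.
    """
    if convention not in ("neg_slope", "one_minus_slope"):
        raise ValueError(f"unknown convention {convention!r}")
    idx = segment_microevents(trace, segment_cm)
    # truncate so every resolution spans the same path stretch (the
    # stride count divides evenly); otherwise the dropped remainder
    # differs per k and even a straight line gets a spurious slope
    kmax = max(RESOLUTIONS)
    m = kmax * ((idx.size - 1) // kmax) + 1
    pos = trace.xy[idx[:m]]
    lk = {k: path_length_at_resolution(pos, k) for k in RESOLUTIONS}
    if any(v <= 0 for v in lk.values()):
        raise ValueError("degenerate path: zero length at some resolution")
    x = np.log2(np.array(RESOLUTIONS, float))
    y = np.log2(np.array([lk[k] for k in RESOLUTIONS]))
    # equal lengths at all resolutions (straight path) is slope 0 exactly
    slope = 0.0 if np.ptp(y) == 0 else float(np.polyfit(x, y, 1)[0])
    d = -slope if convention == "neg_slope" else 1.0 - slope
    return SpatialDFit(microevent_indices=idx, L_k=lk, slope=slope,
                       spatial_d=d, convention=convention)
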