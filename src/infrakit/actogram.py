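"""Actogram matrix construction (single, double, and modulo plotting).

An actogram folds a count series at a fixed row period — classically 24 h,
or an arbitrary "modulo" period such as the animal's own infradian peak
period — into a rows x bins matrix, one row per cycle.  Double plotting
(``n_plot = 2``) lays each row's successor alongside it so rhythms that
cross the fold remain readable.  Masked bins and the trailing partial row
are NaN in the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .timeseries import ActivityRecord

__all__ = ["ActogramMatrix", "actogram_matrix"]


@dataclass(frozen=True)
class ActogramMatrix:
    """Folded count matrix; NaN cells are masked or padding."""

    matrix: np.ndarray
    row_period: float            # hours
    n_plot: int                  # 1 = single, 2 = double plot
    bin_width: float             # minutes

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def bins_per_row(self) -> int:
        return self.matrix.shape[1]


def actogram_matrix(record: ActivityRecord, row_period: float = 24.0,
                    n_plot: int = 1) -> ActogramMatrix:
    """Fold a record at ``row_period`` into an actogram matrix.

    ``row_period`` must lie in [16, 96] h; when it is not an integer
    multiple of the bin width the row length is rounded to the nearest
    bin and a warning records the residual.  Consecutive rows advance by
    exactly one row period; with ``n_plot = 2`` row ``r`` shows rows
    ``r`` and ``r + 1`` side by side.
    """
    if record.n_bins == 0:
        raise ValueError("empty record")
    if not (16.0 <= row_period <= 96.0):
        raise ValueError("row_period must lie in [16, 96] hours")
    if n_plot not in (1, 2):
        raise ValueError("n_plot must be 1 or 2")
    bw_h = record.bin_width / 60.0
    exact = row_period / bw_h
    per_row = int(round(exact))
    if per_row < 1:
        raise ValueError("row period shorter than one bin")
    residual = (exact - per_row) * bw_h
    if abs(residual) > 1e-9:
        warnings.warn(
            f"row period {row_period} h rounded to {per_row} bins "
            f"(residual {residual * 60:.3f} min per row)", stacklevel=2)

    vals = np.where(record.gap_mask, np.nan, record.counts)
    n_rows = int(np.ceil(record.n_bins / per_row))
    padded = np.full(n_rows * per_row, np.nan)
    padded[: record.n_bins] = vals
    single = padded.reshape(n_rows, per_row)
    if n_plot == 1:
        return ActogramMatrix(single, row_period, 1, record.bin_width)
    nxt = np.full_like(single, np.nan)
    nxt[:-1] = single[1:]
    return ActogramMatrix(np.hstack([single, nxt]), row_period, 2,
                          record.bin_width)
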