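"""Optional PNG renders mirroring the field's display conventions.

Actogram raster, periodogram with the significance threshold line, and
scalogram heatmap with the ridge overlaid as a black trace.  These are
conveniences for visual inspection; all quantification lives in the
analysis modules and the CSV exports.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .actogram import ActogramMatrix  # noqa: E402
from .spectral import Periodogram  # noqa: E402
from .wavelet import Ridge, Scalogram  # noqa: E402

__all__ = ["plot_actogram", "plot_periodogram", "plot_scalogram"]


def plot_actogram(mat: ActogramMatrix, path, cmap: str = "Greys") -> None:
    """Raster render of a folded actogram matrix; gaps are shown gray."""
    fig, ax = plt.subplots(figsize=(6, 0.25 * mat.n_rows + 1))
    shown = np.ma.masked_invalid(mat.matrix)
    ax.imshow(shown, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xlabel(f"time in row (x{mat.bin_width:g} min bins, "
                  f"row = {mat.n_plot} x {mat.row_period:g} h)")
    ax.set_ylabel("cycle")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_periodogram(pg: Periodogram, path) -> None:
    """Power vs period with the significance threshold as a green line."""
    fig, ax = plt.subplots(figsize=(6, 3))
    order = np.argsort(pg.periods)
    ax.plot(pg.periods[order], pg.power[order], lw=0.8, color="k")
    ax.axhline(pg.sig_level, color="green", lw=1,
               label=f"threshold (alpha={pg.alpha:g})")
    ax.set_xlabel("period (h)")
    ax.set_ylabel("LS power")
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_scalogram(scal: Scalogram, path, ridge: Ridge | None = None) -> None:
    """Time x period power heatmap, ridge overlaid as a black trace."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.pcolormesh(scal.times, scal.periods,
                  np.where(scal.valid, scal.power, np.nan),
                  shading="nearest", cmap="viridis")
    if ridge is not None:
        shown = np.where(ridge.valid, ridge.peak_period, np.nan)
        ax.plot(ridge.times, shown, color="k", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("period (h)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
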