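"""Optional matplotlib renderings of the standard outputs.

Imported lazily; the rest of the package works without matplotlib.
"""

from __future__ import annotations

import math

import numpy as np

from .concordance import ORMatrix, export_read_profiles
from .read_calling import ReadCallMatrix

__all__ = ["plot_or_heatmap", "plot_read_profiles", "plot_site_percent"]


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_or_heatmap(orm: ORMatrix, out_path: str, ceiling: float = 20.0):
    """OR matrix as a red heatmap; +inf renders at the colormap ceiling.

    The ceiling is configurable because the saturating OR is a display
    choice, not a property of the statistic.
    """
    plt = _plt()
    arr = orm.values()
    shown = np.where(np.isinf(arr), ceiling, arr)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(shown, cmap="Reds", vmin=0, vmax=ceiling)
    ax.set_xticks(range(len(orm.indices)), orm.indices)
    ax.set_yticks(range(len(orm.indices)), orm.indices)
    ax.set_xlabel("CpG")
    ax.set_ylabel("CpG")
    fig.colorbar(im, ax=ax, label="odds ratio")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_read_profiles(matrix: ReadCallMatrix, out_path: str,
                       ordering: str = "by_methylation_count_desc"):
    """Raster of per-read profiles: black = methylated, white =
    unmethylated, grey = no call."""
    plt = _plt()
    profiles = export_read_profiles(matrix, ordering=ordering)
    code = {"M": 0.0, "U": 1.0, "N": 0.5}
    img = np.array([[code[c] for c in row] for row in profiles])
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(img, cmap="gray", aspect="auto", interpolation="nearest", vmin=0, vmax=1)
    ax.set_xticks(range(matrix.n_sites), [s.global_index for s in matrix.sites])
    ax.set_xlabel("CpG")
    ax.set_ylabel("read")
    ax.set_yticks([])
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_site_percent(table, out_path: str):
    """Bar graph of per-CpG modification percent with CI error bars,
    from a :func:`ampliconmeth.site_table` DataFrame."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = table["global_index"]
    y = table["p_percent"]
    err = np.vstack([
        (y - table["ci_low_percent"]).clip(lower=0),
        (table["ci_high_percent"] - y).clip(lower=0),
    ])
    ax.bar(x, y, color="0.2", yerr=np.nan_to_num(err), capsize=2)
    ax.set_xlabel("CpG (locus-wide index)")
    ax.set_ylabel("% modified of total C")
    ax.set_ylim(0, 100)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
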