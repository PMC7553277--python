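"""Niche-panel figures: two occupancy densities in the PC1-PC2 plane.

Each panel shows the reference and compared occupancy densities, arrows
for the environmental- and niche-centroid shifts, and solid/dashed
contours holding 100% and 50% of each background's density mass.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .niche_overlap import density_grid, pooled_bounds  # noqa: E402

__all__ = ["plot_niche_panel"]


def _mass_contour_level(e: np.ndarray, mass: float) -> float:
    """Density level whose superlevel set holds the given density mass."""
    flat = np.sort(e[e > 0])[::-1]
    cum = np.cumsum(flat) / flat.sum()
    k = int(np.searchsorted(cum, mass))
    return float(flat[min(k, flat.size - 1)])


def plot_niche_panel(occ1, occ2, bg1, bg2, R=100, labels=("1", "2"),
                     path=None):
    occ1, occ2 = np.atleast_2d(occ1), np.atleast_2d(occ2)
    bg1, bg2 = np.atleast_2d(bg1), np.atleast_2d(bg2)
    bounds = pooled_bounds(bg1, bg2, occ1, occ2)
    g1 = density_grid(occ1, bg1, R, bounds)
    g2 = density_grid(occ2, bg2, R, bounds)
    xs, ys = g1.cell_centers()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.contourf(xs, ys, g1.z.T, levels=8, cmap="Greens", alpha=0.6)
    ax.contourf(xs, ys, g2.z.T, levels=8, cmap="Purples", alpha=0.45)
    for g, color in ((g1, "darkgreen"), (g2, "indigo")):
        for mass, style in ((0.999, "-"), (0.5, "--")):
            ax.contour(xs, ys, g.e.T,
                       levels=[_mass_contour_level(g.e, mass)],
                       colors=[color], linestyles=[style], linewidths=0.8)
    env_c1, env_c2 = bg1.mean(axis=0), bg2.mean(axis=0)
    occ_c1, occ_c2 = occ1.mean(axis=0), occ2.mean(axis=0)
    ax.annotate("", xy=env_c2[:2], xytext=env_c1[:2],
                arrowprops=dict(arrowstyle="->", color="grey", lw=1.5))
    ax.annotate("", xy=occ_c2[:2], xytext=occ_c1[:2],
                arrowprops=dict(arrowstyle="->", color="black", lw=1.5))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"{labels[0]} (green) vs {labels[1]} (purple)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return None
    return fig, ax
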