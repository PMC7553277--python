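"""PCA-env niche overlap: density grids, Schoener's D, tests, dynamics.

The environmental plane is the first two standardized PCA axes.  For each
population an R x R grid holds the kernel density of its occurrences (o)
and of its available environment (e); the occupancy z = o/e (0 where e is
0), normalized to sum 1, corrects the occurrence density for what climate
is actually available in each region.  Overlap between two occupancies is
Schoener's D = 1 - 0.5 * sum |z1 - z2|.

Two randomization tests accompany D: the equivalence test (pool and
re-split the occurrences) and the similarity test (recenter one
population's observed occurrence density at random within its own
background).  The occupancy pair also decomposes into expansion,
stability and unfilling proportions over the analogous environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import stable_seed

__all__ = [
    "DensityGrid", "OverlapResult", "pooled_bounds", "density_grid",
    "schoener_d", "equivalence_test", "similarity_test", "niche_dynamics",
    "dynamics_category", "silverman_bandwidth",
]

TRUNC = 5.0  # kernel truncated at this many bandwidths per axis

# Cells whose background density is below this fraction of its peak are
# treated as unavailable environment when forming occupancy: the o/e ratio
# in the far tail of the truncated background kernel is a ratio of two
# near-zero tails and would otherwise concentrate occupancy mass in
# single meaningless cells.
E_SUPPORT_FRAC = 1e-4


@dataclass
class DensityGrid:
    """Occurrence (o), environment (e) and occupancy (z) densities.

    Cell [i, j] covers x-bin i, y-bin j; ``bounds`` is (x0, x1, y0, y1).
    ``z`` is o/e where e > 0 (else 0), normalized to sum 1.
    """

    R: int
    bounds: tuple[float, float, float, float]
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    bandwidths: tuple[float, float, float, float]  # (hx_occ, hy_occ, hx_bg, hy_bg)
    occ_xy: np.ndarray | None = None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, y0, y1 = self.bounds
        xs = x0 + (np.arange(self.R) + 0.5) * (x1 - x0) / self.R
        ys = y0 + (np.arange(self.R) + 0.5) * (y1 - y0) / self.R
        return xs, ys

    def same_geometry(self, other: "DensityGrid") -> bool:
        return self.R == other.R and np.allclose(self.bounds, other.bounds)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.349) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def pooled_bounds(*coord_sets: np.ndarray,
                  margin: float = 0.10) -> tuple[float, float, float, float]:
    """Joint PC1/PC2 min-max of the pooled backgrounds, widened by a margin."""
    allc = np.vstack([np.atleast_2d(c) for c in coord_sets])
    x0, y0 = allc.min(axis=0)
    x1, y1 = allc.max(axis=0)
    mx, my = margin * (x1 - x0), margin * (y1 - y0)
    return (x0 - mx, x1 + mx, y0 - my, y1 + my)


def _kernel_1d(points: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    """Truncated Gaussian kernel matrix (n_points x n_centers)."""
    d = (centers[None, :] - points[:, None]) / h
    K = np.exp(-0.5 * d * d)
    K[np.abs(d) > TRUNC] = 0.0
    return K / (h * np.sqrt(2.0 * np.pi))


def _kde_grid(xy: np.ndarray, xs: np.ndarray, ys: np.ndarray,
              hx: float, hy: float) -> np.ndarray:
    Kx = _kernel_1d(xy[:, 0], xs, hx)
    Ky = _kernel_1d(xy[:, 1], ys, hy)
    return np.einsum("ki,kj->ij", Kx, Ky) / xy.shape[0]


def density_grid(occ_pc: np.ndarray, bg_pc: np.ndarray, R: int = 100,
                 bounds: tuple[float, float, float, float] | None = None
                 ) -> DensityGrid:
    """Build one population's density grid on the PC1-PC2 plane.

    Kernels are product Gaussians truncated at 5 bandwidths per axis, with
    per-axis Silverman bandwidths estimated on the occurrences (for o) and
    the background (for e).  When two populations are compared their grids
    must share ``bounds``; pass the pooled-background bounds explicitly.
    """
    occ = np.atleast_2d(np.asarray(occ_pc, dtype=float))[:, :2]
    bg = np.atleast_2d(np.asarray(bg_pc, dtype=float))[:, :2]
    if occ.shape[0] < 5:
        raise ValueError("need at least 5 occurrences")
    if bounds is None:
        bounds = pooled_bounds(bg)
    x0, x1, y0, y1 = bounds
    if (np.any(occ[:, 0] < x0) or np.any(occ[:, 0] > x1)
            or np.any(occ[:, 1] < y0) or np.any(occ[:, 1] > y1)):
        raise ValueError("occurrence outside the grid bounds")
    hx_o, hy_o = silverman_bandwidth(occ[:, 0]), silverman_bandwidth(occ[:, 1])
    hx_e, hy_e = silverman_bandwidth(bg[:, 0]), silverman_bandwidth(bg[:, 1])
    if min(hx_o, hy_o, hx_e, hy_e) <= 0:
        raise ValueError("zero kernel bandwidth (constant coordinates)")
    xs = x0 + (np.arange(R) + 0.5) * (x1 - x0) / R
    ys = y0 + (np.arange(R) + 0.5) * (y1 - y0) / R
    o = _kde_grid(occ, xs, ys, hx_o, hy_o)
    e = _kde_grid(bg, xs, ys, hx_e, hy_e)
    z = _occupancy(o, e)
    return DensityGrid(R=R, bounds=tuple(bounds), o=o, e=e, z=z,
                       bandwidths=(hx_o, hy_o, hx_e, hy_e), occ_xy=occ)


def _occupancy(o: np.ndarray, e: np.ndarray) -> np.ndarray:
    """z = o/e over the background support, normalized to sum 1."""
    support = e > E_SUPPORT_FRAC * e.max() if e.max() > 0 else e > 0
    z = np.where(support, o / np.where(support, e, 1.0), 0.0)
    total = z.sum()
    if total > 0:
        z = z / total
    return z


def schoener_d(grid1: DensityGrid, grid2: DensityGrid) -> float:
    """Schoener's D = 1 - 0.5 sum |z1 - z2| over shared cells, in [0, 1]."""
    if not grid1.same_geometry(grid2):
        raise ValueError("grids do not share bounds and resolution")
    d = 1.0 - 0.5 * np.abs(grid1.z - grid2.z).sum()
    return float(min(max(d, 0.0), 1.0))


# ----------------------------------------------------------------------
# Randomization tests

def equivalence_test(occ1: np.ndarray, occ2: np.ndarray, bg1: np.ndarray,
                     bg2: np.ndarray, nrep: int = 100, seed: int = 0,
                     R: int = 100) -> float:
    """Niche equivalence: pool the occurrences and re-split at random.

    Each replicate re-assigns the pooled occurrences to two groups of the
    original sizes (backgrounds stay fixed) and recomputes D.  The p-value
    (1 + #{D_null <= D_obs}) / (nrep + 1) is small when the observed niches
    are less equivalent than random splits.
    """
    if nrep < 1:
        raise ValueError("nrep must be >= 1")
    occ1 = np.atleast_2d(np.asarray(occ1, float))[:, :2]
    occ2 = np.atleast_2d(np.asarray(occ2, float))[:, :2]
    bg1 = np.atleast_2d(np.asarray(bg1, float))[:, :2]
    bg2 = np.atleast_2d(np.asarray(bg2, float))[:, :2]
    bounds = pooled_bounds(bg1, bg2, occ1, occ2)
    g1 = density_grid(occ1, bg1, R, bounds)
    g2 = density_grid(occ2, bg2, R, bounds)
    d_obs = schoener_d(g1, g2)
    pooled = np.vstack([occ1, occ2])
    n1 = occ1.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nrep):
        perm = rng.permutation(pooled.shape[0])
        a, b = pooled[perm[:n1]], pooled[perm[n1:]]
        d_null = schoener_d(density_grid(a, bg1, R, bounds),
                            density_grid(b, bg2, R, bounds))
        if d_null <= d_obs + 1e-12:
            count += 1
    return (1 + count) / (nrep + 1)


def _center_of_mass_cell(o: np.ndarray) -> tuple[int, int]:
    total = o.sum()
    ix = np.arange(o.shape[0])
    iy = np.arange(o.shape[1])
    cx = (o.sum(axis=1) * ix).sum() / total
    cy = (o.sum(axis=0) * iy).sum() / total
    return int(round(cx)), int(round(cy))


def _shift_array(a: np.ndarray, dx: int, dy: int) -> np.ndarray | None:
    """Translate with zero fill; None if nonzero mass would leave the grid."""
    nz = np.nonzero(a)
    if nz[0].size == 0:
        return None
    x0, x1 = nz[0].min() + dx, nz[0].max() + dx
    y0, y1 = nz[1].min() + dy, nz[1].max() + dy
    if x0 < 0 or y0 < 0 or x1 >= a.shape[0] or y1 >= a.shape[1]:
        return None
    out = np.zeros_like(a)
    src = a[nz]
    out[nz[0] + dx, nz[1] + dy] = src
    return out


def similarity_test(grid_ref: DensityGrid, occ_shift: np.ndarray,
                    bg_shift: np.ndarray, nrep: int = 1000, seed: int = 0,
                    grid_shift: DensityGrid | None = None) -> float:
    """Niche similarity (background) test, one direction.

    The shifted population's observed occurrence density is translated to a
    uniformly random center within its own background support (cells with
    positive e); placements whose density would leave the grid are
    resampled (no wrapping).  Each replicate recomputes occupancy against
    the unmoved background and D against ``grid_ref``.  The p-value
    (1 + #{D_null >= D_obs}) / (nrep + 1) is small when the observed
    overlap is higher than expected by chance.
    """
    if nrep < 1:
        raise ValueError("nrep must be >= 1")
    if grid_shift is None:
        grid_shift = density_grid(np.atleast_2d(occ_shift)[:, :2],
                                  np.atleast_2d(bg_shift)[:, :2],
                                  grid_ref.R, grid_ref.bounds)
    if not grid_ref.same_geometry(grid_shift):
        raise ValueError("grids do not share bounds and resolution")
    d_obs = schoener_d(grid_ref, grid_shift)
    sup = np.nonzero(grid_shift.e > 0)
    if sup[0].size == 0:
        raise ValueError("shifted population has empty background support")
    cx, cy = _center_of_mass_cell(grid_shift.o)
    rng = np.random.default_rng(seed)
    count = done = attempts = 0
    max_attempts = 100 * nrep
    while done < nrep:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"no valid random placement after {max_attempts} attempts")
        attempts += 1
        k = rng.integers(sup[0].size)
        o_null = _shift_array(grid_shift.o, int(sup[0][k]) - cx,
                              int(sup[1][k]) - cy)
        if o_null is None:
            continue
        z_null = _occupancy(o_null, grid_shift.e)
        d_null = 1.0 - 0.5 * np.abs(grid_ref.z - z_null).sum()
        if d_null >= d_obs - 1e-12:
            count += 1
        done += 1
    return (1 + count) / (nrep + 1)


# ----------------------------------------------------------------------
# Niche dynamics

def niche_dynamics(grid1: DensityGrid, grid2: DensityGrid,
                   env_quantile: float = 0.0) -> tuple[float, float, float]:
    """Expansion, stability and unfilling of niche 2 against reference 1.

    Restricted to the analogous environment (cells where both backgrounds'
    e exceed their ``env_quantile`` density quantile; quantile 0 means
    simply e > 0 for both):

    * stability S  = share of z2 mass lying where z1 > 0,
    * expansion E  = 1 - S (z2 mass in conditions novel to niche 1),
    * unfilling U  = share of z1 mass lying where z2 = 0.
    """
    if not grid1.same_geometry(grid2):
        raise ValueError("grids do not share bounds and resolution")
    if not (0.0 <= env_quantile < 1.0):
        raise ValueError("env_quantile must lie in [0, 1)")
    thr1 = thr2 = 0.0
    if env_quantile > 0:
        thr1 = np.quantile(grid1.e[grid1.e > 0], env_quantile)
        thr2 = np.quantile(grid2.e[grid2.e > 0], env_quantile)
    analogous = (grid1.e > thr1) & (grid2.e > thr2)
    if not analogous.any():
        raise ValueError("empty analogous environment")
    z1, z2 = grid1.z, grid2.z
    z2_total = z2[analogous].sum()
    z1_total = z1[analogous].sum()
    if z2_total <= 0 or z1_total <= 0:
        raise ValueError("a population has no occupancy in the analogous "
                         "environment")
    S = z2[analogous & (z1 > 0)].sum() / z2_total
    E = 1.0 - S
    U = z1[analogous & (z2 == 0)].sum() / z1_total
    return float(E), float(S), float(U)


def write_density_grid(grid: DensityGrid, path) -> None:
    """Write o, e and z as one plain-text file of stacked matrices."""
    with open(path, "w") as fh:
        fh.write(f"# R {grid.R}\n")
        fh.write("# bounds " + " ".join(f"{b:.12g}" for b in grid.bounds) + "\n")
        fh.write("# bandwidths "
                 + " ".join(f"{b:.12g}" for b in grid.bandwidths) + "\n")
        for name, arr in (("o", grid.o), ("e", grid.e), ("z", grid.z)):
            fh.write(f"# {name}\n")
            np.savetxt(fh, arr, fmt="%.12g")


def dynamics_category(value: float) -> str:
    """Categorize a dynamics proportion: >0.7 high, 0.5-0.7 partial, <0.5 low."""
    if not (0.0 <= value <= 1.0):
        raise ValueError("dynamics index must lie in [0, 1]")
    if value > 0.7:
        return "high"
    if value >= 0.5:
        return "partial"
    return "low"


@dataclass
class OverlapResult:
    """Full niche-comparison result for one population pair."""

    D: float
    equivalence_p: float
    similarity_p_12: float
    similarity_p_21: float
    expansion: float
    stability: float
    unfilling: float

    @property
    def similarity_p(self) -> float:
        """Conservative per-pair similarity p: the worse direction."""
        return max(self.similarity_p_12, self.similarity_p_21)

    def categories(self) -> dict[str, str]:
        return {
            "expansion": dynamics_category(self.expansion),
            "stability": dynamics_category(self.stability),
            "unfilling": dynamics_category(self.unfilling),
        }


def compare_niches(occ1: np.ndarray, occ2: np.ndarray, bg1: np.ndarray,
                   bg2: np.ndarray, R: int = 100, nrep_similarity: int = 1000,
                   nrep_equivalence: int = 100, env_quantile: float = 0.0,
                   seed: int = 0) -> OverlapResult:
    """One-call niche comparison of two populations on the PC1-PC2 plane."""
    occ1 = np.atleast_2d(np.asarray(occ1, float))[:, :2]
    occ2 = np.atleast_2d(np.asarray(occ2, float))[:, :2]
    bg1 = np.atleast_2d(np.asarray(bg1, float))[:, :2]
    bg2 = np.atleast_2d(np.asarray(bg2, float))[:, :2]
    bounds = pooled_bounds(bg1, bg2, occ1, occ2)
    g1 = density_grid(occ1, bg1, R, bounds)
    g2 = density_grid(occ2, bg2, R, bounds)
    d = schoener_d(g1, g2)
    eq_p = equivalence_test(occ1, occ2, bg1, bg2, nrep_equivalence,
                            stable_seed(seed, "equivalence"), R)
    sim12 = similarity_test(g1, occ2, bg2, nrep_similarity,
                            stable_seed(seed, "similarity", "12"),
                            grid_shift=g2)
    sim21 = similarity_test(g2, occ1, bg1, nrep_similarity,
                            stable_seed(seed, "similarity", "21"),
                            grid_shift=g1)
    E, S, U = niche_dynamics(g1, g2, env_quantile)
    return OverlapResult(D=d, equivalence_p=eq_p, similarity_p_12=sim12,
                         similarity_p_21=sim21, expansion=E, stability=S,
                         unfilling=U)
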