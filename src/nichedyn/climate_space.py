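"""Layer standardization and correlation-matrix PCA of the climate space.

The PCA fitted here defines both the predictor space of the niche models
and the plane on which niche overlap is measured.  It is a correlation-PCA:
the eigendecomposition of the inter-layer correlation matrix over all valid
cells (both regions pooled — the entire environmental space of the study),
with axis scores re-standardized to zero mean and unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import ClimateStack

__all__ = ["EnvSpace", "standardize", "standardize_pooled", "fit_pca",
           "project"]

_EIG_FLOOR = 1e-12  # below this an axis is treated as numerically degenerate


@dataclass
class EnvSpace:
    """A fitted correlation-PCA basis.

    ``loadings`` is variables x axes (columns are unit eigenvectors, ordered
    by non-increasing eigenvalue, each oriented so its largest-magnitude
    loading is positive).  ``center``/``scale`` are the per-variable mean and
    sample (n-1) standard deviation used before projection; ``axis_scale``
    re-standardizes the scores to unit variance.  ``retained`` is the number
    of leading axes kept (always >= 2).
    """

    names: list[str]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    retained: int
    cumvar: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    axis_scale: np.ndarray

    def __post_init__(self):
        if self.retained < 2:
            raise ValueError("at least 2 axes must be retained")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def standardize(stack: ClimateStack) -> ClimateStack:
    """Z-score every layer over its valid cells (sample sd, ddof=1).

    Raises on a zero-variance layer, naming it.
    """
    out = stack.values.copy()
    for i, name in enumerate(stack.names):
        vals = stack.values[i, stack.mask]
        sd = vals.std(ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            raise ValueError(f"layer {name!r} has zero variance")
        out[i] = (stack.values[i] - vals.mean()) / sd
    return ClimateStack(list(stack.names), out, stack.mask.copy(),
                        stack.transform, stack.crs)


def standardize_pooled(stacks: Sequence[ClimateStack]) -> list[ClimateStack]:
    """Z-score layers with mean/sd pooled over all stacks' valid cells.

    This is the multi-region analogue of :func:`standardize`: the whole
    study area shares one center and scale, so between-region regime
    offsets are preserved in the standardized values.
    """
    names, X = _pooled_table(stacks)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        bad = names[int(np.argmin(scale))]
        raise ValueError(f"layer {bad!r} has zero variance")
    out = []
    for s in stacks:
        vals = (s.values - center[:, None, None]) / scale[:, None, None]
        out.append(ClimateStack(list(s.names), vals, s.mask.copy(),
                                s.transform, s.crs))
    return out


def _pooled_table(stacks: Sequence[ClimateStack]) -> tuple[list[str], np.ndarray]:
    names = list(stacks[0].names)
    for s in stacks[1:]:
        if list(s.names) != names:
            raise ValueError("stacks carry different layer sets")
    return names, np.vstack([s.valid_table() for s in stacks])


def fit_pca(stacks: ClimateStack | Sequence[ClimateStack],
            cumvar_threshold: float = 0.97) -> EnvSpace:
    """Correlation-PCA over the pooled valid cells of one or more stacks.

    Retains the smallest number of leading axes whose cumulative variance
    fraction reaches ``cumvar_threshold`` (never fewer than 2, since the
    niche-overlap plane is 2-D).  Being a correlation PCA, the result is
    identical whether the stacks were standardized first or not.
    """
    if not (0.0 < cumvar_threshold <= 1.0):
        raise ValueError("cumvar_threshold must lie in (0, 1]")
    if isinstance(stacks, ClimateStack):
        stacks = [stacks]
    names, X = _pooled_table(stacks)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 layers")
    if n <= p:
        raise ValueError("need more valid cells than layers")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        bad = names[int(np.argmin(scale))]
        raise ValueError(f"layer {bad!r} has zero variance")
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading of each axis is positive
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    cumvar = np.cumsum(eigval) / eigval.sum()
    retained = int(np.searchsorted(cumvar, cumvar_threshold - 1e-12) + 1)
    retained = max(retained, 2)
    # standardized variables projected on unit eigenvectors have variance
    # equal to the eigenvalue; dividing by sqrt(eigenvalue) gives unit-sd
    # scores.  Degenerate axes keep scale 1 (their scores are ~0 anyway).
    axis_scale = np.where(eigval > _EIG_FLOOR, np.sqrt(eigval), 1.0)
    return EnvSpace(names=names, loadings=eigvec, eigenvalues=eigval,
                    retained=retained, cumvar=cumvar, center=center,
                    scale=scale, axis_scale=axis_scale)


def project(values: np.ndarray, space: EnvSpace,
            n_axes: int | None = None) -> np.ndarray:
    """Project climate-variable rows onto the standardized PCA axes.

    ``values`` is (n_points, n_vars) in the original variable order used at
    fit time; returns (n_points, n_axes) scores (default: the retained
    axes).  A cell used in fitting reproduces its stored score; the
    per-variable mean point maps to the origin.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if X.shape[1] != len(space.names):
        raise ValueError(
            f"expected {len(space.names)} variables, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing variable value in projection input")
    if n_axes is None:
        n_axes = space.retained
    Z = (X - space.center) / space.scale
    scores = Z @ space.loadings[:, :n_axes]
    return scores / space.axis_scale[:n_axes]


def write_score_rasters(stack: ClimateStack, space: EnvSpace, out_dir,
                        prefix: str = "") -> list:
    """Write one ESRI ASCII grid per retained axis of a stack's scores."""
    from .raster import write_ascii_grid

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = project(stack.valid_table(), space)
    paths = []
    for j in range(space.retained):
        grid = np.full(stack.shape, 0.0)
        grid[stack.mask] = scores[:, j]
        p = out_dir / f"{prefix}PC{j + 1}.asc"
        write_ascii_grid(p, grid, stack.mask, stack.transform)
        paths.append(p)
    return paths


# ----------------------------------------------------------------------
# plain-text serialization

def write_env_space(space: EnvSpace, path) -> None:
    """Serialize loadings/eigenvalues/centering as one plain-text table."""
    df = pd.DataFrame(space.loadings, index=space.names,
                      columns=[f"PC{j + 1}" for j in range(space.loadings.shape[1])])
    df.insert(0, "center", space.center)
    df.insert(1, "scale", space.scale)
    with open(path, "w") as fh:
        fh.write(f"# retained {space.retained}\n")
        fh.write("# eigenvalues " + " ".join(f"{v:.12g}" for v in space.eigenvalues) + "\n")
        fh.write("# axis_scale " + " ".join(f"{v:.12g}" for v in space.axis_scale) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.12g")


def read_env_space(path) -> EnvSpace:
    lines = Path(path).read_text().splitlines()
    retained = int(lines[0].split()[-1])
    eigval = np.array([float(v) for v in lines[1].split()[2:]])
    axis_scale = np.array([float(v) for v in lines[2].split()[2:]])
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(lines[3:])), sep="\t", index_col=0)
    center = df.pop("center").to_numpy()
    scale = df.pop("scale").to_numpy()
    return EnvSpace(names=list(df.index), loadings=df.to_numpy(),
                    eigenvalues=eigval, retained=retained,
                    cumvar=np.cumsum(eigval) / eigval.sum(),
                    center=center, scale=scale, axis_scale=axis_scale)
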