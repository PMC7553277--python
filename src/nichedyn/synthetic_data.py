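"""Virtual climates, virtual species and presence-only sampling.

The generator emulates the statistical structure the downstream analysis
assumes: two spatially disjoint regions under different multivariate climate
regimes (separated by a dry corridor, so their extents never touch), a
species whose suitability is a smooth unimodal (Gaussian product) function
of climate, and presence-only samples drawn proportionally to suitability.
A controllable centroid shift applied to the second region's population
turns true niche divergence into a dial the tests can sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import ClimateStack, GeoTransform

__all__ = [
    "RegionSpec", "VirtualSpecies", "generate_climate", "suitability",
    "sample_occurrences", "default_regions", "default_species",
    "write_occurrences", "read_occurrences",
]

# Weight of the shared latent gradient mixed into every layer, so that the
# inter-layer correlation matrix is non-trivial and the correlation-PCA step
# downstream has structure to find.
_SHARED_WEIGHT = 0.6


@dataclass(frozen=True)
class RegionSpec:
    """One study region: extent, resolution and climate regime.

    ``extent`` is (lon_min, lon_max, lat_min, lat_max) in degrees;
    ``layer_means``/``layer_sds`` give the per-variable regime (climate
    units); ``spatial_smoothing`` is the moving-average correlation length
    in cells (0 means i.i.d. noise).
    """

    name: str
    extent: tuple[float, float, float, float]
    resolution: float
    layer_means: tuple[float, ...]
    layer_sds: tuple[float, ...]
    spatial_smoothing: int = 3

    def __post_init__(self):
        lon0, lon1, lat0, lat1 = self.extent
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError("extent is degenerate")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if any(s <= 0 for s in self.layer_sds):
            raise ValueError("layer_sds must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        lon0, lon1, lat0, lat1 = self.extent
        ncols = int(round((lon1 - lon0) / self.resolution))
        nrows = int(round((lat1 - lat0) / self.resolution))
        return nrows, ncols

    def transform(self) -> GeoTransform:
        lon0, _, _, lat1 = self.extent
        return GeoTransform(west=lon0, north=lat1, cellsize=self.resolution)

    def overlaps(self, other: "RegionSpec") -> bool:
        a, b = self.extent, other.extent
        return not (a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2])


@dataclass(frozen=True)
class VirtualSpecies:
    """A virtual species with a Gaussian (product-kernel) climatic niche.

    ``niche_centroid`` is the per-variable optimum, ``niche_breadth`` the
    per-variable tolerance (both in climate units).  ``shift`` is the
    centroid displacement applied to the second region's population; with
    shift 0 both populations share one true niche.
    """

    name: str
    niche_centroid: tuple[float, ...]
    niche_breadth: tuple[float, ...]
    shift: tuple[float, ...] = ()

    def __post_init__(self):
        if any(b <= 0 for b in self.niche_breadth):
            raise ValueError("niche_breadth must be strictly positive")
        if len(self.niche_breadth) != len(self.niche_centroid):
            raise ValueError("centroid and breadth lengths differ")
        if self.shift and len(self.shift) != len(self.niche_centroid):
            raise ValueError("shift length must match centroid")

    def centroid_for(self, shifted: bool) -> np.ndarray:
        c = np.asarray(self.niche_centroid, dtype=float)
        if shifted and self.shift:
            c = c + np.asarray(self.shift, dtype=float)
        return c

    def with_shift_breadths(self, delta: float) -> "VirtualSpecies":
        """Return a copy whose shift is ``delta`` niche breadths per variable."""
        shift = tuple(delta * b for b in self.niche_breadth)
        return VirtualSpecies(self.name, self.niche_centroid,
                              self.niche_breadth, shift)


def _smooth_field(field: np.ndarray, length: int) -> np.ndarray:
    """Moving-average smoothing; re-standardized to unit sample variance."""
    if length > 0:
        field = ndimage.uniform_filter(field, size=2 * length + 1,
                                       mode="nearest")
    field = field - field.mean()
    sd = field.std(ddof=1)
    if sd > 0:
        field = field / sd
    return field


def generate_climate(region: RegionSpec, n_layers: int, seed: int) -> ClimateStack:
    """Generate spatially autocorrelated, inter-correlated climate layers.

    Every layer mixes a shared latent gradient with its own smoothed noise,
    then is rescaled so its sample mean and standard deviation over the grid
    match the regime requested by ``region`` exactly.  Deterministic for a
    given seed.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if len(region.layer_means) != n_layers or len(region.layer_sds) != n_layers:
        raise ValueError("region regime must provide one mean/sd per layer")
    nrows, ncols = region.shape
    if nrows * ncols < 4:
        raise ValueError("degenerate extent: fewer than 4 cells")
    rng = np.random.default_rng(seed)
    latent = _smooth_field(rng.standard_normal((nrows, ncols)),
                           region.spatial_smoothing)
    layers = np.empty((n_layers, nrows, ncols))
    w = _SHARED_WEIGHT
    for i in range(n_layers):
        own = _smooth_field(rng.standard_normal((nrows, ncols)),
                            region.spatial_smoothing)
        raw = np.sqrt(w) * latent + np.sqrt(1.0 - w) * own
        raw = (raw - raw.mean()) / raw.std(ddof=1)
        layers[i] = region.layer_means[i] + region.layer_sds[i] * raw
    names = [f"bio{i + 1}" for i in range(n_layers)]
    mask = np.ones((nrows, ncols), dtype=bool)
    return ClimateStack(names, layers, mask, region.transform())


def suitability(species: VirtualSpecies, climate_values: np.ndarray,
                shifted: bool = False) -> np.ndarray:
    """Gaussian-niche suitability in [0, 1].

    ``climate_values`` is (..., n_vars); the result drops the last axis.
    Equals 1 exactly at the (possibly shifted) centroid and decays as the
    product over variables of exp(-(x - mu)^2 / (2 sigma^2)).
    """
    x = np.asarray(climate_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("climate values contain missing/non-finite entries")
    mu = species.centroid_for(shifted)
    sigma = np.asarray(species.niche_breadth, dtype=float)
    if x.shape[-1] != mu.size:
        raise ValueError("climate values do not match the species' variables")
    z = (x - mu) / sigma
    return np.exp(-0.5 * np.sum(z * z, axis=-1))


def sample_occurrences(species: VirtualSpecies, climate: ClimateStack,
                       region: RegionSpec, n: int, seed: int,
                       shifted: bool = False) -> pd.DataFrame:
    """Presence-only sample: cells drawn without replacement w.p. ∝ suitability.

    One record per drawn cell, placed at the cell center.  Returns a
    DataFrame with columns ``species, lon, lat, region``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = climate.valid_rowcol()
    env = climate.valid_table()
    s = suitability(species, env, shifted=shifted)
    positive = s > 0
    n_pos = int(positive.sum())
    if n_pos < n:
        raise ValueError(
            f"only {n_pos} cells with positive suitability; {n} requested")
    rng = np.random.default_rng(seed)
    idx = np.nonzero(positive)[0]
    p = s[idx] / s[idx].sum()
    chosen = rng.choice(idx, size=n, replace=False, p=p)
    lon, lat = climate.transform.cell_center(rows[chosen], cols[chosen])
    return pd.DataFrame({
        "species": species.name,
        "lon": np.asarray(lon, dtype=float),
        "lat": np.asarray(lat, dtype=float),
        "region": region.name,
    })


# ----------------------------------------------------------------------
# Default study conditions

def default_regions(n_layers: int = 5) -> tuple[RegionSpec, RegionSpec]:
    """The two default study regions.

    Disjoint extents separated by a dry gap; the second regime has more
    climatic variation, lower temperature-like values and less
    precipitation-like volume than the first, while overlapping it enough
    that an unshifted species can occupy both.
    """
    base_means_a = [26.0, 2.0, 2500.0, 60.0, 180.0]
    base_sds_a = [2.0, 1.0, 400.0, 30.0, 40.0]
    base_means_b = [25.6, 2.2, 2420.0, 66.0, 172.0]
    base_sds_b = [2.6, 1.3, 520.0, 39.0, 52.0]

    def cycle(vals, k):
        return tuple(vals[i % len(vals)] for i in range(k))

    amazonia = RegionSpec(
        name="AM", extent=(-75.0, -50.0, -15.0, 5.0), resolution=0.5,
        layer_means=cycle(base_means_a, n_layers),
        layer_sds=cycle(base_sds_a, n_layers), spatial_smoothing=3)
    atlantic = RegionSpec(
        name="MA", extent=(-48.0, -35.0, -30.0, -8.0), resolution=0.5,
        layer_means=cycle(base_means_b, n_layers),
        layer_sds=cycle(base_sds_b, n_layers), spatial_smoothing=3)
    return amazonia, atlantic


def default_species(name: str = "virtualis", n_layers: int = 5,
                    shift_breadths: float = 0.0) -> VirtualSpecies:
    """A default virtual species centered between the two default regimes.

    The breadth is comparable to the regional climate spread so both regions
    contain suitable cells when the shift is zero.
    """
    reg_a, reg_b = default_regions(n_layers)
    mu_a = np.asarray(reg_a.layer_means)
    mu_b = np.asarray(reg_b.layer_means)
    sd = np.maximum(np.asarray(reg_a.layer_sds), np.asarray(reg_b.layer_sds))
    centroid = tuple(0.5 * (mu_a + mu_b))
    breadth = tuple(0.4 * sd)
    sp = VirtualSpecies(name, centroid, breadth)
    if shift_breadths:
        sp = sp.with_shift_breadths(shift_breadths)
    return sp


# ----------------------------------------------------------------------
# Occurrence table I/O

def write_occurrences(occ: pd.DataFrame, path) -> None:
    occ.to_csv(path, index=False, columns=["species", "lon", "lat", "region"])


def read_occurrences(path) -> pd.DataFrame:
    occ = pd.read_csv(path)
    missing = {"species", "lon", "lat", "region"} - set(occ.columns)
    if missing:
        raise ValueError(f"occurrence file lacks columns: {sorted(missing)}")
    return occ
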