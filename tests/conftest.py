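"""Shared fixtures: small synthetic regions, climates and samples."""

import numpy as np
import pytest

from nichedyn._seeds import stable_seed
from nichedyn.climate_space import fit_pca, project, standardize_pooled
from nichedyn.raster import ClimateStack, GeoTransform
from nichedyn.synthetic_data import (default_regions, default_species,
                                     generate_climate, sample_occurrences)


def make_stack(values, mask=None, west=0.0, north=None, cellsize=1.0,
               names=None):
    """Build a ClimateStack from a (n_layers, nrows, ncols) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    n_layers, nrows, ncols = values.shape
    if mask is None:
        mask = np.ones((nrows, ncols), dtype=bool)
    if north is None:
        north = float(nrows) * cellsize
    if names is None:
        names = [f"v{i}" for i in range(n_layers)]
    return ClimateStack(names, values, mask,
                        GeoTransform(west=west, north=north, cellsize=cellsize))


@pytest.fixture(scope="session")
def tiny_regions():
    """The default study regions at default resolution."""
    return default_regions()


@pytest.fixture(scope="session")
def study_pair(tiny_regions):
    """One shift-0 synthetic study pair with pooled PCA, reused across tests."""
    reg_a, reg_b = tiny_regions
    seed = 20240
    stack_a = generate_climate(reg_a, 5, stable_seed(seed, "ca"))
    stack_b = generate_climate(reg_b, 5, stable_seed(seed, "cb"))
    sp = default_species()
    occ_a = sample_occurrences(sp, stack_a, reg_a, 200, stable_seed(seed, "oa"))
    occ_b = sample_occurrences(sp, stack_b, reg_b, 100, stable_seed(seed, "ob"),
                               shifted=True)
    std_a, std_b = standardize_pooled([stack_a, stack_b])
    space = fit_pca([std_a, std_b])
    return {
        "regions": (reg_a, reg_b),
        "species": sp,
        "stacks": {reg_a.name: std_a, reg_b.name: std_b},
        "raw_stacks": {reg_a.name: stack_a, reg_b.name: stack_b},
        "occ": {reg_a.name: occ_a, reg_b.name: occ_b},
        "space": space,
        "seed": seed,
    }


def synthetic_study(shift_breadths, seed, n_a=200, n_b=100):
    """Full synthetic pair: stacks, pooled PCA, occurrence/background PCs."""
    from nichedyn.niche_overlap import pooled_bounds

    reg_a, reg_b = default_regions()
    stack_a = generate_climate(reg_a, 5, stable_seed(seed, "ca"))
    stack_b = generate_climate(reg_b, 5, stable_seed(seed, "cb"))
    sp = default_species(shift_breadths=shift_breadths)
    occ_a = sample_occurrences(sp, stack_a, reg_a, n_a, stable_seed(seed, "oa"))
    occ_b = sample_occurrences(sp, stack_b, reg_b, n_b, stable_seed(seed, "ob"),
                               shifted=True)
    std_a, std_b = standardize_pooled([stack_a, stack_b])
    space = fit_pca([std_a, std_b])
    bg_a = project(std_a.valid_table(), space, n_axes=2)
    bg_b = project(std_b.valid_table(), space, n_axes=2)
    pc_a = project(std_a.values_at(occ_a["lon"].to_numpy(),
                                   occ_a["lat"].to_numpy()), space, n_axes=2)
    pc_b = project(std_b.values_at(occ_b["lon"].to_numpy(),
                                   occ_b["lat"].to_numpy()), space, n_axes=2)
    return {
        "occ": {reg_a.name: occ_a, reg_b.name: occ_b},
        "stacks": {reg_a.name: std_a, reg_b.name: std_b},
        "space": space,
        "pc": (pc_a, pc_b),
        "bg": (bg_a, bg_b),
        "bounds": pooled_bounds(bg_a, bg_b, pc_a, pc_b),
        "labels": (reg_a.name, reg_b.name),
    }


def synthetic_pair_d(shift_breadths, seed, n_a=200, n_b=100, R=100):
    """Schoener's D of one synthetic pair on PCA-env grids."""
    from nichedyn.niche_overlap import density_grid, schoener_d

    s = synthetic_study(shift_breadths, seed, n_a, n_b)
    g1 = density_grid(s["pc"][0], s["bg"][0], R, s["bounds"])
    g2 = density_grid(s["pc"][1], s["bg"][1], R, s["bounds"])
    return schoener_d(g1, g2)


def env_coords(study, region_label, n_axes=2):
    """Occurrence and background PC coordinates for one region."""
    stack = study["stacks"][region_label]
    occ = study["occ"][region_label]
    pc = project(stack.values_at(occ["lon"].to_numpy(),
                                 occ["lat"].to_numpy()),
                 study["space"], n_axes=n_axes)
    bg = project(stack.valid_table(), study["space"], n_axes=n_axes)
    return pc, bg
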