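"""Study orchestration: data hygiene, configuration, end-to-end runs.

A study takes occurrence tables and climate stacks for two regions (real
inputs or the synthetic generator), applies cell-level deduplication and
the minimum-records filter, fits the pooled correlation-PCA, runs the
reciprocal niche-model transfer and the PCA-env niche comparison per
species, and emits an AUC table, an overlap table, a machine-readable
summary and a run log.  All stage seeds are derived from one master seed
by stable hashing, so a fixed seed reproduces every emitted number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessible_area as aa
from ._seeds import stable_seed
from .climate_space import fit_pca, project, standardize_pooled
from .enm import EnmConfig, auc_category, reciprocal_run
from .niche_overlap import compare_niches
from .raster import ClimateStack
from .synthetic_data import (RegionSpec, VirtualSpecies, default_regions,
                             default_species, generate_climate,
                             sample_occurrences)

logger = logging.getLogger("nichedyn")

__all__ = ["StudyConfig", "SpeciesSim", "StudyResult", "dedupe_to_cells",
           "filter_min_records", "run_study"]


@dataclass
class SpeciesSim:
    """Simulation spec for one species: its niche and per-region sample sizes."""

    species: VirtualSpecies
    n_region_a: int = 200
    n_region_b: int = 100


@dataclass
class StudyConfig:
    """All study constants in one place.

    Defaults follow the analysis conventions this pipeline implements: a
    0.97 cumulative-variance cut for retained PCA axes, a 100 x 100
    overlap grid, a 1-degree accessible-area buffer, a 10-unique-records
    minimum per region, and 1,000 similarity-test replicates.
    """

    regions: tuple[RegionSpec, RegionSpec] = field(default_factory=default_regions)
    species: list[SpeciesSim] = field(default_factory=list)
    n_layers: int = 5
    cumvar_threshold: float = 0.97
    grid_R: int = 100
    buffer_deg: float = 1.0
    min_records: int = 10
    nrep_similarity: int = 1000
    nrep_equivalence: int = 100
    env_quantile: float = 0.0
    seed: int = 0
    algorithms: tuple[str, ...] = ("GLM", "RDF", "SVM", "GAU")

    def __post_init__(self):
        if self.regions[0].overlaps(self.regions[1]):
            raise ValueError("study regions must have disjoint extents")
        if not (0 < self.cumvar_threshold <= 1):
            raise ValueError("cumvar_threshold outside (0, 1]")
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if not self.species:
            self.species = [SpeciesSim(default_species(n_layers=self.n_layers))]

    @property
    def labels(self) -> tuple[str, str]:
        return self.regions[0].name, self.regions[1].name

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "regions" in raw:
            kwargs["regions"] = tuple(
                RegionSpec(name=r["name"], extent=tuple(r["extent"]),
                           resolution=r["resolution"],
                           layer_means=tuple(r["layer_means"]),
                           layer_sds=tuple(r["layer_sds"]),
                           spatial_smoothing=r.get("spatial_smoothing", 3))
                for r in raw["regions"])
        if "species" in raw:
            sims = []
            for s in raw["species"]:
                sp = default_species(s.get("name", "virtualis"),
                                     n_layers=raw.get("n_layers", 5),
                                     shift_breadths=s.get("shift_breadths", 0.0))
                sims.append(SpeciesSim(sp, s.get("n_region_a", 200),
                                       s.get("n_region_b", 100)))
            kwargs["species"] = sims
        for key in ("n_layers", "cumvar_threshold", "grid_R", "buffer_deg",
                    "min_records", "nrep_similarity", "nrep_equivalence",
                    "env_quantile", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "algorithms" in raw:
            kwargs["algorithms"] = tuple(raw["algorithms"])
        return cls(**kwargs)


# ----------------------------------------------------------------------
# Data hygiene

def dedupe_to_cells(occurrences: pd.DataFrame,
                    stack: ClimateStack) -> pd.DataFrame:
    """Keep at most one record per raster cell per species per region.

    The retained record is the first in input order; records outside the
    stack extent are dropped with a logged warning.
    """
    occ = occurrences.reset_index(drop=True)
    row, col = stack.transform.rowcol(occ["lon"].to_numpy(),
                                      occ["lat"].to_numpy())
    nrows, ncols = stack.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d occurrence record(s) outside the raster extent "
                       "dropped", n_out)
    occ = occ[inside].assign(_row=row[inside], _col=col[inside])
    occ = occ.drop_duplicates(subset=["species", "region", "_row", "_col"],
                              keep="first")
    return occ.drop(columns=["_row", "_col"]).reset_index(drop=True)


def filter_min_records(occurrences: pd.DataFrame,
                       min_records: int = 10) -> list[str]:
    """Species with at least ``min_records`` unique records in BOTH regions."""
    counts = occurrences.groupby(["species", "region"]).size().unstack(fill_value=0)
    n_regions = counts.shape[1]
    keep = counts[(counts >= min_records).sum(axis=1) == n_regions].index
    kept = sorted(keep)
    if not kept:
        logger.warning("no species passes the %d-records-per-region filter",
                       min_records)
    return kept


# ----------------------------------------------------------------------
# Study runner

@dataclass
class StudyResult:
    auc_table: pd.DataFrame
    overlap_table: pd.DataFrame
    summary: dict
    log: list[str]
    env_space: object = None


def _auc_columns(algorithms, labels):
    cols = []
    for alg in ("ENS",) + tuple(algorithms):
        for lab in labels:
            cols.append(f"{alg}_{lab}")
    return cols


def run_study(config: StudyConfig, out_dir: str | Path | None = None,
              occurrences: pd.DataFrame | None = None,
              stacks: dict[str, ClimateStack] | None = None,
              write_plots: bool = True) -> StudyResult:
    """Run the full study; simulate inputs unless both are supplied.

    Per-species failures are logged and reported as NA rows; the study
    continues for the remaining species.
    """
    lab_a, lab_b = config.labels
    log: list[str] = [f"master seed {config.seed}"]

    if stacks is None:
        stacks = {}
        for region in config.regions:
            s = stable_seed(config.seed, "climate", region.name)
            stacks[region.name] = generate_climate(region, config.n_layers, s)
            log.append(f"climate {region.name}: seed {s}")
    if occurrences is None:
        frames = []
        for sim in config.species:
            for region, n, shifted in ((config.regions[0], sim.n_region_a, False),
                                       (config.regions[1], sim.n_region_b, True)):
                s = stable_seed(config.seed, "sample", sim.species.name,
                                region.name)
                frames.append(sample_occurrences(
                    sim.species, stacks[region.name], region, n, s,
                    shifted=shifted))
                log.append(f"sample {sim.species.name}/{region.name}: "
                           f"n={n} seed={s} shifted={shifted}")
        occurrences = pd.concat(frames, ignore_index=True)

    occurrences = pd.concat(
        [dedupe_to_cells(occurrences[occurrences["region"] == lab], stacks[lab])
         for lab in (lab_a, lab_b)], ignore_index=True)
    kept = filter_min_records(occurrences, config.min_records)
    all_species = sorted(occurrences["species"].unique())
    for sp in all_species:
        if sp not in kept:
            log.append(f"excluded {sp}: fewer than {config.min_records} "
                       "unique records in a region")

    std_a, std_b = standardize_pooled([stacks[lab_a], stacks[lab_b]])
    std_stacks = {lab_a: std_a, lab_b: std_b}
    space = fit_pca([std_a, std_b], config.cumvar_threshold)
    log.append(f"PCA retained {space.retained} axes "
               f"(cumvar {space.cumvar[space.retained - 1]:.4f})")

    auc_cols = _auc_columns(config.algorithms, (lab_a, lab_b))
    auc_rows, overlap_rows = [], []
    panels, enm_results = {}, {}
    enm_cfg = EnmConfig(algorithms=tuple(config.algorithms),
                        buffer_deg=config.buffer_deg)
    for sp in kept:
        occ_sp = occurrences[occurrences["species"] == sp]
        occ_a = occ_sp[occ_sp["region"] == lab_a].reset_index(drop=True)
        occ_b = occ_sp[occ_sp["region"] == lab_b].reset_index(drop=True)
        auc_row = {"species": sp, **{c: np.nan for c in auc_cols}}
        ov_row = {"species": sp, "D": np.nan, "equivalence": np.nan,
                  "similarity": np.nan, "expansion": np.nan,
                  "stability": np.nan, "unfilling": np.nan,
                  "expansion_cat": "NA", "stability_cat": "NA",
                  "unfilling_cat": "NA"}
        try:
            enm_seed = stable_seed(config.seed, "enm", sp)
            res_ab, res_ba = reciprocal_run(occ_a, occ_b, std_stacks, space,
                                            enm_cfg, enm_seed)
            enm_results[sp] = (res_ab, res_ba)
            for res, lab in ((res_ab, lab_a), (res_ba, lab_b)):
                auc_row[f"ENS_{lab}"] = res.ensemble_auc
                for alg, v in res.per_algorithm_auc.items():
                    auc_row[f"{alg}_{lab}"] = v
            log.append(f"enm {sp}: seed {enm_seed} "
                       f"ENS_{lab_a}={res_ab.ensemble_auc:.3f} "
                       f"ENS_{lab_b}={res_ba.ensemble_auc:.3f}")
        except Exception as exc:  # per-species failure: NA + log, keep going
            log.append(f"enm {sp} FAILED: {exc}")
        try:
            bgs, occ_pc = {}, {}
            for lab, occ_r in ((lab_a, occ_a), (lab_b, occ_b)):
                area = aa.build_accessible_area(
                    occ_r[["lon", "lat"]].to_numpy(), config.buffer_deg)
                masked = aa.mask(std_stacks[lab], area)
                bgs[lab] = project(masked.valid_table(), space, n_axes=2)
                occ_pc[lab] = project(
                    masked.values_at(occ_r["lon"].to_numpy(),
                                     occ_r["lat"].to_numpy()), space, n_axes=2)
            ov_seed = stable_seed(config.seed, "overlap", sp)
            res = compare_niches(occ_pc[lab_a], occ_pc[lab_b], bgs[lab_a],
                                 bgs[lab_b], R=config.grid_R,
                                 nrep_similarity=config.nrep_similarity,
                                 nrep_equivalence=config.nrep_equivalence,
                                 env_quantile=config.env_quantile,
                                 seed=ov_seed)
            cats = res.categories()
            ov_row.update(D=res.D, equivalence=res.equivalence_p,
                          similarity=res.similarity_p,
                          expansion=res.expansion, stability=res.stability,
                          unfilling=res.unfilling,
                          expansion_cat=cats["expansion"],
                          stability_cat=cats["stability"],
                          unfilling_cat=cats["unfilling"])
            panels[sp] = (occ_pc, bgs)
            log.append(f"overlap {sp}: seed {ov_seed} D={res.D:.3f} "
                       f"sim_p={res.similarity_p:.3f}")
        except Exception as exc:
            log.append(f"overlap {sp} FAILED: {exc}")
        auc_rows.append(auc_row)
        overlap_rows.append(ov_row)

    auc_table = pd.DataFrame(auc_rows, columns=["species"] + auc_cols)
    overlap_table = pd.DataFrame(
        overlap_rows, columns=["species", "D", "equivalence", "similarity",
                               "expansion", "stability", "unfilling",
                               "expansion_cat", "stability_cat",
                               "unfilling_cat"])
    summary = _summarize(auc_table, overlap_table, (lab_a, lab_b))
    result = StudyResult(auc_table=auc_table, overlap_table=overlap_table,
                         summary=summary, log=log, env_space=space)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir), panels, write_plots,
                       std_stacks, space, enm_results)
    return result


def _summarize(auc_table: pd.DataFrame, overlap_table: pd.DataFrame,
               labels) -> dict:
    """The study-level aggregates: D/E/S/U moments, similarity fraction,
    AUC category shares per region."""
    ov = overlap_table.dropna(subset=["D"])
    summary = {
        "n_species": int(len(overlap_table)),
        "n_analyzed": int(len(ov)),
        "D_mean": float(ov["D"].mean()) if len(ov) else None,
        "D_sd": float(ov["D"].std(ddof=1)) if len(ov) > 1 else None,
        "expansion_mean": float(ov["expansion"].mean()) if len(ov) else None,
        "stability_mean": float(ov["stability"].mean()) if len(ov) else None,
        "unfilling_mean": float(ov["unfilling"].mean()) if len(ov) else None,
        "frac_similarity_significant":
            float((ov["similarity"] < 0.05).mean()) if len(ov) else None,
    }
    for lab in labels:
        col = f"ENS_{lab}"
        if col in auc_table.columns:
            vals = auc_table[col].dropna()
            cats = vals.map(auc_category)
            summary[f"auc_categories_{lab}"] = {
                c: float((cats == c).mean()) if len(cats) else None
                for c in ("random", "acceptable", "good", "optimal")}
    return summary


def _write_outputs(result: StudyResult, config: StudyConfig, out_dir: Path,
                   panels: dict, write_plots: bool, stacks=None, space=None,
                   enm_results=None) -> None:
    from .climate_space import write_score_rasters
    from .raster import write_ascii_grid

    out_dir.mkdir(parents=True, exist_ok=True)
    if stacks is not None and space is not None:
        for lab, stack in stacks.items():
            write_score_rasters(stack, space, out_dir / "pc_rasters",
                                prefix=f"{lab}_")
    if enm_results:
        raster_dir = out_dir / "enm_rasters"
        raster_dir.mkdir(parents=True, exist_ok=True)
        for sp, pair in enm_results.items():
            for res in pair:
                eval_lab = res.direction.split("->")[1]
                tag = res.direction.replace("->", "_to_")
                for kind, grid in (("suit", res.ensemble_map),
                                   ("binary", res.binary_map)):
                    write_ascii_grid(raster_dir / f"{sp}_{tag}_{kind}.asc",
                                     np.nan_to_num(grid), ~np.isnan(grid),
                                     stacks[eval_lab].transform)
    result.auc_table.to_csv(out_dir / "auc_table.csv", index=False,
                            float_format="%.6f")
    result.overlap_table.to_csv(out_dir / "overlap_table.csv", index=False,
                                float_format="%.6f")
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    (out_dir / "run_log.txt").write_text("\n".join(result.log) + "\n")
    if write_plots:
        from .plots import plot_niche_panel
        lab_a, lab_b = config.labels
        for sp, (occ_pc, bgs) in panels.items():
            plot_niche_panel(occ_pc[lab_a], occ_pc[lab_b], bgs[lab_a],
                             bgs[lab_b], R=config.grid_R,
                             labels=(lab_a, lab_b),
                             path=out_dir / f"niche_{sp}.png")
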