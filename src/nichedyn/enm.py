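"""Ecological niche models with a reciprocal fit/transfer design.

Models are fit on one region's presences plus Bioclim-profile pseudo-
absences (RSEP: random sampling outside the environmental profile,
restricted to the accessible area), then transferred to the other region
and scored there against that region's presences and its own RSEP
pseudo-absences.  Four algorithms are supported — logistic GLM with
quadratic terms, random forest, RBF support-vector machine with
probability calibration, and a Gaussian-process classifier — evaluated by
Mann-Whitney AUC, binarized at the max-sensitivity+specificity threshold,
and combined by averaging the better-than-mean-AUC models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import accessible_area as aa
from ._seeds import stable_seed
from .climate_space import EnvSpace, project
from .raster import ClimateStack

__all__ = [
    "ALGORITHMS", "BioclimEnvelope", "TrainingSet", "EnmResult",
    "bioclim_fit", "rsep_sample", "fit_model", "auc", "auc_category",
    "threshold_max_ss", "ensemble", "reciprocal_run",
]

ALGORITHMS = ("GLM", "RDF", "SVM", "GAU")


# ----------------------------------------------------------------------
# Bioclim envelope

@dataclass
class BioclimEnvelope:
    """Per-variable training ranges and empirical distributions.

    Suitability of a point is ``min_j 1 - 2|F_j(x_j) - 0.5|`` with F_j the
    training empirical CDF (midrank convention for ties); a point outside
    any variable's [min, max] scores 0 and is outside the binary envelope.
    """

    mins: np.ndarray
    maxs: np.ndarray
    training: np.ndarray  # (n, p), sorted per column

    def _cdf(self, X: np.ndarray) -> np.ndarray:
        n = self.training.shape[0]
        F = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            col = self.training[:, j]
            less = np.searchsorted(col, X[:, j], side="left")
            leq = np.searchsorted(col, X[:, j], side="right")
            ties = leq - less
            F[:, j] = (less + (ties + 1) / 2.0) / n
        return F

    def suitability(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = self._cdf(X)
        score = np.min(1.0 - 2.0 * np.abs(F - 0.5), axis=1)
        return np.where(self.inside(X), np.clip(score, 0.0, 1.0), 0.0)

    def inside(self, X: np.ndarray) -> np.ndarray:
        """Binary envelope: inside iff every variable is within [min, max]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.all((X >= self.mins) & (X <= self.maxs), axis=1)


def bioclim_fit(presence_env_rows: np.ndarray) -> BioclimEnvelope:
    """Fit the Bioclim envelope on presence rows (n >= 2)."""
    X = np.atleast_2d(np.asarray(presence_env_rows, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("bioclim needs at least 2 presences")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    for j in np.nonzero(mins == maxs)[0]:
        warnings.warn(
            f"variable {j} is constant across presences; its envelope is a "
            "single value", stacklevel=2)
    return BioclimEnvelope(mins=mins, maxs=maxs,
                           training=np.sort(X, axis=0))


def rsep_sample(envelope: BioclimEnvelope, candidate_cells: np.ndarray,
                n: int, seed: int) -> np.ndarray:
    """RSEP pseudo-absences: uniform draw of cells outside the envelope.

    ``candidate_cells`` are the accessible-area cells' env rows; sampling is
    without replacement and deterministic given ``seed``.
    """
    cand = np.atleast_2d(np.asarray(candidate_cells, dtype=float))
    outside = ~envelope.inside(cand)
    avail = int(outside.sum())
    if avail < n:
        raise ValueError(
            f"only {avail} candidate cells outside the envelope; {n} needed")
    rng = np.random.default_rng(seed)
    idx = rng.choice(np.nonzero(outside)[0], size=n, replace=False)
    return cand[np.sort(idx)]


# ----------------------------------------------------------------------
# Training set and algorithms

@dataclass
class TrainingSet:
    """Presences and matched pseudo-absences in env-axis coordinates."""

    presences: np.ndarray
    pseudo_absences: np.ndarray
    region: str = ""
    species: str = ""

    def __post_init__(self):
        self.presences = np.atleast_2d(np.asarray(self.presences, float))
        self.pseudo_absences = np.atleast_2d(
            np.asarray(self.pseudo_absences, float))
        if self.pseudo_absences.shape[0] != self.presences.shape[0]:
            raise ValueError("pseudo-absence count must equal presence count")
        if not (np.all(np.isfinite(self.presences))
                and np.all(np.isfinite(self.pseudo_absences))):
            raise ValueError("training rows contain missing values")

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack([self.presences, self.pseudo_absences])
        y = np.r_[np.ones(len(self.presences)),
                  np.zeros(len(self.pseudo_absences))]
        return X, y


def _with_quadratic(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, X ** 2])


class _FittedModel:
    """A suitability function wrapping a fitted classifier."""

    def __init__(self, algorithm: str, predict: Callable[[np.ndarray], np.ndarray]):
        self.algorithm = algorithm
        self._predict = predict

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite coordinates")
        return np.clip(self._predict(X), 0.0, 1.0)


def fit_model(algorithm: str, training_set: TrainingSet, seed: int) -> _FittedModel:
    """Fit one algorithm; returns a map env-axis rows -> suitability [0, 1].

    GLM: binomial logistic regression on linear + quadratic axis terms.
    RDF: 500 classification trees; suitability = presence-vote fraction.
    SVM: RBF soft-margin classifier with probability calibration.
    GAU: Gaussian-process classifier with an RBF kernel.
    Deterministic given ``seed``.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of "
                         f"{ALGORITHMS}")
    X, y = training_set.xy()
    if algorithm == "GLM":
        # C=inf: plain (unpenalized) binomial logistic regression
        est = LogisticRegression(C=np.inf, max_iter=5000)
        est.fit(_with_quadratic(X), y)
        return _FittedModel("GLM",
                            lambda Z: est.predict_proba(_with_quadratic(Z))[:, 1])
    if algorithm == "RDF":
        est = RandomForestClassifier(n_estimators=500, random_state=seed,
                                     n_jobs=1)
        est.fit(X, y)
        return _FittedModel("RDF", lambda Z: est.predict_proba(Z)[:, 1])
    if algorithm == "SVM":
        # RBF soft-margin SVC with sigmoid probability calibration
        est = CalibratedClassifierCV(SVC(kernel="rbf", C=1.0,
                                         random_state=seed),
                                     method="sigmoid", cv=5, ensemble=False)
        est.fit(X, y)
        return _FittedModel("SVM", lambda Z: est.predict_proba(Z)[:, 1])
    # GAU
    kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
    est = GaussianProcessClassifier(kernel=kernel, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return _FittedModel("GAU", lambda Z: est.predict_proba(Z)[:, 1])


# ----------------------------------------------------------------------
# Evaluation

def auc(presence_scores: Sequence[float], absence_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(presence score > absence score), ties count 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.r_[np.ones(p.size), np.zeros(a.size)]
    s = np.r_[p, a]
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def auc_category(value: float) -> str:
    """Accuracy bin of an AUC value (lower-inclusive bins)."""
    if not (0.0 <= value <= 1.0):
        raise ValueError("AUC must lie in [0, 1]")
    if value < 0.5:
        return "random"
    if value < 0.7:
        return "acceptable"
    if value < 0.9:
        return "good"
    return "optimal"


def threshold_max_ss(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Cutoff maximizing sensitivity + specificity.

    Candidates are the midpoints between adjacent sorted unique scores
    (predicted present iff score >= cutoff); ties break toward the lower
    cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    if uniq.size == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best_c, best_v = None, -np.inf
    for c in cands:  # ascending: strict > keeps the lowest tied cutoff
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        if sens + spec > best_v + 1e-12:
            best_v, best_c = sens + spec, c
    return float(best_c)


def ensemble(maps: Sequence[np.ndarray], aucs: Sequence[float]) -> np.ndarray:
    """Cell-wise mean of the maps whose AUC >= mean AUC (>= 1 map kept)."""
    maps = [np.asarray(m, dtype=float) for m in maps]
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps are not co-registered (shape mismatch)")
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size != len(maps):
        raise ValueError("one AUC per map required")
    keep = aucs >= aucs.mean() - 1e-12
    return np.mean([m for m, k in zip(maps, keep) if k], axis=0)


# ----------------------------------------------------------------------
# Reciprocal design

@dataclass
class EnmResult:
    """One transfer direction: per-algorithm AUCs and the ensemble map."""

    direction: str
    per_algorithm_auc: dict[str, float]
    ensemble_auc: float
    threshold: float
    ensemble_map: np.ndarray  # 2-D, NaN outside the evaluation mask
    binary_map: np.ndarray    # 2-D, NaN outside the evaluation mask
    per_algorithm_maps: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class EnmConfig:
    algorithms: tuple[str, ...] = ALGORITHMS
    buffer_deg: float = 1.0


def _env_rows(occ, stack: ClimateStack, space: EnvSpace) -> np.ndarray:
    vals = stack.values_at(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    return project(vals, space)


def _fit_direction(occ_fit, stack_fit, occ_eval, stack_eval, space: EnvSpace,
                   config: EnmConfig, seed: int, direction: str) -> EnmResult:
    rng_seeds = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)

    pres_fit = _env_rows(occ_fit, stack_fit, space)
    cand_fit = project(stack_fit.valid_table(), space)
    env_fit = bioclim_fit(pres_fit)
    absn_fit = rsep_sample(env_fit, cand_fit, len(pres_fit), int(rng_seeds[0]))
    train = TrainingSet(pres_fit, absn_fit, region=direction.split("->")[0])

    pres_eval = _env_rows(occ_eval, stack_eval, space)
    cand_eval = project(stack_eval.valid_table(), space)
    env_eval = bioclim_fit(pres_eval)
    absn_eval = rsep_sample(env_eval, cand_eval, len(pres_eval),
                            int(rng_seeds[1]))

    aucs: dict[str, float] = {}
    maps: dict[str, np.ndarray] = {}
    pres_scores: dict[str, np.ndarray] = {}
    absn_scores: dict[str, np.ndarray] = {}
    for i, alg in enumerate(config.algorithms):
        model = fit_model(alg, train, int(rng_seeds[2 + i]))
        pres_scores[alg] = model(pres_eval)
        absn_scores[alg] = model(absn_eval)
        aucs[alg] = auc(pres_scores[alg], absn_scores[alg])
        maps[alg] = model(cand_eval)

    auc_arr = np.array([aucs[a] for a in config.algorithms])
    keep = auc_arr >= auc_arr.mean() - 1e-12
    kept = [a for a, k in zip(config.algorithms, keep) if k]
    ens_cells = ensemble([maps[a] for a in config.algorithms], auc_arr)
    ens_pres = np.mean([pres_scores[a] for a in kept], axis=0)
    ens_absn = np.mean([absn_scores[a] for a in kept], axis=0)
    ens_auc = auc(ens_pres, ens_absn)
    cutoff = threshold_max_ss(np.r_[ens_pres, ens_absn],
                              np.r_[np.ones(len(ens_pres), int),
                                    np.zeros(len(ens_absn), int)])

    ens_map = np.full(stack_eval.shape, np.nan)
    ens_map[stack_eval.mask] = ens_cells
    bin_map = np.full(stack_eval.shape, np.nan)
    bin_map[stack_eval.mask] = (ens_cells >= cutoff).astype(float)
    full_maps = {}
    for a in config.algorithms:
        m = np.full(stack_eval.shape, np.nan)
        m[stack_eval.mask] = maps[a]
        full_maps[a] = m
    return EnmResult(direction=direction, per_algorithm_auc=aucs,
                     ensemble_auc=ens_auc, threshold=cutoff,
                     ensemble_map=ens_map, binary_map=bin_map,
                     per_algorithm_maps=full_maps)


def reciprocal_run(occ_a, occ_b, stacks: dict[str, ClimateStack],
                   env_space: EnvSpace, config: EnmConfig | None = None,
                   seed: int = 0) -> tuple[EnmResult, EnmResult]:
    """Fit on each region and evaluate on the other (both directions).

    ``occ_a``/``occ_b`` are occurrence DataFrames whose ``region`` column
    names keys of ``stacks``.  Accessible areas (MCP + buffer) are built per
    region and the stacks masked to them before pseudo-absence sampling and
    map projection.  Returns the pair (A->B, B->A); with the same seeds,
    swapping the inputs swaps the pair.
    """
    config = config or EnmConfig()
    label_a = str(occ_a["region"].iloc[0])
    label_b = str(occ_b["region"].iloc[0])
    masked = {}
    for label, occ in ((label_a, occ_a), (label_b, occ_b)):
        area = aa.build_accessible_area(
            occ[["lon", "lat"]].to_numpy(), config.buffer_deg)
        masked[label] = aa.mask(stacks[label], area)
    # direction seeds depend on the labels, not the argument order, so
    # swapping (occ_a, occ_b) swaps the result pair exactly
    seed_ab = stable_seed(seed, "direction", label_a, label_b)
    seed_ba = stable_seed(seed, "direction", label_b, label_a)
    res_ab = _fit_direction(occ_a, masked[label_a], occ_b, masked[label_b],
                            env_space, config, seed_ab,
                            f"{label_a}->{label_b}")
    res_ba = _fit_direction(occ_b, masked[label_b], occ_a, masked[label_a],
                            env_space, config, seed_ba,
                            f"{label_b}->{label_a}")
    return res_ab, res_ba
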