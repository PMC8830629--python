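"""Presence-background habitat suitability modeling.

The suitability model is a ridge-penalized presence-background logistic
regression with linear + quadratic features, fit as a bootstrap ensemble:
per replicate the presences are split into calibration (default 75%) and
evaluation (25%) sets, the calibration set is bootstrap-resampled, a fresh
uniform background sample is drawn, and the model is fit with an iteration
cap.  Replicate predictions are averaged into the habitat-suitability
surface HS in [0, 1].

Evaluation uses the rank (Mann-Whitney) AUC of evaluation presences
against the replicate's background sample.  Continuous maps are binarized
by either the 10th-percentile training-presence threshold or the mean
suitability at the occurrence points.  Variable importance is permutation
based (mean AUC drop, rescaled to sum to 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .grid import Grid, OccurrenceSet, Stack

__all__ = [
    "ModelConfig",
    "ReplicateModel",
    "SuitabilityEnsemble",
    "BinaryThresholdRule",
    "fit_ensemble",
    "predict_suitability",
    "auc",
    "p10_threshold",
    "mean_threshold",
    "resolve_threshold",
    "apply_threshold",
    "variable_importance",
    "response_curve",
    "prey_availability",
]


@dataclass
class ModelConfig:
    """Ensemble settings; defaults are the analysis defaults
    (10 replicates, 10000 background points, 500-iteration cap, 75% of
    presences used to calibrate)."""

    n_background: int = 10000
    n_replicates: int = 10
    max_iterations: int = 500
    train_fraction: float = 0.75
    regularization: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")


@dataclass
class ReplicateModel:
    coef: np.ndarray  # (2k,) linear then quadratic terms
    intercept: float
    test_auc: float
    converged: bool
    train_idx: np.ndarray
    test_idx: np.ndarray
    background_cells: np.ndarray  # flat indices into the valid-cell table


@dataclass
class SuitabilityEnsemble:
    """Fitted replicate models plus the feature transform that produced
    them (per-variable standardization, linear + quadratic expansion)."""

    variable_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    replicates: list[ReplicateModel]
    config: ModelConfig

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean([r.test_auc for r in self.replicates]))

    def features(self, raw: np.ndarray) -> np.ndarray:
        """(n, k) raw variable values -> (n, 2k) standardized linear +
        quadratic design matrix."""
        z = (raw - self.means) / self.sds
        return np.hstack([z, z ** 2])

    def predict_rows(self, raw: np.ndarray) -> np.ndarray:
        """(n_replicates, n) per-replicate logistic predictions."""
        X = self.features(raw)
        return np.stack([expit(X @ r.coef + r.intercept) for r in self.replicates])

    def coefficient_table(self) -> pd.DataFrame:
        cols = [f"{v}" for v in self.variable_names] + [
            f"{v}^2" for v in self.variable_names
        ]
        df = pd.DataFrame([r.coef for r in self.replicates], columns=cols)
        df.insert(0, "intercept", [r.intercept for r in self.replicates])
        df.insert(0, "test_auc", [r.test_auc for r in self.replicates])
        return df


def _stack_table(stack: Stack) -> tuple[np.ndarray, np.ndarray]:
    """Raw values of all valid cells: (flat_indices, (n_valid, k) array)."""
    arr = stack.array()
    valid = stack.valid_mask()
    flat = np.flatnonzero(valid.ravel())
    return flat, arr.reshape(len(stack), -1)[:, flat].T


def fit_ensemble(
    occurrences: OccurrenceSet, stack: Stack, config: ModelConfig
) -> SuitabilityEnsemble:
    """Fit the bootstrap ensemble of presence-background models.

    A replicate is flagged non-converged when the solver hits the
    iteration cap; the ensemble is valid while at least half the
    replicates converge.
    """
    geometry = stack.geometry
    flat_valid, table = _stack_table(stack)
    means = table.mean(axis=0)
    sds = table.std(axis=0)
    sds[sds == 0] = 1.0

    cells = occurrences.cells(geometry)
    pres_flat = cells[:, 0] * geometry.n_cols + cells[:, 1]
    pos_in_table = {f: i for i, f in enumerate(flat_valid)}
    try:
        pres_rows = np.array([pos_in_table[f] for f in pres_flat])
    except KeyError as e:
        raise ValueError(f"presence point falls on a nodata cell (flat {e})") from e
    n_pres = len(pres_rows)
    if n_pres < 20:
        warnings.warn(f"only {n_pres} presences; ensemble may be unstable")

    ens = SuitabilityEnsemble(
        variable_names=stack.names,
        means=means,
        sds=sds,
        replicates=[],
        config=config,
    )
    pres_X = ens.features(table[pres_rows])
    C = 1.0 / max(config.regularization, 1e-8)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_train = max(int(round(config.train_fraction * n_pres)), 1)

    for rep in range(config.n_replicates):
        perm = rng.permutation(n_pres)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        boot = rng.choice(train_idx, size=len(train_idx), replace=True)
        bg_rows = rng.integers(0, len(table), size=config.n_background)
        X = np.vstack([pres_X[boot], ens.features(table[bg_rows])])
        y = np.concatenate([np.ones(len(boot)), np.zeros(len(bg_rows))])
        model = LogisticRegression(
            C=C, max_iter=config.max_iterations, solver="lbfgs"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        converged = int(model.n_iter_[0]) < config.max_iterations
        coef = model.coef_[0]
        intercept = float(model.intercept_[0])
        bg_scores = expit(ens.features(table[bg_rows]) @ coef + intercept)
        if len(test_idx):
            test_scores = expit(pres_X[test_idx] @ coef + intercept)
            rep_auc = auc(test_scores, bg_scores)
        else:
            rep_auc = np.nan
        ens.replicates.append(
            ReplicateModel(
                coef=coef,
                intercept=intercept,
                test_auc=rep_auc,
                converged=converged,
                train_idx=train_idx,
                test_idx=test_idx,
                background_cells=bg_rows,
            )
        )
        occurrences.partitions[rep] = (train_idx, test_idx)

    n_ok = sum(r.converged for r in ens.replicates)
    if n_ok < config.n_replicates / 2:
        raise RuntimeError(
            f"only {n_ok}/{config.n_replicates} replicates converged "
            f"within {config.max_iterations} iterations"
        )
    return ens


def predict_suitability(ensemble: SuitabilityEnsemble, stack: Stack) -> Grid:
    """Per-cell mean of replicate logistic predictions (HS in [0, 1])."""
    missing = [v for v in ensemble.variable_names if v not in stack.names]
    if missing:
        raise ValueError(f"stack is missing model variables: {missing}")
    stack = stack.subset(ensemble.variable_names)
    flat_valid, table = _stack_table(stack)
    preds = ensemble.predict_rows(table).mean(axis=0)
    out = np.full(stack.geometry.shape, np.nan).ravel()
    out[flat_valid] = preds
    return stack.geometry.copy(values=out.reshape(stack.geometry.shape))


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Rank (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score lists must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


# ---------------------------------------------------------------------------
# Binarization thresholds
# ---------------------------------------------------------------------------

@dataclass
class BinaryThresholdRule:
    method: str  # "p10_training_presence" | "mean_presence_suitability"
    value: float

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 1:
            raise ValueError("threshold must lie in [0, 1]")


def p10_threshold(values: Sequence[float]) -> float:
    """10th percentile (linear interpolation between order statistics)."""
    return float(np.percentile(np.asarray(values, float), 10))


def mean_threshold(values: Sequence[float]) -> float:
    return float(np.mean(values))


def resolve_threshold(
    ensemble: SuitabilityEnsemble,
    occurrences: OccurrenceSet,
    hs: Grid,
    method: str = "p10_training_presence",
) -> BinaryThresholdRule:
    """Resolve a binarization rule against the fitted ensemble.

    ``p10_training_presence``: 10th percentile of HS at the union of the
    replicates' training presences.  ``mean_presence_suitability``: mean HS
    at all occurrence points.
    """
    cells = occurrences.cells(hs)
    hs_at = hs.values[cells[:, 0], cells[:, 1]]
    if method == "p10_training_presence":
        train = sorted(
            {int(i) for r in ensemble.replicates for i in r.train_idx}
        )
        if len(train) < 10:
            raise ValueError("need >= 10 training presences for the p10 rule")
        value = p10_threshold(hs_at[train])
    elif method == "mean_presence_suitability":
        value = mean_threshold(hs_at)
    else:
        raise ValueError(f"unknown threshold method '{method}'")
    return BinaryThresholdRule(method=method, value=value)


def apply_threshold(hs: Grid, rule: BinaryThresholdRule) -> Grid:
    """Suitable (1) where HS >= threshold, else 0; nodata preserved."""
    out = np.where(hs.values >= rule.value, 1.0, 0.0)
    out[~hs.mask] = np.nan
    return hs.copy(values=out)


# ---------------------------------------------------------------------------
# Variable importance and response curves
# ---------------------------------------------------------------------------

def variable_importance(
    ensemble: SuitabilityEnsemble,
    occurrences: OccurrenceSet,
    stack: Stack,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance as percent contributions summing to 100.

    For every variable, its raw values are shuffled across the evaluation
    rows (presences + a background sample) and the mean AUC drop over
    replicates and permutations is recorded; negative drops are clipped to
    zero and the drops are rescaled to sum to 100.
    """
    stack = stack.subset(ensemble.variable_names)
    _, table = _stack_table(stack)
    geometry = stack.geometry
    cells = occurrences.cells(geometry)
    flat_valid, _ = _stack_table(stack)
    pos_in_table = {f: i for i, f in enumerate(flat_valid)}
    pres_rows = np.array(
        [pos_in_table[r * geometry.n_cols + c] for r, c in cells]
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    bg_rows = rng.integers(0, len(table), size=min(len(table), 2000))
    rows = np.concatenate([pres_rows, bg_rows])
    y_pres = len(pres_rows)
    raw = table[rows]

    def mean_auc(raw_eval: np.ndarray) -> float:
        preds = ensemble.predict_rows(raw_eval)
        return float(
            np.mean([auc(p[:y_pres], p[y_pres:]) for p in preds])
        )

    base = mean_auc(raw)
    drops = np.zeros(len(ensemble.variable_names))
    for j in range(len(ensemble.variable_names)):
        for _ in range(n_permutations):
            shuffled = raw.copy()
            shuffled[:, j] = rng.permutation(shuffled[:, j])
            drops[j] += base - mean_auc(shuffled)
    drops = np.clip(drops / n_permutations, 0, None)
    if drops.sum() == 0:
        pct = np.full_like(drops, 100.0 / len(drops))
    else:
        pct = 100.0 * drops / drops.sum()
    return pd.Series(pct, index=ensemble.variable_names, name="percent_contribution")


def response_curve(
    ensemble: SuitabilityEnsemble, stack: Stack, variable: str, n_points: int = 50
) -> pd.DataFrame:
    """Mean HS as the target variable sweeps its observed range with every
    other variable held at its mean."""
    if variable not in ensemble.variable_names:
        raise KeyError(f"variable '{variable}' not in the fitted ensemble")
    stack = stack.subset(ensemble.variable_names)
    _, table = _stack_table(stack)
    j = ensemble.variable_names.index(variable)
    lo, hi = table[:, j].min(), table[:, j].max()
    sweep = np.linspace(lo, hi, n_points)
    raw = np.tile(table.mean(axis=0), (n_points, 1))
    raw[:, j] = sweep
    hs = ensemble.predict_rows(raw).mean(axis=0)
    return pd.DataFrame({variable: sweep, "mean_hs": hs})


# ---------------------------------------------------------------------------
# Prey availability
# ---------------------------------------------------------------------------

def prey_availability(species_maps: Sequence[tuple[Grid, Grid]]) -> Grid:
    """Cellwise sum over species of suitability x density."""
    if not species_maps:
        raise ValueError("need at least one prey species")
    first_suit = species_maps[0][0]
    total = np.zeros(first_suit.shape)
    for suit, dens in species_maps:
        first_suit.assert_same_geometry(suit, "prey suitability")
        first_suit.assert_same_geometry(dens, "prey density")
        total = total + suit.values * dens.values
    return first_suit.copy(values=total)
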