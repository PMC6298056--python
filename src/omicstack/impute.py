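"""Iterative random-forest missing-value interpolation (missForest scheme).

Missing cells are initialized with feature means; features are then visited
in order of increasing missingness, each regressed on all other features
with a random forest trained on its observed rows, and only the missing
cells are overwritten.  Iteration stops when the normalized change between
successive completed matrices stops decreasing (the missForest stopping
rule), falls below tolerance, or the iteration cap is reached.  Observed
entries are never modified.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

from .datamodel import MultiomicsCohort, OmicsDataset
from .errors import ImputationError, ValidationError


@dataclass(frozen=True)
class ImputeConfig:
    """Hyperparameters of the iterative forest imputer."""

    n_trees: int = 100
    max_iterations: int = 10
    convergence_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.max_iterations < 1:
            raise ValidationError("n_trees and max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be > 0")


class RandomForestImputer(BaseEstimator, TransformerMixin):
    """scikit-learn style transformer wrapping the missForest procedure.

    ``transform`` completes a matrix in one shot (the procedure is
    transductive — there is no separate training set), so ``fit`` only
    validates parameters.

    Attributes after ``transform``: ``n_iterations_`` (iterations actually
    run) and ``converged_`` (whether the stopping rule fired before the cap).
    """

    def __init__(self, n_trees: int = 100, max_iterations: int = 10,
                 convergence_tol: float = 1e-4, seed: int = 0):
        self.n_trees = n_trees
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.seed = seed

    def fit(self, X, y=None):
        ImputeConfig(self.n_trees, self.max_iterations,
                     self.convergence_tol, self.seed)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def transform(self, X):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        values = df.to_numpy(float)
        mask = np.isnan(values)
        if not mask.any():
            self.n_iterations_, self.converged_ = 0, True
            return df.copy()

        fully_missing = np.flatnonzero(mask.all(axis=0))
        if fully_missing.size:
            names = [str(df.columns[j]) for j in fully_missing]
            raise ImputationError(f"feature(s) fully missing: {names}")
        if mask.all(axis=1).any():
            rows = df.index[mask.all(axis=1)].tolist()
            raise ImputationError(f"sample(s) fully missing: {rows}")

        rng = np.random.default_rng(self.seed)
        filled = values.copy()
        col_means = np.nanmean(values, axis=0)
        filled[mask] = np.take(col_means, np.nonzero(mask)[1])

        # least-missing first, most-missing last
        order = np.argsort(mask.sum(axis=0), kind="stable")
        order = [j for j in order if mask[:, j].any()]

        prev = filled.copy()
        prev_change = np.inf
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iterations + 1):
            for j in order:
                obs = ~mask[:, j]
                others = np.delete(np.arange(filled.shape[1]), j)
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                rf.fit(filled[np.ix_(obs, others)], filled[obs, j])
                filled[~obs, j] = rf.predict(filled[np.ix_(~obs, others)])
            num = float(((filled[mask] - prev[mask]) ** 2).sum())
            den = float((filled[mask] ** 2).sum())
            change = num / den if den > 0 else 0.0
            if change > prev_change:
                filled = prev              # revert to the better iterate
                self.converged_ = True
                break
            prev = filled.copy()
            if change < self.convergence_tol:
                self.converged_ = True
                break
            prev_change = change
        self.n_iterations_ = it

        out = df.copy()
        out.iloc[:, :] = filled
        return out


def rf_impute(dataset: OmicsDataset, config: ImputeConfig | None = None) -> OmicsDataset:
    """Complete one modality's matrix; observed entries are unchanged."""
    config = config or ImputeConfig()
    imp = RandomForestImputer(config.n_trees, config.max_iterations,
                              config.convergence_tol, config.seed)
    completed = imp.transform(dataset.matrix)
    return OmicsDataset(dataset.modality_name, completed)


def _derived_seed(base: int, tag: str) -> int:
    return (int(base) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def impute_cohort(cohort: MultiomicsCohort, config: ImputeConfig | None = None) -> MultiomicsCohort:
    """Apply :func:`rf_impute` to every modality independently.

    Each modality gets a seed derived deterministically from the config seed
    and its name, so adding or removing a modality never perturbs the
    others' imputations.  Metadata is untouched.
    """
    config = config or ImputeConfig()
    completed = {}
    for name, ds in cohort.datasets.items():
        mod_cfg = ImputeConfig(
            config.n_trees, config.max_iterations, config.convergence_tol,
            _derived_seed(config.seed, name),
        )
        completed[name] = rf_impute(ds, mod_cfg) if ds.n_missing else ds.copy()
    return MultiomicsCohort(cohort.metadata, completed,
                            dropped_sample_ids=list(cohort.dropped_sample_ids))
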