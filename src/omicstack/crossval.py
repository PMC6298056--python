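"""Subject-blocked two-layer cross-validation.

Samples from the same subject are statistically dependent (they share a
random subject effect), so generalization must be assessed by holding out
*all* of a subject's samples together.  The outer layer is a
leave-one-subject-out (LOSO) partition of the pregnancy samples; within
each outer training fold a second LOSO grid search selects the elastic-net
hyperparameters.  The held-out subject therefore never influences the model
that predicts it — neither through fitting nor through hyperparameter
selection ("blinded" predictions).

Besides the elastic-net path, a regressor-agnostic benchmark harness runs
arbitrary adapters (random forest, SVR, Gaussian process, XGBoost, ...)
under the *same* fold plan for fair comparison.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path

from .datamodel import OmicsDataset, SampleMetadata, MultiomicsCohort
from .elastic_net import ENHyperparams, ElasticNetRegressor, fit_en, _ALPHA_FLOOR
from .errors import InsufficientDataError, ValidationError

# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Evaluation:
    """Spearman rho, its p-value and RMSE for a prediction vector."""

    rho: float
    p: float
    rmse: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.rho, self.p, self.rmse))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p-value for Spearman's rho (small n).

    Enumerates all n! pairings of the average ranks; ties are handled by the
    Pearson-on-ranks definition.  Returns (rho_observed, p).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0:
        return 0.0, 1.0
    rho_obs = float(rxc @ ryc) / denom
    n = len(x)
    total = math.factorial(n)
    count = 0
    it = itertools.permutations(ry)
    chunk = 100_000
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        rhos = (block @ rxc) / denom  # centering of block is free: sum(rxc)=0
        count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
    return rho_obs, count / total


def spearman_test(x, y) -> tuple[float, float, bool]:
    """(rho, p, degenerate): average-rank Spearman with exact permutation
    p for n <= 10 and the t-approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0, 1.0, True
    if len(x) <= 10:
        rho, p = _exact_spearman_p(x, y)
        return rho, p, False
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), False


def evaluate_predictions(pred, truth) -> Evaluation:
    """Score a prediction vector against the truth (both in weeks)."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValidationError("pred and truth must be equal-length vectors")
    if len(pred) < 3:
        raise ValidationError("need at least 3 points to evaluate")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    rho, p, degenerate = spearman_test(pred, truth)
    return Evaluation(rho=rho, p=p, rmse=rmse, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    subject_id: str
    test_ids: tuple
    train_ids: tuple


@dataclass(frozen=True)
class FoldPlan:
    """Deterministic leave-one-subject-out partition of pregnancy samples."""

    folds: tuple

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)

    @property
    def subjects(self) -> list[str]:
        return [f.subject_id for f in self.folds]

    def signature(self) -> str:
        """Stable content hash, for cross-layer synchronization checks."""
        h = hashlib.sha256()
        for f in self.folds:
            h.update(repr((f.subject_id, f.test_ids, f.train_ids)).encode())
        return h.hexdigest()


def make_loso_folds(metadata: SampleMetadata) -> FoldPlan:
    """One fold per subject; postpartum samples appear in no fold.

    Fold order is sorted by subject id; construction is RNG-free, so the
    same metadata always yields the identical plan.
    """
    preg = metadata.pregnancy_sample_ids()
    subj = metadata.subject
    subjects = sorted({subj[s] for s in preg})
    if len(subjects) < 3:
        raise InsufficientDataError(
            f"leave-one-subject-out needs >= 3 subjects, got {len(subjects)}"
        )
    folds = []
    for s in subjects:
        test = tuple(i for i in preg if subj[i] == s)
        train = tuple(i for i in preg if subj[i] != s)
        folds.append(Fold(s, test, train))
    return FoldPlan(tuple(folds))


# ---------------------------------------------------------------------------
# Hyperparameter grid and inner selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperGrid:
    """Elastic-net search grid.

    ``alphas`` is the mixing grid; for each alpha the lambda grid is
    ``n_lambdas`` points log-spaced from lambda_max (smallest lambda zeroing
    every coefficient on the training fold at that alpha) down to
    ``lambda_max * lambda_min_ratio``.  ``fixed_lambdas`` overrides the
    data-driven lambda path with an explicit grid.
    """

    alphas: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    fixed_lambdas: tuple | None = None

    def __post_init__(self):
        if not self.alphas:
            raise ValidationError("alphas must be non-empty")
        if any(not (0.0 <= a <= 1.0) for a in self.alphas):
            raise ValidationError("alphas must lie in [0, 1]")
        if list(self.alphas) != sorted(self.alphas):
            raise ValidationError("alphas must be sorted ascending")
        if self.fixed_lambdas is None:
            if self.n_lambdas < 1:
                raise ValidationError("n_lambdas must be >= 1")
            if not (0.0 < self.lambda_min_ratio < 1.0):
                raise ValidationError("lambda_min_ratio must be in (0, 1)")
        elif not self.fixed_lambdas:
            raise ValidationError("fixed_lambdas must be non-empty if given")


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _lambda_grid(Z: np.ndarray, yc: np.ndarray, alpha: float, grid: HyperGrid) -> np.ndarray:
    """Descending lambda grid for one alpha on a (standardized) training fold."""
    if grid.fixed_lambdas is not None:
        return np.array(sorted(grid.fixed_lambdas, reverse=True), float)
    lam_max = 2.0 * np.abs(Z.T @ yc).max() / max(alpha, _ALPHA_FLOOR)
    if lam_max == 0:
        lam_max = 1.0
    if grid.n_lambdas == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(0.0, np.log10(grid.lambda_min_ratio),
                                 grid.n_lambdas)


def _fit_path(Z: np.ndarray, yc: np.ndarray, alpha: float, lams: np.ndarray) -> np.ndarray:
    """Coefficient paths (p x len(lams)) for descending lams at one alpha."""
    n, p = Z.shape
    if alpha == 0.0:
        G = Z.T @ Z
        w, V = np.linalg.eigh(G)
        b = V.T @ (Z.T @ yc)
        coefs = np.stack([V @ (b / (w + lam)) for lam in lams], axis=1)
        return coefs
    sk_alphas = lams * (2.0 - alpha) / (2.0 * n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            Z, yc, l1_ratio=alpha / (2.0 - alpha), alphas=sk_alphas,
        )
    return coefs


def inner_select(train_X, train_Y, train_metadata: SampleMetadata,
                 grid: HyperGrid, return_score: bool = False):
    """Select (alpha, lam) by an inner LOSO grid search on a training fold.

    The criterion is the RMSE of the pooled inner blinded predictions.
    Ties are broken toward larger lam, then smaller alpha (prefer sparser,
    smoother models).  The lambda grid for each alpha is computed once on
    the full training fold.  With ``return_score`` the winning inner RMSE
    (weeks) is returned alongside the hyperparameters.
    """
    X = train_X.to_numpy(float) if isinstance(train_X, pd.DataFrame) else np.asarray(train_X, float)
    y = np.asarray(train_Y, float)
    sample_ids = (train_X.index.tolist() if isinstance(train_X, pd.DataFrame)
                  else list(range(len(y))))
    pos = {s: i for i, s in enumerate(sample_ids)}
    inner_folds = make_loso_folds(train_metadata)

    Zfull, _, _ = _standardize(X)
    ycfull = y - y.mean()
    lam_grids = {a: _lambda_grid(Zfull, ycfull, a, grid) for a in grid.alphas}

    sq = {a: np.zeros(len(lam_grids[a])) for a in grid.alphas}
    n_pred = 0
    for f in inner_folds:
        tr = [pos[s] for s in f.train_ids]
        te = [pos[s] for s in f.test_ids]
        Ztr, mu, sd = _standardize(X[tr])
        yc = y[tr] - y[tr].mean()
        Zte = (X[te] - mu) / sd
        for a in grid.alphas:
            coefs = _fit_path(Ztr, yc, a, lam_grids[a])
            preds = Zte @ coefs + y[tr].mean()            # (n_te, n_lams)
            sq[a] += ((preds - y[te][:, None]) ** 2).sum(axis=0)
        n_pred += len(te)

    best = None  # (rmse, -lam, alpha, hp)
    for a in grid.alphas:
        rmses = np.sqrt(sq[a] / n_pred)
        for lam, rmse in zip(lam_grids[a], rmses):
            key = (round(float(rmse), 12), -float(lam), float(a))
            if best is None or key < best[0]:
                best = (key, ENHyperparams(float(a), float(lam)), float(rmse))
    if return_score:
        return best[1], best[2]
    return best[1]


# ---------------------------------------------------------------------------
# Nested CV for the elastic net
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Outcome of two-layer LOSO cross-validation on one feature matrix."""

    name: str
    truth: pd.Series
    blinded_predictions: pd.Series
    training_predictions: pd.Series
    fold_hyperparams: dict
    fold_models: dict
    folds: FoldPlan
    blinded_eval: Evaluation
    training_eval: Evaluation


def run_nested_cv(dataset: OmicsDataset, metadata: SampleMetadata,
                  grid: HyperGrid | None = None,
                  folds: FoldPlan | None = None) -> CVResult:
    """Two-layer LOSO cross-validation of an elastic net on one modality.

    Per fold: the inner layer selects (alpha, lam) among the grid using only
    the training subjects, the model is refit on the whole training fold,
    and the held-out subject's samples receive blinded predictions.  The
    training prediction of a sample is the median over the models whose
    training fold contained it (one per other subject).
    """
    grid = grid or HyperGrid()
    folds = folds or make_loso_folds(metadata)
    if dataset.n_missing:
        raise ValidationError(
            f"{dataset.modality_name}: impute before cross-validation "
            f"({dataset.n_missing} missing values)"
        )
    matrix = dataset.matrix
    missing_ids = set(metadata.pregnancy_sample_ids()) - set(dataset.sample_ids)
    if missing_ids:
        raise ValidationError(f"dataset lacks samples: {sorted(missing_ids)[:5]}")
    outcome = metadata.outcome

    fold_models, fold_hp = {}, {}
    blinded = {}
    train_preds: dict[str, list[float]] = {}
    for f in folds:
        Xtr = matrix.loc[list(f.train_ids)]
        ytr = outcome[list(f.train_ids)]
        hp = inner_select(Xtr, ytr, metadata.subset(f.train_ids), grid)
        model = fit_en(Xtr, ytr, hp)
        fold_models[f.subject_id] = model
        fold_hp[f.subject_id] = hp
        for sid, val in zip(f.test_ids, model.predict(matrix.loc[list(f.test_ids)])):
            blinded[sid] = float(val)
        for sid, val in zip(f.train_ids, model.predict(Xtr)):
            train_preds.setdefault(sid, []).append(float(val))

    order = metadata.pregnancy_sample_ids()
    blinded_s = pd.Series({s: blinded[s] for s in order}, name="blinded")[order]
    training_s = pd.Series(
        {s: float(np.median(train_preds[s])) for s in order}, name="training"
    )[order]
    truth = outcome[order]
    return CVResult(
        name=dataset.modality_name,
        truth=truth,
        blinded_predictions=blinded_s,
        training_predictions=training_s,
        fold_hyperparams=fold_hp,
        fold_models=fold_models,
        folds=folds,
        blinded_eval=evaluate_predictions(blinded_s, truth),
        training_eval=evaluate_predictions(training_s, truth),
    )


# ---------------------------------------------------------------------------
# Regressor-agnostic benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class RegressorAdapter:
    """Uniform fit/predict wrapper for the benchmark harness.

    ``candidates(X, y)`` returns the hyperparameter dicts to search in the
    inner layer; ``build(params)`` returns an unfitted estimator with a
    scikit-learn fit/predict interface.
    """

    name: str
    build: callable
    candidates: callable = field(default=lambda X, y: [{}])


def _en_candidates(grid: HyperGrid):
    def cands(X, y):
        out = []
        Z, _, _ = _standardize(np.asarray(X, float))
        yc = np.asarray(y, float) - np.mean(y)
        for a in grid.alphas:
            for lam in _lambda_grid(Z, yc, a, grid):
                out.append({"alpha": float(a), "lam": float(lam)})
        return out
    return cands


def default_adapters(seed: int = 0, en_grid: HyperGrid | None = None) -> list:
    """EN plus the standard multivariate regressors it is compared against."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, WhiteKernel
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR
    import xgboost as xgb

    en_grid = en_grid or HyperGrid(alphas=(0.1, 0.5, 0.9), n_lambdas=10,
                                   lambda_min_ratio=1e-2)
    adapters = [
        RegressorAdapter(
            "elastic_net",
            build=lambda p: ElasticNetRegressor(alpha=p["alpha"], lam=p["lam"]),
            candidates=_en_candidates(en_grid),
        ),
        RegressorAdapter(
            "random_forest",
            build=lambda p: RandomForestRegressor(
                n_estimators=200, random_state=seed, n_jobs=1, **p),
        ),
        RegressorAdapter(
            "svr",
            build=lambda p: make_pipeline(StandardScaler(), SVR(**p)),
            candidates=lambda X, y: [
                {"kernel": k, "C": c}
                for k in ("rbf", "linear", "poly", "sigmoid")
                for c in (0.1, 1.0, 10.0)
            ],
        ),
        RegressorAdapter(
            "gaussian_process",
            build=lambda p: make_pipeline(
                StandardScaler(),
                GaussianProcessRegressor(
                    kernel=RBF() + WhiteKernel(noise_level=p["noise"]),
                    normalize_y=True, random_state=seed),
            ),
            candidates=lambda X, y: [
                {"noise": v} for v in (1e-3, 1e-1, 1e1, 1e4)
            ],
        ),
        RegressorAdapter(
            "xgboost",
            build=lambda p: xgb.XGBRegressor(
                n_estimators=100, random_state=seed, verbosity=0, n_jobs=1, **p),
        ),
    ]
    return adapters


def _generic_nested_cv(matrix: pd.DataFrame, metadata: SampleMetadata,
                       folds: FoldPlan, adapter: RegressorAdapter) -> Evaluation:
    outcome = metadata.outcome
    blinded = {}
    for f in folds:
        Xtr = matrix.loc[list(f.train_ids)]
        ytr = outcome[list(f.train_ids)].to_numpy(float)
        cands = adapter.candidates(Xtr.to_numpy(float), ytr)
        if len(cands) > 1:
            inner = make_loso_folds(metadata.subset(f.train_ids))
            sq = np.zeros(len(cands))
            for g in inner:
                Xi, yi = matrix.loc[list(g.train_ids)], outcome[list(g.train_ids)]
                Xt, yt = matrix.loc[list(g.test_ids)], outcome[list(g.test_ids)]
                for c, params in enumerate(cands):
                    est = adapter.build(params)
                    est.fit(Xi.to_numpy(float), yi.to_numpy(float))
                    pred = est.predict(Xt.to_numpy(float))
                    sq[c] += float(((pred - yt.to_numpy(float)) ** 2).sum())
            best = cands[int(np.argmin(sq))]
        else:
            best = cands[0]
        est = adapter.build(best)
        est.fit(Xtr.to_numpy(float), ytr)
        pred = est.predict(matrix.loc[list(f.test_ids)].to_numpy(float))
        for sid, val in zip(f.test_ids, pred):
            blinded[sid] = float(val)
    order = metadata.pregnancy_sample_ids()
    pred = np.array([blinded[s] for s in order])
    return evaluate_predictions(pred, outcome[order].to_numpy(float))


def benchmark_regressors(cohort: MultiomicsCohort, adapters: list | None = None,
                         folds: FoldPlan | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Compare regressors across modalities under one shared fold plan.

    Returns one row per (regressor, modality) with blinded Spearman rho, p
    and RMSE; adapter failures are isolated per cell and recorded in the
    ``error`` column.  The ``fold_hash`` column is constant by construction
    (every cell uses the identical plan).
    """
    adapters = adapters if adapters is not None else default_adapters(seed)
    folds = folds or make_loso_folds(cohort.metadata)
    sig = folds.signature()
    rows = []
    for name, ds in cohort.datasets.items():
        for ad in adapters:
            row = {"regressor": ad.name, "modality": name, "fold_hash": sig,
                   "rho": np.nan, "p": np.nan, "rmse": np.nan, "error": None}
            try:
                ev = _generic_nested_cv(ds.matrix, cohort.metadata, folds, ad)
                row.update(rho=ev.rho, p=ev.p, rmse=ev.rmse)
            except Exception as exc:  # isolate per cell, keep going
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
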