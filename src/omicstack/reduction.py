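"""Bootstrap model reduction.

To trim each modality's model down to a small, stable feature set:

1. **Stability profile** — refit the elastic net (at the modality's
   full-data inner-selected hyperparameters) on many bootstrap resamples of
   the pregnancy samples and average the absolute coefficients per feature.
2. **Threshold sweep** — retain the features whose profile exceeds each of
   a range of thresholds and re-run the full nested CV on each retained
   subset, under the *same* fold plan as the full model.
3. **Breakpoint selection** — fit a two-segment continuous ("broken-stick")
   linear regression of model quality against retained feature count and
   keep the feature count at the knee, breaking ties toward fewer features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import CVResult, FoldPlan, HyperGrid, run_nested_cv
from .datamodel import OmicsDataset, SampleMetadata
from .elastic_net import ENHyperparams, fit_en
from .errors import InsufficientDataError, ValidationError


@dataclass
class BootstrapProfile:
    """Per-feature mean absolute elastic-net coefficient across resamples."""

    modality_name: str
    values: pd.Series          # index = feature ids, >= 0
    hyperparams: ENHyperparams
    n_iterations: int
    draw_size: int
    seed: int

    def top_features(self, k: int) -> list:
        return self.values.sort_values(ascending=False).head(k).index.tolist()


def bootstrap_coefficients(dataset: OmicsDataset, metadata: SampleMetadata,
                           hp: ENHyperparams, n_iterations: int = 100,
                           draw_size: int | None = None,
                           seed: int = 0,
                           identity_draws: bool = False) -> BootstrapProfile:
    """Average |coefficient| over elastic nets fit on bootstrap resamples.

    Each iteration draws ``draw_size`` pregnancy samples with replacement
    (default: the full training sample count) and refits at the fixed
    hyperparameters `hp`.  Features that are constant within a draw
    contribute a zero coefficient for that draw.  Deterministic under
    `seed`.  ``identity_draws`` replaces the resampling with the full
    sample in order — a degenerate diagnostic configuration whose profile
    equals the single full-data fit's |coefficients|.
    """
    samples = [s for s in metadata.pregnancy_sample_ids()
               if s in set(dataset.sample_ids)]
    if draw_size is None:
        draw_size = len(samples)
    if draw_size < 3:
        raise ValidationError("draw_size must be >= 3")
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if dataset.n_missing:
        raise ValidationError("impute before bootstrapping")

    rng = np.random.default_rng(seed)
    matrix = dataset.matrix.loc[samples]
    outcome = metadata.outcome[samples]
    acc = np.zeros(dataset.n_features)
    for _ in range(n_iterations):
        if identity_draws:
            idx = np.arange(len(samples))
        else:
            idx = rng.integers(0, len(samples), size=draw_size)
        Xb = matrix.iloc[idx]
        yb = outcome.iloc[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance features in a draw
            model = fit_en(Xb, yb, hp)
        acc += np.abs(model.coef_)
    values = pd.Series(acc / n_iterations, index=dataset.feature_ids,
                       name="mean_abs_coef")
    return BootstrapProfile(dataset.modality_name, values, hp,
                            n_iterations, draw_size, seed)


@dataclass
class ReductionCurve:
    """Threshold sweep results and the selected feature count.

    ``table`` rows are sorted by retained feature count and hold, per
    threshold: n_features, blinded rho / p / RMSE of the refit reduced
    model.  ``selected_n_features`` is the knee of the piecewise fit (None
    when the curve has fewer than 5 points).
    """

    modality_name: str
    table: pd.DataFrame
    selected_n_features: int | None
    selected_features: list
    skipped_thresholds: list
    results: dict  # threshold -> CVResult


def threshold_sweep(profile: BootstrapProfile, dataset: OmicsDataset,
                    metadata: SampleMetadata, grid: HyperGrid | None = None,
                    folds: FoldPlan | None = None,
                    n_thresholds: int | None = None,
                    criterion: str = "p") -> ReductionCurve:
    """Refit the nested CV at each stability threshold and pick the knee.

    Thresholds are the unique positive profile values (optionally reduced
    to ``n_thresholds`` evenly spaced quantiles of them); a feature is
    retained when its profile value is >= the threshold, so the lowest
    threshold keeps every feature with a nonzero profile.  Every refit uses
    the caller's fold plan, keeping reduced-model evaluations comparable to
    the full model's.  `criterion` chooses the knee's y-axis: ``"p"`` uses
    -log10 blinded Spearman p (quality; higher is better), ``"rmse"`` the
    blinded RMSE.
    """
    if criterion not in ("p", "rmse"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    vals = profile.values
    thresholds = np.unique(vals[vals > 0].to_numpy())
    if thresholds.size == 0:
        raise ValidationError("profile has no nonzero values")
    if n_thresholds is not None and thresholds.size > n_thresholds:
        qs = np.linspace(0, 1, n_thresholds)
        thresholds = np.unique(np.quantile(thresholds, qs, method="lower"))

    rows, skipped, results = [], [], {}
    for t in thresholds:
        feats = vals.index[vals.to_numpy() >= t].tolist()
        if not feats:
            skipped.append(float(t))
            continue
        res = run_nested_cv(dataset.subset_features(feats), metadata,
                            grid, folds)
        results[float(t)] = res
        ev = res.blinded_eval
        rows.append({"threshold": float(t), "n_features": len(feats),
                     "rho": ev.rho, "p": ev.p, "rmse": ev.rmse})
    table = pd.DataFrame(rows).sort_values("n_features").reset_index(drop=True)

    selected_n, selected_feats = None, []
    if len(table) >= 5:
        xs = table["n_features"].to_numpy(float)
        if criterion == "p":
            ys = -np.log10(np.maximum(table["p"].to_numpy(float), 1e-300))
        else:
            ys = table["rmse"].to_numpy(float)
        selected_n = int(piecewise_breakpoint(xs, ys))
        selected_feats = profile.top_features(selected_n)
    return ReductionCurve(profile.modality_name, table, selected_n,
                          selected_feats, skipped, results)


def piecewise_breakpoint(xs, ys) -> float:
    """Knee of a two-segment continuous linear fit.

    Exhaustively tries every observed x as the breakpoint of the hinge
    model ``y = b0 + b1 (x - c) + b2 max(x - c, 0)`` and returns the x
    minimizing total SSE; ties (including the degenerate all-equal case of
    perfectly linear data) break toward the smallest x, i.e. toward fewer
    features.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValidationError("xs and ys must be equal-length vectors")
    if len(xs) < 5:
        raise InsufficientDataError("piecewise fit needs >= 5 points")
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    best_sse, best_x = np.inf, None
    for c in np.unique(xs):
        h = np.maximum(xs - c, 0.0)
        A = np.column_stack([np.ones_like(xs), xs - c, h])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        sse = float(((A @ coef - ys) ** 2).sum())
        if sse < best_sse - 1e-12 or (
            abs(sse - best_sse) <= 1e-12 and (best_x is None or c < best_x)
        ):
            best_sse, best_x = sse, float(c)
    return best_x
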