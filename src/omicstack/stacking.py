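"""Stacked generalization across modalities with synchronized folds.

Each modality first gets its own elastic net under two-layer LOSO
cross-validation.  The per-modality gestational-age estimates then become
the features of a *meta* elastic net — essentially a weighted average of the
base models, with the weights learned.  Cross-validation folds are
synchronized between layers: the meta model of fold f is trained and
evaluated exclusively on base predictions produced by fold f's base models,
which never saw the held-out subject.  Hence a subject's stacked blinded
prediction is blinded to that subject at *every* layer.

Fitted fold models (base and meta) are retained so the whole stack can be
applied post hoc to samples outside the fold plan — notably postpartum
visits, where the per-modality prediction trajectories show how fast each
biological modality reverts toward a non-pregnant state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import (
    CVResult,
    Evaluation,
    FoldPlan,
    HyperGrid,
    evaluate_predictions,
    inner_select,
    make_loso_folds,
    run_nested_cv,
)
from .datamodel import MultiomicsCohort
from .elastic_net import ElasticNetRegressor, fit_en
from .errors import ApplicationError, SynchronizationError, ValidationError


@dataclass
class StackedModel:
    """A fitted stack: per-modality CV results plus the meta layer.

    ``meta_model`` is the summary elastic net fit on the full out-of-fold
    blinded base-prediction matrix; because the elastic net standardizes its
    features internally, its coefficients are directly comparable across
    modalities and serve as the importance measure for ablation.
    ``meta_cv`` holds the fold-synchronized blinded/training stacked
    predictions and their evaluation.
    """

    modality_names: list
    base_results: dict
    meta_cv: CVResult
    meta_model: ElasticNetRegressor
    meta_features: pd.DataFrame
    folds: FoldPlan

    @property
    def meta_coefficients(self) -> pd.Series:
        return pd.Series(self.meta_model.coef_, index=self.meta_model.feature_ids_,
                         name="meta_coefficient")


def _fold_prediction_matrix(base_results: dict, matrix_samples, modalities,
                            cohort: MultiomicsCohort, fold_subject: str) -> pd.DataFrame:
    """Predictions of fold `fold_subject`'s base models on given samples."""
    cols = {}
    for m in modalities:
        model = base_results[m].fold_models[fold_subject]
        cols[m] = model.predict(cohort.datasets[m].matrix.loc[list(matrix_samples)])
    return pd.DataFrame(cols, index=list(matrix_samples))


def stack(cohort: MultiomicsCohort, grid: HyperGrid | None = None,
          folds: FoldPlan | None = None, base_results: dict | None = None,
          meta_grid: HyperGrid | None = None) -> StackedModel:
    """Fit the full two-layer stack on an imputed, aligned cohort.

    Parameters
    ----------
    base_results : optional precomputed per-modality :class:`CVResult` map
        (they are deterministic given the fold plan, so callers such as
        :func:`ablate` reuse them).  Their fold plans must match `folds`
        exactly; a mismatch is a hard synchronization failure.
    """
    grid = grid or HyperGrid()
    meta_grid = meta_grid or grid
    folds = folds or make_loso_folds(cohort.metadata)
    modalities = cohort.modality_names
    if any(ds.n_missing for ds in cohort.datasets.values()):
        raise ValidationError("cohort must be imputed before stacking")

    if base_results is None:
        base_results = {
            m: run_nested_cv(cohort.datasets[m], cohort.metadata, grid, folds)
            for m in modalities
        }
    else:
        base_results = {m: base_results[m] for m in modalities}
        sig = folds.signature()
        for m, res in base_results.items():
            if res.folds.signature() != sig:
                raise SynchronizationError(
                    f"base result {m!r} was computed under a different fold plan"
                )

    metadata = cohort.metadata
    outcome = metadata.outcome
    order = metadata.pregnancy_sample_ids()

    meta_fold_models, meta_fold_hp = {}, {}
    blinded = {}
    train_preds: dict[str, list[float]] = {}
    for f in folds:
        F_tr = _fold_prediction_matrix(base_results, f.train_ids, modalities,
                                       cohort, f.subject_id)
        F_te = _fold_prediction_matrix(base_results, f.test_ids, modalities,
                                       cohort, f.subject_id)
        ytr = outcome[list(f.train_ids)]
        hp = inner_select(F_tr, ytr, metadata.subset(f.train_ids), meta_grid)
        mm = fit_en(F_tr, ytr, hp)
        meta_fold_models[f.subject_id] = mm
        meta_fold_hp[f.subject_id] = hp
        for sid, val in zip(f.test_ids, mm.predict(F_te)):
            blinded[sid] = float(val)
        for sid, val in zip(f.train_ids, mm.predict(F_tr)):
            train_preds.setdefault(sid, []).append(float(val))

    blinded_s = pd.Series({s: blinded[s] for s in order})[order]
    training_s = pd.Series(
        {s: float(np.median(train_preds[s])) for s in order})[order]
    truth = outcome[order]
    meta_cv = CVResult(
        name="stacked",
        truth=truth,
        blinded_predictions=blinded_s,
        training_predictions=training_s,
        fold_hyperparams=meta_fold_hp,
        fold_models=meta_fold_models,
        folds=folds,
        blinded_eval=evaluate_predictions(blinded_s, truth),
        training_eval=evaluate_predictions(training_s, truth),
    )

    # summary meta model on the full out-of-fold blinded prediction matrix
    meta_features = pd.DataFrame(
        {m: base_results[m].blinded_predictions for m in modalities}
    ).loc[order]
    hp_full = inner_select(meta_features, truth, metadata.subset(order), meta_grid)
    meta_model = fit_en(meta_features, truth, hp_full)

    return StackedModel(
        modality_names=list(modalities),
        base_results=base_results,
        meta_cv=meta_cv,
        meta_model=meta_model,
        meta_features=meta_features,
        folds=folds,
    )


def apply_models(stacked: StackedModel, cohort: MultiomicsCohort,
                 target_visits: set | None = None) -> pd.DataFrame:
    """Apply the fitted fold models to arbitrary samples without refitting.

    For each target sample the prediction (per modality and stacked) is the
    median over the fold models whose training included that subject's
    pregnancy samples — i.e. every fold except the subject's own.  Applied
    to the pregnancy visits this reproduces the CV training predictions
    exactly; applied to postpartum visits it quantifies how far each
    modality's clock has reverted.

    Returns a table indexed by sample id with subject, visit, outcome, one
    column per modality and a ``stacked`` column.
    """
    meta = cohort.metadata
    if target_visits is None:
        targets = meta.sample_ids
    else:
        targets = [s for s in meta.sample_ids if meta.visit[s] in target_visits]
    if not targets:
        raise ApplicationError("no samples match the requested visits")
    for m in stacked.modality_names:
        if m not in cohort.datasets:
            raise ApplicationError(f"cohort lacks modality {m!r}")
        missing = set(targets) - set(cohort.datasets[m].sample_ids)
        if missing:
            raise ApplicationError(
                f"modality {m!r} lacks target samples: {sorted(missing)[:5]}"
            )

    subjects = meta.subject
    fold_subjects = stacked.folds.subjects
    # per fold: base predictions (n_targets x M) and stacked predictions
    base_per_fold, stacked_per_fold = {}, {}
    for fs in fold_subjects:
        F = _fold_prediction_matrix(stacked.base_results, targets,
                                    stacked.modality_names, cohort, fs)
        base_per_fold[fs] = F
        stacked_per_fold[fs] = stacked.meta_cv.fold_models[fs].predict(F)

    rows = {}
    for i, sid in enumerate(targets):
        use = [fs for fs in fold_subjects if fs != subjects[sid]] or fold_subjects
        row = {
            m: float(np.median([base_per_fold[fs].iloc[i][m] for fs in use]))
            for m in stacked.modality_names
        }
        row["stacked"] = float(np.median([stacked_per_fold[fs][i] for fs in use]))
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index").loc[targets]
    out.insert(0, "subject_id", [subjects[s] for s in targets])
    out.insert(1, "visit", [meta.visit[s] for s in targets])
    out.insert(2, "outcome", [meta.outcome[s] for s in targets])
    out.index.name = "sample_id"
    return out


@dataclass
class AblationTrace:
    """Record of iterative modality removal from the stack.

    ``records[k]`` describes the stack over the remaining ``M - k``
    modalities: the meta coefficients, the blinded evaluation, the modality
    removed next, and whether a tie was broken lexicographically.
    """

    order: str
    removed: list
    records: list

    def coefficients_frame(self) -> pd.DataFrame:
        """(iteration x modality) meta-coefficient table, NaN once removed."""
        return pd.DataFrame([r["coefficients"] for r in self.records])

    def evaluations(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"iteration": k, "n_modalities": len(r["modalities"]),
                 "removed": r["removed"], "rho": r["evaluation"].rho,
                 "p": r["evaluation"].p, "rmse": r["evaluation"].rmse}
                for k, r in enumerate(self.records)
            ]
        )


def ablate(cohort: MultiomicsCohort, grid: HyperGrid | None = None,
           folds: FoldPlan | None = None, order: str = "most_important",
           base_results: dict | None = None,
           meta_grid: HyperGrid | None = None) -> AblationTrace:
    """Iteratively remove modalities from the stack and re-fit the meta layer.

    Importance is the absolute meta coefficient of the current stack's
    summary model (the elastic net standardizes its features, so magnitudes
    are comparable).  ``most_important`` removes the argmax each iteration,
    ``least_important`` the argmin; ties break lexicographically by modality
    name and are flagged in the trace.  Base per-modality CV results do not
    depend on which modalities remain, so they are computed once and reused.
    """
    if order not in ("most_important", "least_important"):
        raise ValidationError(f"unknown ablation order {order!r}")
    if len(cohort.datasets) < 2:
        raise ValidationError("ablation needs at least 2 modalities")
    grid = grid or HyperGrid()
    folds = folds or make_loso_folds(cohort.metadata)
    if base_results is None:
        base_results = {
            m: run_nested_cv(cohort.datasets[m], cohort.metadata, grid, folds)
            for m in cohort.modality_names
        }

    current = list(cohort.modality_names)
    removed, records = [], []
    while current:
        sub = cohort.subset_modalities(current)
        st = stack(sub, grid, folds,
                   base_results={m: base_results[m] for m in current},
                   meta_grid=meta_grid)
        coefs = st.meta_coefficients
        imp = coefs.abs()
        best = imp.max() if order == "most_important" else imp.min()
        candidates = sorted(imp.index[np.isclose(imp, best)])
        choice = candidates[0]
        records.append({
            "modalities": list(current),
            "coefficients": coefs.to_dict(),
            "evaluation": st.meta_cv.blinded_eval,
            "removed": choice,
            "tie_broken": len(candidates) > 1,
        })
        removed.append(choice)
        current.remove(choice)
    return AblationTrace(order=order, removed=removed, records=records)
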