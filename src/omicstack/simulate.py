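"""Synthetic longitudinal multiomics cohort generator.

The generator emulates the statistical design the pipeline assumes: a cohort
of subjects sampled at three pregnancy visits (first, second and third
trimester), optionally once postpartum, with several omics modalities
measured on every sample.  Each modality is a latent-block factor model:

* features are partitioned into ``n_latent`` correlated blocks;
* informative blocks carry a shared continuous "clock" signal that is
  linear in gestational age (``latent = signal_strength * ga + subject
  effect``), uninformative blocks are pure noise plus the subject effect;
* each feature loads on its block's latent value with an individual loading
  and adds independent Gaussian noise;
* a per-(subject, block) random intercept induces the intra-subject
  correlation that subject-blocked cross-validation exists to guard against;
* postpartum latent state interpolates, by ``recovery_rate``, between the
  third-trimester endpoint (no recovery) and a pre-pregnancy baseline
  defined as the week-0 extrapolation of the linear clock (full recovery,
  hence *below* the first-trimester level);
* missing entries are injected completely at random.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import MultiomicsCohort, OmicsDataset, SampleMetadata
from .errors import ValidationError

#: Standard deviation of uninformative latent factors, chosen on the same
#: scale as the clock spread so noise blocks are not trivially small.
UNINFORMATIVE_LATENT_SD = 3.0


@dataclass(frozen=True)
class ModalitySpec:
    """Generating parameters for one synthetic modality.

    Parameters
    ----------
    name : modality identifier.
    n_features : number of measured features.
    n_latent : number of correlated feature blocks; controls modularity.
    signal_strength : latent-units per week of gestational age on the
        informative blocks (0 = pure-noise modality).
    n_informative_latent : how many of the blocks carry the clock signal.
    noise_sd : per-feature Gaussian noise standard deviation.
    missing_rate : MCAR missingness probability per cell.
    recovery_rate : 1 = postpartum latent state reverts fully to the
        pre-pregnancy baseline (below T1); 0 = remains at the T3 level.
    """

    name: str
    n_features: int
    n_latent: int
    signal_strength: float = 0.5
    n_informative_latent: int = 1
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    recovery_rate: float = 0.5

    def __post_init__(self):
        if self.n_features < 1 or self.n_latent < 1:
            raise ValidationError(f"{self.name}: n_features/n_latent must be >= 1")
        if self.n_features < self.n_latent:
            raise ValidationError(f"{self.name}: n_features < n_latent")
        if self.signal_strength < 0 or self.noise_sd <= 0:
            raise ValidationError(f"{self.name}: bad signal_strength/noise_sd")
        if self.signal_strength > 0 and self.n_informative_latent < 1:
            raise ValidationError(
                f"{self.name}: signal_strength > 0 needs n_informative_latent >= 1"
            )
        if self.n_informative_latent > self.n_latent:
            raise ValidationError(f"{self.name}: n_informative_latent > n_latent")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError(f"{self.name}: missing_rate must be in [0, 1)")
        if not (0.0 <= self.recovery_rate <= 1.0):
            raise ValidationError(f"{self.name}: recovery_rate must be in [0, 1]")


#: Trimester sampling windows in weeks of gestation.
DEFAULT_VISIT_WINDOWS = {"T1": (7.0, 14.0), "T2": (15.0, 20.0), "T3": (24.0, 32.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Full design of a synthetic cohort."""

    n_subjects: int = 17
    visit_windows: dict = field(default_factory=lambda: dict(DEFAULT_VISIT_WINDOWS))
    include_postpartum: bool = False
    subject_effect_sd: float = 1.0
    modalities: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.subject_effect_sd < 0:
            raise ValidationError("subject_effect_sd must be >= 0")
        if not self.modalities:
            raise ValidationError("at least one ModalitySpec is required")
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            raise ValidationError("modality names must be unique")
        wins = [self.visit_windows[v] for v in ("T1", "T2", "T3")]
        for (lo, hi) in wins:
            if not (0 < lo < hi):
                raise ValidationError("visit windows must satisfy 0 < lo < hi")
        if not (wins[0][1] < wins[1][0] < wins[1][1] < wins[2][0]):
            raise ValidationError("visit windows must be non-overlapping, T1<T2<T3")


@dataclass
class GroundTruth:
    """Generator internals for downstream scoring.

    Attributes
    ----------
    outcomes : per-sample gestational age used to build the signal (includes
        the implied week-0 baseline semantics; PP rows hold NaN).
    latents : modality -> (samples x blocks) latent factor values.
    blocks : modality -> list of block records
        ``{"block": int, "informative": bool, "features": [...],
        "loadings": {...}}``.
    """

    outcomes: pd.Series
    latents: dict[str, pd.DataFrame]
    blocks: dict[str, list[dict]]

    def informative_features(self, modality: str) -> list[str]:
        out = []
        for b in self.blocks[modality]:
            if b["informative"]:
                out.extend(b["features"])
        return out


def default_cohort_spec(seed: int = 0, include_postpartum: bool = False) -> CohortSpec:
    """The default study design: 17 subjects x 3 pregnancy visits x 7
    modalities of widely differing feature counts and modularity.

    Feature counts are scaled down from assay-realistic magnitudes to keep
    simulation and cross-validation tractable while preserving the
    qualitative contrasts (a high-dimensional weakly modular transcriptome,
    compact cytokine panels, a noisy microbiome, strongly clocked proteome
    and immunome).
    """
    modalities = (
        ModalitySpec("cellfree_rna", 150, 25, 0.6, 5, 1.0, 0.00, 0.2),
        ModalitySpec("plasma_luminex", 40, 6, 0.5, 2, 1.0, 0.00, 0.5),
        ModalitySpec("serum_luminex", 30, 5, 0.4, 2, 1.0, 0.00, 0.5),
        ModalitySpec("microbiome", 120, 40, 0.3, 4, 2.0, 0.00, 0.9),
        ModalitySpec("immunome", 80, 8, 0.8, 3, 0.8, 0.00, 0.1),
        ModalitySpec("metabolome", 100, 15, 0.7, 4, 1.0, 0.01, 0.8),
        ModalitySpec("proteome", 60, 10, 0.9, 3, 0.7, 0.01, 0.3),
    )
    return CohortSpec(
        n_subjects=17,
        include_postpartum=include_postpartum,
        subject_effect_sd=1.0,
        modalities=modalities,
        seed=seed,
    )


def _sample_outcomes(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-(subject, visit) gestational ages; PP rows get NaN outcome."""
    rows = []
    visits = ["T1", "T2", "T3"] + (["PP"] if spec.include_postpartum else [])
    for i in range(spec.n_subjects):
        subject = f"S{i + 1:02d}"
        for visit in visits:
            if visit == "PP":
                ga = np.nan
            else:
                lo, hi = spec.visit_windows[visit]
                ga = rng.uniform(lo, hi)
            rows.append(
                {"sample_id": f"{subject}_{visit}", "subject_id": subject,
                 "visit": visit, "outcome": ga}
            )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> tuple[MultiomicsCohort, GroundTruth]:
    """Generate a cohort and its ground truth under `spec`.

    Deterministic under ``spec.seed``: the same spec yields bit-identical
    matrices, metadata and missingness masks.
    """
    rng = np.random.default_rng(spec.seed)
    meta_df = _sample_outcomes(spec, rng)
    metadata = SampleMetadata(meta_df)
    sample_ids = metadata.sample_ids
    ga = metadata.outcome.to_numpy(float)          # NaN on PP rows
    visits = metadata.visit.to_numpy()
    subjects = metadata.subject.to_numpy()
    subj_index = {s: k for k, s in enumerate(metadata.subject_ids)}
    # third-trimester outcome per subject, for the no-recovery endpoint
    t3_ga = {
        s: metadata.outcome[(subjects == s) & (visits == "T3")].iloc[0]
        for s in subj_index
    }

    datasets: dict[str, OmicsDataset] = {}
    latents: dict[str, pd.DataFrame] = {}
    blocks_out: dict[str, list[dict]] = {}

    for mod in spec.modalities:
        feature_ids = [f"{mod.name}_f{j + 1:04d}" for j in range(mod.n_features)]
        block_assign = np.array_split(np.arange(mod.n_features), mod.n_latent)
        subj_eff = rng.normal(
            0.0, spec.subject_effect_sd, size=(len(subj_index), mod.n_latent)
        )
        loadings = rng.uniform(0.5, 1.5, size=mod.n_features) * rng.choice(
            [-1.0, 1.0], size=mod.n_features
        )

        L = np.empty((len(sample_ids), mod.n_latent))
        for b in range(mod.n_latent):
            informative = b < mod.n_informative_latent and mod.signal_strength > 0
            for i, sid in enumerate(sample_ids):
                eff = subj_eff[subj_index[subjects[i]], b]
                if informative:
                    if visits[i] == "PP":
                        # interpolate between the T3 endpoint and the week-0
                        # extrapolated baseline (= subject effect alone)
                        endpoint = mod.signal_strength * t3_ga[subjects[i]]
                        L[i, b] = eff + (1.0 - mod.recovery_rate) * endpoint
                    else:
                        L[i, b] = mod.signal_strength * ga[i] + eff
                else:
                    L[i, b] = rng.normal(0.0, UNINFORMATIVE_LATENT_SD) + eff

        X = np.empty((len(sample_ids), mod.n_features))
        for b, feats in enumerate(block_assign):
            for j in feats:
                X[:, j] = loadings[j] * L[:, b] + rng.normal(
                    0.0, mod.noise_sd, size=len(sample_ids)
                )

        if mod.missing_rate > 0:
            mask = rng.random(X.shape) < mod.missing_rate
            X = np.where(mask, np.nan, X)

        datasets[mod.name] = OmicsDataset(
            mod.name, pd.DataFrame(X, index=sample_ids, columns=feature_ids)
        )
        latents[mod.name] = pd.DataFrame(
            L, index=sample_ids, columns=[f"block{b}" for b in range(mod.n_latent)]
        )
        blocks_out[mod.name] = [
            {
                "block": b,
                "informative": bool(b < mod.n_informative_latent
                                    and mod.signal_strength > 0),
                "features": [feature_ids[j] for j in feats],
                "loadings": {feature_ids[j]: float(loadings[j]) for j in feats},
            }
            for b, feats in enumerate(block_assign)
        ]

    cohort = MultiomicsCohort(metadata, datasets)
    truth = GroundTruth(outcomes=metadata.outcome.copy(), latents=latents,
                        blocks=blocks_out)
    return cohort, truth


def inject_missing(dataset: OmicsDataset, rate: float, seed: int) -> OmicsDataset:
    """Flag each entry missing independently with probability `rate`.

    The returned dataset carries the original complete matrix as a
    ``shadow`` attribute so imputation accuracy can be scored afterwards.
    Deterministic under `seed`.
    """
    if not (0.0 <= rate < 1.0):
        raise ValidationError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    X = dataset.matrix.to_numpy(float)
    mask = rng.random(X.shape) < rate
    out = OmicsDataset(
        dataset.modality_name,
        pd.DataFrame(np.where(mask, np.nan, X), index=dataset.sample_ids,
                     columns=dataset.feature_ids),
    )
    out.shadow = dataset.matrix.copy()
    return out
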