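"""Shared fixtures: small synthetic cohorts sized for fast tests."""

import numpy as np
import pandas as pd
import pytest

from omicstack import (
    CohortSpec,
    HyperGrid,
    ModalitySpec,
    MultiomicsCohort,
    OmicsDataset,
    SampleMetadata,
    generate_cohort,
)


def make_metadata(n_subjects: int, seed: int = 0,
                  include_pp: bool = False) -> SampleMetadata:
    """Subjects x trimester visits with outcomes drawn from the standard
    windows."""
    rng = np.random.default_rng(seed)
    windows = {"T1": (7, 14), "T2": (15, 20), "T3": (24, 32)}
    rows = []
    for i in range(n_subjects):
        s = f"S{i + 1:02d}"
        for v in ["T1", "T2", "T3"] + (["PP"] if include_pp else []):
            ga = rng.uniform(*windows[v]) if v != "PP" else np.nan
            rows.append({"sample_id": f"{s}_{v}", "subject_id": s,
                         "visit": v, "outcome": ga})
    return SampleMetadata(pd.DataFrame(rows))


def noisy_copy_cohort(n_subjects: int, noise_sds: dict, seed: int = 0,
                      n_features: int = 1) -> MultiomicsCohort:
    """Each modality's features are independent noisy copies of the outcome.

    ``noise_sds`` maps modality name -> noise standard deviation (weeks);
    a value of None makes the modality pure noise (no outcome signal).
    """
    rng = np.random.default_rng(seed)
    meta = make_metadata(n_subjects, seed=seed)
    ga = meta.outcome.to_numpy(float)
    datasets = {}
    for name, sd in noise_sds.items():
        cols = {}
        for j in range(n_features):
            if sd is None:
                cols[f"{name}_f{j}"] = rng.normal(20.0, 7.0, size=len(meta))
            else:
                cols[f"{name}_f{j}"] = ga + rng.normal(0.0, sd, size=len(meta))
        datasets[name] = OmicsDataset(
            name, pd.DataFrame(cols, index=meta.sample_ids))
    return MultiomicsCohort(meta, datasets)


@pytest.fixture(scope="session")
def tiny_grid():
    return HyperGrid(alphas=(0.1, 0.5, 0.9), n_lambdas=8, lambda_min_ratio=1e-2)


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects, one informative and one pure-noise modality, complete."""
    spec = CohortSpec(
        n_subjects=8,
        modalities=(
            ModalitySpec("signal", n_features=24, n_latent=4,
                         signal_strength=0.8, n_informative_latent=2,
                         noise_sd=0.8),
            ModalitySpec("noise", n_features=16, n_latent=4,
                         signal_strength=0.0, n_informative_latent=0,
                         noise_sd=1.0),
        ),
        seed=7,
    )
    cohort, truth = generate_cohort(spec)
    return cohort, truth
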