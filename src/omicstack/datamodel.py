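"""Core data containers, matrix/metadata I/O, cohort alignment and the
modality-modularity diagnostic.

The in-memory containers are thin, validated wrappers around
:class:`pandas.DataFrame`:

* :class:`SampleMetadata` — one row per sample with subject, visit
  (trimesters T1/T2/T3 or postpartum PP) and the continuous outcome
  (gestational age in weeks at sampling).
* :class:`OmicsDataset` — one modality's samples x features numeric matrix.
  Missing entries are represented as NaN and are always explicit.
* :class:`MultiomicsCohort` — several modalities aligned by sample key onto
  a shared metadata table.

All alignment is key-based on sample identifiers, never positional, so
ordering differences between files cannot silently corrupt data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateDataError,
    IdentifierError,
    ParseError,
    ValidationError,
)

#: Recognised visit labels: three pregnancy trimesters and postpartum.
VISITS = ("T1", "T2", "T3", "PP")

#: Visit labels for which an outcome value is mandatory.
PREGNANCY_VISITS = ("T1", "T2", "T3")

#: Missing tokens accepted on read; `MISSING_TOKEN` is written on output.
MISSING_TOKENS = ("NA", "NaN", "")
MISSING_TOKEN = "NA"

#: Plausibility bounds (weeks) for a gestational-age outcome.
OUTCOME_RANGE = (0.0, 45.0)


class SampleMetadata:
    """Validated sample-level metadata table.

    Parameters
    ----------
    table : pandas.DataFrame
        Must contain columns ``sample_id``, ``subject_id``, ``visit`` and
        ``outcome`` (or be indexed by ``sample_id`` with the other three
        columns).  Outcome may be missing only on PP rows.
    """

    REQUIRED = ("sample_id", "subject_id", "visit", "outcome")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if df.index.name == "sample_id":
            df = df.reset_index()
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"metadata lacks columns: {missing_cols}")
        df = df.loc[:, list(self.REQUIRED)]
        df["sample_id"] = df["sample_id"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
        df["visit"] = df["visit"].astype(str)
        df["outcome"] = pd.to_numeric(df["outcome"], errors="coerce")
        self._df = df.set_index("sample_id", drop=False)
        self._validate()

    def _validate(self) -> None:
        df = self._df
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise IdentifierError(f"duplicate sample_id values: {dup}")
        bad_visits = sorted(set(df["visit"]) - set(VISITS))
        if bad_visits:
            raise ValidationError(
                f"unknown visit labels {bad_visits}; expected one of {VISITS}"
            )
        pair_dup = df.duplicated(subset=["subject_id", "visit"])
        if pair_dup.any():
            pairs = df.loc[pair_dup, ["subject_id", "visit"]].values.tolist()
            raise IdentifierError(f"duplicate (subject_id, visit) pairs: {pairs}")
        preg = df[df["visit"].isin(PREGNANCY_VISITS)]
        bad = preg["outcome"].isna() | ~np.isfinite(preg["outcome"].to_numpy(float))
        if bad.any():
            raise ValidationError(
                "missing/non-finite outcome on pregnancy rows: "
                f"{preg.index[bad].tolist()}"
            )
        lo, hi = OUTCOME_RANGE
        present = df["outcome"].dropna()
        out_of_range = present[(present <= lo) | (present >= hi)]
        if len(out_of_range):
            raise ValidationError(
                f"outcome outside ({lo}, {hi}) weeks for: "
                f"{out_of_range.index.tolist()}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """The underlying table, indexed by sample_id."""
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def subject_ids(self) -> list[str]:
        """Sorted unique subject identifiers."""
        return sorted(self._df["subject_id"].unique())

    @property
    def outcome(self) -> pd.Series:
        return self._df["outcome"]

    @property
    def visit(self) -> pd.Series:
        return self._df["visit"]

    @property
    def subject(self) -> pd.Series:
        return self._df["subject_id"]

    def pregnancy_sample_ids(self) -> list[str]:
        """Sample ids of non-PP (T1/T2/T3) rows, in table order."""
        mask = self._df["visit"].isin(PREGNANCY_VISITS)
        return self._df.index[mask].tolist()

    def subset(self, sample_ids) -> "SampleMetadata":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleMetadata(self._df.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"SampleMetadata({len(self)} samples, "
            f"{len(self.subject_ids)} subjects)"
        )


class OmicsDataset:
    """One modality's samples x features numeric matrix.

    Missing entries are NaN.  Feature identifiers are unique within the
    modality; global uniqueness across modalities is guaranteed by the
    (modality_name, feature_id) pair.
    """

    def __init__(self, modality_name: str, matrix: pd.DataFrame):
        self.modality_name = str(modality_name)
        m = matrix.copy()
        m.index = m.index.astype(str)
        m.columns = m.columns.astype(str)
        dup_f = m.columns[m.columns.duplicated()].unique().tolist()
        if dup_f:
            raise IdentifierError(
                f"{self.modality_name}: duplicate feature ids {dup_f}"
            )
        dup_s = m.index[m.index.duplicated()].unique().tolist()
        if dup_s:
            raise IdentifierError(
                f"{self.modality_name}: duplicate sample ids {dup_s}"
            )
        self.matrix = m.astype(float)
        self.matrix.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.matrix.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.matrix.isna().to_numpy().sum())

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(float)

    def subset_samples(self, sample_ids) -> "OmicsDataset":
        return OmicsDataset(self.modality_name, self.matrix.loc[list(sample_ids)])

    def subset_features(self, feature_ids) -> "OmicsDataset":
        return OmicsDataset(self.modality_name, self.matrix.loc[:, list(feature_ids)])

    def copy(self) -> "OmicsDataset":
        return OmicsDataset(self.modality_name, self.matrix)

    def __repr__(self) -> str:
        return (
            f"OmicsDataset({self.modality_name!r}, {self.n_samples} samples x "
            f"{self.n_features} features, {self.n_missing} missing)"
        )


@dataclass
class MultiomicsCohort:
    """Named modalities aligned on a shared metadata table.

    Invariant: every dataset's rows are exactly the metadata's samples, in
    metadata order.  Construct through :func:`align_cohort` to enforce it.
    """

    metadata: SampleMetadata
    datasets: dict[str, OmicsDataset]
    dropped_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        meta_ids = self.metadata.sample_ids
        for name, ds in self.datasets.items():
            if ds.sample_ids != meta_ids:
                raise AlignmentError(
                    f"dataset {name!r} rows do not match metadata samples"
                )

    @property
    def modality_names(self) -> list[str]:
        return list(self.datasets)

    @property
    def n_instances(self) -> int:
        """Total sample-modality instances (datasets x samples)."""
        return len(self.datasets) * len(self.metadata)

    def subset_modalities(self, names) -> "MultiomicsCohort":
        return MultiomicsCohort(
            self.metadata, {n: self.datasets[n] for n in names}
        )

    def __repr__(self) -> str:
        return (
            f"MultiomicsCohort({len(self.datasets)} modalities x "
            f"{len(self.metadata)} samples)"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_omics_matrix(path, modality_name: str, delimiter: str | None = None) -> OmicsDataset:
    """Read a samples x features matrix from a delimited text file.

    First row holds feature ids, first column holds sample ids.  Cells must
    be numeric or one of the missing tokens ``NA``/``NaN``/empty; anything
    else raises :class:`ParseError` with its coordinates.
    """
    sep = _sniff_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dup = [h for h in set(header[1:]) if header[1:].count(h) > 1]
    if dup:
        raise IdentifierError(f"{path}: duplicate feature ids {sorted(dup)}")
    raw = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    raw.index = raw.index.astype(str)
    parsed = {}
    for col in raw.columns:
        cell = raw[col].str.strip()
        parsed[col] = _exact_floats(cell, path, col)
    matrix = pd.DataFrame(parsed, index=raw.index)
    return OmicsDataset(modality_name, matrix)


def _exact_floats(cell: pd.Series, path, col) -> np.ndarray:
    """Parse a string column with Python's exact float conversion.

    ``pandas.to_numeric`` can be off by an ulp on long decimals, which would
    break the exact read/write round-trip contract."""
    out = np.empty(len(cell), float)
    for i, v in enumerate(cell):
        if v in MISSING_TOKENS:
            out[i] = np.nan
            continue
        try:
            out[i] = float(v)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric cell at row {cell.index[i]!r}, "
                f"column {col!r}: {v!r}"
            ) from None
    return out


def write_omics_matrix(dataset: OmicsDataset, path, delimiter: str | None = None) -> None:
    """Write a matrix in the format :func:`read_omics_matrix` reads.

    Deterministic: fixed column order (the dataset's), shortest-exact float
    repr, canonical missing token."""
    sep = _sniff_delimiter(path, delimiter)
    dataset.matrix.to_csv(path, sep=sep, na_rep=MISSING_TOKEN)


def read_metadata(path, delimiter: str | None = None) -> SampleMetadata:
    """Read the sample metadata table (sample_id, subject_id, visit, outcome)."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    df = df.replace({c: {t: np.nan for t in MISSING_TOKENS} for c in df.columns})
    if "outcome" in df.columns:
        df["outcome"] = _exact_floats(df["outcome"].fillna("NA"), path, "outcome")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path, delimiter: str | None = None) -> None:
    sep = _sniff_delimiter(path, delimiter)
    metadata.table.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_cohort(datasets, metadata: SampleMetadata, mode: str = "strict") -> MultiomicsCohort:
    """Reconcile modality matrices and metadata onto a common sample set.

    Parameters
    ----------
    datasets : iterable of OmicsDataset or mapping name -> OmicsDataset
    metadata : SampleMetadata
    mode : {"strict", "intersect"}
        ``strict`` raises on any membership mismatch; ``intersect`` keeps the
        common sample set and records dropped ids on the returned cohort.
    """
    if isinstance(datasets, dict):
        ds_map = dict(datasets)
    else:
        ds_map = {d.modality_name: d for d in datasets}
    if not ds_map:
        raise ValidationError("align_cohort needs at least one dataset")
    if len(metadata) == 0:
        raise ValidationError("align_cohort needs non-empty metadata")
    if mode not in ("strict", "intersect"):
        raise ValidationError(f"unknown alignment mode {mode!r}")

    meta_ids = set(metadata.sample_ids)
    common = set(meta_ids)
    for ds in ds_map.values():
        common &= set(ds.sample_ids)

    if mode == "strict":
        for name, ds in ds_map.items():
            if set(ds.sample_ids) != meta_ids:
                extra = sorted(set(ds.sample_ids) - meta_ids)
                missing = sorted(meta_ids - set(ds.sample_ids))
                raise AlignmentError(
                    f"dataset {name!r} membership mismatch "
                    f"(missing {missing}, extra {extra})"
                )
        order = metadata.sample_ids
        aligned = {n: ds.subset_samples(order) for n, ds in ds_map.items()}
        return MultiomicsCohort(metadata, aligned)

    if not common:
        raise AlignmentError("no sample id is shared by all datasets and metadata")
    all_ids = meta_ids.union(*(set(d.sample_ids) for d in ds_map.values()))
    dropped = sorted(all_ids - common)
    meta = metadata.subset(common)
    order = meta.sample_ids
    aligned = {n: ds.subset_samples(order) for n, ds in ds_map.items()}
    return MultiomicsCohort(meta, aligned, dropped_sample_ids=dropped)


# ---------------------------------------------------------------------------
# Modularity diagnostic
# ---------------------------------------------------------------------------

def modularity(dataset: OmicsDataset, variance_fraction: float = 0.9) -> int:
    """Number of principal components needed to reach `variance_fraction`
    of a modality's total variance.

    Computed on columns standardized to zero mean / unit variance
    (correlation-matrix PCA) so the metric is comparable across modalities
    with different units.  Low values indicate highly intercorrelated
    ("modular") features.  Constant columns are dropped (with a warning)
    before the decomposition.
    """
    if not (0.0 < variance_fraction <= 1.0):
        raise ValidationError("variance_fraction must be in (0, 1]")
    if dataset.n_missing:
        raise ValidationError(
            f"{dataset.modality_name}: modularity requires a complete matrix "
            f"({dataset.n_missing} missing entries)"
        )
    if dataset.n_samples < 2:
        raise ValidationError("modularity requires at least 2 samples")
    X = dataset.values()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise DegenerateDataError(
            f"{dataset.modality_name}: all columns constant"
        )
    n_const = int((~keep).sum())
    if n_const:
        warnings.warn(
            f"{dataset.modality_name}: dropped {n_const} constant column(s) "
            "before PCA"
        )
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    sv = np.linalg.svd(Z, compute_uv=False)
    eig = sv ** 2
    frac = np.cumsum(eig) / eig.sum()
    # float-safe: first k with cumulative fraction >= target
    k = int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)
    return min(k, len(eig))
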