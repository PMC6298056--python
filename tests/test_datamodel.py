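"""Containers, I/O round trips, alignment and the modularity diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicstack import (
    OmicsDataset,
    SampleMetadata,
    align_cohort,
    modularity,
    read_metadata,
    read_omics_matrix,
    write_metadata,
    write_omics_matrix,
)
from omicstack.errors import (
    AlignmentError,
    DegenerateDataError,
    IdentifierError,
    ParseError,
    ValidationError,
)
from conftest import make_metadata


def _dataset(matrix, name="m", samples=None, features=None):
    n, p = matrix.shape
    samples = samples or [f"s{i}" for i in range(n)]
    features = features or [f"f{j}" for j in range(p)]
    return OmicsDataset(name, pd.DataFrame(matrix, index=samples, columns=features))


class TestMatrixIO:
    def test_missing_token_flagged(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,f1,f2\ns1,1.0,2.0\ns2,NA,3.0\ns3,4.0,5.0\n")
        ds = read_omics_matrix(path, "m")
        assert ds.n_missing == 1
        assert np.isnan(ds.matrix.loc["s2", "f1"])
        assert ds.matrix.loc["s3", "f2"] == 5.0

    def test_duplicate_feature_header_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,f1,f1\ns1,1,2\n")
        with pytest.raises(IdentifierError):
            read_omics_matrix(path, "m")

    def test_non_numeric_cell_reported_with_coordinates(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,f1,f2\ns1,1.0,oops\ns2,2.0,3.0\n")
        with pytest.raises(ParseError, match="s1.*f2"):
            read_omics_matrix(path, "m")

    @pytest.mark.parametrize("suffix,with_missing", [(".csv", False),
                                                     (".csv", True),
                                                     (".tsv", True)])
    def test_round_trip_identity(self, tmp_path, suffix, with_missing):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 10)) * 10.0 ** rng.integers(-3, 4, size=(10, 10))
        if with_missing:
            X[rng.random(X.shape) < 0.1] = np.nan
        ds = _dataset(X)
        path = tmp_path / f"m{suffix}"
        write_omics_matrix(ds, path)
        back = read_omics_matrix(path, "m")
        assert back.feature_ids == ds.feature_ids
        assert back.sample_ids == ds.sample_ids
        pd.testing.assert_frame_equal(back.matrix, ds.matrix)


class TestMetadata:
    def test_study_geometry_accepted(self):
        meta = make_metadata(17)
        assert len(meta) == 51
        assert len(meta.subject_ids) == 17

    def test_pregnancy_row_requires_outcome(self):
        df = make_metadata(3).table.reset_index(drop=True)
        df.loc[df["visit"] == "T2", "outcome"] = np.nan
        with pytest.raises(ValidationError):
            SampleMetadata(df)

    def test_postpartum_row_may_lack_outcome(self):
        meta = make_metadata(3, include_pp=True)
        assert meta.outcome.isna().sum() == 3
        assert len(meta.pregnancy_sample_ids()) == 9

    def test_duplicate_sample_id_rejected(self):
        df = make_metadata(3).table.reset_index(drop=True)
        df.loc[1, "sample_id"] = df.loc[0, "sample_id"]
        with pytest.raises(IdentifierError):
            SampleMetadata(df)

    def test_outcome_range_enforced(self):
        df = make_metadata(3).table.reset_index(drop=True)
        df.loc[0, "outcome"] = 50.0
        with pytest.raises(ValidationError):
            SampleMetadata(df)

    def test_metadata_round_trip(self, tmp_path):
        meta = make_metadata(4, include_pp=True)
        path = tmp_path / "meta.csv"
        write_metadata(meta, path)
        assert read_metadata(path) == meta


class TestAlignment:
    def test_full_study_instance_count(self):
        meta = make_metadata(17)
        rng = np.random.default_rng(0)
        datasets = [
            _dataset(rng.normal(size=(51, 3)), name=f"mod{k}",
                     samples=meta.sample_ids)
            for k in range(7)
        ]
        cohort = align_cohort(datasets, meta, mode="strict")
        assert cohort.n_instances == 357

    def test_strict_rejects_membership_mismatch(self):
        meta = make_metadata(4)
        rng = np.random.default_rng(0)
        full = _dataset(rng.normal(size=(12, 2)), "a", samples=meta.sample_ids)
        short = _dataset(rng.normal(size=(11, 2)), "b",
                         samples=meta.sample_ids[:-1])
        with pytest.raises(AlignmentError):
            align_cohort([full, short], meta, mode="strict")

    def test_intersect_drops_and_reports(self):
        meta = make_metadata(4)
        rng = np.random.default_rng(0)
        full = _dataset(rng.normal(size=(12, 2)), "a", samples=meta.sample_ids)
        short = _dataset(rng.normal(size=(11, 2)), "b",
                         samples=meta.sample_ids[:-1])
        cohort = align_cohort([full, short], meta, mode="intersect")
        assert len(cohort.metadata) == 11
        assert cohort.dropped_sample_ids == [meta.sample_ids[-1]]

    def test_empty_intersection_is_an_error(self):
        meta = make_metadata(3)
        ds = _dataset(np.zeros((2, 2)), "a", samples=["x1", "x2"])
        with pytest.raises(AlignmentError):
            align_cohort([ds], meta, mode="intersect")

    def test_alignment_is_key_based_not_positional(self):
        meta = make_metadata(3)
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(9, 2)), index=meta.sample_ids,
                          columns=["f0", "f1"])
        shuffled = OmicsDataset("a", df.iloc[::-1])
        cohort = align_cohort([shuffled], meta, mode="strict")
        pd.testing.assert_frame_equal(cohort.datasets["a"].matrix,
                                      OmicsDataset("a", df).matrix)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(drop=st.lists(st.integers(min_value=0, max_value=8),
                         max_size=5, unique=True),
           which=st.integers(min_value=0, max_value=1))
    def test_intersect_invariants_hold_for_random_membership(self, drop, which):
        meta = make_metadata(3)
        rng = np.random.default_rng(0)
        keep_a = [s for i, s in enumerate(meta.sample_ids)
                  if which == 1 or i not in drop]
        keep_b = [s for i, s in enumerate(meta.sample_ids)
                  if which == 0 or i not in drop]
        a = _dataset(rng.normal(size=(len(keep_a), 2)), "a", samples=keep_a)
        b = _dataset(rng.normal(size=(len(keep_b), 2)), "b", samples=keep_b)
        common = set(keep_a) & set(keep_b)
        if not common:
            with pytest.raises(AlignmentError):
                align_cohort([a, b], meta, mode="intersect")
            return
        cohort = align_cohort([a, b], meta, mode="intersect")
        # membership identical across tables and equal to the intersection
        assert set(cohort.metadata.sample_ids) == common
        for ds in cohort.datasets.values():
            assert ds.sample_ids == cohort.metadata.sample_ids


class TestModularity:
    def test_rank_one_matrix_needs_one_component(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        X = np.tile(col[:, None], (1, 10)) * rng.uniform(0.5, 2.0, size=10)
        assert modularity(_dataset(X)) == 1

    def test_two_orthogonal_factors_need_two_components(self):
        # 5 noiseless columns per latent factor -> exactly 2 PCs carry
        # all variance (verified against the eigendecomposition of the
        # constructed covariance: eigenvalues {5, 5, 0, ...})
        rng = np.random.default_rng(1)
        f1 = rng.normal(size=40)
        f2 = rng.normal(size=40)
        f2 -= f1 * (f1 @ f2) / (f1 @ f1)  # orthogonalize
        X = np.column_stack([f1] * 5 + [f2] * 5)
        X = X * rng.uniform(0.5, 2.0, size=10)
        assert modularity(_dataset(X)) == 2

    def test_independent_noise_needs_nearly_all_components(self):
        ks = []
        for seed in range(11):
            X = np.random.default_rng(seed).normal(size=(500, 10))
            k = modularity(_dataset(X))
            assert k in (8, 9, 10)
            ks.append(k)
        assert int(np.median(ks)) == 9

    def test_non_increasing_in_variance_fraction(self):
        X = np.random.default_rng(5).normal(size=(40, 12))
        ds = _dataset(X)
        ks = [modularity(ds, f) for f in (0.5, 0.7, 0.9, 0.99, 1.0)]
        assert ks == sorted(ks)
        assert ks[-1] <= min(39, 12)

    def test_all_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            modularity(_dataset(np.ones((5, 3))))

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        X[:, 2] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            k = modularity(_dataset(X))
        assert k >= 1

    def test_missing_entries_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            modularity(_dataset(X))
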