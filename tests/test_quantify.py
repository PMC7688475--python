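"""Latent-Gaussian quantification, dummy coding, optimal scaling, PCA helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from medtraj.quantify import (
    dummy_encode,
    estimate_intrinsic_dimension_pca,
    optimal_scaling,
    quantify_dataset,
    quantify_ordinal_univariate,
    reduce_dimension,
    zscore,
)


def _oracle_scores(counts):
    """Independent normal-quantile oracle for the level scores."""
    p = np.asarray(counts, float) / np.sum(counts)
    return norm.ppf(np.cumsum(p) - p / 2)


class TestUnivariateQuantification:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 5), (-0.6745, 0.6745)),
            ((1, 2, 1), (-1.1503, 0.0, 1.1503)),
        ],
    )
    def test_known_quantiles(self, counts, expected):
        assert quantify_ordinal_univariate(counts) == pytest.approx(expected, abs=1e-4)

    def test_single_level_scores_zero(self):
        assert quantify_ordinal_univariate([17]) == pytest.approx([0.0])

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            quantify_ordinal_univariate([0, 0])

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_quantile_oracle(self, counts):
        scores = quantify_ordinal_univariate(counts)
        assert np.allclose(scores, _oracle_scores(counts), atol=1e-10)
        assert (np.diff(scores) > 0).all() or len(counts) == 1


class TestDummyEncode:
    def test_keep_all_rows_sum_to_one(self):
        s = pd.Series(["a", "b", "c", "a"], name="grp")
        d = dummy_encode(s, ["a", "b", "c"])
        assert d.shape == (4, 3)
        assert (d.sum(axis=1) == 1).all()

    def test_drop_first(self):
        s = pd.Series(["a", "b", "c"], name="grp")
        assert dummy_encode(s, ["a", "b", "c"], drop_first=True).shape == (3, 2)

    def test_seven_level_outcome_encoding(self):
        # cause-of-death style field: 7 nonzero causes -> 7 binary features
        s = pd.Series([str(i % 7 + 1) for i in range(21)], name="cause")
        d = dummy_encode(s, [str(i) for i in range(1, 8)])
        assert d.shape[1] == 7

    def test_missing_propagates_to_all_dummies(self):
        s = pd.Series(["a", None, "b"], name="grp")
        d = dummy_encode(s, ["a", "b"], missing=s.isna())
        assert d.iloc[1].isna().all()

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            dummy_encode(pd.Series(["a"], name="g"), ["a"])


class TestQuantifyDataset:
    def test_mixed_fixture_shapes_and_nans(self, small_mixed):
        qm = quantify_dataset(small_mixed)
        # sev, flag, bp pass through; grp expands to 3 dummies
        assert qm.data.shape == (4, 6)
        assert qm.data.isna().to_numpy().sum() == 3  # one missing cell each in sev/flag/bp
        assert qm.kinds["sev"] == "ordinal" and qm.kinds["grp=a"] == "binary"

    def test_binary_treated_as_two_level_ordinal(self, small_mixed):
        qm = quantify_dataset(small_mixed)
        scores = qm.maps["flag"].scores
        assert len(scores) == 2 and scores[0] < scores[1]


class TestOptimalScaling:
    def _qm(self, codes, n_levels, extra=None, seed=0):
        from medtraj.datasets import MixedDataset, VariableMeta

        cols, meta = {}, []
        for name, c in codes.items():
            cols[name] = pd.Series([str(v) for v in c])
            meta.append(VariableMeta(name, "ordinal", tuple(str(i) for i in range(n_levels))))
        if extra is not None:
            for name, v in extra.items():
                cols[name] = pd.Series(v)
                meta.append(VariableMeta(name, "continuous"))
        df = pd.DataFrame(cols)
        ds = MixedDataset(df, df.isna(), meta)
        return quantify_dataset(ds)

    def test_identical_columns_reach_perfect_correlation(self):
        codes = list(np.tile([0, 1, 2, 3], 10))
        qm = self._qm({"a": codes, "b": codes}, 4)
        out, trace = optimal_scaling(qm)
        assert trace[-1] == pytest.approx(1.0, abs=1e-8)

    def test_objective_trace_monotone_on_binned_latent(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=400)
        codes = {
            "a": np.digitize(z + rng.normal(0, 0.3, 400), [-0.5, 0.5]),
            "b": np.digitize(z + rng.normal(0, 0.3, 400), [-1.0, 0.0, 1.0]),
            "c": np.digitize(z + rng.normal(0, 0.3, 400), [0.0]),
        }
        qm = self._qm({k: list(v) for k, v in codes.items()}, 4)
        out, trace = optimal_scaling(qm)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert trace[-1] >= trace[0]

    def test_rescored_maps_stay_monotone(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=300)
        qm = self._qm(
            {"a": list(np.digitize(z, [-0.5, 0.5]))}, 3,
            extra={"y": -z + rng.normal(0, 0.1, 300)},
        )
        out, _ = optimal_scaling(qm)
        scores = out.maps["a"].scores
        observed = scores[~np.isnan(scores)]
        assert (np.diff(observed) >= -1e-12).all()

    def test_rescored_columns_standardized(self):
        codes = list(np.tile([0, 1, 2], 30))
        qm = self._qm({"a": codes, "b": codes}, 3)
        out, _ = optimal_scaling(qm)
        assert out.data["a"].mean() == pytest.approx(0, abs=1e-9)
        assert out.data["a"].std(ddof=0) == pytest.approx(1, abs=1e-9)


class TestZscore:
    def test_population_convention(self, small_mixed):
        from medtraj.quantify import QuantifiedMatrix

        qm = QuantifiedMatrix(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        out = zscore(qm)
        assert np.allclose(out.data["x"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_standardized_column_unchanged(self):
        from medtraj.quantify import QuantifiedMatrix

        x = np.array([-1.2247448, 0.0, 1.2247448])
        out = zscore(QuantifiedMatrix(pd.DataFrame({"x": x})))
        assert np.allclose(out.data["x"], x, atol=1e-6)

    def test_constant_column_left_at_zero_with_warning(self):
        from medtraj.quantify import QuantifiedMatrix

        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore(QuantifiedMatrix(pd.DataFrame({"x": [2.0, 2.0, 2.0]})))
        assert (out.data["x"] == 0).all()


class TestIntrinsicDimension:
    def test_threshold_rule_on_planted_spectrum(self):
        rng = np.random.default_rng(0)
        # diagonal covariance with eigenvalues 10, 5, 0.5
        X = rng.normal(size=(20000, 3)) * np.sqrt([10.0, 5.0, 0.5])
        assert estimate_intrinsic_dimension_pca(X, C=10) == 2

    def test_isotropic_gaussian_recovers_full_dimension(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 6))
        assert estimate_intrinsic_dimension_pca(X, C=10) == 6

    def test_rank_one_data(self):
        t = np.linspace(0, 1, 50)
        X = np.outer(t, [1.0, 2.0, 3.0])
        assert estimate_intrinsic_dimension_pca(X, C=10) == 1


class TestReduceDimension:
    def test_line_fully_explained_by_one_component(self):
        t = np.linspace(0, 1, 40)
        X = np.column_stack([t, 2 * t])
        _, _, evr = reduce_dimension(X, 1)
        assert evr[0] == pytest.approx(1.0)

    def test_variance_ratio_four_to_one(self):
        rng = np.random.default_rng(2)
        n = 200000
        X = np.column_stack([rng.normal(0, 2, n), rng.normal(0, 1, n)])
        _, _, evr = reduce_dimension(X, 1)
        assert evr[0] == pytest.approx(0.8, abs=0.01)

    def test_matches_spectral_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 10))
        _, _, evr = reduce_dimension(X, 10)
        ev = np.linalg.eigvalsh(np.cov(X - X.mean(0), rowvar=False))[::-1]
        assert np.allclose(evr, ev / ev.sum(), atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            reduce_dimension(np.eye(3), 4)

    def test_rank_n_reconstruction_is_optimal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6))
        scores, loadings, _ = reduce_dimension(X, 2)
        recon = scores @ loadings + X.mean(0)
        err = np.linalg.norm(X - recon)
        # Eckart-Young optimum from a full SVD of the centered matrix
        u, s, vt = np.linalg.svd(X - X.mean(0), full_matrices=False)
        best = np.sqrt(np.sum(s[2:] ** 2))
        assert err == pytest.approx(best, rel=1e-9)
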