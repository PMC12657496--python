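"""Preprocessing, k-means, elbow selection, stability, attribution, PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import normalized_mutual_info_score

from fhstrat import clustering as cl
from fhstrat import schema
from fhstrat.config import GeneratorConfig
from fhstrat.simulate import apply_mcar_mask, generate_cohort


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_standardized_columns(self, feature_matrix):
        X = feature_matrix.values
        active = X.std(axis=0) > 0
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(X[:, active].std(axis=0), 1.0, atol=1e-8)

    def test_no_missing_after_preprocessing(self, feature_matrix):
        assert np.isfinite(feature_matrix.values).all()

    def test_integer_encoding_keeps_33_columns(self, fhsup_cohort):
        fm = cl.preprocess_features(fhsup_cohort, encoding="integer")
        assert fm.values.shape[1] == 33
        assert fm.feature_names == schema.FEATURE_NAMES

    def test_onehot_maps_columns_to_source_features(self, feature_matrix):
        assert set(feature_matrix.source_features) == set(schema.FEATURE_NAMES)
        n_cats = sum(len(f.categories) for f in schema.FEATURES)
        assert feature_matrix.values.shape[1] == n_cats

    def test_imputation_noop_without_missing(self, fhsup_cohort):
        a = cl.preprocess_features(fhsup_cohort, encoding="integer")
        b = cl.preprocess_features(fhsup_cohort.copy(), encoding="integer")
        np.testing.assert_array_equal(a.values, b.values)

    def test_mode_imputation_matches_brute_force(self, fhsup_cohort, rng):
        """20% MCAR-masked column is filled with the observed mode."""
        col = "family_income"
        masked = apply_mcar_mask(fhsup_cohort, [col], 0.2, rng)
        fm = cl.preprocess_features(masked, encoding="integer")
        spec = schema.FEATURES_BY_NAME[col]
        observed = masked[col].dropna().map(spec.codes)
        mode = observed.value_counts().sort_index().idxmax()
        # invert the standardization to recover imputed codes
        j = fm.feature_names.index(col)
        raw = masked[col].map(spec.codes).to_numpy(dtype=float)
        filled = raw.copy()
        filled[np.isnan(raw)] = mode
        z = (filled - filled.mean()) / filled.std()
        np.testing.assert_allclose(fm.values[:, j], z, atol=1e-10)

    def test_constant_column_zeroed_with_warning(self, caplog):
        df = pd.DataFrame({f.name: [f.categories[0]] * 4 for f in schema.FEATURES})
        df["family_income"] = ["<$5K", "$5K-$12K", "<$5K", "$5K-$12K"]
        with caplog.at_level("WARNING"):
            fm = cl.preprocess_features(df, encoding="integer")
        j = fm.feature_names.index("parent_employment")
        assert (fm.values[:, j] == 0).all()
        assert "constant" in caplog.text

    def test_unknown_category_error_names_feature_and_value(self, fhsup_cohort):
        bad = fhsup_cohort.head(20).copy()
        bad.loc[bad.index[0], "family_income"] = "$1M"
        with pytest.raises(ValueError, match=r"\$1M.*family_income"):
            cl.preprocess_features(bad)

    def test_missing_feature_error(self, fhsup_cohort):
        with pytest.raises(ValueError, match="parent_employment"):
            cl.preprocess_features(fhsup_cohort.drop(columns=["parent_employment"]))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def _exhaustive_best_kmeans(points, k):
    """Oracle: minimum within-cluster SS over all k-partitions (tiny n only)."""
    n = len(points)
    best = (math.inf, None)
    def partitions(idx, parts):
        if not idx:
            if len(parts) == k:
                yield parts
            return
        head, rest = idx[0], idx[1:]
        for i in range(len(parts)):
            yield from partitions(rest, parts[:i] + [parts[i] + [head]] + parts[i+1:])
        if len(parts) < k:
            yield from partitions(rest, parts + [[head]])
    for parts in partitions(list(range(n)), []):
        ss = sum(((points[p] - points[p].mean(axis=0)) ** 2).sum()
                 for p in (np.array(part) for part in parts))
        if ss < best[0]:
            best = (ss, parts)
    return best


class TestFitKMeans:
    def test_three_triplets_exact_partition(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1],
                        [10, 10], [10.1, 10], [10, 10.1],
                        [-10, 10], [-10.1, 10], [-10, 10.1]])
        sol = cl.fit_kmeans(pts, 3, n_init=10, seed=0)
        best_ss, best_parts = _exhaustive_best_kmeans(pts, 3)
        assert sol.distortion == pytest.approx(best_ss, rel=1e-8)
        labels = sol.labels
        for part in best_parts:
            assert len(set(labels[part])) == 1

    def test_k1_closed_form(self, rng):
        pts = rng.normal(size=(50, 4))
        sol = cl.fit_kmeans(pts, 1)
        np.testing.assert_allclose(sol.centroids[0], pts.mean(axis=0))
        assert sol.distortion == pytest.approx(((pts - pts.mean(0)) ** 2).sum())

    def test_duplicate_rows_share_labels(self, rng):
        pts = rng.normal(size=(30, 3))
        doubled = np.vstack([pts, pts])
        sol = cl.fit_kmeans(doubled, 4, seed=1)
        np.testing.assert_array_equal(sol.labels[:30], sol.labels[30:])

    def test_distortion_recomputable_from_labels_and_centroids(self, feature_matrix):
        sol = cl.fit_kmeans(feature_matrix, 5, seed=2)
        recomputed = cl.recompute_distortion(feature_matrix, sol)
        assert recomputed == pytest.approx(sol.distortion, rel=1e-8)
        assert len(np.unique(sol.labels)) == 5  # every cluster non-empty

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cl.fit_kmeans(np.zeros((3, 2)), 4)

    def test_deterministic_given_seed(self, feature_matrix):
        a = cl.fit_kmeans(feature_matrix, 4, seed=9)
        b = cl.fit_kmeans(feature_matrix, 4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.distortion == b.distortion


# ---------------------------------------------------------------------------
# elbow selection
# ---------------------------------------------------------------------------

def _equidistant_blobs(k, n_per=150, d=6, sep=25.0, seed=0):
    """k well-separated spherical blobs at mutually equal distances."""
    rng = np.random.default_rng(seed)
    centers = np.eye(k, d) * sep / np.sqrt(2)
    pts = np.vstack([rng.normal(c, 1.0, size=(n_per, d)) for c in centers])
    return pts


class TestElbow:
    @pytest.mark.parametrize("k", [3, 4, 5])
    @pytest.mark.parametrize("fixture_seed", [0, 1, 2])
    def test_permutation_rule_recovers_planted_blobs(self, k, fixture_seed):
        pts = _equidistant_blobs(k, d=8, sep=12.0, seed=fixture_seed)
        res = cl.select_k_elbow(pts, seed=fixture_seed)
        assert res.k_star == k
        assert not res.low_confidence

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_second_difference_recovers_equidistant_blobs(self, k):
        pts = _equidistant_blobs(k)
        res = cl.select_k_elbow(pts, seed=0, method="second_difference")
        assert res.k_star == k
        assert not res.low_confidence

    def test_structureless_gaussian_flagged(self, rng):
        pts = rng.normal(size=(500, 10))
        perm = cl.select_k_elbow(pts, seed=0)
        second = cl.select_k_elbow(pts, seed=0, method="second_difference")
        assert perm.low_confidence
        assert second.low_confidence

    def test_distortion_curve_nonincreasing(self, feature_matrix):
        res = cl.select_k_elbow(feature_matrix, k_range=range(2, 7), seed=0,
                                n_references=4, n_seeds=3)
        d = res.curve["distortion"].to_numpy()
        total = cl.fit_kmeans(feature_matrix, 1).distortion
        assert (np.diff(d) <= 1e-6 * total).all()

    def test_validity_indices_attached(self, feature_matrix):
        res = cl.select_k_elbow(feature_matrix, k_range=range(2, 5), seed=0,
                                n_references=4, n_seeds=2)
        for col in ("silhouette", "davies_bouldin", "calinski_harabasz"):
            assert res.curve[col].notna().all()
        assert res.curve["silhouette"].between(-1, 1).all()
        assert (res.curve["davies_bouldin"] >= 0).all()

    def test_invalid_k_range(self, feature_matrix):
        with pytest.raises(ValueError):
            cl.select_k_elbow(feature_matrix, k_range=range(1, 5))


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def nmi_oracle(a, b):
    """From-scratch contingency-table NMI (arithmetic normalization)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ha = hb = mi = 0.0
    pa = {x: np.mean(a == x) for x in set(a)}
    pb = {y: np.mean(b == y) for y in set(b)}
    for x, px in pa.items():
        ha -= px * math.log(px)
    for y, py in pb.items():
        hb -= py * math.log(py)
    for x, px in pa.items():
        for y, py in pb.items():
            pxy = np.mean((a == x) & (b == y))
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    if ha == 0.0 and hb == 0.0:
        return 1.0
    return mi / ((ha + hb) / 2)


class TestNMI:
    def test_identity_and_label_permutation(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert normalized_mutual_info_score(labels, labels) == 1.0
        assert normalized_mutual_info_score(labels, (labels + 1) % 3) == 1.0

    def test_matches_oracle_on_random_labelings(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, size=10)
            b = rng.integers(0, 2, size=10)
            assert normalized_mutual_info_score(a, b) == pytest.approx(
                nmi_oracle(a, b), abs=1e-10)

    def test_matches_oracle_exhaustively_on_five_points(self):
        """All pairs of 2-labelings of 5 points (exhaustive small-case check)."""
        labelings = list(itertools.product([0, 1], repeat=5))
        for a in labelings:
            for b in labelings:
                assert normalized_mutual_info_score(a, b) == pytest.approx(
                    nmi_oracle(a, b), abs=1e-10)


class TestStability:
    def test_separated_blobs_have_zero_seed_shift(self):
        pts = _equidistant_blobs(3)
        rep = cl.seed_stability(pts, 3, n_seeds=6)
        assert rep.seed_mean_centroid_shift <= 1e-9

    def test_identical_seeds_zero_shift(self, feature_matrix):
        a = cl.fit_kmeans(feature_matrix, 5, seed=3)
        b = cl.fit_kmeans(feature_matrix, 5, seed=3)
        shifts = cl._match_centroids(a.centroids, b.centroids)
        assert shifts.max() == 0.0

    def test_bootstrap_reference_self_consistency(self):
        pts = _equidistant_blobs(3, n_per=80)
        rep = cl.bootstrap_stability(pts, 3, n_boot=10, seed=0)
        assert rep.bootstrap_nmi_mean == pytest.approx(1.0, abs=1e-9)
        assert rep.n_boot == 10

    def test_nmi_values_within_unit_interval(self, feature_matrix):
        rep = cl.bootstrap_stability(feature_matrix, 4, n_boot=5, n_init=5, seed=1)
        assert 0.0 <= rep.bootstrap_nmi_min <= rep.bootstrap_nmi_mean \
            <= rep.bootstrap_nmi_max <= 1.0


# ---------------------------------------------------------------------------
# attribution & PCA
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    n = 400
    labels = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 8))
    X[:, 1] += 4.0 * labels
    X[:, 4] -= 4.0 * labels
    X[:, 6] = 0.0  # uninformative constant feature
    return X, labels


class TestAttribution:
    @pytest.mark.parametrize("surrogate", ["gbt", "logistic"])
    def test_planted_features_rank_first(self, planted, surrogate):
        X, labels = planted
        out = cl.feature_attribution(X, labels, surrogate=surrogate, seed=0)
        top2 = set(out["feature"].iloc[:2])
        assert top2 == {"x1", "x4"}

    def test_constant_feature_attribution_zero(self, planted):
        X, labels = planted
        out = cl.feature_attribution(X, labels, seed=0)
        row = out[out["feature"] == "x6"]
        assert row["mean_abs_shap"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_ranking_invariant_to_column_order(self, planted):
        X, labels = planted
        perm = [3, 1, 4, 0, 2, 6, 5, 7]
        a = cl.feature_attribution(X, labels, seed=0)
        b = cl.feature_attribution(X[:, perm], labels, seed=0)
        renamed = [f"x{perm[int(f[1:])]}" for f in b["feature"]]
        assert list(a["feature"].iloc[:2]) == renamed[:2]

    def test_single_cluster_rejected(self, planted):
        X, _ = planted
        with pytest.raises(ValueError, match="two clusters"):
            cl.feature_attribution(X, np.zeros(len(X), dtype=int))

    def test_discriminative_features_dominate_on_cohort(self, feature_matrix):
        sol = cl.fit_kmeans(feature_matrix, 5, n_init=30, seed=1)
        out = cl.feature_attribution(feature_matrix, sol.labels, seed=0)
        top = set(out["feature"].iloc[:6])
        informative = set(schema.DISCRIMINATIVE_FEATURES) - {
            "rule_breaking_peer_involvement"}
        assert top <= informative


class TestPCA:
    def test_axis_aligned_for_diagonal_covariance(self, rng):
        X = np.column_stack([rng.normal(0, 5, 600), rng.normal(0, 1, 600)])
        coords, evr = cl.pca_project(X)
        corr = abs(np.corrcoef(coords[:, 0], X[:, 0])[0, 1])
        assert corr > 0.99

    def test_explained_variance_properties(self, feature_matrix):
        _, evr = cl.pca_project(feature_matrix, n_components=5)
        assert evr.sum() <= 1.0 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_rank_one_data_second_component_null(self, rng):
        base = rng.normal(size=600)
        X = np.column_stack([base, 2 * base, -base])
        _, evr = cl.pca_project(X)
        assert evr[1] == pytest.approx(0.0, abs=1e-10)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            cl.pca_project(np.zeros((10, 1)))
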