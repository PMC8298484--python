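"""Fourier features, PAM, validity indices and stability diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import circatemp as ct

D_TOY = squareform(pdist(np.array([[0.0], [1.0], [10.0], [11.0]])))
L_TOY = np.array([0, 0, 1, 1])
X_TOY = np.array([[0.0], [1.0], [10.0], [11.0]])


class TestDFTFeatures:
    def test_constant_series_dc_only(self):
        f = ct.dft_features(np.full((1, 2880), 33.0), H=24)[0]
        assert f[0] == pytest.approx(33.0)
        np.testing.assert_allclose(f[1:], 0.0, atol=1e-12)

    def test_single_harmonic_isolated(self):
        n = 2880
        y = np.cos(2 * np.pi * 2 * np.arange(n) / n)
        f = ct.dft_features(y[None, :], H=5)[0]
        # layout: [dc, re1, im1, re2, im2, ...]; only harmonic 2 is nonzero
        assert abs(f[3]) == pytest.approx(0.5, abs=1e-9)
        others = np.delete(f, 3)
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=512)
        coeffs = np.fft.fft(y) / len(y)
        energy_direct = np.sum(y**2)
        energy_spectral = len(y) * np.sum(np.abs(coeffs) ** 2)
        assert energy_spectral == pytest.approx(energy_direct, rel=1e-6)
        # retained features are exactly those coefficients
        f = ct.dft_features(y[None, :], H=10)[0]
        assert f[0] == pytest.approx(coeffs[0].real, abs=1e-12)
        assert f[1] == pytest.approx(coeffs[1].real, abs=1e-12)
        assert f[2] == pytest.approx(coeffs[1].imag, abs=1e-12)

    def test_mean_shift_changes_only_dc(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=1024)
        f1 = ct.dft_features(y[None, :], H=8)[0]
        f2 = ct.dft_features((y + 5.0)[None, :], H=8)[0]
        assert f2[0] - f1[0] == pytest.approx(5.0, abs=1e-9)
        np.testing.assert_allclose(f1[1:], f2[1:], atol=1e-9)

    def test_nan_rejected(self):
        X = np.ones((2, 100))
        X[0, 3] = np.nan
        with pytest.raises(ValueError):
            ct.dft_features(X, H=4)


class TestKMedoids:
    def test_separated_clouds_exact_partition(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 0.01, (20, 3)), rng.normal(100, 0.01, (25, 3))])
        labels = ct.KMedoids(n_clusters=2, random_state=0).fit_predict(X)
        truth = np.array([0] * 20 + [1] * 25)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_matches_exhaustive_enumeration(self):
        """PAM total cost equals the optimum over all C(8,2) medoid pairs."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(8, 2))
        D = squareform(pdist(X))
        best = min(
            D[:, list(pair)].min(axis=1).sum()
            for pair in itertools.combinations(range(8), 2)
        )
        km = ct.KMedoids(n_clusters=2, random_state=0, n_restarts=10).fit(X)
        assert km.inertia_ == pytest.approx(best, abs=1e-12)

    def test_medoid_belongs_to_own_cluster(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(40, 4))
        km = ct.KMedoids(n_clusters=3, random_state=1).fit(X)
        for c, m in enumerate(km.medoid_indices_):
            assert km.labels_[m] == c

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(50, 3))
        a = ct.KMedoids(n_clusters=3, random_state=7).fit(X)
        b = ct.KMedoids(n_clusters=3, random_state=7).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        assert a.inertia_ == b.inertia_

    def test_invalid_k_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            ct.KMedoids(n_clusters=1).fit(X)
        with pytest.raises(ValueError):
            ct.KMedoids(n_clusters=5).fit(X)

    def test_duplicate_points_exceeding_distinct_rejected(self):
        X = np.zeros((6, 2))
        X[0] = [1, 1]
        with pytest.raises(ValueError):
            ct.KMedoids(n_clusters=3).fit(X)

    def test_relabelling_by_mean_level(self):
        # cluster with the highest mean DC term must get label 0
        rng = np.random.default_rng(20)
        low = np.column_stack([rng.normal(32.8, 0.01, 10), rng.normal(0, 0.01, 10)])
        high = np.column_stack([rng.normal(34.3, 0.01, 12), rng.normal(0, 0.01, 12)])
        sol = ct.pam_cluster(np.vstack([low, high]), 2, seed=0)
        assert (sol.labels[:10] == 1).all() and (sol.labels[10:] == 0).all()


class TestValidityIndices:
    def test_silhouette_hand_value(self):
        assert ct.silhouette_index(D_TOY, L_TOY) == pytest.approx(0.8997, abs=5e-4)

    def test_silhouette_coincident_clusters(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        D = squareform(pdist(X))
        assert ct.silhouette_index(D, np.array([0, 0, 1, 1])) <= 0.0

    def test_dunn_hand_value(self):
        assert ct.dunn_index(D_TOY, L_TOY) == pytest.approx(9.0)

    def test_dunn_overlap_zero_and_scale_invariance(self):
        X = np.array([[0.0], [1.0], [1.0], [5.0]])
        D = squareform(pdist(X))
        assert ct.dunn_index(D, np.array([0, 0, 1, 1])) == 0.0
        assert ct.dunn_index(3.7 * D_TOY, L_TOY) == pytest.approx(9.0)

    def test_davies_bouldin_hand_value(self):
        assert ct.davies_bouldin_index(X_TOY, L_TOY) == pytest.approx(0.1)

    def test_davies_bouldin_duplication_invariant(self):
        X2 = np.vstack([X_TOY, X_TOY])
        L2 = np.concatenate([L_TOY, L_TOY])
        assert ct.davies_bouldin_index(X2, L2) == pytest.approx(
            ct.davies_bouldin_index(X_TOY, L_TOY)
        )

    def test_indices_invariant_to_feature_translation(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(6, 1, (15, 4))])
        lab = np.array([0] * 15 + [1] * 15)
        Xs = X + 42.0
        D, Ds = squareform(pdist(X)), squareform(pdist(Xs))
        assert ct.silhouette_index(D, lab) == pytest.approx(
            ct.silhouette_index(Ds, lab))
        assert ct.dunn_index(D, lab) == pytest.approx(ct.dunn_index(Ds, lab))
        assert ct.davies_bouldin_index(X, lab) == pytest.approx(
            ct.davies_bouldin_index(Xs, lab))


class TestDimensionFitIndices:
    def test_exact_rank_k_reports_zero_rmsea(self):
        rng = np.random.default_rng(22)
        scores = rng.normal(size=(100, 2))
        load = rng.normal(size=(2, 6))
        X = scores @ load  # exact rank 2
        rep = ct.dimension_fit_indices(X, range(0, 5))
        assert rep.loc[rep.k == 2, "rmsea_like"].iloc[0] == 0.0

    def test_spherical_null_accepts_k0(self):
        hits = 0
        for s in range(20):
            X = np.random.default_rng(s).normal(size=(500, 5))
            rep = ct.dimension_fit_indices(X, [0])
            hits += rep["rmsea_like"].iloc[0] < 0.05
        assert hits >= 18

    def test_rmsea_non_increasing_with_separated_eigenvalues(self):
        # each added component absorbs the largest remaining eigenvalue, so
        # the fit statistic improves monotonically on this spectrum
        rng = np.random.default_rng(23)
        scores = rng.normal(size=(300, 3)) * np.array([10.0, 3.0, 1.0])
        X = scores @ rng.normal(size=(3, 8)) + 1.0 * rng.normal(size=(300, 8))
        rep = ct.dimension_fit_indices(X, range(0, 6)).dropna()
        vals = rep["rmsea_like"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)
        # acceptable fit is first reached at the true rank
        assert vals[3] < 0.05 < vals[2]

    def test_k_too_large_reported_missing(self):
        X = np.random.default_rng(24).normal(size=(50, 4))
        rep = ct.dimension_fit_indices(X, [3, 4])
        assert rep["rmsea_like"].isna().all()


class TestSelectK:
    @staticmethod
    def _report(sil, dunn, db, rmsea, ebic):
        return pd.DataFrame({
            "k": range(2, 2 + len(sil)), "silhouette": sil, "dunn": dunn,
            "db": db, "rmsea_like": rmsea, "ebic_like": ebic,
        })

    def test_votes_surfaced_on_disagreement(self):
        rep = self._report([0.5, 0.6], [0.2, 0.4], [0.5, 0.8],
                           [0.2, 0.03], [10.0, -5.0])
        sel = ct.select_k(rep)
        assert sel["votes"] == {"silhouette": 3, "dunn": 3, "db": 2,
                                "rmsea_like": 3, "ebic_like": 3}
        assert sel["consensus"] == 3

    def test_unanimous(self):
        rep = self._report([0.4, 0.9, 0.5], [0.1, 0.9, 0.2], [0.9, 0.1, 0.5],
                           [0.2, 0.01, 0.01], [5.0, -9.0, -1.0])
        assert ct.select_k(rep)["consensus"] == 3

    def test_ties_broken_toward_smaller_k(self):
        rep = self._report([0.9, 0.5], [0.1, 0.9], [0.1, 0.9],
                           [0.01, 0.01], [5.0, -9.0])
        # votes: sil->2, db->2, rmsea->2 vs dunn->3, ebic->3 : majority 2
        sel = ct.select_k(rep)
        assert sel["consensus"] == 2

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            ct.select_k(pd.DataFrame())


class TestStabilityDiagnostics:
    @staticmethod
    def _three_clouds(n=30, sep=50.0, seed=25):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(i * sep, 1.0, (n, 5)) for i in range(3)])
        labels = np.repeat(np.arange(3), n)
        return X, labels

    def test_tsne_preserves_separated_clusters(self):
        X, labels = self._three_clouds()
        emb, ari = ct.tsne_stability(X, labels, perplexity=15.0, seed=3)
        assert emb.shape == (90, 2)
        assert ari == 1.0

    def test_tsne_null_labels_near_zero(self):
        X, labels = self._three_clouds()
        rng = np.random.default_rng(26)
        _, ari = ct.tsne_stability(X, rng.permutation(labels), perplexity=15.0, seed=3)
        assert abs(ari) < 0.1

    def test_tsne_deterministic(self):
        X, labels = self._three_clouds(n=15)
        e1, _ = ct.tsne_stability(X, labels, perplexity=10.0, seed=4)
        e2, _ = ct.tsne_stability(X, labels, perplexity=10.0, seed=4)
        np.testing.assert_array_equal(e1, e2)

    def test_tsne_perplexity_validated(self):
        X, labels = self._three_clouds(n=5)
        with pytest.raises(ValueError):
            ct.tsne_stability(X, labels, perplexity=10.0)

    def test_network_modularity_of_blocks(self):
        X, labels = self._three_clouds(n=20, sep=20.0)
        G, pos, mod = ct.network_diagnostics(X, labels)
        assert mod > 0.3
        assert len(pos) == 60
        rng = np.random.default_rng(27)
        _, _, mod_null = ct.network_diagnostics(X, rng.permutation(labels))
        assert abs(mod_null) < 0.15

    def test_equidistant_points_equal_weights(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        G, _, _ = ct.network_diagnostics(X, np.array([0, 1, 2]), n_neighbors=2)
        w = [d["weight"] for _, _, d in G.edges(data=True)]
        assert max(w) == pytest.approx(min(w))


def test_full_stack_recovers_archetypes(small_archetypes):
    """dft -> PAM -> select_k recommends k=3 and recovers the truth labels
    on a low-noise scaled-down cohort."""
    bundle = ct.generate_cohort(
        small_archetypes, ct.NoiseSpec(sigma=0.05, missing_fraction=0.02), seed=77
    )
    series = [ct.harmonize_start(r) for r in bundle.recordings]
    M = ct.impute_missing(np.vstack([s.values for s in series]), ncp=2)
    F = ct.dft_features(M, H=24)
    rep = ct.validity_report(F, range(2, 5), seed=7)
    assert ct.select_k(rep)["votes"]["silhouette"] == 3
    sol = ct.pam_cluster(F, 3, seed=7)
    truth = bundle.truth["label"].to_numpy()
    assert adjusted_rand_score(truth, sol.labels) >= 0.95
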