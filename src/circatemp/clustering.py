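"""Fourier-feature k-medoids clustering of temperature profiles.

Each 48-h series is reduced to its DC term plus the first H harmonics of
the discrete Fourier transform (real/imaginary pairs, normalized so the DC
term equals the series mean).  Subjects are clustered with Partitioning
Around Medoids (PAM: greedy BUILD then steepest-descent SWAP) on Euclidean
feature distances, and the number of clusters is chosen with a battery of
validity indices — Silhouette, Dunn, Davies-Bouldin, plus eigenvalue-based
RMSEA-like and eBIC-like dimension-fit indices — backed by t-SNE and
network-modularity stability diagnostics.  Disagreement between indices is
surfaced, never silently collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.manifold import TSNE
from sklearn.metrics import (
    adjusted_rand_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "DFTFeaturizer",
    "dft_features",
    "KMedoids",
    "ClusterSolution",
    "pam_cluster",
    "silhouette_index",
    "dunn_index",
    "davies_bouldin_index",
    "dimension_fit_indices",
    "validity_report",
    "select_k",
    "tsne_stability",
    "network_diagnostics",
]


# ---------------------------------------------------------------------------
# Fourier features


class DFTFeaturizer(TransformerMixin, BaseEstimator):
    """DC term + first ``n_harmonics`` DFT coefficients as real features.

    Normalized convention: coefficients are divided by the series length, so
    the DC feature equals the series mean (the mesor separates clusters and
    is kept by default; ``drop_dc`` gives shape-only features).  With
    ``magnitudes=True`` each harmonic contributes |c_h| instead of its
    (Re, Im) pair.
    """

    def __init__(self, n_harmonics: int = 24, drop_dc: bool = False, magnitudes: bool = False):
        self.n_harmonics = n_harmonics
        self.drop_dc = drop_dc
        self.magnitudes = magnitudes

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[1]
        if np.isnan(X).any():
            raise ValueError("DFT features require an imputed (NaN-free) matrix")
        if not 1 <= self.n_harmonics <= n // 2 - 1:
            raise ValueError(f"n_harmonics must lie in [1, {n // 2 - 1}]")
        coeffs = np.fft.rfft(X, axis=1) / n
        h = coeffs[:, 1 : self.n_harmonics + 1]
        if self.magnitudes:
            harm = np.abs(h)
        else:
            harm = np.empty((X.shape[0], 2 * self.n_harmonics))
            harm[:, 0::2] = h.real
            harm[:, 1::2] = h.imag
        if self.drop_dc:
            return harm
        return np.column_stack([coeffs[:, 0].real, harm])


def dft_features(matrix: np.ndarray, H: int = 24, **kwargs) -> np.ndarray:
    return DFTFeaturizer(n_harmonics=H, **kwargs).transform(matrix)


# ---------------------------------------------------------------------------
# PAM (k-medoids)


class KMedoids(ClusterMixin, BaseEstimator):
    """Partitioning Around Medoids with BUILD + steepest-descent SWAP.

    SWAP repeatedly applies the single (medoid, candidate) exchange that
    most lowers the total distance to the nearest medoid, until no exchange
    improves — so the returned solution is locally optimal under single
    swaps.  ``n_restarts`` runs the algorithm over random permutations of
    the input order (ties in BUILD/SWAP depend on order) and keeps the
    lowest-cost solution.  Deterministic given ``random_state``.
    """

    def __init__(self, n_clusters: int = 3, n_restarts: int = 10, random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _build(D: np.ndarray, k: int) -> list[int]:
        n = D.shape[0]
        medoids = [int(np.argmin(D.sum(axis=1)))]
        for _ in range(1, k):
            dmin = D[:, medoids].min(axis=1)
            # gain of adding each candidate: total reduction in nearest-distance
            gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        return medoids

    @staticmethod
    def _swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
        n = D.shape[0]
        medoids = list(medoids)
        while True:
            Dm = D[:, medoids]
            order = np.argsort(Dm, axis=1)
            nearest = Dm[np.arange(n), order[:, 0]]
            second = Dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
            nearest_idx = order[:, 0]
            best_delta, best_pair = -1e-12, None
            for mi in range(len(medoids)):
                served = nearest_idx == mi
                # cost change of replacing medoid mi by each candidate h:
                # served points move to min(d(.,h), second), others may defect to h
                cand = np.delete(np.arange(n), medoids)
                Dh = D[:, cand]  # n x n_cand
                new_served = np.minimum(Dh[served], second[served, None]).sum(axis=0)
                delta_served = new_served - nearest[served].sum()
                delta_other = np.minimum(Dh[~served] - nearest[~served, None], 0.0).sum(axis=0)
                delta = delta_served + delta_other
                j = int(np.argmin(delta))
                if delta[j] < best_delta:
                    best_delta, best_pair = delta[j], (mi, int(cand[j]))
            if best_pair is None:
                break
            medoids[best_pair[0]] = best_pair[1]
        cost = float(D[:, medoids].min(axis=1).sum())
        return medoids, cost

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if not 2 <= k < n:
            raise ValueError(f"need 2 <= n_clusters < n_samples, got k={k}, n={n}")
        D = squareform(pdist(X))
        if len(np.unique(X, axis=0)) < k:
            raise ValueError("fewer distinct points than clusters")
        rng = np.random.default_rng(self.random_state)
        best_cost, best_medoids = np.inf, None
        for r in range(max(self.n_restarts, 1)):
            perm = np.arange(n) if r == 0 else rng.permutation(n)
            Dp = D[np.ix_(perm, perm)]
            medoids, cost = self._swap(Dp, self._build(Dp, k))
            if cost < best_cost - 1e-12:
                best_cost, best_medoids = cost, sorted(int(perm[m]) for m in medoids)
        self.medoid_indices_ = np.array(best_medoids)
        self.labels_ = np.argmin(D[:, self.medoid_indices_], axis=1)
        # a medoid always belongs to its own cluster, even under distance ties
        self.labels_[self.medoid_indices_] = np.arange(k)
        self.inertia_ = best_cost
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    medoid_ids: np.ndarray
    total_cost: float
    seed: int | None = None


def pam_cluster(
    features: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_restarts: int = 10,
    relabel_by_dc: bool = True,
) -> ClusterSolution:
    """PAM on feature vectors, relabelled so cluster 0 has the highest mean
    DC term (i.e. mean temperature level) among its members — the
    highest-mesor-first numbering convention used in reports."""
    km = KMedoids(n_clusters=k, n_restarts=n_restarts, random_state=seed).fit(features)
    labels, medoids = km.labels_, km.medoid_indices_
    if relabel_by_dc:
        features = np.asarray(features, dtype=float)
        means = np.array([features[labels == c, 0].mean() for c in range(k)])
        order = np.argsort(-means)  # descending DC
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[labels]
        medoids = medoids[order]
    return ClusterSolution(k=k, labels=labels, medoid_ids=medoids,
                           total_cost=km.inertia_, seed=seed)


# ---------------------------------------------------------------------------
# validity indices


def _as_distance_matrix(distances) -> np.ndarray:
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix")
    return D


def silhouette_index(distances: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)); singletons score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(_as_distance_matrix(distances), labels, metric="precomputed"))


def dunn_index(distances: np.ndarray, labels: np.ndarray, inf_guard: float = 1e12) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    D = _as_distance_matrix(distances)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index undefined for a single cluster")
    max_diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_sep = np.inf
    for i, ci in enumerate(uniq):
        for cj in uniq[i + 1 :]:
            a, b = np.flatnonzero(labels == ci), np.flatnonzero(labels == cj)
            min_sep = min(min_sep, float(D[np.ix_(a, b)].min()))
    if max_diam == 0.0:
        return inf_guard
    return min_sep / max_diam


def davies_bouldin_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean worst-pair scatter-to-separation ratio."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Davies-Bouldin undefined for a single cluster")
    return float(davies_bouldin_score(np.asarray(features, dtype=float), labels))


def dimension_fit_indices(
    features: np.ndarray,
    candidate_ks: range | list[int],
    max_components: int = 10,
) -> pd.DataFrame:
    """Eigenvalue-based RMSEA-like and eBIC-like dimension-fit indices.

    This is a documented reconstruction, not a published formula: for each
    candidate dimensionality k, a Bartlett-style statistic tests sphericity
    of the trailing p-k eigenvalues of the feature covariance,
    chi2 = c * [(p-k)*ln(mean lambda) - sum ln lambda_j] with the standard
    small-sample factor c = n - 1 - (2p+5)/6 - 2k/3 and
    df = (p-k+2)(p-k-1)/2; then RMSEA-like = sqrt(max(0, (chi2/df - 1)/(n-1)))
    and eBIC-like = chi2 - df*ln(n).  Rows with k >= p-1 are reported as
    missing.
    """
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    if p >= n or p > max_components:
        # reduce to leading principal components so eigenvalues are stable
        Xc = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        p = min(max_components, min(n - 1, X.shape[1]))
        X = Xc @ vt[:p].T
    cov = np.cov(X, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    rows = []
    for k in candidate_ks:
        if k >= p - 1 or k < 0:
            rows.append({"k": k, "rmsea_like": np.nan, "ebic_like": np.nan})
            continue
        tail = eigvals[k:]
        if np.all(tail < 1e-12):  # exact rank-k data: perfect fit
            rows.append({"k": k, "rmsea_like": 0.0, "ebic_like": -np.inf})
            continue
        tail = np.maximum(tail, 1e-300)
        m = p - k
        c = n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
        chi2 = c * (m * np.log(tail.mean()) - np.sum(np.log(tail)))
        df = (m + 2) * (m - 1) / 2.0
        rmsea = float(np.sqrt(max(0.0, (chi2 / df - 1.0) / (n - 1))))
        rows.append({"k": k, "rmsea_like": rmsea, "ebic_like": float(chi2 - df * np.log(n))})
    return pd.DataFrame(rows)


def validity_report(
    features: np.ndarray,
    k_range: range | list[int],
    seed: int | None = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Cluster each candidate k with PAM and tabulate all validity indices."""
    features = np.asarray(features, dtype=float)
    D = squareform(pdist(features))
    dim = dimension_fit_indices(features, list(k_range)).set_index("k")
    rows = []
    for k in k_range:
        sol = pam_cluster(features, k, seed=seed, n_restarts=n_restarts)
        rows.append(
            {
                "k": k,
                "db": davies_bouldin_index(features, sol.labels),
                "dunn": dunn_index(D, sol.labels),
                "silhouette": silhouette_index(D, sol.labels),
                "rmsea_like": dim.loc[k, "rmsea_like"],
                "ebic_like": dim.loc[k, "ebic_like"],
                "total_cost": sol.total_cost,
            }
        )
    return pd.DataFrame(rows)


def select_k(report: pd.DataFrame, rmsea_cutoff: float = 0.05) -> dict:
    """Per-index k recommendations plus a majority consensus (ties -> smaller k).

    Votes: max silhouette, max Dunn, min Davies-Bouldin, first k with
    RMSEA-like below ``rmsea_cutoff``, min eBIC-like.  Disagreement between
    the indices is preserved in the ``votes`` field.
    """
    if report.empty or len(report) < 2:
        raise ValueError("validity report must cover at least two candidate k")
    rep = report.sort_values("k").reset_index(drop=True)
    votes: dict[str, int | None] = {}
    votes["silhouette"] = int(rep.loc[rep["silhouette"].idxmax(), "k"])
    votes["dunn"] = int(rep.loc[rep["dunn"].idxmax(), "k"])
    votes["db"] = int(rep.loc[rep["db"].idxmin(), "k"])
    ok = rep[rep["rmsea_like"] < rmsea_cutoff]
    votes["rmsea_like"] = int(ok["k"].iloc[0]) if len(ok) else None
    eb = rep.dropna(subset=["ebic_like"])
    votes["ebic_like"] = int(eb.loc[eb["ebic_like"].idxmin(), "k"]) if len(eb) else None
    cast = [v for v in votes.values() if v is not None]
    counts = pd.Series(cast).value_counts()
    top = counts[counts == counts.max()].index
    consensus = int(min(top))
    return {"votes": votes, "consensus": consensus}


# ---------------------------------------------------------------------------
# stability diagnostics


def tsne_stability(
    features: np.ndarray,
    labels: np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """2-D t-SNE embedding plus agreement (ARI) of a k-medoids re-clustering
    of the embedding with the supplied labels."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for n={n}")
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features)
    k = len(np.unique(labels))
    re_labels = KMedoids(n_clusters=k, random_state=seed).fit_predict(emb)
    return emb, float(adjusted_rand_score(labels, re_labels))


def network_diagnostics(
    features: np.ndarray,
    labels: np.ndarray,
    n_neighbors: int = 10,
    seed: int = 0,
    layout_iterations: int = 50,
) -> tuple[nx.Graph, dict, float]:
    """Gaussian-kernel nearest-neighbour graph, force-directed layout, and
    Newman modularity of the supplied labels.

    Edge weights are exp(-d^2 / (2 sigma^2)) with sigma the median pairwise
    distance; each node keeps its ``n_neighbors`` nearest neighbours
    (symmetrized).  Disconnection is flagged on the graph, not raised.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("network diagnostics need at least 3 subjects")
    D = squareform(pdist(X))
    tri = D[np.triu_indices(n, 1)]
    sigma = float(np.median(tri)) or 1.0
    W = np.exp(-(D**2) / (2.0 * sigma**2))
    np.fill_diagonal(W, 0.0)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    kth = min(n_neighbors, n - 1)
    for i in range(n):
        for j in np.argsort(D[i])[1 : kth + 1]:
            G.add_edge(i, int(j), weight=float(W[i, j]))
    G.graph["connected"] = nx.is_connected(G)
    pos = nx.spring_layout(G, seed=seed, iterations=layout_iterations, weight="weight")
    communities = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
    mod = nx.algorithms.community.modularity(G, communities, weight="weight")
    return G, pos, float(mod)
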