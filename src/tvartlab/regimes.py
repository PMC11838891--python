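"""Regime identification from TVART temporal modes.

Windows with similar linear dynamics have nearby temporal-mode vectors,
so clustering the rows of U3 recovers the recurring dynamical regimes.
Low-dimensional systems use full-covariance Gaussian mixtures (which
also yield posterior cluster probabilities and a likelihood-gain
statistic); high-dimensional systems use agglomerative clustering on
Manhattan distances.  Cluster labels are matched to ground-truth
attractor indices by the best label permutation before accuracy is
computed (in percent, with windows as the classification unit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture

from .attractors import AttractorSet, window_attractor_indices
from .tvart import TVARTConfig, build_windows, fit_tvart

__all__ = [
    "ClusterAssignment",
    "DendrogramCurve",
    "cluster_temporal_modes_gmm",
    "delta_log_likelihood",
    "match_clusters_to_attractors",
    "chance_level",
    "hierarchical_cluster_curve",
    "clustering_quality",
    "hyperparameter_sensitivity",
    "write_metric_table",
    "write_dendrogram_curve",
]

_GMM_KW = dict(covariance_type="full", n_init=10, max_iter=500, reg_covar=1e-6)


@dataclass
class ClusterAssignment:
    """Mixture-model cluster labels with posterior diagnostics."""

    labels: np.ndarray
    posteriors: np.ndarray  # per-window max posterior probability
    mean_posterior: float
    model_loglik: float  # total log-likelihood
    k: int
    seed: int


@dataclass
class DendrogramCurve:
    """Cluster count as a function of the dendrogram distance cutoff."""

    cutoffs: np.ndarray
    counts: np.ndarray
    metric: str = "cityblock"
    linkage_method: str = "average"


def cluster_temporal_modes_gmm(U3: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """k-component full-covariance Gaussian mixture on temporal modes.

    Ten restarts, best likelihood kept; the mean posterior is the mean
    over windows of each window's maximum posterior probability.
    """
    U3 = np.asarray(U3, dtype=float)
    T = U3.shape[0]
    if T < 2 * k:
        raise ValueError(f"need at least 2*k = {2 * k} windows, got {T}")
    gm = GaussianMixture(n_components=k, random_state=seed, **_GMM_KW)
    labels = gm.fit_predict(U3)
    post = gm.predict_proba(U3).max(axis=1)
    return ClusterAssignment(
        labels=labels,
        posteriors=post,
        mean_posterior=float(post.mean()),
        model_loglik=float(gm.score(U3) * T),
        k=k,
        seed=seed,
    )


def delta_log_likelihood(U3: np.ndarray, n_components: int, seed: int = 0) -> float:
    """Likelihood gain of an n-component mixture over a single Gaussian,

        dL_n = loglik(n components) - loglik(1 component),

    both total log-likelihoods on the same data.  Large positive values
    indicate genuinely multimodal temporal modes.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    ll_n = cluster_temporal_modes_gmm(U3, n_components, seed).model_loglik
    ll_1 = cluster_temporal_modes_gmm(U3, 1, seed).model_loglik
    return ll_n - ll_1


def match_clusters_to_attractors(cluster_labels: np.ndarray, attractor_indices: np.ndarray) -> dict:
    """Best-permutation matching of cluster labels to attractor indices.

    Brute force over label permutations for k <= 6, Hungarian assignment
    on the confusion matrix otherwise.  Returns the permutation (mapping
    cluster label -> attractor label) and the accuracy in percent.
    """
    cl = np.asarray(cluster_labels)
    at = np.asarray(attractor_indices)
    if cl.shape != at.shape:
        raise ValueError("label vectors must have the same length")
    k = int(max(cl.max(initial=0), at.max(initial=0))) + 1
    conf = np.zeros((k, k))
    np.add.at(conf, (cl, at), 1)
    if k <= 6:
        best_perm, best_hits = None, -1
        for perm in itertools.permutations(range(k)):
            hits = sum(conf[i, perm[i]] for i in range(k))
            if hits > best_hits:
                best_hits, best_perm = hits, perm
        perm = np.asarray(best_perm)
    else:
        rows, cols = linear_sum_assignment(-conf)
        perm = np.empty(k, dtype=int)
        perm[rows] = cols
        best_hits = conf[rows, cols].sum()
    accuracy = 100.0 * best_hits / len(cl)
    return {"permutation": perm, "accuracy": float(accuracy)}


def chance_level(
    attractor_indices: np.ndarray, k: int, n_shuffles: int = 1000, seed: int = 0
) -> dict:
    """Null distribution of matched accuracy under uniform label shuffles.

    Returns the median and the 5th/95th percentiles (percent).
    """
    if n_shuffles < 100:
        raise ValueError("use at least 100 shuffles")
    at = np.asarray(attractor_indices)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        fake = rng.integers(0, k, size=len(at))
        accs[i] = match_clusters_to_attractors(fake, at)["accuracy"]
    return {
        "median": float(np.median(accs)),
        "p5": float(np.percentile(accs, 5)),
        "p95": float(np.percentile(accs, 95)),
    }


def hierarchical_cluster_curve(
    U3: np.ndarray, cutoffs, linkage_method: str = "average"
) -> DendrogramCurve:
    """Agglomerative clustering on pairwise Manhattan distances; the
    number of flat clusters at each distance cutoff."""
    U3 = np.asarray(U3, dtype=float)
    if U3.shape[0] < 2:
        raise ValueError("need at least two windows")
    Z = linkage(pdist(U3, metric="cityblock"), method=linkage_method)
    cutoffs = np.asarray(cutoffs, dtype=float)
    counts = np.array(
        [len(np.unique(fcluster(Z, c, criterion="distance"))) for c in cutoffs]
    )
    return DendrogramCurve(cutoffs, counts, "cityblock", linkage_method)


def clustering_quality(points: np.ndarray, labels: np.ndarray) -> dict:
    """Davies-Bouldin and Dunn indices of a flat clustering.

    Davies-Bouldin: mean over clusters of the largest (s_i + s_j)/d_ij,
    with s_i the mean distance to the cluster centroid and d_ij the
    centroid separation (smaller is better).  Dunn: smallest distance
    between observations in different clusters divided by the largest
    intra-cluster pairwise distance (larger is better; infinite if every
    cluster is a single repeated point).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    cents = np.array([points[labels == u].mean(axis=0) for u in uniq])
    spreads = np.array(
        [np.linalg.norm(points[labels == u] - cents[i], axis=1).mean() for i, u in enumerate(uniq)]
    )
    K = len(uniq)
    db = 0.0
    for i in range(K):
        worst = 0.0
        for j in range(K):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            worst = max(worst, (spreads[i] + spreads[j]) / d)
        db += worst
    db /= K

    D = squareform(pdist(points))
    same = labels[:, None] == labels[None, :]
    inter = D[~same]
    intra_max = 0.0
    for u in uniq:
        block = D[np.ix_(labels == u, labels == u)]
        if block.size:
            intra_max = max(intra_max, float(block.max()))
    dunn = float(inter.min() / intra_max) if intra_max > 0 else float("inf")
    return {"davies_bouldin": float(db), "dunn": dunn}


def hyperparameter_sensitivity(
    traj,
    attractors: AttractorSet,
    eta_grid,
    beta_grid,
    config_base: TVARTConfig,
    n_repeats: int = 2,
    n_components: int | None = None,
    seed: int = 0,
) -> list[dict]:
    """TVART + clustering metrics over an (eta, beta) grid.

    For each grid cell, ``n_repeats`` fits (different initialization
    seeds) are run and the metrics averaged: prediction r2, likelihood
    gain dL_n, mean posterior, matched accuracy, Davies-Bouldin and Dunn
    indices.  Individual fit failures are recorded per cell, not fatal.
    """
    if len(eta_grid) == 0 or len(beta_grid) == 0:
        raise ValueError("grids must be nonempty")
    k = n_components if n_components is not None else attractors.n_stable
    data = build_windows(traj, config_base.window_M, config_base.delay_steps)
    truth = window_attractor_indices(traj, attractors, config_base.window_M, n_windows=data.T)
    rows = []
    for eta in eta_grid:
        for beta in beta_grid:
            metrics = {m: [] for m in ("r2", "delta_loglik", "mean_posterior", "accuracy", "davies_bouldin", "dunn")}
            failures = 0
            for rep in range(n_repeats):
                cfg = config_base.with_(eta=float(eta), beta=float(beta), seed=seed + rep)
                try:
                    fit = fit_tvart(data, cfg)
                    ca = cluster_temporal_modes_gmm(fit.U3, k, seed=seed + rep)
                    dll = delta_log_likelihood(fit.U3, k, seed=seed + rep) if k >= 2 else 0.0
                    acc = match_clusters_to_attractors(ca.labels, truth)["accuracy"]
                    qual = clustering_quality(fit.U3, ca.labels) if len(np.unique(ca.labels)) >= 2 else {
                        "davies_bouldin": float("nan"), "dunn": float("nan")}
                except (np.linalg.LinAlgError, ValueError):
                    failures += 1
                    continue
                metrics["r2"].append(fit.r2)
                metrics["delta_loglik"].append(dll)
                metrics["mean_posterior"].append(ca.mean_posterior)
                metrics["accuracy"].append(acc)
                metrics["davies_bouldin"].append(qual["davies_bouldin"])
                metrics["dunn"].append(qual["dunn"])
            row = {"eta": float(eta), "beta": float(beta), "failures": failures}
            for m, vals in metrics.items():
                row[m] = float(np.mean(vals)) if vals else float("nan")
            rows.append(row)
    return rows


def write_metric_table(path, rows: list[dict]) -> None:
    """Write a list of per-cell metric dicts (e.g. the output of
    :func:`hyperparameter_sensitivity`) as CSV."""
    import csv

    if not rows:
        raise ValueError("nothing to write")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def write_dendrogram_curve(path, curve: DendrogramCurve) -> None:
    """CSV export of a cluster-count-vs-cutoff curve."""
    np.savetxt(
        path,
        np.column_stack([curve.cutoffs, curve.counts]),
        delimiter=",",
        header="cutoff,count",
        comments="",
    )
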