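"""Unsupervised cluster-fidelity evaluation.

Embeddings are reduced to 10 dimensions (UMAP, or a deterministic PCA
fallback), clustered with affinity propagation — which infers the number of
clusters from the data, emulating analysis of a fully unlabelled dataset —
and scored against the known habitat/site classes with a Pearson chi-squared
statistic on the cluster-by-class contingency table. Higher chi-squared means
clusters align better with the true classes; significance of the alignment is
assessed against a label-permutation null.

The affinity-propagation message passing (responsibilities/availabilities
with damping, Frey & Dueck) is implemented here directly; similarities are
negative squared Euclidean distances, and the exemplar preference defaults to
the median off-diagonal similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "ClusterResult",
    "FidelityScore",
    "pca_reduce",
    "reduce_dims",
    "AffinityPropagation",
    "negative_sq_euclidean",
    "contingency",
    "chi_square",
    "permutation_fidelity",
]


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignments for a set of minutes, with exemplar keys."""

    assignments: tuple
    exemplars: tuple
    n_clusters: int
    converged: bool
    row_keys: tuple

    def __post_init__(self) -> None:
        labels = np.asarray(self.assignments)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise ValueError("cluster ids must be contiguous from 0")
        if len(self.exemplars) != self.n_clusters:
            raise ValueError("one exemplar per cluster required")
        key_to_label = dict(zip(self.row_keys, self.assignments))
        for k, ex in enumerate(self.exemplars):
            if key_to_label[ex] != k:
                raise ValueError(f"exemplar {ex!r} not assigned to its own cluster {k}")


@dataclass(frozen=True)
class FidelityScore:
    """Chi-squared fidelity of clusters to known classes."""

    chi2: float
    df: int
    p: float
    table: pd.DataFrame
    dropped_rows: int = 0
    dropped_cols: int = 0


def pca_reduce(X: np.ndarray, d: int) -> np.ndarray:
    """Deterministic principal-component projection to ``d`` dimensions.

    Eigendecomposition of the covariance matrix; component signs are fixed so
    the largest-magnitude loading of each component is positive, making the
    output platform-independent.
    """
    X = np.asarray(X, dtype=np.float64)
    if d >= X.shape[1]:
        raise ValueError(f"target dimension {d} must be < input dimension {X.shape[1]}")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / max(1, X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:d]
    comps = eigvec[:, order]
    for j in range(comps.shape[1]):
        k = np.argmax(np.abs(comps[:, j]))
        if comps[k, j] < 0:
            comps[:, j] = -comps[:, j]
    return Xc @ comps


def reduce_dims(X, d: int = 10, method: str = "umap", seed: int = 0,
                scale: bool = True):
    """Reduce embeddings to ``d`` dimensions.

    ``method="umap"`` delegates to umap-learn with a fixed random state;
    ``method="pca"`` uses the deterministic in-package projection. Accepts an
    :class:`~reefscape.embeddings.EmbeddingMatrix` (returned reduced) or a
    plain array. With ``scale=True`` (default) columns are standardised
    first — compound-index features span several orders of magnitude and
    would otherwise dominate the distance structure; constant columns are
    left at zero.
    """
    from .embeddings import EmbeddingMatrix

    is_em = isinstance(X, EmbeddingMatrix)
    arr = X.vectors if is_em else np.asarray(X, dtype=np.float64)
    if d >= arr.shape[1]:
        raise ValueError(f"target dimension {d} must be < input dimension {arr.shape[1]}")
    if scale:
        sd = arr.std(axis=0, ddof=0)
        arr = np.where(sd > 0, (arr - arr.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    if method == "pca":
        reduced = pca_reduce(arr, d)
    elif method == "umap":
        import umap

        reducer = umap.UMAP(n_components=d, random_state=seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # umap warns about forced n_jobs=1
            reduced = np.asarray(reducer.fit_transform(arr), dtype=np.float64)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    if is_em:
        return EmbeddingMatrix(reduced, X.row_keys, f"{X.extractor_id}+{method}{d}")
    return reduced


def negative_sq_euclidean(X: np.ndarray) -> np.ndarray:
    """Pairwise similarity matrix S[i, j] = -||x_i - x_j||^2."""
    X = np.asarray(X, dtype=np.float64)
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return -d2


class AffinityPropagation(ClusterMixin, BaseEstimator):
    """Exemplar-based clustering by responsibility/availability message passing.

    Parameters
    ----------
    damping : float in [0.5, 1)
        Update damping factor.
    max_iter, convergence_iter : int
        Iteration cap and the number of iterations the exemplar set must stay
        unchanged to declare convergence.
    preference : float or None
        Self-similarity placed on the diagonal; None uses the median
        off-diagonal similarity.
    affinity : "euclidean" | "precomputed"
        With "euclidean", ``fit(X)`` builds S as negative squared Euclidean
        distances from the feature rows.

    Attributes (after ``fit``)
    --------------------------
    labels_, cluster_centers_indices_, n_iter_, converged_
    """

    def __init__(self, damping: float = 0.5, max_iter: int = 200,
                 convergence_iter: int = 15, preference: float | None = None,
                 affinity: str = "euclidean"):
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter
        self.preference = preference
        self.affinity = affinity

    def fit(self, X, y=None):
        if not 0.5 <= self.damping < 1.0:
            raise ValueError("damping must be in [0.5, 1)")
        if self.affinity == "precomputed":
            S = np.array(X, dtype=np.float64)
        elif self.affinity == "euclidean":
            S = negative_sq_euclidean(X)
        else:
            raise ValueError(f"unknown affinity {self.affinity!r}")
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        n = S.shape[0]
        if self.preference is None:
            off = ~np.eye(n, dtype=bool)
            pref = float(np.median(S[off])) if n > 1 else 0.0
        else:
            pref = float(self.preference)
        self.preference_ = pref
        S = S.copy()
        S.flat[:: n + 1] = pref

        A = np.zeros((n, n))
        R = np.zeros((n, n))
        ind = np.arange(n)
        e_history = np.zeros((n, self.convergence_iter), dtype=int)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # responsibilities
            tmp = A + S
            I = np.argmax(tmp, axis=1)
            Y = tmp[ind, I]
            tmp[ind, I] = -np.inf
            Y2 = np.max(tmp, axis=1)
            tmp = S - Y[:, None]
            tmp[ind, I] = S[ind, I] - Y2
            tmp *= 1.0 - self.damping
            R *= self.damping
            R += tmp
            # availabilities
            tmp = np.maximum(R, 0)
            tmp.flat[:: n + 1] = R.flat[:: n + 1]
            tmp -= np.sum(tmp, axis=0)
            dA = np.diag(tmp).copy()
            np.clip(tmp, 0, np.inf, out=tmp)
            tmp.flat[:: n + 1] = dA
            tmp *= 1.0 - self.damping
            A *= self.damping
            A -= tmp
            # convergence: exemplar set stable across the window
            E = (np.diag(A) + np.diag(R)) > 0
            e_history[:, (it - 1) % self.convergence_iter] = E
            if it >= self.convergence_iter:
                se = e_history.sum(axis=1)
                stable = np.all((se == self.convergence_iter) | (se == 0))
                if stable and E.sum() > 0:
                    converged = True
                    break
        self.n_iter_ = it
        self.converged_ = converged

        I = np.flatnonzero((np.diag(A) + np.diag(R)) > 0)
        if len(I) == 0:
            warnings.warn(
                "affinity propagation produced no exemplars; "
                "returning a single best-effort cluster",
                stacklevel=2,
            )
            I = np.array([int(np.argmax(S.sum(axis=0)))])
            self.converged_ = False
        K = len(I)
        c = np.argmax(S[:, I], axis=1)
        c[I] = np.arange(K)
        # refine each exemplar to the intra-cluster similarity maximiser
        for k in range(K):
            ii = np.flatnonzero(c == k)
            j = np.argmax(np.sum(S[ii[:, None], ii], axis=0))
            I[k] = ii[j]
        c = np.argmax(S[:, I], axis=1)
        c[I] = np.arange(K)
        self.cluster_centers_indices_ = I
        self.labels_ = c
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def result(self, row_keys) -> ClusterResult:
        """Package fitted labels as a :class:`ClusterResult` keyed by minutes."""
        row_keys = tuple(row_keys)
        return ClusterResult(
            assignments=tuple(int(l) for l in self.labels_),
            exemplars=tuple(row_keys[i] for i in self.cluster_centers_indices_),
            n_clusters=len(self.cluster_centers_indices_),
            converged=bool(self.converged_),
            row_keys=row_keys,
        )


def contingency(assignments, true_classes) -> pd.DataFrame:
    """Cluster-by-class contingency table: counts[c, k] = minutes assigned to
    cluster c whose known class is k."""
    assignments = list(assignments)
    true_classes = list(true_classes)
    if len(assignments) != len(true_classes):
        raise ValueError(
            f"length mismatch: {len(assignments)} assignments, "
            f"{len(true_classes)} classes"
        )
    return pd.crosstab(
        pd.Series(assignments, name="cluster"), pd.Series(true_classes, name="class")
    )


def chi_square(table: pd.DataFrame | np.ndarray) -> FidelityScore:
    """Pearson chi-squared on a contingency table (no continuity correction).

    Rows/columns with zero marginals are dropped first; a table degenerate to
    one row or one column scores chi2 = 0 with df = 0.
    """
    df_in = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    arr = df_in.to_numpy(dtype=float)
    if arr.sum() <= 0:
        raise ValueError("contingency table total must be positive")
    keep_r = arr.sum(axis=1) > 0
    keep_c = arr.sum(axis=0) > 0
    trimmed = df_in.loc[keep_r, keep_c]
    dropped_rows = int((~keep_r).sum())
    dropped_cols = int((~keep_c).sum())
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        return FidelityScore(0.0, 0, 1.0, trimmed, dropped_rows, dropped_cols)
    chi2, p, dof, _ = stats.chi2_contingency(trimmed.to_numpy(float), correction=False)
    return FidelityScore(float(chi2), int(dof), float(p), trimmed,
                         dropped_rows, dropped_cols)


def permutation_fidelity(assignments, true_classes, n_permutations: int = 200,
                         seed: int = 0) -> dict:
    """Chi-squared on the true labels versus a label-permutation null.

    Cluster assignments stay fixed; class labels are permuted
    ``n_permutations`` times. Returns the observed chi2, the permutation
    distribution, and the observed value's percentile within it.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(true_classes))
    observed = chi_square(contingency(assignments, labels))
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = chi_square(contingency(assignments, rng.permutation(labels))).chi2
    percentile = float(np.mean(null < observed.chi2) * 100.0)
    return {
        "chi2": observed.chi2,
        "df": observed.df,
        "p": observed.p,
        "null_chi2": null,
        "percentile": percentile,
        "null_q99": float(np.quantile(null, 0.99)),
    }
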