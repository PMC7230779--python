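"""Unsupervised cluster-number selection and discriminant analysis (DAPC).

The workflow mirrors the classical DAPC pipeline: genotypes are centered and
decomposed by PCA; k-means over a grid of k on the retained principal
components selects the cluster number by an AIC surrogate
``AIC(k) = n ln(WSS_k / n) + 2k``; linear discriminant analysis on the PC
scores with the inferred labels yields at most k-1 discriminant axes and
Gaussian membership probabilities; new individuals (spats) are projected
through the stored PCA and discriminant transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "ClusterModel",
    "pca",
    "find_clusters",
    "dapc_fit",
    "xval_select_npca",
    "assign_spats",
    "fit_structure",
]


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, k) projections
    loadings: np.ndarray  # (loci, k) eigenvector weights
    mean: np.ndarray  # per-locus centering vector
    explained_variance: np.ndarray
    locus_key: np.ndarray  # "scaffold:pos" identifiers for projection checks

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def cumulative_variance_axes(self, fraction: float = 0.95) -> int:
        frac = np.cumsum(self.explained_variance) / self.explained_variance.sum()
        return int(np.searchsorted(frac, fraction) + 1)


def _locus_key(matrix: GenotypeMatrix) -> np.ndarray:
    lm = matrix.locus_meta
    return (lm["scaffold"].astype(str) + ":" + lm["pos"].astype(str)).to_numpy()


def pca(matrix: GenotypeMatrix, scale: bool = False) -> PCAResult:
    """Centered PCA of the genotype matrix (requires imputed, complete input).

    Axis signs are fixed by forcing each axis's largest-magnitude loading
    positive, so repeated runs are bit-identical.
    """
    if np.any(matrix.genotypes == MISSING):
        raise ValueError("PCA requires complete genotypes; impute first")
    x = matrix.genotypes.astype(float)
    mean = x.mean(axis=0)
    xc = x - mean
    sd = None
    if scale:
        sd = xc.std(axis=0)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign convention
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    n = x.shape[0]
    explained = s**2 / max(n - 1, 1)
    keep = s > 1e-10 * max(s[0], 1.0) if s.size else np.zeros(0, bool)
    return PCAResult(
        scores=(u * s)[:, keep],
        loadings=vt[keep].T,
        mean=mean if sd is None else np.vstack([mean, sd]),
        explained_variance=explained[keep],
        locus_key=_locus_key(matrix),
    )


@dataclass
class FindClustersResult:
    aic_by_k: pd.DataFrame  # columns: k, wss, aic
    best_k: int
    assignments: np.ndarray
    n_axes_used: int


def find_clusters(
    pca_result: PCAResult,
    k_max: int = 10,
    seed: int = 0,
    n_axes: int | None = None,
    n_init: int = 10,
) -> FindClustersResult:
    """K-means over k = 1..k_max on retained PCs; pick k minimizing AIC.

    ``n_axes`` defaults to the axes covering 95% of cumulative variance.
    """
    scores = pca_result.scores
    n = scores.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be < number of individuals")
    if n_axes is None:
        n_axes = pca_result.cumulative_variance_axes(0.95)
    n_axes = min(n_axes, scores.shape[1])
    x = scores[:, :n_axes]

    rows, assignments = [], {}
    for k in range(1, k_max + 1):
        if k == 1:
            centroid = x.mean(axis=0)
            wss = float(((x - centroid) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            labels = km.fit_predict(x)
            wss = float(km.inertia_)
        aic = n * np.log(max(wss, 1e-300) / n) + 2.0 * k
        rows.append({"k": k, "wss": wss, "aic": aic})
        assignments[k] = labels
    tab = pd.DataFrame(rows)
    best_k = int(tab.loc[tab["aic"].idxmin(), "k"])
    return FindClustersResult(
        aic_by_k=tab,
        best_k=best_k,
        assignments=assignments[best_k],
        n_axes_used=n_axes,
    )


@dataclass
class ClusterModel:
    """Fitted PCA + discriminant model with membership probabilities."""

    k: int
    pca_axes_retained: int
    pca_loadings: np.ndarray
    pca_mean: np.ndarray
    locus_key: np.ndarray
    centroids: np.ndarray
    aic_by_k: pd.DataFrame | None
    assignments: np.ndarray
    membership: np.ndarray
    discriminant_axes: np.ndarray
    classes: np.ndarray
    lda: LinearDiscriminantAnalysis = field(repr=False, default=None)

    def membership_by_site(self, sites: np.ndarray) -> pd.DataFrame:
        """Mean membership per sampling site (composition-plot table)."""
        df = pd.DataFrame(self.membership, columns=[f"cluster{c}" for c in self.classes])
        df["site"] = np.asarray(sites)
        return df.groupby("site").mean()


def dapc_fit(
    pca_result: PCAResult,
    labels: np.ndarray,
    n_pca: int | None = None,
    aic_by_k: pd.DataFrame | None = None,
) -> ClusterModel:
    """Linear discriminant analysis on the first ``n_pca`` PC scores.

    Membership probabilities come from the shared-covariance Gaussian model
    of classical LDA.  At most k-1 discriminant axes exist for k groups.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every label needs >= 2 members")
    if n_pca is None:
        n_pca = pca_result.cumulative_variance_axes(0.95)
    if n_pca > pca_result.n_axes:
        warnings.warn("n_pca exceeds available axes; truncated")
        n_pca = pca_result.n_axes
    x = pca_result.scores[:, :n_pca]
    lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=False)
    try:
        lda.fit(x, labels)
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6)
        lda.fit(x, labels)
    membership = lda.predict_proba(x)
    centroids = np.vstack([x[labels == c].mean(axis=0) for c in classes])
    return ClusterModel(
        k=len(classes),
        pca_axes_retained=n_pca,
        pca_loadings=pca_result.loadings,
        pca_mean=pca_result.mean,
        locus_key=pca_result.locus_key,
        centroids=centroids,
        aic_by_k=aic_by_k,
        assignments=lda.predict(x),
        membership=membership,
        discriminant_axes=lda.scalings_[:, : len(classes) - 1],
        classes=classes,
        lda=lda,
    )


def xval_select_npca(
    pca_result: PCAResult,
    labels: np.ndarray,
    grid: list[int] | None = None,
    holdout_fraction: float = 0.1,
    n_rep: int = 30,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Repeated stratified holdout to pick the number of PCs for DAPC.

    Returns ``(best_n_pca, curve)``; ties resolve to the smallest grid value.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    usable_classes = classes[counts >= 2]
    if len(usable_classes) < len(classes):
        warnings.warn("classes with < 2 members excluded from stratification")
    keep = np.isin(labels, usable_classes)
    x_all, y_all = pca_result.scores[keep], labels[keep]
    if grid is None:
        grid = sorted(set(np.unique(np.linspace(1, pca_result.n_axes - 1, 8, dtype=int))))
    grid = [g for g in grid if 0 <= g < x_all.shape[0]]

    success = np.zeros((len(grid), n_rep))
    for rep in range(n_rep):
        test_idx = []
        for c in usable_classes:
            idx = np.flatnonzero(y_all == c)
            n_hold = max(1, int(round(holdout_fraction * len(idx))))
            test_idx.extend(rng.choice(idx, size=n_hold, replace=False))
        test_idx = np.asarray(test_idx)
        train_mask = np.ones(len(y_all), dtype=bool)
        train_mask[test_idx] = False
        for gi, npc in enumerate(grid):
            if npc == 0:
                # no information: predict the majority class
                maj = usable_classes[np.argmax([np.sum(y_all[train_mask] == c) for c in usable_classes])]
                success[gi, rep] = np.mean(y_all[test_idx] == maj)
                continue
            lda = LinearDiscriminantAnalysis()
            lda.fit(x_all[train_mask, :npc], y_all[train_mask])
            success[gi, rep] = lda.score(x_all[test_idx, :npc], y_all[test_idx])
    curve = pd.DataFrame({"n_pca": grid, "mean_success": success.mean(axis=1)})
    best = int(curve.loc[curve["mean_success"].idxmax(), "n_pca"])
    return best, curve


def assign_spats(
    model: ClusterModel, spat_matrix: GenotypeMatrix
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project spats through the fitted PCA + LDA; return membership + labels."""
    key = _locus_key(spat_matrix)
    if len(key) != len(model.locus_key) or not np.array_equal(key, model.locus_key):
        extra = set(key) - set(model.locus_key)
        missing = set(model.locus_key) - set(key)
        raise ValueError(
            f"locus mismatch: {len(missing)} missing, {len(extra)} extra "
            f"(e.g. missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
        )
    if np.any(spat_matrix.genotypes == MISSING):
        raise ValueError("spat matrix must be complete; impute first")
    x = spat_matrix.genotypes.astype(float)
    if model.pca_mean.ndim == 2:  # scaled PCA stored (mean, sd)
        xc = (x - model.pca_mean[0]) / model.pca_mean[1]
    else:
        xc = x - model.pca_mean
    scores = xc @ model.pca_loadings[:, : model.pca_axes_retained]
    membership = model.lda.predict_proba(scores)
    hard = model.lda.predict(scores)
    out = pd.DataFrame(
        membership,
        columns=[f"cluster{c}" for c in model.classes],
        index=spat_matrix.individual_meta["id"].to_numpy(),
    )
    return out, hard


def fit_structure(
    matrix: GenotypeMatrix,
    k_max: int = 10,
    seed: int = 0,
    n_pca: int | None = None,
) -> tuple[PCAResult, FindClustersResult, ClusterModel]:
    """Convenience wrapper: PCA -> find_clusters -> DAPC on the inferred labels."""
    pc = pca(matrix)
    fc = find_clusters(pc, k_max=k_max, seed=seed)
    if fc.best_k < 2:
        raise ValueError("best k = 1: no discriminable structure to fit")
    model = dapc_fit(pc, fc.assignments, n_pca=n_pca, aic_by_k=fc.aic_by_k)
    return pc, fc, model
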