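"""Dimensionality reduction and clustering views of the genotype matrix.

PCA is computed on mean-imputed, column-centred dosage codes; LDA is a
Fisher discriminant with a small ridge on the within-class scatter,
needed because the number of sites typically dwarfs the number of
samples and the scatter matrix is singular.  Axis signs are fixed by
making each axis's largest-magnitude loading positive, so projections
are fully deterministic.  Class separation in a projection is scored by
the mean silhouette.  The structure check appends the top principal
components as extra features and re-runs the consensus ensemble: if any
PC reaches the consensus threshold, phenotype and population structure
are confounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.cluster.hierarchy import leaves_list, linkage

from .boost import FitResult
from .ensemble import ConsensusSet, EnsembleConfig, consensus_select
from .genotype import GenotypeMatrix, PhenotypeTable

__all__ = [
    "Projection",
    "pca_project",
    "lda_project",
    "separation_score",
    "structure_check",
    "StructureReport",
    "cluster_heatmap",
    "HeatmapClustering",
]


@dataclass
class Projection:
    coordinates: np.ndarray  # (n_samples, k)
    axis_labels: list[str]
    method: str
    explained_variance_fraction: np.ndarray | None = None  # PCA only
    sample_ids: list[str] = field(default_factory=list)
    loadings: np.ndarray | None = None  # (n_sites, k)
    center: np.ndarray | None = None    # per-site mean used for centring

    def transform(self, matrix: GenotypeMatrix) -> "Projection":
        """Project new samples with the fitted axes (same site subset)."""
        if self.loadings is None or self.center is None:
            raise ValueError("projection has no stored loadings")
        X = matrix.imputed()
        coords = (X - self.center) @ self.loadings
        return Projection(
            coordinates=coords, axis_labels=self.axis_labels,
            method=self.method, sample_ids=list(matrix.sample_ids),
            loadings=self.loadings, center=self.center,
        )


def _fix_signs(components: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each axis so its largest-magnitude loading is positive."""
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
            coords[:, i] *= -1
    return components, coords


def pca_project(
    matrix: GenotypeMatrix, k: int = 2, max_sites: int | None = 200_000, seed: int = 0
) -> Projection:
    """Principal-component projection of the imputed, centred codes.

    When the matrix exceeds ``max_sites`` columns, a seeded uniform
    subsample of sites keeps the decomposition at desk scale (the cap is
    recorded in the axis metadata).
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.imputed()
    capped = False
    if max_sites is not None and X.shape[1] > max_sites:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(X.shape[1], size=max_sites, replace=False))
        X = X[:, cols]
        capped = True
    if k > min(matrix.n_samples - 1, X.shape[1]):
        raise ValueError(f"k={k} exceeds the rank bound")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :k] * s[:k]
    total_var = float((s**2).sum())
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    if total_var == 0:
        coords = np.zeros((matrix.n_samples, k))
        components = Vt[:k]
    else:
        components, coords = _fix_signs(Vt[:k].copy(), coords)
    labels = [f"PC{i+1}" + (" (site-capped)" if capped else "") for i in range(k)]
    return Projection(
        coordinates=coords, axis_labels=labels, method="pca",
        explained_variance_fraction=np.asarray(explained),
        sample_ids=list(matrix.sample_ids),
        loadings=components.T if total_var > 0 else Vt[:k].T,
        center=X.mean(axis=0),
    )


def lda_project(
    matrix: GenotypeMatrix,
    phenos: PhenotypeTable,
    k: int = 2,
    ridge: float = 1e-6,
) -> Projection:
    """Fisher linear discriminant projection.

    Maximizes between-class over within-class scatter of the imputed,
    centred codes.  The within-class scatter is regularized by
    ``ridge * trace(Sw)/d`` on the diagonal, since with many more sites
    than samples Sw is singular.  ``k`` is capped at n_classes - 1.
    """
    y = np.array(phenos.labels_for(matrix.sample_ids))
    classes = [c for c in phenos.class_set if (y == c).sum() > 0]
    rank_bound = len(classes) - 1
    if rank_bound < 1:
        raise ValueError("LDA needs at least 2 classes")
    k = min(k, rank_bound)
    X = matrix.imputed()
    Xc = X - X.mean(axis=0)
    d = Xc.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    grand = Xc.mean(axis=0)
    for c in classes:
        Xi = Xc[y == c]
        mu = Xi.mean(axis=0)
        dev = Xi - mu
        Sw += dev.T @ dev
        diff = (mu - grand)[:, None]
        Sb += Xi.shape[0] * (diff @ diff.T)
    lam = ridge * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0)
    Sw_reg = Sw + lam * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1][:k]
    W = eigvecs[:, order]
    coords = Xc @ W
    W_T, coords = _fix_signs(W.T.copy(), coords)
    return Projection(
        coordinates=coords,
        axis_labels=[f"LD{i+1}" for i in range(k)],
        method="lda",
        sample_ids=list(matrix.sample_ids),
        loadings=W_T.T,
        center=X.mean(axis=0),
    )


def separation_score(projection: Projection, phenos: PhenotypeTable) -> float:
    """Mean silhouette of the class labelling in projected space.

    Degenerate geometry (all coordinates identical) and singleton
    classes contribute 0 by convention.
    """
    from scipy.spatial.distance import squareform, pdist

    y = np.array(phenos.labels_for(projection.sample_ids))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("silhouette needs at least 2 classes")
    D = squareform(pdist(projection.coordinates))
    n = len(y)
    scores = np.zeros(n)
    for i in range(n):
        same = (y == y[i])
        n_same = same.sum()
        if n_same <= 1:
            scores[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(
            D[i, y == c].mean() for c in classes if c != y[i]
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


@dataclass
class StructureReport:
    confounded: bool
    pc_model_counts: dict[str, int]
    n_pcs: int
    consensus: ConsensusSet


def structure_check(
    matrix: GenotypeMatrix,
    phenos: PhenotypeTable,
    config: EnsembleConfig,
    n_pcs: int = 10,
    pc_gain_share_min: float = 0.05,
) -> StructureReport:
    """Confounding check: top PCs as extra features in the ensemble.

    The top ``n_pcs`` principal-component coordinates are appended as
    additional feature columns and the full consensus procedure re-runs.
    If any PC feature reaches ``min_models`` replicate support, the
    phenotype is flagged as confounded with population structure.

    Because PC coordinates are continuous they offer far more split
    points than 0/1/2 dosages and accumulate small noise gains in almost
    every model; a PC therefore counts as important in a replicate only
    when it captures at least ``pc_gain_share_min`` of that replicate's
    total gain, which keeps the flag quiet when the signal sits in the
    SNPs (structure-driven phenotypes put an order of magnitude more
    gain on the PCs than chance splits do).
    """
    from . import ensemble as _ens
    from .boost import stratified_split, train_eval, tune

    if n_pcs == 0:
        res = _ens.run_ensemble(matrix, phenos, config)
        consensus = consensus_select(res, config.min_models)
        return StructureReport(confounded=False, pc_model_counts={},
                               n_pcs=0, consensus=consensus)

    proj = pca_project(matrix, k=min(n_pcs, matrix.n_samples - 1), max_sites=None)
    pc_ids = [f"PC{i+1}" for i in range(proj.coordinates.shape[1])]
    X = np.hstack([matrix.to_features(), proj.coordinates.astype(np.float32)])
    feature_ids = matrix.site_ids + pc_ids
    aug = _AugmentedFeatures(matrix, X, feature_ids)

    fits: list[FitResult] = []
    for r in range(config.n_replicates):
        split_seed, tune_seed = config.replicate_seeds(r)
        split = stratified_split(phenos, config.n_test, seed=split_seed)
        params, cv_auc = tune(
            aug, phenos, split.train_ids,
            n_trials=config.n_trials_per_replicate,
            n_folds=config.n_folds, seed=tune_seed,
            space=config.search_space, auc_average=config.auc_average,
        )
        fits.append(train_eval(aug, phenos, split, params, cv_auc=cv_auc,
                               auc_average=config.auc_average))
    consensus = consensus_select(fits, config.min_models)
    pc_counts = {p: 0 for p in pc_ids}
    for fit in fits:
        total_gain = sum(fit.importance.values())
        if total_gain <= 0:
            continue
        for p in pc_ids:
            if fit.importance.get(p, 0.0) / total_gain >= pc_gain_share_min:
                pc_counts[p] += 1
    confounded = any(c >= config.min_models for c in pc_counts.values())
    return StructureReport(confounded=confounded, pc_model_counts=pc_counts,
                           n_pcs=n_pcs, consensus=consensus)


class _AugmentedFeatures:
    """GenotypeMatrix look-alike carrying extra non-genotype columns.

    Exposes just the surface the training stage touches: sample_ids,
    site_ids and to_features().
    """

    def __init__(self, matrix: GenotypeMatrix, X: np.ndarray, feature_ids: list[str]):
        self.sample_ids = list(matrix.sample_ids)
        self._X = X
        self.site_ids = feature_ids

    def to_features(self) -> np.ndarray:
        return self._X


@dataclass
class HeatmapClustering:
    sample_linkage: np.ndarray
    site_linkage: np.ndarray | None
    sample_order: list[int]
    site_order: list[int]
    matrix: np.ndarray  # imputed codes, rendering payload
    sample_ids: list[str]
    site_ids: list[str]


def cluster_heatmap(matrix: GenotypeMatrix, phenos: PhenotypeTable | None = None) -> HeatmapClustering:
    """Average-linkage hierarchical clustering of samples and sites.

    Distances are Euclidean on dosage codes with MISSING imputed to the
    site mean (rendering may still show missing cells as their own
    category).  Returns merge heights and leaf orders for both axes.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty site subset")
    X = matrix.imputed()
    if matrix.n_samples == 1:
        return HeatmapClustering(
            sample_linkage=np.empty((0, 4)), site_linkage=None,
            sample_order=[0], site_order=list(range(matrix.n_sites)),
            matrix=X, sample_ids=list(matrix.sample_ids), site_ids=matrix.site_ids,
        )
    sample_link = linkage(X, method="average", metric="euclidean")
    sample_order = leaves_list(sample_link).tolist()
    if matrix.n_sites >= 2:
        site_link = linkage(X.T, method="average", metric="euclidean")
        site_order = leaves_list(site_link).tolist()
    else:
        site_link, site_order = None, [0]
    return HeatmapClustering(
        sample_linkage=sample_link, site_linkage=site_link,
        sample_order=sample_order, site_order=site_order,
        matrix=X, sample_ids=list(matrix.sample_ids), site_ids=matrix.site_ids,
    )
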