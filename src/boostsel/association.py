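"""Univariate mixed-model association baseline.

Per-SNP linear mixed models on binary class contrasts:

    y = 1 alpha + x beta + u + eps,   u ~ N(0, sg2 K),  eps ~ N(0, se2 I)

with K the centred relatedness (kinship) matrix, K = (1/p) sum_j c_j c_j'
over mean-centred genotype columns c_j.  The variance-ratio
delta = se2 / sg2 is profiled out by a one-off eigendecomposition of K
(the spectral trick): rotating by the eigenvectors makes the covariance
diagonal, so for any delta the generalized least-squares fit is a
weighted regression and the restricted likelihood is cheap to evaluate.
delta is maximized over a log-spaced grid with golden-section
refinement; the Wald statistic (beta/se)^2 is referred to chi-square(1).

Class contrasts run pairwise over all unordered class pairs; a fixed
genome-wide threshold (default 1e-8) marks significance, following the
convention of reporting a single Bonferroni-style cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .genotype import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "KinshipMatrix",
    "AssocResult",
    "centered_relatedness",
    "lmm_wald",
    "pairwise_gwas",
    "PairwiseGwasResult",
    "compare_selections",
]


@dataclass
class KinshipMatrix:
    values: np.ndarray  # (n, n)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = K


def centered_relatedness(matrix: GenotypeMatrix) -> KinshipMatrix:
    """Centred relatedness matrix K = (1/p) sum_j c_j c_j'.

    Missing genotypes are imputed to the site mean before centring, so
    every row and column of K sums to zero.
    """
    if matrix.n_sites == 0:
        raise ValueError("kinship needs at least one site")
    X = matrix.imputed()
    Xc = X - X.mean(axis=0)
    K = (Xc @ Xc.T) / matrix.n_sites
    return KinshipMatrix(values=K, sample_ids=list(matrix.sample_ids))


@dataclass
class AssocResult:
    site_id: str
    contrast: tuple[str, str]
    beta: float
    se: float
    wald_stat: float
    p_value: float
    significant: bool
    skipped: bool = False
    skip_reason: str = ""


def _reml_neg_loglik(
    log_delta: float,
    yr: np.ndarray,
    Xr: np.ndarray,
    S: np.ndarray,
) -> float:
    """-2x restricted log-likelihood (up to constants) at a given delta.

    Inputs are the phenotype and design rotated into the eigenbasis of
    K; S holds the kinship eigenvalues.
    """
    delta = np.exp(log_delta)
    d = S + delta
    w = 1.0 / d
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    n, c = Xr.shape
    rss = float(r @ (r * w))
    if rss <= 0:
        return np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    # REML: (n-c) log sigma_g^2 + log|H| + log|X' H^-1 X|
    return (n - c) * np.log(rss / (n - c)) + float(np.log(d).sum()) + logdet_XtWX


def _fit_delta(
    yr: np.ndarray,
    Xr: np.ndarray,
    S: np.ndarray,
    grid_lo: float = 1e-5,
    grid_hi: float = 1e5,
    n_grid: int = 60,
) -> float:
    """REML estimate of delta = se2/sg2 by grid search + local refinement."""
    grid = np.log(np.logspace(np.log10(grid_lo), np.log10(grid_hi), n_grid))
    vals = np.array([_reml_neg_loglik(g, yr, Xr, S) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if lo == hi:
        return float(np.exp(grid[i]))
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(yr, Xr, S), method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    return float(np.exp(best))


def lmm_wald(
    matrix: GenotypeMatrix,
    y: np.ndarray,
    K: KinshipMatrix,
    p_threshold: float = 1e-8,
    contrast: tuple[str, str] = ("0", "1"),
) -> list[AssocResult]:
    """Per-site Wald tests under the kinship mixed model.

    ``y`` is a binary 0/1 phenotype over ``matrix.sample_ids`` (order
    must match ``K``).  Sites with zero genotypic variance after
    imputation are skipped with a recorded reason.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both classes")
    if K.sample_ids != matrix.sample_ids:
        raise ValueError("kinship sample order differs from the genotype matrix")
    S, U = np.linalg.eigh(K.values)
    S = np.clip(S, 0.0, None)
    yr = U.T @ y
    ones_r = U.T @ np.ones(matrix.n_samples)
    X = matrix.imputed()

    results: list[AssocResult] = []
    for j, sid in enumerate(matrix.site_ids):
        x = X[:, j]
        if np.var(x) == 0:
            results.append(AssocResult(
                site_id=sid, contrast=contrast, beta=np.nan, se=np.nan,
                wald_stat=np.nan, p_value=np.nan, significant=False,
                skipped=True, skip_reason="zero genotypic variance",
            ))
            continue
        Xr = np.column_stack([ones_r, U.T @ x])
        delta = _fit_delta(yr, Xr, S)
        w = 1.0 / (S + delta)
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (yr * w)
        XtWX_inv = np.linalg.inv(XtWX)
        beta_hat = XtWX_inv @ XtWy
        r = yr - Xr @ beta_hat
        n, c = Xr.shape
        sg2 = float(r @ (r * w)) / (n - c)  # REML scale
        var_beta = sg2 * XtWX_inv[1, 1]
        beta = float(beta_hat[1])
        se = float(np.sqrt(var_beta))
        wald = (beta / se) ** 2
        p = float(chi2.sf(wald, df=1))
        results.append(AssocResult(
            site_id=sid, contrast=contrast, beta=beta, se=se,
            wald_stat=float(wald), p_value=p, significant=p < p_threshold,
        ))
    return results


@dataclass
class PairwiseGwasResult:
    per_pair: dict[tuple[str, str], list[AssocResult]]
    significant_union: dict[str, list[tuple[str, str]]]  # site -> pairs
    p_threshold: float


def pairwise_gwas(
    matrix: GenotypeMatrix,
    phenos: PhenotypeTable,
    classes: list[str] | None = None,
    p_threshold: float = 1e-8,
    kinship_per_pair: bool = True,
) -> PairwiseGwasResult:
    """LMM-Wald scan for every unordered pair of the named classes.

    For each pair the samples are restricted to the two classes and (by
    default) the kinship matrix is recomputed on that subset.  The union
    of significant sites is reported with per-pair provenance.
    """
    if classes is None:
        classes = list(phenos.class_set)
    counts = phenos.class_counts()
    for c in classes:
        if c not in phenos.class_set:
            raise ValueError(f"unknown class {c!r}")
        if counts.get(c, 0) == 0:
            raise ValueError(f"class {c!r} has no samples")
    full_K = None if kinship_per_pair else centered_relatedness(matrix)
    per_pair: dict[tuple[str, str], list[AssocResult]] = {}
    union: dict[str, list[tuple[str, str]]] = {}
    for a, b in itertools.combinations(classes, 2):
        keep = [
            i for i, s in enumerate(matrix.sample_ids)
            if phenos.assignments.get(s) in (a, b)
        ]
        sub = matrix.subset_samples(keep)
        y = np.array(
            [1.0 if phenos.assignments[s] == b else 0.0 for s in sub.sample_ids]
        )
        if kinship_per_pair:
            K = centered_relatedness(sub)
        else:
            K = KinshipMatrix(
                values=full_K.values[np.ix_(keep, keep)],
                sample_ids=sub.sample_ids,
            )
        res = lmm_wald(sub, y, K, p_threshold=p_threshold, contrast=(a, b))
        per_pair[(a, b)] = res
        for r in res:
            if r.significant:
                union.setdefault(r.site_id, []).append((a, b))
    return PairwiseGwasResult(per_pair=per_pair, significant_union=union,
                              p_threshold=p_threshold)


def compare_selections(
    gwas_sites: "set[str] | dict | list[str]",
    consensus_sites: "set[str] | list[str]",
    gwas_genes: set[str] | None = None,
    consensus_genes: set[str] | None = None,
) -> dict:
    """Overlap report between the GWAS union and the consensus set."""
    g = set(gwas_sites)
    c = set(consensus_sites)
    report = {
        "n_gwas": len(g),
        "n_consensus": len(c),
        "snp_intersection": sorted(g & c),
        "n_snp_intersection": len(g & c),
        "size_ratio": round(len(g) / len(c), 1) if c else float("inf"),
    }
    if gwas_genes is not None and consensus_genes is not None:
        inter = set(gwas_genes) & set(consensus_genes)
        report.update({
            "n_gwas_genes": len(set(gwas_genes)),
            "n_consensus_genes": len(set(consensus_genes)),
            "gene_intersection": sorted(inter),
            "n_gene_intersection": len(inter),
        })
    return report
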