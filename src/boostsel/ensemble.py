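"""Replicate-model ensemble, consensus SNP selection and collinear expansion.

The ensemble trains R independently tuned boosted classifiers on R random
stratified splits (replicate r uses split seed ``base_seed + r``).  A SNP
enters the consensus set when it carries strictly positive gain in at
least ``min_models`` replicates — the operational reading of "important
in at least m models".  The consensus set is then expanded with collinear
SNPs: any non-selected site whose genotype column has |Pearson r| at or
above ``r_min`` with a selected anchor (pairwise-complete over called
genotypes, minimum 10 shared samples) joins the combined set.  Retraining
the same replicate seeds on the column-restricted matrix quantifies the
noise-removal improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .boost import FitResult, HyperParams, SearchSpace, stratified_split, train_eval, tune
from .genotype import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "EnsembleConfig",
    "CollinearHit",
    "ConsensusSet",
    "EnsembleResult",
    "run_ensemble",
    "consensus_select",
    "expand_collinear",
    "retrain_subset",
]


@dataclass
class EnsembleConfig:
    n_replicates: int = 100
    min_models: int = 9
    n_test: int = 24
    n_trials_per_replicate: int = 250
    n_folds: int = 4
    base_seed: int = 0
    search_space: SearchSpace = field(default_factory=SearchSpace)
    auc_average: str = "macro"  # "macro" | "weighted" one-vs-rest

    def __post_init__(self) -> None:
        if not 1 <= self.min_models:
            raise ValueError("min_models must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def replicate_seeds(self, r: int) -> tuple[int, int]:
        """(split seed, tuning seed) for replicate r."""
        split_seed = self.base_seed + r
        tune_seed = int(
            np.random.SeedSequence([self.base_seed, r]).generate_state(1)[0] % (2**31)
        )
        return split_seed, tune_seed


@dataclass
class CollinearHit:
    site_id: str
    anchor_id: str
    r: float


@dataclass
class ConsensusSet:
    """Selected SNPs with replicate support, plus collinear additions."""

    selected: dict[str, int]  # site id -> model_count
    collinear_added: list[CollinearHit] = field(default_factory=list)

    @property
    def combined(self) -> list[str]:
        extra = [h.site_id for h in self.collinear_added]
        return list(self.selected) + [s for s in dict.fromkeys(extra) if s not in self.selected]


@dataclass
class EnsembleResult:
    fits: list[FitResult]
    summary: dict

    def __iter__(self):
        return iter(self.fits)


def _summarize(fits: list[FitResult]) -> dict:
    acc = [f.test_metrics["accuracy"] for f in fits]
    f1w = [f.test_metrics["weighted"]["f1"] for f in fits]
    auc = [f.test_metrics["auc"] for f in fits]
    cv = [f.cv_auc for f in fits]
    return {
        "n_replicates": len(fits),
        "mean_accuracy": float(np.mean(acc)),
        "max_accuracy": float(np.max(acc)),
        "min_accuracy": float(np.min(acc)),
        "mean_f1_weighted": float(np.mean(f1w)),
        "mean_auc": float(np.nanmean(auc)),
        "mean_cv_auc": float(np.nanmean(cv)),
    }


def run_ensemble(
    matrix: GenotypeMatrix, phenos: PhenotypeTable, config: EnsembleConfig
) -> EnsembleResult:
    """Train ``n_replicates`` independently tuned models on random splits."""
    fits: list[FitResult] = []
    for r in range(config.n_replicates):
        split_seed, tune_seed = config.replicate_seeds(r)
        split = stratified_split(phenos, config.n_test, seed=split_seed)
        params, cv_auc = tune(
            matrix, phenos, split.train_ids,
            n_trials=config.n_trials_per_replicate,
            n_folds=config.n_folds, seed=tune_seed,
            space=config.search_space, auc_average=config.auc_average,
        )
        fits.append(
            train_eval(matrix, phenos, split, params, cv_auc=cv_auc,
                       auc_average=config.auc_average)
        )
    return EnsembleResult(fits=fits, summary=_summarize(fits))


def consensus_select(results: list[FitResult] | EnsembleResult, min_models: int) -> ConsensusSet:
    """SNPs with strictly positive gain in at least ``min_models`` replicates."""
    fits = list(results)
    if not fits:
        raise ValueError("no fit results")
    if min_models > len(fits):
        warnings.warn(
            f"min_models={min_models} exceeds the {len(fits)} replicates; "
            "consensus set is empty", stacklevel=2,
        )
    counts: dict[str, int] = {}
    for fit in fits:
        for site, gain in fit.importance.items():
            if gain > 0:
                counts[site] = counts.get(site, 0) + 1
    selected = {s: c for s, c in counts.items() if c >= min_models}
    return ConsensusSet(selected=selected)


def _pairwise_complete_pearson(
    anchor: np.ndarray, others: np.ndarray, min_shared: int
) -> np.ndarray:
    """|r| between one anchor column and each column of ``others``.

    Pairwise-complete over non-missing entries; pairs with fewer than
    ``min_shared`` shared called samples, or zero variance on either
    side, yield NaN.
    """
    a_ok = anchor != MISSING
    o_ok = others != MISSING
    both = a_ok[:, None] & o_ok
    n = both.sum(axis=0).astype(float)
    a = np.where(both, anchor[:, None], 0.0)
    b = np.where(both, others, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = a.sum(axis=0) / n
        mean_b = b.sum(axis=0) / n
        cov = (a * b).sum(axis=0) / n - mean_a * mean_b
        var_a = (a * a).sum(axis=0) / n - mean_a**2
        var_b = (b * b).sum(axis=0) / n - mean_b**2
        r = cov / np.sqrt(var_a * var_b)
    r[(n < min_shared) | (var_a <= 0) | (var_b <= 0)] = np.nan
    return r


def expand_collinear(
    matrix: GenotypeMatrix,
    selected: "ConsensusSet | dict[str, int] | list[str]",
    r_min: float = 0.97,
    signed: bool = False,
    min_shared: int = 10,
) -> list[CollinearHit]:
    """Find non-selected sites collinear with a selected anchor.

    By default correlation is taken in absolute value (allele coding
    makes the sign arbitrary); ``signed=True`` requires r >= r_min
    directly.  Each hit records the anchor with the strongest
    correlation.  Constant columns never match.
    """
    if isinstance(selected, ConsensusSet):
        anchor_ids = list(selected.selected)
    elif isinstance(selected, dict):
        anchor_ids = list(selected)
    else:
        anchor_ids = list(selected)
    id_to_col = {sid: j for j, sid in enumerate(matrix.site_ids)}
    missing_anchors = [a for a in anchor_ids if a not in id_to_col]
    if missing_anchors:
        raise ValueError(f"anchor sites not in matrix: {missing_anchors[:5]}")
    anchor_cols = [id_to_col[a] for a in anchor_ids]
    anchor_set = set(anchor_cols)
    other_cols = np.array([j for j in range(matrix.n_sites) if j not in anchor_set], dtype=int)
    if len(other_cols) == 0 or not anchor_cols:
        return []
    codes = matrix.codes.astype(np.float64)
    others = codes[:, other_cols]
    best_score = np.full(len(other_cols), -np.inf)
    best_r = np.full(len(other_cols), np.nan)
    best_anchor = np.full(len(other_cols), -1, dtype=int)
    for k, aj in enumerate(anchor_cols):
        r = _pairwise_complete_pearson(codes[:, aj], others, min_shared)
        score = r if signed else np.abs(r)
        score = np.where(np.isnan(score), -np.inf, score)
        better = score > best_score
        best_score[better] = score[better]
        best_r[better] = r[better]
        best_anchor[better] = k
    hits: list[CollinearHit] = []
    site_ids = matrix.site_ids
    for i, j in enumerate(other_cols):
        if best_score[i] >= r_min:
            hits.append(
                CollinearHit(site_id=site_ids[j], anchor_id=anchor_ids[best_anchor[i]],
                             r=float(best_r[i]))
            )
    return hits


def retrain_subset(
    matrix: GenotypeMatrix,
    phenos: PhenotypeTable,
    site_ids: list[str],
    config: EnsembleConfig,
) -> EnsembleResult:
    """Re-run the ensemble on a column-restricted matrix, same seeds."""
    if not site_ids:
        raise ValueError("site set is empty")
    id_to_col = {sid: j for j, sid in enumerate(matrix.site_ids)}
    cols = [id_to_col[s] for s in site_ids]
    return run_ensemble(matrix.subset_sites(cols), phenos, config)


def consensus_table(consensus: ConsensusSet, matrix: GenotypeMatrix):
    """Tab-ready table of the combined set: chrom, pos, model_count, anchor, r."""
    import pandas as pd

    meta = {s.site_id: s for s in matrix.sites}
    rows = []
    for sid, count in consensus.selected.items():
        site = meta[sid]
        rows.append({"site_id": sid, "chrom": site.chrom, "pos": site.pos,
                     "model_count": count, "anchor": "", "r": np.nan})
    for hit in consensus.collinear_added:
        site = meta[hit.site_id]
        rows.append({"site_id": hit.site_id, "chrom": site.chrom, "pos": site.pos,
                     "model_count": 0, "anchor": hit.anchor_id, "r": hit.r})
    return pd.DataFrame(rows)
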