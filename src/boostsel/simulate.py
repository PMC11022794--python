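"""Synthetic genotype/phenotype generator for desk-scale pipeline studies.

Genotypes follow the Balding-Nichols model: an ancestral allele frequency
p_j ~ Uniform(freq_lo, freq_hi) per site, a subpopulation frequency drawn
from Beta(p_j(1-F)/F, (1-p_j)(1-F)/F) at fixation index F, and diploid
dosages Binomial(2, subpop frequency).  Linkage disequilibrium is modeled
by intra-block template copying: within each block of ``ld_block_size``
consecutive sites, every site after the first copies the first site's
genotype column, re-drawing each entry independently from the genotype
distribution with probability ``ld_flip_prob``.  This produces the
Pearson-correlated columns the collinearity stage needs without
simulating recombination.

Colour classes come from a multinomial-logit liability over a small set
of planted causal SNPs: score_c(i) = intercept_c + sum_j effects[c][j] *
dosage(i, causal_j), with missing dosages counted as 0 so missingness
never leaks class information.  Labels are the argmax of the scores or a
softmax draw.

The default configuration mirrors a three-colour re-sequencing cohort at
reduced scale: 300 accessions, 5000 SNPs, three classes at roughly a
45:27:23 imbalance, mild structure (3 subpopulations, FST 0.05), tight
5-site LD blocks and 8 causal SNPs with strong effects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype import MISSING, GenotypeMatrix, PhenotypeTable, VariantSite

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "assign_phenotypes",
    "simulate_dataset",
    "emit_vcf",
    "write_truth",
]


def _default_effects() -> list[list[float]]:
    # class order: white (reference, all zero), beige, orange; each
    # non-reference class loads on its own four causal SNPs with signed,
    # mixed-magnitude effects so liability scores are centred around the
    # intercepts on a fine lattice (intercepts chosen by exact enumeration
    # to give roughly 45:27:23 class proportions at causal frequency 0.5).
    return [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [2.0, 1.2, -2.0, -1.2, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 2.0, 1.2, -2.0, -1.2],
    ]


@dataclass
class SimulationConfig:
    n_samples: int = 300
    n_sites: int = 5000
    n_subpops: int = 3
    fst: float = 0.05
    freq_lo: float = 0.1
    freq_hi: float = 0.9
    ld_block_size: int = 5
    ld_flip_prob: float = 0.01
    missing_rate: float = 0.02
    n_causal: int = 8
    class_labels: tuple[str, ...] = ("white", "beige", "orange")
    intercepts: tuple[float, ...] = (1.2, 0.1, 0.0)
    effects: list[list[float]] = field(default_factory=_default_effects)
    sampling_mode: str = "argmax"  # "argmax" | "softmax-draw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_sites:
            raise ValueError("n_causal cannot exceed n_sites")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 < self.freq_lo <= self.freq_hi < 1.0:
            raise ValueError("frequency bounds must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.ld_flip_prob <= 0.5:
            raise ValueError("ld_flip_prob must be in [0, 0.5]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        k = len(self.class_labels)
        if len(self.intercepts) != k:
            raise ValueError("one intercept per class required")
        eff = np.asarray(self.effects, dtype=float)
        if eff.shape != (k, self.n_causal):
            raise ValueError(
                f"effects must be (n_classes={k}) x (n_causal={self.n_causal}),"
                f" got {eff.shape}"
            )
        if self.sampling_mode not in ("argmax", "softmax-draw"):
            raise ValueError("sampling_mode must be 'argmax' or 'softmax-draw'")


@dataclass
class SyntheticTruth:
    """Planted signal: which sites are causal and how they map to classes."""

    causal_indices: list[int]
    effects: np.ndarray  # (n_classes, n_causal)
    subpop_assignment: np.ndarray  # (n_samples,) integer

    def __post_init__(self) -> None:
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ValueError("causal indices must be distinct")


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw a genotype matrix under the Balding-Nichols + LD-block model."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_sites
    k_pop = config.n_subpops

    ancestral = rng.uniform(config.freq_lo, config.freq_hi, size=p)
    # Causal sites sit at LD-block template positions with their ancestral
    # frequency pinned to the middle of the band: templates propagate to
    # their block (giving every causal SNP collinear proxies) and the fixed
    # frequency keeps liability-score spread, hence class proportions,
    # comparable across seeds.
    bs = config.ld_block_size
    templates = np.arange(0, p, bs)
    if config.n_causal > len(templates):
        raise ValueError("n_causal exceeds the number of LD blocks")
    causal = np.sort(rng.choice(templates, size=config.n_causal, replace=False))
    ancestral[causal] = 0.5
    if config.fst > 0.0:
        a = ancestral * (1.0 - config.fst) / config.fst
        b = (1.0 - ancestral) * (1.0 - config.fst) / config.fst
        subpop_freq = rng.beta(a[None, :], b[None, :], size=(k_pop, p))
    else:
        subpop_freq = np.broadcast_to(ancestral, (k_pop, p)).copy()

    subpop = rng.integers(0, k_pop, size=n)
    freq_per_sample = subpop_freq[subpop, :]  # (n, p)
    codes = rng.binomial(2, freq_per_sample).astype(np.int8)

    # LD blocks: sites 2..k of each block copy site 1's column, with an
    # independent per-entry re-draw at ld_flip_prob.
    if bs > 1:
        for start in range(0, p, bs):
            stop = min(start + bs, p)
            for j in range(start + 1, stop):
                col = codes[:, start].copy()
                redraw = rng.random(n) < config.ld_flip_prob
                if redraw.any():
                    col[redraw] = rng.binomial(
                        2, freq_per_sample[redraw, j]
                    ).astype(np.int8)
                codes[:, j] = col

    if config.missing_rate > 0.0:
        miss = rng.random((n, p)) < config.missing_rate
        codes[miss] = MISSING

    sample_ids = [f"S{i:04d}" for i in range(n)]
    sites = [
        VariantSite(chrom="chr1", pos=100 * (j + 1), ref="A", alt="T")
        for j in range(p)
    ]
    matrix = GenotypeMatrix(sample_ids=sample_ids, sites=sites, codes=codes)
    truth = SyntheticTruth(
        causal_indices=[int(c) for c in causal],
        effects=np.asarray(config.effects, dtype=float),
        subpop_assignment=subpop,
    )
    return matrix, truth


def liability_scores(
    matrix: GenotypeMatrix, truth: SyntheticTruth, config: SimulationConfig
) -> np.ndarray:
    """(n_samples, n_classes) liability scores; MISSING dosages count as 0."""
    dose = matrix.codes[:, truth.causal_indices].astype(float)
    dose[dose == MISSING] = 0.0
    return np.asarray(config.intercepts, dtype=float)[None, :] + dose @ truth.effects.T


def assign_phenotypes(
    matrix: GenotypeMatrix, truth: SyntheticTruth, config: SimulationConfig
) -> PhenotypeTable:
    """Assign class labels from the multinomial-logit liability."""
    scores = liability_scores(matrix, truth, config)
    labels = list(config.class_labels)
    if config.sampling_mode == "argmax":
        choice = np.argmax(scores, axis=1)
    else:
        rng = np.random.default_rng(config.seed + 1)
        z = scores - scores.max(axis=1, keepdims=True)
        prob = np.exp(z)
        prob /= prob.sum(axis=1, keepdims=True)
        u = rng.random((matrix.n_samples, 1))
        choice = (prob.cumsum(axis=1) < u).sum(axis=1)
    assignments = {
        sid: labels[c] for sid, c in zip(matrix.sample_ids, choice)
    }
    return PhenotypeTable(assignments=assignments, class_set=labels)


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[GenotypeMatrix, PhenotypeTable, SyntheticTruth]:
    """Convenience wrapper: genotypes + phenotypes in one call."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    matrix, truth = simulate_genotypes(config)
    phenos = assign_phenotypes(matrix, truth, config)
    return matrix, phenos, truth


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def emit_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the matrix as a minimal VCF 4.2 file with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for s in matrix.sites:
            if s.chrom not in chroms:
                chroms.append(s.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + matrix.sample_ids) + "\n")
        for j, site in enumerate(matrix.sites):
            gts = "\t".join(_GT_STR[int(c)] for c in matrix.codes[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_truth(
    truth: SyntheticTruth,
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    path: str | os.PathLike,
) -> None:
    """Tab-separated truth file: site index, chrom, pos, per-class effects."""
    labels = config.class_labels
    with open(path, "w") as fh:
        fh.write("#site_index\tchrom\tpos\t" + "\t".join(f"effect_{l}" for l in labels) + "\n")
        for k, j in enumerate(truth.causal_indices):
            site = matrix.sites[j]
            eff = "\t".join(f"{truth.effects[c][k]:g}" for c in range(len(labels)))
            fh.write(f"{j}\t{site.chrom}\t{site.pos}\t{eff}\n")
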