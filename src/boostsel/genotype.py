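"""Genotype matrix I/O: VCF reading with site-level filters, 012 encoding.

The central container is :class:`GenotypeMatrix`, a samples x sites grid of
alternate-allele dosages (0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate) with a reserved ``MISSING`` sentinel (-1) for
uncalled genotypes.  On disk the matrix round-trips through the three-file
``012`` text dialect popularised by vcftools: ``<prefix>.012`` (one row per
sample, leading row index, missing written as -1), ``<prefix>.012.indv``
(sample ids) and ``<prefix>.012.pos`` (chrom/pos pairs).

Coordinates are 1-based inclusive externally (VCF/GFF convention); no
internal conversion is needed because sites are point positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "PhenotypeTable",
    "VcfFilterConfig",
    "VcfParseError",
    "read_vcf",
    "write_012",
    "read_012",
    "maf_filter",
    "read_phenotypes",
    "write_phenotypes",
]

#: In-memory and on-disk sentinel for an uncalled genotype.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed or violates expectations."""


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNP site.

    ``site_stats`` carries whatever numeric INFO annotations the caller
    emitted (MQ, DP, FS, ...); absent keys simply do not constrain
    filtering.
    """

    chrom: str
    pos: int  # 1-based
    ref: str = "A"
    alt: str = "T"
    site_stats: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of 0/1/2 dosage codes with MISSING = -1."""

    sample_ids: list[str]
    sites: list[VariantSite]
    codes: np.ndarray  # (n_samples, n_sites), integer

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        n, p = self.codes.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"codes has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.sites):
            raise ValueError(f"codes has {p} columns but {len(self.sites)} sites")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise ValueError(f"codes outside {{0,1,2,{MISSING}}}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def to_features(self) -> np.ndarray:
        """Float copy with MISSING as NaN, suitable for tree learners."""
        X = self.codes.astype(np.float32)
        X[self.codes == MISSING] = np.nan
        return X

    def imputed(self) -> np.ndarray:
        """Float copy with MISSING replaced by the per-site mean of called codes.

        Sites with no called genotypes impute to 0.
        """
        X = self.codes.astype(np.float64)
        miss = self.codes == MISSING
        if miss.any():
            X[miss] = np.nan
            col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
            col_mean = np.nan_to_num(col_mean, nan=0.0)
            idx = np.where(miss)
            X[idx] = col_mean[idx[1]]
        return X

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=[self.sites[i] for i in idx],
            codes=self.codes[:, idx].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            sites=list(self.sites),
            codes=self.codes[idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and [(s.chrom, s.pos) for s in self.sites]
            == [(s.chrom, s.pos) for s in other.sites]
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class PhenotypeTable:
    """Sample -> categorical class label, with an ordered label universe."""

    assignments: dict[str, str]
    class_set: list[str]

    def __post_init__(self) -> None:
        extra = set(self.assignments.values()) - set(self.class_set)
        if extra:
            raise ValueError(f"labels outside class_set: {sorted(extra)}")
        if len(set(self.class_set)) != len(self.class_set):
            raise ValueError("class_set entries must be unique")

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.assignments[s] for s in sample_ids]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_set}
        for lab in self.assignments.values():
            counts[lab] += 1
        return counts

    def restrict(self, classes: Iterable[str]) -> "PhenotypeTable":
        keep = [c for c in self.class_set if c in set(classes)]
        assignments = {s: l for s, l in self.assignments.items() if l in keep}
        return PhenotypeTable(assignments=assignments, class_set=keep)


@dataclass
class VcfFilterConfig:
    """Site-level hard filters applied while reading a VCF.

    Thresholds follow common GATK-style hard filtering for short variants.
    A site lacking a given annotation passes that single criterion; the
    filters constrain only what the variant caller emitted.  ``dp_*``
    bounds apply to the per-site total depth (the cohort-wide DP INFO
    field); set them to +/-inf for per-sample callers.
    """

    mq_min: float = 30.0
    mleaf_min: float = 0.01
    dp_min: float = 300.0
    dp_max: float = 1500.0
    fs_max: float = 60.0
    mqranksum_abs_max: float = 12.5
    readpos_abs_max: float = 8.0
    baseq_abs_max: float = 12.5
    biallelic_only: bool = True
    max_nocall_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_nocall_fraction <= 1.0:
            raise ValueError("max_nocall_fraction must be in [0, 1]")

    @classmethod
    def pass_all(cls) -> "VcfFilterConfig":
        """A configuration that retains every biallelic site."""
        inf = float("inf")
        return cls(
            mq_min=-inf, mleaf_min=-inf, dp_min=-inf, dp_max=inf, fs_max=inf,
            mqranksum_abs_max=inf, readpos_abs_max=inf, baseq_abs_max=inf,
            max_nocall_fraction=1.0,
        )

    def site_passes(self, stats: Mapping[str, float]) -> bool:
        """Apply every annotation threshold present in ``stats``."""

        def ok(key: str, test) -> bool:
            v = stats.get(key)
            return v is None or test(float(v))

        return (
            ok("MQ", lambda v: v > self.mq_min)
            and ok("MLEAF", lambda v: v > self.mleaf_min)
            and ok("DP", lambda v: self.dp_min < v < self.dp_max)
            and ok("FS", lambda v: v < self.fs_max)
            and ok("MQRankSum", lambda v: abs(v) <= self.mqranksum_abs_max)
            and ok("ReadPosRankSum", lambda v: abs(v) <= self.readpos_abs_max)
            and ok("BaseQRankSum", lambda v: abs(v) <= self.baseq_abs_max)
        )


_STAT_KEYS = ("MQ", "MLEAF", "DP", "FS", "MQRankSum", "ReadPosRankSum", "BaseQRankSum")


def read_vcf(path: str | os.PathLike, filters: VcfFilterConfig | None = None) -> GenotypeMatrix:
    """Read a VCF into a 0/1/2 genotype matrix, applying site filters.

    Multi-allelic records are dropped when ``biallelic_only`` is set;
    genotype calls map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 and any
    missing call -> MISSING (phase separators are ignored).  Sites whose
    missing-call fraction exceeds ``max_nocall_fraction`` are removed.
    Site order is preserved.
    """
    from cyvcf2 import VCF

    if filters is None:
        filters = VcfFilterConfig()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on bad input
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} declares zero samples")

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    n = len(samples)
    try:
        for rec in vcf:
            if filters.biallelic_only and len(rec.ALT) != 1:
                continue
            if not rec.ALT:
                continue
            stats = {}
            for key in _STAT_KEYS:
                v = rec.INFO.get(key)
                if v is not None:
                    stats[key] = float(v)
            if not filters.site_passes(stats):
                continue
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types
            col = np.full(n, MISSING, dtype=np.int8)
            col[gt == 0] = 0
            col[gt == 1] = 1
            col[gt == 3] = 2
            nocall = float(np.mean(col == MISSING))
            if nocall > filters.max_nocall_fraction:
                continue
            sites.append(
                VariantSite(
                    chrom=rec.CHROM, pos=rec.POS,
                    ref=rec.REF, alt=rec.ALT[0], site_stats=stats,
                )
            )
            columns.append(col)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc

    codes = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=samples, sites=sites, codes=codes)


def write_012(matrix: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write the vcftools-style three-file 012 dialect.

    ``<prefix>.012`` rows carry a leading 0-based row index; MISSING is
    written as -1.
    """
    prefix = str(prefix)
    with open(prefix + ".012", "w") as fh:
        for i in range(matrix.n_samples):
            row = "\t".join(str(int(c)) for c in matrix.codes[i])
            fh.write(f"{i}\t{row}\n" if matrix.n_sites else f"{i}\n")
    with open(prefix + ".012.indv", "w") as fh:
        for sid in matrix.sample_ids:
            fh.write(sid + "\n")
    with open(prefix + ".012.pos", "w") as fh:
        for site in matrix.sites:
            fh.write(f"{site.chrom}\t{site.pos}\n")


def read_012(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Inverse of :func:`write_012`; -1 maps back to MISSING."""
    prefix = str(prefix)
    with open(prefix + ".012.indv") as fh:
        sample_ids = [ln.strip() for ln in fh if ln.strip()]
    sites: list[VariantSite] = []
    with open(prefix + ".012.pos") as fh:
        for ln in fh:
            if not ln.strip():
                continue
            chrom, pos = ln.split("\t")
            sites.append(VariantSite(chrom=chrom, pos=int(pos)))
    rows: list[list[int]] = []
    with open(prefix + ".012") as fh:
        for ln in fh:
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            rows.append([int(x) for x in fields[1:]])
    if len(rows) != len(sample_ids):
        raise ValueError(
            f"{prefix}.012 has {len(rows)} rows but .012.indv lists "
            f"{len(sample_ids)} samples"
        )
    for r in rows:
        if len(r) != len(sites):
            raise ValueError(
                f"{prefix}.012 row width {len(r)} != {len(sites)} sites in .012.pos"
            )
        bad = set(r) - _VALID_CODES
        if bad:
            raise ValueError(f"codes outside 012 domain in {prefix}.012: {sorted(bad)}")
    codes = (
        np.array(rows, dtype=np.int8)
        if sites
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=sample_ids, sites=sites, codes=codes)


def alt_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site alt-allele frequency over called genotypes; NaN if none called."""
    called = matrix.codes != MISSING
    n_called = called.sum(axis=0)
    alt_sum = np.where(called, matrix.codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt_sum / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    return freq


def maf_filter(matrix: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Drop sites whose minor-allele frequency falls below ``maf_min``.

    Frequency is computed over non-missing codes; sites with zero called
    genotypes have undefined frequency and are removed.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    freq = alt_allele_frequency(matrix)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(~np.isnan(maf) & (maf >= maf_min))[0]
    return matrix.subset_sites(keep)


def read_phenotypes(path: str | os.PathLike, class_set: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a two-column tab-separated sample/label table.

    Lines starting with ``#`` are comments.  When ``class_set`` is not
    given, labels are ordered by first appearance.
    """
    assignments: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
            sid, lab = fields[0].strip(), fields[1].strip()
            if sid in assignments:
                raise ValueError(f"{path}:{i}: duplicate sample id {sid!r}")
            assignments[sid] = lab
            if lab not in order:
                order.append(lab)
    return PhenotypeTable(
        assignments=assignments,
        class_set=list(class_set) if class_set is not None else order,
    )


def write_phenotypes(phenos: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tclass_label\n")
        for sid, lab in phenos.assignments.items():
            fh.write(f"{sid}\t{lab}\n")
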