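"""SNP genotype matrices: simulation, I/O, and quality control.

Genotypes are coded 0/1/2 as the count of an arbitrary reference allele
("aa", "Aa", "AA"); -1 marks a missing call.  The simulator emulates a
dense bovine SNP-chip panel: biallelic SNPs arranged in LD blocks along
chromosomes, a uniform minor-allele-frequency spectrum, Hardy-Weinberg
genotype proportions at each locus, and a small uniform missing-call rate.
QC mirrors standard pre-prediction filtering: chromosome exclusion, MAF,
per-SNP missing rate, and an exact Hardy-Weinberg equilibrium test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "GenotypeSimConfig",
    "QCConfig",
    "QCReport",
    "simulate_genotypes",
    "hwe_test",
    "apply_qc",
    "read_genotypes",
    "write_genotypes",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """n x m genotype codes with a SNP map.

    Attributes
    ----------
    samples : list of sample IDs (length n).
    snps : list of SNP IDs (length m).
    chrom : per-SNP chromosome label, dtype object/str.
    pos : per-SNP 1-based base-pair position; strictly increasing within
        a chromosome.
    codes : (n, m) int8 array in {0, 1, 2} with -1 for missing.
    """

    samples: list[str]
    snps: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.codes = np.asarray(self.codes)
        n, m = self.codes.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("SNP map length does not match number of SNPs")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2} or -1 (missing)")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return self.missing_mask.mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency p of the counted allele among non-missing calls."""
        codes = np.ma.masked_equal(self.codes, MISSING)
        return np.asarray(codes.mean(axis=0) / 2.0)

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Codes as float with missing entries filled by the SNP's rounded mean."""
        out = self.codes.astype(np.float64)
        mask = self.missing_mask
        if mask.any():
            fill = np.rint(2.0 * self.allele_freq)
            out[mask] = np.broadcast_to(fill, out.shape)[mask]
        return out

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            snps=[self.snps[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            codes=self.codes[:, idx],
        )


@dataclass
class GenotypeSimConfig:
    n_individuals: int = 2000
    n_snps: int = 5000
    n_chromosomes: int = 10
    block_length: int = 20
    within_block_corr: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        if self.n_chromosomes <= 0 or self.block_length <= 0:
            raise ValueError("n_chromosomes and block_length must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class QCConfig:
    maf_min: float = 0.05
    missing_max: float = 0.05
    hwe_alpha: float = 1e-6
    drop_chroms: frozenset[str] = frozenset({"X"})

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.missing_max <= 1.0):
            raise ValueError("missing_max must be in [0, 1]")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in (0, 1)")
        self.drop_chroms = frozenset(str(c) for c in self.drop_chroms)


@dataclass
class QCReport:
    """SNP IDs removed by each rule (a SNP may appear under several rules)."""

    removed: dict[str, list[str]] = field(default_factory=dict)
    n_before: int = 0
    n_after: int = 0

    @property
    def removed_any(self) -> set[str]:
        return set().union(*self.removed.values()) if self.removed else set()


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_genotypes(config: GenotypeSimConfig) -> GenotypeMatrix:
    """Simulate a biallelic SNP panel with block LD structure.

    Each SNP's counted-allele frequency is uniform on ``maf_range`` with
    random allele orientation.  Haplotypes follow a first-order Markov
    copula within LD blocks: a latent uniform is either carried over from
    the previous SNP (probability ``within_block_corr``) or redrawn, and
    the allele is the indicator ``u < p``.  This preserves exact marginal
    allele frequencies (hence Hardy-Weinberg proportions at the genotype
    level, genotype = sum of two independent haplotypes) while inducing
    adjacent-SNP correlation that rises with ``within_block_corr``.
    Missing calls are injected uniformly at random afterwards.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - maf, maf)

    # chromosome/position map: m SNPs split as evenly as possible
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chrom = np.concatenate(
        [np.full(k, str(c + 1), dtype=object) for c, k in enumerate(per_chrom)]
    )
    pos = np.concatenate([np.arange(1, k + 1, dtype=np.int64) * 1000 for k in per_chrom])

    # block starts never straddle a chromosome boundary
    chrom_starts = np.cumsum(np.concatenate([[0], per_chrom[:-1]]))
    block_start = np.zeros(m, dtype=bool)
    for s, k in zip(chrom_starts, per_chrom):
        block_start[s : s + k : config.block_length] = True

    n_hap = 2 * n
    u = rng.random((n_hap, m))
    carry = rng.random((n_hap, m)) < config.within_block_corr
    for j in range(1, m):
        if block_start[j]:
            continue
        u[:, j] = np.where(carry[:, j], u[:, j - 1], u[:, j])
    alleles = (u < p).astype(np.int8)
    codes = alleles[:n] + alleles[n:]

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        codes = np.where(miss, np.int8(MISSING), codes)

    samples = [f"ind{i + 1:05d}" for i in range(n)]
    snps = [f"snp{j + 1:06d}" for j in range(m)]
    return GenotypeMatrix(samples=samples, snps=snps, chrom=chrom, pos=pos, codes=codes)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_test(n_aa: int, n_Aa: int, n_AA: int) -> float:
    """Two-sided exact test for departure from Hardy-Weinberg proportions.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of all tables no more
    probable than the observed one (plain exact test, no mid-p
    correction).  Monomorphic SNPs return 1.0: with one segregating
    allele there is no testable deviation.
    """
    if min(n_aa, n_Aa, n_AA) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_Aa + n_AA
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # count of the rarer-or-not allele "a"
    n_A = 2 * n_AA + n_Aa
    n_minor = min(n_a, n_A)
    if n_minor == 0:
        return 1.0

    # heterozygote count shares the parity of the minor-allele count
    het = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - het) // 2
    hom_major = n - het - hom_minor
    # P(het | allele counts) under HWE, Levene-Haldane distribution
    logp = (
        gammaln(n + 1)
        - gammaln(het + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
        + het * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    observed = prob[het == n_Aa][0]
    return float(min(1.0, prob[prob <= observed * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def apply_qc(g: GenotypeMatrix, qc: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by chromosome, MAF, missing rate, and exact HWE.

    A SNP failing any rule is dropped; the report lists removals per
    rule, so rule order never changes the surviving set.  Residual
    missing calls in the surviving matrix are imputed to each SNP's
    rounded mean code; the pre-imputation mask is kept on the result
    (``missing_before_imputation``).
    """
    qc = qc or QCConfig()
    report = QCReport(n_before=g.m)
    snp_ids = np.asarray(g.snps, dtype=object)

    chrom_fail = np.isin(g.chrom.astype(str), list(qc.drop_chroms))
    maf_fail = g.maf < qc.maf_min
    miss_fail = g.missing_rate > qc.missing_max

    hwe_p = np.ones(g.m)
    codes = g.codes
    for j in range(g.m):
        col = codes[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        n_aa = int((col == 0).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        hwe_p[j] = hwe_test(n_aa, n_Aa, n_AA)
    hwe_fail = hwe_p < qc.hwe_alpha

    report.removed = {
        "chrom": list(snp_ids[chrom_fail]),
        "maf": list(snp_ids[maf_fail]),
        "missing": list(snp_ids[miss_fail]),
        "hwe": list(snp_ids[hwe_fail]),
    }
    keep = ~(chrom_fail | maf_fail | miss_fail | hwe_fail)
    report.n_after = int(keep.sum())
    if report.n_after == 0:
        raise ValueError("QC removed every SNP")

    out = g.take_snps(np.flatnonzero(keep))
    mask = out.missing_mask.copy()
    if mask.any():
        fill = np.rint(2.0 * out.allele_freq).astype(np.int8)
        filled = out.codes.copy()
        filled[mask] = np.broadcast_to(fill, filled.shape)[mask]
        out = replace(out, codes=filled)
    out.missing_before_imputation = mask  # type: ignore[attr-defined]
    return out, report


# ---------------------------------------------------------------------------
# I/O: TSV (samples x SNPs), PLINK .raw, VCF v4.2
# ---------------------------------------------------------------------------

_FORMATS = ("tsv", "plink_raw", "vcf")


def _map_path(path: str) -> str:
    return str(path) + ".map"


def _write_map(g: GenotypeMatrix, path: str) -> None:
    with open(_map_path(path), "w") as fh:
        fh.write("snp\tchrom\tpos\n")
        for s, c, p in zip(g.snps, g.chrom, g.pos):
            fh.write(f"{s}\t{c}\t{p}\n")


def _read_map(path: str, snps: list[str]) -> tuple[np.ndarray, np.ndarray]:
    import os

    if os.path.exists(_map_path(path)):
        rows = {}
        with open(_map_path(path)) as fh:
            next(fh)
            for line in fh:
                s, c, p = line.rstrip("\n").split("\t")
                rows[s] = (c, int(p))
        chrom = np.array([rows[s][0] for s in snps], dtype=object)
        pos = np.array([rows[s][1] for s in snps], dtype=np.int64)
        return chrom, pos
    return (
        np.array(["1"] * len(snps), dtype=object),
        np.arange(1, len(snps) + 1, dtype=np.int64),
    )


def write_genotypes(g: GenotypeMatrix, path, format: str = "tsv") -> str:
    """Write a genotype matrix; inverse of :func:`read_genotypes`.

    TSV and PLINK .raw carry the SNP map in a ``<path>.map`` sidecar;
    VCF records it inline.  Missing calls are written as empty cell /
    ``NA`` / ``./.`` respectively.
    """
    path = str(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(g.snps) + "\n")
            for i, s in enumerate(g.samples):
                row = ["" if c == MISSING else str(int(c)) for c in g.codes[i]]
                fh.write(s + "\t" + "\t".join(row) + "\n")
        _write_map(g, path)
    elif format == "plink_raw":
        cols = [f"{s}_A" for s in g.snps]
        with open(path, "w") as fh:
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(cols) + "\n")
            for i, s in enumerate(g.samples):
                row = ["NA" if c == MISSING else str(int(c)) for c in g.codes[i]]
                fh.write(f"{s} {s} 0 0 0 -9 " + " ".join(row) + "\n")
        _write_map(g, path)
    elif format == "vcf":
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in dict.fromkeys(g.chrom):  # preserves order
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(g.samples)
                + "\n"
            )
            for j in range(g.m):
                calls = "\t".join(gt[int(c)] for c in g.codes[:, j])
                fh.write(
                    f"{g.chrom[j]}\t{g.pos[j]}\t{g.snps[j]}\tA\tG\t.\t.\t.\tGT\t{calls}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return path


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix written by :func:`write_genotypes`.

    VCF genotypes map to ALT-allele counts (``0/1`` -> 1, ``./.`` ->
    missing); multi-allelic records are rejected.  PLINK .raw ``NA``
    tokens and empty TSV cells map to missing.
    """
    path = str(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "sample":
                raise ValueError("malformed TSV header: first column must be 'sample'")
            snps = header[1:]
            samples, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                rows.append([MISSING if v == "" else int(v) for v in parts[1:]])
        codes = np.array(rows, dtype=np.int8)
        chrom, pos = _read_map(path, snps)
    elif format == "plink_raw":
        with open(path) as fh:
            header = fh.readline().split()
            if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
                raise ValueError("malformed PLINK .raw header")
            snps = [c.rsplit("_", 1)[0] for c in header[6:]]
            samples, rows = [], []
            for line in fh:
                parts = line.split()
                samples.append(parts[1])
                rows.append([MISSING if v == "NA" else int(v) for v in parts[6:]])
        codes = np.array(rows, dtype=np.int8)
        chrom, pos = _read_map(path, snps)
    elif format == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(path, gts012=True)
        samples = list(vcf.samples)
        snps, chrom_l, pos_l, cols = [], [], [], []
        for rec in vcf:
            if len(rec.ALT) > 1:
                raise ValueError(f"multi-allelic record not supported: {rec.ID}")
            snps.append(rec.ID)
            chrom_l.append(rec.CHROM)
            pos_l.append(rec.POS)
            # gts012: 0/1/2 = ALT count, 3 = missing
            gt = np.asarray(rec.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            cols.append(gt)
        codes = np.column_stack(cols).astype(np.int8)
        chrom = np.array(chrom_l, dtype=object)
        pos = np.array(pos_l, dtype=np.int64)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return GenotypeMatrix(samples=samples, snps=snps, chrom=chrom, pos=pos, codes=codes)
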