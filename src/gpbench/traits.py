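"""Quantitative-trait simulation on SNP genotypes.

Places quantitative trait nucleotides (QTN) either at random or in
clusters of three consecutive map positions, samples additive, dominance
and two-locus epistatic effects, builds the four Hadamard-product
interaction codings (A x A, A x D, D x A, D x D), and assembles a
phenotype whose variance partition is calibrated to target heritabilities:
each genetic component is rescaled so its realized variance equals its
target fraction of a unit phenotypic variance, and the residual variance
makes up the remainder.

Effect distributions: additive a_k ~ N(0, 1); dominance d_k ~ N(0, sd 0.5)
(zero for a purely additive trait); each epistatic effect has magnitude
~ Gamma(shape 0.1, scale 10) with an independent random sign.  The allele
substitution effect is alpha_k = a_k + d_k (q_k - p_k).  Each QTN
interacts with its three downstream neighbours in genome order, giving
3*n_qtn - 6 interacting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "ArchitectureConfig",
    "QTNSet",
    "EpistaticPairList",
    "EffectSet",
    "SimulatedTrait",
    "place_qtn",
    "build_epistatic_pairs",
    "dominance_code",
    "interaction_code",
    "sample_effects",
    "compute_genetic_values",
    "assemble_phenotype",
    "simulate_trait",
]


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureConfig:
    """Genetic architecture of a simulated trait.

    ``target_h2_a``, ``target_h2_d``, ``target_h2_I`` are the target
    fractions of phenotypic variance for the additive, dominance and
    epistatic components; their sum is the broad-sense heritability.
    Additive gene action forces the dominance and epistasis targets to
    zero.  Defaults reproduce the purely additive trait with
    heritability 0.30.
    """

    gene_action: str = "additive"
    n_qtn: int = 100
    placement: str = "clustered"
    target_h2_a: float = 0.30
    target_h2_d: float = 0.0
    target_h2_I: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_action not in ("additive", "nonadditive"):
            raise ValueError("gene_action must be 'additive' or 'nonadditive'")
        if self.placement not in ("clustered", "random"):
            raise ValueError("placement must be 'clustered' or 'random'")
        if self.n_qtn <= 0:
            raise ValueError("n_qtn must be positive")
        targets = (self.target_h2_a, self.target_h2_d, self.target_h2_I)
        if any(t < 0 for t in targets):
            raise ValueError("heritability targets must be non-negative")
        if sum(targets) >= 1.0:
            raise ValueError("heritability targets must sum to < 1")
        if self.gene_action == "additive" and (self.target_h2_d or self.target_h2_I):
            raise ValueError("additive gene action requires zero dominance/epistasis targets")

    @property
    def broad_h2(self) -> float:
        return self.target_h2_a + self.target_h2_d + self.target_h2_I


@dataclass
class QTNSet:
    indices: np.ndarray  # SNP column indices, genome order
    core_flags: np.ndarray  # True where the QTN is a cluster core
    placement: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.core_flags = np.asarray(self.core_flags, dtype=bool)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("QTN indices must be distinct")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("QTN indices must be sorted in genome order")

    @property
    def n_qtn(self) -> int:
        return len(self.indices)


@dataclass
class EpistaticPairList:
    pairs: np.ndarray  # (n_pairs, 2) indices INTO the QTN list, k < k'

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy k < k'")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class EffectSet:
    additive: np.ndarray  # a_k
    dominance: np.ndarray  # d_k
    substitution: np.ndarray  # alpha_k = a_k + d_k (q_k - p_k)
    epi_aa: np.ndarray
    epi_ad: np.ndarray
    epi_da: np.ndarray
    epi_dd: np.ndarray


@dataclass
class SimulatedTrait:
    g_additive: np.ndarray
    g_dominance: np.ndarray
    g_epistatic: np.ndarray
    residual: np.ndarray
    phenotype: np.ndarray
    realized_partition: dict[str, float]
    scaling: dict[str, float]
    qtn: QTNSet | None = None
    pairs: EpistaticPairList | None = None
    effects: EffectSet | None = None
    arch: ArchitectureConfig | None = None

    @property
    def genetic_value(self) -> np.ndarray:
        """Total genetic value: the prediction target for simulated traits."""
        return self.g_additive + self.g_dominance + self.g_epistatic


# ---------------------------------------------------------------------------
# QTN placement and pairing
# ---------------------------------------------------------------------------


def place_qtn(g: GenotypeMatrix, n_qtn: int, mode: str = "clustered", seed: int = 0) -> QTNSet:
    """Choose causal SNP columns.

    Random mode: uniform sample without replacement.  Clustered mode:
    one third of the QTN are core loci sampled at random, and the two
    SNPs flanking each core on the map are QTN too, so clusters are
    triplets of consecutive map positions.  Clusters never overlap and
    never straddle a chromosome boundary.  When ``n_qtn`` is not a
    multiple of three, random singleton QTN top the set up to exactly
    ``n_qtn``.
    """
    if n_qtn > g.m:
        raise ValueError(f"n_qtn={n_qtn} exceeds number of SNPs m={g.m}")
    rng = np.random.default_rng(seed)
    if mode == "random":
        idx = np.sort(rng.choice(g.m, size=n_qtn, replace=False))
        return QTNSet(indices=idx, core_flags=np.zeros(n_qtn, dtype=bool), placement=mode)
    if mode != "clustered":
        raise ValueError("mode must be 'clustered' or 'random'")

    n_cores = n_qtn // 3
    # candidate cores: both neighbours exist on the same chromosome
    chrom = g.chrom
    interior = np.flatnonzero(
        (np.arange(g.m) > 0)
        & (np.arange(g.m) < g.m - 1)
        & (np.roll(chrom, 1) == chrom)
        & (np.roll(chrom, -1) == chrom)
    )
    if n_cores > 0 and interior.size == 0:
        raise ValueError("no chromosome is long enough to host a QTN cluster")

    taken = np.zeros(g.m, dtype=bool)
    cores: list[int] = []
    order = rng.permutation(interior)
    for c in order:
        if len(cores) == n_cores:
            break
        if not taken[c - 1 : c + 2].any():
            cores.append(int(c))
            taken[c - 1 : c + 2] = True
    if len(cores) < n_cores:
        raise ValueError("could not place non-overlapping QTN clusters; too dense")

    n_extra = n_qtn - 3 * n_cores
    free = np.flatnonzero(~taken)
    extras = rng.choice(free, size=n_extra, replace=False) if n_extra else np.empty(0, int)

    idx = np.concatenate([[c - 1, c, c + 1] for c in cores] + [extras]).astype(np.int64)
    core = np.zeros(g.m, dtype=bool)
    core[cores] = True
    ordering = np.argsort(idx)
    idx = idx[ordering]
    return QTNSet(indices=idx, core_flags=core[idx], placement=mode)


def build_epistatic_pairs(q: QTNSet) -> EpistaticPairList:
    """Pair each QTN with its three downstream neighbours in genome order.

    Yields 3*n_qtn - 6 pairs (the last three QTN run out of partners:
    2 + 1 + 0 fewer than three each).
    """
    n = q.n_qtn
    if n < 4:
        raise ValueError("epistatic pairing needs at least 4 QTN")
    pairs = [(k, k + off) for k in range(n) for off in (1, 2, 3) if k + off < n]
    return EpistaticPairList(pairs=np.array(sorted(pairs), dtype=np.int64))


# ---------------------------------------------------------------------------
# codings
# ---------------------------------------------------------------------------


def dominance_code(x_col: np.ndarray) -> np.ndarray:
    """Dominance coding: genotypes aa/Aa/AA (0/1/2) map to 0/1/0."""
    x = np.asarray(x_col)
    if not np.isin(x, (0, 1, 2)).all():
        raise ValueError("genotype codes must be in {0, 1, 2}")
    return (x == 1).astype(x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64)


def interaction_code(col1: np.ndarray, col2: np.ndarray, kind: str) -> np.ndarray:
    """Two-locus interaction coding as a Hadamard product.

    ``kind`` selects which coding each locus contributes: "AA" uses the
    additive 0/1/2 codes at both loci (products in {0,1,2,4}), "AD" and
    "DA" mix additive with dominance 0/1/0 codes (products in {0,1,2}),
    and "DD" uses dominance codes at both loci (products in {0,1}).
    """
    c1 = np.asarray(col1, dtype=np.float64)
    c2 = np.asarray(col2, dtype=np.float64)
    if c1.shape != c2.shape:
        raise ValueError("interaction columns must have equal length")
    if kind == "AA":
        return c1 * c2
    if kind == "AD":
        return c1 * dominance_code(c2)
    if kind == "DA":
        return dominance_code(c1) * c2
    if kind == "DD":
        return dominance_code(c1) * dominance_code(c2)
    raise ValueError("kind must be one of 'AA', 'AD', 'DA', 'DD'")


# ---------------------------------------------------------------------------
# effects and genetic values
# ---------------------------------------------------------------------------

# sub-stream indices off the architecture seed, so that e.g. residual
# draws can be varied while QTN effects stay fixed
_STREAMS = {"placement": 0, "additive": 1, "dominance": 2, "epi_sign": 3, "epi_mag": 4, "residual": 5}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[_STREAMS[name]])


def sample_effects(
    q: QTNSet,
    pairs: EpistaticPairList | None,
    arch: ArchitectureConfig,
    freqs: np.ndarray,
) -> EffectSet:
    """Draw QTN effects for the architecture.

    a_k ~ N(0,1); d_k ~ N(0, sd 0.5) under non-additive action, else 0;
    alpha_k = a_k + d_k (q_k - p_k); each epistatic effect vector has
    magnitudes ~ Gamma(0.1, 10) and independent signs +/-1 w.p. 1/2.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("QTN allele frequencies must lie in (0, 1)")
    if len(freqs) != q.n_qtn:
        raise ValueError("freqs length must equal n_qtn")
    n = q.n_qtn
    a = _stream(arch.seed, "additive").standard_normal(n)
    if arch.gene_action == "nonadditive":
        d = _stream(arch.seed, "dominance").normal(0.0, 0.5, size=n)
    else:
        d = np.zeros(n)
    alpha = a + d * ((1.0 - freqs) - freqs)

    n_pairs = pairs.n_pairs if (pairs is not None and arch.gene_action == "nonadditive") else 0
    if n_pairs:
        mag = _stream(arch.seed, "epi_mag").gamma(0.1, 10.0, size=(4, n_pairs))
        sign = _stream(arch.seed, "epi_sign").choice((-1.0, 1.0), size=(4, n_pairs))
        epi = mag * sign
    else:
        epi = np.zeros((4, 0))
    return EffectSet(
        additive=a,
        dominance=d,
        substitution=alpha,
        epi_aa=epi[0],
        epi_ad=epi[1],
        epi_da=epi[2],
        epi_dd=epi[3],
    )


def compute_genetic_values(
    g: GenotypeMatrix,
    q: QTNSet,
    pairs: EpistaticPairList | None,
    eff: EffectSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual additive, dominance and epistatic genetic values.

    g_additive = X alpha; g_dominance = D d; g_epistatic sums the four
    interaction codings weighted by their pair effects.  QTN columns must
    be complete (post-QC / post-imputation).
    """
    X = g.imputed()[:, q.indices]
    if X.shape[1] != len(eff.substitution):
        raise ValueError("effect vectors do not match the number of QTN")
    D = (X == 1).astype(np.float64)
    g_add = X @ eff.substitution
    g_dom = D @ eff.dominance
    g_epi = np.zeros(g.n)
    if pairs is not None and pairs.n_pairs and len(eff.epi_aa):
        if pairs.n_pairs != len(eff.epi_aa):
            raise ValueError("epistatic effect vectors do not match the pair list")
        k1 = pairs.pairs[:, 0]
        k2 = pairs.pairs[:, 1]
        X1, X2 = X[:, k1], X[:, k2]
        D1, D2 = D[:, k1], D[:, k2]
        g_epi = (
            (X1 * X2) @ eff.epi_aa
            + (X1 * D2) @ eff.epi_ad
            + (D1 * X2) @ eff.epi_da
            + (D1 * D2) @ eff.epi_dd
        )
    return g_add, g_dom, g_epi


def assemble_phenotype(
    components: tuple[np.ndarray, np.ndarray, np.ndarray],
    arch: ArchitectureConfig,
    seed: int | None = None,
) -> SimulatedTrait:
    """Calibrate components to the target variance partition and add noise.

    Each genetic component is multiplied by a constant so that its
    empirical variance equals its target fraction of a unit phenotypic
    variance (components with a zero target are zeroed).  Residuals are
    i.i.d. N(0, 1 - broad_h2).  The realized partition reports raw
    variance ratios Var(component)/Var(phenotype); covariances between
    components may make these deviate slightly from the targets.
    """
    g_add, g_dom, g_epi = (np.asarray(c, dtype=np.float64) for c in components)
    targets = {"a": arch.target_h2_a, "d": arch.target_h2_d, "I": arch.target_h2_I}
    comps = {"a": g_add, "d": g_dom, "I": g_epi}
    scaling: dict[str, float] = {}
    for key, target in targets.items():
        if target == 0.0:
            comps[key] = np.zeros_like(comps[key])
            scaling[key] = 0.0
            continue
        v = comps[key].var()
        if v <= 0:
            raise ValueError(f"component '{key}' has zero variance but a positive target")
        s = np.sqrt(target / v)
        comps[key] = (comps[key] - comps[key].mean()) * s
        scaling[key] = float(s)

    sigma2_e = 1.0 - arch.broad_h2
    rng = _stream(arch.seed if seed is None else seed, "residual")
    residual = rng.normal(0.0, np.sqrt(sigma2_e), size=len(g_add))
    phenotype = comps["a"] + comps["d"] + comps["I"] + residual

    vp = phenotype.var()
    partition = {
        "h2_a": float(comps["a"].var() / vp),
        "h2_d": float(comps["d"].var() / vp),
        "h2_I": float(comps["I"].var() / vp),
    }
    partition["H2_B"] = partition["h2_a"] + partition["h2_d"] + partition["h2_I"]
    return SimulatedTrait(
        g_additive=comps["a"],
        g_dominance=comps["d"],
        g_epistatic=comps["I"],
        residual=residual,
        phenotype=phenotype,
        realized_partition=partition,
        scaling=scaling,
        arch=arch,
    )


def simulate_trait(g: GenotypeMatrix, arch: ArchitectureConfig) -> SimulatedTrait:
    """End-to-end trait simulation on a genotype matrix."""
    q = place_qtn(g, arch.n_qtn, arch.placement, seed=_stream(arch.seed, "placement").integers(2**31))
    pairs = build_epistatic_pairs(q) if arch.gene_action == "nonadditive" else None
    freqs = g.allele_freq[q.indices]
    eff = sample_effects(q, pairs, arch, freqs)
    comps = compute_genetic_values(g, q, pairs, eff)
    trait = assemble_phenotype(comps, arch)
    trait.qtn = q
    trait.pairs = pairs
    trait.effects = eff
    return trait
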