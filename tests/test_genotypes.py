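"""Genotype simulation, exact HWE testing, QC filtering, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gpbench as gp
from gpbench.genotypes import MISSING, QCConfig, hwe_test


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def test_simulation_is_reproducible():
    cfg = gp.GenotypeSimConfig(n_individuals=50, n_snps=100, seed=3)
    a = gp.simulate_genotypes(cfg)
    b = gp.simulate_genotypes(cfg)
    assert np.array_equal(a.codes, b.codes)
    assert a.samples == b.samples and a.snps == b.snps


def test_zero_block_correlation_gives_independent_snps():
    g = gp.simulate_genotypes(
        gp.GenotypeSimConfig(
            n_individuals=5000, n_snps=40, within_block_corr=0.0, missing_rate=0.0, seed=9
        )
    )
    codes = g.codes.astype(float)
    r2 = [
        np.corrcoef(codes[:, j], codes[:, j + 1])[0, 1] ** 2
        for j in range(g.m - 1)
        if g.chrom[j] == g.chrom[j + 1]
    ]
    assert np.mean(r2) < 0.005  # Monte-Carlo error only


def test_block_correlation_raises_adjacent_ld():
    lo = gp.simulate_genotypes(
        gp.GenotypeSimConfig(n_individuals=2000, n_snps=60, within_block_corr=0.1,
                             missing_rate=0.0, seed=5)
    )
    hi = gp.simulate_genotypes(
        gp.GenotypeSimConfig(n_individuals=2000, n_snps=60, within_block_corr=0.9,
                             missing_rate=0.0, seed=5)
    )

    def mean_adjacent_r2(g):
        codes = g.codes.astype(float)
        vals = [
            np.corrcoef(codes[:, j], codes[:, j + 1])[0, 1] ** 2
            for j in range(g.m - 1)
            if g.chrom[j] == g.chrom[j + 1]
        ]
        return np.mean(vals)

    assert mean_adjacent_r2(hi) > mean_adjacent_r2(lo) + 0.2


def test_fixed_maf_recovered_in_large_sample():
    g = gp.simulate_genotypes(
        gp.GenotypeSimConfig(
            n_individuals=10_000, n_snps=50, maf_range=(0.3, 0.3), missing_rate=0.0, seed=11
        )
    )
    assert abs(g.maf.mean() - 0.3) < 0.02


def test_maf_recomputable_and_missing_rate():
    g = gp.simulate_genotypes(
        gp.GenotypeSimConfig(n_individuals=400, n_snps=80, missing_rate=0.05, seed=1)
    )
    j = 4
    col = g.codes[:, j]
    obs = col[col != MISSING]
    p = obs.mean() / 2.0
    assert abs(g.allele_freq[j] - p) < 1e-12
    assert abs(g.missing_rate.mean() - 0.05) < 0.01


def test_invalid_sim_config_rejected():
    with pytest.raises(ValueError):
        gp.GenotypeSimConfig(n_individuals=0)
    with pytest.raises(ValueError):
        gp.GenotypeSimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        gp.GenotypeSimConfig(maf_range=(0.1, 0.6))


# ---------------------------------------------------------------------------
# exact HWE test
# ---------------------------------------------------------------------------


def _hwe_enumeration_oracle(n_aa, n_Aa, n_AA):
    """Brute-force Levene-Haldane enumeration using exact rational-ish sums."""
    from math import comb

    n = n_aa + n_Aa + n_AA
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = {}
    total = 0.0
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        # multinomial count of genotype tables x 2^het haplotype phasings
        w = comb(n, het) * comb(n - het, hom_minor) * (2**het)
        probs[het] = w
        total += w
    obs = probs[n_Aa] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12)))


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((25, 50, 25), 1.0),  # heterozygote count is the modal table
        ((0, 0, 60), 1.0),  # monomorphic: nothing testable
    ],
)
def test_hwe_exact_values(counts, expected):
    assert hwe_test(*counts) == pytest.approx(expected)


def test_hwe_extreme_departure_filtered():
    assert hwe_test(50, 0, 50) < 1e-6


@given(
    n_aa=st.integers(0, 70),
    n_Aa=st.integers(0, 70),
    n_AA=st.integers(0, 70),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_matches_enumeration_oracle(n_aa, n_Aa, n_AA):
    if n_aa + n_Aa + n_AA == 0:
        return
    assert hwe_test(n_aa, n_Aa, n_AA) == pytest.approx(
        _hwe_enumeration_oracle(n_aa, n_Aa, n_AA), rel=1e-9
    )


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_test(-1, 0, 5)
    with pytest.raises(ValueError):
        hwe_test(0, 0, 0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _toy_matrix():
    """Hand-built matrix with one SNP failing each rule."""
    rng = np.random.default_rng(0)
    n = 200
    # SNP0: MAF 0.04; SNP1: 6% missing; SNP2: on chromosome X; SNP3: HWE fail;
    # SNP4..9: clean MAF ~0.3
    codes = np.zeros((n, 10), dtype=np.int8)
    freqs = [0.04, 0.3, 0.3, 0.5, 0.3, 0.3, 0.25, 0.35, 0.3, 0.4]
    for j, p in enumerate(freqs):
        codes[:, j] = rng.binomial(1, p, n) + rng.binomial(1, p, n)
    codes[:, 0] = 0
    codes[:16, 0] = 1  # exactly 16/400 alleles: MAF 0.04
    codes[: int(0.06 * n), 1] = MISSING
    codes[:, 3] = np.where(codes[:, 3] == 1, 0, codes[:, 3])  # kill heterozygotes
    chrom = np.array(["1"] * 2 + ["X"] + ["1"] * 7, dtype=object)
    pos = np.array([1, 2, 1, 3, 4, 5, 6, 7, 8, 9]) * 100
    return gp.GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        snps=[f"m{j}" for j in range(10)],
        chrom=chrom,
        pos=pos,
        codes=codes,
    )


def test_qc_rules_remove_expected_snps():
    g = _toy_matrix()
    out, report = gp.apply_qc(g, QCConfig())
    assert "m0" in report.removed["maf"]
    assert "m1" in report.removed["missing"]
    assert report.removed["chrom"] == ["m2"]
    assert "m3" in report.removed["hwe"]
    assert set(out.snps) == {"m4", "m5", "m6", "m7", "m8", "m9"}


def test_qc_chromosome_rule_is_sole_trigger():
    g = _toy_matrix()
    _, report = gp.apply_qc(g, QCConfig())
    for rule in ("maf", "missing", "hwe"):
        assert "m2" not in report.removed[rule]


def test_qc_is_idempotent(small_genotypes):
    once, _ = gp.apply_qc(small_genotypes, QCConfig())
    twice, rep2 = gp.apply_qc(once, QCConfig())
    assert once.snps == twice.snps
    assert rep2.n_before == rep2.n_after


def test_qc_imputes_residual_missingness():
    g = gp.simulate_genotypes(
        gp.GenotypeSimConfig(n_individuals=300, n_snps=60, missing_rate=0.03, seed=8)
    )
    out, _ = gp.apply_qc(g, QCConfig())
    assert not out.missing_mask.any()
    assert out.missing_before_imputation.any()


def test_qc_survival_high_at_default_settings(small_genotypes):
    _, report = gp.apply_qc(small_genotypes, QCConfig())
    assert report.n_after / report.n_before > 0.90


def test_qc_all_removed_is_error():
    g = _toy_matrix()
    with pytest.raises(ValueError):
        gp.apply_qc(g, QCConfig(maf_min=0.5))


# ---------------------------------------------------------------------------
# I/O round-trips
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["tsv", "plink_raw", "vcf"])
def test_write_read_round_trip(tmp_path, fmt):
    g = gp.simulate_genotypes(
        gp.GenotypeSimConfig(n_individuals=25, n_snps=40, missing_rate=0.05, seed=13)
    )
    path = tmp_path / f"geno.{fmt}"
    gp.write_genotypes(g, path, fmt)
    back = gp.read_genotypes(path, fmt)
    assert np.array_equal(back.codes, g.codes)
    assert back.samples == g.samples
    assert back.snps == g.snps
    assert np.array_equal(back.pos, g.pos)
    assert list(back.chrom) == list(g.chrom)


def test_vcf_code_convention(tmp_path):
    g = gp.GenotypeMatrix(
        samples=["a", "b", "c"],
        snps=["s1"],
        chrom=np.array(["1"], dtype=object),
        pos=np.array([100]),
        codes=np.array([[0], [1], [MISSING]], dtype=np.int8),
    )
    path = tmp_path / "one.vcf"
    gp.write_genotypes(g, path, "vcf")
    text = path.read_text()
    assert "0/0\t0/1\t./." in text
    back = gp.read_genotypes(path, "vcf")
    assert back.codes[1, 0] == 1 and back.codes[2, 0] == MISSING


def test_plink_raw_na_token(tmp_path):
    path = tmp_path / "g.raw"
    path.write_text(
        "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_A\n"
        "f1 s1 0 0 0 -9 2 NA\n"
        "f2 s2 0 0 0 -9 0 1\n"
    )
    g = gp.read_genotypes(path, "plink_raw")
    assert g.codes[0, 1] == MISSING
    assert g.codes[0, 0] == 2


def test_unknown_format_rejected(tmp_path):
    g = gp.simulate_genotypes(gp.GenotypeSimConfig(n_individuals=5, n_snps=5, seed=0))
    with pytest.raises(ValueError, match="format"):
        gp.write_genotypes(g, tmp_path / "x", "bed")
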