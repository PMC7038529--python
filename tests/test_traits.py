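"""QTN placement, effect sampling, interaction codings, phenotype assembly."""

import numpy as np
import pytest

import gpbench as gp
from gpbench.traits import (
    EffectSet,
    build_epistatic_pairs,
    compute_genetic_values,
    dominance_code,
    interaction_code,
    place_qtn,
    sample_effects,
)


# ---------------------------------------------------------------------------
# QTN placement
# ---------------------------------------------------------------------------


def test_clustered_placement_divisible_case(small_genotypes):
    q = place_qtn(small_genotypes, 9, "clustered", seed=1)
    assert q.n_qtn == 9
    assert q.core_flags.sum() == 3
    # each cluster is three consecutive map positions around a core
    cores = q.indices[q.core_flags]
    for c in cores:
        assert {c - 1, c, c + 1} <= set(q.indices)


def test_clustered_placement_top_up_rule(small_genotypes):
    q = place_qtn(small_genotypes, 100, "clustered", seed=2)
    assert q.n_qtn == 100
    assert q.core_flags.sum() == 33  # 33 clusters (99 QTN) + 1 random singleton


def test_clusters_never_straddle_chromosomes(small_genotypes):
    q = place_qtn(small_genotypes, 30, "clustered", seed=3)
    chrom = small_genotypes.chrom
    for c in q.indices[q.core_flags]:
        assert chrom[c - 1] == chrom[c] == chrom[c + 1]


def test_random_placement_uniform_coverage(desk_genotypes):
    """Uniform sampling: bin-count chi-square not rejected across 50 seeds."""
    from scipy import stats

    m = desk_genotypes.m
    rejected = 0
    for seed in range(50):
        q = place_qtn(desk_genotypes, 100, "random", seed=seed)
        assert len(set(q.indices)) == 100
        counts, _ = np.histogram(q.indices, bins=10, range=(0, m))
        p = stats.chisquare(counts).pvalue
        rejected += p < 0.01
    assert rejected <= 3  # ~0.5 expected under uniformity


def test_placement_errors(small_genotypes):
    with pytest.raises(ValueError):
        place_qtn(small_genotypes, small_genotypes.m + 1, "random", seed=0)


# ---------------------------------------------------------------------------
# epistatic pairs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_qtn, expected", [(100, 294), (1000, 2994)])
def test_pair_counts_match_three_neighbour_rule(n_qtn, expected):
    q = gp.traits.QTNSet(
        indices=np.arange(n_qtn), core_flags=np.zeros(n_qtn, bool), placement="random"
    )
    assert build_epistatic_pairs(q).n_pairs == expected


def test_pairs_exhaustive_for_four_qtn():
    q = gp.traits.QTNSet(
        indices=np.arange(4), core_flags=np.zeros(4, bool), placement="random"
    )
    pairs = build_epistatic_pairs(q)
    expected = {(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)}
    assert set(map(tuple, pairs.pairs)) == expected


def test_pairs_require_four_qtn():
    q = gp.traits.QTNSet(indices=np.arange(3), core_flags=np.zeros(3, bool), placement="random")
    with pytest.raises(ValueError):
        build_epistatic_pairs(q)


# ---------------------------------------------------------------------------
# codings
# ---------------------------------------------------------------------------


def test_dominance_code_definition():
    assert dominance_code(np.array([0, 1, 2])).tolist() == [0.0, 1.0, 0.0]
    assert dominance_code(np.array([0, 2, 0, 2])).sum() == 0
    col = np.array([0, 1, 1, 2, 1, 0])
    assert dominance_code(col).sum() == (col == 1).sum()


def test_dominance_code_rejects_bad_codes():
    with pytest.raises(ValueError):
        dominance_code(np.array([0, 3]))


@pytest.mark.parametrize(
    "kind, g1, g2, expected",
    [
        ("AA", 2, 2, 4.0),
        ("AA", 1, 2, 2.0),
        ("AA", 1, 1, 1.0),
        ("AA", 0, 2, 0.0),
        ("AD", 2, 1, 2.0),  # additive 2 x heterozygote dominance 1
        ("AD", 2, 2, 0.0),  # homozygote has dominance code 0
        ("DA", 1, 2, 2.0),
        ("DD", 1, 1, 1.0),
        ("DD", 2, 1, 0.0),
    ],
)
def test_interaction_coding_values(kind, g1, g2, expected):
    out = interaction_code(np.array([g1]), np.array([g2]), kind)
    assert out[0] == expected


def test_interaction_code_ranges(rng):
    c1 = rng.integers(0, 3, 50)
    c2 = rng.integers(0, 3, 50)
    assert set(interaction_code(c1, c2, "AA")) <= {0.0, 1.0, 2.0, 4.0}
    assert set(interaction_code(c1, c2, "AD")) <= {0.0, 1.0, 2.0}
    assert set(interaction_code(c1, c2, "DD")) <= {0.0, 1.0}


def test_interaction_code_length_mismatch():
    with pytest.raises(ValueError):
        interaction_code(np.array([1, 2]), np.array([1]), "AA")


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------


def _qtn(n):
    return gp.traits.QTNSet(indices=np.arange(n), core_flags=np.zeros(n, bool), placement="random")


def test_substitution_effect_arithmetic():
    # alpha = a + d (q - p): additive case d=0 -> alpha = a; p=q -> alpha = a
    arch = gp.ArchitectureConfig(gene_action="additive", n_qtn=10, seed=0)
    eff = sample_effects(_qtn(10), None, arch, np.full(10, 0.3))
    assert np.allclose(eff.substitution, eff.additive)
    assert np.all(eff.dominance == 0)

    arch_na = gp.ArchitectureConfig(
        gene_action="nonadditive", n_qtn=10, target_h2_a=0.1, target_h2_d=0.1,
        target_h2_I=0.5, seed=0,
    )
    eff_half = sample_effects(_qtn(10), build_epistatic_pairs(_qtn(10)), arch_na, np.full(10, 0.5))
    assert np.allclose(eff_half.substitution, eff_half.additive)  # q - p = 0

    # direct arithmetic: a=0.5, d=0.2, p=0.3 -> alpha = 0.58
    a, d, p = 0.5, 0.2, 0.3
    assert a + d * ((1 - p) - p) == pytest.approx(0.58)


def test_epistatic_effect_distribution():
    arch = gp.ArchitectureConfig(
        gene_action="nonadditive", n_qtn=200, target_h2_a=0.1, target_h2_d=0.1,
        target_h2_I=0.5, seed=4,
    )
    q = _qtn(200)
    eff = sample_effects(q, build_epistatic_pairs(q), arch, np.full(200, 0.4))
    mags = np.abs(np.concatenate([eff.epi_aa, eff.epi_ad, eff.epi_da, eff.epi_dd]))
    signs = np.sign(np.concatenate([eff.epi_aa, eff.epi_ad, eff.epi_da, eff.epi_dd]))
    # Gamma(0.1, 10) has mean 1; signs balanced
    assert abs(mags.mean() - 1.0) < 0.2
    assert abs(signs.mean()) < 0.1


def test_additive_action_zeroes_nonadditive_effects():
    arch = gp.ArchitectureConfig(gene_action="additive", n_qtn=20, seed=1)
    eff = sample_effects(_qtn(20), None, arch, np.full(20, 0.25))
    assert eff.epi_aa.size == 0
    assert np.all(eff.dominance == 0)


# ---------------------------------------------------------------------------
# genetic values
# ---------------------------------------------------------------------------


def _matrix_from_codes(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return gp.GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        snps=[f"m{j}" for j in range(m)],
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1),
        codes=codes,
    )


def test_genetic_values_hand_example():
    g = _matrix_from_codes([[0, 2], [2, 1]])
    q = _qtn(2)
    eff = EffectSet(
        additive=np.array([1.0, -0.5]),
        dominance=np.zeros(2),
        substitution=np.array([1.0, -0.5]),
        epi_aa=np.empty(0), epi_ad=np.empty(0), epi_da=np.empty(0), epi_dd=np.empty(0),
    )
    g_add, g_dom, g_epi = compute_genetic_values(g, q, None, eff)
    assert np.allclose(g_add, [-1.0, 1.5])
    assert np.allclose(g_dom, 0) and np.allclose(g_epi, 0)


def test_single_pair_aa_contribution():
    g = _matrix_from_codes([[2, 2, 0, 0], [1, 2, 0, 0]])
    q = _qtn(4)
    pairs = gp.traits.EpistaticPairList(pairs=np.array([[0, 1]]))
    aa = 0.7
    eff = EffectSet(
        additive=np.zeros(4), dominance=np.zeros(4), substitution=np.zeros(4),
        epi_aa=np.array([aa]), epi_ad=np.zeros(1), epi_da=np.zeros(1), epi_dd=np.zeros(1),
    )
    _, _, g_epi = compute_genetic_values(g, q, pairs, eff)
    assert g_epi[0] == pytest.approx(4 * aa)  # genotypes (2,2) -> coefficient 4
    assert g_epi[1] == pytest.approx(2 * aa)


def test_zero_effects_give_zero_components(small_genotypes):
    q = place_qtn(small_genotypes, 10, "random", seed=0)
    eff = EffectSet(
        additive=np.zeros(10), dominance=np.zeros(10), substitution=np.zeros(10),
        epi_aa=np.empty(0), epi_ad=np.empty(0), epi_da=np.empty(0), epi_dd=np.empty(0),
    )
    comps = compute_genetic_values(small_genotypes, q, None, eff)
    for c in comps:
        assert np.allclose(c, 0)


def test_genetic_values_match_double_loop_oracle(rng):
    """Vectorized component computation vs a naive per-individual double loop."""
    n, n_qtn = 20, 8
    codes = rng.integers(0, 3, size=(n, n_qtn)).astype(np.int8)
    g = _matrix_from_codes(codes)
    q = _qtn(n_qtn)
    pairs = build_epistatic_pairs(q)
    arch = gp.ArchitectureConfig(
        gene_action="nonadditive", n_qtn=n_qtn, target_h2_a=0.1, target_h2_d=0.1,
        target_h2_I=0.5, seed=9,
    )
    eff = sample_effects(q, pairs, arch, np.full(n_qtn, 0.4))
    g_add, g_dom, g_epi = compute_genetic_values(g, q, pairs, eff)

    X = codes.astype(float)
    D = (X == 1).astype(float)
    for i in range(n):
        add = sum(X[i, k] * eff.substitution[k] for k in range(n_qtn))
        dom = sum(D[i, k] * eff.dominance[k] for k in range(n_qtn))
        epi = 0.0
        for idx, (k, kp) in enumerate(pairs.pairs):
            epi += X[i, k] * X[i, kp] * eff.epi_aa[idx]
            epi += X[i, k] * D[i, kp] * eff.epi_ad[idx]
            epi += D[i, k] * X[i, kp] * eff.epi_da[idx]
            epi += D[i, k] * D[i, kp] * eff.epi_dd[idx]
        assert g_add[i] == pytest.approx(add)
        assert g_dom[i] == pytest.approx(dom)
        assert g_epi[i] == pytest.approx(epi)


# ---------------------------------------------------------------------------
# phenotype assembly
# ---------------------------------------------------------------------------


def test_additive_partition_calibrated(small_genotypes):
    vals = []
    for seed in range(10):
        arch = gp.ArchitectureConfig(gene_action="additive", n_qtn=20, seed=seed)
        trait = gp.simulate_trait(small_genotypes, arch)
        vals.append(trait.realized_partition["h2_a"])
    assert abs(np.mean(vals) - 0.30) < 0.03


def test_null_trait_is_pure_noise(small_genotypes):
    arch = gp.ArchitectureConfig(
        gene_action="additive", n_qtn=10, target_h2_a=0.0, seed=3
    )
    trait = gp.simulate_trait(small_genotypes, arch)
    assert np.allclose(trait.g_additive, 0)
    assert trait.realized_partition["H2_B"] == 0
    assert abs(trait.phenotype.std() - 1.0) < 0.15


def test_phenotype_is_sum_of_components(small_genotypes):
    arch = gp.ArchitectureConfig(
        gene_action="nonadditive", n_qtn=12, target_h2_a=0.1, target_h2_d=0.1,
        target_h2_I=0.5, seed=5,
    )
    t = gp.simulate_trait(small_genotypes, arch)
    assert np.allclose(
        t.phenotype, t.g_additive + t.g_dominance + t.g_epistatic + t.residual
    )
    assert all(0 <= v <= 1 for v in t.realized_partition.values())


def test_total_variance_conserved_across_seeds(small_genotypes):
    """Mean realized phenotypic variance is ~1 over seeds."""
    vs = []
    for seed in range(10):
        arch = gp.ArchitectureConfig(
            gene_action="nonadditive", n_qtn=12, target_h2_a=0.1, target_h2_d=0.1,
            target_h2_I=0.5, seed=seed,
        )
        vs.append(gp.simulate_trait(small_genotypes, arch).phenotype.var())
    assert abs(np.mean(vs) - 1.0) < 0.1


def test_placement_mode_does_not_perturb_effect_stream(small_genotypes):
    """Same seed: switching placement changes QTN but not the effect draws."""
    archs = [
        gp.ArchitectureConfig(gene_action="additive", n_qtn=15, placement=p, seed=11)
        for p in ("clustered", "random")
    ]
    effs = []
    for arch in archs:
        q = place_qtn(small_genotypes, arch.n_qtn, arch.placement, seed=0)
        effs.append(sample_effects(q, None, arch, np.full(arch.n_qtn, 0.3)))
    assert np.array_equal(effs[0].additive, effs[1].additive)


def test_zero_variance_component_with_positive_target_rejected():
    comps = (np.zeros(50), np.zeros(50), np.zeros(50))
    arch = gp.ArchitectureConfig(gene_action="additive", n_qtn=5, seed=0)
    with pytest.raises(ValueError):
        gp.assemble_phenotype(comps, arch)


def test_architecture_validation():
    with pytest.raises(ValueError):
        gp.ArchitectureConfig(gene_action="additive", target_h2_I=0.5)
    with pytest.raises(ValueError):
        gp.ArchitectureConfig(
            gene_action="nonadditive", target_h2_a=0.5, target_h2_d=0.3, target_h2_I=0.3
        )
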