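"""Degeneracy annotation and missing-data-aware pi."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from slocus.diversity import (
    annotate_degeneracy,
    degeneracy_counts,
    pi_from_genotypes,
    pi_ratio,
    summarize_gene_groups,
)
from slocus.synth import simulate_genotype_matrix


# --- degeneracy -------------------------------------------------------------


def test_degeneracy_examples():
    assert annotate_degeneracy("GGG")[2] == "4-fold"  # GGN all glycine
    assert list(annotate_degeneracy("ATG")) == ["0-fold", "0-fold", "0-fold"]
    assert annotate_degeneracy("ATT")[2] == "other"  # isoleucine, 3-fold


def test_degeneracy_errors():
    with pytest.raises(ValueError, match="divisible by 3"):
        annotate_degeneracy("ATGA")
    with pytest.raises(ValueError, match="internal stop"):
        annotate_degeneracy("TGAGGG")
    # a terminal stop codon is tolerated and excluded from both classes
    assert annotate_degeneracy("ATGTAA")[3:].tolist() == ["other"] * 3


@pytest.mark.parametrize("seed", range(5))
def test_degeneracy_agrees_with_substitution_enumeration(seed):
    """Classes partition the CDS and match per-site brute-force
    substitution of all three alternative bases."""
    rng = np.random.default_rng(seed)
    codons = []
    while len(codons) < 60:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if str(Seq(c).translate()) != "*":
            codons.append(c)
    cds = "".join(codons)
    classes = annotate_degeneracy(cds)
    counts = degeneracy_counts(cds)
    assert sum(counts.values()) == len(cds)
    for i in range(len(cds)):
        codon_start = 3 * (i // 3)
        codon = cds[codon_start : codon_start + 3]
        aa = str(Seq(codon).translate())
        changed = 0
        for b in "ACGT":
            if b == cds[i]:
                continue
            mut = list(codon)
            mut[i % 3] = b
            if str(Seq("".join(mut)).translate()) != aa:
                changed += 1
        want = {0: "4-fold", 3: "0-fold"}.get(changed, "other")
        assert classes[i] == want


# --- pi ---------------------------------------------------------------------


def _matrix(rows, individuals):
    idx = pd.MultiIndex.from_tuples(
        [("g", i + 1) for i in range(len(rows))], names=["chrom", "pos"]
    )
    return pd.DataFrame(rows, index=idx, columns=individuals)


def test_monomorphic_sample_has_zero_pi():
    m = _matrix([[0, 0, 0]] * 10, ["a", "b", "c"])
    assert pi_from_genotypes(m).pi == 0.0


def test_hand_computed_two_homozygote_example():
    """Two homozygous diploids differing at 1 of 100 callable sites:
    pi = (2*2 / C(4,2)) / 100."""
    rows = [[0, 2]] + [[0, 0]] * 99
    m = _matrix(rows, ["a", "b"])
    est = pi_from_genotypes(m)
    assert est.pi == pytest.approx((4 / 6) / 100)
    assert est.comparisons == 100 * 6


def test_missing_genotypes_shrink_comparisons():
    rows = [[1, -1, 0, 0]]
    m = _matrix(rows, list("abcd"))
    est = pi_from_genotypes(m)
    # 6 called alleles: 1 alt, 5 ref -> 5 diffs over C(6,2)=15 comparisons
    assert est.diffs == 5
    assert est.comparisons == 15


def test_undefined_pi_warns_and_is_nan():
    m = _matrix([[-1, -1]], ["a", "b"])
    with pytest.warns(UserWarning, match="undefined"):
        est = pi_from_genotypes(m)
    assert np.isnan(est.pi)


def _oracle_pi(matrix):
    """Naive all-pairs haplotype comparison, site by site."""
    diffs = comps = 0
    for _, row in matrix.iterrows():
        alleles = []
        for g in row:
            if g >= 0:
                alleles += [1] * int(g) + [0] * (2 - int(g))
        if len(alleles) < 2:
            continue
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                comps += 1
                diffs += alleles[i] != alleles[j]
    return diffs / comps if comps else float("nan")


@pytest.mark.parametrize("seed", range(10))
def test_pi_matches_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    gt = rng.choice([-1, 0, 1, 2], size=(20, 8), p=[0.1, 0.5, 0.25, 0.15])
    m = _matrix(gt.tolist(), [f"i{k}" for k in range(8)])
    assert pi_from_genotypes(m).pi == pytest.approx(_oracle_pi(m), abs=1e-12)


def test_haploid_mode_counts_one_allele_per_individual():
    # two hemizygotes recorded as homozygous diploids, one ref one alt
    m = _matrix([[0, 2]], ["a", "b"])
    est = pi_from_genotypes(m, haploid=True)
    assert est.diffs == 1 and est.comparisons == 1


def test_theta_is_recovered_at_10kb():
    theta = 0.005
    m = simulate_genotype_matrix(
        {"g": [f"i{k}" for k in range(20)]}, {"g": theta},
        n_sites=10_000, seed=11,
    )
    est = pi_from_genotypes(m)
    # 3 Monte-Carlo standard errors of the aggregate estimate
    se = np.sqrt(0.25 * 2 * theta / 10_000)
    assert abs(est.pi - theta) < 3 * se


def test_selfing_group_shows_reduced_diversity():
    wins = 0
    for seed in range(60):
        m = simulate_genotype_matrix(
            {"out": [f"o{k}" for k in range(10)], "self": [f"s{k}" for k in range(10)]},
            {"out": 0.003, "self": 0.0005},
            n_sites=10_000, inbreeding={"self": 0.9}, seed=seed,
        )
        pi_out = pi_from_genotypes(m, individuals=[f"o{k}" for k in range(10)]).pi
        pi_self = pi_from_genotypes(m, individuals=[f"s{k}" for k in range(10)]).pi
        wins += pi_out > pi_self
    assert wins >= 59


def test_cohort_homostyles_less_diverse_for_every_gene(bundle):
    """The packaged selfing (homostyle) group is less diverse than the
    outcrossing group at every gene, mirroring the expected contrast."""
    matrices = bundle["matrices"]
    groups = bundle["matrix_groups"]
    for gene, matrix in matrices.items():
        pi_het = pi_from_genotypes(matrix, individuals=groups[gene]["heterostyle"]).pi
        pi_hom = pi_from_genotypes(matrix, individuals=groups[gene]["homostyle"]).pi
        assert pi_hom < pi_het, gene


# --- ratios and summaries ---------------------------------------------------


def test_pi_ratio_rules():
    assert pi_ratio(0.0007, 0.0026) == pytest.approx(0.0007 / 0.0026)
    assert np.isnan(pi_ratio(0.0015, 0.0))  # "NA" when pi_S is zero
    assert pi_ratio(0.0, 0.001) == 0.0
    assert np.isnan(pi_ratio(float("nan"), 0.001))


def test_summary_mean_and_se():
    df = pd.DataFrame(
        {
            "gene": ["CYP^T", "GLO^T", "CCM^T", "KFB^T", "PUM^T"],
            "group": ["thrum"] * 5,
            "n": [37] * 5,
            "pi_s": [0.0026, 0.0, 0.0018, 0.0004, 0.0001],
            "pi_n": [0.0007, 0.0015, 0.0016, 0.0007, 0.0011],
            "ratio": [0.28, np.nan, 0.91, 1.83, 10.36],
        }
    )
    out = summarize_gene_groups(df).iloc[0]
    assert out["pi_s_mean"] == pytest.approx(0.00098)  # prints as 0.0010
    assert round(out["pi_s_mean"], 4) == 0.0010
    # NA ratios are excluded from the ratio average
    assert out["ratio_mean"] == pytest.approx(np.mean([0.28, 0.91, 1.83, 10.36]))
    # excluding the outlier gene recomputes over the remainder
    excl = summarize_gene_groups(df, exclude=("PUM^T",)).iloc[0]
    assert excl["n_genes"] == 4
    assert excl["ratio_mean"] == pytest.approx(np.mean([0.28, 0.91, 1.83]))


def test_single_value_summary_has_no_se():
    df = pd.DataFrame(
        {"gene": ["g"], "group": ["x"], "n": [5],
         "pi_s": [0.001], "pi_n": [0.002], "ratio": [2.0]}
    )
    out = summarize_gene_groups(df).iloc[0]
    assert np.isnan(out["pi_s_se"])
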