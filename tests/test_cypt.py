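"""CYP^T disruption screens: consequences, group SNPs, structure, alleles."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from slocus.cypt import (
    DeletionCall,
    GeneModel,
    ReferenceMismatchError,
    Variant,
    annotate_cds_consequence,
    classify_cypt_allele,
    detect_zero_depth_runs,
    flag_discordant_pairs,
    screen_group_specific_snps,
)
from slocus.synth import allele_specs, make_gene_model


@pytest.fixture(scope="module")
def locus():
    return make_gene_model(seed=0)


@pytest.fixture(scope="module")
def specs(locus):
    return allele_specs(locus)


# --- consequence annotation -------------------------------------------------


def test_planted_exon2_stop_gain(locus, specs):
    ev = specs["CYP^T-2"].events[0]
    call = annotate_cds_consequence(
        locus.cypt, locus.cds["CYP^T"],
        Variant("S_locus", ev.pos, ev.ref, ev.alt),
    )
    assert call.csq_class == "stop_gain"
    assert call.exon == 2
    assert call.protein_change == "p.Ser125*"


def test_planted_exon1_8bp_frameshift(locus, specs):
    ev = specs["CYP^T-6"].events[0]
    call = annotate_cds_consequence(
        locus.cypt, locus.cds["CYP^T"],
        Variant("S_locus", ev.pos, ev.ref, ev.alt),
    )
    assert call.csq_class == "frameshift"
    assert call.exon == 1


def test_intron_snv_is_noncoding(locus):
    intron_pos0 = locus.cypt.introns[0][0] + 5
    base = locus.sequences["S_locus"][intron_pos0]
    alt = "A" if base != "A" else "G"
    call = annotate_cds_consequence(
        locus.cypt, locus.cds["CYP^T"],
        Variant("S_locus", intron_pos0 + 1, base, alt),
    )
    assert call.csq_class == "noncoding"


def test_reference_mismatch_raises(locus):
    e1s = locus.cypt.exons[0][0]
    wrong = "A" if locus.cds["CYP^T"][10] != "A" else "C"
    with pytest.raises(ReferenceMismatchError):
        annotate_cds_consequence(
            locus.cypt, locus.cds["CYP^T"],
            Variant("S_locus", e1s + 11, wrong, "T"),
        )


def _brute_force_class(cds, cds_pos0, alt):
    """Independent oracle: translate the whole mutated CDS."""
    mutated = cds[:cds_pos0] + alt + cds[cds_pos0 + 1 :]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutated).translate())
    if p_alt == p_ref:
        return "synonymous"
    if "*" in p_alt:
        return "stop_gain"
    return "missense"


def test_snv_consequences_agree_with_full_translation():
    """Every possible SNV in a 200-codon single-exon gene is classified the
    same way by codon logic and by brute-force translation."""
    rng = np.random.default_rng(7)
    codons = []
    bases = "ACGT"
    while len(codons) < 200:
        c = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if str(Seq(c).translate()) != "*":
            codons.append(c)
    cds = "".join(codons)
    model = GeneModel("toy", "chr", exons=((100, 100 + len(cds)),))
    mismatches = []
    for pos0 in range(len(cds)):
        for alt in "ACGT":
            if alt == cds[pos0]:
                continue
            got = annotate_cds_consequence(
                model, cds, Variant("chr", 100 + pos0 + 1, cds[pos0], alt)
            ).csq_class
            want = _brute_force_class(cds, pos0, alt)
            if got != want:
                mismatches.append((pos0, alt, got, want))
    assert mismatches == []


@pytest.mark.parametrize("length, expected", [(8, "frameshift"), (6, "inframe_indel")])
def test_exonic_deletion_frame_class(locus, length, expected):
    e1s = locus.cypt.exons[0][0]
    seq = locus.sequences["S_locus"]
    anchor = e1s + 20
    var = Variant("S_locus", anchor + 1, seq[anchor : anchor + length + 1], seq[anchor])
    call = annotate_cds_consequence(locus.cypt, locus.cds["CYP^T"], var)
    assert call.csq_class == expected
    assert call.exon == 1


# --- group-specific SNP screen ----------------------------------------------


def _matrix(hom, thr):
    """hom/thr: dict site -> list of genotypes per individual."""
    sites = sorted(set(hom) | set(thr))
    h_names = [f"h{i}" for i in range(len(next(iter(hom.values()))))]
    t_names = [f"t{i}" for i in range(len(next(iter(thr.values()))))]
    data = {
        **{n: [hom[s][i] for s in sites] for i, n in enumerate(h_names)},
        **{n: [thr[s][i] for s in sites] for i, n in enumerate(t_names)},
    }
    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"])
    return pd.DataFrame(data, index=idx), {"homostyle": h_names, "thrum": t_names}


def test_fixed_homostyle_snp_is_reported_fixed():
    matrix, groups = _matrix(
        hom={("S_locus", 10): [2, 2, 1, 2]},
        thr={("S_locus", 10): [0, 0, 0, 0]},
    )
    out = screen_group_specific_snps(matrix, groups)
    assert len(out) == 1
    assert bool(out.iloc[0]["fixed_in_homostyles"])
    assert out.iloc[0]["carriers"] == 4


def test_partial_carrier_snp_is_reported_unfixed():
    hom_gt = [1] * 8 + [0] * 23  # 8 of 31 homostyles carry the variant
    matrix, groups = _matrix(
        hom={("S_locus", 259566): hom_gt},
        thr={("S_locus", 259566): [0] * 37},
    )
    out = screen_group_specific_snps(matrix, groups)
    assert len(out) == 1
    assert not bool(out.iloc[0]["fixed_in_homostyles"])
    assert out.iloc[0]["carriers"] == 8


def test_thrum_carried_snp_is_not_reported():
    matrix, groups = _matrix(
        hom={("S_locus", 10): [1, 1, 1, 1]},
        thr={("S_locus", 10): [0, 1, 0, 0]},
    )
    assert screen_group_specific_snps(matrix, groups).empty


def test_empty_group_is_an_error():
    matrix, groups = _matrix(
        hom={("S_locus", 10): [1]}, thr={("S_locus", 10): [0]}
    )
    with pytest.raises(ValueError, match="empty"):
        screen_group_specific_snps(matrix, {"homostyle": [], "thrum": groups["thrum"]})


def test_cohort_intron_screen_finds_no_fixed_homostyle_snp(bundle):
    """With three distinct disruption alleles segregating among the 31
    homostyles, allele-specific intronic SNPs are carried by subsets only:
    no SNP is fixed across all homostyles."""
    cohort = bundle["cohort"]
    homs = cohort.loc[cohort.phenotype == "homostyle"]
    thrums = cohort.loc[cohort.phenotype == "thrum", "individual"].tolist()
    # allele-specific intron markers: carried by every carrier of one allele
    sites = {}
    for i, allele in enumerate(["CYP^T-2", "CYP^T-6", "CYP^T-8"]):
        carried = (
            (homs[["allele_1", "allele_2"]] == allele).any(axis=1).astype(int)
        )
        sites[("S_locus", 4200 + i)] = carried.tolist()
    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"])
    matrix = pd.DataFrame(
        {n: [sites[s][j] for s in idx] for j, n in enumerate(homs.individual)},
        index=idx,
    )
    for t in thrums:
        matrix[t] = 0
    out = screen_group_specific_snps(
        matrix, {"homostyle": homs.individual.tolist(), "thrum": thrums}
    )
    assert len(out) == 3  # each allele marker is homostyle-specific
    assert not out["fixed_in_homostyles"].any()


# --- structural screens -----------------------------------------------------


def test_zero_depth_run_detection_examples():
    calls = detect_zero_depth_runs(
        np.array([5, 0, 0, 0, 7]), region=(0, 5), min_length=2,
        positions=np.arange(1, 6),
    )
    assert [(c.start, c.end, c.length) for c in calls] == [(1, 4, 3)]
    assert detect_zero_depth_runs(
        np.array([5, 3, 8]), region=(0, 3), min_length=1, positions=np.arange(1, 4)
    ) == []


@pytest.mark.parametrize("seed", range(10))
def test_zero_depth_runs_match_naive_scan(seed):
    rng = np.random.default_rng(seed)
    depth = rng.integers(0, 2, 300)
    min_len = int(rng.integers(1, 6))
    calls = detect_zero_depth_runs(
        depth, region=(0, 300), min_length=min_len, positions=np.arange(1, 301)
    )
    # naive scan
    runs, i = [], 0
    while i < len(depth):
        if depth[i] == 0:
            j = i
            while j < len(depth) and depth[j] == 0:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    assert [(c.start, c.end) for c in calls] == runs


def test_en6m_deletion_recovered_with_features(bundle):
    locus = bundle["locus"]
    cohort = bundle["cohort"]
    depth = bundle["depth"]
    sub = depth[depth.chrom == "S_locus"]
    ind = cohort.query("population == 'EN6-M'").individual.iloc[0]
    calls = detect_zero_depth_runs(
        sub[ind].to_numpy(), locus.cypt_screen_region, min_length=50,
        chrom="S_locus", positions=sub["pos"].to_numpy(), model=locus.cypt,
    )
    assert len(calls) == 1
    assert calls[0].length == 2150
    assert "exon1" in calls[0].overlapped_features
    assert "promoter" in calls[0].overlapped_features
    assert all(f"motif{i}" in calls[0].overlapped_features for i in range(1, 9))


def test_discordant_pair_tallies():
    from slocus.synth import make_read_pairs

    pairs = make_read_pairs((0, 5000), n_normal=100, seed=0)
    out = flag_discordant_pairs(pairs, (0, 5000), "S_locus")
    assert out["normal_count"] == 100
    assert out["same_orientation_count"] == 0
    assert out["cross_contig_count"] == 0

    pairs = make_read_pairs((0, 5000), n_normal=20, n_inverted=10,
                            n_cross_contig=5, seed=1)
    out = flag_discordant_pairs(pairs, (0, 5000), "S_locus")
    assert out["same_orientation_count"] == 10
    assert out["cross_contig_count"] == 5

    incomplete = pairs.copy()
    incomplete.loc[0, "strand2"] = None
    out = flag_discordant_pairs(incomplete, (0, 5000), "S_locus")
    assert out["unresolvable_count"] == 1


# --- allele classification --------------------------------------------------


def test_no_events_is_functional(locus):
    call = classify_cypt_allele([], [], locus.cypt)
    assert call.allele == "CYP^T-1"
    assert call.functional_status == "functional"


def test_catalogue_signatures(locus, specs):
    cds = locus.cds["CYP^T"]
    stop_ev = specs["CYP^T-2"].events[0]
    stop = annotate_cds_consequence(
        locus.cypt, cds, Variant("S_locus", stop_ev.pos, stop_ev.ref, stop_ev.alt)
    )
    fs_ev = specs["CYP^T-6"].events[0]
    fs = annotate_cds_consequence(
        locus.cypt, cds, Variant("S_locus", fs_ev.pos, fs_ev.ref, fs_ev.alt)
    )
    e1 = locus.cypt.exons[0]
    sv = DeletionCall("S_locus", e1[0] - 1700, e1[0] + 450)

    assert classify_cypt_allele([stop], [], locus.cypt).allele == "CYP^T-2"
    assert classify_cypt_allele([fs], [], locus.cypt).allele == "CYP^T-6"
    assert classify_cypt_allele([], [sv], locus.cypt).allele == "CYP^T-8"
    # conflicting signatures are flagged novel, never forced into the catalogue
    novel = classify_cypt_allele([stop, fs], [], locus.cypt)
    assert novel.allele == "novel"
    assert novel.functional_status == "disrupted"


def test_cohort_allele_recovery_end_to_end(bundle):
    """Every homostyle's planted disruption is recovered and every thrum
    except the S/S* heterozygote is called functional."""
    locus = bundle["locus"]
    specs = allele_specs(locus)
    cohort = bundle["cohort"]
    depth = bundle["depth"]
    sub = depth[depth.chrom == "S_locus"]
    pos = sub["pos"].to_numpy()

    for row in cohort.itertuples():
        if row.phenotype == "pin":
            continue
        consequences = []
        for allele in (row.allele_1, row.allele_2):
            if not allele:
                continue
            for ev in specs[allele].events:
                if ev.kind in ("snv", "deletion"):
                    consequences.append(
                        annotate_cds_consequence(
                            locus.cypt, locus.cds["CYP^T"],
                            Variant("S_locus", ev.pos, ev.ref, ev.alt),
                        )
                    )
        deletions = detect_zero_depth_runs(
            sub[row.individual].to_numpy(), locus.cypt_screen_region,
            min_length=50, chrom="S_locus", positions=pos, model=locus.cypt,
        )
        call = classify_cypt_allele(
            consequences, deletions, locus.cypt, individual=row.individual
        )
        carried = {a for a in (row.allele_1, row.allele_2) if a}
        if row.phenotype == "homostyle":
            assert call.functional_status == "disrupted"
            assert call.allele in carried
        elif carried == {"CYP^T-1"}:
            assert call.functional_status == "functional"
        else:  # the designed S/S* heterozygous thrum
            assert row.s_genotype == "S/S*"
            assert call.functional_status == "disrupted"
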