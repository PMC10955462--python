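"""Synthetic cohorts with known ground truth for every pipeline stage.

Generates a miniature two-contig genome — an ``S_locus`` contig carrying
CYP^T (5 exons; exon 1 = 286 bp, exon 2 = 227 bp; a 3-kb promoter with
eight designated cis-element motifs) plus four further S-genes, and a
``Chr1`` contig carrying four S-gene paralogs — together with cohorts of
individuals whose S-locus genotypes, CYP^T alleles, per-site depth tracks,
read-pair tables and genotype matrices are all emitted alongside
machine-readable truth records.

The disruption alleles mirror the three operationally defined mutation
classes: CYP^T-2 (exon-2 serine-to-stop SNV), CYP^T-6 (8-bp exon-1
frameshift deletion) and CYP^T-8 (2150-bp structural deletion spanning
exon 1 and the proximal promoter motifs).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .cypt import GeneModel, Variant
from .crosby import GENOTYPES, PopulationState
from .ploidy import DepthSummary

__all__ = [
    "SyntheticLocus",
    "AlleleSpec",
    "MutationEvent",
    "CohortSpec",
    "make_gene_model",
    "allele_specs",
    "apply_allele",
    "simulate_cohort",
    "simulate_depth",
    "simulate_relative_depths",
    "simulate_genotype_matrix",
    "make_read_pairs",
    "make_cohort_inputs",
    "write_vcf",
    "PRESETS",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

# fixed structural coordinates (bp)
_E1_START = 3500
_CYPT_EXONS = (286, 227, 180, 120, 210)  # 1023 bp = 341 codons
_CYPT_INTRONS = (400, 350, 300, 250)
_MOTIF_DISTANCES = (1361, 917, 460, 177, 171, 80, 64, 15)  # upstream of exon 1
_MOTIF_WIDTH = 15
_DELETION_SPAN = (_E1_START - 1700, _E1_START + 450)  # 2150 bp, covers exon 1
_STOP_CODON_INDEX = 124  # codon 125; CDS position 374 is its middle base


@dataclass(frozen=True)
class MutationEvent:
    kind: str  # snv | deletion | structural_deletion
    pos: int  # 1-based genomic position (anchor base for deletions)
    ref: str
    alt: str
    span: tuple[int, int] | None = None  # 0-based half-open, structural only
    truth_class: str = ""
    exon: int | None = None


@dataclass(frozen=True)
class AlleleSpec:
    label: str
    events: tuple[MutationEvent, ...]

    @property
    def disrupted(self) -> bool:
        return len(self.events) > 0


@dataclass
class SyntheticLocus:
    """The synthetic reference: gene models, sequences and region tracks."""

    cypt: GeneModel
    s_genes: dict[str, GeneModel]  # includes cypt
    paralogs: dict[str, GeneModel]
    sequences: dict[str, str]
    cds: dict[str, str]  # per gene

    @property
    def slocus_coding_regions(self) -> sio.RegionSet:
        return {"S_locus": sorted(iv for g in self.s_genes.values() for iv in g.exons)}

    @property
    def genome_coding_regions(self) -> sio.RegionSet:
        return {"Chr1": sorted(iv for g in self.paralogs.values() for iv in g.exons)}

    @property
    def cypt_screen_region(self) -> tuple[int, int]:
        """Window around CYP^T covered by depth tracks (promoter to 3' end)."""
        return (1500, 6000)

    def depth_positions(self) -> pd.DataFrame:
        """(chrom, 1-based pos) rows the depth simulator covers."""
        rows = []
        a, b = self.cypt_screen_region
        pos_s = set(range(a, b))
        for g in self.s_genes.values():
            for s, e in g.exons:
                pos_s.update(range(s, e))
        rows.extend(("S_locus", p + 1) for p in sorted(pos_s))
        pos_g = set()
        for g in self.paralogs.values():
            for s, e in g.exons:
                pos_g.update(range(s, e))
        rows.extend(("Chr1", p + 1) for p in sorted(pos_g))
        return pd.DataFrame(rows, columns=["chrom", "pos"])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by random non-stop codons (no internal or terminal stop)."""
    sense = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), n_codons - 1)]
    return "".join(codons)


def _lay_gene(
    contig_seq: list[str],
    gene_id: str,
    contig: str,
    start: int,
    exon_lengths,
    intron_lengths,
    cds: str,
    promoter: tuple[int, int] | None = None,
    motifs: tuple[tuple[int, int], ...] = (),
) -> GeneModel:
    exons = []
    pos = start
    cds_off = 0
    for i, elen in enumerate(exon_lengths):
        exons.append((pos, pos + elen))
        contig_seq[pos : pos + elen] = list(cds[cds_off : cds_off + elen])
        cds_off += elen
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return GeneModel(
        gene_id=gene_id,
        contig=contig,
        exons=tuple(exons),
        promoter=promoter,
        motifs=motifs,
    )


def make_gene_model(seed: int = 0) -> SyntheticLocus:
    """Build the synthetic reference with CYP^T, four S-genes and paralogs.

    Exon 1 (286 bp) and exon 2 (227 bp) of CYP^T match the real gene; the
    remaining exon/intron/intergenic lengths are free parameters.  Codon
    125 of CYP^T is forced to TCA (Ser) so that a single C->G substitution
    at CDS position 374 creates a premature TGA stop, mirroring the
    catalogued exon-2 disruption.
    """
    rng = np.random.default_rng(seed)

    # S_locus contig
    s_len = 12_500
    s_seq = list(_BASES[rng.integers(0, 4, s_len)])
    cypt_cds = _random_cds(rng, sum(_CYPT_EXONS) // 3)
    i = 3 * _STOP_CODON_INDEX
    cypt_cds = cypt_cds[:i] + "TCA" + cypt_cds[i + 3 :]
    motifs = tuple(
        (_E1_START - d - _MOTIF_WIDTH, _E1_START - d) for d in _MOTIF_DISTANCES
    )
    cypt = _lay_gene(
        s_seq, "CYP^T", "S_locus", _E1_START, _CYPT_EXONS, _CYPT_INTRONS,
        cypt_cds, promoter=(_E1_START - 3000, _E1_START), motifs=motifs,
    )
    cds = {"CYP^T": cypt_cds}
    s_genes = {"CYP^T": cypt}
    pos = 6500
    for gid in ("GLO^T", "CCM^T", "PUM^T", "KFB^T"):
        gene_cds = _random_cds(rng, 300)  # 900 bp over two exons
        s_genes[gid] = _lay_gene(
            s_seq, gid, "S_locus", pos, (450, 450), (200,), gene_cds
        )
        cds[gid] = gene_cds
        pos += 1500

    # paralog contig
    c_len = 6_500
    c_seq = list(_BASES[rng.integers(0, 4, c_len)])
    paralogs = {}
    pos = 500
    for gid in ("CYP734A51", "GLO1", "CCM1", "KFB1"):
        gene_cds = _random_cds(rng, 300)
        paralogs[gid] = _lay_gene(
            c_seq, gid, "Chr1", pos, (450, 450), (200,), gene_cds
        )
        cds[gid] = gene_cds
        pos += 1500

    return SyntheticLocus(
        cypt=cypt,
        s_genes=s_genes,
        paralogs=paralogs,
        sequences={"S_locus": "".join(s_seq), "Chr1": "".join(c_seq)},
        cds=cds,
    )


def allele_specs(locus: SyntheticLocus) -> dict[str, AlleleSpec]:
    """The operationally defined CYP^T allele catalogue for this reference."""
    model = locus.cypt
    seq = locus.sequences["S_locus"]
    e1s = model.exons[0][0]
    e2s = model.exons[1][0]

    # exon-2 stop gain: CDS offset 373 (position 374, middle of codon 125)
    stop_pos0 = e2s + (3 * _STOP_CODON_INDEX + 1 - _CYPT_EXONS[0])
    stop = MutationEvent(
        kind="snv", pos=stop_pos0 + 1, ref=seq[stop_pos0], alt="G",
        truth_class="stop_gain", exon=2,
    )
    assert seq[stop_pos0] == "C"  # middle base of the planted TCA codon

    # 8-bp deletion near the start of exon 1 (VCF-style anchored)
    anchor = e1s + 3
    del8 = MutationEvent(
        kind="deletion", pos=anchor + 1,
        ref=seq[anchor : anchor + 9], alt=seq[anchor],
        truth_class="frameshift", exon=1,
    )

    sv = MutationEvent(
        kind="structural_deletion", pos=_DELETION_SPAN[0] + 1, ref="", alt="",
        span=_DELETION_SPAN, truth_class="structural_deletion", exon=1,
    )

    return {
        "CYP^T-1": AlleleSpec("CYP^T-1", ()),
        "CYP^T-2": AlleleSpec("CYP^T-2", (stop,)),
        "CYP^T-6": AlleleSpec("CYP^T-6", (del8,)),
        "CYP^T-8": AlleleSpec("CYP^T-8", (sv,)),
    }


def apply_allele(
    reference: str, spec: AlleleSpec
) -> tuple[str, list[dict]]:
    """Apply an allele's mutation events to the reference contig sequence.

    Returns the mutated haplotype sequence and one truth record per event
    (kind, position, expected consequence class).
    """
    seq = reference
    truth = []
    # apply right-to-left so earlier coordinates stay valid
    for ev in sorted(spec.events, key=lambda e: -e.pos):
        if ev.kind == "snv":
            p0 = ev.pos - 1
            if seq[p0] != ev.ref:
                raise ValueError(f"reference mismatch at {ev.pos}")
            seq = seq[:p0] + ev.alt + seq[p0 + 1 :]
        elif ev.kind == "deletion":
            p0 = ev.pos - 1
            if seq[p0 : p0 + len(ev.ref)] != ev.ref:
                raise ValueError(f"reference mismatch at {ev.pos}")
            seq = seq[:p0] + ev.alt + seq[p0 + len(ev.ref) :]
        elif ev.kind == "structural_deletion":
            a, b = ev.span
            if b > len(seq):
                raise ValueError("structural deletion out of bounds")
            seq = seq[:a] + seq[b:]
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        truth.append(
            {"allele": spec.label, "kind": ev.kind, "pos": ev.pos,
             "expected_class": ev.truth_class, "exon": ev.exon}
        )
    return seq, truth


# ---------------------------------------------------------------------------
# cohorts

#: population -> list of (phenotype, genotype, allele1, allele2, count)
#: Dimorphic/trimorphic composition follows the published survey; the full
#: cohort totals 37 pins, 37 thrums (34 S/0, 2 S/S, 1 S/S*), 31 homostyles
#: (10 S*/0, 21 S*/S*).
PRESETS: dict[str, dict[str, list[tuple]]] = {
    "full-cohort": {
        "TR-D": [("thrum", "S/0", "CYP^T-1", None, 5), ("pin", "0/0", None, None, 5)],
        "SK-D": [("thrum", "S/0", "CYP^T-1", None, 5), ("pin", "0/0", None, None, 5)],
        "CH-D": [("thrum", "S/0", "CYP^T-1", None, 5), ("pin", "0/0", None, None, 5)],
        "EN1-D": [("thrum", "S/0", "CYP^T-1", None, 5), ("pin", "0/0", None, None, 4)],
        "EN2-D": [
            ("thrum", "S/0", "CYP^T-1", None, 4),
            ("thrum", "S/S", "CYP^T-1", "CYP^T-1", 1),
            ("pin", "0/0", None, None, 4),
        ],
        "EN3-D": [("thrum", "S/0", "CYP^T-1", None, 5), ("pin", "0/0", None, None, 5)],
        "EN4-T": [
            ("thrum", "S/0", "CYP^T-1", None, 2),
            ("thrum", "S/S*", "CYP^T-1", "CYP^T-2", 1),
            ("pin", "0/0", None, None, 4),
            ("homostyle", "S*/0", "CYP^T-6", None, 4),
            ("homostyle", "S*/S*", "CYP^T-6", "CYP^T-6", 4),
            ("homostyle", "S*/S*", "CYP^T-2", "CYP^T-2", 2),
        ],
        "EN5-T": [
            ("thrum", "S/0", "CYP^T-1", None, 3),
            ("thrum", "S/S", "CYP^T-1", "CYP^T-1", 1),
            ("pin", "0/0", None, None, 5),
            ("homostyle", "S*/0", "CYP^T-2", None, 6),
            ("homostyle", "S*/S*", "CYP^T-2", "CYP^T-2", 4),
        ],
        "EN6-M": [("homostyle", "S*/S*", "CYP^T-8", "CYP^T-8", 11)],
    },
}
PRESETS["en4t"] = {"EN4-T": PRESETS["full-cohort"]["EN4-T"]}
PRESETS["en5t"] = {"EN5-T": PRESETS["full-cohort"]["EN5-T"]}
PRESETS["en6m"] = {"EN6-M": PRESETS["full-cohort"]["EN6-M"]}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort."""

    preset: str = "full-cohort"
    lam: float = 18.9  # genome-wide mean per-site depth
    dispersion: float = 0.0  # 0 = Poisson; > 0 = negative binomial
    theta_outcrossing: float = 0.003
    theta_selfing: float = 0.0005
    missing_rate: float = 0.05
    seed: int = 0


_GT_PHENOTYPE = {"0/0": "pin", "S/0": "thrum", "S/S": "thrum", "S/S*": "thrum",
                 "S*/0": "homostyle", "S*/S*": "homostyle"}


def simulate_cohort(
    preset: str = "full-cohort",
    seed: int = 0,
    state: PopulationState | None = None,
    n: int | None = None,
) -> pd.DataFrame:
    """Individuals with phenotype, S-locus genotype and CYP^T alleles.

    With ``state`` and ``n``, genotype counts are drawn multinomially from
    the model state (homostyles receive the exon-2 stop allele); otherwise
    the named preset composition is expanded verbatim.
    """
    rows = []
    if state is not None:
        if n is None or n <= 0:
            raise ValueError("multinomial sampling needs a positive n")
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, state.as_array())
        comp = {"SIM": []}
        for gt, c in zip(GENOTYPES, counts):
            if c == 0:
                continue
            if gt == "0/0":
                comp["SIM"].append(("pin", gt, None, None, int(c)))
            elif gt == "S/0":
                comp["SIM"].append(("thrum", gt, "CYP^T-1", None, int(c)))
            elif gt == "S*/0":
                comp["SIM"].append(("homostyle", gt, "CYP^T-2", None, int(c)))
            else:
                comp["SIM"].append(("homostyle", gt, "CYP^T-2", "CYP^T-2", int(c)))
    else:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        comp = PRESETS[preset]

    i = 0
    for pop, entries in comp.items():
        for phenotype, genotype, a1, a2, count in entries:
            if _GT_PHENOTYPE[genotype] != phenotype:
                raise ValueError(f"impossible composition: {phenotype} with {genotype}")
            for _ in range(count):
                i += 1
                rows.append(
                    {
                        "individual": f"{pop}_{i:03d}",
                        "population": pop,
                        "phenotype": phenotype,
                        "s_genotype": genotype,
                        "allele_1": a1,
                        "allele_2": a2,
                    }
                )
    df = pd.DataFrame(rows)
    df["cypt_status"] = [_cypt_status(r) for r in df.itertuples()]
    return df


def _cypt_status(row) -> str:
    alleles = [a for a in (row.allele_1, row.allele_2) if a]
    if not alleles:
        return "absent"
    disrupted = [a != "CYP^T-1" for a in alleles]
    if all(disrupted):
        return "disrupted"
    if any(disrupted):
        return "heterozygous_functional_disrupted"
    return "functional"


def simulate_depth(
    cohort: pd.DataFrame,
    locus: SyntheticLocus,
    lam: float = 18.9,
    dispersion: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site depth track for every individual.

    Depth is Poisson (or negative binomial when ``dispersion`` > 0) with
    mean ``lam`` on the diploid paralog contig and ``lam * copies / 2`` on
    the S-locus contig, where ``copies`` is the number of carried S
    haplotypes not deleted at that position.  Pins therefore have zero
    S-locus depth, and structural-deletion carriers have zero depth across
    the deleted span.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = np.random.default_rng(seed)
    specs = allele_specs(locus)
    frame = locus.depth_positions()
    on_s = (frame["chrom"] == "S_locus").to_numpy()
    pos0 = frame["pos"].to_numpy() - 1

    columns = {}
    for row in cohort.itertuples():
        copies = np.zeros(len(frame))
        copies[~on_s] = 2.0  # paralog contig: always diploid
        for allele in (row.allele_1, row.allele_2):
            if allele is None or (isinstance(allele, float) and np.isnan(allele)):
                continue
            covered = np.ones(len(frame), dtype=bool)
            for ev in specs[allele].events:
                if ev.kind == "structural_deletion":
                    a, b = ev.span
                elif ev.kind == "deletion":
                    a, b = ev.pos, ev.pos - 1 + len(ev.ref)
                else:
                    continue
                covered &= ~(on_s & (pos0 >= a) & (pos0 < b))
            copies[on_s] += covered[on_s]
        means = lam * copies / 2.0
        depth = np.zeros(len(frame), dtype=int)
        has_mean = means > 0
        depth[has_mean] = _draw_per_site(rng, means[has_mean], dispersion)
        columns[row.individual] = depth
    return pd.concat([frame, pd.DataFrame(columns)], axis=1)


def _draw_per_site(rng, means, dispersion):
    if dispersion > 0:
        k = dispersion
        return rng.negative_binomial(k, k / (k + means))
    return rng.poisson(means)


def simulate_relative_depths(
    n_individuals: int,
    copies: int,
    lam: float = 19.0,
    n_slocus_sites: int = 50_000,
    n_genome_sites: int = 50_000,
    seed: int = 0,
) -> list[DepthSummary]:
    """Depth summaries for individuals with a known S-locus copy number.

    Per-site depth is Poisson with mean ``lam`` over the genome-wide coding
    sites and ``lam * copies / 2`` over the S-locus coding sites.
    """
    rng = np.random.default_rng(seed)
    out = []
    s_mean = lam * copies / 2.0
    for i in range(n_individuals):
        genome = rng.poisson(lam, n_genome_sites)
        s = rng.poisson(s_mean, n_slocus_sites) if s_mean > 0 else np.zeros(
            n_slocus_sites, dtype=int
        )
        out.append(
            DepthSummary(
                individual=f"sim_{copies}_{i:04d}",
                depth_slocus=float(s.mean()),
                depth_genome=float(genome.mean()),
            )
        )
    return out


def simulate_genotype_matrix(
    groups: dict[str, list[str]],
    theta: dict[str, float],
    n_sites: int,
    missing_rate: float = 0.0,
    inbreeding: dict[str, float] | None = None,
    seed: int = 0,
    chrom: str = "gene",
    start: int = 1,
) -> pd.DataFrame:
    """Sites x individuals matrix of alternate-allele counts (-1 missing).

    Each site is independently polymorphic within a group with probability
    2 * theta[group] at allele frequency 1/2, which makes the expected
    per-site heterozygosity (and hence pi) equal theta.  ``inbreeding``
    raises homozygosity without changing allele frequencies, emulating a
    selfing group.  Sites are unlinked; invariant sites are included.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    for group, inds in groups.items():
        th = theta[group]
        if th < 0:
            raise ValueError("theta must be >= 0")
        f_in = (inbreeding or {}).get(group, 0.0)
        poly = rng.random(n_sites) < 2 * th
        p_alt_hom = 0.25 + 0.25 * f_in
        p_het = 0.5 * (1 - f_in)
        u = rng.random((n_sites, len(inds)))
        gt = np.where(u < p_alt_hom, 2, np.where(u < p_alt_hom + p_het, 1, 0))
        gt[~poly, :] = 0
        if missing_rate > 0:
            gt = np.where(rng.random(gt.shape) < missing_rate, -1, gt)
        for j, ind in enumerate(inds):
            cols[ind] = gt[:, j]
    index = pd.MultiIndex.from_arrays(
        [[chrom] * n_sites, np.arange(start, start + n_sites)],
        names=["chrom", "pos"],
    )
    return pd.DataFrame(cols, index=index)


def make_read_pairs(
    region: tuple[int, int],
    contig: str = "S_locus",
    n_normal: int = 100,
    n_inverted: int = 0,
    n_cross_contig: int = 0,
    other_contig: str = "Chr1",
    insert: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Simplified read-pair table with planted discordant signals."""
    rng = np.random.default_rng(seed)
    start, end = region
    rows = []

    def _pos():
        return int(rng.integers(start + 1, max(start + 2, end - insert)))

    k = 0
    for _ in range(n_normal):
        k += 1
        p = _pos()
        rows.append((f"pair{k:05d}", contig, p, "+", contig, p + insert, "-"))
    for _ in range(n_inverted):
        k += 1
        p = _pos()
        rows.append((f"pair{k:05d}", contig, p, "+", contig, p + insert, "+"))
    for _ in range(n_cross_contig):
        k += 1
        p = _pos()
        rows.append((f"pair{k:05d}", contig, p, "+", other_contig,
                     int(rng.integers(1, 5000)), "-"))
    return pd.DataFrame(rows, columns=sio.PAIR_COLUMNS)


def write_vcf(
    matrix: pd.DataFrame,
    path,
    ref: str = "A",
    alt: str = "T",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a genotype matrix as a minimal VCF 4.2 (invariant sites kept)."""
    inds = list(matrix.columns)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    lines = ["##fileformat=VCFv4.2"]
    contigs = {ix[0] for ix in matrix.index}
    for c in sorted(contigs):
        length = (contig_lengths or {}).get(c, 10**6)
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds))
    for (chrom, pos), row in matrix.iterrows():
        variant = (row > 0).any()
        alt_field = alt if variant else "."
        gts = "\t".join(gt_map[int(g)] for g in row)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def make_cohort_inputs(
    spec: CohortSpec | None = None, outdir: str | Path | None = None
) -> dict:
    """Generate the complete input bundle for one preset cohort.

    Returns a dict with the reference locus, the cohort table, the depth
    track, a read-pair table around CYP^T, per-gene genotype matrices
    (S-genes scored in thrums and homostyles; paralogs in heterostyles and
    homostyles) and the allele truth table.  With ``outdir`` the bundle is
    also written as FASTA/BED/TSV/VCF files.
    """
    spec = spec or CohortSpec()
    locus = make_gene_model(seed=spec.seed)
    cohort = simulate_cohort(spec.preset, seed=spec.seed)
    depth = simulate_depth(cohort, locus, lam=spec.lam,
                           dispersion=spec.dispersion, seed=spec.seed + 1)

    n_cypt8 = int((cohort[["allele_1", "allele_2"]] == "CYP^T-8").any(axis=1).sum())
    pairs = make_read_pairs(
        locus.cypt_screen_region, n_normal=200,
        n_cross_contig=5 if n_cypt8 else 0, seed=spec.seed + 2,
    )

    thrums = cohort.loc[cohort.phenotype == "thrum", "individual"].tolist()
    pins = cohort.loc[cohort.phenotype == "pin", "individual"].tolist()
    homs = cohort.loc[cohort.phenotype == "homostyle", "individual"].tolist()
    matrices = {}
    groups = {}
    rng = np.random.default_rng(spec.seed + 3)
    all_genes = {**locus.s_genes, **locus.paralogs}
    for gene, model in all_genes.items():
        is_s_gene = gene in locus.s_genes
        out_group = thrums if is_s_gene else (pins + thrums)
        grp = {}
        if out_group:
            grp["heterostyle"] = out_group
        if homs:
            grp["homostyle"] = homs
        if not grp:
            continue
        matrices[gene] = simulate_genotype_matrix(
            groups=grp,
            theta={"heterostyle": spec.theta_outcrossing,
                   "homostyle": spec.theta_selfing},
            n_sites=model.cds_length,
            missing_rate=spec.missing_rate,
            inbreeding={"homostyle": 0.9},
            seed=int(rng.integers(0, 2**31 - 1)),
            chrom=model.contig,
            start=model.exons[0][0] + 1,
        )
        groups[gene] = grp

    specs = allele_specs(locus)
    truth = []
    for label, aspec in specs.items():
        _, recs = apply_allele(locus.sequences["S_locus"], aspec)
        truth.extend(recs)
    truth_df = pd.DataFrame(truth)

    phenotype_counts = (
        cohort.groupby("population")["phenotype"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["pin", "thrum", "homostyle"], fill_value=0)
        .rename(columns=lambda c: f"n_{c}")
        .reset_index()
    )

    bundle = {
        "spec": spec,
        "locus": locus,
        "cohort": cohort,
        "depth": depth,
        "pairs": pairs,
        "matrices": matrices,
        "matrix_groups": groups,
        "allele_truth": truth_df,
        "phenotype_counts": phenotype_counts,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    locus: SyntheticLocus = bundle["locus"]
    sio.write_fasta(locus.sequences, outdir / "reference.fasta")
    sio.write_fasta(locus.cds, outdir / "cds.fasta")
    sio.write_bed(locus.slocus_coding_regions, outdir / "slocus_coding.bed")
    sio.write_bed(locus.genome_coding_regions, outdir / "genome_coding.bed")
    features: sio.RegionSet = {"S_locus": []}
    names = {}
    for i, iv in enumerate(locus.cypt.exons, 1):
        features["S_locus"].append(iv)
        names[("S_locus", iv)] = f"CYP^T_exon{i}"
    if locus.cypt.promoter:
        features["S_locus"].append(locus.cypt.promoter)
        names[("S_locus", locus.cypt.promoter)] = "CYP^T_promoter"
    for i, iv in enumerate(locus.cypt.motifs, 1):
        features["S_locus"].append(iv)
        names[("S_locus", iv)] = f"CYP^T_motif{i}"
    sio.write_bed(features, outdir / "cypt_features.bed", names=names)
    sio.write_depth_tsv(bundle["depth"], outdir / "depth.tsv")
    sio.write_pairs_tsv(bundle["pairs"], outdir / "read_pairs.tsv")
    sio.write_phenotype_counts(bundle["phenotype_counts"], outdir / "phenotypes.tsv")
    bundle["cohort"].to_csv(outdir / "cohort_truth.tsv", sep="\t", index=False)
    bundle["allele_truth"].to_csv(outdir / "allele_truth.tsv", sep="\t", index=False)
    lengths = {c: len(s) for c, s in locus.sequences.items()}
    for gene, matrix in bundle["matrices"].items():
        safe = gene.replace("^", "").replace("/", "_")
        write_vcf(matrix, outdir / f"{safe}.vcf", contig_lengths=lengths)
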