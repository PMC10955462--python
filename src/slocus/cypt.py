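"""Screens for disruption of the S-locus style-length gene CYP^T.

Homostyly in *Primula vulgaris* arises when CYP^T, the brassinosteroid-
degrading cytochrome P450 of the S-locus, loses function.  Three mutation
categories are screened for:

1. exonic loss-of-function variants (premature stops, frameshifts),
2. homostyle-specific SNPs in introns / promoter / motif intervals
   (present in homostyles, absent in thrums),
3. structural rearrangements: deletions seen as runs of zero read depth,
   and inversion/translocation signals from discordant read-pair
   orientation.

The known allele catalogue maps mutation signatures to allele labels:
CYP^T-1 is the functional thrum copy, CYP^T-2 carries an exon-2 stop gain,
CYP^T-6 an 8-bp exon-1 frameshift deletion, and CYP^T-8 a ~2150-bp deletion
removing exon 1 together with the proximal promoter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Variant",
    "ConsequenceCall",
    "DeletionCall",
    "AlleleCall",
    "ReferenceMismatchError",
    "annotate_cds_consequence",
    "screen_group_specific_snps",
    "detect_zero_depth_runs",
    "flag_discordant_pairs",
    "classify_cypt_allele",
    "DEFAULT_CATALOGUE",
]


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference CDS."""


@dataclass(frozen=True)
class GeneModel:
    """A plus-strand gene model on one contig.

    Exons are 0-based half-open intervals ordered 5'->3'; the promoter is
    the region upstream of exon 1 (3 kb by convention) and motif intervals
    are externally supplied cis-element positions inside it.
    """

    gene_id: str
    contig: str
    exons: tuple[tuple[int, int], ...]
    promoter: tuple[int, int] | None = None
    motifs: tuple[tuple[int, int], ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.exons, self.exons[1:]):
            if b0 < a1:
                raise ValueError("exons must be non-overlapping and ordered 5'->3'")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a1, b0) for (_, a1), (b0, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    def cds_position(self, genomic_pos0: int) -> int | None:
        """0-based CDS offset of a 0-based genomic position, or None."""
        offset = 0
        for start, end in self.exons:
            if start <= genomic_pos0 < end:
                return offset + (genomic_pos0 - start)
            offset += end - start
        return None

    def exon_of(self, genomic_pos0: int) -> int | None:
        """1-based exon number containing a genomic position, or None."""
        for i, (start, end) in enumerate(self.exons, start=1):
            if start <= genomic_pos0 < end:
                return i
        return None

    def features_overlapping(self, start0: int, end0: int) -> list[str]:
        """Names of gene features intersecting [start0, end0)."""
        feats = []
        for i, (s, e) in enumerate(self.exons, start=1):
            if s < end0 and start0 < e:
                feats.append(f"exon{i}")
        for i, (s, e) in enumerate(self.introns, start=1):
            if s < end0 and start0 < e:
                feats.append(f"intron{i}")
        if self.promoter and self.promoter[0] < end0 and start0 < self.promoter[1]:
            feats.append("promoter")
        for i, (s, e) in enumerate(self.motifs, start=1):
            if s < end0 and start0 < e:
                feats.append(f"motif{i}")
        return feats


@dataclass(frozen=True)
class Variant:
    """A VCF-style variant: 1-based pos, anchored ref/alt strings."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = "."

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def indel_length(self) -> int:
        """Signed length change (insertions positive)."""
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class ConsequenceCall:
    variant_id: str
    csq_class: str  # synonymous | missense | stop_gain | frameshift | inframe_indel | noncoding
    exon: int | None
    protein_change: str = ""


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start: int  # 0-based half-open
    end: int
    overlapped_features: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlleleCall:
    individual: str
    allele: str
    functional_status: str  # functional | disrupted


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}


def annotate_cds_consequence(
    model: GeneModel, ref_cds: str, variant: Variant
) -> ConsequenceCall:
    """Classify a variant's effect on the coding sequence.

    SNVs are classified by codon translation under the standard genetic
    code; indels whose length change inside the CDS is not a multiple of 3
    are frameshifts.  Variants not touching an exon are ``noncoding``.
    """
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if "*" in str(Seq(ref_cds).translate())[:-1]:
        raise ValueError("reference CDS contains an internal stop codon")
    if variant.chrom != model.contig:
        return ConsequenceCall(variant.variant_id, "noncoding", None)

    pos0 = variant.pos - 1
    if variant.is_snv:
        cds_pos = model.cds_position(pos0)
        if cds_pos is None:
            return ConsequenceCall(variant.variant_id, "noncoding", None)
        if ref_cds[cds_pos].upper() != variant.ref.upper():
            raise ReferenceMismatchError(
                f"{variant.variant_id}: CDS has {ref_cds[cds_pos]!r} at "
                f"offset {cds_pos}, variant says {variant.ref!r}"
            )
        codon_i = cds_pos // 3
        codon = ref_cds[3 * codon_i : 3 * codon_i + 3]
        mutated = list(codon)
        mutated[cds_pos % 3] = variant.alt
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq("".join(mutated)).translate())
        change = f"p.{_AA3[aa_ref]}{codon_i + 1}{_AA3[aa_alt]}"
        if aa_alt == aa_ref:
            cls = "synonymous"
        elif aa_alt == "*":
            cls = "stop_gain"
        else:
            cls = "missense"
        return ConsequenceCall(variant.variant_id, cls, model.exon_of(pos0), change)

    # Indel: the first REF base is the anchor; the affected span starts one
    # base to its right for deletions.
    if variant.indel_length < 0:
        del_start = pos0 + len(variant.alt)
        del_end = pos0 + len(variant.ref)
        cds_bases = sum(
            1 for g in range(del_start, del_end) if model.cds_position(g) is not None
        )
        if cds_bases == 0:
            return ConsequenceCall(variant.variant_id, "noncoding", None)
        exon = model.exon_of(del_start) or model.exon_of(del_end - 1)
        cls = "frameshift" if cds_bases % 3 else "inframe_indel"
        return ConsequenceCall(variant.variant_id, cls, exon)
    # Insertion: inserted bases land after the anchor position.
    if model.cds_position(pos0) is None:
        return ConsequenceCall(variant.variant_id, "noncoding", None)
    ins = variant.indel_length
    cls = "frameshift" if ins % 3 else "inframe_indel"
    return ConsequenceCall(variant.variant_id, cls, model.exon_of(pos0))


def screen_group_specific_snps(
    genotypes: pd.DataFrame,
    groups: dict[str, list[str]],
    regions=None,
) -> pd.DataFrame:
    """SNPs carried by homostyles and absent from thrums.

    ``genotypes`` is a sites x individuals matrix of alternate-allele
    counts (0/1/2; -1 for missing) whose index carries (chrom, pos).
    ``groups`` maps "homostyle" and "thrum" to individual lists.  A site is
    reported when >= 1 homostyle carries the alternate allele and no thrum
    does; it is flagged fixed when every homostyle with a non-missing call
    carries it.  ``regions`` optionally restricts sites (a RegionSet).
    """
    for name in ("homostyle", "thrum"):
        if not groups.get(name):
            raise ValueError(f"group {name!r} is empty")
    hom = genotypes[groups["homostyle"]]
    thr = genotypes[groups["thrum"]]
    if regions is not None:
        from .io import positions_mask

        chroms = np.array([ix[0] for ix in genotypes.index])
        pos = np.array([ix[1] for ix in genotypes.index])
        keep = positions_mask(chroms, pos, regions)
        hom, thr = hom[keep], thr[keep]
    rows = []
    for site in hom.index:
        h = hom.loc[site].to_numpy()
        t = thr.loc[site].to_numpy()
        carriers = int((h > 0).sum())
        if carriers >= 1 and not (t > 0).any():
            called = h >= 0
            fixed = bool(called.any() and (h[called] > 0).all())
            rows.append(
                {
                    "chrom": site[0],
                    "pos": site[1],
                    "carriers": carriers,
                    "fixed_in_homostyles": fixed,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "carriers", "fixed_in_homostyles"])


def detect_zero_depth_runs(
    depth: pd.Series | np.ndarray,
    region: tuple[int, int],
    min_length: int = 50,
    chrom: str = "",
    positions: np.ndarray | None = None,
    model: GeneModel | None = None,
) -> list[DeletionCall]:
    """Maximal runs of zero depth of length >= ``min_length`` in a region.

    ``region`` is 0-based half-open.  Positions of the region absent from
    the depth track count as depth 0.  ``positions`` gives 1-based
    coordinates for the depth values (defaults to the Series index); if a
    gene model is supplied, each call is annotated with the features it
    overlaps.
    """
    start, end = region
    full = np.zeros(end - start, dtype=float)
    if positions is None:
        if isinstance(depth, pd.Series):
            positions = depth.index.to_numpy()
        else:
            positions = np.arange(start + 1, end + 1)
    values = np.asarray(depth, dtype=float)
    pos0 = np.asarray(positions) - 1
    inside = (pos0 >= start) & (pos0 < end)
    full[pos0[inside] - start] = values[inside]

    calls: list[DeletionCall] = []
    zero = full == 0
    i = 0
    n = len(zero)
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= min_length:
                a, b = start + i, start + j
                feats = tuple(model.features_overlapping(a, b)) if model else ()
                calls.append(DeletionCall(chrom=chrom, start=a, end=b,
                                          overlapped_features=feats))
            i = j
        else:
            i += 1
    return calls


def flag_discordant_pairs(
    pairs: pd.DataFrame,
    region: tuple[int, int],
    contig: str,
) -> dict[str, int]:
    """Tally read-pair orientation classes over a region.

    Convergent pairs on one contig are normal; same-orientation pairs
    signal an inversion; mates on different contigs signal a translocation.
    Pairs with missing mate information are counted as unresolvable.
    """
    start, end = region
    counts = {
        "normal_count": 0,
        "same_orientation_count": 0,
        "cross_contig_count": 0,
        "unresolvable_count": 0,
    }
    for _, row in pairs.iterrows():
        fields = [row.get(c) for c in
                  ("contig1", "pos1", "strand1", "contig2", "pos2", "strand2")]
        if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in fields):
            counts["unresolvable_count"] += 1
            continue
        in_region = any(
            row[f"contig{i}"] == contig and start <= row[f"pos{i}"] - 1 < end
            for i in (1, 2)
        )
        if not in_region:
            continue
        if row["contig1"] != row["contig2"]:
            counts["cross_contig_count"] += 1
        elif row["strand1"] == row["strand2"]:
            counts["same_orientation_count"] += 1
        else:
            counts["normal_count"] += 1
    return counts


@dataclass(frozen=True)
class AlleleDefinition:
    label: str
    functional: bool
    description: str
    operational: bool = True  # False: defined in prior work, no signature here


DEFAULT_CATALOGUE: tuple[AlleleDefinition, ...] = (
    AlleleDefinition("CYP^T-1", True, "functional thrum copy"),
    AlleleDefinition("CYP^T-2", False, "stop gain in exon 2"),
    AlleleDefinition("CYP^T-3", False, "defined in prior work", operational=False),
    AlleleDefinition("CYP^T-4", False, "defined in prior work", operational=False),
    AlleleDefinition("CYP^T-5", False, "defined in prior work", operational=False),
    AlleleDefinition("CYP^T-6", False, "8-bp frameshift deletion in exon 1"),
    AlleleDefinition("CYP^T-7", False, "defined in prior work", operational=False),
    AlleleDefinition("CYP^T-8", False, "structural deletion of exon 1 and promoter"),
)


def classify_cypt_allele(
    consequences: list[ConsequenceCall],
    deletions: list[DeletionCall],
    model: GeneModel,
    individual: str = "",
) -> AlleleCall:
    """Match observed disruptive events to the allele catalogue.

    Disruptive events are stop gains, frameshifts and structural deletions
    removing a whole exon.  No disruptive event -> functional (CYP^T-1-like);
    one recognised signature -> the catalogued allele; conflicting or
    unrecognised disruptive signatures -> "novel" (still disrupted).
    """
    e1_start, e1_end = model.exons[0]
    whole_exon1_deleted = any(
        d.start <= e1_start and d.end >= e1_end for d in deletions
    )
    stop_exon2 = any(
        c.csq_class == "stop_gain" and c.exon == 2 for c in consequences
    )
    fs_exon1_8bp = any(
        c.csq_class == "frameshift" and c.exon == 1 for c in consequences
    )
    other_disruptive = any(
        c.csq_class in ("stop_gain", "frameshift")
        and not ((c.csq_class == "stop_gain" and c.exon == 2)
                 or (c.csq_class == "frameshift" and c.exon == 1))
        for c in consequences
    )

    signatures = [x for x, hit in (
        ("CYP^T-8", whole_exon1_deleted),
        ("CYP^T-2", stop_exon2),
        ("CYP^T-6", fs_exon1_8bp),
    ) if hit]

    if not signatures and not other_disruptive:
        return AlleleCall(individual, "CYP^T-1", "functional")
    if len(signatures) == 1 and not other_disruptive:
        return AlleleCall(individual, signatures[0], "disrupted")
    return AlleleCall(individual, "novel", "disrupted")
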