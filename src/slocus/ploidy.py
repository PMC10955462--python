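"""S-locus copy-number classification from relative sequencing depth.

The S-locus is hemizygous, so an individual's mean read depth over S-locus
coding regions, normalised by its genome-wide coding depth, estimates how
many copies of the locus it carries: a relative depth near 0.5 indicates a
haploid S-locus, near 1 a diploid one, and near 0 its absence (pins).
Combining the copy-number call with floral phenotype and the functional
status of the style-length gene CYP^T yields the six-way S-locus genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RegionSet, positions_mask, region_length

__all__ = [
    "DepthSummary",
    "CopyNumberCall",
    "SGenotypeCall",
    "summarize_depth",
    "classify_copy_number",
    "assign_s_genotype",
    "classify_cohort",
]


@dataclass(frozen=True)
class DepthSummary:
    """Mean depths over S-locus and genome-wide coding regions.

    ``rel_depth = depth_slocus / depth_genome``; positions inside a target
    interval with no depth record count as depth 0.
    """

    individual: str
    depth_slocus: float
    depth_genome: float

    def __post_init__(self) -> None:
        if self.depth_genome <= 0:
            raise ValueError(
                f"{self.individual}: genome-wide depth must be > 0 "
                "(uninformative individual)"
            )

    @property
    def rel_depth(self) -> float:
        return self.depth_slocus / self.depth_genome


@dataclass(frozen=True)
class CopyNumberCall:
    individual: str
    call: str  # absent | haploid | diploid | unclassifiable
    rel_depth: float


@dataclass(frozen=True)
class SGenotypeCall:
    individual: str
    phenotype: str  # pin | thrum | homostyle
    cypt_status: str  # functional | disrupted | heterozygous_functional_disrupted | absent
    genotype: str  # 0/0 | S/0 | S/S | S/S* | S*/0 | S*/S* | inconsistent


def summarize_depth(
    depth: pd.DataFrame,
    slocus_regions: RegionSet,
    coding_regions: RegionSet,
) -> list[DepthSummary]:
    """Per-individual mean depth over two interval sets.

    ``depth`` has columns chrom, pos (1-based) and one column per
    individual.  The mean is taken over every position inside the interval
    set: positions without a record contribute depth 0, so the denominator
    is the total interval length, not the number of recorded rows.
    """
    if region_length(slocus_regions) == 0 or region_length(coding_regions) == 0:
        raise ValueError("interval sets must be non-empty")
    chroms = depth["chrom"].to_numpy()
    pos = depth["pos"].to_numpy()
    s_mask = positions_mask(chroms, pos, slocus_regions)
    g_mask = positions_mask(chroms, pos, coding_regions)
    s_len = region_length(slocus_regions)
    g_len = region_length(coding_regions)
    out = []
    for ind in depth.columns[2:]:
        d = depth[ind].to_numpy(dtype=float)
        out.append(
            DepthSummary(
                individual=str(ind),
                depth_slocus=float(d[s_mask].sum()) / s_len,
                depth_genome=float(d[g_mask].sum()) / g_len,
            )
        )
    return out


def classify_copy_number(
    summary: DepthSummary,
    threshold_absent: float = 0.05,
) -> CopyNumberCall:
    """Band the relative S-locus depth into a copy-number call.

    0.5 +/- 0.25 is called haploid and 1 +/- 0.25 diploid; the shared
    boundary 0.75 belongs to the haploid band.  Values below
    ``threshold_absent`` are called absent (pins have no S-locus reads);
    anything else is unclassifiable.
    """
    rd = summary.rel_depth
    if rd < threshold_absent:
        call = "absent"
    elif 0.25 <= rd <= 0.75:
        call = "haploid"
    elif 0.75 < rd <= 1.25:
        call = "diploid"
    else:
        call = "unclassifiable"
    return CopyNumberCall(individual=summary.individual, call=call, rel_depth=rd)


_GENOTYPE_TABLE = {
    ("pin", "absent", "absent"): "0/0",
    ("thrum", "haploid", "functional"): "S/0",
    ("thrum", "diploid", "functional"): "S/S",
    ("thrum", "diploid", "heterozygous_functional_disrupted"): "S/S*",
    ("homostyle", "haploid", "disrupted"): "S*/0",
    ("homostyle", "diploid", "disrupted"): "S*/S*",
}


def assign_s_genotype(
    call: CopyNumberCall, phenotype: str, cypt_status: str
) -> SGenotypeCall:
    """Combine copy number, phenotype and CYP^T status into a genotype.

    Combinations outside the consistency table (e.g. a pin with S-locus
    reads, or a homostyle with a functional CYP^T) are flagged
    ``inconsistent`` rather than coerced.
    """
    genotype = _GENOTYPE_TABLE.get((phenotype, call.call, cypt_status), "inconsistent")
    return SGenotypeCall(
        individual=call.individual,
        phenotype=phenotype,
        cypt_status=cypt_status,
        genotype=genotype,
    )


def classify_cohort(
    depth: pd.DataFrame,
    slocus_regions: RegionSet,
    coding_regions: RegionSet,
    phenotypes: dict[str, str],
    cypt_status: dict[str, str],
    threshold_absent: float = 0.05,
) -> pd.DataFrame:
    """Run the full depth -> copy number -> genotype chain for a cohort.

    Returns one row per individual with depth summaries, the copy-number
    call and the assigned S-locus genotype.
    """
    rows = []
    for summ in summarize_depth(depth, slocus_regions, coding_regions):
        cn = classify_copy_number(summ, threshold_absent=threshold_absent)
        gt = assign_s_genotype(
            cn,
            phenotypes[summ.individual],
            cypt_status[summ.individual],
        )
        rows.append(
            {
                "individual": summ.individual,
                "depth_slocus": summ.depth_slocus,
                "depth_genome": summ.depth_genome,
                "rel_depth": summ.rel_depth,
                "copy_number": cn.call,
                "phenotype": gt.phenotype,
                "cypt_status": gt.cypt_status,
                "genotype": gt.genotype,
            }
        )
    return pd.DataFrame(rows)
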