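"""Missing-data-aware nucleotide diversity at degenerate coding sites.

pi is estimated the way pixy does it: per site, with c_ref and c_alt the
allele counts among non-missing genotypes,

    diffs       = c_ref * c_alt
    comparisons = (c_ref + c_alt) * (c_ref + c_alt - 1) / 2

and the aggregate over a site set is sum(diffs) / sum(comparisons).
Invariant sites contribute comparisons but no differences, so they dilute
pi rather than being ignored, and missing genotypes shrink a site's
comparisons instead of biasing the estimate.  pi_S is computed over 4-fold
degenerate (synonymous) sites and pi_N over 0-fold degenerate
(non-synonymous) sites; their ratio indexes the efficacy of purifying
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "annotate_degeneracy",
    "degeneracy_counts",
    "PiEstimate",
    "pi_from_genotypes",
    "pi_ratio",
    "diversity_table",
    "summarize_gene_groups",
]

_BASES = "ACGT"


def _codon_degeneracy() -> dict[str, tuple[str, str, str]]:
    """Per-position site class for every sense codon of the standard code."""
    table: dict[str, tuple[str, str, str]] = {}
    for codon in map("".join, product(_BASES, repeat=3)):
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        classes = []
        for i in range(3):
            changed = sum(
                str(Seq(codon[:i] + b + codon[i + 1:]).translate()) != aa
                for b in _BASES if b != codon[i]
            )
            if changed == 0:
                classes.append("4-fold")
            elif changed == 3:
                classes.append("0-fold")
            else:
                classes.append("other")
        table[codon] = tuple(classes)
    return table


_DEGENERACY = _codon_degeneracy()


def annotate_degeneracy(cds: str) -> np.ndarray:
    """Site class ("0-fold", "4-fold" or "other") per CDS position.

    A position is 4-fold degenerate iff all three alternative nucleotides
    preserve the amino acid and 0-fold iff all three change it; everything
    else (2-/3-fold positions, ambiguity codons) is "other" and excluded
    from both pi_S and pi_N.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    classes = np.empty(len(cds), dtype=object)
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in _DEGENERACY:
            classes[i : i + 3] = _DEGENERACY[codon]
        elif set(codon) <= set(_BASES):
            if i + 3 == len(cds):  # terminal stop codon
                classes[i : i + 3] = "other"
            else:
                raise ValueError(f"internal stop codon {codon} at CDS offset {i}")
        else:
            classes[i : i + 3] = "other"  # ambiguity characters
    return classes


def degeneracy_counts(cds: str) -> dict[str, int]:
    classes = annotate_degeneracy(cds)
    return {k: int((classes == k).sum()) for k in ("0-fold", "4-fold", "other")}


@dataclass(frozen=True)
class PiEstimate:
    pi: float  # nan when no comparisons are available
    diffs: float
    comparisons: float
    n_sites: int


def pi_from_genotypes(
    matrix: pd.DataFrame,
    sites=None,
    individuals: list[str] | None = None,
    haploid: bool = False,
) -> PiEstimate:
    """Aggregate pi over a site subset and individual group.

    ``matrix`` is sites x individuals with alternate-allele counts
    (0/1/2, -1 for missing); hemizygous individuals typically appear as
    diploid homozygotes.  With ``haploid=True`` each individual contributes
    a single allele (its genotype collapsed to presence of the alternate),
    the appropriate treatment when every "diploid" call is really one
    chromosome.  Sites with fewer than two called alleles are excluded from
    both sums.
    """
    sub = matrix
    if sites is not None:
        sub = sub.loc[sites]
    if individuals is not None:
        if not individuals:
            raise ValueError("individual group must be non-empty")
        sub = sub[individuals]
    gt = sub.to_numpy(dtype=float)
    called = gt >= 0
    if haploid:
        alt = np.where(called, (gt > 0).astype(float), 0.0).sum(axis=1)
        total = called.sum(axis=1).astype(float)
    else:
        alt = np.where(called, gt, 0.0).sum(axis=1)
        total = 2.0 * called.sum(axis=1)
    ref = total - alt
    usable = total >= 2
    diffs = float((ref[usable] * alt[usable]).sum())
    comps = float((total[usable] * (total[usable] - 1) / 2).sum())
    if comps == 0:
        warnings.warn("no allele comparisons available; pi undefined", stacklevel=2)
        pi = float("nan")
    else:
        pi = diffs / comps
    return PiEstimate(pi=pi, diffs=diffs, comparisons=comps, n_sites=int(usable.sum()))


def pi_ratio(pi_n: float, pi_s: float) -> float:
    """pi_N / pi_S, or NaN ("NA") when pi_S is zero or undefined."""
    if not np.isfinite(pi_s) or not np.isfinite(pi_n) or pi_s == 0:
        return float("nan")
    return pi_n / pi_s


def diversity_table(
    matrices: dict[str, pd.DataFrame],
    site_classes: dict[str, np.ndarray],
    groups: dict[str, dict[str, list[str]]],
    haploid: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-group pi_S / pi_N / ratio table.

    ``matrices[gene]`` is the genotype matrix over that gene's CDS sites
    (rows aligned with ``site_classes[gene]``), and ``groups[gene]`` maps
    group names to individual lists (S-genes are only scored in thrums and
    homostyles, paralogs in heterostyles and homostyles).
    """
    rows = []
    for gene, matrix in matrices.items():
        classes = site_classes[gene]
        syn = np.flatnonzero(classes == "4-fold")
        non = np.flatnonzero(classes == "0-fold")
        for group, inds in groups[gene].items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est_s = pi_from_genotypes(
                    matrix.iloc[syn], individuals=inds, haploid=haploid
                )
                est_n = pi_from_genotypes(
                    matrix.iloc[non], individuals=inds, haploid=haploid
                )
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n": len(inds),
                    "pi_s": est_s.pi,
                    "pi_n": est_n.pi,
                    "ratio": pi_ratio(est_n.pi, est_s.pi),
                }
            )
    return pd.DataFrame(rows)


def summarize_gene_groups(
    estimates: pd.DataFrame, exclude: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Mean and standard error of each statistic per group.

    NaN ("NA") entries are excluded from ratio averages; ``exclude`` drops
    the listed genes before averaging (e.g. a single outlier gene).  Cells
    with a single value report the mean with SE = NaN.
    """
    df = estimates[~estimates["gene"].isin(exclude)]
    rows = []
    for group, sub in df.groupby("group", sort=False):
        row = {"group": group, "n_genes": len(sub)}
        for stat in ("pi_s", "pi_n", "ratio"):
            vals = sub[stat].dropna().to_numpy()
            row[f"{stat}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{stat}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
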