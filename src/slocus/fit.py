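"""Observed genotype tables and chi-squared fit to model expectations.

Population surveys count floral phenotypes (pin / thrum / homostyle); the
sequenced subsample tells what fraction of each phenotype carries which
S-locus genotype.  Multiplying phenotype counts by those proportions gives
observed genotype counts, which are tested against the expected frequencies
of the genotype-frequency recursion over a (viability x generation) grid
with Pearson chi-squared tests and Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crosby import GENOTYPES, PopulationState

__all__ = ["GenotypeTable", "FitResult", "observed_genotype_table", "chisq_fit", "fit_grid"]


@dataclass(frozen=True)
class GenotypeTable:
    """Per-population genotype counts over the four model classes.

    Thrum subclasses (S/S, S/S*) are kept separately when supplied but are
    collapsed into the S/0 class for model comparison, matching the
    four-genotype state space of the recursion.
    """

    population: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        return {g: c / self.total for g, c in self.counts.items()}

    def model_counts(self) -> np.ndarray:
        """Counts collapsed onto (0/0, S/0, S*/0, S*/S*)."""
        thrum = sum(self.counts.get(g, 0) for g in ("S/0", "S/S", "S/S*"))
        return np.array(
            [
                self.counts.get("0/0", 0),
                thrum,
                self.counts.get("S*/0", 0),
                self.counts.get("S*/S*", 0),
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class FitResult:
    population: str
    v: float | None
    generation: int | None
    chi2: float
    df: int
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None


def _split_counts(n: int, props) -> list[int]:
    """Round n*props to integers; the residual goes to the largest class."""
    props = np.asarray(props, dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1) > 1e-6:
        raise ValueError("proportions must be non-negative and sum to 1")
    raw = n * props
    counts = np.rint(raw).astype(int)
    counts[int(np.argmax(counts))] += n - counts.sum()
    return counts.tolist()


def observed_genotype_table(
    population: str,
    phenotype_counts: tuple[int, int, int],
    homostyle_props: tuple[float, float],
    thrum_props: tuple[float, float, float] | None = None,
) -> GenotypeTable:
    """Build a genotype table from phenotype counts and subsample splits.

    ``phenotype_counts`` is (thrum, pin, homostyle).  ``homostyle_props``
    is the (S*/0, S*/S*) split among classified homostyles;
    ``thrum_props``, when given, splits thrums into (S/0, S/S, S/S*).
    Fractional counts are rounded to the nearest integer with the residual
    assigned to the larger class.
    """
    n_thrum, n_pin, n_hom = phenotype_counts
    counts: dict[str, int] = {"0/0": n_pin}
    hap, dip = _split_counts(n_hom, homostyle_props)
    counts["S*/0"] = hap
    counts["S*/S*"] = dip
    if thrum_props is None:
        counts["S/0"] = n_thrum
    else:
        s0, ss, sx = _split_counts(n_thrum, thrum_props)
        counts.update({"S/0": s0, "S/S": ss, "S/S*": sx})
    return GenotypeTable(population=population, counts=counts)


def chisq_fit(
    observed: GenotypeTable,
    expected: PopulationState | np.ndarray,
) -> FitResult:
    """Pearson goodness of fit of observed counts to expected frequencies.

    Cells with expected frequency 0 and observed count 0 are dropped (the
    statistic is undefined there and they carry no information); an
    expected-0 cell with a positive observed count makes the table
    incompatible (p = 0).  df = included cells - 1.
    """
    exp_freq = (
        expected.as_array()
        if isinstance(expected, PopulationState)
        else np.asarray(expected, dtype=float)
    )
    obs = observed.model_counts()
    n = obs.sum()
    exp = exp_freq * n

    nonzero = exp > 0
    included = int(nonzero.sum())
    if included < 2:
        raise ValueError("need at least 2 cells with positive expectation")
    if np.any((exp == 0) & (obs > 0)):
        return FitResult(observed.population, None, None,
                         chi2=float("inf"), df=included - 1, p_raw=0.0)
    chi2 = float(((obs[nonzero] - exp[nonzero]) ** 2 / exp[nonzero]).sum())
    df = included - 1
    p = float(stats.chi2.sf(chi2, df))
    return FitResult(observed.population, None, None, chi2=chi2, df=df, p_raw=p)


def fit_grid(
    observed_tables: list[GenotypeTable],
    expected_grid: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Chi-squared fit of each population against every grid cell.

    ``expected_grid`` is the output of
    :func:`slocus.crosby.expected_frequency_grid` (columns v, generation,
    p, q, r, s).  The Bonferroni family defaults to all (v, generation)
    cells tested per population; ``p_adjusted = min(1, p_raw * m)`` and a
    cell is flagged compatible when p_adjusted >= alpha.  The ``stars``
    column marks raw p < .01 with "**".
    """
    m = family_size if family_size is not None else len(expected_grid)
    if m < 1:
        raise ValueError("Bonferroni family size must be >= 1")
    rows = []
    for table in observed_tables:
        for _, cell in expected_grid.iterrows():
            exp = np.array([cell["p"], cell["q"], cell["r"], cell["s"]])
            base = chisq_fit(table, exp)
            p_adj = min(1.0, base.p_raw * m)
            rows.append(
                {
                    "population": table.population,
                    "v": cell["v"],
                    "generation": int(cell["generation"]),
                    "chi2": base.chi2,
                    "df": base.df,
                    "p_raw": base.p_raw,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                    "compatible": p_adj >= alpha,
                    "stars": "**" if base.p_raw < 0.01 else "",
                }
            )
    return pd.DataFrame(rows)
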