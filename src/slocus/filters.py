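"""GATK-style hard filtering of variant records.

Records are retained when every annotated statistic passes its threshold:
QD > 2.0, MQ > 40.0, FS < 60.0, MQRankSum > -12.5, ReadPosRankSum > -8.0
and 0.5 x mean depth < DP < 3 x mean depth.  Sites with fixed
heterozygosity (InbreedingCoeff < -0.99) are dropped as likely artifacts.
A missing annotation (e.g. MQRankSum at sites without heterozygous calls)
passes its sub-filter rather than failing the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["FilterThresholds", "record_passes", "apply_hard_filters", "filter_vcf"]


@dataclass(frozen=True)
class FilterThresholds:
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    dp_low_factor: float = 0.5
    dp_high_factor: float = 3.0
    inbreeding_min: float = -0.99

    def __post_init__(self) -> None:
        if not self.dp_low_factor < self.dp_high_factor:
            raise ValueError("dp_low_factor must be < dp_high_factor")


def _get(info: Mapping, key: str):
    val = info.get(key)
    if val is None:
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        return None


def record_passes(
    info: Mapping,
    thresholds: FilterThresholds | None = None,
    mean_depth: float | None = None,
) -> bool:
    """Whether one record's INFO annotations pass all hard filters.

    ``mean_depth`` is the depth the DP band is relative to (typically the
    cohort mean site depth); with ``mean_depth=None`` the DP sub-filter is
    skipped.
    """
    t = thresholds or FilterThresholds()
    qd = _get(info, "QD")
    if qd is not None and not qd > t.qd_min:
        return False
    mq = _get(info, "MQ")
    if mq is not None and not mq > t.mq_min:
        return False
    fs = _get(info, "FS")
    if fs is not None and not fs < t.fs_max:
        return False
    mqrs = _get(info, "MQRankSum")
    if mqrs is not None and not mqrs > t.mqranksum_min:
        return False
    rprs = _get(info, "ReadPosRankSum")
    if rprs is not None and not rprs > t.readpos_min:
        return False
    dp = _get(info, "DP")
    if dp is not None and mean_depth is not None:
        if not (t.dp_low_factor * mean_depth < dp < t.dp_high_factor * mean_depth):
            return False
    ic = _get(info, "InbreedingCoeff")
    if ic is not None and ic < t.inbreeding_min:
        return False
    return True


def apply_hard_filters(
    records: Iterable[Mapping],
    thresholds: FilterThresholds | None = None,
    mean_depth: float | None = None,
) -> tuple[list, dict]:
    """Filter an iterable of INFO-like mappings.

    Returns the retained records and a summary ``{"kept": int,
    "removed": int, "malformed": int}``.  Malformed entries (not mappings)
    are skipped and counted.
    """
    kept: list = []
    stats = {"kept": 0, "removed": 0, "malformed": 0}
    for rec in records:
        if not isinstance(rec, Mapping):
            stats["malformed"] += 1
            continue
        if record_passes(rec, thresholds, mean_depth):
            kept.append(rec)
            stats["kept"] += 1
        else:
            stats["removed"] += 1
    return kept, stats


_INFO_KEYS = ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum", "DP", "InbreedingCoeff")


def filter_vcf(
    path,
    thresholds: FilterThresholds | None = None,
    mean_depth: float | None = None,
) -> pd.DataFrame:
    """Apply the hard filters to a VCF and return the retained sites.

    When ``mean_depth`` is None it defaults to the cohort mean of the INFO
    DP field over all records (the "X" of the DP band).  Returns a
    DataFrame with chrom, pos, ref, alt, the INFO annotations and a
    ``passed`` flag.
    """
    from cyvcf2 import VCF

    rows = []
    for var in VCF(str(path)):
        info = {k: var.INFO.get(k) for k in _INFO_KEYS}
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": ",".join(var.ALT) if var.ALT else "",
                **info,
            }
        )
    df = pd.DataFrame(rows)
    if mean_depth is None and len(df) and df["DP"].notna().any():
        mean_depth = float(df["DP"].dropna().astype(float).mean())
    df["passed"] = [
        record_passes({k: row[k] for k in _INFO_KEYS}, thresholds, mean_depth)
        for _, row in df.iterrows()
    ]
    return df
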