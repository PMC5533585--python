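"""Bait-vs-control enrichment, significance, hit calling, and volcano export.

Each BioID bait is compared against a soluble-ligase control, both run in
replicate (typically quadruplicate).  Per protein:

* the average dNSAF is taken over replicates with non-zero dNSAF;
* fold enrichment is the ratio avg_dNSAF(bait) / avg_dNSAF(control);
* significance is a two-tailed two-sample Student t-test across the raw
  replicate dNSAF vectors (zeros included);
* a protein is a hit when fold > 3, p < 0.05 and the average raw bait
  spectral count > 2 (all strict), decoys excluded.

A separate, slightly looser two-tier rule maps proximal proteins as
mid (2-3 fold) or high (>= 3 fold) at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: smallest representable positive p, used when both groups are constant
#: but different (the t statistic diverges).
P_FLOOR = np.nextafter(0.0, 1.0)

TIER_NONE = "none"
TIER_MID = "mid"
TIER_HIGH = "high"


@dataclass(frozen=True)
class HitCriteria:
    """Hit thresholds; every comparison is strict."""

    min_fold: float = 3.0
    max_p: float = 0.05
    min_avg_spc: float = 2.0


def average_nonzero(replicate_values) -> float:
    """Arithmetic mean over the strictly positive entries; 0 if none."""
    values = np.asarray(replicate_values, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        return 0.0
    return float(positive.mean())


def fold_enrichment(avg_bait: float, avg_control: float) -> float:
    """Bait/control ratio of average dNSAF.

    Control 0 with bait > 0 gives +inf (passes any fold threshold);
    0/0 gives NaN (never a hit).  Negative inputs are rejected.
    """
    if avg_bait < 0 or avg_control < 0:
        raise ValueError("average dNSAF values must be non-negative")
    if avg_control == 0:
        return float("inf") if avg_bait > 0 else float("nan")
    return avg_bait / avg_control


def two_tailed_ttest(bait_reps, control_reps) -> float:
    """Two-sample equal-variance (Student) t-test, two-tailed p-value.

    Degenerate cases where the pooled variance vanishes: both groups
    constant and equal -> p = 1; constant and different -> the smallest
    representable positive p (the t statistic diverges).
    """
    bait = np.asarray(bait_reps, dtype=float)
    control = np.asarray(control_reps, dtype=float)
    if bait.size < 2 or control.size < 2:
        raise ValueError("need at least two replicates per group")
    if bait.std() == 0 and control.std() == 0:
        return 1.0 if bait.mean() == control.mean() else P_FLOOR
    return float(stats.ttest_ind(bait, control, equal_var=True).pvalue)


def ttest_matrix(
    bait: pd.DataFrame, control: pd.DataFrame, equal_var: bool = True
) -> pd.Series:
    """Row-wise two-tailed t-test p-values for replicate matrices.

    Vectorized counterpart of :func:`two_tailed_ttest` for whole
    experiments (rows = proteins, columns = replicates), with the same
    degenerate-case conventions.
    """
    res = stats.ttest_ind(
        bait.to_numpy(dtype=float),
        control.to_numpy(dtype=float),
        axis=1,
        equal_var=equal_var,
    )
    p = pd.Series(res.pvalue, index=bait.index)
    zero_var = (bait.std(axis=1, ddof=0) == 0) & (control.std(axis=1, ddof=0) == 0)
    equal_mean = bait.mean(axis=1) == control.mean(axis=1)
    p[zero_var & equal_mean] = 1.0
    p[zero_var & ~equal_mean] = P_FLOOR
    return p


def enrichment_table(
    bait_dnsaf: pd.DataFrame,
    control_dnsaf: pd.DataFrame,
    bait_spc: pd.DataFrame | None = None,
    decoy: pd.Series | None = None,
    criteria: HitCriteria | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Build the per-protein enrichment record table for one bait.

    Inputs are proteins x replicates dNSAF matrices for bait and control
    (indexes are aligned on their union; missing proteins count as zero)
    plus the raw bait spectral-count matrix used for the average-count
    criterion.  Returns one row per protein with columns ``avg_dnsaf_bait``,
    ``avg_dnsaf_control``, ``fold_enrichment``, ``p_value``,
    ``avg_spectral_count``, ``is_decoy``, ``is_hit`` and ``tier``.
    """
    criteria = criteria or HitCriteria()
    proteins = bait_dnsaf.index.union(control_dnsaf.index)
    bait_dnsaf = bait_dnsaf.reindex(proteins, fill_value=0.0)
    control_dnsaf = control_dnsaf.reindex(proteins, fill_value=0.0)

    records = pd.DataFrame(index=proteins)
    records["avg_dnsaf_bait"] = [
        average_nonzero(row) for row in bait_dnsaf.to_numpy()
    ]
    records["avg_dnsaf_control"] = [
        average_nonzero(row) for row in control_dnsaf.to_numpy()
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = records["avg_dnsaf_bait"] / records["avg_dnsaf_control"]
    fold[(records["avg_dnsaf_control"] == 0) & (records["avg_dnsaf_bait"] > 0)] = np.inf
    fold[(records["avg_dnsaf_control"] == 0) & (records["avg_dnsaf_bait"] == 0)] = np.nan
    records["fold_enrichment"] = fold
    records["p_value"] = ttest_matrix(bait_dnsaf, control_dnsaf, equal_var=equal_var)
    if bait_spc is not None:
        records["avg_spectral_count"] = (
            bait_spc.reindex(proteins, fill_value=0).mean(axis=1)
        )
    else:
        records["avg_spectral_count"] = np.nan
    records["is_decoy"] = (
        decoy.reindex(proteins, fill_value=False)
        if decoy is not None
        else pd.Series(False, index=proteins)
    )
    records["is_hit"] = call_hits(records, criteria)
    records["tier"] = proximity_tiers(records)
    return records


def call_hits(records: pd.DataFrame, criteria: HitCriteria | None = None) -> pd.Series:
    """Boolean hit flag per protein: fold > 3, p < 0.05, avg SpC > 2.

    All comparisons strict; +inf fold passes any threshold, NaN fold never
    does; decoy proteins are never hits.
    """
    criteria = criteria or HitCriteria()
    fold = records["fold_enrichment"]
    ok = (
        (fold > criteria.min_fold)
        & (records["p_value"] < criteria.max_p)
        & (records["avg_spectral_count"] > criteria.min_avg_spc)
        & ~records["is_decoy"].astype(bool)
    )
    return ok.fillna(False)


def proximity_tiers(records: pd.DataFrame) -> pd.Series:
    """Two-tier proximity map: high (fold >= 3), mid (2 <= fold < 3), at
    p < 0.05; everything else none.  Note the high tier is inclusive at 3,
    unlike the hit rule's strict > 3."""
    fold = records["fold_enrichment"]
    sig = records["p_value"] < 0.05
    tier = pd.Series(TIER_NONE, index=records.index, dtype=object)
    tier[sig & (fold >= 2) & (fold < 3)] = TIER_MID
    tier[sig & (fold >= 3)] = TIER_HIGH
    return tier


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2 fold enrichment vs -log10 p.

    Rows with infinite fold (control never detected) are exported with the
    log2 fold capped at one unit above the largest finite value, marked by
    a ``capped`` flag; hit logic upstream already used the exact sentinel.
    """
    fold = records["fold_enrichment"].astype(float)
    finite = fold[np.isfinite(fold) & (fold > 0)]
    cap = (np.log2(finite.max()) + 1.0) if len(finite) else 1.0
    with np.errstate(divide="ignore"):
        log2_fold = np.where(np.isinf(fold), cap, np.log2(fold))
        neg_log10_p = -np.log10(records["p_value"].astype(float))
    out = pd.DataFrame(
        {
            "log2_fold": log2_fold,
            "neg_log10_p": neg_log10_p,
            "is_hit": records["is_hit"].astype(bool),
            "capped": np.isinf(fold),
        },
        index=records.index,
    )
    return out
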