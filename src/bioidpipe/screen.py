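"""Secondary screen nominating dynein-activator candidates.

Known activators are long coiled-coil proteins, so the screen pools the
enrichment tables of datasets in which at least one known activator was a
hit and selects proteins that (a) reach a pooled bait/control dNSAF ratio
greater than 3 in some dataset, (b) are present (non-zero dNSAF) in at
least 3 of 4 replicates of some pooled dataset, (c) carry a predicted
coiled-coil interval of at least 100 aa, and (d) are not on any exclusion
list (nuclear proteins, dynein/dynactin subunits, proteins that are
entirely coiled coil).  Exclusion lists are plain inputs, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class CoiledCoilAnnotation:
    """Predicted coiled-coil intervals for one protein, 1-based inclusive."""

    protein_id: str
    intervals: list  # of (start, end) tuples

    def __post_init__(self):
        for start, end in self.intervals:
            if start > end or start < 1:
                raise ValueError(
                    f"bad coiled-coil interval ({start}, {end}) on {self.protein_id}"
                )

    @property
    def max_interval_length(self) -> int:
        if not self.intervals:
            return 0
        return max(end - start + 1 for start, end in self.intervals)


@dataclass(frozen=True)
class ScreenCriteria:
    """Selection rules of the secondary screen."""

    min_ratio: float = 3.0          # strict
    min_replicates_present: int = 3  # of the experiment's 4
    min_cc_length: int = 100         # inclusive, in aa
    excluded: frozenset = frozenset()  # union of the exclusion lists


def merge_exclusions(*lists) -> frozenset:
    """Union several plain exclusion lists (nuclear, dynein/dynactin,
    entirely-coiled-coil) into one frozen set of protein ids."""
    out: set = set()
    for lst in lists:
        out.update(lst)
    return frozenset(out)


def select_candidates(
    pooled: dict[str, pd.DataFrame],
    cc_annotations: dict[str, CoiledCoilAnnotation],
    criteria: ScreenCriteria | None = None,
) -> pd.DataFrame:
    """Evaluate every protein in the pooled datasets against the screen.

    ``pooled`` maps dataset label to a per-protein table with a ``ratio``
    column (bait/control dNSAF ratio) and one column per replicate holding
    that replicate's dNSAF (zero = not detected).  A protein's ratio
    criterion uses the maximum ratio over pooled datasets; the presence
    criterion asks for non-zero dNSAF in >= ``min_replicates_present``
    replicates of at least one single dataset.  A protein without
    coiled-coil annotation counts as coiled-coil length 0.

    Returns one row per protein with boolean columns ``ratio_ok``,
    ``presence_ok``, ``cc_ok``, ``not_excluded`` and the conjunction
    ``is_candidate``, plus the supporting numbers.
    """
    criteria = criteria or ScreenCriteria()
    proteins: set = set()
    for table in pooled.values():
        proteins.update(table.index)

    rows = []
    for pid in sorted(proteins):
        max_ratio = 0.0
        best_presence = 0
        for table in pooled.values():
            if pid not in table.index:
                continue
            row = table.loc[pid]
            max_ratio = max(max_ratio, float(row["ratio"]))
            reps = row.drop(labels=["ratio"])
            best_presence = max(best_presence, int((reps > 0).sum()))
        cc = cc_annotations.get(pid)
        cc_len = cc.max_interval_length if cc is not None else 0
        ratio_ok = max_ratio > criteria.min_ratio
        presence_ok = best_presence >= criteria.min_replicates_present
        cc_ok = cc_len >= criteria.min_cc_length
        not_excluded = pid not in criteria.excluded
        rows.append(
            {
                "protein_id": pid,
                "max_ratio": max_ratio,
                "replicates_present": best_presence,
                "cc_length": cc_len,
                "ratio_ok": ratio_ok,
                "presence_ok": presence_ok,
                "cc_ok": cc_ok,
                "not_excluded": not_excluded,
                "is_candidate": ratio_ok and presence_ok and cc_ok and not_excluded,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")
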