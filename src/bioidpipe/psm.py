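"""Peptide-spectrum-match filtering, parsimonious protein inference, and FDR.

A search engine produces one row per candidate peptide-spectrum match (PSM)
carrying SEQUEST-style scores: the cross-correlation ``xcorr``, the
normalized score gap to the next-best peptide ``deltcn``, and the
preliminary-score rank ``sp_rank``.  The filter cascade keeps a PSM only if
the peptide is at least seven residues long, fully tryptic, and the scores
clear charge-dependent thresholds (all boundaries inclusive).  Retained PSMs
are rolled up into protein-level evidence: a protein needs two distinct
peptides, or one peptide observed in two independent spectra, and proteins
whose peptide set is a strict subset of another's are removed.

Decoy ("shuffled") database entries flow through filtering and inference
exactly like targets, so the two false-discovery-rate statistics —
spectral FDR = 2*shuffled/total*100 and protein FDR = shuffled/total*100 —
are meaningful on the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a PSM table must carry, one row per peptide-spectrum match.
PSM_COLUMNS = (
    "spectrum_id",
    "charge",
    "peptide",
    "flank_n",
    "flank_c",
    "xcorr",
    "deltcn",
    "sp_rank",
    "protein_ids",  # semicolon-joined protein identifiers
)

#: Flank marker used for a protein terminus (no preceding/following residue).
TERMINUS = "-"

DEFAULT_DECOY_PREFIX = "shuffled_"


@dataclass(frozen=True)
class FilterThresholds:
    """Score thresholds of the PSM filter cascade; all inclusive."""

    min_peptide_length: int = 7
    min_deltcn: float = 0.08
    min_xcorr_by_charge: dict = field(
        default_factory=lambda: {1: 1.8, 2: 2.5, 3: 3.5}
    )
    max_sp_rank: int = 10
    require_fully_tryptic: bool = True
    #: optional rule suppressing cleavage before proline; off by default.
    proline_suppression: bool = False

    def min_xcorr(self, charge: int) -> float:
        """Charge-specific XCorr floor; charges above the largest key share
        the top threshold (triply-charged and up)."""
        if charge in self.min_xcorr_by_charge:
            return self.min_xcorr_by_charge[charge]
        return self.min_xcorr_by_charge[max(self.min_xcorr_by_charge)]


@dataclass
class ProteinEvidence:
    """Retained-peptide evidence for one protein after inference.

    ``group`` lists proteins whose retained-peptide sets were identical;
    such proteins are indistinguishable on the evidence and are reported
    together under a canonical joint identifier.
    """

    protein_id: str
    is_decoy: bool
    peptide_counts: dict  # peptide -> number of independent spectra
    group: tuple = ()

    @property
    def peptides(self) -> frozenset:
        return frozenset(self.peptide_counts)

    @property
    def total_spectral_count(self) -> int:
        return sum(self.peptide_counts.values())

    @property
    def group_id(self) -> str:
        members = self.group if self.group else (self.protein_id,)
        return ";".join(sorted(members))


def is_fully_tryptic(
    peptide: str, flank_n: str, flank_c: str, proline_suppression: bool = False
) -> bool:
    """True if both peptide termini are consistent with trypsin cleavage.

    The N-terminal side must follow a K/R (or be the protein N-terminus,
    flank ``-``) and the peptide must end in K/R (or sit at the protein
    C-terminus).  With ``proline_suppression`` a cleavage site directly
    followed by proline is disallowed.
    """
    n_ok = flank_n in ("K", "R", TERMINUS)
    if proline_suppression and flank_n in ("K", "R") and peptide[:1] == "P":
        n_ok = False
    c_ok = peptide[-1:] in ("K", "R") or flank_c == TERMINUS
    if proline_suppression and peptide[-1:] in ("K", "R") and flank_c == "P":
        c_ok = flank_c == TERMINUS
    return n_ok and c_ok


def filter_psms(
    psms: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    return_reasons: bool = False,
):
    """Apply the score-filter cascade to a PSM table.

    Rows with a missing score or a non-positive charge are rejected (with a
    logged reason), never raised on.  Returns the retained sub-table; with
    ``return_reasons=True`` also a Series giving the first failed criterion
    per rejected row.
    """
    thresholds = thresholds or FilterThresholds()
    reasons = pd.Series("", index=psms.index, dtype=object)

    def mark(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    charge = pd.to_numeric(psms["charge"], errors="coerce")
    xcorr = pd.to_numeric(psms["xcorr"], errors="coerce")
    deltcn = pd.to_numeric(psms["deltcn"], errors="coerce")
    sp_rank = pd.to_numeric(psms["sp_rank"], errors="coerce")

    mark(charge.isna() | (charge < 1), "bad_charge")
    mark(xcorr.isna() | deltcn.isna() | sp_rank.isna(), "missing_score")

    peptide = psms["peptide"].astype(str)
    mark(peptide.str.len() < thresholds.min_peptide_length, "short_peptide")

    if thresholds.require_fully_tryptic:
        tryptic = pd.Series(
            [
                is_fully_tryptic(p, n, c, thresholds.proline_suppression)
                for p, n, c in zip(peptide, psms["flank_n"], psms["flank_c"])
            ],
            index=psms.index,
        )
        mark(~tryptic, "not_fully_tryptic")

    mark(deltcn < thresholds.min_deltcn, "low_deltcn")
    xcorr_floor = charge.map(
        lambda z: thresholds.min_xcorr(int(z)) if pd.notna(z) and z >= 1 else float("inf")
    )
    mark(xcorr < xcorr_floor, "low_xcorr")
    mark(sp_rank > thresholds.max_sp_rank, "high_sp_rank")

    rejected = reasons != ""
    if rejected.any():
        for reason, count in reasons[rejected].value_counts().items():
            logger.info("rejected %d PSMs: %s", count, reason)

    retained = psms.loc[~rejected]
    if return_reasons:
        return retained, reasons[rejected]
    return retained


def split_protein_ids(cell) -> list:
    """Protein ids of one PSM row (semicolon-joined string or iterable)."""
    if isinstance(cell, str):
        return [p for p in cell.split(";") if p]
    return list(cell)


def infer_proteins(
    retained: pd.DataFrame,
    database: dict,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> list[ProteinEvidence]:
    """Roll retained PSMs up to a parsimonious protein list.

    ``database`` maps protein id to anything truthy (typically sequence or
    length); an id not present is a hard error, since it means the PSM table
    and database are out of sync.  A protein is kept if it has at least two
    distinct retained peptides, or one peptide supported by at least two
    independent spectra.  A protein whose peptide set is a strict subset of
    another kept protein's set is then removed; proteins with identical sets
    are kept and annotated as a group.
    """
    per_protein: dict[str, dict[str, int]] = {}
    for _, row in retained.iterrows():
        for pid in split_protein_ids(row["protein_ids"]):
            if pid not in database:
                raise KeyError(f"protein id {pid!r} not in database")
            per_protein.setdefault(pid, {})
            per_protein[pid][row["peptide"]] = (
                per_protein[pid].get(row["peptide"], 0) + 1
            )

    evidences = [
        ProteinEvidence(
            protein_id=pid,
            is_decoy=pid.startswith(decoy_prefix),
            peptide_counts=counts,
        )
        for pid, counts in per_protein.items()
        if len(counts) >= 2 or sum(counts.values()) >= 2
    ]
    return remove_subset_proteins(evidences)


def remove_subset_proteins(
    evidences: list[ProteinEvidence],
) -> list[ProteinEvidence]:
    """Drop proteins whose peptide set is a strict subset of another's.

    Equal peptide sets are all retained, each annotated with the full group
    of ids sharing that set.  Idempotent.
    """
    kept = []
    by_set: dict[frozenset, list[str]] = {}
    for ev in evidences:
        by_set.setdefault(ev.peptides, []).append(ev.protein_id)
    for ev in evidences:
        strict_superset = any(
            ev.peptides < other for other in by_set if ev.peptides < other
        )
        if strict_superset:
            continue
        members = by_set[ev.peptides]
        ev.group = tuple(sorted(members)) if len(members) > 1 else (ev.protein_id,)
        kept.append(ev)
    return kept


def spectral_fdr(shuffled_spectral_counts: int, total_spectral_counts: int) -> float:
    """Spectral-level false discovery rate in percent: 2*shuffled/total*100.

    The factor 2 reflects that a decoy match implies an equally likely
    unseen false target match.
    """
    if total_spectral_counts <= 0:
        raise ValueError("total spectral counts must be positive")
    if not 0 <= shuffled_spectral_counts <= total_spectral_counts:
        raise ValueError("shuffled counts must lie in [0, total]")
    return 2.0 * shuffled_spectral_counts / total_spectral_counts * 100.0


def protein_fdr(shuffled_protein_count: int, total_protein_count: int) -> float:
    """Protein-level false discovery rate in percent: shuffled/total*100."""
    if total_protein_count <= 0:
        raise ValueError("total protein count must be positive")
    if not 0 <= shuffled_protein_count <= total_protein_count:
        raise ValueError("shuffled count must lie in [0, total]")
    return shuffled_protein_count / total_protein_count * 100.0
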