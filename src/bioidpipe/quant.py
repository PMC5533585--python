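"""Spectral-count quantification: shared-count distribution and dNSAF.

The distributed Normalized Spectral Abundance Factor (dNSAF) is a label-free
relative abundance estimate built from spectral counts.  Spectra from
peptides unique to one protein (uSpC) are credited directly; spectra from
peptides shared between proteins (sSpC) are apportioned to each parent in
proportion to its unique-spectrum evidence, giving distributed counts dSpC.
The length-normalized abundance dSAF_k = (uSpC_k + dSpC_k) / L_k is then
normalized across detected proteins so each replicate's dNSAF vector sums
to one.

Also houses the densitometry helper used to express what fraction of a
tagged subunit is incorporated into its parent complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Per-replicate spectral counts with shared-peptide structure.

    ``unique``: proteins x replicates integer uSpC.
    ``shared``: one row per shared peptide; a ``parents`` column holding a
    tuple of protein ids (always >= 2) plus the same replicate columns with
    that peptide's spectral counts.
    ``lengths``: protein lengths in amino acids (> 0).
    ``decoy``: boolean flag per protein (shuffled-database entries).
    """

    unique: pd.DataFrame
    shared: pd.DataFrame
    lengths: pd.Series
    decoy: pd.Series = None

    def __post_init__(self):
        if self.decoy is None:
            self.decoy = pd.Series(False, index=self.unique.index)
        if (self.lengths.reindex(self.unique.index) <= 0).any():
            raise ValueError("protein lengths must be positive")
        for parents in self.shared["parents"] if len(self.shared) else []:
            if len(parents) < 2:
                raise ValueError("shared peptides need >= 2 parent proteins")

    @property
    def replicates(self) -> list:
        return list(self.unique.columns)

    def total_counts(self, replicate) -> pd.Series:
        """uSpC plus distributed shared counts (dSpC) per protein."""
        return self.unique[replicate].astype(float) + distribute_shared_counts(
            self, replicate
        )


def empty_shared(replicates) -> pd.DataFrame:
    """A shared-peptide table with no rows, for experiments without
    shared-peptide structure."""
    return pd.DataFrame(columns=["parents", *replicates])


def distribute_shared_counts(counts: CountMatrix, replicate) -> pd.Series:
    """Distributed shared spectral counts dSpC per protein for one replicate.

    For each shared peptide j with parents P(j) and sSpC_j spectra, protein
    k in P(j) receives sSpC_j * uSpC_k / sum_{i in P(j)} uSpC_i.  When every
    parent has zero unique counts the proportional rule is 0/0 and the
    spectra are split equally, which keeps the column total conserved:
    sum_k dSpC_k equals the total number of shared spectra exactly.
    """
    if replicate not in counts.unique.columns:
        raise KeyError(f"no replicate {replicate!r}")
    dspc = pd.Series(0.0, index=counts.unique.index)
    uspc = counts.unique[replicate]
    for _, row in counts.shared.iterrows():
        sspc = row[replicate]
        if sspc == 0:
            continue
        parents = list(row["parents"])
        weights = uspc[parents].astype(float)
        denom = weights.sum()
        if denom == 0:
            share = pd.Series(sspc / len(parents), index=parents)
        else:
            share = sspc * weights / denom
        dspc[parents] += share
    return dspc


def compute_dnsaf(
    counts: CountMatrix, replicate, include_decoys: bool = False
) -> pd.Series:
    """dNSAF vector for one replicate.

    dSAF_k = (uSpC_k + dSpC_k) / L_k, normalized to sum to one over the
    proteins in the denominator.  Decoy proteins are excluded from the
    normalization by default, since downstream enrichment comparisons are
    target-only; pass ``include_decoys=True`` to normalize over everything.
    Proteins with zero total counts get dNSAF 0.  An all-zero replicate
    returns an all-zero vector.
    """
    dspc = distribute_shared_counts(counts, replicate)
    total = counts.unique[replicate].astype(float) + dspc
    if not include_decoys:
        total = total[~counts.decoy.reindex(total.index, fill_value=False)]
    dsaf = total / counts.lengths.reindex(total.index)
    denom = dsaf.sum()
    if denom == 0:
        return pd.Series(0.0, index=total.index)
    return dsaf / denom


def dnsaf_matrix(counts: CountMatrix, include_decoys: bool = False) -> pd.DataFrame:
    """dNSAF for every replicate, proteins x replicates."""
    return pd.DataFrame(
        {
            rep: compute_dnsaf(counts, rep, include_decoys=include_decoys)
            for rep in counts.replicates
        }
    )


def dnsaf_from_count_table(
    unique: pd.DataFrame, lengths: pd.Series, decoy: pd.Series | None = None
) -> pd.DataFrame:
    """Vectorized dNSAF for experiments without shared-peptide structure.

    Equivalent to :func:`dnsaf_matrix` on a CountMatrix with an empty shared
    table, but computed with one matrix expression; used for large simulated
    screens.
    """
    if decoy is not None:
        unique = unique.loc[~decoy]
        lengths = lengths.loc[unique.index]
    saf = unique.astype(float).div(lengths, axis=0)
    col_sums = saf.sum(axis=0)
    out = saf.div(col_sums.where(col_sums > 0, np.nan), axis=1)
    return out.fillna(0.0)


@dataclass(frozen=True)
class DensitometryPair:
    """Band intensities of the free and complex-incorporated species."""

    intensity_free: float
    intensity_incorporated: float

    def __post_init__(self):
        if self.intensity_free < 0 or self.intensity_incorporated < 0:
            raise ValueError("intensities must be non-negative")
        if self.intensity_free == 0 and self.intensity_incorporated == 0:
            raise ValueError("at least one intensity must be non-zero")


def fraction_incorporated(pair: DensitometryPair) -> float:
    """Percent incorporation: 100 * incorporated / (free + incorporated)."""
    total = pair.intensity_free + pair.intensity_incorporated
    return 100.0 * pair.intensity_incorporated / total
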