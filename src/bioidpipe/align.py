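"""Pairwise global protein alignment with affine gaps and free end gaps.

Percent identity and similarity between activator paralogs are computed
from a Needleman-Wunsch global alignment under BLOSUM62 with affine gap
penalties (default open 10, extend 0.5, applying open to the first gapped
position and extend to each subsequent one) and unpenalized end gaps.
Identity counts columns with identical residues; similarity counts columns
whose substitution score is positive; both are expressed against the full
alignment length including gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentParams:
    """Aligner parameterization (the cited tool's documented defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    free_end_gaps: bool = True

    def __post_init__(self):
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("need gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/similarity summary of one global pairwise alignment."""

    id_a: str
    id_b: str
    percent_identity: float
    percent_similarity: float
    alignment_length: int
    score: float


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    for pos, residue in enumerate(seq, start=1):
        if residue not in VALID_RESIDUES:
            raise ValueError(
                f"illegal residue {residue!r} at position {pos} of {name}"
            )


def make_aligner(params: AlignmentParams | None = None) -> Align.PairwiseAligner:
    """A configured global pairwise aligner."""
    params = params or AlignmentParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams | None = None,
    id_a: str = "A",
    id_b: str = "B",
) -> AlignmentResult:
    """Globally align two protein sequences and report identity/similarity.

    When several alignments are co-optimal the first one enumerated is
    used; the score is unique, identity/similarity can in principle differ
    between co-optimal tracebacks.
    """
    params = params or AlignmentParams()
    _check_sequence(seq_a, id_a)
    _check_sequence(seq_b, id_b)
    aligner = make_aligner(params)
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix

    length = len(gapped_a)
    identical = 0
    similar = 0
    for ra, rb in zip(gapped_a, gapped_b):
        if ra == "-" or rb == "-":
            continue
        if ra == rb:
            identical += 1
        if matrix[ra, rb] > 0:
            similar += 1
    return AlignmentResult(
        id_a=id_a,
        id_b=id_b,
        percent_identity=100.0 * identical / length,
        percent_similarity=100.0 * similar / length,
        alignment_length=length,
        score=float(alignment.score),
    )
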