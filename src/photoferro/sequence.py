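"""Pairwise global sequence alignment and conservation of residue sets.

Two HiPIP paralogues can share a fold at modest sequence identity; whether
one can substitute the other functionally depends on conservation of the
specific residues forming the partner interface.  This module wraps global
Needleman-Wunsch alignment with affine gap costs (BLOSUM62 by default,
via Bio.Align.PairwiseAligner), percent identity under two denominators,
and the partition of an interface residue set into conserved / substituted
/ unaligned positions.

Gap cost convention: a gap of length L costs gap_open + gap_extend * L.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignmentResult:
    """A global pairwise alignment.

    ``aligned_columns`` lists (pos_a, pos_b) with 1-based sequence positions
    or None for a gap; no column has two gaps and positions are strictly
    increasing within each sequence.
    """

    seq_a: str
    seq_b: str
    aligned_columns: list[tuple[int | None, int | None]]
    score: float

    @property
    def identity(self) -> float:
        return percent_identity(self, convention="aligned_pairs")


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    for i, c in enumerate(seq):
        if c.upper() not in STANDARD_AA:
            raise ValueError(
                f"sequence {name}: non-standard residue {c!r} at position {i + 1}")


def nw_align(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
             gap_open: float = 10.0, gap_extend: float = 0.5) -> AlignmentResult:
    """Optimal global alignment with affine gap costs.

    ``gap_open``/``gap_extend`` are positive penalties; a gap of length L
    costs gap_open + L*gap_extend.  The optimal score is unique; the
    reported traceback is the aligner's first optimal alignment, which is
    deterministic for a fixed library version.
    """
    _check_sequence(seq_a, "A")
    _check_sequence(seq_b, "B")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    columns: list[tuple[int | None, int | None]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        pa = pb = None
        if ca != "-":
            ia += 1
            pa = ia
        if cb != "-":
            ib += 1
            pb = ib
        columns.append((pa, pb))
    return AlignmentResult(seq_a=seq_a, seq_b=seq_b,
                           aligned_columns=columns, score=float(aln.score))


def percent_identity(alignment: AlignmentResult,
                     convention: str = "aligned_pairs") -> float:
    """Fraction of identical residues.

    ``aligned_pairs`` divides by the number of gapless columns (the
    default); ``alignment_length`` divides by all columns including gaps.
    """
    if convention not in ("aligned_pairs", "alignment_length"):
        raise ValueError(f"unknown convention {convention!r}")
    cols = alignment.aligned_columns
    if not cols:
        raise ValueError("empty alignment")
    pairs = [(pa, pb) for pa, pb in cols if pa is not None and pb is not None]
    ident = sum(1 for pa, pb in pairs
                if alignment.seq_a[pa - 1] == alignment.seq_b[pb - 1])
    denom = len(pairs) if convention == "aligned_pairs" else len(cols)
    if denom == 0:
        raise ValueError("alignment has no aligned pairs")
    return ident / denom


@dataclass
class ConservationPartition:
    conserved: set[int]
    substituted: set[int]
    unaligned: set[int]

    @property
    def not_conserved(self) -> set[int]:
        return self.substituted | self.unaligned


def conservation_of_set(alignment: AlignmentResult,
                        residue_set_a) -> ConservationPartition:
    """Label each sequence-A residue of a set by its fate in the alignment.

    conserved: aligned to the identical residue type in B;
    substituted: aligned to a different residue; unaligned: opposite a gap.
    """
    positions = set(int(r) for r in residue_set_a)
    n_a = len(alignment.seq_a)
    bad = [r for r in positions if not (1 <= r <= n_a)]
    if bad:
        raise ValueError(f"residues {sorted(bad)} outside sequence A (1-{n_a})")
    partner = {pa: pb for pa, pb in alignment.aligned_columns if pa is not None}
    conserved, substituted, unaligned = set(), set(), set()
    for r in positions:
        pb = partner.get(r)
        if pb is None:
            unaligned.add(r)
        elif alignment.seq_a[r - 1] == alignment.seq_b[pb - 1]:
            conserved.add(r)
        else:
            substituted.add(r)
    return ConservationPartition(conserved=conserved, substituted=substituted,
                                 unaligned=unaligned)
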