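"""Rab6 subfamily sequence analysis.

Pairwise global (Needleman-Wunsch, affine-gap) protein alignment,
percent identity/conservation, and classification of Rab6 isoforms into
the Rab6A-like and Rab6B-like subfamilies from the diagnostic residues
at positions 63, 106 and 139 (1-based positions in the ungapped Rab6A
reference).

The subfamily call uses positions 106 and 139 only: threonine-106 plus
serine-139 is Rab6A-like, serine-106 plus threonine-139 is Rab6B-like,
anything else (including a gap at either column) is ambiguous.  Position
63 (valine vs isoleucine) is reported for inspection but does not enter
the call, because it partitions the family differently from the 106/139
pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinSeq",
    "AlignmentResult",
    "DiagnosticProfile",
    "read_fasta",
    "write_fasta",
    "global_align",
    "conservation_percent",
    "diagnostic_profile",
    "DIAGNOSTIC_POSITIONS",
    "SIMILARITY_GROUPS",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

# Strong-similarity groups used for the "conserved" (identical + similar)
# count: conservative substitutions within a group are scored as similar.
SIMILARITY_GROUPS = ("ST", "DE", "KR", "NQ", "ILVM", "FYW", "AG")

_GROUP_OF = {aa: grp for grp in SIMILARITY_GROUPS for aa in grp}

DIAGNOSTIC_POSITIONS = (63, 106, 139)

GAP = "-"


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence with an identifier (accession or name)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper().replace(" ", "")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: invalid residues {sorted(bad)} "
                "(expected the 20 standard amino acids plus X)")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentResult:
    """A pairwise global alignment and its derived statistics."""

    seq_a: ProteinSeq
    seq_b: ProteinSeq
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_conservation: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if self.aligned_a.replace(GAP, "") != self.seq_a.residues:
            raise ValueError("ungapping aligned_a does not recover seq_a")
        if self.aligned_b.replace(GAP, "") != self.seq_b.residues:
            raise ValueError("ungapping aligned_b does not recover seq_b")

    def column_of_a_position(self, pos: int) -> int:
        """Alignment column (0-based) holding 1-based position ``pos`` of
        the ungapped sequence A."""
        if not 1 <= pos <= len(self.seq_a):
            raise IndexError(f"position {pos} outside sequence A "
                             f"(length {len(self.seq_a)})")
        count = 0
        for col, ch in enumerate(self.aligned_a):
            if ch != GAP:
                count += 1
                if count == pos:
                    return col
        raise AssertionError("unreachable: position not found")

    def residue_of_b_at_a_position(self, pos: int) -> str:
        """Residue of sequence B aligned to position ``pos`` of A ('-' if
        B has a gap there)."""
        return self.aligned_b[self.column_of_a_position(pos)]


@dataclass(frozen=True)
class DiagnosticProfile:
    """Residues at the diagnostic positions and the subfamily call."""

    query_id: str
    residue_63: str
    residue_106: str
    residue_139: str
    subfamily: str  # "Rab6A-like" | "Rab6B-like" | "ambiguous"


def read_fasta(path) -> list[ProteinSeq]:
    """Read protein sequences from a FASTA file.

    Wrapped sequence lines are concatenated, whitespace is stripped and
    case is normalized to upper.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSeq(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(path, seqs: list[ProteinSeq], width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def _make_aligner(matrix: Optional[str], match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: ProteinSeq,
    b: ProteinSeq,
    matrix: Optional[str] = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gap penalties.

    Defaults to BLOSUM62 with gap open 10 / extend 0.5.  Pass
    ``matrix=None`` to use simple match/mismatch scores (useful for
    validation against enumeration).  Among co-optimal alignments the
    aligner's first reported alignment is taken, which is deterministic
    for fixed inputs.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ident = _percent(sa, sb, similar=False)
    cons = _percent(sa, sb, similar=True)
    return AlignmentResult(seq_a=a, seq_b=b, aligned_a=sa, aligned_b=sb,
                           score=float(aln.score), percent_identity=ident,
                           percent_conservation=cons)


def _percent(sa: str, sb: str, similar: bool) -> float:
    n_cols = 0
    n_hit = 0
    for x, y in zip(sa, sb):
        if x == GAP or y == GAP:
            continue
        n_cols += 1
        if x == y:
            n_hit += 1
        elif similar and _GROUP_OF.get(x) is not None and _GROUP_OF.get(x) == _GROUP_OF.get(y):
            n_hit += 1
    if n_cols == 0:
        return float("nan")
    return 100.0 * n_hit / n_cols


def conservation_percent(aln: AlignmentResult, mode: str = "identity_plus_similar") -> float:
    """Percent of ungapped alignment columns that are conserved.

    ``mode="identity"`` counts identical columns only;
    ``mode="identity_plus_similar"`` additionally counts substitutions
    within a strong-similarity group.  The denominator is the number of
    columns with no gap in either sequence.  Returns NaN if there are no
    ungapped columns.
    """
    if mode == "identity":
        return _percent(aln.aligned_a, aln.aligned_b, similar=False)
    if mode == "identity_plus_similar":
        return _percent(aln.aligned_a, aln.aligned_b, similar=True)
    raise ValueError(f"unknown mode {mode!r}")


def diagnostic_profile(aln_vs_rab6a: AlignmentResult) -> DiagnosticProfile:
    """Classify the query (sequence B) from its residues at the Rab6A
    diagnostic positions.

    The alignment's sequence A must be the Rab6A reference; the query's
    residues at the columns aligned to Rab6A positions 63, 106 and 139
    are extracted, and the subfamily is called from the 106/139 pair:
    (T, S) is Rab6A-like, (S, T) is Rab6B-like, anything else (including
    a gap) is ambiguous.
    """
    if len(aln_vs_rab6a.seq_a) < max(DIAGNOSTIC_POSITIONS):
        raise ValueError(
            f"reference sequence shorter than position {max(DIAGNOSTIC_POSITIONS)}")
    r63, r106, r139 = (aln_vs_rab6a.residue_of_b_at_a_position(p)
                       for p in DIAGNOSTIC_POSITIONS)
    if (r106, r139) == ("T", "S"):
        call = "Rab6A-like"
    elif (r106, r139) == ("S", "T"):
        call = "Rab6B-like"
    else:
        call = "ambiguous"
    return DiagnosticProfile(query_id=aln_vs_rab6a.seq_b.id,
                             residue_63=r63, residue_106=r106,
                             residue_139=r139, subfamily=call)
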