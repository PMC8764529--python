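"""Diagnostic-residue screening of enzyme homologs from multiple alignments.

The substrate tolerance of CofC-type guanylyltransferases toward
3-phospho-D-glycerate tracks a single alignment position: the column
homologous to the reference serine (S162 in the *M. rhizoxinica* enzyme).
Homologs carrying serine or threonine there are called tolerant, anything
else non-tolerant, and a gap indeterminate.  The module maps a reference
residue number to its alignment column, applies the rule, and provides
Needleman--Wunsch global alignment plus percent identity for pairwise
sequence comparison.

Alignments are consumed, never computed here (aligned FASTA or Clustal);
columns and residue numbers are 1-based.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass

from Bio import SeqIO

from .errors import SelectorError, ValidationError

__all__ = [
    "SequenceRecord",
    "AlignedRow",
    "MultipleAlignment",
    "ColumnMap",
    "SpecificityCall",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "global_align",
    "percent_identity",
    "map_residue_to_column",
    "classify_diagnostic",
    "summarize_calls",
]

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")
DEFAULT_TOLERATED = frozenset({"S", "T"})


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped, uppercase protein sequence."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRow:
    """One gapped row of a multiple alignment."""

    id: str
    description: str
    residues: str    # uppercase, '-' gaps

    def degapped(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.description,
                              self.residues.replace(GAP, ""))


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows; columns are 1-based."""

    rows: list[AlignedRow]

    def __post_init__(self):
        if not self.rows:
            raise ValidationError("alignment has no rows")
        n = len(self.rows[0].residues)
        for r in self.rows:
            if len(r.residues) != n:
                raise ValidationError(
                    f"row {r.id!r} has length {len(r.residues)}, expected {n}")

    @property
    def length(self) -> int:
        return len(self.rows[0].residues)

    def row(self, row_id: str) -> AlignedRow:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise SelectorError(f"row {row_id!r} not found in alignment")


@dataclass(frozen=True)
class ColumnMap:
    reference_id: str
    residue_number: int     # 1-based position in the ungapped reference
    column: int             # 1-based alignment column
    reference_residue: str


@dataclass(frozen=True)
class SpecificityCall:
    sequence_id: str
    column_residue: str
    call: str               # tolerant | non_tolerant | indeterminate


# ---------------------------------------------------------------------------
# FASTA / alignment I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def _norm(seq: str) -> str:
    return str(seq).upper().replace(".", GAP)


def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text into ungapped sequence records.

    Record ids are the first whitespace-delimited header token.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = _norm(rec.seq)
        if GAP in seq:
            raise ValidationError(f"record {rec.id!r} contains gap characters; "
                                  "use read_alignment for aligned input")
        records.append(SequenceRecord(rec.id, rec.description, seq))
    if not records:
        raise ValidationError("no FASTA records found")
    return records


def write_fasta(records, width: int = 60) -> str:
    """Serialize records (or aligned rows) as FASTA, wrapped at ``width``."""
    out = []
    for r in records:
        header = r.description if r.description else r.id
        if not header.startswith(r.id):
            header = f"{r.id} {header}"
        out.append(f">{header}")
        seq = r.residues
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def read_alignment(text: str) -> MultipleAlignment:
    """Read an aligned-FASTA or Clustal alignment.

    '.' gaps are normalized to '-'; ragged input raises an error naming
    the offending row.
    """
    stripped = text.lstrip()
    if stripped.upper().startswith("CLUSTAL"):
        from Bio import AlignIO
        aln = AlignIO.read(io.StringIO(text), "clustal")
        rows = [AlignedRow(r.id, r.description or r.id, _norm(r.seq)) for r in aln]
    else:
        rows = [AlignedRow(rec.id, rec.description, _norm(rec.seq))
                for rec in SeqIO.parse(io.StringIO(text), "fasta")]
    if not rows:
        raise ValidationError("no alignment rows found")
    n = len(rows[0].residues)
    for r in rows:
        if len(r.residues) != n:
            raise ValidationError(
                f"alignment row {r.id!r} has length {len(r.residues)}, "
                f"expected {n}")
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# pairwise global alignment and identity
# ---------------------------------------------------------------------------

def global_align(a: SequenceRecord, b: SequenceRecord,
                 match: float = 1.0, mismatch: float = 0.0,
                 gap: float = -1.0) -> tuple[str, str, float]:
    """Needleman--Wunsch optimal global alignment under linear gap scoring.

    Ties are broken deterministically: diagonal, then up (gap in ``b``),
    then left (gap in ``a``).  Returns the two gapped rows and the score.
    """
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    NEG = float("-inf")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]   # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i][0] = i * gap
        ptr[i][0] = 1
    for j in range(1, m + 1):
        score[0][j] = j * gap
        ptr[0][j] = 2
    for i in range(1, n + 1):
        si = sa[i - 1]
        row, prev = score[i], score[i - 1]
        prow = ptr[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if si == sb[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            best, p = diag, 0
            if up > best:
                best, p = up, 1
            if left > best:
                best, p = left, 2
            row[j] = best
            prow[j] = p
    # traceback
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i][j]
        if p == 0 and i > 0 and j > 0:
            ra.append(sa[i - 1])
            rb.append(sb[j - 1])
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            ra.append(sa[i - 1])
            rb.append(GAP)
            i -= 1
        else:
            ra.append(GAP)
            rb.append(sb[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), score[n][m]


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity of two gapped rows.

    Denominator: columns where at least one row carries a residue;
    numerator: columns where both carry the same residue.  Symmetric.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned rows differ in length")
    num = den = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x == GAP and y == GAP:
            continue
        den += 1
        if x == y and x != GAP:
            num += 1
    if den == 0:
        raise ValidationError("identity undefined: no residue-bearing columns")
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# residue-to-column mapping and the diagnostic screen
# ---------------------------------------------------------------------------

def map_residue_to_column(aln: MultipleAlignment, reference_id: str,
                          residue_number: int) -> ColumnMap:
    """Alignment column of the ``residue_number``-th reference residue."""
    row = aln.row(reference_id)
    if residue_number < 1:
        raise ValidationError("residue_number is 1-based and must be >= 1")
    count = 0
    for col, ch in enumerate(row.residues, start=1):
        if ch != GAP:
            count += 1
            if count == residue_number:
                return ColumnMap(reference_id, residue_number, col, ch)
    raise ValidationError(
        f"residue {residue_number} exceeds the {count} residues of "
        f"{reference_id!r}")


def classify_diagnostic(aln: MultipleAlignment, column: int,
                        tolerated: frozenset[str] = DEFAULT_TOLERATED,
                        ) -> list[SpecificityCall]:
    """Classify every row by the residue in the diagnostic column.

    Residues in ``tolerated`` (default {S, T}) call the homolog tolerant
    of the bulkier 3-PG substrate, a gap is indeterminate, anything else
    non-tolerant.
    """
    if not (1 <= column <= aln.length):
        raise ValidationError(
            f"column {column} outside alignment of length {aln.length}")
    calls = []
    for r in aln.rows:
        ch = r.residues[column - 1]
        if ch == GAP:
            call = "indeterminate"
        elif ch in tolerated:
            call = "tolerant"
        else:
            call = "non_tolerant"
        calls.append(SpecificityCall(r.id, ch, call))
    return calls


def summarize_calls(calls) -> dict[str, int]:
    """Counts per call category, all three keys always present."""
    c = Counter(call.call for call in calls)
    return {k: c.get(k, 0) for k in ("tolerant", "non_tolerant", "indeterminate")}
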