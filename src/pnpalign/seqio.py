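"""Core sequence/alignment types and FASTA/CLUSTAL I/O.

The three domain types are deliberately thin:

* :class:`Sequence` — a named, ungapped, uppercase residue string.
* :class:`Family` — an ordered collection of at least two sequences with
  unique ids; the unit of input for the aligner.
* :class:`Alignment` — a gapped matrix over a family; every row degaps back
  to its input sequence and no column is all gaps.

Parsing is delegated to Biopython (``Bio.SeqIO`` / ``Bio.AlignIO``); this
module adds the validation the pipeline relies on.  CLUSTAL output is
written here directly so blocks wrap at the conventional 60 columns.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO

from .errors import InputError

GAP = "-"
#: gap characters tolerated on input; normalized to ``GAP``
INPUT_GAPS = "-."

ALIGNED_FASTA = "fasta"
CLUSTAL = "clustal"
FORMATS = (ALIGNED_FASTA, CLUSTAL)


@dataclass(frozen=True)
class Sequence:
    """A named residue string with no gap characters."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) & set(INPUT_GAPS)
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains gap character(s) {sorted(bad)}; "
                "unaligned input must be ungapped"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Family:
    """An ordered family of >= 2 sequences with unique ids."""

    sequences: tuple[Sequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.sequences) < 2:
            raise InputError("at least two sequences required")
        ids = [s.id for s in self.sequences]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise InputError(f"duplicate sequence id(s): {sorted(dupes)}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, i: int) -> Sequence:
        return self.sequences[i]

    def __iter__(self):
        return iter(self.sequences)


@dataclass
class Alignment:
    """A gapped matrix: list of ``(id, gapped row)`` of equal length."""

    rows: list[tuple[str, str]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no rows")
        self.rows = [(rid, row.upper().replace(".", GAP)) for rid, row in self.rows]
        lengths = {len(row) for _, row in self.rows}
        if len(lengths) > 1:
            a, b = sorted(lengths)[:2]
            raise InputError(f"unequal row lengths {a} vs {b}")
        for col in range(self.ncols):
            if all(row[col] == GAP for _, row in self.rows):
                raise InputError(f"column {col + 1} consists entirely of gaps")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def degapped(self) -> list[tuple[str, str]]:
        """``(id, ungapped residues)`` per row, in row order."""
        return [(rid, row.replace(GAP, "")) for rid, row in self.rows]

    def __eq__(self, other) -> bool:  # metadata is not part of identity
        return isinstance(other, Alignment) and self.rows == other.rows


def _strip_all_gap_columns(rows: list[tuple[str, str]]) -> list[tuple[str, str]]:
    if not rows:
        return rows
    keep = [
        c for c in range(len(rows[0][1])) if any(row[c] != GAP for _, row in rows)
    ]
    return [(rid, "".join(row[c] for c in keep)) for rid, row in rows]


def read_fasta(path: str | os.PathLike) -> Family:
    """Read an unaligned FASTA file into a :class:`Family`.

    Input order is preserved and residues are uppercased.  Gap characters,
    duplicate ids, fewer than two records or malformed headers are errors.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise InputError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise InputError(f"{path}: empty FASTA file")
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if len(records) < 2:
        raise InputError("at least two sequences required")
    return Family(tuple(Sequence(r.id, str(r.seq)) for r in records))


def read_alignment(path: str | os.PathLike, fmt: str | None = None) -> Alignment:
    """Read an aligned FASTA or CLUSTAL file.

    The format is sniffed from the first line when ``fmt`` is None.  '.' gaps
    are normalized to '-', and all-gap columns are dropped so the Alignment
    invariants always hold.  Ragged rows are reported with both lengths.
    """
    path = os.fspath(path)
    if fmt is None:
        with open(path) as handle:
            first = handle.readline()
        fmt = CLUSTAL if first.upper().startswith("CLUSTAL") else ALIGNED_FASTA
    if fmt == CLUSTAL:
        with open(path) as handle:
            # '!' lines are this package's metadata comments, not sequence rows
            text = "".join(l for l in handle if not l.startswith("!"))
        try:
            msa = AlignIO.read(io.StringIO(text), "clustal")
        except ValueError as exc:
            raise InputError(f"{path}: cannot parse CLUSTAL: {exc}") from exc
        rows = [(r.id, str(r.seq)) for r in msa]
    elif fmt == ALIGNED_FASTA:
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise InputError(f"{path}: empty or non-FASTA file")
        rows = [(r.id, str(r.seq)) for r in records]
        lengths = sorted({len(r) for _, r in rows})
        if len(lengths) > 1:
            raise InputError(f"unequal row lengths {lengths[0]} vs {lengths[1]}")
    else:
        raise InputError(f"unknown alignment format {fmt!r}")
    rows = [(rid, row.upper().replace(".", GAP)) for rid, row in rows]
    return Alignment(_strip_all_gap_columns(rows))


def write_alignment(
    alignment: Alignment, path: str | os.PathLike, fmt: str = ALIGNED_FASTA
) -> None:
    """Write an alignment as aligned FASTA or CLUSTAL (60-column blocks).

    Round-trip property: ``read_alignment(write_alignment(a)) == a``.
    Pipeline metadata, if present, is emitted as ``!`` comment lines in the
    CLUSTAL header (FASTA has no comment syntax).
    """
    if fmt not in FORMATS:
        raise InputError(f"unknown alignment format {fmt!r}")
    with open(path, "w") as handle:
        write_alignment_handle(alignment, handle, fmt)


def write_alignment_handle(alignment: Alignment, handle, fmt: str) -> None:
    """As :func:`write_alignment`, but to an open text handle."""
    if fmt not in FORMATS:
        raise InputError(f"unknown alignment format {fmt!r}")
    if fmt == ALIGNED_FASTA:
        for rid, row in alignment.rows:
            handle.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                handle.write(row[i : i + 60] + "\n")
    else:
        handle.write("CLUSTAL multiple sequence alignment\n")
        for key, val in alignment.metadata.items():
            handle.write(f"! {key} = {val}\n")
        handle.write("\n")
        width = max(len(rid) for rid in alignment.ids) + 3
        for start in range(0, alignment.ncols, 60):
            for rid, row in alignment.rows:
                handle.write(f"{rid:<{width}}{row[start : start + 60]}\n")
            handle.write("\n")


def family_from_alignment(alignment: Alignment) -> Family:
    """The ungapped family underlying an alignment (row order preserved)."""
    return Family(tuple(Sequence(rid, seq) for rid, seq in alignment.degapped()))


def check_degap_identity(alignment: Alignment, family: Family) -> None:
    """Raise unless degapping ``alignment`` reproduces ``family`` exactly."""
    from .errors import InvariantError

    got = dict(alignment.degapped())
    for seq in family:
        if got.get(seq.id) != seq.residues:
            raise InvariantError(
                f"degapped alignment row for {seq.id!r} does not match its "
                "input sequence"
            )
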