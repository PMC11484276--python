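"""Protein sequence and alignment I/O with sequence-level quality control.

Reads and writes plain and gapped (aligned) FASTA, validates residue
alphabets, and removes sequences carrying ambiguous residue codes — the
first curation step before any phylogenetic interpretation of an ortholog
alignment.

Conventions
-----------
* Unaligned sequences use the 20 canonical amino acids plus the extended
  codes ``B Z X J U O`` and the stop mark ``*``. Gaps (``-``) are rejected
  by the unaligned reader.
* Aligned rows additionally allow ``-`` and the lowercase mask mark ``x``,
  which replaces a residue judged unreliable (e.g. near an indel) while
  preserving column geometry. ``x`` is never legal in unaligned input.
* Residues are uppercased on read; the mask mark is the single exception.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA = "BZXJUO"
STOP = "*"
GAP = "-"
MASK = "x"

#: residue codes legal in an unaligned ProteinSequence
SEQUENCE_ALPHABET = frozenset(CANONICAL_AA + EXTENDED_AA + STOP)
#: additionally legal inside an alignment row
ALIGNMENT_ALPHABET = SEQUENCE_ALPHABET | {GAP, MASK}

#: codes treated as "ambiguous" by default. U (selenocysteine) and O
#: (pyrrolysine) are genuine residues and kept; the set is configurable.
DEFAULT_AMBIGUOUS = frozenset("BZXJ" + STOP)

#: NCBI-style organism annotation: text inside the last square brackets.
DEFAULT_SPECIES_REGEX = r"\[([^\[\]]+)\]"


class FastaError(ValueError):
    """Malformed FASTA input (duplicates, bad characters, ragged rows)."""


@dataclass
class ProteinSequence:
    """One unaligned protein sequence with optional species annotation."""

    id: str
    residues: str
    species: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} is empty")
        if GAP in self.residues:
            raise FastaError(f"sequence {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered, equal-length set of gapped rows with unique ids.

    Rows are stored as (id, gapped string) pairs; degapping a row recovers
    the underlying unaligned sequence (mask marks stand in for single
    residues, so length is conserved).
    """

    def __init__(
        self,
        rows: Sequence[tuple[str, str]],
        descriptions: dict[str, str] | None = None,
    ) -> None:
        if not rows:
            raise FastaError("alignment must contain at least one row")
        ids = [r[0] for r in rows]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise FastaError(f"duplicate id in alignment: {i!r}")
            seen.add(i)
        lengths = {len(r[1]) for r in rows}
        if len(lengths) != 1:
            offending = ", ".join(f"{i}:{len(s)}" for i, s in rows)
            raise FastaError(f"ragged alignment (id:length): {offending}")
        self._ids = ids
        self._seqs = [r[1] for r in rows]
        self._index = {i: k for k, i in enumerate(ids)}
        self.descriptions = dict(descriptions or {})

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def n_rows(self) -> int:
        return len(self._ids)

    @property
    def n_cols(self) -> int:
        return len(self._seqs[0])

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def row(self, key: int | str) -> str:
        if isinstance(key, str):
            key = self._index[key]
        return self._seqs[key]

    def rows(self) -> list[tuple[str, str]]:
        return list(zip(self._ids, self._seqs))

    def column(self, col: int) -> str:
        if not 0 <= col < self.n_cols:
            raise IndexError(f"column {col} out of range [0, {self.n_cols})")
        return "".join(s[col] for s in self._seqs)

    def degap(self, key: int | str) -> str:
        return self.row(key).replace(GAP, "")

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        rows = [(i, "".join(s[c] for c in cols)) for i, s in zip(self._ids, self._seqs)]
        return Alignment(rows, self.descriptions)

    def take_rows(self, ids: Iterable[str]) -> "Alignment":
        return Alignment([(i, self.row(i)) for i in ids], self.descriptions)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self.rows() == other.rows()

    def __repr__(self) -> str:
        return f"Alignment({self.n_rows} rows x {self.n_cols} cols)"


# ---------------------------------------------------------------------------
# FASTA reading / writing
# ---------------------------------------------------------------------------

def parse_species(description: str, regex: str = DEFAULT_SPECIES_REGEX) -> str | None:
    """Extract the species label from a FASTA description (last bracket pair)."""
    hits = re.findall(regex, description)
    return hits[-1] if hits else None


def _records(stream: TextIO | str):
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return SeqIO.parse(stream, "fasta")


def read_fasta(
    stream: TextIO | str,
    species_regex: str = DEFAULT_SPECIES_REGEX,
) -> list[ProteinSequence]:
    """Read unaligned protein FASTA into a list of :class:`ProteinSequence`.

    The id is the first whitespace-delimited header token; the remainder is
    kept as the description. Gap characters and the mask mark are rejected —
    use :func:`read_alignment` for gapped input.
    """
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in _records(stream):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise FastaError(f"empty record: {rec.id!r}")
        residues = raw.upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in SEQUENCE_ALPHABET:
                raise FastaError(
                    f"sequence {rec.id!r}: illegal character {ch!r} at position {pos}"
                )
        desc = rec.description[len(rec.id):].strip()
        out.append(
            ProteinSequence(
                id=rec.id,
                residues=residues,
                species=parse_species(desc, species_regex),
                description=desc,
            )
        )
    return out


def read_alignment(stream: TextIO | str) -> Alignment:
    """Read aligned FASTA (gap ``-``, mask mark ``x`` allowed) into an Alignment."""
    rows: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    for rec in _records(stream):
        raw = str(rec.seq)
        if not raw:
            raise FastaError(f"empty record: {rec.id!r}")
        gapped = "".join(c if c == MASK else c.upper() for c in raw)
        for pos, ch in enumerate(gapped, start=1):
            if ch not in ALIGNMENT_ALPHABET:
                raise FastaError(
                    f"row {rec.id!r}: illegal character {ch!r} at column {pos}"
                )
        rows.append((rec.id, gapped))
        desc = rec.description[len(rec.id):].strip()
        if desc:
            descriptions[rec.id] = desc
    return Alignment(rows, descriptions)


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(seqs: Iterable[ProteinSequence], stream: TextIO) -> None:
    for s in seqs:
        header = f">{s.id} {s.description}".rstrip()
        stream.write(f"{header}\n{_wrap(s.residues)}\n")


def write_alignment(aln: Alignment, stream: TextIO) -> None:
    for seq_id, gapped in aln.rows():
        desc = aln.descriptions.get(seq_id, "")
        header = f">{seq_id} {desc}".rstrip()
        stream.write(f"{header}\n{_wrap(gapped)}\n")


# ---------------------------------------------------------------------------
# Sequence-level QC
# ---------------------------------------------------------------------------

def drop_ambiguous(
    seqs: Sequence[ProteinSequence],
    ambiguous_set: frozenset[str] | set[str] = DEFAULT_AMBIGUOUS,
) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Split sequences into (kept, removed) by presence of ambiguous residues.

    A sequence is removed iff it contains at least one residue from
    ``ambiguous_set``; order is preserved on both sides and each removal is
    logged with the offending residue.
    """
    ambiguous = set(ambiguous_set)
    kept: list[ProteinSequence] = []
    removed: list[ProteinSequence] = []
    for s in seqs:
        hit = next((c for c in s.residues if c in ambiguous), None)
        if hit is None:
            kept.append(s)
        else:
            logger.info("dropping %s: ambiguous residue %r", s.id, hit)
            removed.append(s)
    return kept, removed
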