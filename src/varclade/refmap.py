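"""Reference-coordinate service: 1-based reference positions <-> 0-based columns.

Variants are stated on the reference protein (e.g. human Dicer1
NP-style coordinates); conservation evidence lives in alignment columns.
A :class:`ReferenceMap` is the bijection between the two, rebuilt after
every realignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import Alignment, GAP, MASK


class ReferenceMapError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceMap:
    """Bijection between reference positions 1..L and alignment columns.

    ``pos_to_col[p-1]`` is the 0-based column of reference position ``p``;
    columns where the reference row has a gap carry no position.
    """

    ref_id: str
    pos_to_col: np.ndarray  # shape (L,), strictly increasing
    n_cols: int

    @property
    def length(self) -> int:
        return int(self.pos_to_col.shape[0])

    def column_of(self, pos: int) -> int:
        """Alignment column of 1-based reference position ``pos``."""
        if not 1 <= pos <= self.length:
            raise ReferenceMapError(
                f"position {pos} outside reference {self.ref_id!r} (1..{self.length})"
            )
        return int(self.pos_to_col[pos - 1])

    def position_of(self, col: int) -> int | None:
        """1-based reference position at column ``col``; None on reference gaps."""
        if not 0 <= col < self.n_cols:
            raise ReferenceMapError(f"column {col} out of range [0, {self.n_cols})")
        i = int(np.searchsorted(self.pos_to_col, col))
        if i < self.length and int(self.pos_to_col[i]) == col:
            return i + 1
        return None


def build_reference_map(aln: Alignment, ref_id: str) -> ReferenceMap:
    """Build the position/column map from the reference row of ``aln``.

    The reference row must be present and unmasked: masking the very
    sequence that anchors coordinates would corrupt every downstream lookup.
    """
    if ref_id not in aln:
        raise ReferenceMapError(f"reference id {ref_id!r} not in alignment")
    row = aln.row(ref_id)
    if MASK in row:
        raise ReferenceMapError(f"reference row {ref_id!r} contains mask marks")
    cols = np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != GAP.encode())
    if cols.size == 0:
        raise ReferenceMapError(f"reference row {ref_id!r} is all gaps")
    return ReferenceMap(ref_id=ref_id, pos_to_col=cols.astype(np.int64), n_cols=aln.n_cols)
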