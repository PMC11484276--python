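"""Domain-wise refinement of a full-length ortholog alignment.

A multidomain protein aligns poorly as one block: long interdomain linkers
drift, and a misalignment in one domain contaminates columns elsewhere. The
remedy implemented here is the classic split–clean–realign–reassemble loop:

1. partition the reference protein into domain and non-domain segments from
   a domain-coordinate table (initial / domain / interdomain / terminal);
2. slice the full alignment into per-segment alignments;
3. per segment, discard rows with too little sequence coverage and mask
   residues adjacent to indels (misalignment is concentrated there);
4. realign every segment independently;
5. concatenate the segments back into a full-length refined alignment.

Segment realignment uses either an external command (e.g. ``mafft``) or the
built-in center-star aligner: every row is globally aligned to the
reference subsequence (Gotoh affine-gap DP, BLOSUM62), and the pairwise
alignments are merged under "once a gap, always a gap".
"""

from __future__ import annotations

import logging
import os
import subprocess
import tempfile
from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import substitution_matrices

from .msa_io import (
    Alignment,
    DEFAULT_AMBIGUOUS,
    FastaError,
    GAP,
    MASK,
    ProteinSequence,
    read_alignment,
    write_fasta,
)
from .refmap import ReferenceMap, build_reference_map

logger = logging.getLogger(__name__)


class DomainTableError(ValueError):
    pass


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainDefinition:
    """One annotated domain: name, annotation rule id, 1-based inclusive span."""

    name: str
    rule_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DomainTableError(
                f"domain {self.name!r}: invalid span {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class Segment:
    """One tile of the reference partition (domain or non-domain)."""

    kind: str  # domain | initial | interdomain | terminal
    name: str
    start: int  # 1-based inclusive
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CurationConfig:
    """Tunable knobs of the refinement pipeline.

    min_segment_coverage
        Fraction of a segment's reference-occupied columns a row must cover
        with real (non-gap, non-masked) residues to survive; rows below it
        are discarded as incomplete in that segment.
    indel_mask_window
        Residues within this many columns of a gap-run boundary are masked;
        0 disables masking.
    drop_policy
        ``gap_fill`` pads a row discarded in one segment with gaps there,
        keeping its evidence elsewhere; ``global`` removes it everywhere.
    """

    min_segment_coverage: float = 0.5
    indel_mask_window: int = 2
    ambiguous_set: frozenset[str] = DEFAULT_AMBIGUOUS
    aligner: str = "builtin"
    drop_policy: str = "gap_fill"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_segment_coverage <= 1.0:
            raise CurationError("min_segment_coverage must be in [0, 1]")
        if self.indel_mask_window < 0:
            raise CurationError("indel_mask_window must be >= 0")
        if self.drop_policy not in ("gap_fill", "global"):
            raise CurationError(f"unknown drop_policy {self.drop_policy!r}")


# ---------------------------------------------------------------------------
# Domain table and reference partition
# ---------------------------------------------------------------------------

def read_domain_table(stream) -> list[DomainDefinition]:
    """Read a TSV of domain coordinates (name, rule_id, start, end; 1-based).

    Rows are sorted by start; overlapping domains are an error. Thousands
    separators in coordinates ("1,042") are tolerated.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str)
    required = {"name", "rule_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DomainTableError(f"domain table missing columns: {sorted(missing)}")
    domains = [
        DomainDefinition(
            name=str(r["name"]).strip(),
            rule_id=str(r["rule_id"]).strip(),
            start=int(str(r["start"]).replace(",", "")),
            end=int(str(r["end"]).replace(",", "")),
        )
        for _, r in df.iterrows()
    ]
    domains.sort(key=lambda d: (d.start, d.end))
    for a, b in zip(domains, domains[1:]):
        if b.start <= a.end:
            raise DomainTableError(
                f"domains overlap: {a.name!r} ({a.start}..{a.end}) and "
                f"{b.name!r} ({b.start}..{b.end})"
            )
    return domains


def partition_reference(domains: list[DomainDefinition], length: int) -> list[Segment]:
    """Tile reference positions 1..length into domain and non-domain segments.

    Flanking and linker segments are emitted only where a real gap exists, so
    k pairwise-separated interior domains yield 2k+1 segments.
    """
    domains = sorted(domains, key=lambda d: d.start)
    for d in domains:
        if d.end > length:
            raise DomainTableError(
                f"domain {d.name!r} ends at {d.end} beyond reference length {length}"
            )
    segments: list[Segment] = []
    cursor = 1
    for i, d in enumerate(domains):
        if d.start > cursor:
            kind = "initial" if not segments else "interdomain"
            segments.append(Segment(kind, kind, cursor, d.start - 1))
        segments.append(Segment("domain", d.name, d.start, d.end))
        cursor = d.end + 1
    if cursor <= length:
        segments.append(Segment("terminal", "terminal", cursor, length))
    return segments


# ---------------------------------------------------------------------------
# Slicing and per-segment QC
# ---------------------------------------------------------------------------

def _segment_column_span(
    refmap: ReferenceMap, seg: Segment, next_start: int | None
) -> tuple[int, int]:
    """Half-open column span of a segment.

    Insertion columns (reference-gap columns) interior to the span travel
    with it; insertion columns at a segment boundary belong to the left
    segment, so spans run up to the next segment's first reference column.
    The first segment also absorbs any insertion columns before position 1.
    """
    lo = 0 if seg.start == 1 else refmap.column_of(seg.start)
    hi = refmap.n_cols if next_start is None else refmap.column_of(next_start)
    return lo, hi


def slice_alignment(aln: Alignment, refmap: ReferenceMap, seg: Segment,
                    next_start: int | None = None) -> Alignment:
    """Extract the columns of one segment (plus its insertion columns).

    ``next_start`` is the following segment's start position, if any; it
    fixes which boundary insertion columns the slice owns. Rows all-gap in
    the slice are retained (downstream filtering decides their fate).
    """
    if not 1 <= seg.start <= seg.end <= refmap.length:
        raise CurationError(f"segment {seg.name!r} outside reference 1..{refmap.length}")
    lo, hi = _segment_column_span(refmap, seg, next_start)
    return aln.take_columns(range(lo, hi))


def filter_incomplete(
    seg_aln: Alignment, min_segment_coverage: float, ref_id: str
) -> tuple[Alignment, list[str]]:
    """Drop rows covering too little of the segment's reference span.

    Coverage of a row = real residues (non-gap, non-mask) at reference-
    occupied columns / number of reference-occupied columns. The reference
    row itself is never dropped. Dropping every non-reference row is legal;
    dropping all rows is not.
    """
    ref_row = seg_aln.row(ref_id)
    ref_cols = [i for i, c in enumerate(ref_row) if c != GAP]
    if not ref_cols:
        raise CurationError(f"segment has no reference-occupied columns ({ref_id!r})")
    kept_ids: list[str] = []
    removed: list[str] = []
    for seq_id, row in seg_aln.rows():
        if seq_id == ref_id:
            kept_ids.append(seq_id)
            continue
        covered = sum(1 for c in ref_cols if row[c] not in (GAP, MASK))
        if covered / len(ref_cols) < min_segment_coverage:
            removed.append(seq_id)
        else:
            kept_ids.append(seq_id)
    if not kept_ids:
        raise CurationError("coverage filter removed every row of a segment")
    return seg_aln.take_rows(kept_ids), removed


def mask_near_indels(seg_aln: Alignment, window: int, ref_id: str) -> Alignment:
    """Mask residues within ``window`` columns of any gap-run boundary, per row.

    Residues flanking an indel are the usual victims of misalignment; the
    mask mark removes them from conservation counting without disturbing
    column geometry. The reference row is never masked.
    """
    if window < 0:
        raise CurationError("mask window must be >= 0")
    if window == 0:
        return seg_aln
    out_rows: list[tuple[str, str]] = []
    for seq_id, row in seg_aln.rows():
        if seq_id == ref_id:
            out_rows.append((seq_id, row))
            continue
        chars = list(row)
        n = len(chars)
        i = 0
        while i < n:
            if chars[i] == GAP:
                j = i
                while j < n and chars[j] == GAP:
                    j += 1
                for k in range(max(0, i - window), i):
                    if chars[k] not in (GAP, MASK):
                        chars[k] = MASK
                for k in range(j, min(n, j + window)):
                    if chars[k] not in (GAP, MASK):
                        chars[k] = MASK
                i = j
            else:
                i += 1
        out_rows.append((seq_id, "".join(chars)))
    return Alignment(out_rows, seg_aln.descriptions)


# ---------------------------------------------------------------------------
# Built-in pairwise / center-star aligner
# ---------------------------------------------------------------------------

GAP_OPEN = 10.0   # cost of the first residue of a gap run
GAP_EXTEND = 1.0  # cost of each further residue

_NEG = float("-inf")


def _score_lookup():
    """BLOSUM62 as a dict over (a, b); letters absent from the matrix
    (J, U, O and the mask mark) score as X."""
    m = substitution_matrices.load("BLOSUM62")
    letters = set(m.alphabet)
    table: dict[tuple[str, str], float] = {}
    alphabet = list(m.alphabet) + ["J", "U", "O", MASK]

    def canon(c: str) -> str:
        return c if c in letters else "X"

    for a in alphabet:
        for b in alphabet:
            table[(a, b)] = float(m[canon(a), canon(b)])
    return table


_BLOSUM62 = _score_lookup()


def pairwise_global(a: str, b: str) -> tuple[str, str, float]:
    """Global affine-gap alignment of two peptides (Gotoh), BLOSUM62 scores.

    End gaps are penalized. Traceback ties break deterministically:
    diagonal, then gap-in-``b`` (consume ``a``), then gap-in-``a``.
    Returns (gapped_a, gapped_b, score).
    """
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return "", "", 0.0
    if n == 0:
        return GAP * m, b, -(GAP_OPEN + (m - 1) * GAP_EXTEND)
    if m == 0:
        return a, GAP * n, -(GAP_OPEN + (n - 1) * GAP_EXTEND)

    S = _BLOSUM62
    # DP over three states: M (diagonal), X (gap in b, consume a), Y (gap in a)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)
    for j in range(1, m + 1):
        Y[0][j] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
    for i in range(1, n + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Mi[j] = S[(ai, b[j - 1])] + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Xi[j] = max(Mi1[j] - GAP_OPEN, Xi1[j] - GAP_EXTEND, Yi1[j] - GAP_OPEN)
            Yi[j] = max(Mi[j - 1] - GAP_OPEN, Yi[j - 1] - GAP_EXTEND, Xi[j - 1] - GAP_OPEN)

    # traceback, tie preference M > X > Y throughout
    i, j = n, m
    finals = {"M": M[n][m], "X": X[n][m], "Y": Y[n][m]}
    score = max(finals.values())
    state = next(s for s in "MXY" if finals[s] == score)
    ga: list[str] = []
    gb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            target = M[i][j] - S[(a[i - 1], b[j - 1])]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = next(
                s for s, v in (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j]))
                if v == target
            )
        elif state == "X":
            ga.append(a[i - 1])
            gb.append(GAP)
            val = X[i][j]
            i -= 1
            if M[i][j] - GAP_OPEN == val:
                state = "M"
            elif X[i][j] - GAP_EXTEND == val:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
        else:  # Y
            ga.append(GAP)
            gb.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if M[i][j] - GAP_OPEN == val:
                state = "M"
            elif Y[i][j] - GAP_EXTEND == val:
                state = "Y"
            else:
                state = "X"
            if i == 0 and j == 0:
                break
        # boundary states: only gaps remain
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return "".join(reversed(ga)), "".join(reversed(gb)), score


def center_star_align(seqs: list[ProteinSequence], center_id: str) -> Alignment:
    """Multiple alignment by the center-star heuristic around ``center_id``.

    Every sequence is aligned pairwise to the center; insertions relative to
    the center are merged with "once a gap, always a gap". Row order follows
    input order; output degaps back to the input residues exactly.
    """
    ids = [s.id for s in seqs]
    if center_id not in ids:
        raise CurationError(f"center sequence {center_id!r} not among inputs")
    center = next(s for s in seqs if s.id == center_id)
    c = center.residues
    mlen = len(c)
    if len(seqs) == 1:
        return Alignment([(center.id, c)])

    # per sequence: residues aligned to each center position (or '-'), plus
    # insertion blocks between center positions (index 0..mlen)
    aligned_cols: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    max_ins = [0] * (mlen + 1)
    for s in seqs:
        if s.id == center_id:
            continue
        ca, sa, _ = pairwise_global(c, s.residues)
        cols = []
        ins: list[str] = [""] * (mlen + 1)
        cpos = 0
        for cc, sc in zip(ca, sa):
            if cc == GAP:
                ins[cpos] += sc
            else:
                cols.append(sc)
                cpos += 1
        aligned_cols[s.id] = cols
        inserts[s.id] = ins
        for k in range(mlen + 1):
            max_ins[k] = max(max_ins[k], len(ins[k]))

    def build_row(cols: list[str], ins: list[str]) -> str:
        parts: list[str] = []
        for k in range(mlen + 1):
            block = ins[k]
            parts.append(block + GAP * (max_ins[k] - len(block)))
            if k < mlen:
                parts.append(cols[k])
        return "".join(parts)

    rows: list[tuple[str, str]] = []
    for s in seqs:
        if s.id == center_id:
            rows.append((s.id, build_row(list(c), [""] * (mlen + 1))))
        else:
            rows.append((s.id, build_row(aligned_cols[s.id], inserts[s.id])))
    return Alignment(rows)


def _external_align(seqs: list[ProteinSequence], command_template: str) -> Alignment:
    """Run an external aligner via a shell template with {in}/{out} slots."""
    with tempfile.TemporaryDirectory(prefix="varclade_aln_") as tmp:
        fin = os.path.join(tmp, "in.fasta")
        fout = os.path.join(tmp, "out.fasta")
        with open(fin, "w") as fh:
            write_fasta(seqs, fh)
        cmd = command_template.format(**{"in": fin, "out": fout})
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise CurationError(
                f"external aligner failed (exit {proc.returncode}): {cmd}\n{proc.stderr}"
            )
        try:
            with open(fout) as fh:
                aln = read_alignment(fh)
        except (OSError, FastaError) as exc:
            raise CurationError(f"external aligner produced bad output: {exc}") from exc
    return aln


def realign_segment(
    seqs: list[ProteinSequence], aligner: str = "builtin", ref_id: str | None = None
) -> Alignment:
    """Realign the (degapped) rows of one segment.

    ``aligner`` is either ``"builtin"`` (center-star around the reference,
    which must then be present) or a shell command template containing
    ``{in}`` and ``{out}`` FASTA placeholders.
    """
    if not seqs:
        raise CurationError("nothing to align")
    if aligner == "builtin":
        center = ref_id if ref_id is not None else seqs[0].id
        aln = center_star_align(seqs, center)
    else:
        aln = _external_align(seqs, aligner)
    by_id = {s.id: s.residues for s in seqs}
    if set(aln.ids) != set(by_id):
        raise CurationError("aligner changed the set of sequence ids")
    for seq_id in aln.ids:
        if aln.degap(seq_id) != by_id[seq_id]:
            raise CurationError(f"aligner altered residues of {seq_id!r}")
    return aln


# ---------------------------------------------------------------------------
# Reassembly and the full pipeline
# ---------------------------------------------------------------------------

def reassemble(
    segments: list[tuple[Segment, Alignment]],
    drop_policy: str = "gap_fill",
    row_order: list[str] | None = None,
) -> tuple[Alignment, dict[str, list[str]]]:
    """Concatenate per-segment alignments back into a full-length alignment.

    Under ``gap_fill`` a row missing from some segment is padded with gaps
    there (and reported); under ``global`` only rows present in every
    segment survive. Returns (alignment, {row id: segment names gap-filled}).
    """
    if not segments:
        raise CurationError("no segments to reassemble")
    present: list[set[str]] = [set(a.ids) for _, a in segments]
    if row_order is None:
        row_order = []
        for _, a in segments:
            for i in a.ids:
                if i not in row_order:
                    row_order.append(i)
    if drop_policy == "global":
        survivors = [i for i in row_order if all(i in p for p in present)]
        if not survivors:
            raise CurationError("drop_policy=global left no rows in the assembly")
        row_order = survivors
    flagged: dict[str, list[str]] = {}
    parts: dict[str, list[str]] = {i: [] for i in row_order}
    for (seg, aln), ids in zip(segments, present):
        pad = GAP * aln.n_cols
        for i in row_order:
            if i in ids:
                parts[i].append(aln.row(i))
            else:
                parts[i].append(pad)
                flagged.setdefault(i, []).append(seg.name)
    rows = [(i, "".join(parts[i])) for i in row_order]
    return Alignment(rows), flagged


@dataclass
class CurationReport:
    """What the pipeline did: one (id, segment, action, reason) row per event."""

    events: list[tuple[str, str, str, str]] = field(default_factory=list)
    n_segments: int = 0

    def add(self, seq_id: str, segment: str, action: str, reason: str) -> None:
        self.events.append((seq_id, segment, action, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["id", "segment", "action", "reason"])


def curate(
    aln: Alignment,
    domains: list[DomainDefinition],
    ref_id: str,
    config: CurationConfig | None = None,
) -> tuple[Alignment, CurationReport]:
    """Run the full split–filter–mask–realign–reassemble refinement.

    Input is a full-length alignment containing the reference row; output is
    the refined full-length alignment plus a report of every removal,
    masking and gap-fill event.
    """
    config = config or CurationConfig()
    refmap = build_reference_map(aln, ref_id)
    segments = partition_reference(domains, refmap.length)
    report = CurationReport(n_segments=len(segments))
    refined: list[tuple[Segment, Alignment]] = []
    for k, seg in enumerate(segments):
        next_start = segments[k + 1].start if k + 1 < len(segments) else None
        piece = slice_alignment(aln, refmap, seg, next_start)
        piece, removed = filter_incomplete(piece, config.min_segment_coverage, ref_id)
        for i in removed:
            report.add(i, seg.name, "removed", "incomplete")
        masked = mask_near_indels(piece, config.indel_mask_window, ref_id)
        for seq_id in masked.ids:
            n_marks = masked.row(seq_id).count(MASK) - piece.row(seq_id).count(MASK)
            if n_marks > 0:
                report.add(seq_id, seg.name, "masked", f"{n_marks} residues near indels")
        seqs = [
            ProteinSequence(id=i, residues=masked.degap(i))
            for i in masked.ids
            if masked.degap(i)
        ]
        realigned = realign_segment(seqs, config.aligner, ref_id)
        # rows that were all-gap in this segment drop out of the realignment
        for i in masked.ids:
            if i not in realigned:
                report.add(i, seg.name, "removed", "no residues in segment")
        refined.append((seg, realigned))
        logger.info("segment %s (%d..%d): %d rows, %d cols",
                    seg.name, seg.start, seg.end, realigned.n_rows, realigned.n_cols)
    out, flagged = reassemble(refined, config.drop_policy, row_order=aln.ids
                              if config.drop_policy == "global" else None)
    for i, seg_names in flagged.items():
        for s in seg_names:
            report.add(i, s, "gap_filled", "absent from segment after filtering")
    build_reference_map(out, ref_id)  # sanity: reference survives reassembly
    return out, report
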