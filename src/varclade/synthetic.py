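"""Synthetic ortholog alignments, gene trees, and variants with known truth.

Every other module is exercised against data generated here: alignments
with designated invariant and variable columns, planted deletions,
truncated rows, ambiguous residues, and divergent paralog contaminants,
plus a matching toy gene tree. The generator records exactly what it
emitted (the truth table), and expected variant verdicts are computed by a
straight-line rule evaluator in this module that shares no code with
:mod:`varclade.classify_core` — so generator truth stays an independent
oracle for the classifier.

All randomness flows from one explicit integer seed through a single
``numpy.random.Generator``; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import Alignment, CANONICAL_AA, GAP, MASK, ProteinSequence
from .classify_core import ClassifyConfig, VariantCall

AA = CANONICAL_AA  # canonical residue pool used by the generator


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for one synthetic ortholog alignment.

    ``n_rows`` counts the reference plus its orthologs; ``paralog_rows``
    adds contaminant rows on top. Variable columns carry (pool, weights);
    the first pool residue is the reference residue. When no columns are
    specified explicitly, a ``variable_fraction`` of positions is made
    variable (pools of 2–4 residues, reference residue dominant) and the
    rest invariant, mirroring an ortholog set that has had time to diverge;
    otherwise unspecified columns are invariant with seed-drawn residues.
    """

    n_rows: int = 40
    L: int = 120
    invariant_columns: dict[int, str] = field(default_factory=dict)
    variable_columns: dict[int, tuple[str, list[float]]] = field(default_factory=dict)
    variable_fraction: float = 0.3
    indel_rate: float = 0.1
    truncation_fraction: float = 0.1
    ambiguous_rate: float = 0.05
    paralog_rows: int = 6
    paralog_divergence: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise FixtureError("need at least a reference and one ortholog")
        for pos in list(self.invariant_columns) + list(self.variable_columns):
            if not 1 <= pos <= self.L:
                raise FixtureError(f"column position {pos} outside 1..{self.L}")
        shared = set(self.invariant_columns) & set(self.variable_columns)
        if shared:
            raise FixtureError(f"columns declared both invariant and variable: {shared}")
        for pos, (pool, weights) in self.variable_columns.items():
            if not pool or len(pool) != len(weights):
                raise FixtureError(f"bad pool/weights at position {pos}")
            if any(c not in AA for c in pool):
                raise FixtureError(f"non-canonical residue in pool at position {pos}")


@dataclass
class MsaTruth:
    """Everything the generator knows about what it emitted."""

    ref_id: str
    ids: list[str]
    rows: dict[str, str]                 # id -> gapped row
    ref_residues: str                    # ungapped reference
    column_kind: dict[int, str]          # pos -> invariant | variable
    observed: dict[int, set[str]]        # pos -> residues among ortholog rows
    truncated: set[str]
    ambiguous: set[str]
    paralogs: set[str]
    species_of: dict[str, str]
    seed: int


def _ortholog_ids(spec: FixtureSpec) -> list[str]:
    return ["ref"] + [f"orth{i:02d}" for i in range(1, spec.n_rows)]


def generate_msa(spec: FixtureSpec) -> tuple[Alignment, MsaTruth]:
    """Emit an alignment (reference first) and its truth table."""
    rng = np.random.default_rng(spec.seed)
    L = spec.L

    variable_columns = dict(spec.variable_columns)
    if not variable_columns and not spec.invariant_columns and spec.variable_fraction > 0:
        n_var = int(round(spec.variable_fraction * L))
        var_pos = sorted(int(p) + 1 for p in rng.choice(L, size=n_var, replace=False))
        for pos in var_pos:
            k = int(rng.integers(2, 5))
            pool = "".join(AA[i] for i in rng.choice(len(AA), size=k, replace=False))
            weights = [0.6] + [0.4 / (k - 1)] * (k - 1)
            variable_columns[pos] = (pool, weights)

    # reference residues and per-column emission rules
    ref = [""] * (L + 1)
    kind: dict[int, str] = {}
    pools: dict[int, tuple[str, np.ndarray]] = {}
    for pos in range(1, L + 1):
        if pos in variable_columns:
            pool, weights = variable_columns[pos]
            w = np.asarray(weights, dtype=float)
            pools[pos] = (pool, w / w.sum())
            ref[pos] = pool[0]
            kind[pos] = "variable"
        else:
            res = spec.invariant_columns.get(pos) or AA[rng.integers(len(AA))]
            ref[pos] = res
            kind[pos] = "invariant"

    ortho_ids = _ortholog_ids(spec)
    rows: dict[str, list[str]] = {}
    for seq_id in ortho_ids:
        if seq_id == "ref":
            rows[seq_id] = [ref[p] for p in range(1, L + 1)]
            continue
        chars = []
        for pos in range(1, L + 1):
            if kind[pos] == "variable":
                pool, w = pools[pos]
                chars.append(pool[rng.choice(len(pool), p=w)])
            else:
                chars.append(ref[pos])
        rows[seq_id] = chars

    # deletions: up to 3 runs per non-reference row
    for seq_id in ortho_ids[1:]:
        n_runs = int(rng.binomial(3, spec.indel_rate))
        for _ in range(n_runs):
            start = int(rng.integers(L))
            length = int(rng.integers(1, 5))
            for c in range(start, min(L, start + length)):
                rows[seq_id][c] = GAP

    # truncations: head or tail replaced by gaps
    n_trunc = int(round(spec.truncation_fraction * (spec.n_rows - 1)))
    trunc_ids = list(rng.choice(ortho_ids[1:], size=n_trunc, replace=False)) if n_trunc else []
    for seq_id in trunc_ids:
        k = int(rng.integers(L // 3, 2 * L // 3))
        if rng.random() < 0.5:
            for c in range(k):
                rows[seq_id][c] = GAP
        else:
            for c in range(L - k, L):
                rows[seq_id][c] = GAP

    # planted ambiguity
    ambiguous_ids: set[str] = set()
    for seq_id in ortho_ids[1:]:
        if rng.random() < spec.ambiguous_rate:
            occupied = [c for c in range(L) if rows[seq_id][c] != GAP]
            if occupied:
                c = occupied[int(rng.integers(len(occupied)))]
                rows[seq_id][c] = "X"
                ambiguous_ids.add(seq_id)

    # paralog contaminants: a fixed fraction of columns redrawn from a
    # residue pool disjoint from that column's ortholog pool
    paralog_ids = [f"par{i:02d}" for i in range(1, spec.paralog_rows + 1)]
    n_div = int(round(spec.paralog_divergence * L))
    for seq_id in paralog_ids:
        chars = [ref[p] for p in range(1, L + 1)]
        div_cols = rng.choice(L, size=n_div, replace=False)
        for c in sorted(int(x) for x in div_cols):
            pos = c + 1
            forbidden = set(pools[pos][0]) if kind[pos] == "variable" else {ref[pos]}
            allowed = [a for a in AA if a not in forbidden]
            chars[c] = allowed[int(rng.integers(len(allowed)))]
        rows[seq_id] = chars

    ids = ortho_ids + paralog_ids
    species = {seq_id: f"Species {i:03d}" for i, seq_id in enumerate(ids)}
    # paralog-bearing species: each paralog shares its species with one ortholog
    for i, seq_id in enumerate(paralog_ids):
        donor = ortho_ids[1 + (i % (len(ortho_ids) - 1))]
        species[seq_id] = species[donor]

    observed: dict[int, set[str]] = {}
    for pos in range(1, L + 1):
        col = {rows[i][pos - 1] for i in ortho_ids}
        observed[pos] = {c for c in col if c not in (GAP, MASK, "X")}

    aln = Alignment([(i, "".join(rows[i])) for i in ids])
    truth = MsaTruth(
        ref_id="ref",
        ids=ids,
        rows={i: "".join(rows[i]) for i in ids},
        ref_residues="".join(ref[1:]),
        column_kind=kind,
        observed=observed,
        truncated=set(trunc_ids),
        ambiguous=ambiguous_ids,
        paralogs=set(paralog_ids),
        species_of=species,
        seed=spec.seed,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Independent rule evaluator (the oracle)
# ---------------------------------------------------------------------------

def evaluate_rules(
    rows: list[str],
    ref_index: int,
    pos: int,
    ref_aa: str,
    alt_aa: str,
    cfg: ClassifyConfig,
) -> str:
    """Straight-line re-statement of the tolerance rules on raw gapped rows.

    Deliberately naive: positions are located by scanning the reference row,
    every quantity is recomputed in place, and nothing is shared with the
    production classifier. Returns the verdict name.
    """
    ref_row = rows[ref_index]
    # pos -> column by counting non-gap reference characters
    col = -1
    seen = 0
    for c, ch in enumerate(ref_row):
        if ch != GAP:
            seen += 1
            if seen == pos:
                col = c
                break
    if col == -1:
        raise FixtureError(f"position {pos} beyond reference")
    if ref_row[col] != ref_aa:
        raise FixtureError(f"reference mismatch at {pos}")
    length = sum(1 for ch in ref_row if ch != GAP)

    column = [r[col] for r in rows]
    residues = [ch for ch in column if ch not in (GAP, MASK)]
    gap_count = sum(1 for ch in column if ch == GAP)
    depth = len(residues)
    if depth < cfg.min_depth or gap_count / len(rows) > cfg.max_gap_fraction:
        return "UNALIGNABLE"

    def col_of(p: int) -> int:
        seen = 0
        for c, ch in enumerate(ref_row):
            if ch != GAP:
                seen += 1
                if seen == p:
                    return c
        raise FixtureError(f"position {p} beyond reference")

    if alt_aa in residues:
        carriers = [k for k, r in enumerate(rows) if r[col] == alt_aa]
        for k in carriers:
            ok = True
            for p in range(pos - cfg.adjacency_window, pos + cfg.adjacency_window + 1):
                if p == pos or p < 1 or p > length:
                    continue
                cc = col_of(p)
                if rows[k][cc] in (GAP, MASK) or rows[k][cc] != ref_row[cc]:
                    ok = False
                    break
            if ok:
                return "TOLERANT"
        return "UNINTERPRETABLE"

    if cfg.mode == "strict":
        return "INTOLERANT"
    counts: dict[str, int] = {}
    for ch in residues:
        counts[ch] = counts.get(ch, 0) + 1
    if len(counts) == 1 or max(counts.values()) / depth >= cfg.conservation_threshold:
        return "INTOLERANT"
    return "UNINTERPRETABLE"


def generate_variants(
    truth: MsaTruth,
    n: int,
    seed: int,
    cfg: ClassifyConfig | None = None,
) -> list[tuple[VariantCall, str]]:
    """Draw ``n`` variants on the reference with oracle-expected verdicts.

    Expected verdicts are evaluated against the ortholog rows only (the
    paralog contaminants are what clade selection removes upstream), by
    :func:`evaluate_rules`. Half the draws aim for residues observed among
    orthologs, half for unobserved ones, so all verdict classes occur.
    """
    cfg = cfg or ClassifyConfig()
    rng = np.random.default_rng(seed)
    ortho_ids = [i for i in truth.ids if i not in truth.paralogs]
    rows = [truth.rows[i] for i in ortho_ids]
    ref_index = ortho_ids.index(truth.ref_id)
    out: list[tuple[VariantCall, str]] = []
    L = len(truth.ref_residues)
    while len(out) < n:
        pos = int(rng.integers(1, L + 1))
        ref_aa = truth.ref_residues[pos - 1]
        observed_alts = sorted(truth.observed[pos] - {ref_aa})
        if observed_alts and rng.random() < 0.5:
            alt = observed_alts[int(rng.integers(len(observed_alts)))]
        else:
            unseen = [a for a in AA if a != ref_aa and a not in truth.observed[pos]]
            if not unseen:
                continue
            alt = unseen[int(rng.integers(len(unseen)))]
        verdict = evaluate_rules(rows, ref_index, pos, ref_aa, alt, cfg)
        out.append((VariantCall(pos, ref_aa, alt), verdict))
    return out


# ---------------------------------------------------------------------------
# Toy gene trees
# ---------------------------------------------------------------------------

def _random_subtree(ids: list[str], rng: np.random.Generator) -> str:
    """Random binary Newick subtree over ids (deterministic under rng)."""
    nodes = list(ids)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        support = int(rng.integers(70, 101))
        nodes.append(f"({a},{b}){support}")
    return nodes[0]


def generate_tree(truth: MsaTruth, seed: int | None = None) -> str:
    """Newick gene tree over the generated rows; paralogs form a sister clade.

    Internal nodes carry synthetic support labels (70–100). Deterministic
    under the seed (defaults to the alignment's own seed).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ortho = [i for i in truth.ids if i not in truth.paralogs]
    para = sorted(truth.paralogs)
    left = _random_subtree(ortho, rng)
    if not para:
        return f"{left};"
    right = _random_subtree(para, rng)
    return f"({left},{right});"


def to_sequences(truth: MsaTruth) -> list[ProteinSequence]:
    """Degapped sequences (with NCBI-style species tags) for the generated rows."""
    out = []
    for seq_id in truth.ids:
        residues = truth.rows[seq_id].replace(GAP, "")
        out.append(
            ProteinSequence(
                id=seq_id,
                residues=residues,
                species=truth.species_of[seq_id],
                description=f"synthetic [{truth.species_of[seq_id]}]",
            )
        )
    return out
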