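"""Evolutionary tolerance classification of missense variants.

The decision rule reads a curated ortholog alignment column by column:

* a substitution observed in at least one ortholog whose neighboring
  positions match the reference is evolutionarily *tolerant* — the protein
  demonstrably functions with it in an otherwise identical local context;
* a substitution observed only in sequences that also differ at adjoining
  positions is *uninterpretable*: the changed local context may compensate;
* a substitution never observed is *intolerant* — in strict mode
  unconditionally, in conservation mode only at invariant or highly
  conserved columns (variable columns then give *uninterpretable*);
* a column with too few informative residues or too many gaps yields
  *unalignable*: there is no evolutionary signal to read.

Verdicts are categorical by design; no pathogenicity score is produced.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .msa_io import Alignment, CANONICAL_AA, GAP, MASK
from .refmap import ReferenceMap

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_UNSUPPORTED_3 = {"Ter", "Sec", "Pyl", "Xaa", "Asx", "Glx", "Xle"}


class VariantError(ValueError):
    pass


class Verdict(str, Enum):
    TOLERANT = "TOLERANT"
    INTOLERANT = "INTOLERANT"
    UNINTERPRETABLE = "UNINTERPRETABLE"
    UNALIGNABLE = "UNALIGNABLE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class VariantCall:
    """One missense substitution in 1-based reference coordinates."""

    pos: int
    ref_aa: str
    alt_aa: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.ref_aa not in CANONICAL_AA or self.alt_aa not in CANONICAL_AA:
            raise VariantError(
                f"non-canonical residue in variant {self.ref_aa}{self.pos}{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise VariantError(
                f"{self.ref_aa}{self.pos}{self.alt_aa} is not a substitution"
            )
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")

    @property
    def token(self) -> str:
        return f"{self.ref_aa}{self.pos}{self.alt_aa}"


@dataclass(frozen=True)
class ClassifyConfig:
    """Classification parameters.

    mode
        ``strict``: an unobserved substitution is intolerant regardless of
        column variability. ``conservation``: unobserved is intolerant only
        at invariant columns or columns whose majority residue frequency
        reaches ``conservation_threshold``; otherwise uninterpretable.
    adjacency_window
        Reference positions on each side that must match the reference in a
        carrier for it to certify tolerance.
    max_gap_fraction / min_depth
        Column-quality gates; failing either yields UNALIGNABLE.
    """

    mode: str = "strict"
    conservation_threshold: float = 0.95
    adjacency_window: int = 1
    max_gap_fraction: float = 0.5
    min_depth: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "conservation"):
            raise VariantError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.conservation_threshold <= 1.0:
            raise VariantError("conservation_threshold must be in (0, 1]")
        if self.adjacency_window < 1:
            raise VariantError("adjacency_window must be >= 1")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise VariantError("max_gap_fraction must be in [0, 1]")
        if self.min_depth < 1:
            raise VariantError("min_depth must be >= 1")


@dataclass(frozen=True)
class ColumnProfile:
    """Residue census of one alignment column (gaps and masks excluded)."""

    col: int
    counts: dict[str, int]
    gap_count: int
    masked_count: int

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def observed_set(self) -> frozenset[str]:
        return frozenset(self.counts)

    @property
    def majority_freq(self) -> float:
        return max(self.counts.values()) / self.depth if self.counts else 0.0


@dataclass
class Classification:
    """A verdict plus the evidence that produced it."""

    variant: VariantCall
    verdict: Verdict
    rule: str
    profile: ColumnProfile
    carriers: list[str] = field(default_factory=list)
    carrier_adjacency: dict[str, bool] = field(default_factory=dict)

    @property
    def passing_carriers(self) -> list[str]:
        return [c for c in self.carriers if self.carrier_adjacency.get(c)]


# ---------------------------------------------------------------------------
# Variant parsing
# ---------------------------------------------------------------------------

def parse_variant(token: str, label: str | None = None) -> VariantCall:
    """Parse ``E1705K`` or HGVS-p ``p.Glu1705Lys`` into a :class:`VariantCall`.

    Only missense substitutions are supported; nonsense (Ter/``*``) and
    frameshift notations are rejected as unsupported.
    """
    t = token.strip()
    if t.startswith("p."):
        t = t[2:]
    if not t:
        raise VariantError("empty variant token")
    if "fs" in t or t.endswith("del") or t.endswith("dup"):
        raise VariantError(f"unsupported (non-missense) variant: {token!r}")

    def unparsable() -> VariantError:
        return VariantError(f"cannot parse variant token {token!r}")

    # 3-letter form: Xxx<digits>Yyy
    if len(t) >= 7 and t[:3].isalpha() and t[0].isupper() and t[1:3].islower():
        aa1, rest = t[:3], t[3:]
        digits = "".join(c for c in rest if c.isdigit())
        aa2 = rest[len(digits):]
        if not digits or not rest.startswith(digits):
            raise unparsable()
        if aa1 in _UNSUPPORTED_3 or aa2 in _UNSUPPORTED_3 or aa2 == "Ter":
            raise VariantError(f"unsupported variant class: {token!r}")
        if aa1 not in AA3_TO_1 or aa2 not in AA3_TO_1:
            raise unparsable()
        return VariantCall(int(digits), AA3_TO_1[aa1], AA3_TO_1[aa2], label)

    # 1-letter form: X<digits>Y
    if len(t) >= 3 and t[0].isalpha() and t[-1].isalpha() and t[1:-1].isdigit():
        return VariantCall(int(t[1:-1]), t[0].upper(), t[-1].upper(), label)
    if len(t) >= 3 and t[0].isalpha() and t[-1] == "*" and t[1:-1].isdigit():
        raise VariantError(f"unsupported variant class: {token!r}")
    raise unparsable()


# ---------------------------------------------------------------------------
# Column profiling and the decision rule
# ---------------------------------------------------------------------------

def column_profile(aln: Alignment, col: int) -> ColumnProfile:
    """Tally residues in one column, excluding gaps and mask marks."""
    counts: Counter[str] = Counter()
    gaps = 0
    masked = 0
    for ch in aln.column(col):
        if ch == GAP:
            gaps += 1
        elif ch == MASK:
            masked += 1
        else:
            counts[ch] += 1
    return ColumnProfile(col=col, counts=dict(counts), gap_count=gaps, masked_count=masked)


def _carrier_adjacent_ok(
    aln: Alignment,
    refmap: ReferenceMap,
    carrier: str,
    pos: int,
    window: int,
) -> bool:
    """Does the carrier match the reference at every adjoining position?

    A gap or mask mark at an adjoining position cannot certify local
    context identity and counts as a mismatch.
    """
    ref_row = aln.row(refmap.ref_id)
    row = aln.row(carrier)
    for p in range(max(1, pos - window), min(refmap.length, pos + window) + 1):
        if p == pos:
            continue
        c = refmap.column_of(p)
        if row[c] in (GAP, MASK) or row[c] != ref_row[c]:
            return False
    return True


def classify_variant(
    aln: Alignment,
    refmap: ReferenceMap,
    variant: VariantCall,
    config: ClassifyConfig | None = None,
) -> Classification:
    """Apply the tolerance rules to one variant against a curated alignment.

    The reference residue at the variant's column must equal the variant's
    stated reference amino acid, otherwise the call is rejected (wrong
    isoform or stale coordinates).
    """
    config = config or ClassifyConfig()
    col = refmap.column_of(variant.pos)  # raises on out-of-range pos
    ref_res = aln.row(refmap.ref_id)[col]
    if ref_res != variant.ref_aa:
        raise VariantError(
            f"variant {variant.token}: reference has {ref_res!r} at position "
            f"{variant.pos}, not {variant.ref_aa!r}"
        )
    profile = column_profile(aln, col)

    # rule 1: column-quality gate
    gap_fraction = profile.gap_count / aln.n_rows
    if profile.depth < config.min_depth or gap_fraction > config.max_gap_fraction:
        return Classification(
            variant, Verdict.UNALIGNABLE, "insufficient_signal", profile
        )

    # rule 2: substitution observed among orthologs
    if variant.alt_aa in profile.observed_set:
        carriers = [i for i, row in aln.rows() if row[col] == variant.alt_aa]
        adjacency = {
            c: _carrier_adjacent_ok(aln, refmap, c, variant.pos, config.adjacency_window)
            for c in carriers
        }
        if any(adjacency.values()):
            return Classification(
                variant, Verdict.TOLERANT, "observed_clean_context", profile,
                carriers, adjacency,
            )
        return Classification(
            variant, Verdict.UNINTERPRETABLE, "co_substituted_context", profile,
            carriers, adjacency,
        )

    # rule 3: substitution never observed
    if config.mode == "strict":
        return Classification(variant, Verdict.INTOLERANT, "unobserved", profile)
    invariant = len(profile.observed_set) == 1
    if invariant or profile.majority_freq >= config.conservation_threshold:
        return Classification(
            variant, Verdict.INTOLERANT, "unobserved_conserved", profile
        )
    return Classification(
        variant, Verdict.UNINTERPRETABLE, "unobserved_variable", profile
    )


def classify_batch(
    aln: Alignment,
    refmap: ReferenceMap,
    variants: list[VariantCall | str],
    config: ClassifyConfig | None = None,
) -> tuple[list[Classification | tuple[str, str]], dict[str, int]]:
    """Classify a variant list; item-level failures never abort the batch.

    Returns (results, summary). ``results`` keeps input order: a
    :class:`Classification` per success, an ``(token, error message)`` pair
    per failure. ``summary`` is the verdict histogram plus an ``"error"``
    count; duplicated input variants are counted as many times as given.
    """
    config = config or ClassifyConfig()
    results: list[Classification | tuple[str, str]] = []
    summary = {v.value: 0 for v in Verdict}
    summary["error"] = 0
    for item in variants:
        try:
            v = parse_variant(item) if isinstance(item, str) else item
            res = classify_variant(aln, refmap, v, config)
            results.append(res)
            summary[res.verdict.value] += 1
        except Exception as exc:  # noqa: BLE001 - item-level errors are collected
            token = item if isinstance(item, str) else getattr(item, "token", repr(item))
            results.append((str(token), str(exc)))
            summary["error"] += 1
    return results, summary


def merge_unalignable(summary: dict[str, int]) -> dict[str, int]:
    """Fold UNALIGNABLE into UNINTERPRETABLE (three-way accounting)."""
    out = dict(summary)
    out[Verdict.UNINTERPRETABLE.value] = (
        out.get(Verdict.UNINTERPRETABLE.value, 0) + out.pop(Verdict.UNALIGNABLE.value, 0)
    )
    return out
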