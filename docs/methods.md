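# Methods

## Model and assumptions

`varclade` treats a curated ortholog alignment as a direct record of which
substitutions evolution has tested. The underlying assumptions are the
standard ones for conservation-based variant interpretation:

- the sequences in the evidence set are true orthologs of the reference and
  functionally equivalent — hence the insistence on removing paralogs by
  clade selection before anything else;
- a residue observed in an ortholog at a reference-aligned column, with the
  local sequence context unchanged, demonstrates that the protein tolerates
  that residue there;
- a residue never observed across a sufficiently deep, well-aligned column
  is evidence of purifying selection against it;
- misalignment, not biology, explains most residue "diversity" adjacent to
  indels in long multidomain alignments, which motivates both the
  domain-wise realignment and the indel-proximity masking.

Verdicts are deliberately categorical (tolerant / intolerant /
uninterpretable / unalignable). No probability or score is attached: the
evidence either exists in the alignment or it does not, and the evidence
record (column census, carrier ids, adjacency outcomes) is returned with
every call so a reviewer can audit it.

## Pipeline order

`curate` runs: ambiguity removal → reference-map construction → domain
partition → per-segment slice → coverage filter → indel-proximity masking →
realignment → reassembly. Filtering precedes masking so that rows are
judged on their own residues; masking precedes realignment so that
suspicious residues cannot attract the aligner.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ambiguous_set` | `{B, Z, X, J, *}` | residue codes that disqualify a sequence. U and O are genuine (seleno-/pyrrolysine) residues and are kept. Configurable, since "ambiguous" has no universal definition. |
| `min_segment_coverage` | 0.5 | fraction of a segment's reference-occupied columns a row must cover with real residues. Discards half-missing domain copies without punishing modest truncations. |
| `indel_mask_window` | 2 columns | residues within this distance of a gap-run boundary are masked (`x`). A small symmetric window automates what is otherwise done by eye around indels; 0 disables. |
| `drop_policy` | `gap_fill` | a row discarded in one segment is gap-padded there but keeps contributing evidence elsewhere; `global` removes it everywhere. |
| gap open / extend | 10 / 1 (costs) | affine gap penalties of the built-in aligner, BLOSUM62 scoring, end gaps penalized. |
| `mode` | `strict` | unobserved ⇒ intolerant. `conservation` mode instead requires the column to be invariant or to have majority-residue frequency ≥ θ; unobserved at a variable column is then uninterpretable. |
| `conservation_threshold` θ | 0.95 | "highly conserved" cutoff used only in conservation mode. |
| `adjacency_window` w | 1 position | adjoining positions a carrier must match the reference at. Gaps and masks there count as mismatches — missing context cannot certify context identity. |
| `min_depth` | 10 residues | columns with fewer informative residues are unalignable. |
| `max_gap_fraction` | 0.5 | columns with more gaps than this (over all rows) are unalignable. |

Strict mode is the default because, in practice, a substitution absent from
a curated ortholog set is treated as damaging even when the position is
variable; conservation mode implements the narrower reading that only
conserved positions support an intolerance call. Both are exposed because
the choice is a genuine judgment call, and the summary report can fold the
unalignable class into uninterpretable (`--paper-compat`) for a three-way
accounting.

## Numerical and tie-breaking choices

- Reference positions are 1-based inclusive everywhere a user sees them;
  alignment columns are 0-based half-open internally.
- A segment's column span runs from the column of its start position to the
  column before the next segment's start, so insertion columns at a
  boundary belong to the left segment and slices tile the alignment
  exactly; the first segment also absorbs insertion columns before
  position 1. Reassembly of unmodified slices is therefore an exact
  round trip.
- The built-in aligner breaks dynamic-programming ties deterministically
  (diagonal, then gap-in-second-sequence, then gap-in-first) and the
  center-star merge processes sequences in input order, so outputs are
  bit-stable. Letters missing from BLOSUM62 (J, U, O, and the mask mark)
  are scored with the X column.
- Gap costs are `open + (k−1)·extend` for a run of length k, matching the
  convention of Biopython's `PairwiseAligner`, which serves as the
  independent scoring oracle in the test suite.
- Rooting for clade selection: the tree is rerooted on the edge above the
  paralog exemplars' most recent common ancestor (paralogs as outgroup).
  Internal nodes without a parseable support label are treated as
  qualifying when a `min_support` threshold is set.
- Degenerate inputs: an empty segment after filtering, a masked or absent
  reference row, overlapping domains, and ragged alignments are hard
  errors; a clade selection where only the reference itself excludes the
  paralogs returns the singleton set with a warning.

## Synthetic data

The generator emulates the statistical structure the method depends on:
invariant columns, variable columns with weighted residue pools (reference
residue dominant), per-row deletion runs, head/tail truncations, planted
ambiguous residues, divergent paralog rows (a fixed fraction of columns
redrawn from a disjoint pool, which makes them separable in the toy trees),
and species labels in which paralog-bearing proteomes are represented.
Defaults: 40 ortholog rows, 120 columns, 30% variable columns, deletion
rate 0.1, truncation fraction 0.1, ambiguity rate 0.05, 6 paralog rows at
divergence 0.4.

What it does **not** emulate: insertion columns (generated alignments keep
one column per reference position; insertion handling is exercised by
hand-built fixtures), realistic substitution processes (no rate matrices or
branch lengths), and correlated evolution between sites. Passing the
generator-truth tests therefore demonstrates that the implementation applies
its own rules exactly — not that those rules are well-calibrated for any
particular real protein family.

Expected verdicts for generated variants are computed by a straight-line
rule evaluator inside the synthetic module that shares no code with the
production classifier, so the comparison is a genuine dual-route check.

## Known limitations

- Curation is idempotent once masking has stabilized (verified
  byte-identical on truncation-only fixtures). When fresh interior indels
  are present, realignment can relocate gaps between passes and a repeated
  run may mask additional flanking residues; the pipeline is designed to be
  run once per input alignment.
- The coverage filter and masking window are surrogates for expert manual
  curation; there is no threshold that separates "erroneous" from merely
  divergent sequences.
- Carriers are counted per sequence, not per species; a species sampled
  twice can certify tolerance on its own. The presence-based rule makes
  this mostly harmless, but users with heavily redundant sequence sets
  should deduplicate upstream.
- Coordinates are tied to one reference isoform; mapping variants across
  isoforms is out of scope.
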