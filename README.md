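# varclade

Domain-wise curation of ortholog multiple sequence alignments and
conservation-based classification of missense variants.

## The problem

Clinical databases are full of missense variants of uncertain significance
(VUS). For a multidomain protein such as Dicer1 — where thousands of
catalogued substitutions fall outside the few known hotspots — automated
effect predictors are hampered by the alignments they are built on: paralogs
that are not functionally equivalent, low-quality and truncated sequences,
and misalignments that concentrate in long multidomain proteins.

`varclade` implements the alternative: build one careful, protein-specific
evidence set and read it directly.

1. **Ortholog selection.** From a gene tree of homologs, take the largest
   clade containing the reference sequence and excluding designated paralog
   exemplars (the paralogs act as the outgroup); optionally also drop
   sequences from species that still carry the paralog.
2. **Domain-wise refinement.** Partition the reference protein into its
   annotated domains and the non-domain stretches between them (initial,
   interdomain, terminal), slice the full-length alignment accordingly,
   discard sequences with poor coverage of a segment, mask residues
   adjacent to indels, realign every segment independently, and reassemble
   the full-length alignment.
3. **Classification.** For a variant `ref_aa` `pos` `alt_aa`, read the
   alignment column at `pos`:
   - *tolerant* — `alt_aa` occurs in at least one ortholog whose adjoining
     positions (±w, default w = 1) all match the reference: evolution has
     tested the substitution in an otherwise identical local context;
   - *uninterpretable* — `alt_aa` occurs, but only in sequences that also
     differ next door: the changed context may compensate;
   - *intolerant* — `alt_aa` is never observed (strict mode; an optional
     conservation mode restricts this call to columns whose majority
     residue frequency reaches a threshold θ, default 0.95);
   - *unalignable* — the column has too few informative residues or too
     many gaps to read at all.

The package ships the seven curated Dicer1 domain coordinates
(`src/varclade/data/dicer1_domains.tsv`), which partition the full-length
protein into 15 alternating domain/non-domain segments, and a synthetic
data generator (`varclade.synthetic`) that produces alignments, gene trees
and variant sets with known ground truth, so the whole pipeline is testable
without any network access.

## Worked example

A complete run on generated data:

```sh
varclade simulate --seed 7 --n-rows 25 --length 120 --paralogs 4 \
    --n-variants 30 --out-dir sim
# wrote synthetic fixture (29 rows x 120 cols) to sim

varclade clade --tree sim/tree.nwk --ref ref \
    --paralogs par01,par02,par03,par04 --out ortho_ids.txt
# 25 sequences selected -> ortho_ids.txt

printf 'name\trule_id\tstart\tend\nN-lobe\tSYN001\t21\t60\nC-lobe\tSYN002\t81\t110\n' \
    > domains.tsv
varclade curate --msa ortho.fasta --domains domains.tsv --ref ref \
    --out refined.fasta --report curation.tsv
# 5 segments processed; refined MSA 24 rows x 120 cols -> refined.fasta

varclade classify --msa refined.fasta --ref ref \
    --variants sim/variants.tsv --out calls.tsv --summary summary.json
# {"error": 0, "intolerant": 24, "tolerant": 6, "unalignable": 0, "uninterpretable": 0}
```

(`ortho.fasta` is the simulated alignment restricted to the ids in
`ortho_ids.txt`.) The two domains plus their flanks give 5 segments; one of
the 25 selected rows carries an ambiguous residue and is removed during
curation, leaving 24. Of the 30 simulated variants, 6 are substitutions the
generator actually planted in clean-context orthologs (tolerant) and 24
were never emitted at their column (intolerant). The per-variant table
records the evidence behind each call:

```
label   pos  ref  alt  verdict     rule                    depth  gap_fraction  observed_set  carrier_count  passing_carriers
var000  87   R    H    INTOLERANT  unobserved              22     0.0833        R             0
var001  29   H    M    TOLERANT    observed_clean_context  23     0.0417        FHM           3              orth07
```

`var001` is tolerant because three sequences carry the M, and at least one
of them (`orth07`) matches the reference at both adjoining positions.

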