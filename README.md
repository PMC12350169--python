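# csvarc

Assembly-based structural variant discovery and haplotype analytics for
haplotype-resolved genome assemblies, built around five pieces:

1. **Variant calling from alignments** — SNVs, indels and SVs (>= 50 bp) from
   the CIGARs of haplotype-to-reference alignment records (PAF with `cg:Z`),
   both *within* a record (`X`/`I`/`D` runs) and *between* query-consecutive
   records (target gap -> DEL, query gap -> INS, inverted record -> INV,
   target overlap of an inverted record -> INVDUP), with query-overlap
   trimming and exclusion-track filtering (CenSat-style repeats, telomeres).
2. **Complex-SV (CSV) resolution** — a directed acyclic graph with alignment
   records as nodes and variants connecting them as edges; each edge costs a
   junction-opening penalty plus per-variant costs, each node credits its
   matched bases, and the minimum-cost source-to-sink path (single-pass
   relaxation in topological order, O(N+E); a literal Bellman–Ford mode is
   provided) selects the accepted variants.  Multi-junction events between
   anchor alignments are named by their ordered token signature, e.g.
   `DEL-INV-DEL` or `INVDUP-INV-INVDUP` (INVDUP = a duplicated inversion,
   one copy in each orientation).
3. **Non-redundant population merging** — greedy, seed-based merge under 50%
   reciprocal overlap and 80% sequence identity (`nr::ro(0.5):match(0.8)`),
   allele frequencies with missing-haplotype exclusion, discovery curves and
   per-caller support.
4. **Haplotype quality evaluation** — windowed variant QV
   (`-10·log10(bp_changes / (2·window_size))` per 1-Mb window, with a >20-bp
   error counter), Merqury-style k-mer QV and completeness, haplotype
   availability QV against a reference panel, parental support from
   contig-to-contig CIGARs, and telomere-to-telomere status classification.
5. **Centromere analytics** — live-HOR array lengths, centromere dip region
   (CDR) detection from binned CpG methylation (5-kb bins, strictly below the
   regional median, merged runs > 50 kb), di-CDR classification (two CDRs
   more than 80 kb apart) and mobile-element placement relative to CDRs.

Everything runs on synthetic diploid genomes from the built-in `simdata`
generator, which implants SNVs/indels/SVs and CSV templates on a seeded
reference, emits exact split alignments derived from the same event ledger,
and simulates alpha-satellite annotations and methylation tracks — so every
pipeline stage can be validated against ground truth.  It is aimed at
developers of assembly-based variant-calling and centromere-analysis
pipelines who need a tested, deterministic reference implementation of these
procedures at desk scale.

## Worked example

Simulate a diploid-style haplotype carrying 20 SNVs, 4 insertions, 4
deletions and one `DEL-INV-DEL` complex event (segments 10 kb / 20 kb /
10 kb at position 100,000 of a 300-kb chromosome), then call and resolve:

```bash
csvarc simdata make --seed 7 --out-dir demo --chrom-length 300000 \
    --snv 20 --ins 4 --dels 4 --csv-template DEL-INV-DEL \
    --csv-start 100000 --ploidy 1
csvarc resolve --paf demo/h1.paf --ref demo/reference.fasta \
    --query demo/h1.fasta --out-tsv demo/csv.tsv
```

which prints

```
wrote reference + 1 haplotype(s) to demo
1 complex + 28 simple -> demo/csv.tsv
```

and `demo/csv.tsv` contains

```
chrom   start   end     signature    junction_count  variant_ids
chr1    100000  140000  DEL-INV-DEL  2               chr1-100000-DEL-10000,chr1-110000-INV-20000,chr1-130000-DEL-10000
```

Read: the resolver found one complex event spanning reference positions
100,000–140,000 whose optimal path crosses two repair junctions; the ordered
member variants are a 10-kb deletion, a 20-kb inversion and a second 10-kb
deletion — exactly the implanted template, at exact coordinates.  The 28
simple calls (the implanted SNVs and indel-class/SV-class insertions and
deletions; the three SV-class members of the complex event are reported
inside it, not double-counted) go to the ordinary callset; `csvarc call`
writes them as a variant table with dual reference/query coordinates.

The same operations are available as a library (`csvarc.simdata`,
`csvarc.align_variants`, `csvarc.csv_resolver`, `csvarc.merge_popgen`,
`csvarc.qv_eval`, `csvarc.centromere`); see `docs/methods.md` for the models,
parameters and numerical choices.

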