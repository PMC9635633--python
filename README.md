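# haplokit

Analyses for repeat-dense, multigene-family MHC-like haplotypes:

- **io_core** — FASTA / GFF3 / RepeatMasker `.out` / aligned-FASTA readers and
  writers, CDS translation, shared 1-based-inclusive coordinate model.
- **synthetic** — a haplotype simulator with exact ground truth: gene-family
  members every ~10 kb, interspersed repeats to a target fraction (default
  40%), and multi-kilobase segmental duplications implanted in direct or
  inverted orientation as full or partial copies. Also generates
  controlled-polymorphism protein alignments and gel-level "observed" band
  ladders (with optional dropout regions emulating unclonable segments).
- **census** — locus census by contig and family with pseudogene subtotals,
  gene density (loci/Mb, half-up), repeat summarization with grouped
  totals, boundary-gap and contig-size arithmetic, and locus typing by exact
  predicted-protein identity.
- **variability** — Wu–Kabat variability index per alignment column
  (`VI = k / (n_max / N)`, gaps excluded), polymorphism calls at an inclusive
  threshold (default 6), and cross-group comparison of polymorphic position
  sets in reference-row numbering.
- **southern** — virtual Southern blot: exact-site restriction digest
  (TaqI `T^CGA` built in), probe hybridization by stringent local alignment
  (≥80% identity over ≥60 bp, either strand), single-linkage band
  co-migration (5% relative tolerance), and greedy one-to-one matching of
  predicted vs observed ladders.
- **dotplot** — exact k-mer anchors (k = 21) in both orientations, diagonal
  chaining into forward/inverted segment chains, duplicated-block calling
  with per-copy orientation and completeness, TSV + PNG export.
- **selection** — Nei–Gojobori (NG86) pairwise dN/dS with pathway averaging
  and Jukes–Cantor correction, per-segment medians over a named codon
  partition, p-distance matrices, and Saitou–Nei neighbor joining with
  deterministic tie-breaking and Newick output.

## CLI

All stages are wired through one entry point; every subcommand writes a
`manifest.json` with parameters and input hashes, and all randomness flows
from `--seed`:

```bash
haplokit simulate --config cfg.json --seed 17 --outdir sim/
haplokit census --gff sim/features.gff3 --rmout sim/repeats.out \
    --fasta sim/contigs.fa --outdir census/
haplokit vi --msa alignment.fa --threshold 6 --outdir vi/
haplokit southern --fasta sim/contigs.fa --probe sim/probe.fa \
    --enzyme TCGA:1 --observed sim/observed_bands.tsv --outdir southern/
haplokit dotplot --fasta sim/contigs.fa --k 21 --min-block 20000 --outdir dp/
haplokit dnds --msa codons.fa --partition segments.json --outdir dnds/
haplokit nj --msa alignment.fa --outdir nj/
haplokit demo --seed 7 --outdir demo/   # end-to-end with truth recovery
```

The dN/dS partition file maps segment names to 1-based inclusive codon
ranges, e.g. `{"alpha1_helix": [[50, 86]], "alpha2_helix": [[140, 176]]}`;
unassigned codons form the `remainder` segment.

## Conventions

- Coordinates are 1-based inclusive throughout (GFF3 convention); the gap
  between adjacent features is `start2 − end1`.
- Percentages are computed from unrounded bp sums and rounded half-up to
  2 dp; grouped repeat rows additionally report the printed-table convention
  of summing the already-rounded member rows (`percent_table`).
- Sequences may contain `N`; digest sites and k-mers spanning `N` are
  skipped.
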