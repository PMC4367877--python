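# Methods

## Coordinates and distance

All coordinates are 1-based and inclusive at both ends, the GenBank and
RepeatMasker convention; the BED export converts to 0-based half-open at the
boundary. Distance between a TE copy and a gene is edge-to-edge: the number
of bases strictly between the two intervals, so adjacent features are at
distance 0 and an overlapping pair is handled as a separate ("within") case.
Midpoint-based distance was the alternative; edge-to-edge keeps "inserted
within a gene" cleanly disjoint from "proximal" and is what interval tools
generally report.

## Filters

The size/similarity filter is inclusive at both bounds (slider-style closed
intervals). Similarity defaults to the 50–100% window; size bounds default to
the observed minimum/maximum of the copies being filtered, i.e. a no-op until
the user narrows them. Filtering is idempotent and order-preserving.
Overlapping and nested hits are never merged or defragmented: fragments are
biologically informative (old, decayed families show sub-consensus-length
fragments) and merging would silently change copy counts.

## Region categories

Each copy gets exactly one category, with precedence:

1. any gene overlap (≥ 1 bp) → **ExonIntronUTR** (a single category; exonic
   vs intronic insertion is not distinguished, since gene spans — outermost
   annotated coordinates — are used as gene bodies);
2. otherwise, among flanking genes at gap ≤ *D* (default 3000 bp,
   inclusive: a gap of exactly 3000 is proximal, 3001 is not), the smallest
   gap wins; the copy is **ProximalPromoter** on the gene's 5' side and
   **Proximal3End** on its 3' side, where "side" applies the gene's strand
   (unstranded genes are treated as forward). An exact gap tie between the
   two flanks resolves to ProximalPromoter, the biologically emphasized
   case;
3. otherwise **Intergenic**.

Neighbor search considers features of kind `gene` and `pseudogene`
(configurable); exons and UTRs are parts of genes, not neighbors. In the
master table the `relation` column is purely chromosomal (left/right/within)
while `region_category` is strand-aware, so the two senses of
"upstream/downstream" never mix in one column.

## Distribution panels

* Occurrence curves split a chromosome into equal-width windows (the last
  absorbs the integer remainder) and count each copy once, in the window
  containing its midpoint — a copy straddling a window edge is never double
  counted. The window count is a free parameter (CLI `--bins`, default 100).
* Genome frequency normalizes each family by its own genome-wide copy total
  (so each family's percentages sum to 100), set against chromosome length
  shares of the genome. Pooling all families into one denominator would make
  family curves incomparable across selections.
* Size histograms span the observed (or user-set) size range in equal bins,
  last bin right-closed, out-of-range copies excluded (default 40
  intervals).
* Coverage proportions use the per-chromosome base-pair union of each item
  class, divided by total genome length; classes overlap freely and are not
  expected to sum to 100%.
* Distance histograms within a proximal category span [0, *D*] in
  left-closed equal bins (last right-closed; default 20), with bin 0 flush
  against the gene boundary.

## GO summaries

`gene2go` rows are optionally taxon-filtered; evidence codes are not
filtered. Annotations project onto a slim vocabulary by ancestor closure
over `is_a` and `part_of` edges (go-basic is acyclic over these; cycles are
rejected at load). Per gene, slim terms are counted as a set, so redundant
annotations to one branch cannot inflate a slice. Genes lacking a numeric
GeneID, GO terms, or any slim hit land in an explicit `unannotated` bucket;
proportions (including `unannotated`, and `other` after the 1% display
pooling) always sum to 1. Three slims are supported: a packaged generic list
(`data/generic_slim_synthetic.txt`, a synthetic stand-in of broad well-known
terms — regenerate from the EBI generic slim for production use), and
TreeLevel1/TreeLevel2 derived from the DAG itself (children of the namespace
roots, and their children, made disjoint by construction).

## Cross-organism couples

A TE–gene couple is (family, case-insensitive gene name, relation side); its
X is the number of distinct organisms containing it at least once. An
optional two-column ortholog map (gene name → ortholog group) replaces name
matching, since gene names rarely align across species. Rows whose couple
falls below `--min-organisms` are dropped from the master table.

## Synthetic data generator

The generator emulates the coordinate structure of an annotated genome plus
a repeat screen. Genes (default 100 per 2 Mb chromosome, lengths uniform
1–5 kb) sit on a jittered regular grid whose spacing is validated to leave,
between any two genes, room for a proximal zone of *D* bp on each side plus
an intergenic zone; TE copies are then placed *constructively* per
pre-assigned category — inside a random gene, at a uniform gap in [0, *D*]
off a random gene's 5' or 3' boundary, or in the middle zone of a random
inter-gene gap — so planted category proportions are exact by construction
and closure tests need no statistical tolerance. Defaults: 2 chromosomes of
2 Mb, 3 families × 200 copies (sizes uniform 100–800 bp, similarities
uniform 80–100% at 0.1% resolution so RepeatMasker divergence round-trips
exactly), planted mix 0.10/0.25/0.25/0.40. The toy ontology is a three-level
tree (root → 6 slim terms → 18 leaves); each gene is annotated to 1–2 random
leaves with probability 0.8.

What the generator does **not** emulate — and hence what passing closure
tests do not show about real data: nucleotide sequence, TE nesting and
fragmentation, centromeric TE clustering and pericentromeric gene scarcity,
chromosome-scale length heterogeneity, and multi-isoform gene structure.
Parsers and panel arithmetic are exercised realistically; biological
conclusions about real genomes still require real inputs.

One pseudo-random stream per file kind (genes, TE copies, ontology), each
derived from the single seed, keeps outputs byte-stable when a file kind is
added. Infeasible requests (within-gene copies with zero genes, chromosomes
too crowded to respect the planted categories) fail loudly at generation.

## Numerical and degenerate-input choices

* Percentages and proportions are plain double-precision ratios; conservation
  invariants (family percentages sum to 100, category and GO proportions sum
  to 1) hold to 1e-9.
* TSVs print floats at 6 decimals; determinism is byte-level for identical
  inputs and options.
* Empty inputs are legal everywhere: zero copies give empty distributions
  (no division by zero), a gene-free chromosome classifies everything
  Intergenic, a copy with no genes on its chromosome yields one placeholder
  master-table row with `relation = none`.
* A size histogram of a single size expands its range by ±0.5 bp to form one
  meaningful bin.
* Gap ties in neighbor search break toward the smaller start coordinate.

## Problem sizes

The default synthetic study (2 × 2 Mb, 200 genes, 600 copies) runs the full
pipeline in about two seconds; the multi-seed conservation sweeps use a
2 × 400 kb / 40-gene / 150-copy layout, which preserves every geometric
constraint of the default layout at a fraction of the cost.

## Known limitations

* Promoters are approximated by gene-span boundaries, not annotated TSSs.
* GFF3/GTF annotation input is not implemented.
* The AB-BLAST and Repet readers accept one documented column map each and
  reject other sub-dialects rather than guessing.
* GO summaries are descriptive proportions; no enrichment statistics are
  computed.
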