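# Methods

## The curation model

`refcure` treats a barcode reference dataset as an ordered collection of
records, each an accession with a seven-rank lineage
(kingdom…species) and an IUPAC DNA sequence. Curation is a fixed
sequence of five deterministic filters followed by optional manual
steps. The order matters and is not configurable: each filter's
bookkeeping (removed vs retained per stage) is defined relative to the
output of the previous one, which is how the summary report stays
interpretable.

### Fungal screen (filter 1)

A SINTAX-style bootstrap k-mer classifier. For a query of length L and
k = 8, the query's distinct k-mers are subsampled (32 draws with
replacement) in each of 100 bootstraps; the reference sharing the most
sampled k-mers wins the bootstrap and votes for its full lineage, ties
going to the smallest accession. Per-rank confidence is the fraction of
all bootstraps voting for the winning name at that rank, tallied
hierarchically (at each rank only lineages extending the winner of the
previous rank compete), so confidence is non-increasing from kingdom to
species by construction.

Two choices matter here:

* **Uninformative bootstraps cast no vote but stay in the
  denominator.** A bootstrap whose sample shares no k-mer with any
  reference says nothing; letting it force a top hit would let
  completely unrelated queries accumulate spurious confidence.
* **The removal decision is taken at genus rank** (configurable).
  Against a fungal-only reference the kingdom prediction is degenerate
  — Fungi is the only kingdom on offer — so "kingdom = Fungi with
  confidence ≥ 0.90" would flag nothing meaningful or everything. A
  record is removed only when the classifier is confident (≥ 0.90)
  about a specific fungal *genus*; unrelated plant sequences share a
  few k-mers with some fungal reference by chance but never
  concentrate 90% of bootstraps on one genus.

Per-record bootstrap seeds are derived as `crc32(accession) XOR
base_seed`, making classifications reproducible and independent of
dataset order.

### Non-target screen (filter 2)

Global affine-gap alignment (match +2, mismatch −4, gap open −20, gap
extend −2; the first gapped position costs the open penalty) against a
trusted set of marker exemplars, one per family. Identity is matching
columns divided by alignment columns excluding terminal gaps — the
analog of the usual usearch/vsearch definition, so a partial-length
marker sequence is not penalised for its missing flanks. Records whose
best hit is below 70% identity (inclusive threshold: exactly 70% is
kept) are removed. Ties in the best-hit search go to the smallest
accession, making the result invariant under reference permutation.

The dynamic programming is delegated to Biopython's PairwiseAligner;
among co-optimal alignments its first traceback is used. Because
co-optimal tracebacks of (a, b) and (b, a) can differ in their column
layout, the pair is first put into a canonical orientation so identity
is exactly symmetric. One consequence of excluding terminal gaps is
worth knowing: a sequence that is a clean prefix/suffix of another
scores identity 1.0 despite unequal lengths. That is intended — it is
how partial marker sequences match full-length ones.

### Incomplete taxonomy (filter 3)

A lineage is incomplete if any rank is empty or the species epithet is
a placeholder ({sp, spp, cf, aff, x, hybrid, unclassified,
environmental, indet}, case-insensitive, trailing dot ignored,
configurable). Such records cannot support species-level barcoding and
are removed, with the offending rank(s) named in the report.

### Chlorophyta screen (filter 4)

Any record with any rank equal (case-insensitively) to "Chlorophyta"
is removed. Green-algae records are out of scope for a vascular-plant
reference and their mislabelled members interfere with classification.

### Intraspecific drop-out ladder (filter 5)

Within each species having at least `min_species_n = 5` sequences
("more than four"), all-against-all global alignments give each member
the median identity to the other members. Three modes:

* **A** — single pass: remove every member with median < 97%.
* **B** — walk the ladder 50, 75, 80, 85, 90, 92.5, 95, 97%; at each
  rung remove members with median (recomputed over survivors) strictly
  below the rung; stop when fewer than two members remain.
* **C** (default) — as B, but skip the rung and stop the ladder if
  applying it would leave fewer than ⌈0.5 × n⌉ of the species' initial
  n members. A "remaining"-basis variant (stop if the rung would remove
  ≥ 50% of the *currently remaining* members) is selectable; the
  initial-basis reading is the default.

Numerical conventions: removal uses strict inequality with a 1e-9
guard, so a median within numerical noise of a rung is *not* removed;
medians over an even count are the mean of the two central values;
pairwise identities are computed once per species and cached — "median
recomputation" re-aggregates the cached matrix over the surviving set.
A species driven below two survivors stops its ladder; a lone survivor
is retained. Species with fewer than five members are never touched.

Mode A is the most aggressive and C the most conservative on real
species structure (a tight conspecific cluster plus distant mislabeled
members), and the tests assert retained(A) ≤ retained(B) ≤ retained(C)
on such sets. This ordering is *not* a theorem for arbitrary symmetric
identity matrices: a member whose initial median is high because of a
few very close partners can lose those partners during the iterative
ladder and fall below the final rung, so a pathological matrix can make
B remove more than A. The oracle-equivalence tests therefore run on a
broad adversarial matrix generator (where implementation and
brute-force simulation must agree exactly, and do), while the ordering
invariant is asserted on cluster-structured sets.

### Manual steps and subsetting

Manual list curation parses 4-field semicolon-delimited entries;
removals delete records, corrections rewrite genus/species from the
corrected binomial and, when an offline 7-column taxonomy TSV resolves
it, all higher ranks too; otherwise the record keeps its old higher
ranks and is flagged `needs_review`. Later entries override earlier
ones (multiple contributor files), with a logged conflict. A
single-token corrected name sets species to `Genus_sp`, which
deliberately fails the completeness check rather than pretending to
species-level knowledge.

Manual addition appends records with generated `MANUAL_NNNN` accessions
and `source=manual`; it never mutates existing records. Geographic
subsetting matches exact binomials after normalisation (case, spaces vs
underscores, authorship stripped, infraspecific ranks truncated);
synonym resolution is out of scope. Coverage percentages round half-up
to integers, as do the loss percentages of the summary report.

## The synthetic-fixture generator

The generator emulates the shape of a freshly downloaded marker
dataset at desk scale, with defaults of 50 clean species (clusters of
2–10 sequences, 300 nt) and planted contaminants: 5 fungal, 10
non-target, 3 incomplete, 2 Chlorophyta, 4 intraspecific outliers.

* References are independent random sequences (one exemplar per plant
  family; 20 fungal references) with enforced margins: within-set
  pairwise identity < 0.7, fungal-to-trusted < 0.6.
* A clean species derives a base sequence from its family exemplar at
  5% substitution, then members from the base at 0.5% each, so
  within-species medians sit near 0.99 — safely above the ladder's top
  rung — while every member still finds its exemplar at ≥ 0.78
  identity, safely above the 70% floor.
* Planted fungal records are fungal references mutated by 1% wearing
  complete plant lineages; planted non-targets are fresh random
  sequences (best trusted identity asserted < 0.62); planted outliers
  replace one member of a ≥ 5-sequence species with another family's
  sequence (median to its host siblings asserted < 0.62); incomplete
  and Chlorophyta plants are exemplar-derived so they survive filters
  1–2 and are caught by their own filter.

Every margin is re-measured at generation time with the package's own
aligner and classifier, and offending pieces are regenerated (bounded
retries), so the planted truth is unambiguous: the pipeline must remove
exactly the manifest accessions, stage by stage. Mutation is
substitution-only by default (an indel knob exists but defaults to 0),
which keeps identity arithmetic predictable.

What the fixtures do **not** emulate: real ITS2 length variation and
secondary structure, rate heterogeneity along the sequence, indel-rich
divergence, shared homology between plant families, chimeras, and the
name-synonymy mess of real checklists. Passing the planted-recovery
tests therefore demonstrates that the filters implement their decision
rules exactly — not that the thresholds themselves are optimal for any
particular real marker; those thresholds are taken as given.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on the
default 50-species fixture across five seeds (~320 records each),
compare the ladder against a brute-force simulation on 200 random
species sets (n ≤ 8), and check alignment optimality by exhaustive
enumeration on sequence pairs up to length 6 — sizes chosen so the
whole verification runs in a couple of minutes on one core while still
exercising every code path at realistic per-species scale. All
randomness flows through explicit numpy generators seeded from a single
integer; no global random state is used anywhere, and identical seeds
reproduce identical datasets, classifications and reports byte for
byte.

## Known limitations

* The aligner emulates usearch/vsearch conventions but is not a
  bit-for-bit reimplementation; scoring parameters and the identity
  definition are configurable precisely because other tools' defaults
  differ.
* The bootstrap classifier is a faithful SINTAX-style method but not a
  clone of any specific implementation; its absolute confidences depend
  on k, subsample size and reference composition.
* Exact-binomial matching in geographic subsetting under-counts
  coverage when checklist and dataset use different synonyms.
* Filter 5 is not idempotent in general (re-running the ladder on its
  own output can remove more once safeguarded members are gone);
  filters 1–4 are idempotent and tested as such.
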