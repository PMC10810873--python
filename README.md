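# refcure

Curation toolkit for DNA-barcode reference datasets.

Taxonomic identification by (meta)barcoding — matching marker sequences
such as the plant ITS2 region against a reference collection — is only
as good as the reference dataset behind it. Sequences pulled from public
repositories carry fungal contaminants sequenced instead of their host
plant, off-target loci deposited under the marker's name, incomplete or
placeholder taxonomies, green-algae records inside "vascular plant"
collections, and misidentified specimens that inflate apparent
intraspecific variability. `refcure` implements a reproducible, fully
offline curation workflow for taxonomy-annotated FASTA datasets, aimed
at anyone building or maintaining barcode reference collections.

## What it does

**Automated curation** applies five filters in fixed order:

1. *Fungal screen* — a bootstrap k-mer classifier (SINTAX-style)
   classifies every record against a fungal reference set; records
   assigned kingdom Fungi with confidence ≥ 0.90 at genus rank are
   removed.
2. *Non-target screen* — records whose best global-alignment identity
   against a trusted marker reference set falls below 70% are removed
   as off-target loci.
3. *Incomplete taxonomy* — records with empty ranks or placeholder
   species epithets (`sp.`, `cf.`, …) are removed.
4. *Chlorophyta screen* — green-algae records are removed from the
   vascular-plant collection.
5. *Intraspecific drop-out ladder* — for each species with ≥ 5
   sequences, all-against-all global alignments give each member a
   median identity m_i to the other members. An increasing threshold
   ladder t ∈ {50, 75, 80, 85, 90, 92.5, 95, 97}% is walked; at each
   rung, members with m_i < t (recomputed over the survivors) are
   dropped — subject, in the default mode C, to a safeguard that keeps
   at least ⌈n/2⌉ of the species' initial n sequences. Mode A (single
   pass at 97%) and mode B (full ladder, no safeguard) are available
   for comparison.

**Manual list curation** applies community-contributed semicolon-delimited
corrections (`accession;wrong_name;corrected_name;curator`; an empty
corrected name removes the record), **manual sequence addition** ingests
plain FASTA with species-name headers and resolves lineages from an
offline taxonomy table, and **geographic subsetting** reduces a global
dataset to a flora checklist and reports coverage.

A seeded synthetic-fixture generator produces reference sets and
"dirty" datasets with planted contaminants of every class plus a
ground-truth manifest, so the entire workflow is testable without any
network access.

## Worked example

Generate a small synthetic bundle and curate it:

```sh
refcure fixtures --seed 42 --out-dir demo --clean-species 8 \
    --fungal 2 --nontarget 2 --incomplete 1 --chlorophyta 1 --outliers 1
refcure curate --input demo/dirty.fasta --fungal-ref demo/fungal_ref.fasta \
    --trusted-ref demo/trusted_ref.fasta --out-prefix demo/run --seed 42
cat demo/run.summary.tsv
```

```
step	removed	retained_sequences	retained_species
start		34	14
fungal	2	32	12
non_target	2	30	10
incomplete_taxonomy	1	29	9
chlorophyta	1	28	8
intraspecific	1	27	8
total	7	27	8
sequence_loss_percent	21		
species_loss_percent	43		
```

The 34-record input carried 8 clean species plus 7 planted
contaminants; each filter removed exactly its own class (compare
`demo/manifest.json`), leaving the 27 clean sequences. The removed-
accession report names the evidence per record, e.g.

```
accession	stage	reason	detail
SYN00008	fungal	classified_as_fungal	genus=Fungen04;confidence=1.00
```

The same operations are available as a library:

```python
from refcure import CurationConfig, run_pipeline, load_taxfasta

ds, _ = load_taxfasta("demo/dirty.fasta")
fungal, _ = load_taxfasta("demo/fungal_ref.fasta")
trusted, _ = load_taxfasta("demo/trusted_ref.fasta")
curated, report = run_pipeline(ds, fungal, trusted, CurationConfig(seed=42))
```

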