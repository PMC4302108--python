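# tfhot

Occupancy-based analysis of multi-factor ChIP-seq binding landscapes:
classification of merged binding regions into **singletons**,
**combinatorials** and **transcriptional hotspots**, followed by
characterization of the three groups across cell types.

## The problem

When ChIP-seq peak sets for many transcription-related factors (TFs,
cofactors, remodellers) are available in one cell type, their binding
events can be merged and each merged region scored by *occupancy* — the
number of distinct factors bound there. Occupancy spectra are strongly
skewed: roughly half of all regions are bound by a single factor, while a
small fraction (≈0.1–2%) is bound by most of the assayed factors. These
high-occupancy regions ("hotspots", bound by more than five factors under
the default rule) behave like cell-type-specific enhancers: they carry
high tag counts, sit near cell-type-specific genes, are enriched for key
TF motifs and pioneer-factor binding, and show a bimodal enhancer-mark
(H3K4me1-like) aggregate profile indicating a nucleosome-depleted center.

`tfhot` implements that full analysis as a tested library and CLI:

* **occupancy** — merge per-factor peak sets (≥1 bp overlap), count
  distinct factors, classify: occupancy 1 → singleton, > 5 (configurable)
  → hotspot, otherwise combinatorial; occupancy spectra; consensus peaks
  across replicate experiments.
* **annotation** — feature classes (promoter −1 kb/+100 bp, 5′/3′ UTR,
  exon, intron, intergenic) and target genes (promoter/gene-body hit,
  else nearest gene within 50 kb).
* **matrices** — unified binary locus × (cell type, group) and gene ×
  (cell type, group) matrices; column clustering by complete linkage on
  `d = 1 − φ`, where φ is the Pearson correlation of binary columns.
* **signal** — peak height as the tag count in a 400-bp summit-centered
  window; two-sided Mann–Whitney U group comparisons (exact for small
  tie-free samples); 10-kb aggregate profiles with mono-/bimodal calls.
* **enrichment** — hypergeometric region-set and gene-set enrichment
  (both tails), exact IUPAC consensus motif scanning on both strands,
  GC-content control, and pioneer-factor detection (> 90% of hotspots
  bound).
* **synthetic** — a landscape generator with planted occupancy tiers,
  heights, profile shapes, motifs, annotations, genes and DE lists, plus
  a full truth manifest, so every stage is testable without downloads.

## Worked example

Generate a single-cell-type landscape (8 factors, 1,000 loci: 52%
singletons, 47% combinatorials, 1% hotspots) and run the stages:

```sh
tfhot simulate --config sim.yaml --out land
tfhot classify --peaks land/manifest.tsv --cell-type ES --out es
```

prints the group summary:

```
{"counts": {"combinatorial": 470, "hotspot": 10, "singleton": 520},
 "fractions": {"combinatorial": 0.47, "hotspot": 0.01, "singleton": 0.52},
 "total_regions": 1000}
```

i.e. the classifier recovers the planted tier sizes exactly, and
`es.spectrum.tsv` shows the skewed occupancy spectrum (52% of regions at
occupancy 1, 0.2% at occupancy 7). Peak heights separate the groups in
the planted direction:

```sh
tfhot signal --regions es.regions.bed --tags land/ES.tags.bed --out es
# es.mwu.tsv:
# group_a        group_b    n_a  n_b  U         p_value
# combinatorial  hotspot    470  10   610.0     6.1e-05
# combinatorial  singleton  470  520  225348.5  9.2e-117
```

and the aggregate enhancer-mark profile is bimodal at hotspots but
monomodal at singletons:

```sh
tfhot profile --regions es.regions.bed --signal land/ES.signal.bedGraph --out es
# {"combinatorial": {"call": "monomodal", ...},
#  "hotspot": {"call": "bimodal", "left_peak_bin": 44, "right_peak_bin": 55},
#  "singleton": {"call": "monomodal", ...}}
```

The bimodal call reports flank maxima ~500 bp either side of the region
center (bins 44 and 55 of 100 over the 10-kb window) — the
nucleosome-displacement signature expected at multi-factor-bound
enhancers. `tfhot pioneers` then tabulates per-factor hotspot occupancy
with the strict > 90% pioneer flag, and `tfhot run --config run.yaml`
executes all stages end to end into a single `report.json`.

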