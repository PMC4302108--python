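# Methods

## Model and procedure

The analysis treats a cell type's regulatory landscape as the union of
all called binding events of its assayed transcription-related factors.
Peaks are merged wherever they share at least one base; each merged
region's *occupancy* is the number of distinct factors contributing at
least one peak (a factor with several peaks in a region counts once).
Regions are then partitioned by occupancy:

* **singleton** — occupancy 1;
* **hotspot** — occupancy ≥ `hotspot_min` (default 6, encoding a
  "more than five factors" rule);
* **combinatorial** — everything in between.

The rule is deliberately absolute rather than scaled to the number of
assayed factors (6–21 per cell type in the emulated study design); the
`hotspot_min` parameter and the occupancy-spectrum operation support
re-deriving a different threshold if desired.

All coordinates are 0-based half-open (BED convention). Merging requires
a strict ≥1 bp overlap: bookended intervals (`[100,200)`, `[200,300)`)
are not joined, and the optional `merge_gap` (bp, default 0) relaxes this
for assays with fragmented peak calls. Consensus peaks across replicate
experiments are computed per base: a base belongs to the consensus iff at
least `min_sets` distinct experiments cover it, and maximal runs of such
bases are reported. This per-base semantics is stricter than merging
whole regions and matches an enumeration oracle exactly.

Downstream characterization:

* **Feature classes.** Each region is classified at its midpoint with the
  priority promoter > 5′ UTR > 3′ UTR > exon > intron > intergenic, so
  wide merged regions still receive a single call. The promoter is
  [TSS−1000, TSS+100) on the plus strand, mirrored on the minus strand.
  Genes without exon structure contribute their whole body as one exon.
* **Target genes.** A region overlapping a promoter window or gene body
  is assigned to that gene; otherwise the nearest gene by edge-to-edge
  distance within 50 kb (either side) is taken; ties break to the
  lexicographically smaller gene id; farther regions stay unassigned.
* **Matrices and clustering.** Per-cell-type regions are unified across
  cell types by the same ≥1 bp-overlap merge. The binary peak matrix has
  one row per unified locus and three columns (singleton, combinatorial,
  hotspot) per cell type; the gene matrix is the analogue at gene level.
  Column similarity is the Pearson correlation of 0/1 columns (the phi
  coefficient); zero-variance columns get similarity 0 (warned) so
  clustering always completes. Columns are clustered by complete linkage
  on `d = 1 − φ`, implemented directly so that equal-distance candidates
  merge in deterministic lexicographic label order; the tree is emitted
  as Newick with branch lengths `parent height − child height`.
* **Peak height.** The tag count (5′ ends, no fragment extension or
  shifting) in the half-open 400-bp window centered on the region summit
  (mean of member-peak summits; midpoint where no summit exists). Groups
  are compared by the two-sided Mann–Whitney U test: exact enumeration
  when min(n, m) ≤ 8 and the pooled sample is tie-free, otherwise the
  normal approximation with tie and continuity corrections.
* **Aggregate profiles and modality.** Signal (per-base coverage or
  tags) is binned over a 10-kb window (100-bp bins) around each region
  center and averaged column-wise. The aggregate is smoothed by a 3-bin
  centered moving average and called **bimodal** when the two highest
  local maxima flank the center (each ≥ `min_separation/2` = 100 bp
  away) and the valley between them dips to ≤ (1 − `min_prominence`) =
  90% of the lower maximum; **monomodal** when the single global maximum
  contains or adjoins the center; otherwise **ambiguous** (including
  all-zero profiles). The dip rule is this package's operationalization
  of "bimodal" — density-plot figures in the literature do not define
  one — and both knobs are exposed. The call is scale-invariant.
* **Enrichment.** Region-set and gene-set enrichment use the
  hypergeometric distribution: with K of N universe items positive, the
  enrichment p of k positives among a group of n is the upper tail
  P(X ≥ k), depletion the lower tail P(X ≤ k); both are always reported
  (they share the point mass, so they sum to ≥ 1). The universe for
  region overlap is the full set of classified regions of the cell type
  and "overlap" means ≥1 bp. Motifs are exact IUPAC consensus matches
  (no PWM, no mismatches) counted over both strands of uniform 400-bp
  summit-centered windows; an `N` in the genome is matched only by motif
  letter `N`. Group contrasts use the pooled two-sided two-proportion
  z-test, with per-sequence GC content (N excluded from the denominator)
  compared by Mann–Whitney as a composition control. A factor is flagged
  as a candidate pioneer iff it overlaps strictly more than 90% of the
  cell type's hotspots. Raw p-values are reported; a Benjamini–Hochberg
  helper exists but never gates results.

## Synthetic landscapes

The generator plants loci on a toy chromosome in the three tiers and
derives every downstream artifact from the same truth manifest:

* **Structure.** Defaults emulate a ten-cell-type compendium with 6–21
  factors per cell type (108 peak sets), 1,000 loci per cell type split
  52% / 47% / 1% into singleton / combinatorial / hotspot tiers —
  matching the skewed occupancy spectra of real multi-factor studies.
  Combinatorial occupancy is drawn uniformly on [2, hotspot_min−1],
  hotspot occupancy on [hotspot_min, n_factors]. A configurable fraction
  of locus coordinates (default 0.3) is shared across cell types.
* **Placement.** Locus centers keep a minimum gap of twice the maximum
  peak width, drawn by the spacing construction (sorted uniforms plus
  fixed offsets), which samples uniformly among valid configurations in
  one pass; an impossible request (chromosome too short) errors
  immediately. Peaks are 200–400 bp wide, centered at the locus ±
  Gaussian jitter clipped at 2 SD, with the constraint jitter SD < half
  the minimum width, so peaks of different loci can never merge and
  planted tiers are recovered exactly at zero jitter.
* **Tags.** Per-locus tag counts are negative-binomial (shape 5) with
  tier means 10 / 30 / 80 — hotspot ≫ singleton by construction,
  emulating the occupancy–height correlation; NB rather than Poisson
  reflects ChIP-seq overdispersion. Positions are uniform in the 400-bp
  locus window.
* **Signal.** Monomodal tiers contribute one Gaussian bump (SD 250 bp)
  at the locus center; bimodal tiers two bumps at ±500 bp (SD = offset /
  2.5), producing a deep central dip; amplitudes are tier-scaled.
* **Sequences, annotations, genes, DE lists.** Background sequence is
  i.i.d. uniform ACGT; a concrete realization of the configured IUPAC
  motif (default `TGASTCA`, chosen for a low random-background hit rate
  in 400-bp windows) is written at locus centers at tier rates
  (0.05 / 0.20 / 0.60). Annotation intervals (±500 bp of the center) are
  planted at tier rates 0.02 / 0.10 / 0.30. One plus-strand gene is
  placed downstream of each locus, with offset and length capped at 30%
  of the gap to the neighboring loci so the planted gene is provably the
  locus's nearest gene within 50 kb. DE lists sample each locus's gene
  at tier rates (default 0.10 / 0.15 / 0.50).
* **Determinism.** All randomness flows from the config seed through
  fixed sub-streams (landscape, tags, signal, sequence), so identical
  configs give byte-identical artifacts and manifest.

What the generator does **not** emulate: realistic genome composition
(repeats, GC structure, mappability), inter-locus background binding,
peak-caller artifacts, replicate variability, chromatin-state context,
and correlated multi-gene neighborhoods. Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted structure, not performance on the noise modes of real data.

## Numerical choices and degenerate inputs

* Exact Mann–Whitney only on tie-free pooled samples (scipy's exact
  method does not tie-correct); the asymptotic path applies tie and
  continuity corrections. The null-uniformity simulation uses two groups
  of 50: with much smaller groups the discreteness of U makes a
  continuous KS test reject spuriously.
* Two-proportion z-tests return z = 0, p = 1 when the pooled proportion
  is degenerate (0 or 1).
* Phi values are clipped to [−1, 1] against floating-point drift; the
  diagonal is forced to 1.
* Empty inputs: empty peak universe → empty region list; a group with no
  members is skipped from pairwise tests with a warning; zero hotspots
  make pioneer detection an error (the fraction is undefined); profile
  windows truncated by a chromosome end are zero-padded and flagged
  rather than dropped, keeping the matrix rectangular.
* Manifest TSV paths are resolved relative to the manifest's directory.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to exercise every code path at comfortable margins:
100–1,500-locus landscapes on 2–4-Mb toy chromosomes, 1,000 random
instances for the merge oracle, exhaustive hypergeometric enumeration to
N = 12, 2,000 null replicates for p-value calibration, 20 seeds for
jitter-recovery and modality checks, and 500 regions per group for
enrichment recovery. These sizes are the package's own defaults for its
validation suite; the library itself streams over arbitrarily many peaks
and cell types.

## Known limitations

* Gene assignment is single-gene; enhancer–promoter contact data are not
  used.
* Motif analysis is consensus-only by design; PWM scoring is out of
  scope.
* The modality rule classifies the *aggregate* profile; per-region shape
  heterogeneity is not modelled.
* Occupancy counts treat all transcription-related factors equally; no
  weighting by factor class or peak score.
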