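# Methods

## The measurement model

MeD-seq profiles DNA methylation with a methylation-dependent restriction
enzyme (LpnPI) that cuts only fully methylated occurrences of its
CpG-containing recognition site, releasing ~32 bp fragments centered on
the methylated site.  After library preparation and 50 bp single-end
sequencing, a fragment-derived read carries the recognition motif with its
anchored base at a characteristic distance of 13–17 bp from one read end.
The analysis therefore treats the genome as a fixed catalog of recognition
sites and the sequencing library as a multinomial sample over those sites
with selection probability proportional to per-site methylation.  Read
counts per site — not bisulfite-style β-values — are the primary signal;
all inference is on counts.

### Site index

A site is one occurrence of the recognition motif (IUPAC-expanded,
optionally on both strands), identified by the genomic coordinate of its
anchor base (for LpnPI, the methylated cytosine at motif offset 1).  A
window matching on both strands — a palindromic occurrence such as CCGG —
is one physical double-stranded site and is indexed once (strand `.`): its
two per-strand cytosines belong to the same CpG, and the enzyme's fragment
is attributed to the site, not to a strand.  The shipped default motif is
LpnPI's vendor-documented CCDG; the synthetic test suite uses CCGG as a
simple palindromic stand-in.  Coordinates are 0-based half-open
throughout; GTF input (1-based closed) is converted on ingest.

### Read filter

A read is kept iff a motif anchor lies at a 1-based distance *d* ∈
[13, 17] from the 5′ or the 3′ end (the terminal base counts as 1).  The
offset is measured to the anchor base rather than the motif start because
the enzymatic cut is centered on the methylated base.  Reads shorter than
`max_off + motif length` are discarded and counted separately.  Filtering
is idempotent.

### Placement and multimapping

Real data enter as SAM/BAM (pysam); synthetic genomes use a built-in
exact full-length matcher (forward read against both genome strands, via
a prefix-index scan of the genome).  A read with *k* locations contributes
weight 1/*k* per location ("fractional" policy; switchable to weight 1,
"count-all"), so total counts are conserved: one read, one count.

### Scoring

Each placement donates its weight to the indexed site whose anchor falls
at a qualifying in-read offset — the filter rule re-applied at scoring
time, so counts can never land on a site the fragment chemistry could not
have produced.  If one placement covers qualifying sites near both ends
(possible when two sites lie 17–25 bp apart in a 50 bp read) the weight
splits equally; placements with no qualifying site accumulate as
unassigned weight.  Counts are floats (1/*k* weights); statistics that
need integers round half-to-even at the point of testing.

### Regions

Three annotated region classes are tested: TSS windows ([TSS − 1 kb,
TSS + 1 kb), symmetric in genomic coordinates; strand determines only
which gene end is the TSS), gene bodies (1 kb downstream of the TSS to
the TES, strand-aware; genes shorter than 1 kb yield no body), and CpG
islands.  The `tss2kb` kind aliases the TSS windows — the same 2 kb
window is used for per-gene boxplot summaries.  Region counts are raw
sums of member-site counts; overlapping regions double-count by design.
No library-size normalization is applied at aggregation time, because the
chi-squared test consumes raw counts with library totals.

### DMR statistics

For groups with library totals *N*₁, *N*₂ and unit counts *n*₁, *n*₂, the
test is Pearson's chi-squared (1 df, no Yates correction; switchable) on
[[*n*₁, *N*₁ − *n*₁], [*n*₂, *N*₂ − *n*₂]].  The library total is the
denominator because count-based MeD-seq has no per-region coverage
denominator.  Degenerate tables (an all-zero column) return stat 0, p 1,
flagged.  Multiple testing: Bonferroni or Benjamini–Hochberg, applied
across all units of one analysis (all regions of a kind, or all sites
genome-wide).  Fold change is the pseudocounted rate ratio
((*n*₂ + ½)/*N*₂)/((*n*₁ + ½)/*N*₁), reported as a magnitude ≥ 1 with the
direction stored separately.  A region is significant iff adjusted p ≤ α
**and** fold ≥ the threshold (2 or 5).

Window mode tests every site, gates sites at α on adjusted p-values by
default (raw-p gating by flag), and bins maximal runs of gated sites that
are consecutive in the index, on one chromosome, and share a fold
direction — a DMR mixing hyper- and hypomethylated sites would be
incoherent.  A run is reported iff it has ≥ `min_sites` (10) sites, spans
≥ `min_span_bp` (100) bp (last − first + 1), and its aggregated counts
reach the fold threshold.  The reported window p is the chi-squared p of
the aggregated counts, Bonferroni-corrected by the number of candidate
runs examined; every member site already passed the genome-wide per-site
correction.  Overlaps with TSS/gene-body/island regions are annotated by
≥ 1 bp half-open intersection.

### Clustering

Read counts of selected regions are standardized per row with the
population (n) standard deviation — Z-scores, the same values shown in
heatmaps.  Zero-variance rows become all-zero and are flagged.
Agglomerative clustering uses Euclidean distance and average linkage by
default (configurable; recorded in output); leaf order is deterministic,
ties resolving to the lower original index.

## The synthetic-data generator

The generator emulates exactly the features the analysis relies on:

* a random genome scrubbed of accidental motif occurrences, with concrete
  motif instances planted at a target density (default 8 sites/kb —
  methylation-dependent RE sites are dense in mammalian genomes) and at
  least 30 bp apart, so each emitted fragment is attributable to a single
  site (sites 17–25 bp apart would legitimately split read weight and make
  per-site ground truth non-unique);
* non-overlapping gene models and CpG islands on a per-chromosome grid;
* per-site per-condition methylation probabilities: background 0.2
  everywhere, with planted DMRs overriding a region's baseline and
  multiplying (up) or dividing (down) the target condition by a fold,
  clipped to [0, 1];
* read emission: site chosen ∝ methylation probability (multinomial — the
  library is a fixed-size sample, matching sequencing reality), offset
  drawn uniformly from 13–17, 5′/3′ end at random, read taken as the
  forward-strand genomic window placing the anchor at that offset;
  `noise_fraction` (default 0.05) of reads are uniform genomic windows;
  substitutions at `error_rate` (default 0.001) per base; constant quality
  scores; all randomness from one seeded generator, seeds logged.

The demo truth plants a "Tcf7-like" promoter that **gains** methylation
5-fold in the chronically stimulated condition from the 0.2 baseline
(promoters of expressed genes are lowly methylated), and a "Pdcd1-like"
regulatory region that **loses** methylation 3-fold from a 0.9 baseline
(a region silenced in functional cells and demethylated under chronic
stimulation).  The 0.9 baseline is also what keeps a 3-fold loss
detectable per site: at 30 reads/site a site at rates 0.9 vs 0.3 yields a
per-site chi-squared far above the genome-wide Bonferroni threshold,
whereas a 0.2 → 0.067 loss would not be; the choice is biological and
made once, a priori, from this power consideration.

What the generator does **not** model: PCR duplicates, quality-score
variation, paired ends, mismatch-tolerant mapping ambiguity, copy-number
variation, or incomplete enzyme digestion.  Passing tests therefore
demonstrate correctness of the counting and statistics on data satisfying
the stated fragment geometry — not robustness to alignment artifacts or
library-preparation biases in real data.

## Problem sizes and numerical choices

* Read-level experiments run on 2 × 100 kb genomes (~1 600 sites,
  ~48 000 reads/sample at the default 30 reads/site); statistical
  experiments (type-I calibration, multi-seed recovery) use the
  count-level sampler `simulate_site_counts`, which draws the identical
  multinomial marginal without materializing reads, on 2 Mb genomes —
  read-to-count fidelity is established separately by exact end-to-end
  conservation tests.
* The null calibration experiment uses ~200 expected reads per region per
  group, the depth scale at which 2 kb promoter windows sit in
  genome-wide count data; there the chi-squared is well calibrated and a
  2-fold null fluctuation is a > 6σ event, so the fold gate keeps null
  runs free of Bonferroni calls.
* Counts are rounded half-to-even before chi-squared testing; count
  conservation is asserted to 1e-9; Z-score standardization is asserted
  to 1e-9.
* Degenerate inputs: empty site index → empty window result; single
  region → correction degenerates to identity; empty group or missing
  sample → fatal; genes whose TSS lies outside the chromosome → fatal.

## Known limitations

* The exact matcher tolerates no mismatches; reads carrying simulated
  sequencing errors are dropped (visible in mapping reports).  Real data
  should be aligned externally and ingested as SAM/BAM.
* The library-total denominator makes the chi-squared sensitive to
  composition effects when a large fraction of the genome changes
  methylation coherently; no compositional normalization is attempted.
* Window-mode run binning requires strict consecutiveness; a single
  non-significant site splits a run.  At adequate depth this is the
  intended behavior; at marginal depth it costs sensitivity.
* The three-condition design is analyzed as pairwise two-group calls; a
  pooled k-group test is deliberately out of scope.
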