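# Methods

This note documents the models, rules and numerical choices implemented in
`riboslicer`, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate about real sequencing data.

## Coordinate model

All analyses run against a single reference sequence representing the
45SN1/47S pre-rRNA transcription unit (13,351 nt).  User-facing tables
(templates, processing sites, site calls, deletion tables, matrix CSV) use
1-based coordinates inclusive on both ends, matching the site notation of
the field (e.g. a cleavage between C3654 and U3655).  Internally every
interval is 0-based half-open; the conversion is confined to I/O code and
to `TemplateEntry.interval0`.  BED exports follow the BED standard (0-based
half-open).

The packaged template and processing-site catalogues are transcribed once
from the literature coordinates on 45SN1.  Tests never rely on the true
human sequence — only on the coordinate tables laid over a synthetic
reference of the same length.  Two deliberate choices in the catalogue:

* The 18S-E extension series is anchored at the 18S 3′ boundary
  (position 5523): the metastable forms end at +10, +24, +36, +40 and +78
  nt, the largest reaching site E (5601 = 5523 + 78).  The `18S-E` template
  itself carries the 18S 3′ boundary as its end coordinate; reads ending
  exactly at the boundary are therefore assigned to mature 18S by the
  lexicographic tie-break, and any 3′-extended read lands on the matching
  +N form.
* The short/long 21S isoform entries (`21S_S`, `21S_L`) carry provisional
  end coordinates (alternative ITS1 endpoints) and exist mainly so both
  isoforms participate in assignment; refining them is a data question,
  not a code question.

## Supervised assignment (minimal reciprocal overlap)

For read *r* and template *t*, `MRO = min(|r∩t|/|r|, |r∩t|/|t|)`; each read
goes to the argmax template.  The score is symmetric and penalises both a
read dangling outside a short template and a short read inside a long one.
Choices:

* **Tie-break** (the rule must be deterministic; equal scores do occur for
  nested catalogues): prefer the template whose length is closest to the
  read's, then the lexicographically smallest name.
* **Assignment floor**: any positive overlap assigns (`min_mro = 0`); a
  configurable floor is exposed for stricter use.
* **No fractional assignment**: each read contributes wholly to one
  template, mirroring the argmax design; an EM-style split is out of scope.
* **RPM** = count / total aligned × 10⁶.  Heatmap values are
  log10(mean-over-replicates RPM + pseudocount) with a 1-RPM pseudocount so
  absent species stay finite; the mean-of-log alternative is available by
  computing from the per-replicate table directly.
* **Condition contrasts**: two-sided Welch t-test on replicate RPM per
  template with Benjamini–Hochberg adjustment.  The choice of test is a
  package decision (the underlying statistic is a per-template location
  shift with unequal variances and n = 3); with a single replicate only the
  fold change is reported and p-values are NaN.

## Template-free intensity matrix

The conceptual length² matrix is stored sparsely (occupied cells only); a
dense array at 13,351² ≈ 1.8×10⁸ cells would be wasteful for data that
occupy a few thousand cells.

* **Hubs**: occupied cells are clustered by Chebyshev distance ≤ 3 nt
  (boundary coordinates of minor species are estimates; the radius is
  configurable), clusters with ≥ 10 reads are retained (inclusive
  threshold), and the apex is the modal cell with lexicographic
  tie-breaking.  Hubs are annotated with the nearest processing site and
  its distance on each axis; no closeness cutoff is imposed — the distance
  is reported and left to the analyst.
* **Hub → template promotion**: retained hubs become new catalogue entries
  named `novel_<start>_<end>` (1-based), skipping intervals already
  catalogued, which makes the operation idempotent.
* **Rendering**: occupied-cell counts are min-max scaled, then clipped at
  the 2nd/98th percentile of occupied-cell values and rescaled (symmetric
  percentile reading of "2 % contrast enhancement", isolated in one
  function).  Contrast 0 reduces to plain min-max; a constant matrix maps
  to zero.  Overlays render each condition independently and blend
  additively in RGB, so single-condition regions keep pure colours.
* **Trails**: a horizontal (fixed end) or vertical (fixed start) profile is
  read off the matrix; pause candidates are interior local maxima with
  prominence above half the profile maximum by default (`scipy.signal.find_peaks`).

## Cleavage-site statistics

Start and end counts are accumulated separately (ends indexed at the last
aligned base, so a template ending at position *e* peaks exactly at *e*).
Within each template interval the baseline is the mean and sample SD
(ddof = 1) of per-position counts; a position is called at count ≥ mean +
k·SD with k = 2 (inclusive, "at least two SDs").  Where template intervals
overlap, the threshold pools the mean of the covering intervals' means and
the mean of their SDs.  Guards and fallbacks:

* positions with zero pooled SD are never called (a uniform interval has no
  signal, and the all-equal degenerate case would otherwise flag
  everything);
* intervals with fewer than two positions are skipped with a warning (SD
  undefined);
* positions outside every template interval use the whole-reference
  mean/SD, so the rule is total;
* start and end vectors are thresholded separately (they answer different
  questions and are exported in different colours).

Replicate consensus keeps a (position, kind) pair present in ≥ 2 of 3
replicate call lists (both counts configurable) and reports the
per-replicate count vector.

## Modification analysis

* A read is modified at a position iff its MM/ML-decoded probability is
  ≥ 0.95 (inclusive; 8-bit ML values scale as v/255).
* Site stoichiometry (`mod_ratio`) divides modified reads by the reads
  carrying a probability record at that position — never by raw coverage —
  and is NaN (not 0) with an empty denominator.
* The U→C mismatch ratio divides C calls by non-deleted coverage at
  reference-U positions; deleted bases express no identity and are excluded
  from the denominator.
* The site filter removes a site whose stoichiometry is below 10 % in
  *every* condition (retain-if-any-condition-reaches reading); the
  per-condition independent alternative is available via
  `per_condition=True`.  Both the 0.95 and 0.10 boundaries are inclusive.
  Low-coverage measurements (default minimum 30 reads, configurable —
  no canonical value exists) never count toward retention.
* Precursor-specific stoichiometry regroups reads by their supervised
  assignment and recomputes ratios per group; sites outside a precursor's
  interval are NaN for that row, and the pooled "all" row equals the
  record-count-weighted mean of the per-precursor rows.
* Raw-current evidence is consumed as a per-read, per-offset table of
  z-normalised signal means (the output contract of an upstream
  resquiggling step); resquiggling itself is not implemented.  The summary
  reports, per offset in a fixed −10..+10 window (21 offsets), the mean
  over reads and semi-standard deviations: root mean square deviation of
  the values strictly below (above) the per-offset mean, 0 for an empty
  side.

## Ingestion

Only primary, forward-strand alignments are used (the rRNA template is
single-stranded; reverse alignments are counted and reported in a
warning).  Soft clips never extend the aligned span.  Large intra-read
deletions (reverse-transcriptase bypass artefacts in cDNA data) are
clustered with a ±20-nt boundary tolerance — deletion boundaries of such
artefacts are fuzzy at the tens-of-nt scale — and reported with modal
boundaries and supporting-read counts; spans are sorted before clustering
so results are read-order invariant.

## Synthetic data generator

`simgen` emulates the data-generating structure of a fractionated rRNA
sequencing experiment:

* reads sample a template by proportion; boundaries get rounded Gaussian
  jitter (default 0, truncated so start < end);
* exonucleolytic trails retract one boundary by a geometric number of nt
  (continuation probability `trail_decay`); the retracted side follows the
  template category — 3′ retraction for precursors/mature species (exosome
  picture), 5′ for spacer fragments and aberrant species;
* a configurable fraction of uniform-random background fragments;
* an optional deletion planted into every read spanning it;
* planted modification stoichiometries: each covering read is modified
  with probability equal to the planted stoichiometry; modified reads draw
  their probability from a clipped Normal(0.99, 0.02), unmodified ones from
  a clipped Normal(0.02, 0.02), and a configurable fraction of modified
  reads basecalls C at the site instead;
* knockdown simulations multiply control proportions by per-template fold
  changes and renormalise, with three independently seeded replicates.

Determinism: all draws flow from one integer seed; replicate seeds derive
from the master via a fixed integer mix (`(seed·2654435761 + 9973·(i+1))
mod 2³¹`), and identical configurations produce byte-identical SAM files.

**What the generator does not emulate**: basecalling error profiles,
alignment ambiguity, coverage biases from library preparation, k-mer-level
current simulation, or sequence heterogeneity across rDNA copies.  Passing
planted-recovery tests therefore demonstrates the correctness of the
statistics and bookkeeping, not robustness to every artefact of real
nanopore data.

## Problem sizes and tolerances in the test suite

Simulated studies are sized to keep the whole suite fast while leaving
comfortable statistical margins: 500× coverage for stoichiometry recovery
(binomial 3-SD bounds, with the detection-sensitivity factor Φ(2) ≈ 0.977
implied by the probability-noise model), 2,400 reads per replicate for the
13-site processing-site recovery (peaks ≥ 20× background), 3 × 30,000 reads
per condition for fold-change recovery (±0.3 log2 tolerance against the
renormalised expectation), and 10⁴–5×10⁴ reads for proportion-recovery
checks.  The acceptance script plants the full 104-site pseudouridine
catalogue at 500× coverage and runs in a few seconds.

## Known limitations

* Site calling reports template-context baselines only as the rule defines
  them; it does not model overdispersion beyond the mean+k·SD heuristic.
* The MM/ML round trip quantises probabilities to 1/255.
* Hub detection is exact connected-components clustering; for pathological
  matrices with millions of occupied cells the O(cells·(2r+1)²)
  neighbourhood scan would dominate.
* The mismatch pileup stores only non-matching calls per read; inputs
  without query sequences cannot contribute mismatch ratios (the
  stoichiometry path still works from MM/ML tags alone).
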