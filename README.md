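# riboslicer

Quantification of human pre-ribosomal RNA processing from long reads aligned
to a single 47S/45S reference.

Ribosome biogenesis converts the polycistronic 47S primary transcript into
the mature 18S, 5.8S and 28S rRNAs through ordered endonucleolytic cleavages
(at sites 01, A0, 1, E, C, 2, B1, 4, 02, ...) and exonucleolytic trimming of
the transcribed spacers (5′ ETS, ITS1, ITS2, 3′ ETS).  Long nanopore reads
aligned against a single rDNA transcription-unit reference (45SN1) capture
whole processing intermediates — each read's alignment start and end are the
5′ and 3′ ends of one RNA molecule.  `riboslicer` turns those boundaries
into quantitative processing readouts for RNA biologists studying rRNA
maturation, its perturbation by factor depletion, and the modification
status of individual precursors.

## What it computes

**Supervised (template-based) quantification.**  Each read *r* is assigned
to the catalogued intermediate *t* maximising the minimal reciprocal
overlap,

```
MRO(r, t) = min( |r ∩ t| / |r| ,  |r ∩ t| / |t| )  ∈ [0, 1],
```

yielding absolute counts, reads per million (RPM), log10 RPM heatmaps, and
per-intermediate condition contrasts (log2 fold change of mean RPM, Welch
t-test, Benjamini–Hochberg correction).  The packaged template catalogue
covers the canonical intermediates (47S, 45S, 30S, 26S, 21S, 21S-C, 18S-E
and its +10/+24/+36/+40/+78 extension series, 32S, 12S, 7S), the mature
rRNAs, spacer fragments and aberrant species (34S, 36S, 36S-C), and can be
extended with newly discovered species.

**Unsupervised (template-free) analysis.**  Every read is embedded in a
sparse 2D intensity matrix at its (start, end) cell.  Dense "hubs"
(clusters of nearby cells with ≥ 10 reads by default) mark abundant RNA
species and are annotated with their nearest processing sites;
one-nucleotide exonucleolytic trails appear as horizontal (5′→3′) or
vertical (3′→5′) lines whose local maxima expose exonuclease pause sites.
Matrices are rendered min-max normalised with 2 % percentile contrast
enhancement and can be overlaid across conditions (e.g. nucleus vs
cytoplasm) in different colours.

**Cleavage-site calling.**  Per-position start/end abundances are
thresholded at mean + 2 SD of their template-interval baseline (mean of
means / mean of SDs where intervals overlap), and sites are retained when
reproduced in ≥ 2 of 3 replicates — single-nucleotide resolution calls
exported as TSV/BED (starts green, ends orange).

**Modification stoichiometry.**  Per-base modification probabilities are
decoded from standard SAM MM/ML tags; a read is called modified at ≥ 0.95
probability, site stoichiometry is the modified fraction of
probability-carrying reads, and the U→C basecall mismatch ratio provides an
orthogonal pseudouridine signal.  Sites below 10 % stoichiometry in every
condition are filtered out (an IVT control contributes nothing), and
stoichiometry can be resolved per precursor via the supervised assignments
— revealing, e.g., hypomodified aberrant species.  Z-normalised raw-current
summaries around a locus (mean of means, semi-standard deviations over a
±10-nt window) are computed from per-read signal tables.

**Synthetic data.**  `riboslicer.simgen` emits ReadSets/SAM files with
known template proportions, boundary jitter, geometric exonucleolytic
trails, background fragments, planted large deletions, replicate/condition
fold changes and planted modification stoichiometries, so the entire
pipeline is testable without sequencing data.

## Worked example

```python
import riboslicer as rl

ref   = rl.make_reference()                     # synthetic 13,351-nt reference
ts    = rl.default_template_set(ref.length)     # packaged intermediate catalogue
sites = rl.default_processing_sites(ref.length)

cfg = rl.SimConfig(seed=1, n_reads=10_000, jitter_sd=2.0, background_rate=0.02,
                   template_proportions={"30S": 0.25, "21S": 0.2, "18S": 0.3,
                                         "12S": 0.15, "32S": 0.1})
sim = rl.simulate_reads(ts, cfg, ref.length)

table = rl.quantify(rl.assign_reads(sim.reads, ts), sim.reads, ts)
print(table.sort_values("count", ascending=False).head(6).to_string(index=False))
```

```
template condition  replicate  count      rpm  log10_rpm
     18S                    1   2988 298800.0   5.475382
     30S                    1   2395 239500.0   5.379307
     21S                    1   1913 191300.0   5.281717
     12S                    1   1512 151200.0   5.179555
     32S                    1    992  99200.0   4.996516
     28S                    1     86   8600.0   3.934549
```

The five planted species are recovered at their planted proportions (counts
≈ 10,000 × proportion; RPM = count / total × 10⁶); the small 28S row
collects background fragments overlapping the 28S interval.  The
unsupervised view recovers the same species as intensity hubs anchored at
processing sites:

```python
m    = rl.build_matrix(sim.reads)
hubs = rl.detect_hubs(m, min_reads=10, merge_radius=3, sites=sites)
print(hubs.to_frame().head(5).to_string(index=False))
```

```
 start   end  total_reads  n_cells nearest_start_site  nearest_start_distance nearest_end_site  nearest_end_distance
  3655  5523         3025      137                  1                       0                3                     1
   425  6472         2384      130                 01                       1                2                     0
  3655  6471         1913      115                  1                       0                2                     1
  6601  7559         1508      119                 B1                       0                4                     0
  6473 12990          979      112                  2                       1               02                     0
```

Each hub apex sits within 1 nt of the catalogued processing sites
delimiting its species (e.g. the 18S hub between sites 1 and 3, the 30S hub
between 01 and 2), despite the 2-nt boundary jitter.

The same objects drive the command line:

```
riboslicer quantify --bam reads.bam --ref 45SN1.fa --out quant/
riboslicer matrix   --bam nuc.bam --bam cyt.bam --ref 45SN1.fa --out matrix/
riboslicer sites    --bam r1.bam --bam r2.bam --bam r3.bam --ref 45SN1.fa --out sites/
riboslicer mods     --bam drs.bam --ref 45SN1.fa --out mods/
riboslicer simulate --config sim.yaml --out sim.sam
```

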