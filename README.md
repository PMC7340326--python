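# medseq

Analysis toolkit for **MeD-seq** — methylation-dependent restriction-enzyme
sequencing.  The enzyme (LpnPI) cuts only fully methylated occurrences of
its CpG-containing recognition site, releasing ~32 bp fragments centered on
the methylated site; after single-end 50 bp sequencing, the read count at
each genomic recognition site is a proxy for its methylation level.  The
package is aimed at epigenomics analysts who need a transparent,
reproducible implementation of the count-based MeD-seq analysis chain,
from trimmed FASTQ to differentially methylated regions (DMRs) — for
example to ask whether a promoter such as *Tcf7*'s gains methylation in
chronically stimulated T cells.

## What it does

1. **Read filtering** — a genuine enzyme-cut fragment carries the
   recognition motif with its anchored (methylated) base 13–17 bp from one
   read end; reads violating this are discarded.
2. **Placement** — SAM/BAM ingestion (pysam) or a built-in exact mapper for
   synthetic genomes.  Multimapped reads are kept: each of a read's *k*
   locations carries weight 1/*k*, so one read contributes one count.
3. **Per-site scoring** — each placement's weight goes to the indexed site
   at a qualifying in-read offset; counts are conserved exactly.
4. **Region aggregation** — TSS windows (TSS ± 1 kb), gene bodies
   (TSS + 1 kb → TES) and CpG islands.
5. **DMR calling** — for two groups with library totals *N*₁, *N*₂ and
   region counts *n*₁, *n*₂, a Pearson chi-squared test (1 df, no
   continuity correction) on

   | | in region | elsewhere |
   |---|---|---|
   | group 1 | *n*₁ | *N*₁ − *n*₁ |
   | group 2 | *n*₂ | *N*₂ − *n*₂ |

   with Bonferroni or Benjamini–Hochberg correction, plus the normalized
   fold change ((*n*₂ + ½)/*N*₂) / ((*n*₁ + ½)/*N*₁).  A genome-wide
   sliding-window mode tests every site, then bins maximal runs of
   consecutive significant same-direction sites; a run is reported as a
   DMR only with ≥ 10 sites, a span ≥ 100 bp and fold change ≥ 2 (or 5).
6. **Clustering** — per-region Z-scores of read counts, agglomerative
   clustering, heatmap + tidy TSV export.
7. **Synthetic data** — a generator that builds genomes with planted
   recognition sites, per-site per-condition methylation probabilities and
   FASTQ reads with the exact fragment geometry above, including planted
   DMRs of configurable fold change, so every stage can be validated
   against known truth.

## Worked example

```python
import numpy as np
from medseq import (SimulationConfig, assign_methylation, generate_reference,
                    simulate_reads, filter_reads, map_reads_exact,
                    assign_site_counts, merge_profiles, aggregate_regions,
                    call_region_dmrs, DMRTestConfig)
from medseq.simulate import exhaustion_demo_dmrs

config = SimulationConfig(n_chroms=2, chrom_length=100_000,
                          reads_per_site=30, seed=1)
genome, sites, catalog = generate_reference(config)
truth = assign_methylation(sites, catalog,
                           planted=exhaustion_demo_dmrs(catalog),
                           conditions=("single", "repeat"))

profiles, groups = [], {}
rng = np.random.default_rng(1)
for cond in ("single", "repeat"):
    reads, _ = simulate_reads(genome, sites, truth, cond, config, rng)
    kept, report = filter_reads(reads, config.motif)
    placements, _ = map_reads_exact(kept, genome)
    profiles.append(assign_site_counts(placements, sites, cond))
    groups[cond] = cond
    print(f"{cond}: {report.n_kept}/{report.n_input} reads pass the 13-17 bp filter")

grouped = merge_profiles(profiles, groups)
matrix = aggregate_regions(grouped, sites, catalog, "tss")
records = call_region_dmrs(matrix, ("single", "repeat"), DMRTestConfig())
top = records[0]
print(f"top DMR: {top.region_id}  fold={top.fold_change:.2f} ({top.direction})  "
      f"chi2={top.chi2_stat:.1f}  p_adj={top.p_adj:.3g}  significant={top.significant}")
```

prints

```
single: 45635/48000 reads pass the 13-17 bp filter
repeat: 45571/48000 reads pass the 13-17 bp filter
top DMR: g0001  fold=5.10 (up)  chi2=1245.4  p_adj=9.78e-272  significant=True
```

About 95 % of reads pass the filter (the default simulation includes 5 %
unanchored noise reads, which almost never satisfy the offset rule), and
the promoter planted with a 5-fold methylation gain in the
repeat-stimulation condition is recovered as the top-ranked, significant
TSS DMR with the planted fold change and direction.

The same analysis is available from the shell:

```bash
medseq run-all --out demo_run --seed 1
```

which writes filter reports, per-site bedGraphs, region matrices, DMR
tables (region and sliding-window mode), a Z-score heatmap, and a run
report with a checksum for every output.

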