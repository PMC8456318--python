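# acidpipe

An end-to-end analysis pipeline for explaining organic-acid divergence
between two fruit varieties, combining bulk RNA-seq differential expression,
weighted co-expression modules, mutual-rank regulatory networks, and
population-genetic selection scans — plus a fully seeded synthetic-data
generator so every stage is testable offline.

## What it does

| Stage | Module | Summary |
| --- | --- | --- |
| I/O | `acidpipe.io_core` | Counts TSV, GFF3, VCF, sample sheets, population maps, YAML run config |
| Simulation | `acidpipe.synthetic_data` | NB counts with block-correlated modules and planted variety effects; acid traits tied to one module; Balding–Nichols + founder-mosaic genotypes with a planted sweep; ground truth serialized |
| Acid phenotypes | `acidpipe.phenotype_acids` | Student/Welch t-tests (raw or mean±SD form), 2^−ΔΔCt, FPKM-vs-qPCR Pearson validation |
| Expression | `acidpipe.expression_profiles` | FPKM, replicate QC, PCA, median-of-ratios size factors, NB Wald test, DEG calling (FPKM > 0.1, FDR < 0.05, |log2FC| > 2), pairwise contrasts, hypergeometric enrichment |
| Co-expression | `acidpipe.coexpression_modules` | Unsigned \|PCC\|^β adjacency (β = 14), TOM, module detection + eigengene merging (minModuleSize 40, mergeCutHeight 0.3), module–trait/GS/MM statistics |
| Regulatory networks | `acidpipe.mutual_rank_network` | Mutual-rank TF–candidate networks per variety (PCC ≥ 0.3, both directed ranks ≤ 5) |
| Selection scans | `acidpipe.selection_scan` | GATK-style hard filters, Weir–Cockerham F_ST (10 kb windows, 1 kb step), an XP-CLR-style composite-likelihood score, LD decay, top-5%/top-1% sweep regions |
| Integration | `acidpipe.integration` | Candidate selection (pathway ∩ DEG ∩ key module), dual-sweep domestication calls, S3 validation (Holm), schema-versioned report |

## CLI

The console script is `pipeline`:

```bash
pipeline simulate --seed 1 --out fixture/        # write a full synthetic input set
pipeline validate-inputs run.yaml                # check a run configuration
pipeline fpkm   --data fixture/ --out fpkm.tsv
pipeline deg    --data fixture/ --out de/
pipeline wgcna  --data fixture/ --out wgcna/
pipeline trn    --data fixture/ --variety AMT --out trn.tsv
pipeline scan   --data fixture/ --stat fst --out fst.tsv
pipeline acids  --traits acids.csv --mode student
pipeline run    --data fixture/ --out report/    # full pipeline + report.json/md
```

`--config` on most commands accepts a YAML file mirroring
`acidpipe.io_core.RunConfig` field names (thresholds, window sizes, seeds).

## Notes

- All interval arithmetic is 0-based half-open internally; GFF3/VCF and all
  emitted window tables are 1-based inclusive.
- Everything is deterministic given the seeds in `SimulationSpec` /
  `RunConfig`; the report is byte-identical across reruns with the same seed.
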