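# clonoscope

Clonality-aware analysis of paired single-cell RNA + TCR sequencing data,
built around the study design of multi-lesion skin-lymphoma cohorts:

* **Clonotype grouping** from CDR3 amino-acid sequences, with the beta-like
  chain (TRB, or TRD for γδ data) as primary key and merging of
  allelic-exclusion alpha variants over a shared beta chain.
* **Dominant-clone calling** per patient (pooled samples) or per sample,
  with deterministic tie-breaking, per-sample clone fractions among TCR+
  cells, and alpha-variant share tracking.
* **Benign-subset gating** of polyclonal T cells (FOXP3+ regulatory, then
  CD8A+ cytotoxic, then CD4+ helper) on log-normalized expression.
* **Differential expression** via a logistic-regression likelihood-ratio
  test (IRLS, 1 df) with Bonferroni correction, natural-log fold changes of
  expm1-means, and the thresholds |logFC| > 0.3 (within-clone comparisons)
  or 0.25 (per-cluster/microenvironment comparisons) at adjusted p < 0.05.
* **Cross-patient marker panels**: per-patient DE within the malignant
  clone between lesion-class groups, strict direction-consistent
  intersection across patients, and a specificity check that re-runs the
  comparison inside every benign subset.
* **Ligand-receptor interaction scoring** I_R(X,Y) = mean of the two
  cluster means, with a cluster-label permutation null (add-one empirical
  p), Benjamini-Hochberg FDR, and between-lesion score deltas per patient.
* **Synthetic data generator** producing count matrices (negative binomial
  with log-normal library-size factors), cell metadata, VDJ contig tables
  with planted dominant clones, allelic exclusion, near-binary gating
  markers, and clone-restricted planted log-fold-change effects — so the
  whole pipeline is testable end to end without external data.

## Command line

```bash
# end-to-end demo run (3 synthetic patients, planted 6-gene panel)
clonoscope run --seed 1 --out-dir demo_run

# individual stages
clonoscope simulate --seed 1 --out-dir data/
clonoscope validate  --counts data/matrix.mtx --features data/features.tsv \
    --barcodes data/barcodes.tsv --metadata data/metadata.csv --contigs data/contigs.csv
clonoscope clonotype --contigs data/contigs.csv --metadata data/metadata.csv \
    --scope patient --out-dir clones/
clonoscope panel --counts ... --class-a plaque,tumor --class-b patch \
    --direction down --out-dir panel/
clonoscope interactions --counts ... --pairs pairs.tsv --n-perm 1000 --seed 7 \
    --min-frac 0.1 --out interactions.tsv
```

Exit codes: 0 success, 2 validation/configuration error, 3 computation
error. `run` writes every intermediate table plus `manifest.json` with the
seed, stage timings, and SHA-256 checksums of all outputs; reruns with the
same config are checksum-identical.

The demo `run` recovers the planted down-regulated panel
(CXCR4, CD69, HSPA1A, ZFP36, IL7R, TXNIP) exactly, with all benign-subset
specificity flags False.

## Layout

```
src/clonoscope/
  io.py            MTX/CSV/TSV/JSON readers and writers, strict validation
  synthetic.py     synthetic dataset generator with planted ground truth
  clonotypes.py    clonotype grouping, dominant clone, clonality labels
  de.py            normalization, gating, logistic-regression LRT DE
  panel.py         per-patient clone DE, consistent panels, specificity
  interactions.py  ligand-receptor scores, permutation null, BH FDR, deltas
  pipeline.py      orchestration, validation, manifest
  cli.py           click-based CLI (subcommands above)
  presets.py       bundled demo configuration
  data/            demo ligand-receptor pair list
```
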