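# senocyto

Senescent-cell phenotyping for mass-cytometry (CyTOF) cohorts.

## The problem

Cellular senescence drives tissue aging, but senescent cells are rare,
heterogeneous, and poorly captured by any single marker: p16 positivity alone
also marks some non-senescent cells, and p21 marks a largely distinct,
non-age-associated population. Multiplexed protein profiling by mass
cytometry measures ~40 metal-tagged antibodies per cell across tens of
thousands of cells per animal, which makes a *combinatorial* definition
possible: a senescent mesenchymal cell is one that is p16-positive,
Ki67-negative (growth-arrested) and BCL-2-positive (apoptosis-resistant) —
a **p16KB** cell, with a **p21KB** analogue. Quantifying these cells across
young, aged, and senolytic-treated cohorts, and locating them within the
bone/marrow mesenchymal populations, is the analysis this package implements
end to end for users of cytometry cohorts: from raw event matrices to
cohort-level statistics.

## What the package does

- **Synthetic cohorts with ground truth** (`senocyto.simulate`): a calibrated
  generator for multi-sample CyTOF cohorts — 11 mesenchymal populations
  defined on identity markers, age/treatment-dependent p16/p21 prevalences
  with conditional BCL-2/Ki67 rates, six p16+ senescence archetypes that
  shift SASP/DNA-damage channels, bead/doublet/dead/debris/CD45+
  contamination, and slow acquisition drift. Every event carries truth
  labels, so each downstream stage is validated against known answers.
- **Preprocessing** (`senocyto.preprocess`): calibration-bead drift
  normalization, arcsinh transform (cofactor 5), and sequential cleanup
  gating (beads → singlets by DNA/event-length → viability → Lin-CD45-
  negative selection) with a per-stage QC report.
- **Senescence gating** (`senocyto.gating`): marker thresholds anchored on a
  p16-knock-out negative control (99.9th percentile of the control channel)
  or on pooled-cohort quantiles; strict-inequality positivity calls; derived
  p16KB/p21KB classes; per-sample percentages, subset shares, and
  fold-changes.
- **Population clustering** (`senocyto.som`, `senocyto.cluster`): batch
  self-organizing map plus hierarchical-consensus metaclustering
  (FlowSOM-style, 10 iterations), marker-rule annotation of metaclusters to
  population names, and silhouette-based selection of the cluster count.
- **Group statistics** (`senocyto.stats`): Shapiro-Wilk-routed Welch t /
  Mann-Whitney comparisons, Holm-Sidak step-down correction, row-standardized
  heatmap scaling.
- **CITRUS-style association** (`senocyto.citrus`): stratified per-sample
  subsampling, average-linkage event hierarchy with a minimum cluster size,
  nested per-cluster abundance/median features, and a SAM permutation model
  (d = Δmean / (s + s0)) with q-values at a target FDR.
- **Subset profiling and clearance** (`senocyto.profiles`): a small boolean
  gate grammar over flags and cluster labels, per-cluster senescent burden,
  and senolytic clearance reports.
- **Pipeline orchestration** (`senocyto.pipeline`, `senocyto` CLI): one YAML
  config runs simulate → preprocess → gate → cluster → diff → citrus →
  report with a digest-bearing run manifest; `senocyto simulate` and
  `senocyto run` are the shell entry points. The per-stage analyses are meant
  to be driven from Python — see `examples/`.

## Worked example

`python examples/02_preprocess_and_gate.py` simulates one old-animal sample
plus a p16-knock-out control, preprocesses both, and gates p16+ cells against
the knock-out-anchored threshold:

```
cleanup stages (events remaining):
  input                  20000
  bead_removal           19619
  singlet_selection      18627
  viability              18008
  lin_cd45_negative      17435

gated %p16+  = 7.59   (truth 7.51)
gated %p16KB = 1.18   (truth 1.37)
```

Reading the output: of 20,000 acquired events, 17,435 survive cleanup as
clean Lin-CD45- mesenchymal cells; 7.59% of them exceed the p16 threshold
derived from the knock-out control (the simulation truth for this sample is
7.51%, so the gate recovers the prevalence to within sampling noise), and
1.18% satisfy the full combinatorial p16KB definition. The other example
scripts cover cohort simulation (`01`), population clustering and annotation
(`03`), routed differential statistics (`04`), and the senolytic-clearance
association analysis (`05`).

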