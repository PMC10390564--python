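# Methods

This note documents the models, defaults and numerical choices behind
`senocyto`: what the synthetic cohorts emulate, how each analysis stage is
defined, and where the genuinely open design decisions were resolved.

## The synthetic cohort model

The simulator (`senocyto.simulate`) generates per-sample event matrices that
carry the statistical structure the analysis assumes, with full per-event
ground truth. It is first-class, tested code: the point is that every
downstream claim (gating recovery, cleanup precision, cluster annotation,
FDR control) can be checked against known answers.

**Marker noise.** Each marker intensity is drawn normal on the arcsinh scale
(cofactor 5), then inverse-transformed to ion counts and truncated at zero.
Unexpressed markers sit at mean 0.2 with SD 0.25 (after truncation this
matches the zero-inflated background of real CyTOF channels); expressed
markers have a configured mean with SD = 0.12 x mean, floored at the
background SD. The lognormal-like raw-scale shape is standard for mass
cytometry; no published noise model exists for this assay, so the choice is
ours.

**Populations.** Eleven mesenchymal populations are specified by
identity-marker means (`config/default_cohort.yaml`): stromal populations
(LeptinR+ BMSCs, Sca-1/PDGFRa+ BMSCs, perivascular BMSCs, Nestin+
pericytes), committed osteolineage populations (early osteoblasts, ALPL+
osteolineage, late osteoblasts/osteocytes), three CD24-defined osteolineage
populations distinguished by CD24 level and Runx2, and pre-adipocytes.
Mixture weights differ by group; the senolytic arm depletes the CD24high
osteolineage and late-osteoblast/osteocyte populations, mirroring the
clearance biology the association analysis must detect.

**Senescence flags.** Per clean cell, flags are drawn hierarchically:
p16 with a group-level marginal prevalence (young 2.81%, old 7.60%)
multiplied by a per-population enrichment (3x in late osteoblasts/osteocytes
and CD24high osteolineage in old animals, renormalized so the marginal
holds); BCL-2 conditional on p16 (P(BCL-2+ | p16+) = 0.178 old / 0.0708
young, background 5%); Ki67 conditional on both (2% among p16+BCL-2+ cells,
10% among p16+BCL-2-, 8% background). These conditionals make the derived
quantities come out at their calibrated values: p16KB = 17.4% of p16+ cells
in old animals, ~98% Ki67-negativity among p16+BCL-2+ cells, a young p16KB
prevalence just under 0.2% of all cells, and a 6.8-fold p16KB expansion with
age. The BCL-2 positive mean (arcsinh 3.87) is solved in closed form from the
requirement that mean BCL-2 within p16+ cells rise 1.8-fold with age given
the two conditional rates. p21 marks a distinct senescence route: the p21
flag is drawn disjointly from p16 (conditional renormalized so the marginal —
young 5.21%, old 3.71% — is preserved), which reflects the observed
non-overlap of the two programs and keeps the p16+ archetype space free of a
spurious p21-bright axis.

**Archetypes.** p16+ cells belong to one of six archetypes in three
flag-compatible families: BCL-2+ (plain or with a strong γH2A-X/pATM
DNA-damage axis), Ki67+ (plain or inflammatory, both with a CENP-B/p53
cycling signature), and neither (inflammatory or unlabeled). Archetype shifts
are additive on the arcsinh scale and touch only SASP/damage/senescence
statistics channels. The shifts are deliberately well separated (pairwise
distances of 4–7.5 channel SDs): the silhouette criterion used for model
selection provably prefers merging a 4%-abundance cluster into a 49%
neighbor when only a single channel separates them, so a recoverable
6-archetype structure requires multi-channel separation. The BCL-2+ families
carry mild (+0.8 to +1.5) shifts on IL-1α, CXCL1, pNFκB, pATM and p21, which
is what makes p16KB cells SASP- and damage-enriched relative to p16- cells.

**Contamination and drift.** Events are beads (bright bead channel, no DNA),
doublets (sums of two independent cells with DNA multiplied by U(1.8, 2.0)
and event length by U(1.4, 1.7) — real doublets are not exact sums), dead
cells (cisplatin-bright), low-DNA debris, or CD45+ hematopoietic carryover;
defaults total 13%. A linear multiplicative drift (default -10% across the
acquisition) scales every channel except event length.

**Between-animal dispersion.** Per-sample p16/p21 prevalences are jittered by
a mean-preserving lognormal factor with CV 0.10. Real inter-animal CVs in
this setting are considerably larger (the biological spread includes age,
sex, and husbandry variation the simulator does not model); the moderate
default is a power choice — it keeps cohort means estimable at n = 12–15
(SE ≈ 3–5% of the mean) while still exercising the per-sample statistics on
heterogeneous inputs. Consequences: passing recovery tests here demonstrates
the *pipeline* is unbiased and correctly seeded, not that n = 12 suffices for
any particular effect size in real animals.

**What the simulator does not emulate.** Isotopic spillover between adjacent
metals, cell-cycle DNA variation beyond doublets, barcode artifacts,
acquisition-rate effects, batch effects beyond within-file drift, and
correlated marker noise within a cell. Results on synthetic cohorts
therefore validate the pipeline's logic and calibration, not its robustness
to those artifacts.

**Seeding.** Every stochastic component takes explicit seed material;
`simulate_cohort` derives per-sample seeds as `(master_seed, crc32(sample_id))`
via `numpy.random.SeedSequence`, so cohorts are bitwise reproducible and
samples are independent.

## Preprocessing

**Bead normalization** partitions events into 20 contiguous acquisition-order
bins (enough resolution for slow drift without noisy bins); each bin's
correction is (global median bead signal)/(bin median bead signal), averaged
over bead channels and computed on detected bead events only, clamped to
[0.2, 5]. Bead detection is two-pass: candidates exceed 10x the background
median, the detected set must show >= 50x median contrast (otherwise the file
is declared bead-free and passed through with a warning), and the final mask
re-thresholds at 10% of the detected bead level so rare background outliers
do not perturb bin medians.

**Cleanup gating** runs in a fixed order — beads, DNA-window/event-length
singlet selection, viability, Lin-CD45- negative selection — with every
stage's counts and per-event attribution recorded. The shipped default
cutoffs are extreme quantiles (~±3.5 SD) of the simulated clean singlet
distributions, stated numerically in the config; they are declared defaults,
not values inferred from any acquisition software. On simulated truth they
give >= 0.95 precision and recall for every contamination class. The lineage
gate applies to panel channels of category `lineage` other than CD45; the
default panel carries only CD45 (lineage depletion happens upstream of the
panel in the assay), so CD45 negative selection carries the stage.

## Gating and thresholds

The p16 cutoff is the 0.999 empirical quantile (linear-interpolation
definition) of the p16 channel in a knock-out control sample processed
through the identical pipeline — capping the false-positive rate at ~0.1%,
far below the youngest cohort's ~2.8% prevalence. Markers without a knock-out
line use a cohort-wide quantile of the pooled young reference; the shipped
quantiles (p21/BCL-2 0.95, Ki67 0.92, SASP 0.99) sit at 1 - (expected pooled
prevalence), i.e. at the antimode between the negative and positive modes.
Cohort-wide (not per-sample) thresholding is a deliberate choice: it makes
percentages comparable across samples at the cost of absorbing any residual
between-sample calibration differences into the calls. Positivity is strict
(>), so control events exactly at the cutoff are negative. Percentages are
reported against two denominators, always both: all cleaned Lin-CD45- cells,
and the parent gate for subset shares.

## Clustering

A rectangular batch SOM (default 10x10, 10 epochs, linearly shrinking
Gaussian neighborhood from half the grid to 0.5) is trained on the
identity channels only — senescence/SASP channels never drive population
structure. Metaclustering is by hierarchical consensus: 10 iterations of
occupancy-weighted node bootstrap, average-linkage Euclidean clustering of
code vectors cut at k, accumulated into a consensus matrix; the final cut is
average linkage on (1 - consensus). Two numerical guards matter:

- **Tie-break.** With well-separated data the consensus matrix is exactly
  binary, all top merge heights tie at 1.0, and a maxclust cut degenerates to
  a single cluster. A deterministic 1e-3 x normalized-Euclidean term added to
  the consensus dissimilarity breaks the ties geometry-consistently.
- **Occupancy guard.** Nodes holding < 0.2% of events (residual doublets,
  population-boundary splinters — 20x below the smallest real population)
  do not seed the cut and instead inherit the nearest seeded node's
  metacluster; otherwise a handful of stray events can consume a k slot and
  force two real populations to merge.

**Annotation** labels each metacluster with the highest-priority rule whose
required-high markers exceed, and required-low markers fall below, cohort
quantile references. The shipped rule set uses the 60th percentile for both
directions: cluster medians of an unexpressed marker sit at the marker's
global median, so a 40th-percentile "low" reference would sit *below* a
background cluster's median and reject it spuriously. The CD24 high/low
split is the exact 1-D Otsu threshold of the CD24+ subset (events above the
high reference) — quantile-of-subset definitions proved brittle to the
relative sizes of the CD24 modes.

**Model selection** maximizes the mean silhouette of metaclustered events
(seeded subsample of <= 10,000 events for scoring); a maximum below 0.4 —
the level a forced split of a single Gaussian blob reaches — flags "no
structure".

## Group statistics

Shapiro-Wilk (alpha 0.05) on each group routes to a two-sided Welch t test
(unequal variances assumed — the safe reading of "unpaired t test") or a
two-sided Mann-Whitney U (exact enumeration when both groups are <= 8 and
tie-free, tie-corrected normal approximation otherwise). Groups under 3
values, or degenerate constant groups, force the nonparametric branch.
Families of comparisons (all metrics within one contrast) are corrected with
Holm-Sidak step-down (via statsmodels; the closed form
`1 - (1 - p_(j))^(m - j + 1)` with a running maximum is kept as an
independent oracle in the tests). Heatmap profiles are row-standardized with
the population-SD convention (divide by n), fixed for bit-stable outputs.

## CITRUS-style association

Per sample, a seeded subsample (default 2,000 events) is pooled and clustered
by average-linkage agglomeration on the identity channels; every dendrogram
node holding >= 2% of pooled events is retained as a cluster, so clusters are
nested and overlapping by construction and abundance features do not sum
to one. Features (per-sample abundance, or per-sample medians of functional
channels) are tested with a SAM moderated statistic d = (mean_B - mean_A) /
(s + s0), where s is the pooled-SE denominator and s0 is the median of s over
features — a deliberate simplification of the original percentile search.
q-values come from balanced label permutations (default 1,000, or all
distinct arrangements when fewer): the expected (mean) number of null
|d*| exceedances at a feature's threshold divided by the observed count,
monotonized so q is nonincreasing in |d|. The mean, not a median, of the
null exceedance count is used: at the most extreme observed threshold the
median null count collapses to zero with high probability, which would
forfeit false-discovery control exactly where it matters. Nested testing is
intrinsic to the method; multiplicity is handled inside the FDR machinery.
Regularized predictive models and cross-validation error curves are out of
scope (the conventional 5-fold setting is recorded in config for provenance
only). Average linkage needs the full condensed distance matrix, so pooled
sizes up to ~20,000 events are practical in 8 GiB; larger designs should
lower the per-sample subsample.

## Subset profiling and clearance

Gate expressions use a minimal grammar (AND/OR/NOT, parentheses, named flags,
`cluster:<label>` references) so manual gates have a reproducible textual
form; evaluation is pure set algebra over per-event booleans. A cluster is
labeled "cleared" under treatment when its abundance drops with adjusted
p < 0.05 and log2 fold-change <= -0.5 (both config-exposed; the visual
marking this encodes has no published numeric rule), "increased"
symmetrically, else "unchanged".

## Problem sizes

The shipped validation runs at desk scale, chosen to keep the full suite
within minutes on one CPU while leaving sampling error well inside the
stated tolerances: cohorts of 15 + 12 samples x 20,000 events for gating
recovery; a 50,000-event pooled cohort for population-structure recovery;
~24,000 pooled p16+ events for archetype model selection; 200-feature,
12 + 12-sample designs with 200-500 permutations for the SAM checks.

## Known limitations

- The FCS codec is a simplified 3.1 dialect (single data segment, list mode,
  float32/float64/uint data, $PnS as marker name); spillover matrices,
  multi-dataset files and vendor dialects are unsupported.
- Annotation operates on metacluster medians; a metacluster that genuinely
  mixes two populations can only receive one label.
- The consensus variant used by interactive cytometry platforms is
  unpublished; equivalence is claimed at the level of recovered population
  structure, not per-event identity.
- SAM q-values are plug-in estimates with pi0 = 1; they are conservative
  when many features carry signal.
- The simulator's calibration targets group-level summaries; absolute raw
  intensity distributions are not matched to any instrument.
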