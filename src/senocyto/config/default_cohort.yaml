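# Default cohort calibration for the synthetic CyTOF simulator.
#
# Group-level prevalences and conditional rates encode the study conditions
# the pipeline is validated against: %p16+ 2.81 (young) / 7.60 (old),
# %p21+ 5.21 / 3.71, P(BCL-2+ | p16+) chosen so that p16KB (p16+/Ki67-/BCL-2+)
# is 17.44% of p16+ cells in old animals and <0.2% of all young cells with a
# 6.8-fold increase across aging, P(Ki67+ | p16+ BCL-2+) = 0.02 (~98% Ki67-),
# and a BCL-2 positive mean solved so mean BCL-2 within p16+ cells rises
# 1.8-fold with age. All intensities are on the arcsinh scale (cofactor 5)
# before inverse transformation to ion counts.
events_per_sample: 20000
cofactor: 5.0
seed: 0

# marker noise model: normal on the arcsinh scale; unexpressed markers sit at
# baseline_mean with baseline_sd; expressed markers at their stated mean with
# sd = positive_cv * mean (floored at baseline_sd)
baseline_mean: 0.2
baseline_sd: 0.25
positive_cv: 0.12

contamination:
  beads: 0.02
  doublets: 0.03
  dead: 0.03
  debris: 0.02
  cd45pos: 0.03

# linear multiplicative signal drift across acquisition order
# (total relative change from file start to file end)
drift_slope: -0.10

# between-animal lognormal dispersion (CV) applied to per-sample p16/p21
# prevalence; mean-preserving
between_animal_cv: 0.10

prevalence:
  p16: {young: 0.0281, old: 0.0760, old_senolytic: 0.0450}
  p21: {young: 0.0521, old: 0.0371, old_senolytic: 0.0371}

conditional:
  bcl2_given_p16: {young: 0.0708, old: 0.1780, old_senolytic: 0.1000}
  bcl2_given_not_p16: 0.05
  ki67_given_p16_bcl2: 0.02
  ki67_given_p16_not_bcl2: 0.10
  ki67_background: 0.08

# arcsinh-scale means of positive (flag-driven) marker distributions
marker_positive_means:
  p16: 4.0
  p21: 3.8
  Ki67: 3.7
  BCL-2: 3.87
  CD45: 4.0

instrument:
  dna_mean: 5.3
  dna_sd: 0.12
  debris_dna_mean: 3.5
  debris_dna_sd: 0.4
  viability_live_mean: 0.3
  viability_live_sd: 0.25
  viability_dead_mean: 3.5
  viability_dead_sd: 0.4
  bead_signal_mean: 5.0
  bead_signal_sd: 0.15
  bead_noise_mean: 0.1
  bead_noise_sd: 0.2
  event_length_mean: 25.0
  event_length_sd: 3.0
  doublet_dna_multiplier: [1.8, 2.0]
  doublet_length_multiplier: [1.4, 1.7]

# default cleanup gate cutoffs (arcsinh scale), placed at extreme quantiles of
# the clean singlet distributions above
cleanup:
  dna_bounds: [4.875, 5.725]
  event_length_max: 2.73
  viability_max: 1.18
  bead_min: 2.0
  cd45_max: 1.08
  lineage_max: 1.08

# marker-positivity thresholding strategy per gated marker
thresholds:
  p16: {source: ko_control, quantile: 0.999}
  p21: {source: quantile_of_pooled, quantile: 0.95}
  Ki67: {source: quantile_of_pooled, quantile: 0.92}
  BCL-2: {source: quantile_of_pooled, quantile: 0.95}
  IL-6: {source: quantile_of_pooled, quantile: 0.99}
  IL-1a: {source: quantile_of_pooled, quantile: 0.99}
  CXCL1: {source: quantile_of_pooled, quantile: 0.99}
  pNFkB: {source: quantile_of_pooled, quantile: 0.99}

# the 11 mesenchymal populations; weights per group sum to 1, identity-marker
# means on the arcsinh scale (unlisted markers sit at baseline);
# senescence_enrichment is the population's relative propensity to hold
# p16+ cells (normalized within each group so the marginal prevalence holds)
populations:
  - name: "Sca-1/PDGFRa+ BMSCs"
    weight: {young: 0.14, old: 0.12, old_senolytic: 0.14}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {Sca-1: 4.0, PDGFRa: 4.0, Podoplanin: 3.0, CD29: 3.0, CXCL12: 1.5, Adiponectin: 1.5}
  - name: "Nestin+ Pericytes"
    weight: {young: 0.06, old: 0.05, old_senolytic: 0.05}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {Nestin: 4.0, CD146: 4.0, CD29: 3.0}
  - name: "Perivascular BMSCs"
    weight: {young: 0.10, old: 0.09, old_senolytic: 0.10}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {CD146: 4.0, Sca-1: 3.0, CD200: 4.0, CD29: 3.0, Adiponectin: 2.0, OCN: 1.5}
  - name: "ALPL+ Osteolineage"
    weight: {young: 0.10, old: 0.10, old_senolytic: 0.11}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {ALPL: 4.0, Runx2: 4.0, Dmp1: 2.0, CXCL12: 1.5}
  - name: "LeptinR+ BMSCs"
    weight: {young: 0.18, old: 0.16, old_senolytic: 0.19}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {LeptinR: 4.0, OsteolectinR: 3.5, CXCL12: 4.0, Adiponectin: 2.5}
  - name: "Early Osteoblasts"
    weight: {young: 0.12, old: 0.11, old_senolytic: 0.12}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {Runx2: 4.0, Osterix: 4.0}
  - name: "Late Osteoblasts/Osteocytes"
    weight: {young: 0.08, old: 0.10, old_senolytic: 0.05}
    senescence_enrichment: {young: 1.0, old: 3.0, old_senolytic: 3.0}
    markers: {Sclerostin: 4.0, Osterix: 4.0, Runx2: 4.0, Dmp1: 3.5, ALPL: 2.0}
  - name: "CD24low Osteolineage"
    weight: {young: 0.08, old: 0.09, old_senolytic: 0.10}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {CD24: 1.8, Osterix: 4.0, Runx2: 4.0}
  - name: "CD24high Osteolineage"
    weight: {young: 0.05, old: 0.07, old_senolytic: 0.02}
    senescence_enrichment: {young: 1.0, old: 3.0, old_senolytic: 3.0}
    markers: {CD24: 5.5, Osterix: 4.0, Runx2: 4.0}
  - name: "CD24+/Osterix+"
    weight: {young: 0.04, old: 0.05, old_senolytic: 0.05}
    senescence_enrichment: {young: 1.0, old: 1.5, old_senolytic: 1.5}
    markers: {CD24: 3.8, Osterix: 4.0}
  - name: "Pre-adipocytes"
    weight: {young: 0.05, old: 0.06, old_senolytic: 0.07}
    senescence_enrichment: {young: 1.0, old: 1.0, old_senolytic: 1.0}
    markers: {PPARg: 4.0, Adiponectin: 3.0}

# p16+ senescence archetypes: the flag-compatible family is chosen from the
# event's BCL-2/Ki67 flags, then the archetype within the family by weight;
# shifts are additive on the arcsinh scale and touch only SASP/damage/
# senescence statistics channels
archetypes:
  - name: bcl2
    family: bcl2
    weight: 0.5
    shifts: {IL-6: 1.2, IL-1a: 1.5, IL-1b: 1.2, CXCL1: 1.5, pNFkB: 1.2, pATM: 1.5, p21: 1.0, p53: 0.5, MCP-1: 0.8, PAI-1: 0.8, TNFa: 0.6, yH2A-X: 0.5}
  - name: bcl2_gh2ax
    family: bcl2
    weight: 0.5
    shifts: {IL-6: 1.2, IL-1a: 1.5, IL-1b: 1.2, CXCL1: 1.5, pNFkB: 1.2, pATM: 3.0, p21: 1.0, p53: 0.5, MCP-1: 0.8, PAI-1: 0.8, TNFa: 0.6, yH2A-X: 4.5}
  - name: ki67
    family: ki67
    weight: 0.5
    shifts: {CENP-B: 2.5, p53: 1.5}
  - name: ki67_inflammatory
    family: ki67
    weight: 0.5
    shifts: {CENP-B: 2.5, p53: 1.5, IL-6: 4.0, CXCL1: 4.0, TNFa: 2.0}
  - name: inflammatory
    family: other
    weight: 0.35
    shifts: {IL-6: 4.0, IL-1a: 4.0, IL-1b: 3.0, CXCL1: 4.0, pNFkB: 3.0, TNFa: 2.5, MCP-1: 2.5}
  - name: unlabeled
    family: other
    weight: 0.65
    shifts: {}
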