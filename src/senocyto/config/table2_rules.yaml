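# Marker rules for annotating metaclusters with mesenchymal population names.
#
# A metacluster is labeled by the highest-priority rule whose required-high
# markers exceed, and required-low markers fall below, the per-marker
# reference level (a cohort-level quantile of the annotated events). A single
# shared reference quantile is used for both directions here: with cluster
# medians as the profile statistic, a background cluster sits near the
# marker's global median, so the "low" reference must sit above it.
# "CD24 (high)" vs "CD24 (low)" is split at the Otsu threshold of the CD24+
# subset (events above the CD24 high reference).
high_quantile: 0.60
low_quantile: 0.60
rules:
  - population: "CD24high Osteolineage"
    priority: 1
    high: [CD24, Osterix, Runx2]
    low: []
    split_high: CD24
  - population: "CD24low Osteolineage"
    priority: 2
    high: [CD24, Osterix, Runx2]
    low: []
    split_low: CD24
  - population: "CD24+/Osterix+"
    priority: 3
    high: [CD24, Osterix]
    low: [Runx2]
  - population: "Late Osteoblasts/Osteocytes"
    priority: 4
    high: [Sclerostin, Osterix, Runx2]
    low: []
  - population: "Early Osteoblasts"
    priority: 5
    high: [Runx2, Osterix]
    low: [Sclerostin, ALPL, CD24]
  - population: "ALPL+ Osteolineage"
    priority: 6
    high: [ALPL, Runx2]
    low: [Osterix]
  - population: "Nestin+ Pericytes"
    priority: 7
    high: [Nestin, CD146]
    low: []
  - population: "Perivascular BMSCs"
    priority: 8
    high: [CD146, CD200]
    low: [Nestin]
  - population: "Sca-1/PDGFRa+ BMSCs"
    priority: 9
    high: [Sca-1, PDGFRa]
    low: []
  - population: "LeptinR+ BMSCs"
    priority: 10
    high: [LeptinR, CXCL12]
    low: []
  - population: "Pre-adipocytes"
    priority: 11
    high: [PPARg]
    low: []
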