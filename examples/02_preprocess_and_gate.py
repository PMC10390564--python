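"""Preprocess one sample and gate senescent cells with a KO-anchored cutoff.

Simulates an old-animal sample plus a p16-knock-out control, normalizes
signal drift to the calibration beads, arcsinh-transforms, removes
beads/doublets/dead cells and CD45+ carryover, derives the p16 threshold from
the knock-out control (99.9th percentile), and prints the gated percentages
against the simulation truth.
"""

import senocyto as sc

config = sc.SimulationConfig.default().replace(events_per_sample=20_000, seed=7)
params = sc.CleanupParams.from_dict(config.cleanup)


def prep(group, seed, ko=False):
    m = sc.simulate_sample(config, group, [7, seed], sample_id=f"s{seed}", ko_control=ko)
    m = sc.arcsinh_transform(sc.bead_normalize(m), config.cofactor)
    clean, qc = sc.cleanup_gate(m, params)
    return clean, qc


clean, qc = prep("old", 1)
ko, _ = prep("young", 99, ko=True)

print("cleanup stages (events remaining):")
for stage, count in qc.stage_counts.items():
    print(f"  {stage:<22s} {count}")

thresholds = sc.ThresholdSet()
thresholds.add(sc.derive_threshold(ko, "p16", quantile=0.999))
for marker in ("p21", "Ki67", "BCL-2"):
    spec = config.thresholds[marker]
    thresholds.add(sc.pooled_quantile_threshold([clean], marker, float(spec["quantile"])))

calls = sc.call_markers(clean, thresholds)
truth = clean.truth
print(f"\ngated %p16+  = {100 * calls['p16'].mean():.2f}   (truth {100 * truth['p16_true'].mean():.2f})")
print(f"gated %p16KB = {100 * calls['p16KB'].mean():.2f}   (truth {100 * truth['p16kb_true'].mean():.2f})")
print(
    "\nThe knock-out control pins the p16 gate so that at most ~0.1% of true"
    "\nnegatives are called positive; the gated percentages track the truth."
)
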