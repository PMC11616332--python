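"""Contraction fraction from capillary-electrophoresis peak tables.

Simulates a fragment-analysis peak table for an edited sample (most
product shortened, some full-length 242-bp molecules, background noise
peaks), applies the 5% height cutoff and reports the shortened-product
percentage from peak areas.
"""

from cagrepair.ce import ce_summary, filter_peaks
from cagrepair.simulate import simulate_ce_peaks

peaks = simulate_ce_peaks(
    {130.0: 0.45, 175.0: 0.20, 242.0: 0.35},
    jitter=0.3, seed=4, n_noise_peaks=6,
)
print("raw peaks: %d" % len(peaks))
kept = filter_peaks(peaks)
print("after 5%% height cutoff: %d" % len(kept))

summary = ce_summary(kept, full_length_bp=242.0, tol_bp=2.0)
for k, v in summary.items():
    print("  %-22s %s" % (k, "%.2f" % v if isinstance(v, float) else v))

print("\npercent_shortened is the area share of products below the")
print("full-length 242-bp amplicon (+/- 2 bp sizing tolerance) — the")
print("fraction of molecules whose CAG tract contracted after editing.")
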