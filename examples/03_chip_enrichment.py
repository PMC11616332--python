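"""ChIP-qPCR percent input and fold enrichment at the cut locus.

Computes input recovery for the repeat-flanking regions and a reference
gene from Cq values, then the fold enrichment of a repair factor (e.g.
MRE11) over the reference, with the twofold significance call.
"""

from cagrepair.qpcr import fold_enrichment, percent_input_recovery

# (region, input Cq, IP Cq); input diluted 10x before qPCR
wells = [
    ("flank_5prime", 22.0, 24.8),
    ("flank_3prime", 22.1, 23.9),
    ("reference_gene", 22.3, 27.6),
]
dilution = 10.0

recoveries = {}
for region, cq_in, cq_ip in wells:
    rec = percent_input_recovery(cq_in, cq_ip, dilution=dilution)
    recoveries[region] = rec
    print("%-15s input recovery %6.3f%%" % (region, rec))

print()
for region in ("flank_5prime", "flank_3prime"):
    fold, sig = fold_enrichment(recoveries[region], recoveries["reference_gene"])
    print("%-15s fold enrichment %5.1f  %s" % (
        region, fold, "significant (>= 2-fold)" if sig else "not significant"))

print("\nInput recovery is the immunoprecipitated fraction of each locus;")
print("fold enrichment compares it to an unbound reference gene. A value")
print(">= 2 marks genuine occupancy of the repair factor at that flank.")
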