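"""Histone-mark metaprofile around TF-bound vs unbound TE copies.

Simulates H3K27ac-like tag tracks whose rate is 5x background within
+/- 500 bp of peak-bound MIRb copies, then computes the 10 kb / 50 bp-bin
RPKM profile for bound and unbound copies, control-subtracted and smoothed
with an Epanechnikov kernel.
"""

from texapt.metaprofile import N_BINS, aggregate_profile, profile_table, stratify_by_binding
from texapt.simulate import SimulationConfig, simulate_all

cfg = SimulationConfig(seed=21, planted_enrichment={"MIRb": 5.0},
                       n_promoter_positives=0, n_decoys_per_class=0)
sim = simulate_all(cfg)
bound, unbound = stratify_by_binding(sim.te_copies, "MIRb", sim.peak_sets["CEBPB"])
reps, ctrl = sim.tracks["H3K27ac"]

b = aggregate_profile(bound, reps, [ctrl], genome=sim.genome, group="bound")
u = aggregate_profile(unbound, reps, [ctrl], genome=sim.genome, group="unbound")
table = profile_table(b, u, bandwidth_bp=150.0)

centre = table.iloc[N_BINS // 2]
edge = table.iloc[5]
print(f"{len(bound)} bound and {len(unbound)} unbound MIRb copies")
print(table.iloc[N_BINS // 2 - 2 : N_BINS // 2 + 3].to_string(index=False))
print(
    f"\ncentre-bin smoothed RPKM, control-subtracted: "
    f"bound {centre['bound_smoothed']:.1f} vs unbound {centre['unbound_smoothed']:.1f}"
)
print(
    f"far-flank ({edge['bin_centre_offset']:+.0f} bp) bound signal: "
    f"{edge['bound_smoothed']:.1f}"
)
print(
    "The bound group carries an excess only near the element (the planted\n"
    "+/-500 bp window); both groups fall to ~0 in the flanks after control\n"
    "subtraction, as for a mark restricted to bound copies."
)
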