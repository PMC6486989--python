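"""TE-derived promoter discovery: the CAGE x TFBS x TE x promoter funnel.

Generates a dataset with 20 planted promoter positives (a CAGE cluster
inside a TE, within 300 bp of a TF peak, inside the strand-matched 2 kb
promoter of a transcript) and 200 decoys each violating exactly one of
those conditions, then runs the hierarchical discovery funnel.
"""

from texapt.promoters import candidates_frame, discover_te_promoters
from texapt.simulate import SimulationConfig, simulate_all

cfg = SimulationConfig(seed=31)  # defaults: 20 positives, 4 x 50 decoys
sim = simulate_all(cfg)
transcripts = [t for ts in sim.transcripts.values() for t in ts]

candidates, funnel = discover_te_promoters(
    sim.cage, sim.peak_sets, sim.te_copies, transcripts,
    window=300, promoter_half_width=1000, genome=sim.genome,
)

print(funnel.as_frame().to_string(index=False))
print()
print(candidates_frame(candidates).head(5).to_string(index=False))

found = {c.cage_id for c in candidates}
truth = set(sim.truth.positives)
print(
    f"\n{len(candidates)} candidates; "
    f"precision {len(found & truth) / len(found):.2f}, "
    f"recall {len(found & truth) / len(truth):.2f}"
)
print(
    "The funnel counts shrink at each geometric filter; on planted truth the\n"
    "procedure is exact (deterministic geometry, not inference), so every\n"
    "planted positive and no decoy survives to the candidate table."
)
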