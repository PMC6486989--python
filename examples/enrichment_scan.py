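"""TE-subfamily enrichment scan on a synthetic genome with planted signal.

Generates a 4 x 2 Mb genome with ~5,000 TE copies from 30 subfamilies and
2,000 ChIP-seq-like peaks in which MIRb and LTR7C receive 5x and 4x the
background overlap rate, then tests every subfamily against the circular
rotation-permutation null.
"""

from texapt.enrichment import results_frame, run_enrichment, significance_threshold
from texapt.simulate import SimulationConfig, simulate_all

cfg = SimulationConfig(
    seed=11,
    planted_enrichment={"MIRb": 5.0, "LTR7C": 4.0},
    n_promoter_positives=0,
    n_decoys_per_class=0,
)
sim = simulate_all(cfg)
results = run_enrichment(
    sim.peak_sets["CEBPB"], sim.te_copies, sim.genome, n_perm=1000, rng_seed=12
)

df = results_frame(results).sort_values("p_value").head(5)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    f"\nBonferroni threshold over {len(results)} subfamilies: "
    f"{significance_threshold(len(results)):.2e}"
)
print(
    "Rows with significant=1 exceed their rotation-null expectation; the\n"
    "enrichment_ratio column (observed / expected overlap) should sit near\n"
    "the planted folds of 5 (MIRb) and 4 (LTR7C), and unplanted subfamilies\n"
    "should stay at ratio ~1 with large p-values."
)
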