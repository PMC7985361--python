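"""Full probabilistic ensemble with dual variance estimates.

Runs the complete pipeline on a small synthetic dataset with boundary
(mixed-tissue) targets: preprocessing, k-means autonomous labels, then
three network configurations x 5 leave-one-out train-test cycles. Prints
each target's per-configuration mean tumor probability, the intra-network
variance V_RA, the inter-network variance V_ER, the probability bin, and
the 1-sigma flags.
"""

from ramanbayes import GeneratorConfig, RunConfig, run_pipeline
from ramanbayes.synth import generate_dataset

sset, manifest = generate_dataset(GeneratorConfig(seed=6), 6, 6, 4, seed=6)
result = run_pipeline(sset, RunConfig(n_cycles=5, base_seed=6))

truth = dict(zip(manifest["target_id"], manifest["mix_fraction"]))
print(
    f"{'target':>7} {'m':>5} {'P_FPHW':>7} {'P_FP':>7} {'P_HW':>7} "
    f"{'V_ER':>9} {'bin':>4} flags"
)
for rec in result.ensemble_records:
    flags = []
    if rec.flag_VER:
        flags.append("VER")
    flags += [f"VRA:{t}" for t, v in rec.flag_VRA.items() if v]
    print(
        f"{rec.target_id:>7} {truth[rec.target_id]:>5.2f} "
        f"{rec.mean_probs['FPHW']:>7.3f} {rec.mean_probs['FP']:>7.3f} "
        f"{rec.mean_probs['HW']:>7.3f} {rec.V_ER:>9.1e} "
        f"{rec.quintile_bin:>4} {' '.join(flags) or '-'}"
    )

print(
    "\nm is the generator's healthy->tumor mixture fraction. End-member"
    "\ntargets land confidently in bins 1 or 5 with tiny variances;"
    "\nboundary targets attract the variance flags -- exactly the cases a"
    "\nsurgeon would want a second look at."
)
print(f"\n1-sigma V_ER threshold used: {result.thresholds.sigma_VER:.3e}")
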