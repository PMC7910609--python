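"""Simulate a four-arm experiment and run the full substrate screen.

Generates 300 proteins with planted cosubstrate binders and enzyme
substrates, runs the complete pipeline (normalization, curve fitting, QC,
contrasts, selection, permutation FDR) and compares the candidate list with
the planted ground truth.
"""

import warnings

import numpy as np

from meltscreen import (
    SimulationConfig,
    evaluate_against_truth,
    run_pipeline,
    simulate_experiment,
)

sim = SimulationConfig(
    n_proteins=300,
    frac_binders=0.05,
    frac_substrates=0.05,
    effect_mean=3.0,
    seed=42,
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(sim.experiment_config(), sim_config=sim, seed=42,
                          n_perm=50)
_, truth = simulate_experiment(sim, rng=np.random.default_rng(42))

for mode in ("cosubstrate_binder", "substrate"):
    cand = result.candidates[mode]
    selected = cand[cand["selected"]]
    ev = evaluate_against_truth(selected, truth, mode)
    fdr = result.fdr[mode]
    print(f"{mode}:")
    print(f"  candidates        : {ev['n_selected']}")
    print(f"  planted recovered : {ev['true_positives']}/{ev['n_planted']}")
    print(f"  empirical FDR     : {100 * ev['empirical_fdr']:.1f}%")
    print(f"  permutation FDR   : {100 * fdr.fdr:.1f}%  "
          f"({fdr.mean_permuted_hits:.1f} mean hits over {fdr.n_permutations} "
          f"shuffles / {fdr.observed_hits} observed)")

print()
print("A substrate call needs a >1 °C shift of the enzyme+cosubstrate arm")
print("against BOTH single arms (p<0.05 / p<0.1) — shifts already present")
print("with cosubstrate alone are binders, not substrates. The permutation")
print("FDR re-runs the whole selection on Tm-shuffled data.")
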