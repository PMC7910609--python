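"""Rank substrate candidates with an OPLS-DA model on the Tm matrix.

The model contrasts the enzyme+cosubstrate samples against the two
single-treatment arms; each protein's VIP score measures how much it
contributes to that separation (mean squared VIP = 1 by construction).
"""

import warnings

import numpy as np

from meltscreen import SimulationConfig, run_pipeline

sim = SimulationConfig(
    n_proteins=200, frac_substrates=0.04, effect_mean=3.5, seed=11,
    missing_rate=0.0,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(sim.experiment_config(), sim_config=sim, seed=11,
                          n_perm=1)

model = result.opls_model
vip = result.vip
print(f"OPLS-DA on {len(model.proteins)} proteins, "
      f"{len(model.samples)} samples (1 predictive + 1 orthogonal component)")
print(f"R²X={model.r2x:.3f}  R²Y={model.r2y:.3f}  Q²={model.q2:.3f}")
print(f"sum(VIP²) = {np.sum(vip['vip'] ** 2):.2f} (= number of proteins)")
print()
print("top 5 proteins by VIP (with 95% jackknife bounds):")
top = vip.sort_values("vip", ascending=False).head(5)
for pid, row in top.iterrows():
    print(f"  {pid}: VIP={row['vip']:.2f} [{row['vip_lo']:.2f}, {row['vip_hi']:.2f}]")
print()
print("High-VIP proteins are the strongest, most reproducible combination-")
print("specific shifts — the candidates to carry into orthogonal validation.")
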