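"""Search for the voltage/time/current scaling factors with CMA-ES.

The hybrid neuron's three scaling factors are fit by minimizing the
post-transient voltage MSE against an OU-driven HH ground truth.  A
randomized scan of the same objective shows the correlated near-optimal
valley: many (V, T, I) combinations score almost equally well, so the
incumbent is one point on a ridge rather than a sharp optimum.
"""

import numpy as np

import memhh as M
from memhh.calibration import fit_scaling, sensitivity_scan

hh = M.HHParams()
nbox = M.MemristorParams.preset("nbox")
stim = M.ou_process(M.OUSpec(duration=400.0, seed=1))

scales, fit = fit_scaling(hh, nbox, stim, seed=1, n_restarts=4, max_iter=60)
print(f"CMA-ES incumbent: V_scale={scales.V_scale:.4f} volt/mV, "
      f"T_scale={scales.T_scale:.3f}, I_scale={scales.I_scale:.3f}")
print(f"post-transient MSE: {fit.loss:.1f} mV^2 over {fit.meta['n_evals']} evaluations")

df = sensitivity_scan(hh, nbox, stim, n_samples=100, seed=2)
good = df[df.mse <= df.mse.quantile(0.15)]
corr = np.corrcoef(np.log10(good.V_scale), np.log10(good.I_scale))[0, 1]
print(f"\nrandomized scan: best sampled MSE {df.mse.min():.1f}, "
      f"log-log corr(V, I) in the best band: {corr:.2f}")
print("strongly negative correlation = the voltage and current scales trade "
      "off along a degenerate valley; the incumbent is not unique")

r2 = M.evaluate_r2(hh, nbox, scales, M.OUSpec(duration=400.0, seed=1),
                   horizon_multiplier=5.0)
print(f"\nR^2 of the incumbent on a fivefold longer held-out horizon: {r2:.3f}")
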