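"""Estimate the recombination rate from a simulated ARG.

Evaluates the log likelihood-ratio curve over a log-spaced grid in r
(effective population size held at truth) and refines the maximum by
scalar optimisation.
"""
import numpy as np

from argsmc import log_grid, loglik_curve, mle_r, simulate

r_true, Ne = 1.25e-8, 10_000.0
arg, _ = simulate(50, 200_000, r_true, Ne, seed=7)

grid = log_grid(r_true / 4, r_true * 4, 13)
curve = loglik_curve(arg, grid, Ne, reference_r=r_true)
print("r / r_true   log likelihood-ratio")
for g, lr in zip(curve.grid, curve.log_ratio):
    bar = "#" * max(0, int(40 + lr / 25))
    print(f"  {g / r_true:6.2f}     {lr:10.2f}  {bar}")

r_hat = mle_r(arg, Ne, (r_true / 4, r_true * 4))
print()
print(f"MLE: r_hat = {r_hat:.3e}  (truth {r_true:.3e}, "
      f"ratio {r_hat / r_true:.2f})")
print("The ratio curve dips near 1: the per-edge likelihood recovers the")
print("generating recombination rate from the graph structure alone.")
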