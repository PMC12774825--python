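"""Infer a three-epoch population-size history from a single small ARG.

Simulates 20 diploid samples on 10 kb under the Hudson coalescent with
Ne = 10,000 / 5,000 / 10,000 (changes at 1,000 and 5,000 generations),
slices the ARG at the change times, and computes an independent uniform-
prior grid posterior on Ne for each slice.
"""
import numpy as np

from argsmc import (
    SliceSpec,
    log_grid,
    piecewise_demography,
    simulate,
    slice_posterior,
)

demography = piecewise_demography([10_000, 5_000, 10_000], [1_000, 5_000])
arg, _ = simulate(40, 10_000, 1.25e-8, demography, seed=11, model="hudson")
print(f"simulated ARG: {arg.num_edges} edges")

sp = slice_posterior(
    arg, SliceSpec([1_000, 5_000]), log_grid(1e3, 1e5, 61), r=1.25e-8
)
truth = [10_000, 5_000, 10_000]
names = ["0-1,000 gen", "1,000-5,000 gen", "> 5,000 gen"]
print(f"{'slice':16s} {'true Ne':>8s} {'post. mode':>11s} {'post. mean':>11s}")
for name, t, mode, mean in zip(names, truth, sp.modes, sp.means):
    print(f"{name:16s} {t:8d} {mode:11.0f} {mean:11.0f}")
print()
print("Each slice is evaluated with its own constant coalescence rate; even")
print("10 kb of sequence localises all three sizes to the right order of")
print("magnitude, with the small middle epoch clearly distinguished.")
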