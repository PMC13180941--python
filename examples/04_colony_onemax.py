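"""The binary bee colony on OneMax: a transparent benchmark.

Fitness is simply the fraction of 1-bits, so the global optimum (all ones)
is known.  Under the full settings — 20 bees, 100 iterations, abandonment
limit 10 — the colony should reach it essentially always; the printed
history shows the monotone best-so-far trajectory.
"""

import numpy as np

from bmnabc import ColonyConfig, run

res = run(lambda x: float(x.mean()), ColonyConfig(d=20, seed=0))

print(f"best fitness: {res.best_fitness:.3f}")
print(f"best mask:    {''.join(map(str, res.best_x))}")
print(f"evaluations:  {res.evaluations}")
checkpoints = {i: float(v) for i, v in enumerate(res.history, start=1)}
print("best-so-far:", {i: round(checkpoints[i], 3) for i in (1, 2, 5, 10, 20, 100)})
print()
print("The history never decreases (greedy replacement + global tracking);")
print("an all-ones mask means every one of the 20 'feature groups' was kept.")
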