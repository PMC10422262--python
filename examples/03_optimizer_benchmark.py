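"""Run both swarm optimizers on the 10-D sphere benchmark.

Maximizes -sum(x^2) over [-1, 1]^10; the optimum is 0 at the origin.  Both
the chameleon swarm and the grasshopper algorithm should report best
fitness within ~1e-2 of zero, with a monotone best-so-far trace.
"""

import numpy as np

from mmgsel import OptimizerConfig, optimize

objective = lambda x: -float(np.sum(x**2))

for algorithm in ("csa", "goa"):
    cfg = OptimizerConfig(dim=10, pop_size=30, max_iter=300, lb=-1.0, ub=1.0, seed=0)
    res = optimize(objective, algorithm, cfg)
    print(
        f"{algorithm}: best fitness {res.best_fitness:.3e} "
        f"after {res.evaluations} evaluations "
        f"(monotone trace: {bool(np.all(np.diff(res.fitness_history) >= 0))})"
    )
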