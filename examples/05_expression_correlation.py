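"""Selection pressure vs organ expression on a planted-correlation fixture.

Simulates an FPKM matrix over the 14 organs for 500 genes whose mean
expression is planted to correlate at rho = -0.5 with their true dN/dS,
then recomputes breadth and average expression (log2(FPKM+1), organs above
0.5 only) and correlates them with the true selection pressure.
"""

import numpy as np

from florevol import (
    average_expression,
    correlate,
    expression_breadth,
    normalize_log2p1,
    simulate_expression,
)

rng = np.random.default_rng(3)
genes = [f"g{i:03d}" for i in range(500)]
omega = {g: float(np.clip(rng.lognormal(np.log(0.2), 0.6), 0.01, 1.5)) for g in genes}

matrix = normalize_log2p1(
    simulate_expression(omega, n_organs=14, correlation_target=-0.5, seed=4)
)
avg = np.array([average_expression(row) for _, row in matrix.values.iterrows()])
breadth = np.array([expression_breadth(row) for _, row in matrix.values.iterrows()])
w = np.array([omega[g] for g in genes])

for name, y in (("average expression", avg), ("expression breadth", breadth)):
    res = correlate(w, y)
    print(f"omega vs {name:18s}: r = {res.r:+.3f}  r2 = {res.r2:.3f}  "
          f"p = {res.p_value:.2e}  n = {res.n}")
# Both correlations come out negative: faster-evolving genes are expressed
# lower and in fewer organs, the planted (and biologically expected) signal.
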