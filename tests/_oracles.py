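"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def bh_enumeration_oracle(pvals):
    """q_i = min{ m * p_(j) / j : p_(j) >= p_i }, straight from the
    Benjamini–Hochberg step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [m * sorted_p[j] / (j + 1)
                      for j in range(m) if sorted_p[j] >= pi - 1e-15]
        q[i] = min(1.0, min(candidates))
    return q
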