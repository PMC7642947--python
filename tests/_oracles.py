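"""Independent analytic oracles used by the test suite."""

from math import comb, factorial

import numpy as np


def stirling2(i: int, j: int) -> int:
    return sum((-1) ** (j - k) * comb(j, k) * k**i for k in range(j + 1)) // factorial(j)


def exact_mean_mrca(n: int) -> float:
    """Exact mean generations to coalescence of n lineages in a size-n
    Wright–Fisher population, by first-step analysis of the ancestral
    (distinct-parent-count) Markov chain."""
    if n == 1:
        return 0.0
    P = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(1, i + 1):
            falling = 1
            for t in range(j):
                falling *= n - t
            P[i, j] = stirling2(i, j) * falling / n**i
    E = np.zeros(n + 1)
    for i in range(2, n + 1):
        E[i] = (1 + sum(P[i, j] * E[j] for j in range(1, i))) / (1 - P[i, i])
    return float(E[n])
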