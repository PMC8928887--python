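"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the diet oracle
enumerates every prey subset instead of using the sequential contingency
rule, and the rate function recomputes intake from the trait tables.
"""

import itertools

import numpy as np


def intake_rate(subset, consumer, traits):
    """R(D) = sum(lambda*E) / (1 + sum(lambda*H)) for an explicit prey set."""
    sub = list(subset)
    if not sub:
        return 0.0
    lam = traits.A[sub, consumer] * traits.N[sub]
    return float(np.sum(lam * traits.E[sub]) / (1.0 + np.sum(lam * traits.H[sub, consumer])))


def brute_force_diet(consumer, traits, n_prey):
    """Exhaustively maximize R over all subsets of feasible prey."""
    feasible = [i for i in range(n_prey) if np.isfinite(traits.H[i, consumer])]
    best, best_rate = set(), 0.0
    for r in range(1, len(feasible) + 1):
        for sub in itertools.combinations(feasible, r):
            rate = intake_rate(sub, consumer, traits)
            if rate > best_rate:
                best_rate, best = rate, set(sub)
    return best, best_rate


def tss_formula(tp, tn, fp, fn):
    """The printed TSS formula, evaluated directly."""
    return (tp * tn - fp * fn) / ((tp + fn) * (fp + tn))
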