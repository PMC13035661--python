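"""Independent brute-force oracles used by several test modules."""

import numpy as np


def brute_force_auc(values, outcomes):
    """Pair-counting AUC: P(event > nonevent) + 0.5 P(tie)."""
    values = np.asarray(values, float)
    outcomes = np.asarray(outcomes, int)
    pos = values[outcomes == 1]
    neg = values[outcomes == 0]
    wins = sum((x > y) + 0.5 * (x == y) for x in pos for y in neg)
    return wins / (len(pos) * len(neg))


def brute_force_ks(a, b):
    """Pooled-point ECDF evaluation of the two-sample KS statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    return max(abs((a <= t).mean() - (b <= t).mean()) for t in pooled)
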