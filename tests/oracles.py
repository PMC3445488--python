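"""Independent brute-force oracles used by the test suite only."""

import math
from collections import Counter

import numpy as np


def mi_oracle(x, y):
    """Plug-in MI in bits via explicit loops over observed state pairs."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((px[a] / n) * (py[b] / n)))
    return total


def mrmr_oracle(states, labels):
    """Naive greedy max-relevance/min-redundancy over all features."""
    m = states.shape[1]
    rel = [mi_oracle(states[:, j], labels) for j in range(m)]
    selected = []
    while len(selected) < m:
        best, best_score = None, -np.inf
        for j in range(m):
            if j in selected:
                continue
            red = (sum(mi_oracle(states[:, j], states[:, s]) for s in selected)
                   / len(selected)) if selected else 0.0
            score = rel[j] - red
            if score > best_score:  # strict: ties keep the lower index
                best, best_score = j, score
        selected.append(best)
    return selected


def mcc_oracle(tp, tn, fp, fn):
    """Direct evaluation of the Matthews correlation coefficient."""
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else 0.0
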