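"""Feature ranking by mutual information: MaxRel and mRMR.

Continuous features are discretised into three states by thresholds at
mean +/- alpha*sd (alpha = 1 by default); binary one-hot columns pass
through untouched.  Mutual information is the discrete plug-in estimate in
bits.  MaxRel orders features by MI with the class label; mRMR greedily
picks, each round, the unselected feature maximising

    relevance(f) - (1/|selected|) * sum_{s in selected} MI(f, s)

(the additive "difference" criterion).  Ties break on the lower original
column index so rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class DiscretizedMatrix:
    """Integer-state view of a feature matrix plus binning metadata."""

    states: np.ndarray       # samples x features, small non-negative ints
    n_states: np.ndarray     # states per feature (1 for constant columns)
    columns: list
    thresholds: list         # (lo, hi) per 3-state column, None for pass-through


def discretize(matrix, alpha=1.0):
    """Bin each continuous column into 3 states at mean +/- alpha*sd.

    ``matrix`` may be a FeatureMatrix or a plain 2-D array (column names
    are synthesised for the latter).  Columns whose values already lie in
    {0, 1} pass through; zero-variance columns collapse to a single state.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    values = getattr(matrix, "values", matrix)
    values = np.asarray(values, dtype=float)
    columns = list(getattr(matrix, "columns", range(values.shape[1])))
    n, m = values.shape
    states = np.zeros((n, m), dtype=np.int8)
    n_states = np.empty(m, dtype=int)
    thresholds = []
    for j in range(m):
        col = values[:, j]
        uniq = np.unique(col)
        if uniq.size == 1:
            n_states[j] = 1
            thresholds.append(None)
        elif np.isin(uniq, (0.0, 1.0)).all():
            states[:, j] = col.astype(np.int8)
            n_states[j] = 2
            thresholds.append(None)
        else:
            mu, sd = col.mean(), col.std()
            lo, hi = mu - alpha * sd, mu + alpha * sd
            states[:, j] = np.digitize(col, [lo, hi])
            n_states[j] = 3
            thresholds.append((lo, hi))
    return DiscretizedMatrix(states, n_states, columns, thresholds)


def mutual_information(x, y):
    """Plug-in mutual information, in bits, between two state vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("state vectors must be 1-D and of equal length")
    nx, ny = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint)


def _mi_from_joint(joint):
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())


def _mi_block_vs_one(states, y, max_state=3):
    """MI of every column of ``states`` against one state vector ``y``.

    Vectorised via indicator mat-muls: for each (a, b) state pair the joint
    count of column j is sum_i [states[i,j]==a][y[i]==b].
    """
    n, m = states.shape
    ny = int(y.max()) + 1
    Y = np.zeros((n, ny))
    Y[np.arange(n), y] = 1.0
    joint = np.empty((m, max_state, ny))
    for a in range(max_state):
        joint[:, a, :] = (states == a).T.astype(float) @ Y
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    denom = px * py
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / denom), 0.0)
    return terms.sum(axis=(1, 2))


@dataclass
class RankedFeatures:
    """MaxRel and mRMR orderings over one feature matrix.

    ``maxrel``: list of (name, relevance) sorted by relevance descending;
    ``mrmr``: list of (name, round, score) where round h = 1..N is the
    selection round (smaller h = more important).
    """

    maxrel: list
    mrmr: list

    @property
    def mrmr_order(self):
        return [name for name, _, _ in self.mrmr]

    @property
    def maxrel_order(self):
        return [name for name, _ in self.maxrel]


def _check_labels(D, labels):
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != D.states.shape[0]:
        raise ValidationError("label count does not match sample count")
    if np.unique(labels).size < 2:
        raise ValidationError("labels must contain both classes")
    return labels


def relevance(D, labels):
    """MI of each feature with the class label, in bits."""
    labels = _check_labels(D, labels)
    return _mi_block_vs_one(D.states, labels)


def maxrel_ranking(D, labels):
    """Features ordered by class relevance (descending, stable ties)."""
    rel = relevance(D, labels)
    order = np.argsort(-rel, kind="stable")
    return [(D.columns[j], float(rel[j])) for j in order]


def mrmr_ranking(D, labels, top_k=None):
    """Greedy max-relevance/min-redundancy ordering of all features.

    Round 1 selects the most relevant feature; round h selects the
    unselected feature maximising relevance minus mean MI with the h-1
    already-selected features.  With ``top_k`` the greedy loop stops early
    and the remaining features are omitted from the mrmr list.
    """
    labels = _check_labels(D, labels)
    rel = relevance(D, labels)
    m = len(D.columns)
    k = m if top_k is None else min(top_k, m)
    selected = []
    red_sum = np.zeros(m)
    available = np.ones(m, dtype=bool)
    for h in range(1, k + 1):
        if h == 1:
            score = rel.copy()
        else:
            score = rel - red_sum / (h - 1)
        score[~available] = -np.inf
        j = int(np.argmax(score))  # argmax takes the lowest index on ties
        selected.append((D.columns[j], h, float(score[j])))
        available[j] = False
        if h < k:
            red_sum += _mi_block_vs_one(D.states, D.states[:, j])
    maxrel = [(D.columns[j], float(rel[j]))
              for j in np.argsort(-rel, kind="stable")]
    return RankedFeatures(maxrel=maxrel, mrmr=selected)
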