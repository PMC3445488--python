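"""Cross-validated scoring, incremental feature selection and analyses.

Incremental feature selection (IFS) walks the mRMR-ranked feature list,
scoring each nested prefix S_i = {f_1 .. f_i} with stratified k-fold
cross-validated random forests, and keeps the prefix with the best
Matthews correlation coefficient.  Metrics:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Ac  = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .features import PSSM_ALPHABET, FAMILY_ORDER, parse_feature_name
from .model import ForestConfig, train


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion counts sum to zero")

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    ac: float
    mcc: float

    def as_dict(self):
        return {"Sn": self.sn, "Sp": self.sp, "Ac": self.ac, "MCC": self.mcc}


def compute_metrics(c):
    """Sensitivity, specificity, accuracy and MCC from a confusion table.

    A zero MCC-denominator factor yields MCC = 0 (standard convention,
    with a warning); an undefined Sn or Sp is reported as NaN.
    """
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    ac = (c.tp + c.tn) / c.total
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        warnings.warn("MCC denominator has a zero factor; reporting MCC=0")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc)


def crossval_confusion(matrix, feature_subset, k=5, seed=0, config=None):
    """Pooled confusion counts from stratified k-fold cross-validation.

    Every sample is predicted exactly once, by a forest trained on the
    other k-1 folds restricted to ``feature_subset``.
    """
    if k < 2:
        raise ValidationError("need at least 2 folds")
    labels = matrix.labels
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("both classes must be present")
    if counts.min() < k:
        raise ValidationError(
            f"minority class has {counts.min()} samples; cannot stratify "
            f"into {k} folds"
        )
    names = list(feature_subset)
    X = matrix.select(names)
    config = config or ForestConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for train_idx, test_idx in skf.split(X, labels):
        fold_model = train(X[train_idx], labels[train_idx],
                           config=config, feature_names=names)
        pred = fold_model.predict(X[test_idx])
        truth = labels[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class IFSTable:
    """Per-prefix-size CV metrics plus the ranked feature order used."""

    records: pd.DataFrame          # columns: i, Sn, Sp, Ac, MCC
    feature_order: list            # full ranked list the prefixes index into


@dataclass
class OptimalFeatureSet:
    features: list                 # ranked order, best prefix
    size: int
    metrics: MetricSet


def _prefix_grid(n, max_prefix=None, step=1, prefix_sizes=None):
    if prefix_sizes is not None:
        sizes = sorted(set(int(i) for i in prefix_sizes))
        if sizes and sizes[-1] > n:
            warnings.warn(f"prefix sizes above {n} clipped")
            sizes = [i for i in sizes if i <= n]
        return sizes
    cap = n
    if max_prefix is not None:
        if max_prefix > n:
            warnings.warn(f"max_prefix={max_prefix} clipped to {n} features")
        cap = min(max_prefix, n)
    return list(range(1, cap + 1, step))


def run_ifs(matrix, ranked, k=5, seed=0, max_prefix=None, step=1,
            prefix_sizes=None, config=None):
    """Score nested prefixes of the mRMR ranking with k-fold CV forests.

    By default every prefix 1..N is scored; ``max_prefix``/``step`` or an
    explicit ``prefix_sizes`` grid give coarser, cheaper scans.
    """
    order = ranked.mrmr_order if hasattr(ranked, "mrmr_order") else list(ranked)
    unknown = [f for f in order if f not in set(matrix.columns)]
    if unknown:
        raise ValidationError(f"ranked features not in matrix: {unknown[:5]}")
    sizes = _prefix_grid(len(order), max_prefix, step, prefix_sizes)
    rows = []
    for i in sizes:
        mets = compute_metrics(
            crossval_confusion(matrix, order[:i], k=k, seed=seed, config=config)
        )
        rows.append({"i": i, "Sn": mets.sn, "Sp": mets.sp,
                     "Ac": mets.ac, "MCC": mets.mcc})
    return IFSTable(records=pd.DataFrame(rows), feature_order=list(order))


def select_optimal(table):
    """Best-MCC prefix of an IFS table; ties go to the smallest prefix."""
    if len(table.records) == 0:
        raise ValidationError("empty IFS table")
    rec = table.records
    best = int(rec["MCC"].to_numpy().argmax())  # first max = smallest prefix
    row = rec.iloc[best]
    size = int(row["i"])
    return OptimalFeatureSet(
        features=table.feature_order[:size],
        size=size,
        metrics=MetricSet(sn=row["Sn"], sp=row["Sp"], ac=row["Ac"], mcc=row["MCC"]),
    )


@dataclass
class FeatureSummary:
    """Tallies of an optimal feature set by family, window site and, for
    PSSM features, by target amino-acid column."""

    by_family: pd.Series
    by_site: pd.Series
    pssm_by_residue: pd.Series

    def top_sites(self, n=3):
        ordered = self.by_site.sort_values(ascending=False, kind="stable")
        return list(ordered.index[:n])


def summarize_optimal_features(optimal, w=None):
    """Decompose an optimal feature set along the name grammar."""
    fam, site, pssm_aa = Counter(), Counter(), Counter()
    max_site = 0
    for name in optimal.features:
        s, family, k = parse_feature_name(name)
        fam[family] += 1
        site[s] += 1
        max_site = max(max_site, s)
        if family == "pssm":
            pssm_aa[PSSM_ALPHABET[k - 1]] += 1
    w = w or max_site
    return FeatureSummary(
        by_family=pd.Series({f: fam.get(f, 0) for f in FAMILY_ORDER}, name="count"),
        by_site=pd.Series({s: site.get(s, 0) for s in range(1, w + 1)}, name="count"),
        pssm_by_residue=pd.Series({aa: pssm_aa.get(aa, 0) for aa in PSSM_ALPHABET},
                                  name="count"),
    )
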