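"""Model/Results front end over the full prediction pipeline.

``CleavageSiteModel`` is built from encoded windows (or directly from a
window list plus annotation providers); ``fit()`` runs mRMR ranking and
incremental feature selection under cross-validated random forests and
returns a ``CleavageSiteResults`` carrying the ranking, the IFS curve,
the optimal feature set with its CV metrics, and the per-family/per-site
feature tallies.  ``results.evaluate(test)`` trains once on all training
windows and scores a protein-disjoint holdout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FeatureMatrix, build_frequency_table, encode_windows
from .model import ForestConfig, evaluate_holdout, train
from .mrmr import discretize, mrmr_ranking
from .selection import (
    run_ifs,
    select_optimal,
    summarize_optimal_features,
)


class CleavageSiteModel:
    """Cleavage-site predictor specification bound to a training matrix."""

    def __init__(self, matrix, alpha=1.0):
        if matrix.values.shape[0] < 2:
            raise ValidationError("need at least two training samples")
        self.matrix = matrix
        self.alpha = alpha

    @classmethod
    def from_windows(cls, windows, providers, freq_table=None, alpha=1.0):
        """Encode labelled windows; the frequency table is built from the
        positive windows unless one is supplied."""
        windows = list(windows)
        if freq_table is None:
            freq_table = build_frequency_table(
                [w for w in windows if w.label == 1]
            )
        matrix = encode_windows(windows, providers, freq_table)
        m = cls(matrix, alpha=alpha)
        m.freq_table = freq_table
        m.providers = providers
        return m

    def fit(self, folds=5, seed=0, forest=None, max_prefix=None, step=1,
            prefix_sizes=None, mrmr_top_k=None):
        """Rank features (mRMR), scan nested prefixes (IFS) and pick the
        best-MCC feature set."""
        forest = forest or ForestConfig(seed=seed)
        D = discretize(self.matrix, alpha=self.alpha)
        ranked = mrmr_ranking(D, self.matrix.labels, top_k=mrmr_top_k)
        ifs = run_ifs(self.matrix, ranked, k=folds, seed=seed,
                      max_prefix=max_prefix, step=step,
                      prefix_sizes=prefix_sizes, config=forest)
        optimal = select_optimal(ifs)
        summary = summarize_optimal_features(optimal, w=self.matrix.w)
        return CleavageSiteResults(
            model=self, ranked=ranked, ifs_table=ifs, optimal=optimal,
            feature_summary=summary, forest_config=forest, folds=folds,
            seed=seed,
        )


@dataclass
class CleavageSiteResults:
    """Fitted-pipeline results: ranking, IFS curve, optimal set, tallies."""

    model: CleavageSiteModel
    ranked: object
    ifs_table: object
    optimal: object
    feature_summary: object
    forest_config: ForestConfig
    folds: int
    seed: int

    @property
    def cv_metrics(self):
        return self.optimal.metrics

    def evaluate(self, test_matrix, config=None):
        """Holdout metrics: train once on all training windows restricted
        to the optimal features, score the disjoint test windows."""
        return evaluate_holdout(self.model.matrix, test_matrix, self.optimal,
                                config=config or self.forest_config)

    def final_model(self):
        """A deployable forest trained on all training windows."""
        names = list(self.optimal.features)
        return train(self.model.matrix.select(names), self.model.matrix.labels,
                     config=self.forest_config, feature_names=names)

    def summary(self):
        """Human-readable report in the spirit of a fitted-model summary."""
        m = self.cv_metrics
        lines = [
            "Cleavage-site predictor (mRMR + IFS + random forest)",
            "=" * 56,
            f"Training windows:      {self.model.matrix.values.shape[0]}"
            f"  ({int(self.model.matrix.labels.sum())} positive)",
            f"Window size:           {self.model.matrix.w}"
            f"  ({len(self.model.matrix.columns)} features)",
            f"CV folds:              {self.folds} (stratified)",
            f"Forest:                {self.forest_config.n_trees} trees, "
            f"m_try={self.forest_config.resolve_m_try(max(2, self.optimal.size))}",
            f"Optimal feature set:   {self.optimal.size} features",
            f"CV Sn/Sp/Ac/MCC:       {m.sn:.4f} / {m.sp:.4f} / "
            f"{m.ac:.4f} / {m.mcc:.4f}",
            "",
            "Optimal-set family tallies:",
        ]
        for fam, cnt in self.feature_summary.by_family.items():
            lines.append(f"  {fam:<9s} {cnt}")
        top = self.feature_summary.top_sites(3)
        lines.append(f"Top window sites:      {top}")
        return "\n".join(lines)


def plot_ifs_curve(ifs_table, ax=None):
    """MCC against prefix size (the IFS curve)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rec = ifs_table.records
    ax.plot(rec["i"], rec["MCC"], marker=".", lw=1)
    best = rec.iloc[int(rec["MCC"].to_numpy().argmax())]
    ax.axvline(best["i"], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("cross-validated MCC")
    ax.set_title("Incremental feature selection")
    return ax
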