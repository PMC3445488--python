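"""Random-forest classification stage with a named-column schema contract.

The forest is bootstrap aggregation of fully grown, unpruned decision
trees: each tree trains on a with-replacement resample of size N and
considers m_try randomly chosen features per split (default
floor(log2(M)) + 1).  Prediction is the majority vote; exact vote ties
resolve to the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .dataset import POSITIVE
from .errors import LeakageError, SchemaMismatchError, ValidationError


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters.

    ``m_try=None`` means floor(log2(M)) + 1 features per split, resolved at
    train time from the actual feature count M; trees are always fully
    grown and unpruned.
    """

    n_trees: int = 100
    m_try: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def resolve_m_try(self, n_features):
        m = self.m_try if self.m_try is not None else int(np.log2(n_features)) + 1
        if m > n_features:
            raise ValidationError(
                f"m_try={m} exceeds feature count {n_features}"
            )
        return m


@dataclass
class TrainedModel:
    """A fitted forest bound to the named feature columns it was trained on."""

    forest: RandomForestClassifier
    feature_names: list
    config: ForestConfig

    def _check_columns(self, names):
        if list(names) == list(self.feature_names):
            return
        missing = sorted(set(self.feature_names) - set(names))
        extra = sorted(set(names) - set(self.feature_names))
        if missing or extra:
            raise SchemaMismatchError(
                f"feature columns do not match the trained schema; "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''}, "
                f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )

    def predict(self, X, names=None):
        """Majority-vote labels for rows of ``X``; vote ties go positive."""
        X = np.asarray(X, dtype=float)
        if names is not None:
            self._check_columns(names)
            order = [list(names).index(f) for f in self.feature_names]
            X = X[:, order]
        if X.shape[0] == 0:
            return np.array([], dtype=int)
        if X.shape[1] != len(self.feature_names):
            raise SchemaMismatchError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {X.shape[1]}"
            )
        proba = self.forest.predict_proba(X)
        pos_col = list(self.forest.classes_).index(POSITIVE)
        return (proba[:, pos_col] >= 0.5).astype(int)


def train(X, labels, config=None, feature_names=None):
    """Fit a random forest on a (samples x features) matrix.

    Deterministic under ``config.seed`` for fixed input.  Accepts a
    FeatureMatrix-like object (uses its values/columns/labels) or a plain
    array with explicit ``labels`` and ``feature_names``.
    """
    config = config or ForestConfig()
    if hasattr(X, "values") and hasattr(X, "columns"):
        feature_names = list(X.columns)
        X = X.values
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if np.unique(labels).size < 2:
        raise ValidationError("training labels must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.resolve_m_try(X.shape[1]),
        bootstrap=True,
        max_depth=None,          # fully grown
        min_samples_leaf=1,      # unpruned
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    return TrainedModel(forest=forest, feature_names=list(feature_names),
                        config=config)


def evaluate_holdout(train_matrix, test_matrix, optimal, config=None):
    """Train once on all training windows (optimal features only) and score
    the held-out windows.

    Raises :class:`LeakageError` if any protein appears in both splits.
    """
    from .selection import ConfusionCounts, compute_metrics

    shared = set(train_matrix.meta["accession"]) & set(test_matrix.meta["accession"])
    if shared:
        raise LeakageError(
            f"proteins present in both train and test: {sorted(shared)[:5]}"
        )
    names = list(optimal.features)
    model = train(train_matrix.select(names), train_matrix.labels,
                  config=config, feature_names=names)
    pred = model.predict(test_matrix.select(names))
    truth = test_matrix.labels
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )
    return compute_metrics(counts)


SCHEMA_VERSION = 1


def save_model(model, dest):
    """Persist config + feature names + trees as a versioned JSON archive."""
    import pickle, base64
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": {"n_trees": model.config.n_trees,
                   "m_try": model.config.m_try,
                   "seed": model.config.seed},
        "feature_names": model.feature_names,
        "forest": base64.b64encode(pickle.dumps(model.forest)).decode(),
    }
    Path(dest).write_text(json.dumps(payload))


def load_model(source):
    import pickle, base64
    payload = json.loads(Path(source).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaMismatchError(
            f"model archive schema {payload.get('schema_version')} is not "
            f"loadable by this version (expected {SCHEMA_VERSION})"
        )
    return TrainedModel(
        forest=pickle.loads(base64.b64decode(payload["forest"])),
        feature_names=payload["feature_names"],
        config=ForestConfig(**payload["config"]),
    )
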