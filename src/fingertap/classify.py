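"""Severity classification: white-box decision tree and rule-based baseline.

Two classifiers map the 15-feature vector to an ordinal severity score 0-4:

* :class:`DecisionTreeModel` — a deterministic CART (Gini impurity, greedy
  binary splits).  Ties between candidate splits are broken by lower feature
  index then lower threshold, so training is reproducible to the byte; the
  fitted tree serializes to a human-readable nested JSON structure with
  feature names and thresholds, honouring the white-box requirement of
  clinical assessment.
* :func:`baseline_sp` — a literal operationalization of the clinical rating
  criteria (interruption counts, decrement onset position, slowing,
  barely-performable), with "worst criterion wins" semantics.  The published
  criteria give qualitative bands only; the numeric slowing/amplitude cutoffs
  here were calibrated once on the default synthetic severity grid and live
  in :class:`BaselineSPConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureVector

SCORES = (0, 1, 2, 3, 4)


# --------------------------------------------------------------------------
# deterministic CART


def _gini(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class _Node:
    prediction: int
    counts: list[int]
    feature: str | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "prediction": self.prediction, "counts": self.counts}
        return {
            "leaf": False,
            "feature": self.feature,
            "threshold": self.threshold,
            "prediction": self.prediction,
            "counts": self.counts,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        node = cls(prediction=int(d["prediction"]), counts=list(d["counts"]))
        if not d["leaf"]:
            node.feature = d["feature"]
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class TreeConfig:
    max_depth: int = 5
    min_samples_leaf: int = 2


class DecisionTreeModel:
    """Greedy CART over the 15 canonical features, Gini impurity.

    Deterministic: candidate features are scanned in canonical order,
    thresholds ascending (midpoints between consecutive distinct values),
    and a candidate replaces the incumbent only when it strictly lowers the
    weighted impurity.  Shallow by default (depth 5) so the printed tree
    stays readable.
    """

    def __init__(self, config: TreeConfig | None = None):
        self.config = config or TreeConfig()
        self.root: _Node | None = None
        self.feature_names: tuple[str, ...] = FEATURE_NAMES

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "DecisionTreeModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"X must be (n_samples, {len(self.feature_names)})"
            )
        if X.shape[0] != y.size or y.size == 0:
            raise ValidationError("X and y must have matching, nonzero length")
        if not np.isfinite(X).all():
            raise ValidationError("feature matrix contains missing values")
        if np.any((y < 0) | (y > 4)):
            raise ValidationError("labels must be severity scores 0-4")
        self.root = self._grow(X, y, depth=0)
        return self

    def _class_counts(self, y: np.ndarray) -> np.ndarray:
        return np.bincount(y, minlength=len(SCORES))

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _Node:
        counts = self._class_counts(y)
        node = _Node(prediction=int(np.argmax(counts)), counts=counts.tolist())
        if (
            depth >= self.config.max_depth
            or np.unique(y).size == 1
            or y.size < 2 * self.config.min_samples_leaf
        ):
            return node
        split = self._best_split(X, y)
        if split is None:
            return node
        j, threshold = split
        mask = X[:, j] <= threshold
        node.feature = self.feature_names[j]
        node.threshold = threshold
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def _best_split(self, X: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
        n = y.size
        min_leaf = self.config.min_samples_leaf
        best_impurity = np.inf
        best: tuple[int, float] | None = None
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xj, yj = X[order, j], y[order]
            # cumulative class counts left of each boundary
            onehot = np.zeros((n, len(SCORES)))
            onehot[np.arange(n), yj] = 1.0
            cum = np.cumsum(onehot, axis=0)
            total = cum[-1]
            for i in range(min_leaf - 1, n - min_leaf):
                if xj[i + 1] <= xj[i]:
                    continue  # not a boundary between distinct values
                left = cum[i]
                right = total - left
                nl, nr = i + 1, n - i - 1
                impurity = (nl * _gini(left) + nr * _gini(right)) / n
                if impurity < best_impurity - 1e-12:
                    best_impurity = impurity
                    best = (j, float(0.5 * (xj[i] + xj[i + 1])))
        # zero-gain splits are allowed (as in standard CART): structure like
        # XOR only pays off two levels down
        return best

    # -- prediction ---------------------------------------------------------

    def _coerce(self, features) -> np.ndarray:
        if isinstance(features, FeatureVector):
            return features.to_array()[None, :]
        if isinstance(features, dict):
            missing = set(self.feature_names) - set(features)
            if missing:
                raise ValidationError(f"missing features: {sorted(missing)}")
            extra = set(features) - set(self.feature_names)
            if extra:
                raise ValidationError(f"unknown features: {sorted(extra)}")
            return np.array([[features[n] for n in self.feature_names]], dtype=float)
        arr = np.asarray(features, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
            )
        return arr

    def predict(self, features) -> np.ndarray:
        """Root-to-leaf traversal; accepts FeatureVector, dict, 1-D or 2-D array."""
        if self.root is None:
            raise ValidationError("model is not fitted")
        X = self._coerce(features)
        name_to_idx = {n: i for i, n in enumerate(self.feature_names)}
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                idx = name_to_idx[node.feature]
                node = node.left if row[idx] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.root is None:
            raise ValidationError("model is not fitted")
        return {
            "model": "decision_tree",
            "feature_names": list(self.feature_names),
            "config": {
                "max_depth": self.config.max_depth,
                "min_samples_leaf": self.config.min_samples_leaf,
            },
            "tree": self.root.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTreeModel":
        model = cls(
            TreeConfig(
                max_depth=int(d["config"]["max_depth"]),
                min_samples_leaf=int(d["config"]["min_samples_leaf"]),
            )
        )
        model.feature_names = tuple(d["feature_names"])
        model.root = _Node.from_dict(d["tree"])
        return model

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        return cls.from_dict(json.loads(text))

    def describe(self) -> str:
        """Indented, human-readable rendering of the decision rules."""
        lines: list[str] = []

        def _walk(node: _Node, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}{prefix}score {node.prediction}  counts={node.counts}")
            else:
                lines.append(f"{pad}{prefix}{node.feature} <= {node.threshold:.4g}?")
                _walk(node.left, indent + 1, "yes: ")
                _walk(node.right, indent + 1, "no:  ")

        if self.root is None:
            return "<unfitted>"
        _walk(self.root, 0, "")
        return "\n".join(lines)


def train_tree(
    X: np.ndarray,
    y: Sequence[int],
    config: TreeConfig | None = None,
    seed: int | None = None,  # noqa: ARG001 - training is deterministic; kept for API symmetry
) -> DecisionTreeModel:
    """Train the deterministic CART; ``seed`` is accepted but unused."""
    return DecisionTreeModel(config).fit(X, y)


# --------------------------------------------------------------------------
# rule-based baseline


@dataclass
class BaselineSPConfig:
    """Numeric cutoffs for the literal clinical-criteria classifier.

    The interruption bands come straight from the rating scale.  Slowing
    cutoffs are on the mean pseudo-velocity (palm units/s) and sit at the
    midpoints between adjacent class means of the default synthetic severity
    grid; the amplitude floor and minimum tap count encode "can only barely
    perform".  ``decrement_slope`` is the incremental-slope threshold below
    which an amplitude trend counts as a decrement.
    """

    slowing_slight: float = 6.5
    slowing_mild: float = 3.9
    slowing_moderate: float = 1.6
    decrement_slope: float = -0.005
    amp_floor: float = 0.15
    min_taps: int = 4


def baseline_sp(
    features: FeatureVector | dict,
    config: BaselineSPConfig | None = None,
) -> int:
    """Severity by the literal rating criteria; worst triggered rule wins.

    Rules (each yields a minimum score; the max is returned, default 0):

    * interruptions (halt/hesitation count): 1-2 -> 1, 3-5 -> 2, >5 -> 3;
    * amplitude decrement (incremental slope below ``decrement_slope``):
      onset in the last third of taps -> 1, middle third -> 2,
      right after the first tap (breakpoint <= 2) -> 3;
    * slowing: mean velocity below the slight/mild/moderate cutoffs
      -> 1/2/3;
    * barely performable (fewer than ``min_taps`` peaks or mean amplitude
      below ``amp_floor``) -> 4.

    The criteria are deliberately strict at class boundaries, as a literal
    reading of the scale is.
    """
    cfg = config or BaselineSPConfig()
    get = features.__getitem__ if isinstance(features, (FeatureVector, dict)) else None
    if get is None:
        raise ValidationError("features must be a FeatureVector or dict")
    hh = int(round(float(get("hh"))))
    n_peaks = int(round(float(get("n_peaks"))))
    amp_avg = float(get("amp_avg"))
    vel_avg = float(get("vel_avg"))
    amp_bp = float(get("amp_bp"))
    amp_alpha2 = float(get("amp_alpha2"))

    triggered = [0]
    if hh > 5:
        triggered.append(3)
    elif hh >= 3:
        triggered.append(2)
    elif hh >= 1:
        triggered.append(1)

    if amp_alpha2 < cfg.decrement_slope and n_peaks > 0:
        position = amp_bp / n_peaks
        if amp_bp <= 2:
            triggered.append(3)
        elif position <= 2.0 / 3.0:
            triggered.append(2)
        else:
            triggered.append(1)

    if vel_avg < cfg.slowing_moderate:
        triggered.append(3)
    elif vel_avg < cfg.slowing_mild:
        triggered.append(2)
    elif vel_avg < cfg.slowing_slight:
        triggered.append(1)

    if n_peaks < cfg.min_taps or amp_avg < cfg.amp_floor:
        triggered.append(4)

    return max(triggered)


# --------------------------------------------------------------------------
# split utility


def stratified_split(
    X: np.ndarray,
    y: Sequence[int],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified random train/test split with a stored seed.

    Returns (X_train, X_test, y_train, y_test); class proportions are
    preserved in both parts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    return train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
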