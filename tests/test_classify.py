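import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from fingertap import (
    FEATURE_NAMES,
    BaselineSPConfig,
    DecisionTreeModel,
    TreeConfig,
    ValidationError,
    baseline_sp,
    stratified_split,
    train_tree,
)

N_FEAT = len(FEATURE_NAMES)


def embed(col0, extra=None, rng=None):
    """Place a 1-D feature into column 0 of an otherwise-zero 15-col matrix."""
    X = np.zeros((len(col0), N_FEAT))
    X[:, 0] = col0
    if extra is not None:
        X[:, 1] = extra
    return X


class TestTreeTraining:
    def test_separable_1d_gives_depth_one_split(self):
        x0 = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0, 9.0])
        y = (x0 >= 5).astype(int)
        model = train_tree(embed(x0), y)
        root = model.root
        assert not root.is_leaf
        assert root.feature == FEATURE_NAMES[0]
        assert 4.0 < root.threshold <= 6.0
        assert root.left.is_leaf and root.right.is_leaf
        assert np.array_equal(model.predict(embed(x0)), y)

    def test_training_is_byte_deterministic(self, rng):
        X = rng.normal(size=(60, N_FEAT))
        y = rng.integers(0, 5, size=60)
        a = train_tree(X, y, seed=1).to_json()
        b = train_tree(X.copy(), y.copy(), seed=1).to_json()
        assert a == b and a.encode() == b.encode()

    def test_xor_needs_depth_two(self):
        x0 = np.array([0.0, 0.0, 1.0, 1.0] * 4)
        x1 = np.array([0.0, 1.0, 0.0, 1.0] * 4)
        y = (x0.astype(int) ^ x1.astype(int)).astype(int)
        X = embed(x0, x1)
        deep = train_tree(X, y, TreeConfig(max_depth=2, min_samples_leaf=1))
        assert np.mean(deep.predict(X) == y) == 1.0
        shallow = train_tree(X, y, TreeConfig(max_depth=1, min_samples_leaf=1))
        assert np.mean(shallow.predict(X) == y) <= 0.75

    def test_single_class_gives_stump(self):
        X = np.zeros((5, N_FEAT))
        model = train_tree(X, [2] * 5)
        assert model.root.is_leaf and model.root.prediction == 2

    def test_memorizes_unique_values_when_fully_grown(self, rng):
        X = rng.normal(size=(16, N_FEAT))
        y = rng.integers(0, 5, size=16)
        model = train_tree(X, y, TreeConfig(max_depth=20, min_samples_leaf=1))
        assert np.array_equal(model.predict(X), y)

    def test_matches_sklearn_training_accuracy(self, rng):
        """Independent CART implementation agrees with sklearn on fit quality."""
        X = rng.normal(size=(120, N_FEAT))
        w = rng.normal(size=N_FEAT)
        y = np.digitize(X @ w, np.quantile(X @ w, [0.2, 0.4, 0.6, 0.8]))
        ours = train_tree(X, y, TreeConfig(max_depth=5, min_samples_leaf=2))
        theirs = DecisionTreeClassifier(
            max_depth=5, min_samples_leaf=2, random_state=0
        ).fit(X, y)
        acc_ours = np.mean(ours.predict(X) == y)
        acc_theirs = theirs.score(X, y)
        assert abs(acc_ours - acc_theirs) < 0.05


class TestTreePrediction:
    def test_manual_two_node_tree(self):
        model = DecisionTreeModel.from_dict(
            {
                "model": "decision_tree",
                "feature_names": list(FEATURE_NAMES),
                "config": {"max_depth": 5, "min_samples_leaf": 2},
                "tree": {
                    "leaf": False,
                    "feature": "amp_avg",
                    "threshold": 0.5,
                    "prediction": 0,
                    "counts": [1, 1, 0, 0, 0],
                    "left": {"leaf": True, "prediction": 3, "counts": [0, 0, 0, 1, 0]},
                    "right": {"leaf": True, "prediction": 0, "counts": [1, 0, 0, 0, 0]},
                },
            }
        )
        below = {name: 0.0 for name in FEATURE_NAMES} | {"amp_avg": 0.2}
        above = {name: 0.0 for name in FEATURE_NAMES} | {"amp_avg": 1.2}
        assert model.predict(below)[0] == 3
        assert model.predict(above)[0] == 0

    def test_unknown_feature_name_is_schema_error(self):
        model = train_tree(np.zeros((4, N_FEAT)), [1, 1, 1, 1])
        bad = {name: 0.0 for name in FEATURE_NAMES}
        bad["velocity_mean"] = bad.pop("vel_avg")
        with pytest.raises(ValidationError):
            model.predict(bad)

    def test_serialization_round_trip_predicts_identically(self, rng):
        X = rng.normal(size=(80, N_FEAT))
        y = rng.integers(0, 5, size=80)
        model = train_tree(X, y)
        clone = DecisionTreeModel.from_json(model.to_json())
        probe = rng.normal(size=(200, N_FEAT))
        assert np.array_equal(model.predict(probe), clone.predict(probe))


def _features(**overrides):
    base = {name: 0.0 for name in FEATURE_NAMES}
    base.update(
        amp_avg=1.2, amp_var=0.01, amp_bp=8.0, amp_alpha1=0.0, amp_alpha2=0.0,
        vel_avg=8.0, vel_var=0.1, vel_bp=8.0, freq=3.0, hh=0.0, n_peaks=10.0,
        age=65.0, sex=1.0,
    )
    base.update(overrides)
    return base


class TestBaselineSP:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({}, 0),
            ({"hh": 1}, 1),
            ({"hh": 2}, 1),
            ({"hh": 3}, 2),
            ({"hh": 4}, 2),
            ({"hh": 5}, 2),
            ({"hh": 6}, 3),
            ({"hh": 11}, 3),
            ({"amp_alpha2": -0.1, "amp_bp": 8.0}, 1),   # decrement near the end
            ({"amp_alpha2": -0.1, "amp_bp": 5.0}, 2),   # midway
            ({"amp_alpha2": -0.1, "amp_bp": 2.0}, 3),   # right after the first tap
            ({"vel_avg": 5.0}, 1),                       # slight slowing
            ({"vel_avg": 3.0}, 2),                       # mild slowing
            ({"vel_avg": 1.0}, 3),                       # moderate slowing
            ({"n_peaks": 3.0}, 4),                       # can barely perform
            ({"amp_avg": 0.1}, 4),
            ({"hh": 1, "vel_avg": 1.0}, 3),              # worst criterion wins
        ],
    )
    def test_rule_table(self, overrides, expected):
        assert baseline_sp(_features(**overrides)) == expected

    def test_monotone_in_halt_count(self):
        scores = [baseline_sp(_features(hh=h)) for h in range(0, 12)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_config_cutoffs_respected(self):
        cfg = BaselineSPConfig(slowing_slight=100.0)
        assert baseline_sp(_features(), cfg) == 1  # everything is "slow" now


class TestSplit:
    def test_stratified_proportions(self, rng):
        X = rng.normal(size=(100, N_FEAT))
        y = np.repeat(np.arange(5), 20)
        Xtr, Xte, ytr, yte = stratified_split(X, y, test_fraction=0.2, seed=3)
        assert len(yte) == 20
        assert all(np.sum(yte == c) == 4 for c in range(5))
        # reproducible by seed
        _, _, _, yte2 = stratified_split(X, y, test_fraction=0.2, seed=3)
        assert np.array_equal(yte, yte2)
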