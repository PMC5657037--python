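"""Decision-tree induction: information measures, split search against a
brute-force oracle, missing-value weighting, pruning, prediction and
model serialization."""

import math

import numpy as np
import pytest

from snvensemble import (
    Label,
    TrainParams,
    best_split,
    entropy,
    information_gain,
    load_model,
    predict,
    rank_features_info_gain,
    save_model,
    train_tree,
)
from snvensemble.features import FeatureVector
from snvensemble.labeling import LabeledExample
from snvensemble.tree import ModelFormatError, fit_arrays, pessimistic_error_bound

from conftest import site, toy_schema


# ---------------------------------------------------------------------------
# independent oracle: plain-loop enumeration of every candidate rule
# ---------------------------------------------------------------------------

def oracle_entropy(counts):
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c > 0)


def oracle_rule_gain(values, y, w, mask_fn, min_leaf):
    """Known-mass-scaled gain of one candidate partition; None if inadmissible."""
    known = [i for i, v in enumerate(values) if v is not None and not (isinstance(v, float) and math.isnan(v))]
    w_total = sum(w)
    w_known = sum(w[i] for i in known)
    if w_known <= 0:
        return None
    def class_counts(idx):
        return [sum(w[i] for i in idx if y[i] == c) for c in (0, 1)]
    left = [i for i in known if mask_fn(values[i])]
    right = [i for i in known if not mask_fn(values[i])]
    wl, wr = sum(w[i] for i in left), sum(w[i] for i in right)
    if wl < min_leaf or wr < min_leaf:
        return None
    h = oracle_entropy(class_counts(known))
    gain = h
    for side, ws in ((left, wl), (right, wr)):
        if ws > 0:
            gain -= (ws / w_known) * oracle_entropy(class_counts(side))
    return (w_known / w_total) * gain


def oracle_best_gain(X, y, w, schema, min_leaf=2.0):
    """Exhaustive max gain over all thresholds/categories of all features."""
    best = 0.0
    for j, name in enumerate(schema.names):
        col = [None if np.isnan(X[i, j]) else X[i, j] for i in range(len(y))]
        known_vals = sorted({v for v in col if v is not None})
        kind = schema.kinds[name]
        if kind == "numeric":
            for a, b in zip(known_vals, known_vals[1:]):
                thr = (a + b) / 2
                g = oracle_rule_gain(col, y, w, lambda v, t=thr: v <= t, min_leaf)
                if g is not None:
                    best = max(best, g)
        elif kind == "boolean":
            g = oracle_rule_gain(col, y, w, lambda v: v == 1.0, min_leaf)
            if g is not None:
                best = max(best, g)
        else:
            for code in known_vals:
                g = oracle_rule_gain(col, y, w, lambda v, c=code: v == c, min_leaf)
                if g is not None:
                    best = max(best, g)
    return best


def _random_dataset(rng, n_features=4, n_max=16):
    kinds = rng.choice(["numeric", "boolean", "categorical"], size=n_features)
    schema = toy_schema({f"GM_f{i}": k for i, k in enumerate(kinds)})
    n = int(rng.integers(4, n_max + 1))
    X = np.empty((n, n_features))
    for j, kind in enumerate(kinds):
        if kind == "numeric":
            X[:, j] = rng.choice([0.0, 1.0, 2.5, 7.0], size=n)
        else:
            X[:, j] = rng.choice([0.0, 1.0], size=n)
        X[rng.random(n) < 0.15, j] = np.nan
    y = rng.integers(0, 2, size=n)
    return schema, X, y


class TestInformationMeasures:
    @pytest.mark.parametrize(
        "counts,expected",
        [((2, 2), 1.0), ((4, 0), 0.0), ((9, 5), 0.94029)],
    )
    def test_entropy_examples(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-4)

    def test_entropy_requires_mass(self):
        with pytest.raises(ValueError):
            entropy((0, 0))

    @pytest.mark.parametrize(
        "parent,children,expected",
        [
            ((2, 2), [(2, 0), (0, 2)], 1.0),
            ((6, 3), [(4, 2), (2, 1)], 0.0),  # children keep the parent ratio
            ((9, 5), [(6, 2), (3, 3)], 0.04813),
        ],
    )
    def test_information_gain_examples(self, parent, children, expected):
        assert information_gain(parent, children) == pytest.approx(expected, abs=1e-4)

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            information_gain((4, 4), [(2, 0), (0, 1)])

    def test_entropy_bounded_by_log2_classes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 20, size=2) + np.array([1, 0])
            assert 0.0 <= entropy(counts) <= 1.0 + 1e-12


class TestBestSplit:
    def test_perfect_binary_separator(self):
        schema = toy_schema({"GM_flag": "boolean"})
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        y = np.array([1, 1, 0, 0])
        rule, gain = best_split(X, y, np.ones(4), schema)
        assert rule.feature == "GM_flag" and gain == pytest.approx(1.0)

    def test_pure_input_returns_none(self):
        schema = toy_schema({"GM_x": "numeric"})
        X = np.array([[1.0], [2.0]])
        assert best_split(X, np.array([1, 1]), np.ones(2), schema) is None

    def test_threshold_is_midpoint(self):
        schema = toy_schema({"GM_x": "numeric"})
        X = np.array([[1.0], [3.0], [10.0], [12.0]])
        y = np.array([0, 0, 1, 1])
        rule, _ = best_split(X, y, np.ones(4), schema, TrainParams(min_leaf=1))
        assert rule.threshold == pytest.approx(6.5)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        """Returned gain equals the exhaustive max on <=4-feature/<=16-example data."""
        rng = np.random.default_rng(seed)
        schema, X, y = _random_dataset(rng)
        w = np.ones(len(y))
        params = TrainParams(min_leaf=2)
        found = best_split(X, y, w, schema, params)
        expected = oracle_best_gain(X, y, w, schema, min_leaf=2)
        if found is None:
            assert expected == pytest.approx(0.0, abs=1e-9)
        else:
            assert found[1] == pytest.approx(expected, abs=1e-9)

    def test_tie_broken_by_schema_order(self):
        schema = toy_schema({"GM_a": "boolean", "GM_b": "boolean"})
        X = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.0], [0.0, 0.0]])
        y = np.array([1, 1, 0, 0])
        rule, _ = best_split(X, y, np.ones(4), schema)
        assert rule.feature == "GM_a"


def _examples(schema, rows, labels):
    out = []
    for i, (row, label) in enumerate(zip(rows, labels)):
        vec = FeatureVector(site(i + 1), list(row))
        out.append(LabeledExample(vec, Label.SOMATIC if label else Label.NOT_SOMATIC))
    return out


class TestTrainAndPredict:
    def test_single_label_gives_single_leaf(self):
        schema = toy_schema({"GM_x": "numeric"})
        model = train_tree(_examples(schema, [[1.0], [2.0]], [1, 1]), schema)
        assert model.root.is_leaf and model.root.predicted is Label.SOMATIC

    def test_xor_learned_at_depth_two(self):
        schema = toy_schema({"GM_a": "boolean", "GM_b": "boolean"})
        rows = [[False, False], [False, True], [True, False], [True, True]]
        labels = [0, 1, 1, 0]
        model = train_tree(_examples(schema, rows, labels), schema, TrainParams(min_leaf=1, prune=False))
        assert not model.root.is_leaf
        assert not model.root.true_child.is_leaf or not model.root.false_child.is_leaf
        for row, label in zip(rows, labels):
            pred, _ = predict(model, FeatureVector(site(99), list(row)))
            assert pred is (Label.SOMATIC if label else Label.NOT_SOMATIC)

    def test_weight_conserved_under_missing(self):
        schema = toy_schema({"GM_x": "numeric", "GM_y": "numeric"})
        rows = [[1.0, 5.0], [2.0, 6.0], [None, 7.0], [8.0, 1.0], [9.0, 2.0], [10.0, None]]
        labels = [0, 0, 0, 1, 1, 1]
        model = train_tree(_examples(schema, rows, labels), schema, TrainParams(min_leaf=1, prune=False))

        def check(node):
            if node.is_leaf:
                return
            assert node.true_child.total + node.false_child.total == pytest.approx(node.total, abs=1e-9)
            check(node.true_child)
            check(node.false_child)

        assert not model.root.is_leaf
        check(model.root)

    def test_all_missing_vector_scores_root_prior(self):
        schema = toy_schema({"GM_x": "numeric", "GM_y": "boolean"})
        rows = [[1.0, True], [2.0, True], [3.0, False], [8.0, False], [9.0, True], [10.0, False]]
        labels = [0, 0, 0, 1, 1, 1]
        model = train_tree(_examples(schema, rows, labels), schema, TrainParams(min_leaf=1, prune=False))
        _, score = predict(model, FeatureVector(site(1), [None, None]))
        assert score == pytest.approx(model.root.somatic_fraction, abs=1e-9)

    def test_scores_in_unit_interval_and_complementary(self):
        schema = toy_schema({"GM_x": "numeric"})
        model = train_tree(_examples(schema, [[1.0], [2.0], [8.0], [9.0]], [0, 0, 1, 1]), schema, TrainParams(min_leaf=1))
        for value in ([0.5], [8.5], [None]):
            label, score = predict(model, FeatureVector(site(1), list(value)))
            assert 0.0 <= score <= 1.0
            assert (label is Label.SOMATIC) == (score >= 0.5)

    def test_training_examples_reproduced_on_consistent_data(self):
        rng = np.random.default_rng(5)
        schema = toy_schema({"GM_a": "numeric", "GM_b": "numeric"})
        rows = [[float(rng.integers(0, 10)), float(rng.integers(0, 10))] for _ in range(12)]
        labels = [int(r[0] + r[1] > 9) for r in rows]
        # drop duplicate-feature conflicts to keep the data consistent
        seen = {}
        rows2, labels2 = [], []
        for r, l in zip(rows, labels):
            key = tuple(r)
            if key not in seen:
                seen[key] = l
                rows2.append(r)
                labels2.append(l)
        model = train_tree(_examples(schema, rows2, labels2), schema, TrainParams(min_leaf=1, prune=False))
        for r, l in zip(rows2, labels2):
            pred, _ = predict(model, FeatureVector(site(1), list(r)))
            assert pred is (Label.SOMATIC if l else Label.NOT_SOMATIC)

    def test_empty_input_rejected(self):
        schema = toy_schema({"GM_x": "numeric"})
        with pytest.raises(ValueError):
            train_tree([], schema)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        schema, X, y = _random_dataset(rng, n_features=3, n_max=16)
        m1 = fit_arrays(X, y.copy(), schema)
        m2 = fit_arrays(X, y.copy(), schema)
        assert _structure(m1.root) == _structure(m2.root)

    def test_matches_sklearn_root_split_on_complete_data(self):
        """Independent check: sklearn's entropy tree picks the same root split."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        y = (X[:, 1] > 0.3).astype(int)
        schema = toy_schema({"GM_a": "numeric", "GM_b": "numeric", "GM_c": "numeric"})
        rule, _ = best_split(X, y, np.ones(len(y)), schema, TrainParams(min_leaf=2))
        clf = sklearn_tree.DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2, random_state=0).fit(X, y)
        assert schema.index(rule.feature) == clf.tree_.feature[0]
        assert rule.threshold == pytest.approx(clf.tree_.threshold[0], abs=1e-6)


class TestPruning:
    def test_bound_closed_form_at_zero_errors(self):
        # zero observed errors in n: bound is n * (1 - CF^(1/n))
        for n in (1.0, 5.0, 20.0):
            assert pessimistic_error_bound(0.0, n, 0.25) == pytest.approx(n * (1 - 0.25 ** (1 / n)), rel=1e-9)

    def test_pruned_not_larger_than_unpruned(self):
        rng = np.random.default_rng(2)
        schema = toy_schema({"GM_a": "numeric", "GM_b": "numeric"})
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.5).astype(int)  # pure noise: pruning should bite
        unpruned = fit_arrays(X, y, schema, TrainParams(prune=False, min_leaf=1))
        pruned = fit_arrays(X, y, schema, TrainParams(prune=True, min_leaf=1))
        assert _count_nodes(pruned.root) <= _count_nodes(unpruned.root)

    def test_pruning_never_worsens_pessimistic_estimate(self):
        from snvensemble.tree import _subtree_error_estimate

        rng = np.random.default_rng(4)
        schema = toy_schema({"GM_a": "numeric"})
        X = rng.normal(size=(30, 1))
        y = (X[:, 0] + rng.normal(scale=1.0, size=30) > 0).astype(int)
        unpruned = fit_arrays(X, y, schema, TrainParams(prune=False, min_leaf=1))
        pruned = fit_arrays(X, y, schema, TrainParams(prune=True, min_leaf=1))
        assert _subtree_error_estimate(pruned.root, 0.25) <= _subtree_error_estimate(unpruned.root, 0.25) + 1e-9


class TestRanking:
    def test_constant_feature_zero_gain(self):
        schema = toy_schema({"GM_a": "numeric", "GM_b": "numeric"})
        examples = _examples(schema, [[5.0, float(i)] for i in range(6)], [0, 0, 0, 1, 1, 1])
        gains = dict(rank_features_info_gain(examples, schema))
        assert gains["GM_a"] == 0.0

    def test_perfect_separator_ranks_first(self):
        schema = toy_schema({"GM_noise": "numeric", "GM_sep": "boolean"})
        rows = [[1.0, True], [4.0, True], [2.0, False], [3.0, False]]
        ranking = rank_features_info_gain(_examples(schema, rows, [1, 1, 0, 0]), schema)
        assert ranking[0] == ("GM_sep", pytest.approx(1.0))

    def test_gains_match_per_feature_oracle(self):
        rng = np.random.default_rng(17)
        schema, X, y = _random_dataset(rng, n_features=3, n_max=10)

        def decode(name, v):
            if np.isnan(v):
                return None
            if schema.kinds[name] == "categorical":
                return schema.categories[name][int(v)]
            return v

        vectors = [
            FeatureVector(site(i + 1), [decode(n, v) for n, v in zip(schema.names, row)])
            for i, row in enumerate(X)
        ]
        examples = [
            LabeledExample(v, Label.SOMATIC if label else Label.NOT_SOMATIC) for v, label in zip(vectors, y)
        ]
        for name, gain in rank_features_info_gain(examples, schema):
            j = schema.index(name)
            sub = toy_schema({name: schema.kinds[name]})
            expected = oracle_best_gain(X[:, [j]], y, np.ones(len(y)), sub, min_leaf=1)
            assert gain == pytest.approx(expected, abs=1e-9)


def _count_nodes(node):
    if node.is_leaf:
        return 1
    return 1 + _count_nodes(node.true_child) + _count_nodes(node.false_child)


def _structure(node):
    if node.is_leaf:
        return ("leaf", tuple(round(c, 9) for c in node.counts), node.predicted.value)
    r = node.rule
    return (
        "split",
        r.feature,
        r.kind,
        None if r.threshold is None else round(r.threshold, 9),
        r.category,
        round(node.p_true, 9),
        _structure(node.true_child),
        _structure(node.false_child),
    )


class TestSerialization:
    def _xor_model(self):
        schema = toy_schema({"GM_a": "boolean", "GM_b": "boolean"})
        rows = [[False, False], [False, True], [True, False], [True, True]]
        return train_tree(_examples(schema, rows, [0, 1, 1, 0]), schema, TrainParams(min_leaf=1, prune=False))

    def test_round_trip_single_leaf(self, tmp_path):
        schema = toy_schema({"GM_x": "numeric"})
        model = train_tree(_examples(schema, [[1.0]], [1]), schema)
        path = tmp_path / "m.txt"
        save_model(model, path)
        back = load_model(path)
        assert _structure(back.root) == _structure(model.root)
        assert predict(back, FeatureVector(site(1), [None]))[1] == predict(model, FeatureVector(site(1), [None]))[1]

    def test_round_trip_xor_structure(self, tmp_path):
        model = self._xor_model()
        path = tmp_path / "m.txt"
        save_model(model, path)
        back = load_model(path)
        assert _structure(back.root) == _structure(model.root)
        assert back.schema.names == model.schema.names
        assert back.params == model.params

    def test_truncated_file_rejected(self, tmp_path):
        model = self._xor_model()
        path = tmp_path / "m.txt"
        save_model(model, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("not a model\nend\n")
        with pytest.raises(ModelFormatError):
            load_model(path)
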