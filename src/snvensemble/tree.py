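"""C4.5-style binary decision tree for somatic/not-somatic classification.

The classifier is an ID3-family tree: at every internal node the split
maximizing information gain (reduction in label entropy) is chosen from
midpoint thresholds on numeric features, one-vs-rest tests on
categorical features, and the single test on boolean features.  Missing
values are handled the C4.5 way: the per-feature gain is computed on the
examples where the feature is known and scaled by the known mass
fraction, and examples missing the split feature descend both branches
with fractional weights proportional to the known mass on each branch.
Post-pruning is pessimistic subtree replacement: a subtree is collapsed
to a leaf when the leaf's upper-confidence-bound error estimate is no
worse than the subtree's.

Binary splits only; the rule-true branch is the left child.  Class 1 is
SOMATIC, class 0 is NOT_SOMATIC; a leaf predicts SOMATIC when its
weighted SOMATIC fraction is at least 0.5.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import beta as beta_dist

from .features import FeatureSchema, FeatureVector, encode_matrix
from .labeling import LabeledExample
from .sites import Label

_TIE_TOL = 1e-12

LABEL_TO_INT = {Label.NOT_SOMATIC: 0, Label.SOMATIC: 1}
INT_TO_LABEL = {0: Label.NOT_SOMATIC, 1: Label.SOMATIC}


class ModelFormatError(ValueError):
    """A serialized model file is corrupted or truncated."""


# ---------------------------------------------------------------------------
# information measures
# ---------------------------------------------------------------------------

def entropy(counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-count vector."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("class counts must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("entropy of an empty node is undefined")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(parent: Sequence[float], children: Sequence[Sequence[float]]) -> float:
    """entropy(parent) − Σ w_child · entropy(child), in bits."""
    parent_arr = np.asarray(parent, dtype=float)
    child_arrs = [np.asarray(c, dtype=float) for c in children]
    total = parent_arr.sum()
    if not np.allclose(sum(c.sum() for c in child_arrs), total, atol=1e-6):
        raise ValueError("child counts must sum to parent counts")
    gain = entropy(parent_arr) - sum(
        (c.sum() / total) * entropy(c) for c in child_arrs if c.sum() > 0
    )
    return float(max(gain, 0.0))


def _h2(p1: np.ndarray) -> np.ndarray:
    """Vectorized binary entropy given the class-1 probability."""
    p1 = np.clip(p1, 0.0, 1.0)
    out = np.zeros_like(p1)
    for p in (p1, 1.0 - p1):
        mask = p > 0
        out[mask] -= p[mask] * np.log2(p[mask])
    return out


# ---------------------------------------------------------------------------
# model structures
# ---------------------------------------------------------------------------

@dataclass
class SplitRule:
    """One binary test; exactly the fields for its kind are set."""

    feature: str
    kind: str  # numeric_threshold | category_equals | boolean
    threshold: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "numeric_threshold" and (self.threshold is None or self.category is not None):
            raise ValueError("numeric_threshold rules carry only a threshold")
        if self.kind == "category_equals" and (self.category is None or self.threshold is not None):
            raise ValueError("category_equals rules carry only a category")
        if self.kind == "boolean" and (self.threshold is not None or self.category is not None):
            raise ValueError("boolean rules carry neither threshold nor category")

    def is_true(self, encoded_value: float, category_code: Optional[int] = None) -> bool:
        if self.kind == "numeric_threshold":
            return encoded_value <= self.threshold
        if self.kind == "boolean":
            return encoded_value == 1.0
        return encoded_value == category_code


@dataclass
class TreeNode:
    counts: tuple[float, float]  # (NOT_SOMATIC, SOMATIC) weighted training mass
    rule: Optional[SplitRule] = None
    true_child: Optional["TreeNode"] = None
    false_child: Optional["TreeNode"] = None
    p_true: float = 0.5  # fraction of known mass sent down the rule-true branch

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    @property
    def total(self) -> float:
        return self.counts[0] + self.counts[1]

    @property
    def somatic_fraction(self) -> float:
        return self.counts[1] / self.total if self.total > 0 else 0.5

    @property
    def predicted(self) -> Label:
        return Label.SOMATIC if self.somatic_fraction >= 0.5 else Label.NOT_SOMATIC

    @property
    def confidence(self) -> float:
        return max(self.somatic_fraction, 1.0 - self.somatic_fraction)


@dataclass
class TrainParams:
    min_leaf: float = 2.0
    prune: bool = True
    prune_confidence: float = 0.25
    max_depth: Optional[int] = None
    seed: int = 0
    criterion: str = "gain"  # or "gain_ratio"
    missing_mode: str = "fractional"  # or "as_category" (missing follows the false branch)
    zero_gain_fallback: bool = True  # split impure nodes even at zero gain (parity labels)

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not (0.0 < self.prune_confidence < 1.0):
            raise ValueError("prune_confidence must be in (0,1)")


@dataclass
class TreeModel:
    root: TreeNode
    schema: FeatureSchema
    params: TrainParams

    def __post_init__(self) -> None:
        def check(node: TreeNode) -> None:
            if node.rule is not None:
                if node.rule.feature not in node_schema_names:
                    raise ValueError(f"split feature {node.rule.feature!r} not in schema")
                check(node.true_child)
                check(node.false_child)

        node_schema_names = set(self.schema.names)
        check(self.root)


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

def _node_entropy(w0: float, w1: float) -> float:
    total = w0 + w1
    if total <= 0:
        return 0.0
    return float(_h2(np.array([w1 / total]))[0])


def _best_numeric_split(vals, wk, yk, h_known, w_known, min_leaf):
    order = np.argsort(vals, kind="mergesort")
    v = vals[order]
    wo = wk[order]
    w1o = wo * (yk[order] == 1)
    cum_w = np.cumsum(wo)
    cum_w1 = np.cumsum(w1o)
    boundaries = np.nonzero(v[1:] > v[:-1])[0]
    if boundaries.size == 0:
        return None, 0.0
    thresholds = (v[boundaries] + v[boundaries + 1]) / 2.0
    wl = cum_w[boundaries]
    w1l = cum_w1[boundaries]
    wr = w_known - wl
    w1r = cum_w1[-1] - w1l
    valid = (wl >= min_leaf) & (wr >= min_leaf) & np.isfinite(thresholds)
    if not valid.any():
        return None, 0.0
    hl = _h2(np.divide(w1l, wl, out=np.zeros_like(w1l), where=wl > 0))
    hr = _h2(np.divide(w1r, wr, out=np.zeros_like(w1r), where=wr > 0))
    gains = h_known - (wl / w_known) * hl - (wr / w_known) * hr
    gains[~valid] = -np.inf
    best = float(np.max(gains))
    # smallest threshold among ties
    idx = int(np.nonzero(gains >= best - _TIE_TOL)[0][0])
    return float(thresholds[idx]), best


def _split_info(wl: float, wr: float) -> float:
    total = wl + wr
    if total <= 0:
        return 0.0
    return _node_entropy(wl, wr)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    schema: FeatureSchema,
    params: Optional[TrainParams] = None,
    _allow_zero_gain: bool = False,
) -> Optional[tuple[SplitRule, float]]:
    """Highest-gain binary rule over all features, or None if no rule helps.

    Gain on a feature is computed over the examples where that feature is
    known and scaled by the known-mass fraction; ties are broken by
    schema order, then by smaller threshold.  Candidates leaving less
    than ``min_leaf`` known mass on either side are discarded.

    ``_allow_zero_gain`` is the training-time fallback for impure nodes
    where every admissible split has zero gain (parity-style label
    structure): the first admissible rule is returned so recursion can
    expose gain one level deeper; pruning removes such splits when they
    never pay off.
    """
    params = params or TrainParams()
    w_total = float(w.sum())
    best_rule: Optional[SplitRule] = None
    best_gain = -1.0 if _allow_zero_gain else 0.0
    for j, name in enumerate(schema.names):
        col = X[:, j]
        known = ~np.isnan(col)
        if params.missing_mode == "as_category":
            # missing is routed down the false branch; treat it as a real
            # (sentinel) value so its mass participates in the gain
            col = np.where(known, col, np.inf)
            known = np.ones_like(known)
        w_known = float(w[known].sum())
        if w_known <= 0:
            continue
        scale = w_known / w_total
        yk = y[known]
        wk = w[known].astype(float)
        w1 = float(wk[yk == 1].sum())
        h_known = _node_entropy(w_known - w1, w1)
        if h_known <= 0:
            continue
        kind = schema.kinds[name]
        vals = col[known].astype(float)
        candidates: list[tuple[SplitRule, float]] = []

        def two_way_gain(mask: np.ndarray) -> Optional[float]:
            wl = float(wk[mask].sum())
            wr = w_known - wl
            if wl < params.min_leaf or wr < params.min_leaf:
                return None
            w1l = float(wk[mask & (yk == 1)].sum())
            w1r = w1 - w1l
            return (
                h_known
                - (wl / w_known) * _node_entropy(wl - w1l, w1l)
                - (wr / w_known) * _node_entropy(wr - w1r, w1r)
            )

        if kind == "numeric":
            threshold, gain = _best_numeric_split(vals, wk, yk, h_known, w_known, params.min_leaf)
            if threshold is not None:
                candidates.append((SplitRule(name, "numeric_threshold", threshold=threshold), gain))
        elif kind == "boolean":
            gain = two_way_gain(vals == 1.0)
            if gain is not None:
                candidates.append((SplitRule(name, "boolean"), gain))
        else:  # categorical, one-vs-rest
            for code in np.unique(vals):
                if not np.isfinite(code):
                    continue  # as_category sentinel never matches a category
                gain = two_way_gain(vals == code)
                if gain is not None:
                    category = schema.categories[name][int(code)]
                    candidates.append((SplitRule(name, "category_equals", category=category), gain))
        for rule, gain in candidates:
            gain *= scale
            if params.criterion == "gain_ratio":
                si = _rule_split_info(rule, vals, wk, schema, name)
                gain = gain / si if si > 0 else 0.0
            if gain > best_gain + _TIE_TOL:
                best_gain = gain
                best_rule = rule
    if best_rule is None or (not _allow_zero_gain and best_gain <= _TIE_TOL):
        return None
    return best_rule, float(max(best_gain, 0.0))


def _rule_split_info(rule: SplitRule, vals, wk, schema, name) -> float:
    mask = _rule_mask(rule, vals, schema)
    wl = float(wk[mask].sum())
    return _split_info(wl, float(wk.sum()) - wl)


def _rule_mask(rule: SplitRule, vals: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    if rule.kind == "numeric_threshold":
        return vals <= rule.threshold
    if rule.kind == "boolean":
        return vals == 1.0
    code = schema.categories[rule.feature].index(rule.category)
    return vals == code


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _examples_to_arrays(examples: Sequence[LabeledExample], schema: FeatureSchema):
    vectors = [ex.vector for ex in examples]
    X = encode_matrix(vectors, schema)
    y = np.array([LABEL_TO_INT[ex.label] for ex in examples], dtype=int)
    return X, y


def _build(X, y, w, schema, params, depth) -> TreeNode:
    w1 = float(w[y == 1].sum())
    w0 = float(w.sum()) - w1
    node = TreeNode(counts=(w0, w1))
    if w0 <= _TIE_TOL or w1 <= _TIE_TOL:
        return node
    if params.max_depth is not None and depth >= params.max_depth:
        return node
    if w.sum() < 2 * params.min_leaf:
        return node
    found = best_split(X, y, w, schema, params)
    if found is None and params.zero_gain_fallback:
        found = best_split(X, y, w, schema, params, _allow_zero_gain=True)
    if found is None:
        return node
    rule, _gain = found
    j = schema.index(rule.feature)
    col = X[:, j]
    known = ~np.isnan(col)
    mask_true = np.zeros(len(w), dtype=bool)
    vals = np.where(known, col, np.nan)
    mask_true[known] = _rule_mask(rule, vals[known], schema)
    w_true_known = float(w[known & mask_true].sum())
    w_known = float(w[known].sum())
    p_true = w_true_known / w_known if w_known > 0 else 0.5
    if params.missing_mode == "as_category":
        p_true_missing, p_false_missing = 0.0, 1.0
    else:
        p_true_missing, p_false_missing = p_true, 1.0 - p_true

    def branch(side_mask: np.ndarray, missing_frac: float):
        keep = side_mask | (~known & (missing_frac > 0))
        wb = w[keep].copy()
        wb[~known[keep]] *= missing_frac
        return X[keep], y[keep], wb

    Xt, yt, wt = branch(known & mask_true, p_true_missing)
    Xf, yf, wf = branch(known & ~mask_true, p_false_missing)
    if wt.sum() <= _TIE_TOL or wf.sum() <= _TIE_TOL:
        return node
    node.rule = rule
    node.p_true = p_true
    node.true_child = _build(Xt, yt, wt, schema, params, depth + 1)
    node.false_child = _build(Xf, yf, wf, schema, params, depth + 1)
    return node


def pessimistic_error_bound(errors: float, n: float, confidence: float) -> float:
    """Upper confidence bound on the true error count of a leaf.

    Exact binomial (beta-quantile) version of the C4.5 pessimistic
    estimate; for zero observed errors this is n·(1 − CF^(1/n)).
    """
    if n <= 0:
        return 0.0
    errors = min(max(errors, 0.0), n)
    if errors >= n:
        return n
    p_upper = float(beta_dist.ppf(1.0 - confidence, errors + 1.0, n - errors))
    return n * p_upper


def _subtree_error_estimate(node: TreeNode, confidence: float) -> float:
    if node.is_leaf:
        n = node.total
        errors = n - max(node.counts)
        return pessimistic_error_bound(errors, n, confidence)
    return _subtree_error_estimate(node.true_child, confidence) + _subtree_error_estimate(
        node.false_child, confidence
    )


def _prune(node: TreeNode, confidence: float) -> TreeNode:
    if node.is_leaf:
        return node
    node.true_child = _prune(node.true_child, confidence)
    node.false_child = _prune(node.false_child, confidence)
    n = node.total
    leaf_est = pessimistic_error_bound(n - max(node.counts), n, confidence)
    subtree_est = _subtree_error_estimate(node, confidence)
    if leaf_est <= subtree_est + 1e-9:
        node.rule = None
        node.true_child = None
        node.false_child = None
    return node


def train_tree(
    examples: Sequence[LabeledExample],
    schema: FeatureSchema,
    params: Optional[TrainParams] = None,
) -> TreeModel:
    """Induce a tree by recursive partitioning on information gain."""
    if not examples:
        raise ValueError("cannot train on an empty example list")
    for ex in examples:
        if ex.label not in (Label.SOMATIC, Label.NOT_SOMATIC):
            raise ValueError(f"training labels must be SOMATIC/NOT_SOMATIC, got {ex.label}")
    params = params or TrainParams()
    X, y = _examples_to_arrays(examples, schema)
    w = np.ones(len(examples), dtype=float)
    root = _build(X, y, w, schema, params, depth=0)
    if params.prune:
        root = _prune(root, params.prune_confidence)
    return TreeModel(root, schema, params)


def fit_arrays(X: np.ndarray, y: np.ndarray, schema: FeatureSchema, params: Optional[TrainParams] = None) -> TreeModel:
    """Train directly from an encoded matrix (used by cross-validation)."""
    params = params or TrainParams()
    root = _build(X, y, np.ones(len(y), dtype=float), schema, params, depth=0)
    if params.prune:
        root = _prune(root, params.prune_confidence)
    return TreeModel(root, schema, params)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _route(node: TreeNode, x: np.ndarray, schema: FeatureSchema, mass: float) -> float:
    """Weighted SOMATIC probability mass carried to the leaves."""
    if node.is_leaf:
        return mass * node.somatic_fraction
    j = schema.index(node.rule.feature)
    value = x[j]
    if np.isnan(value):
        return _route(node.true_child, x, schema, mass * node.p_true) + _route(
            node.false_child, x, schema, mass * (1.0 - node.p_true)
        )
    vals = np.array([value])
    goes_true = bool(_rule_mask(node.rule, vals, schema)[0])
    return _route(node.true_child if goes_true else node.false_child, x, schema, mass)


def predict(model: TreeModel, vector: Union[FeatureVector, np.ndarray]) -> tuple[Label, float]:
    """Classify one site: (label, SOMATIC score in [0,1]).

    Missing values distribute prediction mass down both branches using
    the training-time branch weights; an all-missing vector therefore
    scores the root class prior.
    """
    if isinstance(vector, FeatureVector):
        if len(vector.values) != len(model.schema):
            raise ValueError("feature vector does not match model schema")
        x = encode_matrix([vector], model.schema)[0]
    else:
        x = np.asarray(vector, dtype=float)
        if x.shape != (len(model.schema),):
            raise ValueError("encoded vector does not match model schema")
    score = _route(model.root, x, model.schema, 1.0)
    score = min(max(score, 0.0), 1.0)
    return (Label.SOMATIC if score >= 0.5 else Label.NOT_SOMATIC), score


def predict_matrix(model: TreeModel, X: np.ndarray) -> np.ndarray:
    """SOMATIC scores for each row of an encoded matrix."""
    return np.array([_route(model.root, x, model.schema, 1.0) for x in X])


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------

def rank_features_info_gain(
    examples: Sequence[LabeledExample], schema: FeatureSchema
) -> list[tuple[str, float]]:
    """Single-split information gain per feature, sorted descending.

    Numeric features use their best midpoint threshold; ties keep schema
    order.  Mirrors an InfoGain attribute ranking.
    """
    if len(examples) < 2:
        raise ValueError("ranking needs at least two examples")
    X, y = _examples_to_arrays(examples, schema)
    w = np.ones(len(examples), dtype=float)
    params = TrainParams(min_leaf=1.0, prune=False)
    gains: list[tuple[str, float]] = []
    w_total = float(w.sum())
    for name in schema.names:
        sub = FeatureSchema((name,), {name: schema.kinds[name]}, {k: v for k, v in schema.categories.items() if k == name})
        col = X[:, [schema.index(name)]]
        found = best_split(col, y, w, sub, params)
        gains.append((name, found[1] if found else 0.0))
    gains.sort(key=lambda kv: -kv[1])
    return gains


def export_feature_ranking(gains: Sequence[tuple[str, float]], path) -> None:
    """Tab-delimited ranking: rank, feature, gain."""
    with open(path, "wt") as fh:
        fh.write("rank\tfeature\tinfo_gain\n")
        for rank, (name, gain) in enumerate(gains, start=1):
            fh.write(f"{rank}\t{name}\t{gain:.6f}\n")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MODEL_MAGIC = "snvensemble-tree v1"


def save_model(model: TreeModel, path) -> None:
    """Serialize a model to the documented nested text format."""
    lines = [_MODEL_MAGIC]
    lines.append("features\t" + "\t".join(model.schema.names))
    lines.append("kinds\t" + json.dumps(model.schema.kinds))
    lines.append("categories\t" + json.dumps({k: list(v) for k, v in model.schema.categories.items()}))
    lines.append("params\t" + json.dumps(asdict(model.params)))
    lines.append("tree")

    def emit(node: TreeNode, depth: int) -> None:
        pad = "  " * depth
        w0, w1 = node.counts
        if node.is_leaf:
            lines.append(f"{pad}leaf {node.predicted.value} {w0:.9g} {w1:.9g}")
        else:
            r = node.rule
            detail = {"numeric_threshold": format(r.threshold, ".9g") if r.threshold is not None else "-",
                      "category_equals": r.category, "boolean": "-"}[r.kind]
            lines.append(f"{pad}split {r.feature} {r.kind} {detail} {node.p_true:.9g} {w0:.9g} {w1:.9g}")
            emit(node.true_child, depth + 1)
            emit(node.false_child, depth + 1)

    emit(model.root, 0)
    lines.append("end")
    with open(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> TreeModel:
    """Load a model saved by :func:`save_model`; inverse up to float text."""
    with open(path, "rt") as fh:
        lines = fh.read().splitlines()
    try:
        if lines[0] != _MODEL_MAGIC:
            raise ModelFormatError(f"not a model file (bad magic {lines[0]!r})")
        if lines[-1] != "end":
            raise ModelFormatError("model file is truncated (missing end marker)")
        header = {}
        for i, line in enumerate(lines[1:5], start=1):
            key, _, rest = line.partition("\t")
            header[key] = rest
        names = tuple(header["features"].split("\t"))
        kinds = json.loads(header["kinds"])
        categories = {k: tuple(v) for k, v in json.loads(header["categories"]).items()}
        schema = FeatureSchema(names, kinds, categories)
        params = TrainParams(**json.loads(header["params"]))
        if lines[5] != "tree":
            raise ModelFormatError("missing tree section")
        body = lines[6:-1]
        pos = [0]

        def parse(depth: int) -> TreeNode:
            line = body[pos[0]]
            indent = (len(line) - len(line.lstrip())) // 2
            if indent != depth:
                raise ModelFormatError(f"bad nesting at line {pos[0]}")
            pos[0] += 1
            parts = line.split()
            if parts[0] == "leaf":
                return TreeNode(counts=(float(parts[2]), float(parts[3])))
            if parts[0] != "split":
                raise ModelFormatError(f"unexpected node kind {parts[0]!r}")
            feature, kind, detail, p_true, w0, w1 = parts[1], parts[2], parts[3], parts[4], parts[5], parts[6]
            rule = SplitRule(
                feature,
                kind,
                threshold=float(detail) if kind == "numeric_threshold" else None,
                category=detail if kind == "category_equals" else None,
            )
            node = TreeNode(counts=(float(w0), float(w1)), rule=rule, p_true=float(p_true))
            node.true_child = parse(depth + 1)
            node.false_child = parse(depth + 1)
            return node

        root = parse(0)
        if pos[0] != len(body):
            raise ModelFormatError("trailing content after tree")
        return TreeModel(root, schema, params)
    except (IndexError, KeyError, ValueError, json.JSONDecodeError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"corrupted model file {path}: {exc}") from exc
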