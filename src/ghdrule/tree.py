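"""Gain-ratio decision-tree induction and false-positive branch pruning.

The model-building step grows a C4.5-style tree: nominal attributes split
multiway (one child per observed value), numeric attributes split binary
at a threshold, split quality is the gain ratio (information gain divided
by the intrinsic entropy of the partition), no post-pruning is applied,
and every child must hold at least ``min_records`` rows.  Induction is
deterministic: ties in gain ratio resolve to the earliest feature in
column order and, for numeric splits, the lowest threshold.

Missing values: rows whose split attribute is missing are excluded from
that split's evaluation and routed to the largest child at prediction
time.  By default the gain is *not* penalised for missingness, so a
partially observed attribute (an MRI finding, say) competes on the
strength of its observed subset — matching the behaviour under which
pituitary dysgenesis heads the clinical tree despite being unassessed in
most patients.  ``missing_gain_scaling=True`` switches to the C4.5
convention of scaling the gain by the known-value fraction.

The one non-standard operation is :meth:`TreeResults.prune_false_positive_branch`:
the subtree contributing the most false positives is collapsed into a
control-labelled leaf, trading sensitivity for specificity — the stated
priority of a rule meant to replace a diagnostic test.

Organisation follows the Model/Results convention: :class:`GainRatioTree`
holds the data and hyper-parameters, ``fit()`` returns a
:class:`TreeResults` carrying the fitted tree, predictions, diagnostics
and a ``summary()``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ANTERIOR_DEFICIENCIES, PREDICTORS
from .evaluation import ConfusionMatrix, diagnostic_report

__all__ = [
    "entropy",
    "gini_impurity",
    "gain_ratio",
    "TreeNode",
    "GainRatioTree",
    "TreeResults",
    "build_feature_matrix",
    "select_features",
    "cross_validate_tree",
    "DEFAULT_MODEL_FEATURES",
]

#: Default feature set for model building: the predictors retained by the
#: data-exploration screen, with the three anterior pituitary axes
#: collapsed into a 0 / 1 / >=2 deficiency count.
DEFAULT_MODEL_FEATURES = (
    "pituitary_dysgenesis",
    "anterior_deficiency_count",
    "midline_abnormality",
    "sellar_tumor_surgery",
    "central_diabetes_insipidus",
    "neonatal_hypoglycemia",
    "neonatal_hypogenitalism",
    "cranial_radiotherapy_ge18Gy",
)

_EPS = 1e-12


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits, ``-sum p_i log2 p_i`` over nonzero classes."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("entropy undefined for all-zero class counts")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def gini_impurity(class_counts: Sequence[float]) -> float:
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("gini undefined for all-zero class counts")
    p = counts / total
    return float(1.0 - (p**2).sum())


def _partition_counts(y: np.ndarray) -> np.ndarray:
    # y is a 0/1 int array (1 = case)
    n1 = int(y.sum())
    return np.array([n1, y.size - n1], dtype=float)


def gain_ratio(y: np.ndarray, partitions: Sequence[np.ndarray]) -> float:
    """Gain ratio of a candidate split.

    ``y`` holds the 0/1 labels of the rows with a known attribute value;
    *partitions* are the label arrays of the (>= 2 non-empty) children.
    Raises if the split information is zero (degenerate partition).
    """
    parts = [np.asarray(p) for p in partitions if len(p) > 0]
    if len(parts) < 2:
        raise ValueError("a split must produce at least 2 non-empty parts")
    n = sum(len(p) for p in parts)
    if n != len(y):
        raise ValueError("partitions must cover the known-value rows exactly")
    parent_h = entropy(_partition_counts(np.asarray(y)))
    child_h = sum(len(p) / n * entropy(_partition_counts(p)) for p in parts)
    sizes = np.array([len(p) for p in parts], dtype=float)
    split_info = entropy(sizes)
    if split_info < _EPS:
        raise ValueError("split information is zero; split rejected")
    return (parent_h - child_h) / split_info


@dataclass
class TreeNode:
    """One node of the induced tree.

    Internal nodes carry the split attribute and children keyed by
    nominal value or by the numeric branch labels ``'<='`` / ``'>'``;
    leaves carry only counts and the majority label.
    """

    n_case: int
    n_control: int
    depth: int
    attribute: Optional[str] = None
    kind: Optional[Literal["nominal", "numeric"]] = None
    threshold: Optional[float] = None
    children: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n(self) -> int:
        return self.n_case + self.n_control

    @property
    def majority(self) -> str:
        # ties break toward control: a false positive is the costly error
        return "case" if self.n_case > self.n_control else "control"

    def largest_child_key(self):
        return max(self.children, key=lambda k: (self.children[k].n, str(k)))

    def walk(self):
        yield self
        for key in self.children:
            yield from self.children[key].walk()

    def to_dict(self) -> dict:
        d = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "majority": self.majority,
        }
        if not self.is_leaf:
            d["attribute"] = self.attribute
            d["kind"] = self.kind
            if self.threshold is not None:
                d["threshold"] = self.threshold
            d["children"] = {
                str(k): child.to_dict() for k, child in self.children.items()
            }
        return d


def _as_known_mask(col: pd.Series) -> np.ndarray:
    return col.notna().to_numpy()


class GainRatioTree:
    """Decision-tree model for GHD status on tri-state clinical predictors.

    Parameters
    ----------
    data : DataFrame with the feature columns and a label column.
    features : columns to use; defaults to every column except the label.
    label : label column; values 'case'/'control'.
    numeric_features : names treated as numeric (binary threshold splits);
        everything else is nominal.  ``anterior_deficiency_count`` is
        numeric by default.
    quality : 'gain_ratio' (default) or 'gini'.
    min_records : minimum rows in every node (default 2).
    max_depth : optional depth cap (None = unlimited).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: Optional[Sequence[str]] = None,
        label: str = "ghd_status",
        numeric_features: Sequence[str] = ("anterior_deficiency_count",),
        quality: Literal["gain_ratio", "gini"] = "gain_ratio",
        min_records: int = 2,
        max_depth: Optional[int] = None,
        missing_gain_scaling: bool = False,
    ):
        if features is None:
            features = [c for c in data.columns if c != label]
        if len(data) < 2:
            raise ValueError("need at least 2 rows to fit a tree")
        if len(features) < 1:
            raise ValueError("need at least 1 feature")
        if quality not in ("gain_ratio", "gini"):
            raise ValueError(f"unknown quality measure {quality!r}")
        self.data = data.reset_index(drop=True)
        self.features = list(features)
        self.label = label
        self.numeric = set(numeric_features)
        self.quality = quality
        self.min_records = int(min_records)
        self.max_depth = max_depth
        self.missing_gain_scaling = missing_gain_scaling

        y = self.data[label]
        bad = set(y.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"label column contains non-ascertained values {bad}")
        self._y = (y == "case").to_numpy().astype(np.int8)
        # pre-extract columns: numeric as float arrays (NaN = missing),
        # nominal as object arrays with None for missing
        self._cols: dict[str, np.ndarray] = {}
        self._known: dict[str, np.ndarray] = {}
        for f in self.features:
            col = self.data[f]
            self._known[f] = _as_known_mask(col)
            if f in self.numeric:
                self._cols[f] = pd.to_numeric(col, errors="coerce").to_numpy(
                    dtype=float
                )
            else:
                vals = col.to_numpy(dtype=object)
                vals[~self._known[f]] = None
                self._cols[f] = vals

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "GainRatioTree":
        return cls(data, **kwargs)

    # -- split search --------------------------------------------------

    def _node_impurity(self, counts: np.ndarray) -> float:
        return entropy(counts) if self.quality == "gain_ratio" else gini_impurity(counts)

    def _score_split(self, y_known: np.ndarray, parts: list[np.ndarray],
                     known_frac: float) -> float:
        n = y_known.size
        parent = self._node_impurity(_partition_counts(y_known))
        child = sum(
            p.size / n * self._node_impurity(_partition_counts(p)) for p in parts
        )
        scale = known_frac if self.missing_gain_scaling else 1.0
        gain = scale * (parent - child)
        if gain <= _EPS:
            return -1.0
        if self.quality == "gini":
            return gain
        sizes = np.array([p.size for p in parts], dtype=float)
        split_info = entropy(sizes)
        if split_info < _EPS:
            return -1.0
        return gain / split_info

    def _best_split(self, rows: np.ndarray, candidates: Sequence[str]):
        """Return (score, feature, kind, threshold, groups) or None.

        *groups* maps child key -> row-index array (known-value rows only).
        """
        y = self._y[rows]
        best = None
        best_score = _EPS
        for f in candidates:
            known = self._known[f][rows]
            n_known = int(known.sum())
            if n_known < 2 * self.min_records:
                continue
            kr = rows[known]
            yk = self._y[kr]
            if yk.min() == yk.max():
                continue  # pure on the known subset: no gain possible
            known_frac = n_known / rows.size
            col = self._cols[f]
            if f in self.numeric:
                vals = col[kr]
                order = np.argsort(vals, kind="stable")
                sv, sy, skr = vals[order], yk[order], kr[order]
                distinct = np.unique(sv)
                for i in range(len(distinct) - 1):
                    thr = (distinct[i] + distinct[i + 1]) / 2.0
                    left = sv <= thr
                    nl = int(left.sum())
                    if nl < self.min_records or (len(sv) - nl) < self.min_records:
                        continue
                    parts = [sy[left], sy[~left]]
                    score = self._score_split(sy, parts, known_frac)
                    if score > best_score + _EPS:
                        best_score = score
                        best = (
                            score,
                            f,
                            "numeric",
                            float(thr),
                            {"<=": skr[left], ">": skr[~left]},
                        )
            else:
                vals = col[kr]
                cats = sorted({v for v in vals}, key=repr)
                if len(cats) < 2:
                    continue
                groups = {cat: kr[vals == cat] for cat in cats}
                if any(g.size < self.min_records for g in groups.values()):
                    continue
                parts = [self._y[g] for g in groups.values()]
                score = self._score_split(yk, parts, known_frac)
                if score > best_score + _EPS:
                    best_score = score
                    best = (score, f, "nominal", None, groups)
        return best

    # -- growth --------------------------------------------------------

    def _grow(
        self,
        rows: np.ndarray,
        depth: int,
        feature_sampler: Optional[Callable[[], Sequence[str]]] = None,
    ) -> TreeNode:
        y = self._y[rows]
        node = TreeNode(
            n_case=int(y.sum()), n_control=int(y.size - y.sum()), depth=depth
        )
        if node.n_case == 0 or node.n_control == 0:
            return node
        if self.max_depth is not None and depth >= self.max_depth:
            return node
        candidates = (
            list(feature_sampler()) if feature_sampler is not None else self.features
        )
        found = self._best_split(rows, candidates)
        if found is None and feature_sampler is not None:
            # a random subset may be uninformative; fall back to all features
            found = self._best_split(rows, self.features)
        if found is None:
            return node
        _, f, kind, thr, groups = found
        # rows with a missing split value are not propagated: they were
        # excluded from the split's evaluation and are routed to the
        # largest child only at prediction time
        node.attribute, node.kind, node.threshold = f, kind, thr
        for key, grp in groups.items():
            node.children[key] = self._grow(grp, depth + 1, feature_sampler)
        return node

    def fit(self) -> "TreeResults":
        root = self._grow(np.arange(len(self.data)), 0)
        return TreeResults(self, root)

    # used by the forest: same growth with per-node feature subsampling
    def _fit_sampled(
        self, rows: np.ndarray, feature_sampler: Callable[[], Sequence[str]]
    ) -> TreeNode:
        return self._grow(rows, 0, feature_sampler)


class TreeResults:
    """Fitted decision tree with prediction, diagnostics and pruning."""

    def __init__(self, model: GainRatioTree, root: TreeNode):
        self.model = model
        self.root = root

    # -- prediction ----------------------------------------------------

    def _route(self, row: pd.Series) -> list[TreeNode]:
        """Path of nodes from root to the leaf this row reaches."""
        path = [self.root]
        node = self.root
        while not node.is_leaf:
            value = row.get(node.attribute)
            if pd.isna(value):
                key = node.largest_child_key()
            elif node.kind == "numeric":
                key = "<=" if float(value) <= node.threshold else ">"
            else:
                key = value if value in node.children else node.largest_child_key()
            node = node.children[key]
            path.append(node)
        return path

    def predict_record(self, row: pd.Series) -> str:
        return self._route(row)[-1].majority

    def predict(self, data: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [self.predict_record(row) for _, row in data.iterrows()],
            index=data.index,
            name="predicted",
        )

    def confusion(self, data: pd.DataFrame, label: str = "ghd_status") -> ConfusionMatrix:
        pred = self.predict(data)
        return ConfusionMatrix.from_labels(data[label], pred)

    # -- structure -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.walk())

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.root.walk() if n.is_leaf)

    def to_dict(self) -> dict:
        return self.root.to_dict()

    def to_text(self) -> str:
        lines: list[str] = []

        def emit(node: TreeNode, prefix: str) -> None:
            tag = f"[{node.n_case} case / {node.n_control} control]"
            if node.is_leaf:
                lines.append(f"{prefix}-> {node.majority} {tag}")
                return
            lines.append(f"{prefix}split on {node.attribute} {tag}")
            for key, child in node.children.items():
                if node.kind == "numeric":
                    branch = f"{node.attribute} {key} {node.threshold:g}"
                else:
                    branch = f"{node.attribute} = {key}"
                lines.append(f"{prefix}  {branch}:")
                emit(child, prefix + "    ")

        emit(self.root, "")
        return "\n".join(lines)

    def summary(self) -> str:
        m = self.model
        head = [
            "Gain-ratio decision tree",
            "=" * 40,
            f"quality measure : {m.quality}",
            f"min records/node: {m.min_records}",
            f"features        : {len(m.features)}",
            f"rows            : {len(m.data)}",
            f"nodes / leaves  : {self.n_nodes} / {self.n_leaves}",
            "-" * 40,
        ]
        return "\n".join(head) + "\n" + self.to_text()

    # -- pruning -------------------------------------------------------

    def _fp_tp_by_node(self, data: pd.DataFrame, label: str):
        """Accumulate, for every node, the false/true positives among the
        rows routed through it (counted at their leaf's prediction)."""
        fp: dict[int, int] = {}
        tp: dict[int, int] = {}
        for _, row in data.iterrows():
            path = self._route(row)
            predicted = path[-1].majority
            if predicted != "case":
                continue
            truth = row[label]
            bucket = fp if truth == "control" else tp
            for node in path:
                bucket[id(node)] = bucket.get(id(node), 0) + 1
        return fp, tp

    def prune_false_positive_branch(
        self, data: Optional[pd.DataFrame] = None, label: str = "ghd_status"
    ) -> "TreeResults":
        """Collapse the subtree with the most false positives into a
        control leaf.

        Ties resolve to the deepest such subtree (removing the same number
        of false positives at the least cost in sensitivity), then to
        preorder position.  A tree with no false positives is returned
        unchanged.  Specificity never decreases; sensitivity never
        increases.
        """
        if data is None:
            data = self.model.data
        pruned = TreeResults(self.model, copy.deepcopy(self.root))
        fp, tp = pruned._fp_tp_by_node(data, label)
        if not fp:
            return pruned
        candidates = []
        for order, node in enumerate(pruned.root.walk()):
            if node is pruned.root:
                continue
            node_fp = fp.get(id(node), 0)
            if node_fp > 0:
                candidates.append((node_fp, node.depth, -order, node))
        if not candidates:
            return pruned
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        target = candidates[-1][-1]
        target.children = {}
        target.attribute = target.kind = target.threshold = None
        # force the control label even on a case-majority subtree
        target.n_case, target.n_control = 0, target.n_case + target.n_control
        return pruned

    def reduced_error_prune(
        self, holdout: pd.DataFrame, label: str = "ghd_status"
    ) -> "TreeResults":
        """Classic reduced-error pruning against a holdout set: collapse
        any internal node whose leaf-majority prediction makes no more
        holdout errors than its subtree."""
        pruned = TreeResults(self.model, copy.deepcopy(self.root))

        def errors(res: TreeResults) -> int:
            pred = res.predict(holdout)
            return int((pred != holdout[label]).sum())

        improved = True
        while improved:
            improved = False
            base = errors(pruned)
            for node in pruned.root.walk():
                if node.is_leaf:
                    continue
                saved = (node.attribute, node.kind, node.threshold, node.children)
                node.children = {}
                node.attribute = node.kind = node.threshold = None
                if errors(pruned) <= base:
                    improved = True
                    break
                node.attribute, node.kind, node.threshold, node.children = saved
        return pruned


# -- feature engineering and harnesses ---------------------------------


def build_feature_matrix(
    cohort: pd.DataFrame,
    features: Sequence[str] = DEFAULT_MODEL_FEATURES,
    label: str = "ghd_status",
    missing_deficiency_policy: Literal["zero", "missing"] = "zero",
) -> pd.DataFrame:
    """Assemble the model-building matrix from a cohort table.

    Adds ``anterior_deficiency_count`` — the number of deficient anterior
    pituitary axes (TSH, ACTH, prolactin), capped at 2 so the categories
    read 0 / 1 / >=2 (no deficiency, any single deficiency, multiple
    deficiencies).  Under the default policy a missing deficiency flag
    counts as not deficient; under ``'missing'`` the count is missing
    whenever any axis flag is missing.
    """
    out = pd.DataFrame(index=cohort.index)
    for f in features:
        if f == "anterior_deficiency_count":
            axes = cohort[list(ANTERIOR_DEFICIENCIES)]
            count = axes.fillna(False).astype(bool).sum(axis=1).clip(upper=2)
            count = count.astype(float)
            if missing_deficiency_policy == "missing":
                count[axes.isna().any(axis=1)] = np.nan
            out[f] = count
        else:
            out[f] = cohort[f]
    out[label] = cohort[label]
    return out


def select_features(
    assoc: pd.DataFrame,
    or_threshold: float = 5.0,
    p_threshold: float = 1e-4,
    forced: Sequence[str] = ("cranial_radiotherapy_ge18Gy",),
) -> list[str]:
    """Data-exploration feature screen: keep predictors with OR above
    *or_threshold* and p below *p_threshold*, plus any clinically forced
    inclusions, preserving the association-table order."""
    keep = []
    for pred, row in assoc.iterrows():
        if pred in forced or (
            row["odds_ratio"] > or_threshold and row["p_value"] < p_threshold
        ):
            keep.append(pred)
    return keep


def cross_validate_tree(
    matrix: pd.DataFrame,
    label: str = "ghd_status",
    test_frac: float = 0.2,
    n_repeats: int = 10,
    seed: int = 0,
    **tree_kwargs,
) -> pd.DataFrame:
    """Repeated stratified holdout validation of the tree.

    Each repeat draws a stratified ``test_frac`` test set, fits on the
    remainder and evaluates on the test set.  Returns one row of metrics
    per repeat so the dispersion across repeats can be reported.
    """
    rng = np.random.default_rng(seed)
    is_case = (matrix[label] == "case").to_numpy()
    idx_case = np.flatnonzero(is_case)
    idx_ctrl = np.flatnonzero(~is_case)
    rows = []
    for rep in range(n_repeats):
        test = np.concatenate(
            [
                rng.choice(idx_case, max(1, round(test_frac * idx_case.size)), replace=False),
                rng.choice(idx_ctrl, max(1, round(test_frac * idx_ctrl.size)), replace=False),
            ]
        )
        mask = np.zeros(len(matrix), dtype=bool)
        mask[test] = True
        fit = GainRatioTree(matrix[~mask], label=label, **tree_kwargs).fit()
        cm = fit.confusion(matrix[mask], label=label)
        rep_metrics = diagnostic_report(cm)
        rows.append(
            {
                "repeat": rep,
                "sensitivity": rep_metrics.sensitivity,
                "specificity": rep_metrics.specificity,
                "accuracy": rep_metrics.accuracy,
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
            }
        )
    return pd.DataFrame(rows).set_index("repeat")
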