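"""Tree-ensemble feature-relevance ranking.

A robustness check on the variables the single decision tree selects: an
ensemble of gain-ratio trees is grown on bootstrap resamples with a
random feature subset considered at every split, and each feature's
relevance is the number of times it is chosen to split, weighted by
1/(1+depth) so near-root splits dominate.  Split counts at levels 0-2 are
reported separately.  The forest is used only for feature relevance, not
for prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import GainRatioTree, TreeNode

__all__ = ["ForestParams", "TreeEnsembleRelevance", "ImportanceResults"]


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 100
    features_per_split: int | None = None  # default ceil(sqrt(p))
    bootstrap: bool = True
    max_depth: int | None = None


class TreeEnsembleRelevance:
    """Random-forest feature-relevance model (Model/Results pair).

    ``fit(seed)`` grows the ensemble deterministically for a given seed
    and returns :class:`ImportanceResults`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features=None,
        label: str = "ghd_status",
        params: ForestParams = ForestParams(),
        **tree_kwargs,
    ):
        if len(data) < 10:
            raise ValueError("need at least 10 rows for a forest")
        self.params = params
        self._tree_model = GainRatioTree(
            data,
            features=features,
            label=label,
            max_depth=params.max_depth,
            **tree_kwargs,
        )
        self.features = self._tree_model.features
        self.label = label

    def fit(self, seed: int = 0) -> "ImportanceResults":
        p = len(self.features)
        k = self.params.features_per_split or math.ceil(math.sqrt(p))
        k = min(k, p)
        rng = np.random.default_rng(seed)
        n = len(self._tree_model.data)
        y = self._tree_model._y

        degenerate = y.min() == y.max()
        if degenerate:
            warnings.warn(
                "single-class data: all feature importances are zero",
                stacklevel=2,
            )

        split_counts = {f: np.zeros(3, dtype=int) for f in self.features}
        scores = {f: 0.0 for f in self.features}
        totals = {f: 0 for f in self.features}

        features_arr = np.array(self.features, dtype=object)

        for _ in range(self.params.n_trees):
            if degenerate:
                break
            rows = (
                rng.choice(n, size=n, replace=True)
                if self.params.bootstrap
                else np.arange(n)
            )

            def sampler():
                return list(rng.choice(features_arr, size=k, replace=False))

            root = self._tree_model._fit_sampled(np.sort(rows), sampler)
            for node in root.walk():
                if node.is_leaf:
                    continue
                f = node.attribute
                totals[f] += 1
                scores[f] += 1.0 / (1.0 + node.depth)
                if node.depth <= 2:
                    split_counts[f][node.depth] += 1

        total_score = sum(scores.values())
        table = pd.DataFrame(
            {
                "split_count_total": [totals[f] for f in self.features],
                "splits_level_0": [split_counts[f][0] for f in self.features],
                "splits_level_1": [split_counts[f][1] for f in self.features],
                "splits_level_2": [split_counts[f][2] for f in self.features],
                "importance": [
                    scores[f] / total_score if total_score > 0 else 0.0
                    for f in self.features
                ],
            },
            index=pd.Index(self.features, name="feature"),
        ).sort_values("importance", ascending=False, kind="stable")
        return ImportanceResults(self, table, seed)


class ImportanceResults:
    """Ranked feature-relevance table from a fitted tree ensemble."""

    def __init__(self, model: TreeEnsembleRelevance, table: pd.DataFrame, seed: int):
        self.model = model
        self.importances_ = table
        self.seed = seed

    def rank(self) -> pd.Series:
        """1-based relevance rank per feature (1 = most relevant)."""
        return pd.Series(
            np.arange(1, len(self.importances_) + 1),
            index=self.importances_.index,
            name="rank",
        )

    def summary(self) -> str:
        p = self.model.params
        head = [
            "Tree-ensemble feature relevance",
            "=" * 46,
            f"trees: {p.n_trees}  bootstrap: {p.bootstrap}  seed: {self.seed}",
            "-" * 46,
        ]
        return "\n".join(head) + "\n" + self.importances_.to_string(
            float_format=lambda x: f"{x:.4f}"
        )
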