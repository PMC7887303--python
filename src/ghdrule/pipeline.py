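"""End-to-end pipeline: simulate (or load) a cohort, run the association
panel, induce and prune the decision tree, rank feature relevance,
apply the clinical rule, and evaluate diagnostic performance.

Every output file embeds the seed and a hash of the configuration so a
bundle is reproducible from its own metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import io as cohort_io
from .association import association_table
from .cohort import EraCutoffs
from .evaluation import binomial_significance, diagnostic_report, validation_axes
from .forest import ForestParams, TreeEnsembleRelevance
from .rule import apply_rule_to_cohort
from .synthetic import CohortSpec, default_specs, simulate_cohort
from .tree import GainRatioTree, build_feature_matrix

logger = logging.getLogger("ghdrule")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings; defaults are the study's stated parameters."""

    era_windows: tuple[tuple[int, int, float], ...] = (
        (2004, 2011, 6.1),
        (2012, 2019, 4.7),
    )
    tree_quality: str = "gain_ratio"
    tree_min_records: int = 2
    tree_prune_fp_branch: bool = True
    forest_n_trees: int = 100
    forest_features_per_split: Optional[int] = None
    or_method: str = "woolf_log"
    p_method: str = "pearson"
    conf_level: float = 0.95
    alpha: float = 1e-5
    seed: int = 0

    def cutoffs(self) -> EraCutoffs:
        return EraCutoffs(self.era_windows)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        if "era_windows" in raw:
            raw["era_windows"] = tuple(tuple(w) for w in raw["era_windows"])
        return cls(**raw)


def run_pipeline(
    config: PipelineConfig,
    cohort: Union[pd.DataFrame, CohortSpec, str, Path],
    out_dir: Optional[Union[str, Path]] = None,
    mode: str = "exact_marginal",
) -> dict:
    """Execute the full pipeline and return the report bundle.

    *cohort* may be a DataFrame, a built-in spec name, a
    :class:`~ghdrule.synthetic.CohortSpec`, or a path to a cohort CSV.
    When *out_dir* is given, the bundle is also written to disk
    (association TSV, tree JSON, importance TSV, decisions CSV,
    diagnostics JSON, run log).
    """
    meta = {"seed": config.seed, "config_hash": config.hash()}
    if isinstance(cohort, (str, Path)) and str(cohort) in default_specs():
        cohort = default_specs()[str(cohort)]
    if isinstance(cohort, CohortSpec):
        logger.info("simulating cohort %s (mode=%s)", cohort.name, mode)
        cohort_df = simulate_cohort(cohort, seed=config.seed, mode=mode)
    elif isinstance(cohort, (str, Path)):
        cohort_df = cohort_io.read_cohort(cohort)
    else:
        cohort_df = cohort

    logger.info("association panel on %d patients", len(cohort_df))
    assoc = association_table(
        cohort_df, method=config.or_method, p_method=config.p_method
    )

    matrix = build_feature_matrix(cohort_df)
    tree_model = GainRatioTree(
        matrix,
        quality=config.tree_quality,
        min_records=config.tree_min_records,
    )
    tree_fit = tree_model.fit()
    tree_cm = tree_fit.confusion(matrix)
    pruned_fit = (
        tree_fit.prune_false_positive_branch(matrix)
        if config.tree_prune_fp_branch
        else tree_fit
    )
    pruned_cm = pruned_fit.confusion(matrix)

    forest = TreeEnsembleRelevance(
        matrix,
        params=ForestParams(
            n_trees=config.forest_n_trees,
            features_per_split=config.forest_features_per_split,
        ),
    ).fit(seed=config.seed)

    decisions, rule_cm, n_ineligible = apply_rule_to_cohort(cohort_df)
    rule_report = diagnostic_report(rule_cm, config.conf_level)
    prior = (cohort_df["ghd_status"] == "case").mean()
    n_pos = rule_cm.tp + rule_cm.fp
    binom_p = (
        binomial_significance(rule_cm.tp, n_pos, prior) if n_pos > 0 else 1.0
    )
    axes = validation_axes(rule_report, binom_p, alpha=config.alpha)

    bundle = {
        "meta": meta,
        "association": assoc,
        "tree": tree_fit,
        "tree_confusion": tree_cm,
        "tree_report": diagnostic_report(tree_cm, config.conf_level),
        "pruned_tree": pruned_fit,
        "pruned_confusion": pruned_cm,
        "pruned_report": diagnostic_report(pruned_cm, config.conf_level),
        "importance": forest.importances_,
        "decisions": decisions,
        "rule_confusion": rule_cm,
        "rule_report": rule_report,
        "binomial_p": binom_p,
        "validation_axes": axes,
        "n_ineligible": n_ineligible,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            header = f"# schema=ghdrule-bundle/1 seed={meta['seed']} config={meta['config_hash']}\n"

            def tsv(df: pd.DataFrame, name: str) -> None:
                p = out / name
                with open(p, "w") as fh:
                    fh.write(header)
                    df.to_csv(fh, sep="\t")
                written.append(p)

            tsv(assoc, "association.tsv")
            tsv(forest.importances_, "importance.tsv")
            p = out / "decisions.csv"
            with open(p, "w") as fh:
                fh.write(header)
                decisions.to_csv(fh, index=False)
            written.append(p)
            p = out / "tree.json"
            p.write_text(
                json.dumps(
                    {**meta, "fitted": tree_fit.to_dict(), "pruned": pruned_fit.to_dict()},
                    indent=2,
                )
            )
            written.append(p)
            p = out / "diagnostics.json"
            p.write_text(
                json.dumps(
                    {
                        **meta,
                        "rule": rule_report.to_dict(),
                        "tree": bundle["tree_report"].to_dict(),
                        "pruned_tree": bundle["pruned_report"].to_dict(),
                        "binomial_p": binom_p,
                        "validation_axes": axes,
                        "n_ineligible": n_ineligible,
                    },
                    indent=2,
                )
            )
            written.append(p)
            p = out / "run.log"
            p.write_text(
                f"seed={meta['seed']}\nconfig_hash={meta['config_hash']}\n"
                f"config={config.to_json()}\nn={len(cohort_df)}\n"
            )
            written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    return bundle
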