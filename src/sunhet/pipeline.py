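"""End-to-end orchestration: one config in, a tree of report artifacts out.

``run_grouping`` takes a germplasm panel (from file or the synthetic
generator), integrates the feature blocks, runs all three classifiers,
compares their resolution power, selects representative parents and writes
the line × tester cross design.  ``run_evaluation`` takes parent/hybrid
means (or a replicated trial) and writes heterosis and combining-ability
reports.  Everything is deterministic in (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .cluster import (
    adjusted_rand,
    cluster_purity,
    cut_tree,
    dendrogram_to_frame,
    dendrogram_to_newick,
    hybrid_hkmeans,
    lloyd_kmeans,
    pairwise_euclidean,
    ward_d2_linkage,
)
from .combining import combining_ability, combining_ability_report, cross_means_from_table
from .grouping import build_lxt_design, extract_heterotic_groups, select_group_representatives
from .heterosis import heterosis_significance, heterosis_table, heterosis_wide
from .panel import TRAITS, ValidationError, read_means, read_panel, read_trial
from .preprocess import integrate_features
from .simulate import PanelConfig, generate_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run parameters (one YAML file drives everything)."""

    # inputs: either a panel file or the synthetic generator
    panel_path: str | None = None
    panel_schema: dict = field(default_factory=dict)
    simulate_panel: bool = False
    seed: int = 0
    # preprocessing
    use_yeo_johnson: bool = True
    # clustering
    k_major: int = 2
    k_sub: int = 12
    n_init: int = 10
    # selection
    selection_trait: str = "SYP"
    # evaluation inputs
    parent_means_path: str | None = None
    hybrid_means_path: str | None = None
    trial_path: str | None = None
    use_reference_dataset: bool = False
    replications: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.k_major < 1 or self.k_sub < self.k_major:
            raise ValidationError("need 1 <= k_major <= k_sub")
        if self.selection_trait not in TRAITS:
            raise ValidationError(f"unknown selection trait {self.selection_trait!r}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_grouping(cfg: RunConfig, outdir: str | Path) -> dict:
    """Heterotic-grouping stage; returns the run report dict."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate_panel:
        panel, truth = generate_panel(PanelConfig(seed=cfg.seed))
    elif cfg.panel_path:
        panel, truth = read_panel(cfg.panel_path, cfg.panel_schema or None), None
    else:
        raise ValidationError("config must set panel_path or simulate_panel")
    if cfg.k_sub > panel.n_genotypes:
        raise ValidationError("k_sub exceeds the number of genotypes")

    features = integrate_features(panel, use_yeo_johnson=cfg.use_yeo_johnson)
    features.values.to_csv(out / "features.csv")

    dend = ward_d2_linkage(pairwise_euclidean(features), leaf_ids=panel.genotype_ids)
    (out / "dendrogram.newick").write_text(dendrogram_to_newick(dend) + "\n")
    dendrogram_to_frame(dend).to_csv(out / "dendrogram_merges.csv", index=False)

    grouping = extract_heterotic_groups(dend, cfg.k_major, cfg.k_sub)
    km = lloyd_kmeans(features, k=cfg.k_major, seed=cfg.seed, n_init=cfg.n_init)
    hk = hybrid_hkmeans(features, k=cfg.k_sub)

    labels = grouping.to_frame()
    labels["kmeans_major"] = km.labels
    labels["hkmeans_sub"] = hk.labels
    labels["line_type"] = panel.line_types
    labels.to_csv(out / "labels.csv")

    types = panel.line_types.to_numpy()
    comparison = {}
    for name, lab in (
        ("hierarchical_major", grouping.major_labels),
        ("hierarchical_sub", grouping.sub_labels),
        ("kmeans_major", km.labels),
        ("hkmeans_sub", hk.labels),
    ):
        purity, _ = cluster_purity(lab, types)
        comparison[name] = {"purity_vs_line_type": purity}
    comparison["kmeans_vs_hierarchical_major"] = {
        "ari": adjusted_rand(km.labels, grouping.major_labels)
    }
    comparison["hkmeans_vs_hierarchical_sub"] = {
        "ari": adjusted_rand(hk.labels, grouping.sub_labels)
    }
    if truth is not None:
        comparison["hierarchical_sub_vs_truth"] = {
            "ari": adjusted_rand(grouping.sub_labels, truth.sub_labels)
        }
        comparison["hkmeans_sub_vs_truth"] = {
            "ari": adjusted_rand(hk.labels, truth.sub_labels)
        }

    # eligibility: the restorer-dominated major cluster contributes R
    # parents, the other contributes CMS parents
    r_share = {
        int(m): (types[grouping.major_labels == m] == "R").mean()
        for m in np.unique(grouping.major_labels)
    }
    r_major = max(r_share, key=r_share.get)
    eligible = {
        m: ({"R"} if m == r_major else {"CMS"}) for m in r_share
    }
    try:
        reps = select_group_representatives(
            grouping, panel, trait=cfg.selection_trait, eligible_types=eligible
        )
        reps.to_csv(out / "selected_parents.csv", index=False)
        design = build_lxt_design(
            cms_parents=reps.loc[reps["line_type"] == "CMS", "genotype"],
            r_parents=reps.loc[reps["line_type"] == "R", "genotype"],
        )
        design.to_frame().to_csv(out / "cross_design.csv", index=False)
        design_info = {"l": len(design.lines), "t": len(design.testers),
                       "crosses": len(design)}
    except ValidationError as exc:
        logger.warning("parent selection incomplete: %s", exc)
        design_info = {"error": str(exc)}

    report = {
        "n_genotypes": panel.n_genotypes,
        "n_features": features.values.shape[1],
        "lambdas": {
            k: v.lmbda for k, v in (features.lambdas or {}).items()
        },
        "k_major": cfg.k_major,
        "k_sub": cfg.k_sub,
        "seed": cfg.seed,
        "kmeans_wss": km.wss,
        "hkmeans_wss": hk.wss,
        "comparison": comparison,
        "design": design_info,
    }
    _write_json(out / "grouping_report.json", report)
    return report


def run_evaluation(cfg: RunConfig, outdir: str | Path) -> dict:
    """Hybrid-evaluation stage; returns the run report dict."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    trial = read_trial(cfg.trial_path) if cfg.trial_path else None

    if cfg.use_reference_dataset:
        parents, hybrids, design = datasets.load_reference_trial()
    elif cfg.parent_means_path and cfg.hybrid_means_path:
        parents = read_means(cfg.parent_means_path)
        hybrids = read_means(cfg.hybrid_means_path)
        from .panel import parse_cross

        pairs = [parse_cross(c) for c in hybrids.index]
        testers = list(dict.fromkeys(t for t, _ in pairs))
        lines = list(dict.fromkeys(l for _, l in pairs))
        design = build_lxt_design(cms_parents=lines, r_parents=testers)
    elif trial is not None:
        parents = hybrids = None
        design = build_lxt_design(cms_parents=trial.lines, r_parents=trial.testers)
    else:
        raise ValidationError(
            "config must set use_reference_dataset, mean tables, or a trial"
        )

    report: dict = {}

    if parents is not None:
        het = heterosis_table(parents, hybrids, design)
        mse = None
        error_df = None
        if trial is not None:
            from .combining import lxt_anova

            mse = {
                tr: float(lxt_anova(trial, tr).at["error", "MS"])
                for tr in trial.traits
            }
            error_df = int(
                (trial.n_lines * trial.n_testers - 1) * (trial.n_reps - 1)
            )
            het = heterosis_significance(het, mse, trial.n_reps, error_df)
        else:
            het = heterosis_significance(het, None, cfg.replications, float("nan"))
        het.to_csv(out / "heterosis.csv", index=False)
        heterosis_wide(het, "mph").to_csv(out / "heterosis_mph_wide.csv")
        heterosis_wide(het, "bph").to_csv(out / "heterosis_bph_wide.csv")
        report["heterosis"] = {
            "crosses": int(het["cross"].nunique()),
            "traits": int(het["trait"].nunique()),
            "significance": "available" if mse is not None else "unavailable",
        }

    ca_summary = {}
    if trial is not None:
        for tr in trial.traits:
            res = combining_ability(trial=trial, trait=tr)
            combining_ability_report(res).to_csv(
                out / f"combining_ability_{tr}.csv", index=False
            )
            res.anova.to_csv(out / f"anova_{tr}.csv")
            ca_summary[tr] = {
                "mse": float(res.anova.at["error", "MS"]),
                "significance": "available",
            }
    elif hybrids is not None:
        for tr in TRAITS:
            cm = cross_means_from_table(hybrids, design, tr)
            res = combining_ability(cm=cm)
            rep = combining_ability_report(
                dataclasses.replace(res, trait=tr)
            )
            rep.to_csv(out / f"combining_ability_{tr}.csv", index=False)
            ca_summary[tr] = {"significance": "unavailable"}
    report["combining_ability"] = ca_summary
    _write_json(out / "evaluation_report.json", report)
    return report
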