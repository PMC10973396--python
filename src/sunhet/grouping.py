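"""Heterotic groups, representative parents, and the line × tester design.

A dendrogram cut at ``k_major`` (typically 2: restorers vs the CMS/B/SFP
pool) and at ``k_sub`` (typically 12) yields nested major and sub-cluster
labels.  One representative per sub-cluster — the eligible genotype with the
highest value of a selection trait, seed yield per plant by default — is
then crossed in a full factorial line × tester scheme (CMS females × R
testers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import Dendrogram, cut_tree
from .panel import GermplasmPanel, ValidationError, cross_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeteroticGrouping:
    """Nested major/sub cluster labels for every genotype."""

    genotype_ids: tuple[str, ...]
    major_labels: np.ndarray   # values 1..k_major
    sub_labels: np.ndarray     # values 1..k_sub, nested in major clusters

    def __post_init__(self) -> None:
        n = len(self.genotype_ids)
        if len(self.major_labels) != n or len(self.sub_labels) != n:
            raise ValidationError("label vectors must cover all genotypes")
        # every sub-cluster lies wholly inside one major cluster
        for sub in np.unique(self.sub_labels):
            majors = np.unique(self.major_labels[self.sub_labels == sub])
            if len(majors) != 1:
                raise ValidationError(
                    f"sub-cluster {sub} spans major clusters {majors.tolist()}"
                )

    @property
    def n_major(self) -> int:
        return len(np.unique(self.major_labels))

    @property
    def n_sub(self) -> int:
        return len(np.unique(self.sub_labels))

    def members(self, sub: int) -> list[str]:
        mask = self.sub_labels == sub
        return [g for g, m in zip(self.genotype_ids, mask) if m]

    def major_of_sub(self, sub: int) -> int:
        return int(self.major_labels[self.sub_labels == sub][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"major_cluster": self.major_labels, "sub_cluster": self.sub_labels},
            index=pd.Index(self.genotype_ids, name="genotype"),
        )


@dataclass(frozen=True)
class CrossDesign:
    """Full factorial line × tester cross list."""

    lines: tuple[str, ...]    # CMS (female) parents
    testers: tuple[str, ...]  # restorer (male) parents

    def __post_init__(self) -> None:
        if not self.lines or not self.testers:
            raise ValidationError("lines and testers must be non-empty")
        overlap = set(self.lines) & set(self.testers)
        if overlap:
            raise ValidationError(
                f"parents cannot be both line and tester: {sorted(overlap)}"
            )
        if len(set(self.lines)) != len(self.lines) or len(
            set(self.testers)
        ) != len(self.testers):
            raise ValidationError("duplicate parent ids in design")

    @property
    def crosses(self) -> list[tuple[str, str]]:
        """All (tester, line) pairs, testers varying slowest."""
        return [(t, l) for t in self.testers for l in self.lines]

    @property
    def cross_names(self) -> list[str]:
        return [cross_name(t, l) for t, l in self.crosses]

    def __len__(self) -> int:
        return len(self.lines) * len(self.testers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(cross_name(t, l), l, t) for t, l in self.crosses],
            columns=["cross", "line", "tester"],
        )


def extract_heterotic_groups(
    dend: Dendrogram, k_major: int, k_sub: int
) -> HeteroticGrouping:
    """Cut one tree at two depths to get nested major/sub heterotic groups."""
    if not 1 <= k_major <= k_sub <= dend.n_leaves:
        raise ValidationError(
            f"need 1 <= k_major <= k_sub <= n, got {k_major}, {k_sub}"
        )
    major = cut_tree(dend, k=k_major)
    sub = cut_tree(dend, k=k_sub)
    return HeteroticGrouping(
        genotype_ids=dend.leaf_ids, major_labels=major, sub_labels=sub
    )


def select_group_representatives(
    grouping: HeteroticGrouping,
    panel: GermplasmPanel,
    trait: str = "SYP",
    eligible_types: dict[int, set[str]] | None = None,
) -> pd.DataFrame:
    """Pick the top-``trait`` eligible genotype from every sub-cluster.

    ``eligible_types`` maps a major-cluster label to the line types allowed
    to represent its sub-clusters (e.g. the restorer-dominated cluster is
    restricted to type R).  Ties on the trait break toward the
    lexicographically smaller genotype id (logged).
    """
    if trait not in panel.traits.columns:
        raise ValidationError(f"unknown selection trait {trait!r}")
    rows = []
    values = panel.traits[trait]
    types = panel.line_types
    for sub in sorted(np.unique(grouping.sub_labels)):
        members = grouping.members(int(sub))
        major = grouping.major_of_sub(int(sub))
        allowed = (eligible_types or {}).get(major)
        eligible = [g for g in members if allowed is None or types[g] in allowed]
        if not eligible:
            raise ValidationError(
                f"sub-cluster {sub} has no eligible genotype "
                f"(allowed types: {sorted(allowed) if allowed else 'any'})"
            )
        best_val = max(values[g] for g in eligible)
        tied = sorted(g for g in eligible if values[g] == best_val)
        if len(tied) > 1:
            logger.info("trait tie in sub-cluster %s broken toward %s", sub, tied[0])
        rows.append((int(sub), major, tied[0], types[tied[0]], float(best_val)))
    return pd.DataFrame(
        rows, columns=["sub_cluster", "major_cluster", "genotype", "line_type", trait]
    )


def build_lxt_design(cms_parents, r_parents) -> CrossDesign:
    """Full factorial cross list: every restorer pollinates every CMS line."""
    return CrossDesign(lines=tuple(cms_parents), testers=tuple(r_parents))
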