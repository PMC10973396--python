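"""Synthetic germplasm panels and line × tester trials with known truth.

The panel generator plants the structure the analysis assumes: two
well-separated major populations — restorers on one side, CMS/B/SFP lines
on the other — each split into sub-clusters, with Gaussian trait deviations
around per-cluster means and Bernoulli marker/protein bands whose
frequencies diverge between clusters.  The trial generator draws balanced
plot observations from an additive GCA + SCA + replication + error model,
so estimator recovery can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import load_reference_parents
from .panel import LINE_TYPES, TRAITS, GermplasmPanel, TrialData, ValidationError

#: default class counts for a 109-genotype panel: the restorer population
#: of 31 vs an even split of the remaining 78 CMS/B/SFP lines
DEFAULT_CLASS_PROPORTIONS = {"R": 31 / 109, "CMS": 26 / 109, "B": 26 / 109, "SFP": 26 / 109}


@dataclass(frozen=True)
class PanelConfig:
    """Knobs of the synthetic panel generator.

    ``delta`` is the between-sub-cluster trait separation in units of the
    within-cluster SD; major populations sit a further ``2·delta`` apart.
    Band frequencies are hierarchical: the two populations take anti-phase
    base frequencies 0.5 ± ``major_band_divergence``/2 per column, and each
    sub-cluster shifts its population base by ± ``epsilon``, so the
    restorer/non-restorer split dominates the marker signal while
    sub-clusters stay separable.
    """

    n: int = 109
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_major: int = 2
    n_sub_per_major: int = 6
    delta: float = 6.0
    within_sd: float = 1.0
    epsilon: float = 0.4
    major_band_divergence: float = 0.5
    n_ssr: int = 40
    n_protein: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if set(self.class_proportions) - set(LINE_TYPES):
            raise ValidationError("unknown line type in class proportions")
        if self.delta < 0 or self.epsilon < 0:
            raise ValidationError("delta and epsilon must be non-negative")
        if self.n < self.n_major * self.n_sub_per_major:
            raise ValidationError("need at least one genotype per sub-cluster")


@dataclass(frozen=True)
class PanelTruth:
    """Ground-truth labels of a generated panel."""

    major_labels: np.ndarray
    sub_labels: np.ndarray


def _class_counts(cfg: PanelConfig) -> dict[str, int]:
    raw = {k: cfg.class_proportions.get(k, 0.0) * cfg.n for k in LINE_TYPES}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    # distribute the rounding remainder to the largest fractional parts
    rem = cfg.n - sum(counts.values())
    order = sorted(LINE_TYPES, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


def generate_panel(cfg: PanelConfig) -> tuple[GermplasmPanel, PanelTruth]:
    """Draw a panel with planted 2-population × sub-cluster structure.

    Restorer (R) genotypes populate population 1; CMS, B and SFP genotypes
    populate population 2, mirroring the empirical restorer/non-restorer
    split.  Deterministic in ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _class_counts(cfg)
    n_traits = len(TRAITS)
    n_bands = cfg.n_ssr + cfg.n_protein

    # genotype ids, types, population membership
    ids, types, major = [], [], []
    for lt in LINE_TYPES:
        for i in range(counts[lt]):
            ids.append(f"SYN-{lt}-{i + 1:03d}")
            types.append(lt)
            major.append(1 if lt == "R" else 2)
    major = np.array(major)

    # sub-cluster assignment: round-robin within each population, so every
    # line type present in a population reaches all of its sub-clusters
    sub = np.zeros(len(ids), dtype=int)
    for pop in range(1, cfg.n_major + 1):
        idx = np.nonzero(major == pop)[0]
        for i, g in enumerate(idx):
            sub[g] = (pop - 1) * cfg.n_sub_per_major + (i % cfg.n_sub_per_major) + 1

    # per-cluster trait means: realistic base levels, population offset
    # 2·delta and sub-cluster offsets delta (within-SD units) along random
    # unit directions
    base = load_reference_parents().mean(axis=0).to_numpy()
    scale = cfg.within_sd
    pop_dirs = rng.normal(size=(cfg.n_major, n_traits))
    pop_dirs /= np.linalg.norm(pop_dirs, axis=1, keepdims=True)
    n_clusters = cfg.n_major * cfg.n_sub_per_major
    sub_dirs = rng.normal(size=(n_clusters, n_traits))
    sub_dirs /= np.linalg.norm(sub_dirs, axis=1, keepdims=True)
    cluster_mean = np.empty((n_clusters, n_traits))
    for c in range(n_clusters):
        pop = c // cfg.n_sub_per_major
        cluster_mean[c] = (
            base
            + 2.0 * cfg.delta * scale * pop_dirs[pop]
            + cfg.delta * scale * sub_dirs[c]
        )

    traits = cluster_mean[sub - 1] + rng.normal(scale=scale, size=(len(ids), n_traits))
    traits = np.maximum(traits, 0.0)  # trait domain is non-negative

    # hierarchical band frequencies: anti-phase population bases, then a
    # per-sub-cluster shift of +/- epsilon
    col_sign = rng.choice((-1.0, 1.0), size=n_bands)
    pop_idx = np.arange(cfg.n_major) % 2  # alternate phase across populations
    pop_freq = 0.5 + np.where(pop_idx[:, None] == 0, 1.0, -1.0) * col_sign * (
        cfg.major_band_divergence / 2.0
    )
    signs = rng.choice((-1.0, 1.0), size=(n_clusters, n_bands))
    freq = np.clip(
        pop_freq[np.arange(n_clusters) // cfg.n_sub_per_major]
        + cfg.epsilon * signs,
        0.02,
        0.98,
    )
    bands = (rng.random(size=(len(ids), n_bands)) < freq[sub - 1]).astype(int)

    index = pd.Index(ids, name="genotype")
    panel = GermplasmPanel(
        line_types=pd.Series(types, index=index, name="line_type"),
        traits=pd.DataFrame(traits, index=index, columns=list(TRAITS)),
        ssr_bands=pd.DataFrame(
            bands[:, : cfg.n_ssr], index=index,
            columns=[f"SSR_{i + 1:02d}" for i in range(cfg.n_ssr)],
        ),
        protein_bands=pd.DataFrame(
            bands[:, cfg.n_ssr:], index=index,
            columns=[f"PROT_{i + 1:02d}" for i in range(cfg.n_protein)],
        ),
    )
    return panel, PanelTruth(major_labels=major, sub_labels=sub)


@dataclass(frozen=True)
class TrialTruth:
    """Ground-truth effects of a simulated line × tester trial.

    ``g_lines``, ``g_testers`` and ``s`` are centered at construction so the
    model is identified: estimates can be compared to them directly.
    """

    mu: float
    g_lines: np.ndarray
    g_testers: np.ndarray
    s: np.ndarray
    rep_sd: float = 0.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        g_l = np.asarray(self.g_lines, dtype=float)
        g_t = np.asarray(self.g_testers, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if s.shape != (g_l.size, g_t.size):
            raise ValidationError("s must be l x t")
        object.__setattr__(self, "g_lines", g_l - g_l.mean())
        object.__setattr__(self, "g_testers", g_t - g_t.mean())
        s = s - s.mean(axis=1, keepdims=True)
        s = s - s.mean(axis=0, keepdims=True)
        object.__setattr__(self, "s", s)

    @classmethod
    def random(
        cls,
        l: int,
        t: int,
        mu: float = 60.0,
        gca_sd: float = 5.0,
        sca_sd: float = 3.0,
        rep_sd: float = 0.0,
        sigma: float = 5.0,
        seed: int = 0,
    ) -> "TrialTruth":
        rng = np.random.default_rng(seed)
        return cls(
            mu=mu,
            g_lines=rng.normal(scale=gca_sd, size=l),
            g_testers=rng.normal(scale=gca_sd, size=t),
            s=rng.normal(scale=sca_sd, size=(l, t)),
            rep_sd=rep_sd,
            sigma=sigma,
            seed=seed,
        )


def generate_lxt_trial(
    truth: TrialTruth,
    r: int,
    trait: str = "SYP",
    line_ids=None,
    tester_ids=None,
) -> TrialData:
    """Balanced plot observations y_ijk = μ + g_i + g_j + s_ij + rep_k + e_ijk."""
    l, t = truth.s.shape
    if line_ids is None:
        line_ids = [f"LINE-{i + 1}" for i in range(l)]
    if tester_ids is None:
        tester_ids = [f"TESTER-{j + 1}" for j in range(t)]
    if len(line_ids) != l or len(tester_ids) != t:
        raise ValidationError("id lists must match truth dimensions")
    rng = np.random.default_rng(truth.seed)
    rep_eff = rng.normal(scale=truth.rep_sd, size=r) if truth.rep_sd > 0 else np.zeros(r)
    noise = (
        rng.normal(scale=truth.sigma, size=(l, t, r))
        if truth.sigma > 0
        else np.zeros((l, t, r))
    )
    rows = []
    for i, line in enumerate(line_ids):
        for j, tester in enumerate(tester_ids):
            cell = truth.mu + truth.g_lines[i] + truth.g_testers[j] + truth.s[i, j]
            for k in range(r):
                rows.append((line, tester, k + 1, trait,
                             cell + rep_eff[k] + noise[i, j, k]))
    rec = pd.DataFrame(rows, columns=["line", "tester", "rep", "trait", "value"])
    return TrialData(records=rec)
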