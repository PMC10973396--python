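"""Line × tester ANOVA and combining-ability (GCA/SCA) estimation.

Under the standard line × tester model for cross means Ȳ_ij· (l lines,
t testers, r replications),

    g_i  = Ȳ_i·· − Ȳ···          general combining ability of line i
    g_j  = Ȳ·j· − Ȳ···           general combining ability of tester j
    s_ij = Ȳ_ij· − Ȳ_i·· − Ȳ·j· + Ȳ···   specific combining ability

so that Ȳ_ij· = Ȳ··· + g_i + g_j + s_ij exactly, with all effect vectors
summing to zero.  The randomized-block ANOVA partitions the plot-level sum
of squares into replications, crosses (= lines + testers + line×tester) and
error; standard errors of the effects follow from the error mean square:

    SE(g_line)   = sqrt(MSE / (r t))
    SE(g_tester) = sqrt(MSE / (r l))
    SE(s_ij)     = sqrt(MSE / r)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import CrossDesign
from .panel import TrialData, ValidationError, cross_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossMeans:
    """Per-trait l × t table of cross means plus the replication count."""

    table: pd.DataFrame       # index: lines, columns: testers
    r: int | None             # None when built from a means-only table

    @property
    def lines(self) -> list[str]:
        return list(self.table.index)

    @property
    def testers(self) -> list[str]:
        return list(self.table.columns)

    @property
    def grand_mean(self) -> float:
        return float(self.table.to_numpy().mean())

    @property
    def line_means(self) -> pd.Series:
        return self.table.mean(axis=1)

    @property
    def tester_means(self) -> pd.Series:
        return self.table.mean(axis=0)


@dataclass(frozen=True)
class EffectStandardErrors:
    """Standard errors per effect class and for differences of two effects."""

    gca_line: float
    gca_tester: float
    sca: float

    @property
    def gca_line_diff(self) -> float:
        return math.sqrt(2.0) * self.gca_line

    @property
    def gca_tester_diff(self) -> float:
        return math.sqrt(2.0) * self.gca_tester

    @property
    def sca_diff(self) -> float:
        return math.sqrt(2.0) * self.sca


@dataclass(frozen=True)
class CombiningAbilityResult:
    """GCA/SCA effects with ANOVA and significance for one trait."""

    trait: str
    gca_lines: pd.Series
    gca_testers: pd.Series
    sca: pd.DataFrame
    anova: pd.DataFrame | None
    standard_errors: EffectStandardErrors | None
    error_df: int | None

    def stars(self, effect: float, se: float) -> str:
        if self.standard_errors is None or se == 0:
            return "na"
        p = 2.0 * stats.t.sf(abs(effect) / se, df=self.error_df)
        return "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def cross_means(trial: TrialData, trait: str) -> CrossMeans:
    """Average replications into the l × t cross-mean table for one trait."""
    sub = trial.records[trial.records["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"trial has no observations for trait {trait!r}")
    table = sub.pivot_table(index="line", columns="tester", values="value",
                            aggfunc="mean")
    table = table.loc[list(trial.lines), list(trial.testers)]
    return CrossMeans(table=table, r=trial.n_reps)


def cross_means_from_table(
    hybrids: pd.DataFrame, design: CrossDesign, trait: str, r: int | None = None
) -> CrossMeans:
    """Build CrossMeans from a hybrid-means table (no replicate data)."""
    table = pd.DataFrame(
        {
            t: [float(hybrids.at[cross_name(t, l), trait]) for l in design.lines]
            for t in design.testers
        },
        index=pd.Index(design.lines, name="line"),
    )
    table.columns.name = "tester"
    return CrossMeans(table=table, r=r)


def gca_effects(cm: CrossMeans) -> tuple[pd.Series, pd.Series]:
    """General combining abilities: marginal mean minus grand mean."""
    mu = cm.grand_mean
    return cm.line_means - mu, cm.tester_means - mu


def sca_effects(cm: CrossMeans) -> pd.DataFrame:
    """Specific combining abilities: the interaction residual of the table."""
    mu = cm.grand_mean
    return cm.table.sub(cm.line_means, axis=0).sub(cm.tester_means, axis=1) + mu


def lxt_anova(trial: TrialData, trait: str) -> pd.DataFrame:
    """Randomized-block line × tester ANOVA from definition-level sums of squares."""
    sub = trial.records[trial.records["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"trial has no observations for trait {trait!r}")
    l, t, r = trial.n_lines, trial.n_testers, trial.n_reps
    if r < 2:
        raise ValidationError("ANOVA needs r >= 2 replications")
    y = sub["value"].to_numpy()
    grand = y.mean()
    n = y.size

    ss_total = float(((y - grand) ** 2).sum())
    rep_means = sub.groupby("rep")["value"].mean()
    ss_rep = float(l * t * ((rep_means - grand) ** 2).sum())
    cell = sub.groupby(["line", "tester"])["value"].mean()
    ss_crosses = float(r * ((cell - grand) ** 2).sum())
    line_means = sub.groupby("line")["value"].mean()
    ss_lines = float(t * r * ((line_means - grand) ** 2).sum())
    tester_means = sub.groupby("tester")["value"].mean()
    ss_testers = float(l * r * ((tester_means - grand) ** 2).sum())
    ss_lxt = ss_crosses - ss_lines - ss_testers
    ss_error = ss_total - ss_rep - ss_crosses

    df = {
        "replications": r - 1,
        "crosses": l * t - 1,
        "lines": l - 1,
        "testers": t - 1,
        "line_x_tester": (l - 1) * (t - 1),
        "error": (l * t - 1) * (r - 1),
    }
    ss = {
        "replications": ss_rep,
        "crosses": ss_crosses,
        "lines": ss_lines,
        "testers": ss_testers,
        "line_x_tester": ss_lxt,
        "error": ss_error,
    }
    ms = {k: ss[k] / df[k] for k in ss}
    mse = ms["error"]
    out = pd.DataFrame({"df": df, "SS": ss, "MS": ms})
    f_rows = ["crosses", "lines", "testers", "line_x_tester"]
    out["F"] = np.nan
    out["p"] = np.nan
    if mse > 0:
        for k in f_rows:
            fval = ms[k] / mse
            out.at[k, "F"] = fval
            out.at[k, "p"] = stats.f.sf(fval, df[k], df["error"])
    out.index.name = "source"
    return out


def effect_standard_errors(mse: float, l: int, t: int, r: int) -> EffectStandardErrors:
    if mse < 0:
        raise ValidationError("mse must be non-negative")
    return EffectStandardErrors(
        gca_line=math.sqrt(mse / (r * t)),
        gca_tester=math.sqrt(mse / (r * l)),
        sca=math.sqrt(mse / r),
    )


def combining_ability(
    trial: TrialData | None = None,
    trait: str | None = None,
    cm: CrossMeans | None = None,
) -> CombiningAbilityResult:
    """Full combining-ability analysis for one trait.

    Give either a replicated ``trial`` (effects + ANOVA + SEs) or a
    precomputed means-only ``cm`` (effects only; significance unavailable).
    """
    if (trial is None) == (cm is None):
        raise ValidationError("supply exactly one of trial or cm")
    anova = None
    ses = None
    err_df = None
    if trial is not None:
        if trait is None:
            raise ValidationError("trait required with a trial")
        cm = cross_means(trial, trait)
        anova = lxt_anova(trial, trait)
        mse = float(anova.at["error", "MS"])
        err_df = int(anova.at["error", "df"])
        ses = effect_standard_errors(mse, trial.n_lines, trial.n_testers, trial.n_reps)
    g_l, g_t = gca_effects(cm)
    return CombiningAbilityResult(
        trait=trait or "",
        gca_lines=g_l,
        gca_testers=g_t,
        sca=sca_effects(cm),
        anova=anova,
        standard_errors=ses,
        error_df=err_df,
    )


def combining_ability_report(res: CombiningAbilityResult) -> pd.DataFrame:
    """Tidy (parent/cross, role, effect, star) table mirroring report layout."""
    rows = []
    se = res.standard_errors
    for pid, eff in res.gca_lines.items():
        star = res.stars(eff, se.gca_line) if se else "na"
        rows.append(("line", pid, float(eff), star))
    for pid, eff in res.gca_testers.items():
        star = res.stars(eff, se.gca_tester) if se else "na"
        rows.append(("tester", pid, float(eff), star))
    for line in res.sca.index:
        for tester in res.sca.columns:
            eff = float(res.sca.at[line, tester])
            star = res.stars(eff, se.sca) if se else "na"
            rows.append(("cross", cross_name(tester, line), eff, star))
    return pd.DataFrame(rows, columns=["role", "id", "effect", "sig"])
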