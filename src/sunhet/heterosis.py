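"""Mid-parent heterosis and heterobeltiosis for line × tester hybrids.

For a cross with parent means P1, P2 and F1 mean F1:

    MP  = (P1 + P2) / 2            mid-parent value
    BP  = max(P1, P2)              better parent (larger mean, regardless of
                                   whether the trait is agronomically
                                   "better" when small — flowering dates and
                                   plant height keep the same convention)
    MPH = 100 (F1 − MP) / MP       mid-parent heterosis, %
    BPH = 100 (F1 − BP) / BP       heterobeltiosis, %

When a replicated-trial error mean square is available, deviations are
tested with the standard line × tester variances Var(F1 − MP) = 3·MSE/(2r)
and Var(F1 − BP) = 2·MSE/r and starred at p < 0.05 (*) / p < 0.01 (**).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import CrossDesign
from .panel import TRAITS, ValidationError, cross_name

logger = logging.getLogger(__name__)


def mid_parent_heterosis(f1: float, p1: float, p2: float) -> float:
    """Percent deviation of the F1 from the mid-parent value."""
    mp = (p1 + p2) / 2.0
    if mp == 0:
        raise ValidationError("mid-parent value is zero; MPH undefined")
    return 100.0 * (f1 - mp) / mp


def better_parent_heterosis(f1: float, p1: float, p2: float) -> float:
    """Percent deviation of the F1 from the larger parent mean."""
    bp = max(p1, p2)
    if bp == 0:
        raise ValidationError("better-parent value is zero; BPH undefined")
    return 100.0 * (f1 - bp) / bp


def heterosis_table(
    parents: pd.DataFrame,
    hybrids: pd.DataFrame,
    design: CrossDesign,
    traits=TRAITS,
) -> pd.DataFrame:
    """MPH and BPH for every cross × trait, at full precision.

    ``parents`` and ``hybrids`` are mean tables indexed by genotype id and
    cross name respectively.  Returns a tidy frame with columns
    (cross, line, tester, trait, f1, p_line, p_tester, mp, bp, mph, bph).
    """
    rows = []
    for tester, line in design.crosses:
        name = cross_name(tester, line)
        for pid in (line, tester):
            if pid not in parents.index:
                raise ValidationError(f"cross {name!r} references unknown parent {pid!r}")
        if name not in hybrids.index:
            raise ValidationError(f"no hybrid mean for cross {name!r}")
        for trait in traits:
            p1 = float(parents.at[line, trait])
            p2 = float(parents.at[tester, trait])
            f1 = float(hybrids.at[name, trait])
            rows.append(
                (
                    name, line, tester, trait, f1, p1, p2,
                    (p1 + p2) / 2.0, max(p1, p2),
                    mid_parent_heterosis(f1, p1, p2),
                    better_parent_heterosis(f1, p1, p2),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cross", "line", "tester", "trait", "f1", "p_line", "p_tester",
            "mp", "bp", "mph", "bph",
        ],
    )


def heterosis_t_statistics(f1, mp, bp, mse: float, r: int):
    """t statistics for F1−MP and F1−BP under the replicated-trial model."""
    if mse <= 0:
        raise ValidationError("mse must be positive")
    if r < 2:
        raise ValidationError("need at least two replications")
    t_mp = (np.asarray(f1) - np.asarray(mp)) / math.sqrt(3.0 * mse / (2.0 * r))
    t_bp = (np.asarray(f1) - np.asarray(bp)) / math.sqrt(2.0 * mse / r)
    return t_mp, t_bp


def _stars(p: np.ndarray) -> np.ndarray:
    return np.where(p < 0.01, "**", np.where(p < 0.05, "*", "ns"))


def two_sided_p(t, error_df: float) -> np.ndarray:
    """Two-sided p-value; ``error_df=inf`` uses the normal reference."""
    t = np.abs(np.asarray(t, dtype=float))
    if math.isinf(error_df):
        return 2.0 * stats.norm.sf(t)
    return 2.0 * stats.t.sf(t, df=error_df)


def heterosis_significance(
    table: pd.DataFrame,
    mse: float | dict | None,
    r: int,
    error_df: float,
) -> pd.DataFrame:
    """Annotate a heterosis table with significance stars.

    ``mse`` may be a scalar or a per-trait mapping; when absent the
    annotation is skipped with a warning (mean tables alone carry no error
    information) and the flag columns read ``na``.
    """
    out = table.copy()
    if mse is None:
        logger.warning("no error mean square supplied; significance unavailable")
        out["mph_sig"] = "na"
        out["bph_sig"] = "na"
        return out
    mse_map = mse if isinstance(mse, dict) else {t: mse for t in out["trait"].unique()}
    tm = np.empty(len(out))
    tb = np.empty(len(out))
    for trait, idx in out.groupby("trait").groups.items():
        sub = out.loc[idx]
        tm[out.index.get_indexer(idx)], tb[out.index.get_indexer(idx)] = (
            heterosis_t_statistics(sub["f1"], sub["mp"], sub["bp"], mse_map[trait], r)
        )
    out["mph_t"] = tm
    out["bph_t"] = tb
    out["mph_sig"] = _stars(two_sided_p(tm, error_df))
    out["bph_sig"] = _stars(two_sided_p(tb, error_df))
    return out


def heterosis_wide(table: pd.DataFrame, value: str = "mph", ndigits: int = 2) -> pd.DataFrame:
    """Crosses × traits view of one heterosis column, rounded for reporting."""
    wide = table.pivot(index="cross", columns="trait", values=value)
    wide = wide.loc[:, [t for t in TRAITS if t in wide.columns]]
    return wide.round(ndigits)
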