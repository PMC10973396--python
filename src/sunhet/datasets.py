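"""Bundled reference dataset: 12 sunflower parents and their 36 L×T hybrids.

The package ships the published mean-performance tables of a 6 CMS × 6
restorer line × tester evaluation — nine agro-morphological traits for each
of the 12 parents and the 36 F1 crosses.  These means drive the heterosis
worked examples and the regression tests; no replicate-level data were
released with them, so combining-ability significance is unavailable for
this dataset.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .grouping import CrossDesign
from .panel import check_means_table

CMS_LINES = (
    "CMS-HAP-54", "CMS-HAP-56", "CMS-HAP-112",
    "CMS-HAP-111", "CMS-HAP-12", "CMS-HAP-99",
)
RESTORER_LINES = ("RHP-68", "RHP-41", "RHP-38", "RHP-53", "RHP-71", "RHP-69")


def _read(name: str) -> pd.DataFrame:
    with resources.files("sunhet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_parents() -> pd.DataFrame:
    """Parent means, genotype-indexed, canonical trait columns."""
    df = _read("parent_means.csv").set_index("genotype")
    return check_means_table(df, "parent means")


def load_reference_parent_types() -> pd.Series:
    """Line type (CMS or R) of each reference parent."""
    df = _read("parent_means.csv").set_index("genotype")
    return df["line_type"]


def load_reference_hybrids() -> pd.DataFrame:
    """F1 cross means, cross-name-indexed ("TESTER × LINE")."""
    df = _read("hybrid_means.csv").set_index("cross")
    return check_means_table(df, "hybrid means")


def load_reference_design() -> CrossDesign:
    return CrossDesign(lines=CMS_LINES, testers=RESTORER_LINES)


def load_reference_trial() -> tuple[pd.DataFrame, pd.DataFrame, CrossDesign]:
    """(parents, hybrids, design) for the bundled 6 × 6 evaluation."""
    return load_reference_parents(), load_reference_hybrids(), load_reference_design()
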