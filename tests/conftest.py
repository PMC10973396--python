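from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from sunhet import datasets
from sunhet.panel import TRAITS, GermplasmPanel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference():
    """(parents, hybrids, design) of the bundled 12-parent evaluation."""
    return datasets.load_reference_trial()


@pytest.fixture(scope="session")
def reported_heterosis():
    """Separately reported MPH/BPH values for the bundled dataset (long form)."""
    wide = pd.read_csv(DATA_DIR / "reported_heterosis.csv")
    long = wide.melt(id_vars=["line", "tester"])
    long["trait"] = long["variable"].str.rsplit("_", n=1).str[0]
    long["kind"] = long["variable"].str.rsplit("_", n=1).str[1]
    return long.pivot_table(
        index=["line", "tester", "trait"], columns="kind", values="value"
    ).reset_index()


def make_panel(n=12, n_ssr=5, n_protein=3, seed=0) -> GermplasmPanel:
    """Small random but valid panel for I/O and preprocessing tests."""
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"G{i:02d}" for i in range(n)], name="genotype")
    types = pd.Series(
        [["CMS", "B", "R", "SFP"][i % 4] for i in range(n)], index=ids, name="line_type"
    )
    traits = pd.DataFrame(
        rng.uniform(5, 200, size=(n, len(TRAITS))), index=ids, columns=list(TRAITS)
    )
    ssr = pd.DataFrame(
        rng.integers(0, 2, size=(n, n_ssr)), index=ids,
        columns=[f"SSR_{i + 1:02d}" for i in range(n_ssr)],
    )
    prot = pd.DataFrame(
        rng.integers(0, 2, size=(n, n_protein)), index=ids,
        columns=[f"PROT_{i + 1:02d}" for i in range(n_protein)],
    )
    return GermplasmPanel(line_types=types, traits=traits, ssr_bands=ssr,
                          protein_bands=prot)


@pytest.fixture
def small_panel():
    return make_panel()
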