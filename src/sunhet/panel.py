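"""Domain containers and CSV I/O for germplasm panels and line × tester trials.

The canonical trait schema follows the nine agro-morphological characters
recorded in sunflower breeding trials:

====  =========================  =====
abbr  trait                      units
====  =========================  =====
DFI   days to flower initiation  days
DFC   days to flower completion  days
PH    plant height               cm
LA    leaf area                  cm²
HD    head diameter              cm
SC    stem curvature             cm
LP    leaves per plant           count
HSW   100-seed weight            g
SYP   seed yield per plant       g
====  =========================  =====

Marker (SSR) and seed-protein (SDS-PAGE) profiles enter as presence/absence
(0/1) matrices, one column per scored band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS: tuple[str, ...] = ("DFI", "DFC", "PH", "LA", "HD", "SC", "LP", "HSW", "SYP")

TRAIT_UNITS: dict[str, str] = {
    "DFI": "days",
    "DFC": "days",
    "PH": "cm",
    "LA": "cm2",
    "HD": "cm",
    "SC": "cm",
    "LP": "count",
    "HSW": "g",
    "SYP": "g",
}

LINE_TYPES: tuple[str, ...] = ("CMS", "B", "R", "SFP")

#: separator used in cross identifiers, e.g. "RHP-68 × CMS-HAP-56"
CROSS_SEP = " × "


class ValidationError(ValueError):
    """Input data violates a domain invariant."""


class SchemaError(ValidationError):
    """Input file does not match the declared column schema."""


def cross_name(tester: str, line: str) -> str:
    """Render a cross identifier as ``TESTER × LINE`` (pollinator first)."""
    return f"{tester}{CROSS_SEP}{line}"


def parse_cross(name: str) -> tuple[str, str]:
    """Split a ``TESTER × LINE`` identifier into its (tester, line) pair."""
    parts = name.split(CROSS_SEP)
    if len(parts) != 2:
        # tolerate a plain "x" separator from hand-edited files
        parts = [p.strip() for p in name.replace(" x ", CROSS_SEP).split(CROSS_SEP)]
    if len(parts) != 2 or not all(parts):
        raise ValidationError(f"cannot parse cross identifier {name!r}")
    return parts[0], parts[1]


def _check_binary(df: pd.DataFrame, block: str) -> None:
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            f"({df.index[r]}, {df.columns[c]})={arr[r, c]!r}"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValidationError(
            f"non-binary values in {block} block: " + ", ".join(cells)
        )


@dataclass(frozen=True)
class GermplasmPanel:
    """A genotyped, phenotyped and protein-profiled germplasm collection.

    All three data blocks share the same row order (one row per genotype).
    ``ssr_bands`` and ``protein_bands`` may be empty (zero columns) when a
    panel carries phenotypes only.
    """

    line_types: pd.Series          # index: genotype id, values in LINE_TYPES
    traits: pd.DataFrame           # genotypes × 9, canonical trait columns
    ssr_bands: pd.DataFrame        # genotypes × M_s, values in {0, 1}
    protein_bands: pd.DataFrame    # genotypes × M_p, values in {0, 1}

    def __post_init__(self) -> None:
        ids = self.traits.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate genotype ids: {dupes}")
        for name, block in (
            ("line_types", self.line_types),
            ("ssr_bands", self.ssr_bands),
            ("protein_bands", self.protein_bands),
        ):
            if not block.index.equals(ids):
                raise ValidationError(f"{name} row order differs from traits")
        unknown = set(self.line_types) - set(LINE_TYPES)
        if unknown:
            raise ValidationError(f"unknown line types: {sorted(unknown)}")
        if list(self.traits.columns) != list(TRAITS):
            raise SchemaError(
                f"trait columns must be {list(TRAITS)}, got {list(self.traits.columns)}"
            )
        vals = self.traits.to_numpy(dtype=float)
        if np.isnan(vals).any():
            rows = self.traits.index[np.isnan(vals).any(axis=1)].tolist()
            raise ValidationError(f"missing trait values for genotypes {rows}")
        if (vals < 0).any():
            raise ValidationError("trait values must be non-negative")
        _check_binary(self.ssr_bands, "SSR")
        _check_binary(self.protein_bands, "protein")

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def n_genotypes(self) -> int:
        return len(self.traits)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.traits)


@dataclass(frozen=True)
class TrialData:
    """Replicated line × tester trial observations in long format.

    ``records`` has columns (line, tester, rep, trait, value) and must form a
    complete l × t × r grid for every trait (balanced design).
    """

    records: pd.DataFrame
    lines: tuple[str, ...] = field(init=False)
    testers: tuple[str, ...] = field(init=False)
    n_reps: int = field(init=False)

    def __post_init__(self) -> None:
        req = ["line", "tester", "rep", "trait", "value"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise SchemaError(f"trial table missing columns {missing}")
        rec = self.records
        lines = tuple(pd.unique(rec["line"]))
        testers = tuple(pd.unique(rec["tester"]))
        reps = sorted(pd.unique(rec["rep"]))
        object.__setattr__(self, "lines", lines)
        object.__setattr__(self, "testers", testers)
        object.__setattr__(self, "n_reps", len(reps))
        if not np.isfinite(rec["value"].to_numpy(dtype=float)).all():
            raise ValidationError("trial observations must be finite")
        # balance: every (line, tester, rep) cell present exactly once per trait
        for trait, sub in rec.groupby("trait", sort=False):
            have = set(zip(sub["line"], sub["tester"], sub["rep"]))
            if len(have) != len(sub):
                raise ValidationError(f"duplicate plots for trait {trait}")
            want = {(l, t, r) for l in lines for t in testers for r in reps}
            miss = sorted(want - have)
            if miss:
                raise ValidationError(
                    f"unbalanced trial for trait {trait}: missing plots {miss[:10]}"
                )

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.records["trait"]))

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_testers(self) -> int:
        return len(self.testers)


def check_means_table(df: pd.DataFrame, kind: str = "means") -> pd.DataFrame:
    """Validate a parent- or hybrid-means table (id index × trait columns)."""
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate ids in {kind} table")
    missing = [t for t in TRAITS if t not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing traits {missing}")
    out = df.loc[:, list(TRAITS)].astype(float)
    if out.isna().to_numpy().any():
        raise ValidationError(f"missing values in {kind} table")
    return out


# ---------------------------------------------------------------------------
# file I/O


DEFAULT_SCHEMA: dict = {
    "id": "genotype",
    "line_type": "line_type",
    "traits": {t: t for t in TRAITS},
    "ssr_prefix": "SSR_",
    "protein_prefix": "PROT_",
}


def _resolve_band_columns(
    columns: Sequence[str], schema: Mapping, key: str
) -> list[str]:
    explicit = schema.get(f"{key}_columns")
    if explicit is not None:
        missing = [c for c in explicit if c not in columns]
        if missing:
            raise SchemaError(f"{key} columns not found in file: {missing}")
        return list(explicit)
    prefix = schema.get(f"{key}_prefix", DEFAULT_SCHEMA[f"{key}_prefix"])
    return [c for c in columns if c.startswith(prefix)]


def read_panel(
    path: str | Path,
    schema: Mapping | None = None,
    impute: bool = False,
) -> GermplasmPanel:
    """Read a germplasm panel from CSV/TSV.

    ``schema`` maps the canonical fields onto the source headers; omitted
    entries fall back to the canonical names (see :data:`DEFAULT_SCHEMA`).
    Missing trait values are rejected unless ``impute`` is set, in which case
    they are replaced by the column mean (logged).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")

    id_col = schema["id"]
    type_col = schema["line_type"]
    trait_map = {**{t: t for t in TRAITS}, **dict(schema.get("traits") or {})}
    needed = [id_col, type_col] + [trait_map[t] for t in TRAITS]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise SchemaError(f"panel file {path} missing columns {missing}")

    ids = raw[id_col].astype(str)
    traits = pd.DataFrame(
        {t: pd.to_numeric(raw[trait_map[t]], errors="coerce") for t in TRAITS}
    )
    traits.index = pd.Index(ids, name="genotype")
    if impute and traits.isna().to_numpy().any():
        n_bad = int(traits.isna().to_numpy().sum())
        logger.warning("imputing %d missing trait values with column means", n_bad)
        traits = traits.fillna(traits.mean())

    ssr_cols = _resolve_band_columns(raw.columns, schema, "ssr")
    prot_cols = _resolve_band_columns(raw.columns, schema, "protein")
    ssr = raw[ssr_cols].set_axis(traits.index, axis=0)
    prot = raw[prot_cols].set_axis(traits.index, axis=0)

    panel = GermplasmPanel(
        line_types=raw[type_col].astype(str).set_axis(traits.index).rename("line_type"),
        traits=traits,
        ssr_bands=ssr,
        protein_bands=prot,
    )
    logger.info(
        "read panel %s: %d genotypes, %d SSR bands, %d protein bands",
        path, panel.n_genotypes, ssr.shape[1], prot.shape[1],
    )
    return panel


def _float_fmt(v: float) -> str:
    # shortest decimal string that parses back to exactly the same double,
    # so write -> read -> write is byte-identical
    return np.format_float_positional(v, unique=True, trim="-")


def write_panel(panel: GermplasmPanel, path: str | Path) -> None:
    """Write a panel in the canonical column order (round-trips bit-identically)."""
    path = Path(path)
    out = pd.DataFrame({"genotype": panel.genotype_ids})
    out["line_type"] = panel.line_types.to_numpy()
    for t in TRAITS:
        out[t] = panel.traits[t].to_numpy()
    for c in panel.ssr_bands.columns:
        out[c] = panel.ssr_bands[c].to_numpy(dtype=int)
    for c in panel.protein_bands.columns:
        out[c] = panel.protein_bands[c].to_numpy(dtype=int)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out.to_csv(path, sep=sep, index=False, float_format=_float_fmt)


def read_trial(path: str | Path) -> TrialData:
    """Read a long-format replicated trial table (line, tester, rep, trait, value)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    req = ["line", "tester", "rep", "trait", "value"]
    missing = [c for c in req if c not in raw.columns]
    if missing:
        raise SchemaError(f"trial file {path} missing columns {missing}")
    rec = raw[req].copy()
    rec["line"] = rec["line"].astype(str)
    rec["tester"] = rec["tester"].astype(str)
    rec["rep"] = rec["rep"].astype(int)
    rec["trait"] = rec["trait"].astype(str)
    rec["value"] = rec["value"].astype(float)
    return TrialData(records=rec)


def write_trial(trial: TrialData, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    trial.records.to_csv(path, sep=sep, index=False, float_format=_float_fmt)


def read_means(path: str | Path, id_col: str | None = None) -> pd.DataFrame:
    """Read a parent- or hybrid-means table (first column = identifier)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if id_col is None:
        id_col = raw.columns[0]
    raw = raw.set_index(id_col)
    return check_means_table(raw)
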