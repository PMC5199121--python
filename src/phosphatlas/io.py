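"""Readers and writers for the tabular formats the pipeline touches.

All tables are plain TSV (UTF-8, header required where stated).  Kinase
substrate sets may also be supplied as GMT, with the set name holding the
kinase and members encoded as ``PROT_S123`` tokens.  Matrices are written
rows × conditions with empty cells for missing values.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    COMPENDIUM_COLUMNS,
    ComplexCatalog,
    FlankTable,
    KinaseSubstrateSets,
    PhosphoCompendium,
    SiteID,
)

__all__ = [
    "read_compendium",
    "write_compendium",
    "read_kinase_sets",
    "write_kinase_sets_gmt",
    "read_complexes",
    "write_complexes",
    "read_flanks",
    "write_flanks",
    "read_matrix",
    "write_matrix",
    "SchemaError",
]

MATRIX_FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A required column or field is absent or malformed."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_compendium(path, schema: dict[str, str] | None = None) -> PhosphoCompendium:
    """Read a long-format compendium TSV.

    Parameters
    ----------
    path : str or Path
        Tab-separated table with columns ``study, condition, replicate,
        replicate_kind, protein, residue, position, mod_key, log2_ratio``.
    schema : dict, optional
        Mapping from canonical column name to the column name used in the
        file, for tables with nonstandard headers.

    Rows whose ratio does not parse as a finite number are dropped; the
    count is recorded in ``compendium.report["dropped_unparseable"]``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty input file") from exc
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, COMPENDIUM_COLUMNS, path)
    n_in = len(df)
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    keep = np.isfinite(ratios.to_numpy(dtype=float))
    df = df.loc[keep].copy()
    df["log2_ratio"] = ratios[keep].astype(float)
    df["position"] = df["position"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    comp = PhosphoCompendium(
        df.reset_index(drop=True),
        report={"dropped_unparseable": int(n_in - keep.sum())},
    )
    comp.validate()
    return comp


def write_compendium(comp: PhosphoCompendium, path) -> None:
    comp.records.to_csv(path, sep="\t", index=False, float_format=MATRIX_FLOAT_FORMAT)


def _parse_site(token: str, path, lineno: int) -> SiteID:
    try:
        return SiteID.parse(token)
    except ValueError as exc:
        raise SchemaError(f"{path}:{lineno}: {exc}") from exc


def read_kinase_sets(path, exclude_autophos: bool = True) -> KinaseSubstrateSets:
    """Read kinase → substrate-site sets from GMT or 3-column TSV.

    The format is sniffed from the extension (``.gmt`` → GMT, else TSV with
    columns ``kinase, site, source``).  Duplicate edges are merged with their
    source tags unioned.  With ``exclude_autophos`` (the default) edges whose
    substrate lies on the kinase's own protein are removed.
    """
    path = Path(path)
    sets: dict[str, set[SiteID]] = {}
    sources: dict[tuple[str, SiteID], set[str]] = {}

    if path.suffix.lower() == ".gmt":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise SchemaError(
                        f"{path}:{lineno}: GMT lines need name, description, >=1 member"
                    )
                kinase, description = fields[0], fields[1]
                for token in fields[2:]:
                    if not token:
                        continue
                    site = _parse_site(token, path, lineno)
                    sets.setdefault(kinase, set()).add(site)
                    sources.setdefault((kinase, site), set()).add(description or "gmt")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        _require_columns(df, ["kinase", "site"], path)
        if "source" not in df.columns:
            df["source"] = "tsv"
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            site = _parse_site(row.site, path, lineno)
            sets.setdefault(row.kinase, set()).add(site)
            sources.setdefault((row.kinase, site), set()).add(row.source)

    result = KinaseSubstrateSets(sets, sources)
    if exclude_autophos:
        result = result.exclude_autophosphorylation()
    return result


def write_kinase_sets_gmt(sets: KinaseSubstrateSets, path, description: str = "phosphatlas") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for kinase in sets.kinases():
            members = sorted(str(s) for s in sets.sets[kinase])
            fh.write("\t".join([kinase, description, *members]) + "\n")


def read_complexes(path, deduplicate: bool = True, jaccard_threshold: float = 0.9) -> ComplexCatalog:
    """Read a CORUM-like 2/3-column TSV (``complex_id, protein[, name]``).

    Complexes without subunits are skipped with a warning; on read, exact
    and near-duplicate subunit sets collapse to one copy (see
    :meth:`ComplexCatalog.deduplicate`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["complex_id", "protein"], path)
    complexes: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for cid, grp in df.groupby("complex_id"):
        subunits = frozenset(p for p in grp["protein"] if isinstance(p, str) and p)
        if not subunits:
            import warnings

            warnings.warn(f"complex {cid!r} has no subunits; skipped", stacklevel=2)
            continue
        complexes[cid] = subunits
        if "name" in df.columns:
            names[cid] = grp["name"].iloc[0]
    catalog = ComplexCatalog(complexes, names)
    if deduplicate:
        catalog = catalog.deduplicate(jaccard_threshold)
    return catalog


def write_complexes(catalog: ComplexCatalog, path) -> None:
    rows = [
        {"complex_id": cid, "protein": protein, "name": catalog.names.get(cid, cid)}
        for cid in sorted(catalog.complexes)
        for protein in sorted(catalog.complexes[cid])
    ]
    pd.DataFrame(rows, columns=["complex_id", "protein", "name"]).to_csv(
        path, sep="\t", index=False
    )


def read_flanks(path) -> FlankTable:
    """Read a ``site <tab> flank`` TSV into a :class:`FlankTable`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["site", "flank"], path)
    flanks = {
        SiteID.parse(row.site): row.flank for row in df.itertuples(index=False)
    }
    return FlankTable(flanks)


def write_flanks(table: FlankTable, path) -> None:
    rows = [{"site": str(s), "flank": f} for s, f in sorted(table.flanks.items())]
    pd.DataFrame(rows, columns=["site", "flank"]).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a rows × conditions TSV matrix; empty cells become NaN."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix TSV with a fixed float format so round trips are bit-identical."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    matrix.to_csv(path, sep="\t", float_format=MATRIX_FLOAT_FORMAT)
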