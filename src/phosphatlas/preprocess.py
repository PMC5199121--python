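"""Quality control and normalization of a phosphopeptide compendium.

Turns a long table of raw log2 fold changes into a site × condition
quantification matrix through a fixed sequence of steps:

1. merge peptides carrying the same modification set (ratios averaged),
2. average technical replicates; keep biological replicates as separate
   condition columns,
3. keep monophosphorylated peptides only,
4. drop sites identified in a single study,
5. quantile-normalize across conditions,
6. drop conditions with too few quantifications.

Each filter is idempotent and the pipeline records per-step counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import PhosphoCompendium, count_phosphosites

__all__ = [
    "merge_equivalent_peptides",
    "average_technical_replicates",
    "filter_monophosphorylated",
    "filter_multistudy_sites",
    "to_quant_matrix",
    "quantile_normalize",
    "filter_low_coverage_conditions",
    "run_preprocess",
]

_GROUP_KEY = ["study", "condition", "replicate", "replicate_kind",
              "protein", "residue", "position", "mod_key"]


def merge_equivalent_peptides(comp: PhosphoCompendium) -> PhosphoCompendium:
    """Merge peptides with identical modification sets; ratios are averaged.

    Records sharing (study, condition, replicate, mod_key, site) collapse to
    a single record holding the arithmetic mean of their log2 ratios.
    """
    rec = comp.records
    if rec.empty:
        return comp
    merged = (
        rec.groupby(_GROUP_KEY, sort=False, as_index=False)["log2_ratio"].mean()
    )
    return comp.copy_with(merged, merged_records=int(len(rec) - len(merged)))


def average_technical_replicates(comp: PhosphoCompendium) -> PhosphoCompendium:
    """Collapse technical replicates to their mean; split biological replicates.

    Technical replicates of a condition are averaged per site/peptide.
    Biological replicates remain separate: when a condition carries two or
    more biological replicate indices, each becomes its own condition column
    named ``"<condition>.rep<k>"``.
    """
    rec = comp.records
    if rec.empty:
        return comp
    kinds = set(rec["replicate_kind"].unique())
    unknown = kinds - {"technical", "biological"}
    if unknown:
        raise ValueError(f"unknown replicate_kind values: {sorted(unknown)}")

    tech = rec[rec["replicate_kind"] == "technical"]
    bio = rec[rec["replicate_kind"] == "biological"].copy()

    parts = []
    if len(tech):
        collapsed = (
            tech.groupby(
                ["study", "condition", "protein", "residue", "position", "mod_key"],
                sort=False,
                as_index=False,
            )["log2_ratio"].mean()
        )
        collapsed["replicate"] = 1
        collapsed["replicate_kind"] = "technical"
        parts.append(collapsed)

    if len(bio):
        multi = (
            bio.groupby("condition")["replicate"].nunique().loc[lambda s: s > 1].index
        )
        is_multi = bio["condition"].isin(multi)
        bio.loc[is_multi, "condition"] = (
            bio.loc[is_multi, "condition"]
            + ".rep"
            + bio.loc[is_multi, "replicate"].astype(str)
        )
        bio["replicate"] = 1
        parts.append(bio)

    out = pd.concat(parts, ignore_index=True) if parts else rec.iloc[:0]
    return comp.copy_with(out, technical_averaged=int(len(rec) - len(out)))


def filter_monophosphorylated(comp: PhosphoCompendium) -> PhosphoCompendium:
    """Keep records from peptides carrying exactly one phosphosite."""
    rec = comp.records
    if rec.empty:
        return comp
    n_sites = rec["mod_key"].map(count_phosphosites)
    kept = rec[n_sites == 1]
    return comp.copy_with(kept, dropped_multiphospho=int(len(rec) - len(kept)))


def filter_multistudy_sites(comp: PhosphoCompendium, min_studies: int = 2) -> PhosphoCompendium:
    """Drop sites reported in fewer than ``min_studies`` distinct studies."""
    rec = comp.records
    if rec.empty or min_studies <= 1:
        return comp.copy_with(rec, dropped_single_study_sites=0)
    tokens = comp.site_tokens
    counts = rec.assign(_site=tokens).groupby("_site")["study"].transform("nunique")
    kept = rec[counts.to_numpy() >= min_studies]
    n_sites_dropped = tokens.nunique() - comp.copy_with(kept).site_tokens.nunique()
    return comp.copy_with(kept, dropped_single_study_sites=int(n_sites_dropped))


def to_quant_matrix(comp: PhosphoCompendium) -> pd.DataFrame:
    """Pivot the compendium into a site × condition matrix (NaN = missing)."""
    rec = comp.records
    if rec.empty:
        return pd.DataFrame()
    df = rec.assign(_site=comp.site_tokens)
    return df.pivot_table(
        index="_site", columns="condition", values="log2_ratio", aggfunc="mean"
    ).rename_axis(index="site", columns="condition")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize condition columns to a common reference distribution.

    The reference is the mean of the per-column empirical quantile functions
    evaluated on a common probability grid (linear interpolation), which
    handles columns with different numbers of observed values.  Within each
    column, values are replaced by the reference quantile at their rank;
    tied values receive the average of their target values.  Missing cells
    stay missing.  Columns with fewer than two observed values are excluded
    with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 conditions")
    counts = matrix.notna().sum(axis=0)
    bad = counts[counts < 2].index
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} condition(s) with <2 values: {list(bad)}",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=bad)
        counts = counts.drop(bad)
    if matrix.shape[1] < 2:
        raise ValueError("fewer than 2 usable conditions after exclusion")

    n_max = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_max)
    ref = np.zeros(n_max)
    for col in matrix.columns:
        vals = matrix[col].dropna().to_numpy(dtype=float)
        ref += np.quantile(vals, grid)
    ref /= matrix.shape[1]

    out = matrix.copy()
    for col in matrix.columns:
        observed = matrix[col].dropna()
        vals = observed.to_numpy(dtype=float)
        n = len(vals)
        probs = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        targets = np.interp(probs, grid, ref)
        order = np.argsort(vals, kind="stable")
        assigned = np.empty(n)
        assigned[order] = targets
        # ties: average the assigned targets within equal-value groups
        s = pd.Series(assigned, index=observed.index)
        v = pd.Series(vals, index=observed.index)
        s = s.groupby(v).transform("mean")
        out.loc[s.index, col] = s
    return out


def filter_low_coverage_conditions(
    matrix: pd.DataFrame, min_quant: int = 1000
) -> tuple[pd.DataFrame, list[str]]:
    """Drop condition columns with fewer than ``min_quant`` quantifications.

    Returns the filtered matrix and the list of dropped conditions.
    """
    counts = matrix.notna().sum(axis=0)
    dropped = sorted(counts[counts < min_quant].index)
    return matrix.drop(columns=dropped), dropped


def run_preprocess(
    comp: PhosphoCompendium,
    min_studies: int = 2,
    min_quant: int = 1000,
    normalize: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing pipeline; returns (matrix, step report).

    Steps run in a fixed order: peptide merging, technical-replicate
    averaging, monophospho filter, multi-study site filter, quantile
    normalization, low-coverage condition exclusion.  The report carries
    record/site/condition counts after each step.
    """
    report: dict = {"input_records": len(comp)}

    comp = merge_equivalent_peptides(comp)
    report["after_merge"] = len(comp)

    comp = average_technical_replicates(comp)
    report["after_technical_averaging"] = len(comp)

    comp = filter_monophosphorylated(comp)
    report["after_monophospho_filter"] = len(comp)

    comp = filter_multistudy_sites(comp, min_studies=min_studies)
    report["after_multistudy_filter"] = len(comp)

    matrix = to_quant_matrix(comp)
    report["n_sites"] = int(matrix.shape[0])
    report["n_conditions"] = int(matrix.shape[1])

    if normalize and matrix.shape[1] >= 2:
        matrix = quantile_normalize(matrix)

    matrix, dropped = filter_low_coverage_conditions(matrix, min_quant=min_quant)
    report["dropped_low_coverage_conditions"] = dropped
    report["final_conditions"] = int(matrix.shape[1])
    report["final_quantifications"] = int(matrix.notna().sum().sum())
    report.update(comp.report)
    return matrix, report
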