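"""Kinase × condition activity atlas construction and validation.

``build_activity_matrix`` runs one KSEA test per (kinase, condition) cell
with enough quantified substrates, producing a matrix of signed -log10
empirical p-values ("activities").  Validation operations benchmark the
activities against expected-regulation annotations and against the
quantification profiles of kinase regulatory phosphosites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ksea import (
    KseaNotComputable,
    _null_es_from_positions,
    _sample_hit_positions,
    _walk_es,
    child_rng,
    empirical_pvalue,
)
from .types import KinaseSubstrateSets

__all__ = [
    "ActivityMatrix",
    "build_activity_matrix",
    "call_regulated",
    "benchmark_expected_regulation",
    "regulatory_site_validation",
    "rank_auc",
]


@dataclass
class ActivityMatrix:
    """Signed activities (kinase × condition) with per-cell substrate counts."""

    activities: pd.DataFrame
    n_hits: pd.DataFrame
    n_perm: int
    min_hits: int = 5
    report: dict = field(default_factory=dict)

    @property
    def kinases(self) -> list[str]:
        return list(self.activities.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.activities.columns)


def build_activity_matrix(
    matrix: pd.DataFrame,
    sets: KinaseSubstrateSets,
    min_hits: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    classic_misses: bool = False,
) -> ActivityMatrix:
    """KSEA activity for every (kinase, condition) with >= ``min_hits`` substrates.

    ``matrix`` is the preprocessed site × condition quantification matrix
    (index holds ``PROT_S123`` tokens).  Cells with fewer quantified
    substrates than ``min_hits``, or where the test is degenerate, stay
    missing.  Randomness comes from per-(kinase, condition) streams derived
    from ``seed``, so results do not depend on iteration order.
    """
    kinases = sets.kinases()
    conditions = list(matrix.columns)
    acts = pd.DataFrame(np.nan, index=kinases, columns=conditions)
    hits_df = pd.DataFrame(0, index=kinases, columns=conditions, dtype=int)

    token_sets = {k: {str(s) for s in sites} for k, sites in sets.sets.items()}
    all_tokens = set(matrix.index)
    if not any(all_tokens & toks for toks in token_sets.values()):
        import warnings

        warnings.warn("no kinase substrate overlaps the matrix sites", stacklevel=2)
        return ActivityMatrix(acts, hits_df, n_perm, min_hits)

    for condition in conditions:
        col = matrix[condition].dropna()
        if col.empty:
            continue
        # shared walk order for every kinase tested in this condition
        labels = col.index.to_numpy(dtype=object).astype(str)
        values = col.to_numpy(dtype=float)
        order = np.lexsort((labels, -values))
        w = np.abs(values[order])
        label_index = pd.Index(labels[order])
        n = len(w)
        rank_of = np.empty(n, dtype=np.intp)
        rank_of[order] = np.arange(n)
        for kinase in kinases:
            hit_mask = np.asarray(label_index.isin(token_sets[kinase]))
            m = int(hit_mask.sum())
            hits_df.loc[kinase, condition] = m
            if m < max(min_hits, 1) or m >= n:
                continue
            try:
                es = _walk_es(w, hit_mask, classic_misses=classic_misses)
            except KseaNotComputable:
                continue
            rng = child_rng(seed, kinase, condition)
            subsets = _sample_hit_positions(rng, n, m, n_perm)
            positions = np.sort(rank_of[subsets], axis=1)
            null = _null_es_from_positions(w, positions, classic_misses=classic_misses)
            p = empirical_pvalue(es, null)
            mean_sub = float(values[order][hit_mask].mean())
            sign = 0 if mean_sub == 0 else (1 if mean_sub > 0 else -1)
            acts.loc[kinase, condition] = sign * (-np.log10(p))
    return ActivityMatrix(acts, hits_df, n_perm, min_hits)


def call_regulated(activities: pd.DataFrame, threshold: float = 1.75) -> pd.DataFrame:
    """Boolean regulation calls: |activity| strictly above ``threshold``.

    Missing activities stay missing (nullable boolean dtype).
    """
    calls = (activities.abs() > threshold).astype("boolean")
    return calls.mask(activities.isna())


def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC via the Mann–Whitney rank statistic with average ties."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def benchmark_expected_regulation(
    atlas: ActivityMatrix | pd.DataFrame,
    expected: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
) -> dict:
    """Discrimination of expected kinase–condition regulation from random pairs.

    ``expected`` needs columns ``kinase, condition, direction`` with
    direction in {"up", "down"}.  Positives are scored by direction-matched
    activity (activity × +1 for expected up, × -1 for expected down).  For
    each of ``n_random`` draws, an equally sized negative set of random
    (kinase, condition) cells is sampled from the same kinases and
    conditions, assigned directions resampled from the expected set, and an
    AUC is computed; the mean and SD over draws are returned together with
    a mean ROC curve on a common grid.
    """
    activities = atlas.activities if isinstance(atlas, ActivityMatrix) else atlas
    exp = expected.copy()
    dir_sign = exp["direction"].map({"up": 1.0, "down": -1.0})
    if dir_sign.isna().any():
        raise ValueError("direction must be 'up' or 'down'")
    exp["sign"] = dir_sign

    present = exp.apply(
        lambda r: r["kinase"] in activities.index
        and r["condition"] in activities.columns
        and np.isfinite(activities.loc[r["kinase"], r["condition"]]),
        axis=1,
    )
    n_dropped = int((~present).sum())
    if n_dropped:
        import warnings

        warnings.warn(
            f"{n_dropped} expected pair(s) absent from the activity matrix", stacklevel=2
        )
    exp = exp[present]
    if exp.empty:
        raise ValueError("no expected pair is present in the activity matrix")

    pos_scores = np.array(
        [
            activities.loc[r["kinase"], r["condition"]] * r["sign"]
            for _, r in exp.iterrows()
        ]
    )

    kinases = sorted(exp["kinase"].unique())
    conditions = sorted(exp["condition"].unique())
    pool = [
        (k, c)
        for k in kinases
        for c in conditions
        if np.isfinite(activities.loc[k, c])
    ]
    if not pool:
        raise ValueError("no non-missing cells available for negative sampling")

    rng = np.random.default_rng(seed)
    signs = exp["sign"].to_numpy()
    n_pos = len(pos_scores)
    aucs = np.empty(n_random)
    fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = np.empty((n_random, len(fpr_grid)))
    for i in range(n_random):
        idx = rng.integers(0, len(pool), size=n_pos)
        neg_signs = rng.choice(signs, size=n_pos, replace=True)
        neg_scores = np.array(
            [activities.loc[pool[j][0], pool[j][1]] for j in idx]
        ) * neg_signs
        aucs[i] = rank_auc(pos_scores, neg_scores)
        scores = np.concatenate([pos_scores, neg_scores])
        is_pos = np.concatenate([np.ones(n_pos, bool), np.zeros(n_pos, bool)])
        order = np.argsort(-scores, kind="stable")
        tp = np.cumsum(is_pos[order]) / n_pos
        fp = np.cumsum(~is_pos[order]) / n_pos
        tprs[i] = np.interp(fpr_grid, fp, tp)
    return {
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std(ddof=1)) if n_random > 1 else 0.0,
        "aucs": aucs,
        "fpr": fpr_grid,
        "tpr_mean": tprs.mean(axis=0),
        "n_positives": n_pos,
        "n_dropped": n_dropped,
    }


def regulatory_site_validation(
    atlas: ActivityMatrix | pd.DataFrame,
    matrix: pd.DataFrame,
    regsites: pd.DataFrame,
    min_shared: int = 10,
    min_regulated_abs: float = 1.0,
) -> pd.DataFrame:
    """Correlate kinase activity profiles with their regulatory-site profiles.

    ``regsites`` needs columns ``kinase, site, autophos_capable``.  Kinases
    whose activity profile never exceeds ``min_regulated_abs`` in absolute
    value are discarded (profiles under no regulation carry no signal), and
    (kinase, site) pairs sharing fewer than ``min_shared`` conditions are
    excluded.  Returns one row per retained pair with Spearman rho, its p,
    the linear-regression slope, and the autophosphorylation group label.
    """
    activities = atlas.activities if isinstance(atlas, ActivityMatrix) else atlas
    rows = []
    for _, r in regsites.iterrows():
        kinase, site = r["kinase"], str(r["site"])
        if kinase not in activities.index or site not in matrix.index:
            continue
        act = activities.loc[kinase]
        if not (act.abs() > min_regulated_abs).any():
            continue
        prof = matrix.loc[site]
        common = [c for c in activities.columns if c in matrix.columns]
        a = act[common]
        q = prof[common]
        ok = a.notna() & q.notna()
        if int(ok.sum()) < min_shared:
            continue
        a, q = a[ok].to_numpy(), q[ok].to_numpy()
        rho, rho_p = stats.spearmanr(a, q)
        fit = stats.linregress(a, q)
        rows.append(
            {
                "kinase": kinase,
                "site": site,
                "n_shared": int(ok.sum()),
                "spearman_rho": float(rho),
                "spearman_p": float(rho_p),
                "slope": float(fit.slope),
                "slope_p": float(fit.pvalue),
                "autophos_capable": bool(r["autophos_capable"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kinase",
            "site",
            "n_shared",
            "spearman_rho",
            "spearman_p",
            "slope",
            "slope_p",
            "autophos_capable",
        ],
    )
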