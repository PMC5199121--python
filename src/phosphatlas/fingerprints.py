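"""Condition fingerprinting and kinase-role analyses.

The kinase-activity profile of a condition acts as a molecular fingerprint
of its signaling state.  This module provides: selection of consistently
inferred kinase profiles, regularized iterative-PCA imputation of the
remaining missing cells, PCA of the completed matrix with component
significance criteria (broken stick, Kaiser–Guttman), condition similarity
networks, Boolean logic relations between kinase pairs, generalist scoring,
and betweenness centrality in the directed kinase–kinase network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ActivityMatrix, call_regulated
from .types import KinaseSubstrateSets

__all__ = [
    "PcaModel",
    "ConditionNetwork",
    "select_profiles",
    "impute_iterative_pca",
    "choose_ncp",
    "pca",
    "broken_stick",
    "component_significance",
    "condition_network",
    "logic_relations",
    "generalist_score",
    "kinase_betweenness",
    "biomarker_signature",
]


def _as_df(activities) -> pd.DataFrame:
    return activities.activities if isinstance(activities, ActivityMatrix) else activities


def select_profiles(
    activities,
    min_coverage: float = 0.75,
    redundancy_r: float = 0.99,
    redundancy_min_shared: int = 20,
) -> pd.DataFrame:
    """Restrict to consistently inferred kinases and non-redundant conditions.

    Kinases inferred in at least ``min_coverage`` of the conditions are
    kept.  Condition pairs with Pearson correlation above ``redundancy_r``
    over at least ``redundancy_min_shared`` shared kinases are considered
    redundant; each group of mutually redundant conditions collapses to its
    best-covered representative.
    """
    df = _as_df(activities)
    coverage = df.notna().mean(axis=1)
    df = df.loc[coverage >= min_coverage]

    # collapse near-duplicate condition columns
    drop: set[str] = set()
    cols = list(df.columns)
    redundant = nx.Graph()
    redundant.add_nodes_from(cols)
    for a, b in itertools.combinations(cols, 2):
        pair = df[[a, b]].dropna()
        if len(pair) < redundancy_min_shared:
            continue
        r = pair[a].corr(pair[b])
        if r is not None and r > redundancy_r:
            redundant.add_edge(a, b)
    for component in nx.connected_components(redundant):
        if len(component) > 1:
            keep = max(component, key=lambda c: (df[c].notna().sum(), c))
            drop |= set(component) - {keep}
    return df.drop(columns=sorted(drop))


def impute_iterative_pca(
    matrix: pd.DataFrame,
    ncp: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Impute missing cells with the regularized iterative PCA algorithm.

    Missing cells start at their column means; the matrix is then
    alternately approximated by a rank-``ncp`` SVD with shrunken singular
    values (shrinkage by the residual variance of the discarded components)
    and the missing cells refilled from the reconstruction, until the
    imputed values change by less than ``tol`` (relative).  Observed cells
    are never altered.
    """
    X = matrix.to_numpy(dtype=float)
    missing = np.isnan(X)
    if not missing.any():
        return matrix.copy()
    if missing.all(axis=0).any():
        raise ValueError("cannot impute a column with no observed values")
    n, p = X.shape
    ncp = int(min(ncp, min(n, p) - 1)) or 1

    col_means = np.nanmean(X, axis=0)
    filled = np.where(missing, col_means[None, :], X)
    prev = filled[missing].copy()
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        Xc = filled - mu
        U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
        sigma2 = float(np.mean(d[ncp:] ** 2)) if len(d) > ncp else 0.0
        shrunk = np.maximum(d[:ncp] ** 2 - sigma2, 0.0) / np.where(d[:ncp] > 0, d[:ncp], 1.0)
        fitted = mu + (U[:, :ncp] * shrunk) @ Vt[:ncp]
        filled[missing] = fitted[missing]
        cur = filled[missing]
        denom = max(float(np.abs(prev).max()), 1e-12)
        if np.abs(cur - prev).max() / denom < tol:
            break
        prev = cur.copy()
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def choose_ncp(
    matrix: pd.DataFrame,
    grid=(1, 2, 3, 4, 5),
    mask_fraction: float = 0.05,
    seed: int = 0,
) -> int:
    """Pick the imputation rank by cross-validated masking error.

    A random ``mask_fraction`` of the observed cells is hidden, each
    candidate rank imputes them, and the rank with the lowest RMSE on the
    hidden cells wins (ties go to the smaller rank).
    """
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    observed = np.argwhere(~np.isnan(X))
    n_mask = max(1, int(len(observed) * mask_fraction))
    chosen = observed[rng.choice(len(observed), size=n_mask, replace=False)]
    truth = X[chosen[:, 0], chosen[:, 1]]
    Xm = X.copy()
    Xm[chosen[:, 0], chosen[:, 1]] = np.nan
    masked = pd.DataFrame(Xm, index=matrix.index, columns=matrix.columns)
    # columns fully hidden by the mask cannot be imputed; restore one cell
    col_ok = masked.notna().any(axis=0)
    if not col_ok.all():
        raise ValueError("mask_fraction too large: a column lost all its values")
    best_rank, best_err = None, np.inf
    for ncp in grid:
        if ncp >= min(matrix.shape):
            continue
        imputed = impute_iterative_pca(masked, ncp=ncp)
        pred = imputed.to_numpy()[chosen[:, 0], chosen[:, 1]]
        err = float(np.sqrt(np.mean((pred - truth) ** 2)))
        if err < best_err:
            best_rank, best_err = ncp, err
    return best_rank


@dataclass
class PcaModel:
    """PCA of condition fingerprints: samples = conditions, variables = kinases."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    n_significant_brokenstick: int
    n_significant_kaiser: int


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expectations b_k = (1/p) * sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def component_significance(eigenvalues: np.ndarray) -> dict:
    """Count significant components by the broken-stick and Kaiser criteria.

    Broken stick (stringent): components are significant while their
    variance proportion exceeds the broken-stick expectation, counted as
    the leading run.  Kaiser–Guttman (relaxed): eigenvalue strictly above
    the mean eigenvalue.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    p = len(ev)
    props = ev / ev.sum()
    bstick = broken_stick(p)
    n_bs = 0
    for k in range(p):
        if props[k] > bstick[k]:
            n_bs += 1
        else:
            break
    n_kaiser = int((ev > ev.mean()).sum())
    return {
        "broken_stick_expectations": bstick,
        "n_brokenstick": n_bs,
        "n_kaiser": n_kaiser,
    }


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PcaModel:
    """SVD-based PCA of a complete condition × kinase matrix.

    Centering is on by default and no variable scaling is applied, so
    kinases with larger activity swings contribute more variance.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete; impute first")
    n = X.shape[0]
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = d**2 / (n - 1)
    props = d**2 / (d**2).sum()
    comp_names = [f"PC{i + 1}" for i in range(len(d))]
    scores = pd.DataFrame(U * d, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names)
    sig = component_significance(eigenvalues)
    return PcaModel(
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_proportions=props,
        n_significant_brokenstick=sig["n_brokenstick"],
        n_significant_kaiser=sig["n_kaiser"],
    )


@dataclass
class ConditionNetwork:
    """Condition similarity network: edges are significant profile correlations."""

    edges: pd.DataFrame
    all_pairs: pd.DataFrame
    fdr: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, e in self.edges.iterrows():
            g.add_edge(e["condition_a"], e["condition_b"], rho=e["rho"], q=e["q"])
        return g


def condition_network(
    activities,
    fdr: float = 0.05,
    min_shared: int = 10,
    method: str = "spearman",
) -> ConditionNetwork:
    """Network of significantly (anti-)correlated condition fingerprints.

    Pairwise correlations over shared non-missing kinases (at least
    ``min_shared``), Benjamini–Hochberg corrected over all tested pairs;
    edges with q below ``fdr`` are retained with their sign.
    """
    df = _as_df(activities)
    rows = []
    for a, b in itertools.combinations(df.columns, 2):
        pair = df[[a, b]].dropna()
        if len(pair) < min_shared:
            continue
        x, y = pair[a].to_numpy(), pair[b].to_numpy()
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {"condition_a": a, "condition_b": b, "n_shared": len(pair),
             "rho": float(rho), "p": float(p)}
        )
    all_pairs = pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "n_shared", "rho", "p"]
    )
    if len(all_pairs):
        all_pairs["q"] = multipletests(all_pairs["p"], method="fdr_bh")[1]
        all_pairs["sign"] = np.sign(all_pairs["rho"]).astype(int)
        edges = all_pairs[all_pairs["q"] < fdr].reset_index(drop=True)
    else:
        all_pairs["q"] = []
        all_pairs["sign"] = []
        edges = all_pairs
    return ConditionNetwork(edges=edges, all_pairs=all_pairs, fdr=fdr)


def logic_relations(
    activities,
    pairs: list[tuple[str, str]],
    reg_threshold: float = 1.75,
    alpha: float = 0.05,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Boolean logic labels for kinase pairs from their regulation patterns.

    Regulation is binarized at ``reg_threshold``.  A Fisher exact test on
    the 2×2 co-regulation table (BH-corrected across pairs) classifies each
    pair: significant positive association (odds ratio > 1) is AND when the
    two activities agree in sign where co-regulated and OR when they
    oppose; significant mutual exclusivity (odds ratio < 1) is NOT;
    anything else is none.
    """
    df = _as_df(activities)
    calls = call_regulated(df, reg_threshold)
    rows = []
    for k1, k2 in pairs:
        both = df.loc[[k1, k2]].T.dropna()
        if len(both) < min_shared:
            rows.append({"kinase_a": k1, "kinase_b": k2, "p": np.nan,
                         "odds_ratio": np.nan, "same_sign_fraction": np.nan,
                         "n_shared": len(both)})
            continue
        r1 = calls.loc[k1, both.index].astype(bool).to_numpy()
        r2 = calls.loc[k2, both.index].astype(bool).to_numpy()
        table = [
            [int((r1 & r2).sum()), int((r1 & ~r2).sum())],
            [int((~r1 & r2).sum()), int((~r1 & ~r2).sum())],
        ]
        odds, p = stats.fisher_exact(table)
        co = r1 & r2
        if co.any():
            same = np.sign(both[k1][co]) == np.sign(both[k2][co])
            same_frac = float(same.mean())
        else:
            same_frac = np.nan
        rows.append({"kinase_a": k1, "kinase_b": k2, "p": float(p),
                     "odds_ratio": float(odds), "same_sign_fraction": same_frac,
                     "n_shared": len(both)})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    labels = []
    for _, r in out.iterrows():
        if not np.isfinite(r["q"]) or r["q"] >= alpha:
            labels.append("none")
        elif r["odds_ratio"] > 1:
            if np.isfinite(r["same_sign_fraction"]) and r["same_sign_fraction"] >= 0.5:
                labels.append("AND")
            else:
                labels.append("OR")
        elif r["odds_ratio"] < 1:
            labels.append("NOT")
        else:
            labels.append("none")
    out["label"] = labels
    return out


def generalist_score(
    activities,
    reg_threshold: float = 1.75,
    sets: KinaseSubstrateSets | None = None,
    min_substrates: int = 0,
) -> pd.Series:
    """Number of conditions in which each kinase is regulated.

    With ``sets`` and ``min_substrates`` given, restrict to kinases with
    more than ``min_substrates`` known substrate sites.
    """
    df = _as_df(activities)
    calls = call_regulated(df, reg_threshold)
    counts = calls.fillna(False).astype(bool).sum(axis=1)
    if sets is not None and min_substrates > 0:
        keep = [k for k in counts.index if len(sets.sets.get(k, ())) > min_substrates]
        counts = counts.loc[keep]
    return counts


def kinase_betweenness(
    sets: KinaseSubstrateSets,
    kinase_protein: dict[str, str] | None = None,
) -> pd.Series:
    """Betweenness centrality in the directed kinase–kinase network.

    An edge runs from kinase A to kinase B when B's protein hosts a
    substrate site of A.  By default the kinase identifier is taken as its
    protein accession; pass ``kinase_protein`` to override.  Self-loops are
    removed; betweenness is the (Brandes) count of shortest paths through
    each node, unnormalized.
    """
    if kinase_protein is None:
        kinase_protein = {k: k for k in sets.sets}
    protein_to_kinase: dict[str, list[str]] = {}
    for k, prot in kinase_protein.items():
        protein_to_kinase.setdefault(prot, []).append(k)

    g = nx.DiGraph()
    g.add_nodes_from(sets.sets)
    for src, sites in sets.sets.items():
        for site in sites:
            for dst in protein_to_kinase.get(site.protein, ()):
                if dst != src:
                    g.add_edge(src, dst)
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc).sort_index()


def biomarker_signature(activities, kinases: list[str]) -> pd.DataFrame:
    """Accumulated activity of a kinase signature per condition.

    Missing activities contribute 0 to the sum; the number of missing
    kinases per condition is reported alongside.
    """
    df = _as_df(activities)
    present = [k for k in kinases if k in df.index]
    sub = df.loc[present]
    total = sub.fillna(0.0).sum(axis=0)
    n_missing = sub.isna().sum(axis=0) + (len(kinases) - len(present))
    return pd.DataFrame({"signature": total, "n_missing": n_missing})
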