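"""Co-regulation discovery: effector complexes and candidate substrates.

Two families of analyses share the kinase-activity atlas as input:

* **Complex phospho-regulation.**  Per condition, the distribution of
  absolute fold changes of the sites on a complex's subunits is compared
  against all quantified sites with a two-sample Kolmogorov–Smirnov test;
  the signed -log10 p (sign from the mean fold change of the complex's
  sites) quantifies coordinated regulation.  Correlating these scores with
  kinase activities across conditions proposes kinase → complex couplings,
  evaluated with a PPV/FDR curve against known substrate annotations.

* **Substrate prediction.**  Candidate sites are scored by motif
  similarity to a position-weight matrix built from known substrate flanks
  (log-weight sum and the information-weighted MATCH matrix similarity
  score, both min–max normalized to [0, 1]) and by co-regulation of the
  site's quantification profile with the kinase activity profile; a
  shortlist applies conjunctive thresholds on the available evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ActivityMatrix
from .types import ComplexCatalog, FlankTable, KinaseSubstrateSets, SiteID

__all__ = [
    "AMINO_ACIDS",
    "MotifModel",
    "ComplexRegulationMatrix",
    "complex_regulation",
    "complex_regulation_matrix",
    "kinase_complex_association",
    "ppv_fdr_curve",
    "build_pwm",
    "score_logweights",
    "score_mss",
    "site_coregulation",
    "predict_substrates",
    "shortlist_targets",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"


def _as_df(activities) -> pd.DataFrame:
    return activities.activities if isinstance(activities, ActivityMatrix) else activities


# ---------------------------------------------------------------------------
# complex regulation


def complex_regulation(
    values: pd.Series,
    complex_sites: set,
    min_sites: int = 3,
    background: str = "all",
) -> float:
    """Signed -log10 KS p for coordinated regulation of a complex's sites.

    ``values`` maps site token → log2 ratio for one condition (quantified
    sites only).  The absolute fold changes of the complex's quantified
    sites are compared against the background distribution ("all" sites,
    or the "complement" excluding the complex) with a two-sided two-sample
    KS test; the sign is that of the complex sites' mean signed change.
    Returns NaN when fewer than ``min_sites`` complex sites are quantified.
    """
    tokens = {str(s) for s in complex_sites}
    in_complex = values.index.isin(tokens)
    n_in = int(in_complex.sum())
    if n_in < min_sites or n_in == len(values):
        return float("nan")
    fg = values[in_complex].to_numpy(dtype=float)
    if background == "all":
        bg = values.to_numpy(dtype=float)
    elif background == "complement":
        bg = values[~in_complex].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown background {background!r}")
    p = stats.ks_2samp(np.abs(fg), np.abs(bg), alternative="two-sided").pvalue
    p = max(p, 1e-300)
    sign = 1.0 if fg.mean() > 0 else (-1.0 if fg.mean() < 0 else 0.0)
    return sign * (-math.log10(p))


@dataclass
class ComplexRegulationMatrix:
    """Complex × condition signed log10 KS p-values with per-cell site counts."""

    scores: pd.DataFrame
    n_sites: pd.DataFrame
    min_sites: int = 3


def complex_sites_map(
    matrix_index, catalog: ComplexCatalog
) -> dict[str, set[str]]:
    """Map complex id → matrix site tokens hosted on its subunit proteins."""
    by_protein: dict[str, set[str]] = {}
    for token in matrix_index:
        protein = SiteID.parse(token).protein
        by_protein.setdefault(protein, set()).add(token)
    return {
        cid: set().union(*(by_protein.get(p, set()) for p in subunits))
        for cid, subunits in catalog.complexes.items()
    }


def complex_regulation_matrix(
    matrix: pd.DataFrame,
    catalog: ComplexCatalog,
    min_sites: int = 3,
    background: str = "all",
    exclude_sites: set | None = None,
) -> ComplexRegulationMatrix:
    """Complex regulation scores for every (complex, condition) cell.

    ``exclude_sites`` (site tokens) are removed from the complex foreground
    — used to drop a kinase's training substrates when validating
    kinase–complex associations.
    """
    excl = {str(s) for s in exclude_sites} if exclude_sites else set()
    sites_by_complex = complex_sites_map(matrix.index, catalog)
    if excl:
        sites_by_complex = {c: s - excl for c, s in sites_by_complex.items()}
    complexes = sorted(catalog.complexes)
    scores = pd.DataFrame(np.nan, index=complexes, columns=matrix.columns)
    counts = pd.DataFrame(0, index=complexes, columns=matrix.columns, dtype=int)
    for condition in matrix.columns:
        col = matrix[condition].dropna()
        if col.empty:
            continue
        for cid in complexes:
            cs = sites_by_complex[cid]
            n_in = int(col.index.isin(cs).sum())
            counts.loc[cid, condition] = n_in
            scores.loc[cid, condition] = complex_regulation(
                col, cs, min_sites=min_sites, background=background
            )
    return ComplexRegulationMatrix(scores, counts, min_sites)


def kinase_complex_association(
    activities,
    matrix: pd.DataFrame,
    catalog: ComplexCatalog,
    sets: KinaseSubstrateSets | None = None,
    exclude_kinase_substrates: bool = True,
    min_shared: int = 10,
    min_sites: int = 3,
    background: str = "all",
) -> pd.DataFrame:
    """Correlate kinase activities with complex regulation across conditions.

    For each (kinase, complex) pair sharing at least ``min_shared``
    conditions, a linear fit of the complex score on the kinase activity
    yields Pearson r and its p-value; p-values are BH-corrected over all
    scored pairs.  With ``exclude_kinase_substrates`` (needs ``sets``) the
    kinase's own training substrates are removed from the complex score
    before correlating, so known edges cannot trivially validate
    themselves.  Only complexes whose score actually depends on the
    removed sites are recomputed.
    """
    acts = _as_df(activities)
    base = complex_regulation_matrix(
        matrix, catalog, min_sites=min_sites, background=background
    )
    sites_by_complex = complex_sites_map(matrix.index, catalog)
    rows = []
    for kinase in acts.index:
        act = acts.loc[kinase].dropna()
        if len(act) < min_shared:
            continue
        scores = base.scores
        if exclude_kinase_substrates and sets is not None and kinase in sets.sets:
            sub_tokens = {str(s) for s in sets.sets[kinase]}
            touched = {
                cid for cid, cs in sites_by_complex.items() if cs & sub_tokens
            }
            if touched:
                redone = complex_regulation_matrix(
                    matrix,
                    ComplexCatalog(
                        {c: catalog.complexes[c] for c in touched},
                        {c: catalog.names.get(c, c) for c in touched},
                    ),
                    min_sites=min_sites,
                    background=background,
                    exclude_sites=sub_tokens,
                ).scores
                scores = scores.copy()
                scores.loc[redone.index] = redone
        for cid in scores.index:
            prof = scores.loc[cid].dropna()
            shared = act.index.intersection(prof.index)
            if len(shared) < min_shared:
                continue
            r, p = stats.pearsonr(act[shared], prof[shared])
            rows.append(
                {"kinase": kinase, "complex": cid, "n_shared": len(shared),
                 "r": float(r), "p": float(p)}
            )
    out = pd.DataFrame(rows, columns=["kinase", "complex", "n_shared", "r", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out


def ppv_fdr_curve(
    associations: pd.DataFrame,
    truth: set[tuple[str, str]],
    fdr_grid=None,
) -> pd.DataFrame:
    """Positive predictive value against the FDR threshold.

    ``associations`` must carry ``kinase, complex, q``; ``truth`` holds the
    (kinase, complex) pairs with at least one known substrate subunit.
    For each threshold t, predictions are the pairs with q <= t and
    PPV is the fraction that are true.  The ``baseline`` column is the
    prevalence of true pairs among all scored pairs — the PPV of a random
    predictor.
    """
    df = associations.sort_values("q", kind="stable").reset_index(drop=True)
    is_true = np.array(
        [(k, c) in truth for k, c in zip(df["kinase"], df["complex"])]
    )
    baseline = float(is_true.mean()) if len(df) else float("nan")
    if fdr_grid is None:
        fdr_grid = np.unique(df["q"].to_numpy())
    rows = []
    cum_true = np.cumsum(is_true)
    qs = df["q"].to_numpy()
    for t in fdr_grid:
        n_pred = int(np.searchsorted(qs, t, side="right"))
        if n_pred == 0:
            continue
        rows.append(
            {"fdr": float(t), "n_predictions": n_pred,
             "ppv": float(cum_true[n_pred - 1] / n_pred), "baseline": baseline}
        )
    return pd.DataFrame(rows, columns=["fdr", "n_predictions", "ppv", "baseline"])


# ---------------------------------------------------------------------------
# motif scoring


@dataclass
class MotifModel:
    """Position frequency matrix over a flank window with information vector.

    ``freq`` is positions (-w..w) × 20 amino acids, each row summing to 1;
    ``info[i] = sum_b f(i,b) * ln(20 * f(i,b))`` is the information content
    used by the MATCH matrix similarity score (alphabet size 20).
    """

    freq: pd.DataFrame
    info: pd.Series
    window: int
    pseudocount: float
    n_sequences: int

    def position_range(self) -> list[int]:
        return list(range(-self.window, self.window + 1))


def build_pwm(
    flanks: list[str],
    w: int = 7,
    pseudocount: float = 0.05 / 20,
) -> MotifModel:
    """Build a PWM from substrate flanking sequences.

    Flanks must have length 2w+1; padding characters are excluded from the
    counts (the remaining mass is renormalized).  ``pseudocount`` is added
    to every cell before normalization.
    """
    if not flanks:
        raise ValueError("need at least one flank sequence")
    length = 2 * w + 1
    for f in flanks:
        if len(f) != length:
            raise ValueError(f"flank {f!r} does not match window {w}")
    positions = list(range(-w, w + 1))
    counts = pd.DataFrame(0.0, index=positions, columns=list(AMINO_ACIDS))
    for f in flanks:
        for pos, aa in zip(positions, f):
            if aa == PAD:
                continue
            if aa not in counts.columns:
                raise ValueError(f"unknown residue {aa!r} in flank {f!r}")
            counts.loc[pos, aa] += 1.0
    counts += pseudocount
    totals = counts.sum(axis=1)
    # a position with no observed residues (all padding, zero pseudocount)
    # is uninformative: fall back to the uniform distribution
    uniform = 1.0 / len(AMINO_ACIDS)
    freq = counts.div(totals.where(totals > 0, 1.0), axis=0)
    freq[totals == 0] = uniform
    f = freq.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(20.0 * f), 0.0)  # 0*ln0 := 0
    info = pd.Series(terms.sum(axis=1), index=freq.index)
    return MotifModel(
        freq=freq,
        info=info,
        window=w,
        pseudocount=pseudocount,
        n_sequences=len(flanks),
    )


def _scored_positions(flank: str, pwm: MotifModel, exclude_center: bool):
    positions = pwm.position_range()
    for pos, aa in zip(positions, flank):
        if aa == PAD:
            continue
        if exclude_center and pos == 0:
            continue
        yield pos, aa


def score_logweights(flank: str, pwm: MotifModel, exclude_center: bool = True) -> float:
    """Sum of log frequencies of the matched residues, min–max normalized.

    The raw score sum_i ln f(i, b_i) is mapped to [0, 1] using the
    per-position minimum and maximum log frequencies over the positions
    actually scored (padding and, by default, the fixed central
    phosphoacceptor are skipped), so 1 is the consensus sequence and 0 the
    per-position worst match.
    """
    raw = lo = hi = 0.0
    with np.errstate(divide="ignore"):
        logf = np.log(pwm.freq)
    for pos, aa in _scored_positions(flank, pwm, exclude_center):
        raw += logf.loc[pos, aa]
        lo += logf.loc[pos].min()
        hi += logf.loc[pos].max()
    if hi == lo:
        return 0.0
    return float((raw - lo) / (hi - lo))


def score_mss(flank: str, pwm: MotifModel, exclude_center: bool = True) -> float:
    """MATCH matrix similarity score in [0, 1].

    Current = sum_i I(i) * f(i, b_i); min–max normalized with
    Min/Max = sum_i I(i) * min_b/max_b f(i, b).  A uniform PWM (Max = Min)
    scores 0 by convention.
    """
    cur = lo = hi = 0.0
    for pos, aa in _scored_positions(flank, pwm, exclude_center):
        info = pwm.info.loc[pos]
        cur += info * pwm.freq.loc[pos, aa]
        lo += info * pwm.freq.loc[pos].min()
        hi += info * pwm.freq.loc[pos].max()
    if hi == lo:
        return 0.0
    return float((cur - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# substrate co-regulation and shortlisting


def site_coregulation(
    site_profile: pd.Series,
    activity_profile: pd.Series,
    min_shared: int = 10,
) -> tuple[float, float, int]:
    """Pearson correlation between a site's profile and a kinase activity profile.

    Returns (r, p, n_shared); (nan, nan, n) when fewer than ``min_shared``
    conditions are shared.
    """
    shared = site_profile.dropna().index.intersection(
        activity_profile.dropna().index
    )
    n = len(shared)
    if n < min_shared:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(site_profile[shared], activity_profile[shared])
    return float(r), float(p), n


def predict_substrates(
    kinase: str,
    activities,
    matrix: pd.DataFrame,
    flanks: FlankTable,
    sets: KinaseSubstrateSets,
    min_shared: int = 10,
    pseudocount: float = 0.05 / 20,
    exclude_center: bool = True,
    inhibition: pd.Series | None = None,
    in_vitro: set | None = None,
) -> pd.DataFrame:
    """Score every candidate site in the matrix as a potential kinase substrate.

    Known training substrates of the kinase are excluded.  Each candidate
    gets motif scores (normalized log-weights and MSS against the PWM built
    from the kinase's known substrate flanks), co-regulation r/p with the
    kinase activity profile, and optional inhibition-response and in-vitro
    evidence columns.
    """
    acts = _as_df(activities)
    if kinase not in acts.index:
        raise KeyError(f"kinase {kinase!r} not in the activity matrix")
    known = sets.sets.get(kinase, set())
    known_tokens = {str(s) for s in known}
    training_flanks = [
        flanks.flanks[s] for s in known if s in flanks.flanks
    ]
    if not training_flanks:
        raise ValueError(f"no flanks available for the known substrates of {kinase}")
    pwm = build_pwm(training_flanks, w=flanks.window, pseudocount=pseudocount)
    act = acts.loc[kinase]
    flank_by_token = {str(s): f for s, f in flanks.flanks.items()}
    rows = []
    for token in matrix.index:
        if token in known_tokens:
            continue
        flank = flank_by_token.get(token)
        if flank is None:
            continue
        r, p, n = site_coregulation(matrix.loc[token], act, min_shared=min_shared)
        row = {
            "site": token,
            "logweights": score_logweights(flank, pwm, exclude_center),
            "mss": score_mss(flank, pwm, exclude_center),
            "coregulation_r": r,
            "coregulation_p": p,
            "n_shared": n,
        }
        if inhibition is not None:
            row["inhibition_log2"] = float(inhibition.get(token, np.nan))
        if in_vitro is not None:
            row["in_vitro"] = token in {str(s) for s in in_vitro}
        rows.append(row)
    return pd.DataFrame(rows)


def shortlist_targets(
    predictions: pd.DataFrame,
    coreg_p_max: float | None = 0.01,
    logweights_min: float | None = 0.8,
    mss_min: float | None = 0.6,
    inhibition_max: float | None = None,
    require_in_vitro: bool = False,
) -> pd.DataFrame:
    """Conjunctive shortlist of high-confidence substrate predictions.

    Each filter is optional (pass ``None`` to disable): positive
    co-regulation with p below ``coreg_p_max``, normalized log-weights and
    MSS above their thresholds, inhibition response below
    ``inhibition_max`` (e.g. -0.9 for strong down-regulation on kinase
    inhibition), and an in-vitro evidence flag.
    """
    keep = pd.Series(True, index=predictions.index)
    if coreg_p_max is not None:
        keep &= (predictions["coregulation_p"] < coreg_p_max) & (
            predictions["coregulation_r"] > 0
        )
    if logweights_min is not None:
        keep &= predictions["logweights"] > logweights_min
    if mss_min is not None:
        keep &= predictions["mss"] > mss_min
    if inhibition_max is not None:
        keep &= predictions["inhibition_log2"] < inhibition_max
    if require_in_vitro:
        keep &= predictions["in_vitro"].fillna(False).astype(bool)
    return predictions[keep.fillna(False)].reset_index(drop=True)
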