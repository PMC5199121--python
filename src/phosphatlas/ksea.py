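"""Weighted kinase-set enrichment analysis (KSEA) with a permutation null.

The enrichment score (ES) is a weighted Kolmogorov–Smirnov-like running-sum
statistic: sites are ranked by their log2 fold change (descending) and a
running sum is walked down the list, increasing at known substrate sites
and decreasing elsewhere.  Both increments and decrements are proportional
to the absolute fold change of the site and normalized so that hits and
misses each sum to one, which keeps the path in [-1, 1] and forces it back
to zero at the end.  The ES is the maximum deviation from zero (either
sign) encountered along the walk.

Significance is assessed against a permutation null obtained by drawing
random substrate sets of the same size from the same quantification vector
(values fixed, labels randomized).  The empirical p-value is two-sided on
|ES| with an add-one correction; the reported activity is

    activity = sign(mean fold change of quantified substrates) * (-log10 p)

so a kinase whose substrates are predominantly up-regulated scores
positive ("activated") and |activity| is capped at log10(n_perm + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from zlib import crc32

import numpy as np

__all__ = [
    "ConditionVector",
    "KseaResult",
    "KseaNotComputable",
    "enrichment_score",
    "permutation_null",
    "empirical_pvalue",
    "ksea_activity",
    "exact_pvalue",
    "child_rng",
]


class KseaNotComputable(ValueError):
    """The enrichment score is undefined for this vector/substrate pair.

    Raised when no substrate is quantified, when every quantified site is a
    substrate, or when all substrate values are exactly zero.  Distinct from
    a non-significant result (p = 1).
    """


@dataclass
class ConditionVector:
    """Quantified sites of one condition with their (finite) log2 ratios."""

    sites: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sites) != len(self.values):
            raise ValueError("sites and values must have equal length")
        if len(self.values) == 0:
            raise ValueError("condition vector must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite (subset to quantified sites)")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class KseaResult:
    """One KSEA test: enrichment score, empirical p, and signed activity."""

    es: float
    p: float
    n_perm: int
    sign: int
    activity: float
    n_hits: int
    degenerate_sign: bool = False


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """Deterministic per-key RNG stream derived from a master seed.

    Streams for distinct (kinase, condition) keys are independent, so
    matrix computations are reproducible regardless of evaluation order.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    entropy += [crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _sorted_walk_order(values: np.ndarray, site_labels) -> np.ndarray:
    """Indices sorting values descending; ties broken by ascending site label."""
    labels = np.asarray([str(s) for s in site_labels])
    return np.lexsort((labels, -values))


def _walk_es(w: np.ndarray, hit_mask: np.ndarray, classic_misses: bool = False) -> float:
    """Running-sum ES for |values| ``w`` already in walk order."""
    hit_total = float(w[hit_mask].sum())
    if hit_total == 0.0:
        raise KseaNotComputable("all substrate values are zero")
    inc = np.where(hit_mask, w / hit_total, 0.0)
    if classic_misses:
        n_miss = int((~hit_mask).sum())
        dec = np.where(~hit_mask, 1.0 / n_miss, 0.0)
    else:
        miss_total = float(w[~hit_mask].sum())
        dec = np.where(~hit_mask, w / miss_total if miss_total > 0 else 0.0, 0.0)
    path = np.cumsum(inc - dec)
    return float(path[np.argmax(np.abs(path))])


def enrichment_score(
    vector: ConditionVector,
    substrates: set,
    classic_misses: bool = False,
) -> float:
    """Enrichment score of a substrate set within a ranked condition vector.

    Raises :class:`KseaNotComputable` when the substrate set does not
    intersect the vector, covers it completely, or carries only zeros.
    """
    subs = {str(s) for s in substrates}
    labels = [str(s) for s in vector.sites]
    hit_mask = np.array([s in subs for s in labels], dtype=bool)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise KseaNotComputable("no quantified substrate in the condition vector")
    if n_hits == len(vector):
        raise KseaNotComputable("every quantified site is a substrate")
    order = _sorted_walk_order(vector.values, labels)
    w = np.abs(vector.values[order])
    return _walk_es(w, hit_mask[order], classic_misses=classic_misses)


def _null_es_from_positions(
    w: np.ndarray,
    hits: np.ndarray,
    classic_misses: bool = False,
) -> np.ndarray:
    """ES for many substrate placements given by sorted rank positions.

    ``w`` holds |values| in walk order; ``hits`` is (n_perm, m) of 0-based
    rank positions, sorted ascending within each row.  Path extremes can
    only occur at a hit (local max) or just before one (local min), so the
    ES is computed from those candidates without materializing full paths.
    """
    n = len(w)
    n_perm, m = hits.shape
    cum_all = np.concatenate([[0.0], np.cumsum(w)])  # cum_all[i] = sum w[:i]
    wh = w[hits]
    cum_hit = np.cumsum(wh, axis=1)
    hit_total = cum_hit[:, -1:]
    if classic_misses:
        miss_denom = float(n - m)
        # misses up to and including rank h_j: (h_j + 1) - (j + 1)
        j = np.arange(m)
        miss_at = (hits - j) / miss_denom
        miss_pre = (hits - j) / miss_denom
    else:
        miss_total = cum_all[-1] - hit_total
        safe = np.where(miss_total > 0, miss_total, 1.0)
        miss_at = (cum_all[hits + 1] - cum_hit) / safe
        miss_pre = (cum_all[hits] - (cum_hit - wh)) / safe
    with np.errstate(invalid="ignore", divide="ignore"):
        r_at = cum_hit / hit_total - miss_at
        r_pre = (cum_hit - wh) / hit_total - miss_pre
    # interleave in walk order: pre_1, at_1, pre_2, at_2, ...
    cand = np.empty((n_perm, 2 * m))
    cand[:, 0::2] = r_pre
    cand[:, 1::2] = r_at
    idx = np.argmax(np.abs(cand), axis=1)
    es = cand[np.arange(n_perm), idx]
    # rows whose sampled substrate weights are all zero are undefined; the
    # convention here scores them 0 (they cannot beat any finite |ES|)
    es = np.where(hit_total[:, 0] == 0.0, 0.0, es)
    return es


def _sample_hit_positions(
    rng: np.random.Generator, n: int, m: int, n_perm: int
) -> np.ndarray:
    """(n_perm, m) random distinct rank positions per row, sorted ascending."""
    if m / n > 0.25 or n <= 64:
        keys = rng.random((n_perm, n))
        hits = np.argpartition(keys, m - 1, axis=1)[:, :m] if m < n else np.tile(
            np.arange(n), (n_perm, 1)
        )
        hits.sort(axis=1)
        return hits
    # rejection sampling: redraw rows containing duplicates (cheap for m << n)
    hits = np.sort(rng.integers(0, n, size=(n_perm, m)), axis=1)
    bad = (np.diff(hits, axis=1) == 0).any(axis=1)
    while bad.any():
        hits[bad] = np.sort(rng.integers(0, n, size=(int(bad.sum()), m)), axis=1)
        bad = (np.diff(hits, axis=1) == 0).any(axis=1)
    return hits


def permutation_null(
    vector: ConditionVector,
    n_substrates: int,
    n_perm: int,
    seed=None,
    rng: np.random.Generator | None = None,
    classic_misses: bool = False,
) -> np.ndarray:
    """Null ES distribution from random substrate placements.

    Each permutation draws a uniformly random subset of ``n_substrates``
    sites as pseudo-substrates while keeping the quantifications fixed,
    preserving the value distribution of the observed vector.
    """
    n = len(vector)
    if not 1 <= n_substrates < n:
        raise ValueError(f"n_substrates must be in [1, {n - 1}], got {n_substrates}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = _sorted_walk_order(vector.values, vector.sites)
    w = np.abs(vector.values[order])
    # sample site subsets (not rank positions): under matched seeds the same
    # pseudo-substrate sets are drawn for v and -v, so ES antisymmetry makes
    # the null |ES| samples coincide exactly
    site_subsets = _sample_hit_positions(rng, n, n_substrates, n_perm)
    rank_of = np.empty(n, dtype=np.intp)
    rank_of[order] = np.arange(n)
    hits = np.sort(rank_of[site_subsets], axis=1)
    return _null_es_from_positions(w, hits, classic_misses=classic_misses)


def empirical_pvalue(observed: float, null: np.ndarray) -> float:
    """Two-sided empirical p on |ES| with add-one correction.

    p = (1 + #{|null ES| >= |observed ES|}) / (n_perm + 1), so p is never 0
    and never exceeds 1.
    """
    null = np.asarray(null, dtype=float)
    obs = abs(float(observed))
    tol = 1e-12 * max(1.0, obs)
    exceed = int((np.abs(null) >= obs - tol).sum())
    return (1 + exceed) / (len(null) + 1)


def ksea_activity(
    vector: ConditionVector,
    substrates: set,
    n_perm: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    classic_misses: bool = False,
) -> KseaResult:
    """Full KSEA test: ES, permutation p, and signed -log10 p activity.

    The direction is the sign of the mean fold change over quantified
    substrates: positive means the kinase is predicted activated.  A mean
    of exactly zero yields activity 0 with ``degenerate_sign`` set.
    """
    subs = {str(s) for s in substrates}
    labels = [str(s) for s in vector.sites]
    hit_mask = np.array([s in subs for s in labels], dtype=bool)
    n_hits = int(hit_mask.sum())
    es = enrichment_score(vector, substrates, classic_misses=classic_misses)
    null = permutation_null(
        vector, n_hits, n_perm, seed=seed, rng=rng, classic_misses=classic_misses
    )
    p = empirical_pvalue(es, null)
    mean_sub = float(vector.values[hit_mask].mean())
    if mean_sub > 0:
        sign, degenerate = 1, False
    elif mean_sub < 0:
        sign, degenerate = -1, False
    else:
        sign, degenerate = 0, True
    activity = sign * (-math.log10(p))
    return KseaResult(
        es=es,
        p=p,
        n_perm=n_perm,
        sign=sign,
        activity=activity,
        n_hits=n_hits,
        degenerate_sign=degenerate,
    )


def exact_pvalue(
    vector: ConditionVector,
    substrates: set,
    classic_misses: bool = False,
) -> float:
    """Exact p by exhaustive enumeration of all substrate placements.

    Intended as a small-instance oracle (C(N, m) placements are enumerated,
    so keep N <= ~12).  p is the fraction of placements whose |ES| is at
    least the observed |ES|; the observed placement is one of them, so
    p >= 1/C(N, m) and the Monte-Carlo estimator converges to this value.
    """
    n = len(vector)
    obs = abs(
        enrichment_score(vector, substrates, classic_misses=classic_misses)
    )
    subs = {str(s) for s in substrates}
    m = sum(1 for s in vector.sites if str(s) in subs)
    order = _sorted_walk_order(vector.values, vector.sites)
    w = np.abs(vector.values[order])
    placements = np.array(
        list(itertools.combinations(range(n), m)), dtype=np.intp
    )
    null = _null_es_from_positions(w, placements, classic_misses=classic_misses)
    tol = 1e-12 * max(1.0, obs)
    return float((np.abs(null) >= obs - tol).sum() / len(placements))
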