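"""Shared statistical operations.

One-way ANOVA across phases, Mann-Whitney U (exact small-sample null by full
enumeration, tie-corrected normal approximation otherwise), Benjamini-
Hochberg adjustment, and preranked gene-set enrichment with a gene-label
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MW_MAX_N = 8


def one_way_anova(groups: list[np.ndarray] | dict) -> tuple[float, float]:
    """One-way ANOVA F and p across >= 2 groups of observations.

    Zero total variance (all observations identical) is defined as
    F = 0, p = 1 rather than the indeterminate 0/0.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 observations per group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance
        return float("inf"), 0.0
    return float(f), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x vs y via midranks (ties allowed)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null by full enumeration of all C(n1+n2, n1) group assignments of
    the pooled values when both groups have <= 8 observations (correct under
    ties); tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    u_obs = _u_statistic(x, y)
    if n1 <= EXACT_MW_MAX_N and n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = n1 * n2 / 2
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        offset = n1 * (n1 + 1) / 2
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return u_obs, count / total
    _, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                            method="asymptotic")
    return u_obs, float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------- GSEA

@dataclass
class GSEAResult:
    gene_set: str
    es: float
    nes: float
    pval: float
    fdr: float | None
    size: int
    n_perm: int


def _enrichment_score(order_scores: np.ndarray, hit_mask: np.ndarray,
                      weight_p: float = 1.0) -> float:
    """Signed maximum deviation of the GSEA running sum.

    ``order_scores``: scores sorted in decreasing order; ``hit_mask``:
    boolean, True where the ranked gene belongs to the set. Hits increment
    by |score|^p / sum_hits |score|^p, misses decrement by 1/(N - m).
    """
    n = len(order_scores)
    m = int(hit_mask.sum())
    if m == 0 or m >= n:
        raise ValueError("gene set must be a non-empty strict subset of the "
                         "ranked universe")
    weights = np.abs(order_scores) ** weight_p
    hit_w = np.where(hit_mask, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores are zero: fall back to equal weights
        hit_w = hit_mask.astype(float)
        denom = float(m)
    step = hit_w / denom - (~hit_mask) / (n - m)
    running = np.cumsum(step)
    hi, lo = float(running.max()), float(running.min())
    return hi if hi >= -lo - 1e-12 else lo  # exact ties resolve positive


def _perm_es_max(sorted_weights: np.ndarray, hit_pos: np.ndarray,
                 n: int) -> float:
    """ES for hits at (sorted) ranked positions ``hit_pos``.

    Uses the fact that the running sum is piecewise decreasing between hits,
    so its extrema occur immediately after a hit (candidate maxima) or just
    before one (candidate minima).
    """
    m = len(hit_pos)
    w = sorted_weights[hit_pos]
    denom = w.sum()
    if denom == 0:
        w = np.ones(m)
        denom = float(m)
    cum_hit = np.cumsum(w) / denom
    miss_dec = 1.0 / (n - m)
    i = np.arange(m)
    # misses strictly before hit k: hit_pos[k] - k
    at_hit = cum_hit - (hit_pos - i) * miss_dec
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - (hit_pos - i) * miss_dec
    # the final value (rank N) is 0 by construction and never the extremum
    lo = float(before_hit.min())
    hi = float(at_hit.max())
    return hi if hi >= -lo - 1e-12 else lo


def gsea_preranked(scores: pd.Series, gene_set, n_perm: int = 10_000,
                   weight_p: float = 1.0, seed: int | np.random.Generator = 0,
                   gene_set_name: str = "set") -> GSEAResult:
    """Preranked GSEA with a gene-label permutation null.

    ``scores`` maps gene -> ranking score; genes are ordered by decreasing
    score (ties broken by gene id for determinism). NES = ES divided by the
    mean |permuted ES| of matching sign; nominal p is the one-sided
    permutation tail with the +1 correction. When the universe is small
    enough that all C(N, m) gene-label placements fit within ``n_perm``,
    the null is enumerated exhaustively instead of sampled.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = gene_set - set(scores.index)
    in_set = gene_set & set(scores.index)
    if not in_set:
        raise ValueError("gene set has no members in the ranked universe")
    if missing:
        gene_set = in_set
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    ordered = scores.loc[order]
    order_scores = ordered.to_numpy(dtype=float)
    hit_mask = np.array([g in gene_set for g in order], dtype=bool)
    es = _enrichment_score(order_scores, hit_mask, weight_p)

    n = len(order)
    m = int(hit_mask.sum())
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    weights = np.abs(order_scores) ** weight_p
    from math import comb
    if comb(n, m) <= n_perm:  # exact null by full enumeration
        all_pos = [np.array(c) for c in combinations(range(n), m)]
        perm_es = np.array([_perm_es_max(weights, pos, n)
                            for pos in all_pos])
        n_perm = len(perm_es)
    else:
        perm_es = np.empty(n_perm)
        for k in range(n_perm):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            perm_es[k] = _perm_es_max(weights, pos, n)
    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same:
        nes = es / np.abs(perm_es[same_sign]).mean()
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es) - 1e-12).sum())) \
            / (1 + n_same)
    else:  # no null ES of matching sign: the tail is uninformative
        nes = 0.0
        p = 1.0
    return GSEAResult(gene_set=gene_set_name, es=es, nes=float(nes),
                      pval=float(p), fdr=None, size=m, n_perm=n_perm)


def gsea_batch(scores: pd.Series, gene_sets: dict, n_perm: int = 10_000,
               weight_p: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Run preranked GSEA per gene set; BH-adjust nominal p across sets."""
    rng = np.random.default_rng(seed)
    results = [
        gsea_preranked(scores, genes, n_perm=n_perm, weight_p=weight_p,
                       seed=rng, gene_set_name=name)
        for name, genes in gene_sets.items()
    ]
    df = pd.DataFrame({
        "gene_set": [r.gene_set for r in results],
        "size": [r.size for r in results],
        "es": [r.es for r in results],
        "nes": [r.nes for r in results],
        "pval": [r.pval for r in results],
    })
    df["fdr"] = bh_fdr(df["pval"].to_numpy())
    df["n_perm"] = n_perm
    return df
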