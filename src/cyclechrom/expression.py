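"""Nascent-RNA repression statistics and the RA-differentiation analysis.

Covers promoter-proximal nascent RPM, group box statistics with Mann-Whitney
comparisons, MA up/down fractions, the differential-expression filter
(|FC| > 2, FDR < 0.05, union over contrasts), TMM between-sample
normalization, expression relative to the per-gene geometric mean,
correlation-distance average-linkage clustering into the major response
clusters, and preranked GSEA (see :mod:`cyclechrom.stats`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import ExpressionMatrix
from .stats import mann_whitney

logger = logging.getLogger(__name__)

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def nascent_rpm(matrix: ExpressionMatrix,
                library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per million library reads, per gene and sample.

    The count matrix holds promoter-proximal window counts (TSS..+3 kb in
    gene orientation), so RPM here is the per-gene window count scaled per
    million reads of the sample library.
    """
    libs = matrix.library_sizes if library_sizes is None else library_sizes
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return matrix.counts * 1e6 / libs


def group_boxstats(groups: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box statistics per group plus pairwise two-sided Mann-Whitney p.

    Quartiles use linear interpolation between order statistics; whiskers
    are the most extreme values within 1.5x the interquartile range.
    Returns (per-group stats, pairwise p-value matrix).
    """
    rows = {}
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {label!r}")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        rows[label] = {
            "n": v.size, "median": med, "q1": q1, "q3": q3,
            "whisker_lo": in_lo.min() if in_lo.size else np.nan,
            "whisker_hi": in_hi.max() if in_hi.size else np.nan,
        }
    stats_df = pd.DataFrame(rows).T
    labels = list(groups)
    pmat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            _, p = mann_whitney(groups[a], groups[b])
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return stats_df, pmat


def ma_stats(rpm_a: pd.Series, rpm_b: pd.Series, threshold: float = 1.2,
             pseudocount: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """MA statistics of a (e.g. G1) over b (e.g. G2) plus up/down fractions.

    up = FC > threshold, down = FC < 1/threshold, both strict; fractions are
    percentages of the genes supplied.
    """
    b = rpm_b.reindex(rpm_a.index)
    la = np.log2(rpm_a + pseudocount)
    lb = np.log2(b + pseudocount)
    fc = (rpm_a + pseudocount) / (b + pseudocount)
    per_gene = pd.DataFrame({
        "log2fc": la - lb,
        "mean_abundance": 0.5 * (la + lb),
    })
    # strict inequalities, compared on the fold-change scale so a gene at
    # exactly the threshold is excluded
    n = len(per_gene)
    up = int((fc > threshold).sum())
    down = int((fc < 1.0 / threshold).sum())
    summary = {
        "n": n,
        "pct_up": 100.0 * up / n if n else 0.0,
        "pct_down": 100.0 * down / n if n else 0.0,
    }
    return per_gene, summary


def select_de_genes(de_table: pd.DataFrame, fc_cutoff: float = 2.0,
                    fdr_cutoff: float = 0.05,
                    contrasts=None) -> set[str]:
    """Union over contrasts of genes with |FC| > fc_cutoff and
    FDR < fdr_cutoff (both strict; a gene at exactly FC = 2 or FDR = 0.05
    is excluded)."""
    df = de_table
    if contrasts is not None:
        df = df[df["contrast"].isin(set(contrasts))]
    log2_cut = np.log2(fc_cutoff)
    hit = (df["log2fc"].abs() > log2_cut) & (df["fdr"] < fdr_cutoff)
    return set(df.loc[hit, "gene_id"])


# --------------------------------------------------------------------- TMM

def _quantile75(counts: np.ndarray, lib: float) -> float:
    return float(np.percentile(counts, 75)) / lib


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abundance_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample is the library whose 75th-percentile count (scaled
    by library size) is closest to the mean of those quantiles. For each
    sample, M (log ratio) and A (log abundance) values over genes positive
    in both libraries are trimmed two-sided (30% of M, 5% of A) and the
    factor is the weighted mean of the remaining M values with inverse
    asymptotic (delta-method binomial) variances as weights. Factors are
    rescaled so their geometric mean is 1; they multiply library sizes.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if (libs == 0).any():
        bad = counts.columns[np.flatnonzero(libs == 0)[0]]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    f75 = np.array([_quantile75(mat[:, j], libs[j])
                    for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_j:
            continue
        factors[j] = _tmm_pair(mat[:, j], mat[:, ref_j], libs[j], libs[ref_j],
                               logratio_trim, abundance_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abundance_trim: float) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalized(counts: pd.DataFrame,
                   factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million effective library (library size x TMM factor)."""
    if factors is None:
        factors = tmm_factors(counts)
    eff = counts.sum(axis=0) * factors
    return counts * 1e6 / eff


# ------------------------------------------------------- clustering / ratios

def relative_to_geomean(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2((x + 1) / geometric mean of (x + 1) across the gene's samples).

    Row means of the result are exactly 0.
    """
    lv = np.log2(normalized + 1.0)
    return lv.sub(lv.mean(axis=1), axis=0)


def correlation_linkage(ratio: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree on 1 - Pearson correlation between gene rows."""
    d = pdist(ratio.to_numpy(), metric="correlation")
    return linkage(d, method="average")


def hclust_genes(ratio: pd.DataFrame, k_major: int = 3,
                 subcluster: dict[str, int] | None = None) -> pd.Series:
    """Agglomerative clustering of genes into size-ordered labelled clusters.

    Distance is 1 - Pearson correlation between gene rows, average linkage;
    the tree is cut into ``k_major`` clusters labelled by decreasing size
    (largest = "I"). ``subcluster`` maps a label to a sub-cut count; the
    sub-clusters get letter suffixes by decreasing size ("II-A", "II-B").
    Constant rows (zero variance, where correlation is undefined) are
    assigned to the nearest major cluster by Euclidean distance to the
    cluster mean and logged.
    """
    values = ratio.to_numpy(dtype=float)
    row_sd = values.std(axis=1)
    variable = row_sd > 0
    if variable.sum() < k_major:
        raise ValueError("fewer variable genes than clusters")
    if not variable.all():
        logger.warning("%d constant gene rows assigned by Euclidean fallback",
                       int((~variable).sum()))
    var_df = ratio.loc[variable]
    z = correlation_linkage(var_df)
    raw = fcluster(z, t=k_major, criterion="maxclust")
    # decreasing size; ties break on the cluster id for determinism
    order = sorted(np.unique(raw),
                   key=lambda cid: (-int((raw == cid).sum()), cid))
    label_map = {cid: ROMAN[i] for i, cid in enumerate(order)}
    labels = pd.Series([label_map[c] for c in raw], index=var_df.index)

    if not variable.all():
        centroids = {lab: var_df.loc[labels == lab].mean(axis=0).to_numpy()
                     for lab in labels.unique()}
        extra = {}
        for gene in ratio.index[~variable]:
            row = ratio.loc[gene].to_numpy()
            extra[gene] = min(centroids,
                              key=lambda lab: float(np.sum((row - centroids[lab]) ** 2)))
        labels = pd.concat([labels, pd.Series(extra)])

    if subcluster:
        for parent, k_sub in sorted(subcluster.items()):
            members = labels.index[labels == parent]
            if len(members) < k_sub:
                raise ValueError(f"cluster {parent} too small to sub-cut")
            sub_df = ratio.loc[members]
            sub_sd = sub_df.to_numpy().std(axis=1)
            sub_var = sub_df.loc[sub_sd > 0]
            z_sub = correlation_linkage(sub_var)
            raw_sub = fcluster(z_sub, t=k_sub, criterion="maxclust")
            sub_order = sorted(np.unique(raw_sub),
                               key=lambda cid: (-int((raw_sub == cid).sum()), cid))
            sub_map = {cid: f"{parent}-{chr(ord('A') + i)}"
                       for i, cid in enumerate(sub_order)}
            sub_labels = pd.Series([sub_map[c] for c in raw_sub],
                                   index=sub_var.index)
            labels.loc[sub_labels.index] = sub_labels
            rest = [g for g in members if g not in sub_var.index]
            if rest:
                sub_centroids = {
                    lab: sub_var.loc[sub_labels == lab].mean(axis=0).to_numpy()
                    for lab in sub_labels.unique()}
                for gene in rest:
                    row = ratio.loc[gene].to_numpy()
                    labels.loc[gene] = min(
                        sub_centroids,
                        key=lambda lab: float(np.sum((row - sub_centroids[lab]) ** 2)))
    return labels.reindex(ratio.index)


def _treatment_cols(samples: pd.DataFrame, columns, **criteria) -> list[str]:
    mask = pd.Series(True, index=samples.index)
    for key, val in criteria.items():
        mask &= samples[key] == val
    return [c for c in columns if mask.get(c, False)]


def _robust_cut(var_df: pd.DataFrame, k: int, min_frac: float) -> np.ndarray:
    """Cut the average-linkage tree into k clusters of meaningful size.

    The tree is cut at increasing k until ``k`` clusters each hold at least
    ``min_frac`` of the rows; rows of smaller (outlier) clusters are
    reassigned to the nearest major cluster by Euclidean distance to its
    mean profile. Returns integer labels aligned with ``var_df`` rows.
    """
    n = len(var_df)
    z = correlation_linkage(var_df)
    min_size = max(2, int(np.ceil(min_frac * n)))
    raw = None
    for k_try in range(k, min(k + 10, n) + 1):
        cand = fcluster(z, t=k_try, criterion="maxclust")
        sizes = pd.Series(cand).value_counts()
        if (sizes >= min_size).sum() >= k:
            raw = cand
            break
    if raw is None:
        raw = fcluster(z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    major = sorted(sizes.index[sizes >= min_size],
                   key=lambda cid: (-sizes[cid], cid))[:k]
    if len(major) < k:
        major = sorted(sizes.index, key=lambda cid: (-sizes[cid], cid))[:k]
    values = var_df.to_numpy()
    centroids = {cid: values[raw == cid].mean(axis=0) for cid in major}
    assigned = np.empty(n, dtype=int)
    for i, cid in enumerate(raw):
        if cid in centroids:
            assigned[i] = cid
        else:
            row = values[i]
            assigned[i] = min(centroids, key=lambda c: float(
                np.sum((row - centroids[c]) ** 2)))
    return assigned


def ra_cluster_labels(ratio: pd.DataFrame, samples: pd.DataFrame,
                      k_major: int = 3,
                      min_cluster_frac: float = 0.05) -> pd.Series:
    """Cluster the RA response and name clusters by their treatment profile.

    Wraps the mechanical correlation/average-linkage clustering with two
    analysis conventions: the tree is cut at increasing k until ``k_major``
    clusters each hold at least ``min_cluster_frac`` of the genes (stray
    outlier genes are assigned to the nearest major cluster by Euclidean
    distance to its mean profile), and the major clusters are named by
    response rather than size — II is the cluster with the strongest
    IAA-over-UNT derepression at 6 h, I the more RA-induced and III the
    RA-repressed of the remaining two. Cluster II is sub-cut in two; II-A is
    the sub-cluster with the stronger G1-over-G2 preference in 6h-UNT.
    ``samples`` needs treatment (0h / 6h_UNT / 6h_IAA) and phase columns.
    """
    values = ratio.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    var_df = ratio.loc[variable]
    if len(var_df) < k_major:
        raise ValueError("fewer variable genes than clusters")
    assigned = _robust_cut(var_df, k_major, min_cluster_frac)

    cols = list(ratio.columns)
    col_0h = _treatment_cols(samples, cols, treatment="0h")
    col_unt = _treatment_cols(samples, cols, treatment="6h_UNT")
    col_iaa = _treatment_cols(samples, cols, treatment="6h_IAA")

    def _mean(cid, cc):
        sub = var_df.loc[assigned == cid, cc]
        return float(sub.to_numpy().mean()) if len(cc) else 0.0

    major = sorted(np.unique(assigned))
    cid_ii = max(major, key=lambda c: _mean(c, col_iaa) - _mean(c, col_unt))
    rest = [c for c in major if c != cid_ii]
    cid_i = max(rest, key=lambda c: _mean(c, col_unt + col_iaa) - _mean(c, col_0h))
    cid_iii = [c for c in rest if c != cid_i][0]
    name_map = {cid_i: "I", cid_ii: "II", cid_iii: "III"}
    labels = pd.Series([name_map[c] for c in assigned], index=var_df.index)

    members = labels.index[labels == "II"]
    if len(members) >= 4:
        sub_df = var_df.loc[members]
        raw_sub = _robust_cut(sub_df, 2, min_cluster_frac)
        g1_unt = _treatment_cols(samples, cols, treatment="6h_UNT", phase="G1")
        g2_unt = _treatment_cols(samples, cols, treatment="6h_UNT", phase="G2")

        def _pref(cid):
            sub = sub_df.loc[raw_sub == cid]
            return (float(sub[g1_unt].to_numpy().mean())
                    - float(sub[g2_unt].to_numpy().mean()))

        cid_a = max(np.unique(raw_sub), key=_pref)
        sub_labels = ["II-A" if c == cid_a else "II-B" for c in raw_sub]
        labels.loc[members] = sub_labels

    if not variable.all():
        logger.warning("%d constant gene rows assigned by Euclidean fallback",
                       int((~variable).sum()))
        big_centroids = {lab: var_df.loc[labels == lab].mean(axis=0).to_numpy()
                         for lab in labels.unique()}
        extra = {}
        for gene in ratio.index[~variable]:
            row = ratio.loc[gene].to_numpy()
            extra[gene] = min(big_centroids, key=lambda lab: float(
                np.sum((row - big_centroids[lab]) ** 2)))
        labels = pd.concat([labels, pd.Series(extra)])
    return labels.reindex(ratio.index)
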