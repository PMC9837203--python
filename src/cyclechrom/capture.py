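"""Capture-C quantification over DpnII restriction fragments.

Pooled per-fragment read counts are scaled per capture experiment
(normCounts = raw * nprom * 100,000 / cov, where cov is the total read count
aligning to captured promoters in the sample and nprom the number of
captured promoters). Interactions are called as maximal runs of consecutive
fragments whose interaction score passes the cutoff and that overlap an
accessible (ATAC) region; each interaction is anchored at its summit (the
fragment of maximal G2 normCounts), every condition is normalized to the
interaction's G2 summit value, and windows of +/- span fragments are flipped
so positive positions point toward the viewpoint promoter (proximal) and
negative positions away (distal). Distance-matched control sites mirror each
summit to the opposite side of the viewpoint at the same fragment distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FragmentMap, InteractionTable, PeakSet
from .stats import mann_whitney

logger = logging.getLogger(__name__)

CAPTURE_SCALE = 100_000


@dataclass
class CaptureNormalization:
    """Per-sample scaling: cov reads at captured promoters, nprom promoters."""

    cov: float
    nprom: int
    scale: float = CAPTURE_SCALE

    def __post_init__(self) -> None:
        if self.cov <= 0:
            raise ValueError("cov must be > 0")
        if self.nprom <= 0:
            raise ValueError("nprom must be > 0")

    @property
    def factor(self) -> float:
        return self.nprom * self.scale / self.cov


def norm_counts(raw, norm: CaptureNormalization):
    """normCounts = raw * nprom * 100,000 / cov (vectorized)."""
    return np.asarray(raw, dtype=float) * norm.factor


def normalization_from_table(table: InteractionTable, condition: str,
                             nprom: int | None = None) -> CaptureNormalization:
    """Derive cov (total captured reads in the condition) and nprom from the
    table itself; nprom defaults to the number of distinct viewpoints."""
    sub = table.df[table.df["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    cov = float(sub["counts"].sum())
    if nprom is None:
        nprom = sub["viewpoint_id"].nunique()
    return CaptureNormalization(cov=cov, nprom=nprom)


@dataclass
class Interaction:
    """A called promoter interaction: a run of significant fragments."""

    viewpoint_id: str
    chrom: str
    viewpoint_fragment: int
    i_lo: int
    i_hi: int
    summit: int
    distance: int          # |summit - viewpoint fragment|, fragments
    side: int              # +1 if summit downstream (higher index) of viewpoint
    sums: dict = field(default_factory=dict)        # condition -> sum normCounts
    score_sums: dict = field(default_factory=dict)  # condition -> sum scores

    def __post_init__(self) -> None:
        if not self.i_lo <= self.summit <= self.i_hi:
            raise ValueError("summit outside interaction interval")
        if self.distance < 1:
            raise ValueError("interaction distance must be >= 1 fragment")


def _runs(sorted_indices: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers (gap tolerance 0)."""
    if len(sorted_indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(sorted_indices) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(sorted_indices) - 1]))
    return [(int(sorted_indices[s]), int(sorted_indices[e]))
            for s, e in zip(starts, ends)]


def _atac_fragment_mask(sub: pd.DataFrame, atac: PeakSet) -> np.ndarray:
    """True where the fragment interval overlaps any ATAC peak (>= 1 bp)."""
    chrom_peaks = atac.df[atac.df["chrom"] == sub["chrom"].iloc[0]]
    if chrom_peaks.empty:
        return np.zeros(len(sub), dtype=bool)
    p_start = chrom_peaks["start"].to_numpy()
    p_end = chrom_peaks["end"].to_numpy()
    f_start = sub["frag_start"].to_numpy()[:, None]
    f_end = sub["frag_end"].to_numpy()[:, None]
    return ((f_start < p_end[None, :]) & (f_end > p_start[None, :])).any(axis=1)


def call_interactions(table: InteractionTable, atac_peaks: PeakSet,
                      fragmap: FragmentMap, viewpoints: pd.DataFrame,
                      score_cutoff: float = 5.0,
                      call_condition: str = "G2_WT",
                      summit_condition: str = "G2_WT") -> list[Interaction]:
    """Call interactions per viewpoint from per-fragment scores.

    Fragments with score >= cutoff in ``call_condition`` AND overlapping an
    ATAC peak form maximal consecutive runs; each run is one interaction
    whose summit is the fragment with maximal normCounts in
    ``summit_condition`` (ties go to the fragment closest to the viewpoint).
    The viewpoint's own fragment never enters an interval. ``viewpoints``
    needs columns gene_id, chrom, frag_index.
    """
    norm = normalization_from_table(table, summit_condition)
    interactions: list[Interaction] = []
    vp_index = {row.gene_id: (row.chrom, int(row.frag_index))
                for row in viewpoints.itertuples(index=False)}
    for vp_id, grp in table.df[table.df["condition"] == call_condition] \
            .groupby("viewpoint_id", sort=True):
        if vp_id not in vp_index:
            raise ValueError(f"viewpoint {vp_id!r} unresolvable on the "
                             "fragment map")
        chrom, vp_frag = vp_index[vp_id]
        grp = grp.sort_values("frag_index")
        sig = (grp["score"].to_numpy() >= score_cutoff) \
            & _atac_fragment_mask(grp, atac_peaks) \
            & (grp["frag_index"].to_numpy() != vp_frag)
        sig_idx = grp["frag_index"].to_numpy()[sig]
        summit_counts = table.fragment_series(vp_id, summit_condition)
        for i_lo, i_hi in _runs(sig_idx):
            frag_range = np.arange(i_lo, i_hi + 1)
            vals = norm_counts(
                summit_counts.reindex(frag_range).fillna(0.0).to_numpy(), norm)
            best = vals.max()
            candidates = frag_range[vals >= best - 1e-12]
            summit = int(candidates[np.argmin(np.abs(candidates - vp_frag))])
            interactions.append(Interaction(
                viewpoint_id=vp_id, chrom=chrom, viewpoint_fragment=vp_frag,
                i_lo=i_lo, i_hi=i_hi, summit=summit,
                distance=abs(summit - vp_frag),
                side=1 if summit > vp_frag else -1,
            ))
    return interactions


def sum_interval_counts(interaction: Interaction, table: InteractionTable,
                        condition: str,
                        norm: CaptureNormalization | None = None
                        ) -> tuple[float, float]:
    """Summed normCounts and summed scores over the interaction interval."""
    if norm is None:
        norm = normalization_from_table(table, condition)
    counts = table.fragment_series(interaction.viewpoint_id, condition)
    scores = table.fragment_series(interaction.viewpoint_id, condition, "score")
    frag_range = np.arange(interaction.i_lo, interaction.i_hi + 1)
    c = norm_counts(counts.reindex(frag_range).fillna(0.0).to_numpy(), norm)
    s = scores.reindex(frag_range).fillna(0.0).to_numpy()
    return float(c.sum()), float(s.sum())


@dataclass
class Metaprofile:
    """Per-position mean +/- SEM of summit-normalized values."""

    positions: np.ndarray     # -span..+span, fragment units; + = proximal
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    condition: str
    control: bool = False


def orient_offsets(offsets: np.ndarray, side: int) -> np.ndarray:
    """Map summit-relative fragment offsets to directional positions.

    Positions point from promoter-distal (negative) to promoter-proximal
    (positive): s = +1 when the viewpoint sits at a higher fragment index
    than the summit (side = -1), else s = -1. Applying the map twice returns
    the original offsets (involution).
    """
    s = -1 if side == 1 else 1
    return offsets * s


def _window_values(side: int, center: int,
                   counts: pd.Series, norm: CaptureNormalization,
                   denom: float, n_frag: int, span: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Summit-window values (normCounts / denom) and their positions.

    ``side`` is +1 when the window centre lies at a higher fragment index
    than the viewpoint, so proximal positions always point back toward the
    viewpoint promoter.
    """
    offsets = np.arange(-span, span + 1)
    frag_idx = center + offsets
    in_chrom = (frag_idx >= 0) & (frag_idx < n_frag)
    vals = np.full(2 * span + 1, np.nan)
    raw = counts.reindex(frag_idx[in_chrom]).fillna(0.0).to_numpy()
    vals[in_chrom] = norm_counts(raw, norm) / denom
    positions = orient_offsets(offsets, side)
    return positions, vals


def _aggregate(per_position: dict[int, list[float]], condition: str,
               control: bool) -> Metaprofile:
    positions = np.array(sorted(per_position))
    mean = np.empty(len(positions))
    sem = np.empty(len(positions))
    n = np.empty(len(positions), dtype=int)
    for i, pos in enumerate(positions):
        # sorted accumulation makes the mean independent of interaction
        # order, so mirrored inputs reproduce the profile bit for bit
        vals = np.sort(np.asarray(per_position[pos]))
        n[i] = len(vals)
        mean[i] = vals.mean() if len(vals) else np.nan
        sem[i] = (vals.std(ddof=1) / np.sqrt(len(vals))
                  if len(vals) > 1 else np.nan)
    return Metaprofile(positions=positions, mean=mean, sem=sem, n=n,
                       condition=condition, control=control)


def build_metaprofile(interactions: list[Interaction], table: InteractionTable,
                      fragmap: FragmentMap, conditions=None, span: int = 40,
                      reference_condition: str = "G2_WT",
                      control: bool = False) -> dict[str, Metaprofile]:
    """Summit-anchored, G2-normalized, direction-flipped metaprofiles.

    Every value of every condition is divided by the interaction's summit
    normCounts in the reference (G2) condition, so position 0 of the
    reference profile is exactly 1 for each retained interaction.
    Interactions with a non-positive reference summit value are dropped with
    a warning. With ``control=True`` the windows are taken at the
    distance-matched control site (the summit mirrored about the viewpoint)
    while keeping the interaction's own denominator and orientation scale.
    Positions beyond chromosome ends are excluded from the means.
    """
    if conditions is None:
        conditions = table.conditions()
    norms = {c: normalization_from_table(table, c) for c in conditions}
    if reference_condition not in norms:
        norms[reference_condition] = normalization_from_table(
            table, reference_condition)
    acc = {c: {int(p): [] for p in range(-span, span + 1)} for c in conditions}
    for inter in interactions:
        ref_counts = table.fragment_series(inter.viewpoint_id,
                                           reference_condition)
        raw_summit = float(ref_counts.get(inter.summit, 0.0))
        denom = norm_counts(raw_summit, norms[reference_condition])
        if denom <= 0:
            logger.warning(
                "dropping interaction %s summit %d: non-positive %s summit",
                inter.viewpoint_id, inter.summit, reference_condition)
            continue
        n_frag = fragmap.n_fragments(inter.chrom)
        center, side = inter.summit, inter.side
        if control:
            center = inter.viewpoint_fragment - inter.side * inter.distance
            side = -inter.side  # control lies on the opposite side
            if center - span < 0 or center + span >= n_frag:
                logger.warning(
                    "dropping control for %s: window off chromosome",
                    inter.viewpoint_id)
                continue
        for cond in conditions:
            counts = table.fragment_series(inter.viewpoint_id, cond)
            positions, vals = _window_values(side, center, counts,
                                             norms[cond], float(denom),
                                             n_frag, span)
            for pos, val in zip(positions, vals):
                if np.isfinite(val):
                    acc[cond][int(pos)].append(float(val))
    return {c: _aggregate(acc[c], c, control) for c in conditions}


def control_site(interaction: Interaction) -> int:
    """Distance-matched control: reflect the summit about the viewpoint."""
    return (interaction.viewpoint_fragment
            - interaction.side * interaction.distance)


def distance_matched_controls(interactions: list[Interaction],
                              table: InteractionTable, fragmap: FragmentMap,
                              conditions=None, span: int = 40,
                              reference_condition: str = "G2_WT"
                              ) -> dict[str, Metaprofile]:
    """Control metaprofile at the mirrored sites (same denominators)."""
    return build_metaprofile(interactions, table, fragmap,
                             conditions=conditions, span=span,
                             reference_condition=reference_condition,
                             control=True)


def control_interval_sums(interactions: list[Interaction],
                          table: InteractionTable, condition: str,
                          norm: CaptureNormalization | None = None
                          ) -> list[float]:
    """Summed normCounts over the mirrored control window per interaction
    (same width as the interaction interval)."""
    if norm is None:
        norm = normalization_from_table(table, condition)
    out = []
    for inter in interactions:
        width = inter.i_hi - inter.i_lo
        center = control_site(inter)
        # mirror the run: summit offset within the run is preserved
        lo = center - (inter.i_hi - inter.summit)
        frag_range = np.arange(lo, lo + width + 1)
        counts = table.fragment_series(inter.viewpoint_id, condition)
        vals = norm_counts(counts.reindex(frag_range).fillna(0.0).to_numpy(),
                           norm)
        out.append(float(vals.sum()))
    return out


def compare_interaction_groups(group_a, group_b) -> dict:
    """Means, SEMs and the two-sided Mann-Whitney p for two groups of
    per-interaction summed normCounts."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    u, p = mann_whitney(a, b)
    def _sem(v):
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
    return {
        "mean_a": float(a.mean()), "sem_a": _sem(a),
        "mean_b": float(b.mean()), "sem_b": _sem(b),
        "u": u, "pval": p,
        "n_a": len(a), "n_b": len(b),
    }
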