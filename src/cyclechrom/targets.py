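"""Promoter target sets per factor and the derived PRC gene classes.

A gene is a target of a factor in a phase if any called peak overlaps its
strand-aware promoter window by at least 1 bp; per-factor target sets are
the union across phases. The derived classes follow the polycomb-complex
composition: genes bound by vPRC1, cPRC1 and PRC2 together
(RING1B & RYBP & CBX7 & EZH2) versus genes bound by vPRC1 only
(RING1B & RYBP minus CBX7 or EZH2), plus expression-matched unbound
controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PeakSet, TSSAnnotation


def _promoter_interval(tss: int, strand: str,
                       window: tuple[int, int]) -> tuple[int, int]:
    lo, hi = window
    if strand == "+":
        return tss + lo, tss + hi
    return tss - hi, tss - lo


def assign_peaks_to_promoters(peaks: PeakSet, annotation: TSSAnnotation,
                              window: tuple[int, int] = (-500, 1500)) -> set[str]:
    """Genes whose promoter window overlaps >= 1 bp of any peak.

    Intervals are half-open, so a peak ending exactly at the window start
    does not overlap.
    """
    hits: set[str] = set()
    by_chrom = {c: sub for c, sub in peaks.df.groupby("chrom")}
    for row in annotation.df.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        w_lo, w_hi = _promoter_interval(row.tss, row.strand, window)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if bool(np.any((starts < w_hi) & (ends > w_lo))):
            hits.add(row.gene_id)
    return hits


def union_targets(per_phase_sets: dict[str, set[str]] | list[set[str]]) -> set[str]:
    """Factor-level target set: union across phases."""
    sets = (per_phase_sets.values() if isinstance(per_phase_sets, dict)
            else per_phase_sets)
    out: set[str] = set()
    for s in sets:
        out |= s
    return out


@dataclass
class TargetSets:
    """Named promoter sets per factor/phase and the derived classes."""

    per_factor_phase: dict = field(default_factory=dict)  # (factor, phase) -> set
    ring1b_targets: set = field(default_factory=set)
    rybp_targets: set = field(default_factory=set)
    cbx7_targets: set = field(default_factory=set)
    ezh2_targets: set = field(default_factory=set)
    hc_bivalent: set = field(default_factory=set)  # consumed list, never derived
    vcp_targets: set = field(default_factory=set)
    v_only_targets: set = field(default_factory=set)
    unbound_controls: set = field(default_factory=set)

    @classmethod
    def from_peaks(cls, peaks: dict, annotation: TSSAnnotation,
                   window: tuple[int, int] = (-500, 1500),
                   hc_bivalent: set | None = None) -> "TargetSets":
        """Build per-factor sets from (factor, phase) -> PeakSet."""
        per_fp = {
            key: assign_peaks_to_promoters(pk, annotation, window)
            for key, pk in peaks.items()
        }
        factors: dict[str, list[set]] = {}
        for (factor, _phase), s in per_fp.items():
            factors.setdefault(factor, []).append(s)
        unions = {f: union_targets(ss) for f, ss in factors.items()}
        ts = cls(
            per_factor_phase=per_fp,
            ring1b_targets=unions.get("RING1B", set()),
            rybp_targets=unions.get("RYBP", set()),
            cbx7_targets=unions.get("CBX7", set()),
            ezh2_targets=unions.get("EZH2", set()),
            hc_bivalent=set(hc_bivalent or ()),
        )
        ts.vcp_targets, ts.v_only_targets = classify_prc_classes(ts)
        return ts

    def factor_union(self) -> set[str]:
        """Genes bound by any factor in any phase."""
        return (self.ring1b_targets | self.rybp_targets
                | self.cbx7_targets | self.ezh2_targets)


def classify_prc_classes(sets: TargetSets) -> tuple[set[str], set[str]]:
    """Split PRC1-bound promoters into the two headline classes.

    vcp (vPRC1/cPRC1/PRC2) = RING1B & RYBP & CBX7 & EZH2;
    v_only (vPRC1-specific) = (RING1B & RYBP) - (CBX7 | EZH2).
    Genes bound by an intermediate combination (e.g. RING1B & RYBP & CBX7
    without EZH2) belong to neither class. The two classes are disjoint by
    construction.
    """
    vcp = (sets.ring1b_targets & sets.rybp_targets
           & sets.cbx7_targets & sets.ezh2_targets)
    v_only = ((sets.ring1b_targets & sets.rybp_targets)
              - (sets.cbx7_targets | sets.ezh2_targets))
    return vcp, v_only


def select_unbound_controls(all_genes, target_union,
                            nascent_log2fc_g1_g2: pd.Series,
                            band: float = 0.2) -> set[str]:
    """Control genes: not bound by any factor and cell-cycle neutral.

    A gene qualifies iff it is outside the target union and its nascent
    log2FC(G1/G2) lies strictly inside (-band, +band); genes exactly on the
    boundary are excluded.
    """
    out = set()
    for gene in all_genes:
        if gene in target_union:
            continue
        fc = nascent_log2fc_g1_g2.get(gene)
        if fc is None or not np.isfinite(fc):
            continue
        if abs(fc) < band:
            out.add(gene)
    return out


@dataclass
class OverlapReport:
    n_a: int
    n_intersection: int
    fraction: float          # raw fraction of a contained in b
    percent_rounded: float   # one decimal, round half up
    percent_truncated: float # one decimal, truncated toward zero (display)


def overlap_fraction(a: set, b: set) -> OverlapReport:
    """Percentage of set ``a`` contained in set ``b``.

    Reports the raw fraction, the half-up one-decimal rounding, and the
    truncated one-decimal display value (the convention used for printed
    percentages such as 1575/1678 -> 93.8).
    """
    if not a:
        raise ValueError("overlap_fraction: set a is empty")
    inter = len(a & b)
    frac = inter / len(a)
    pct = 100.0 * frac
    rounded = math.floor(pct * 10 + 0.5) / 10
    truncated = math.floor(pct * 10) / 10
    return OverlapReport(n_a=len(a), n_intersection=inter, fraction=frac,
                         percent_rounded=rounded, percent_truncated=truncated)
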