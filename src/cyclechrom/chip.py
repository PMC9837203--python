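"""Promoter-level ChIP signal quantification per cell-cycle phase.

Tracks are normalized bamCompare-style: per-bin coverage scaled to reads per
million (RPM) minus the matched input track on the same scale. Promoter
signal is the mean normalized value over a strand-aware window around the
TSS (default -500..+1500 bp in gene orientation); TSS-centred profile
matrices, joint percentile trimming for display, G2-referenced ranking, and
the one-way ANOVA comparing phases on the promoter window round out the
stage.

Strand convention: for a minus-strand gene at TSS t the promoter window is
the half-open reflection [t-1500, t+500) of the plus-strand window, so every
per-gene quantity is invariant under reversing the genome and flipping
strands (bit-exact on the 10-bp grid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import SignalTrack, TSSAnnotation
from .stats import one_way_anova


def normalize_track(signal: SignalTrack, input_track: SignalTrack) -> SignalTrack:
    """RPM-scale the signal and subtract the RPM-scaled input.

    out_bin = signal_bin * 1e6 / signal_reads - input_bin * 1e6 / input_reads.
    Values may be negative.
    """
    for trk, name in ((signal, "signal"), (input_track, "input")):
        if not trk.library_size or trk.library_size <= 0:
            raise ValueError(f"{name} track needs library_size > 0")
        if trk.normalized:
            raise ValueError(f"{name} track is already normalized")
    if signal.bin_size != input_track.bin_size:
        raise ValueError("mismatched bin sizes")
    if set(signal.values) != set(input_track.values):
        raise ValueError("mismatched chromosomes between signal and input")
    out = {}
    s_scale = 1e6 / signal.library_size
    i_scale = 1e6 / input_track.library_size
    for chrom, vals in signal.values.items():
        if len(vals) != len(input_track.values[chrom]):
            raise ValueError(f"mismatched binning on {chrom}")
        out[chrom] = (np.asarray(vals, dtype=float) * s_scale
                      - np.asarray(input_track.values[chrom], dtype=float) * i_scale)
    return SignalTrack(values=out, chrom_sizes=dict(signal.chrom_sizes),
                       bin_size=signal.bin_size, factor=signal.factor,
                       phase=signal.phase, condition=signal.condition,
                       library_size=signal.library_size, normalized=True)


def _window_bins(tss: int, strand: str, window: tuple[int, int],
                 bin_size: int) -> tuple[int, int]:
    """Bin index range [b0, b1) covering the strand-aware window."""
    lo, hi = window
    if strand == "+":
        g_lo, g_hi = tss + lo, tss + hi
    else:
        g_lo, g_hi = tss - hi, tss - lo
    b0 = g_lo // bin_size if g_lo >= 0 else -((-g_lo + bin_size - 1) // bin_size)
    b1 = -(-g_hi // bin_size)
    return b0, b1


def promoter_coverage(track: SignalTrack, annotation: TSSAnnotation,
                      window: tuple[int, int] = (-500, 1500)) -> pd.Series:
    """Strand-aware mean signal over the promoter window, per gene.

    Windows exceeding chromosome bounds are truncated to in-bounds bins.
    """
    lo, hi = window
    if (hi - lo) % track.bin_size:
        raise ValueError("window length must be a multiple of the bin size")
    out = {}
    for row in annotation.df.itertuples(index=False):
        if row.chrom not in track.values:
            raise ValueError(f"gene {row.gene_id}: chromosome {row.chrom} "
                             "absent from track")
        vals = track.values[row.chrom]
        b0, b1 = _window_bins(row.tss, row.strand, window, track.bin_size)
        b0 = max(b0, 0)
        b1 = min(b1, len(vals))
        if b1 <= b0:
            out[row.gene_id] = 0.0
        else:
            out[row.gene_id] = float(np.mean(vals[b0:b1]))
    return pd.Series(out, name=track.phase or "signal")


@dataclass
class ProfileMatrix:
    """Genes x positions matrix of signal around the TSS, gene-oriented.

    Columns run upstream -> downstream of the gene in ``bin_size`` steps over
    TSS +/- span. ``oob`` marks bins that fell outside the chromosome (their
    values are 0).
    """

    values: np.ndarray
    gene_ids: list[str]
    span: int
    bin_size: int
    oob: np.ndarray
    factor: str = ""
    phase: str = ""
    trimmed: bool = False

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def positions(self) -> np.ndarray:
        """Genomic offset (bp, gene orientation) of each column's left edge."""
        return np.arange(-self.span, self.span, self.bin_size)


def profile_matrix(track: SignalTrack, annotation: TSSAnnotation,
                   span: int = 10_000, bin_size: int | None = None) -> ProfileMatrix:
    """TSS-centred signal matrix, one row per gene, oriented 5'->3'."""
    bin_size = bin_size or track.bin_size
    if bin_size != track.bin_size:
        raise ValueError("profile bin size must match the track bin size")
    if span % bin_size:
        raise ValueError("span must be a multiple of the bin size")
    half = span // bin_size
    width = 2 * half
    n = len(annotation)
    mat = np.zeros((n, width))
    oob = np.zeros((n, width), dtype=bool)
    for i, row in enumerate(annotation.df.itertuples(index=False)):
        vals = track.values[row.chrom]
        b = row.tss // bin_size
        b0, b1 = b - half, b + half
        c0 = max(b0, 0)
        c1 = min(b1, len(vals))
        segment = np.zeros(width)
        mask = np.ones(width, dtype=bool)
        if c1 > c0:
            segment[c0 - b0:c1 - b0] = vals[c0:c1]
            mask[c0 - b0:c1 - b0] = False
        if row.strand == "-":
            segment = segment[::-1]
            mask = mask[::-1]
        mat[i] = segment
        oob[i] = mask
    return ProfileMatrix(values=mat, gene_ids=annotation.gene_ids, span=span,
                         bin_size=bin_size, oob=oob, factor=track.factor,
                         phase=track.phase)


def trim_percentiles(matrices, low: float = 5.0, high: float = 95.0):
    """Winsorize profile values to joint [low, high] percentiles.

    Percentiles are computed jointly over all entries of the matrices being
    displayed together (linear interpolation between order statistics), so
    cross-phase heatmaps share one scale. Accepts a single matrix or a list;
    returns the same shape of argument. Trimming an already-trimmed matrix
    is a no-op (the clip bounds of winsorized data would otherwise creep
    inward), so the operation is idempotent.
    """
    single = isinstance(matrices, ProfileMatrix)
    mats = [matrices] if single else list(matrices)
    if all(m.trimmed for m in mats):
        return matrices
    pooled = np.concatenate([m.values.ravel() for m in mats])
    p_lo, p_hi = np.percentile(pooled, [low, high])
    out = [
        replace(m, values=np.clip(m.values, p_lo, p_hi), trimmed=True)
        for m in mats
    ]
    return out[0] if single else out


def rank_by_reference(promoter_signal: dict[str, pd.Series],
                      reference_phase: str = "G2") -> list[str]:
    """Gene order by descending reference-phase promoter mean.

    Ties break lexicographically on gene_id; the one order is meant to be
    applied to every phase's matrix.
    """
    ref = promoter_signal[reference_phase]
    return sorted(ref.index, key=lambda g: (-ref[g], g))


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-position mean curve across genes."""
    return matrix.values.mean(axis=0)


def profile_anova(promoter_signal: dict[str, pd.Series]) -> tuple[float, float]:
    """One-way ANOVA with phases as groups, per-gene promoter means as
    observations. Zero total variance is reported as F = 0, p = 1."""
    if len(promoter_signal) < 2:
        raise ValueError("need >= 2 phases")
    return one_way_anova([s.to_numpy() for s in promoter_signal.values()])


def promoter_log2fc(a: pd.Series, b: pd.Series,
                    pseudocount: float = 0.5) -> pd.Series:
    """Per-gene log2((a + pc) / (b + pc)).

    Negative normalized means are floored at 0 before the pseudocount so the
    log is always defined.
    """
    a2 = a.clip(lower=0.0)
    b2 = b.reindex(a.index).clip(lower=0.0)
    return np.log2((a2 + pseudocount) / (b2 + pseudocount))
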