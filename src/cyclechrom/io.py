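"""Readers and writers for the text formats the pipeline touches.

Formats: BED4/5/6, bedGraph (10-bp grid), and TSV tables (tab-separated,
header row, UTF-8, "." for missing). Every reader rejects what its writer
cannot produce, so write-then-read is the identity on valid objects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CAPTURE_CONDITIONS,
    ExpressionMatrix,
    FragmentMap,
    InteractionTable,
    PeakSet,
    SignalTrack,
    TSSAnnotation,
)

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------- TSS tables

def write_tss_table(annotation: TSSAnnotation, path: str | Path) -> None:
    """Write a TSS table as BED6 (1-bp interval at the TSS base)."""
    df = annotation.df
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["tss"],
        "end": df["tss"] + 1,
        "name": df["gene_id"],
        "score": 0,
        "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path: str | Path) -> TSSAnnotation:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, start_i, strand, name))
    df = pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene_id"])
    return TSSAnnotation(df)


# ------------------------------------------------------------------ bedGraph

def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length merging equal adjacent bins.

    Zero-valued runs are omitted (missing intervals read back as 0).
    """
    bs = track.bin_size
    frames = []
    for chrom in sorted(track.values):
        vals = np.asarray(track.values[chrom])
        size = track.chrom_sizes[chrom]
        if len(vals) == 0:
            continue
        # boundaries of equal-value runs
        change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vals)]))
        run_vals = vals[starts]
        keep = run_vals != 0
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts[keep] * bs,
            "end": np.minimum(ends[keep] * bs, size),
            "value": run_vals[keep],
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    fmt = None if pd.api.types.is_integer_dtype(out["value"]) else _FLOAT_FMT
    out.to_csv(path, sep="\t", header=False, index=False, float_format=fmt)


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int],
                  bin_size: int = 10, **metadata) -> SignalTrack:
    """Read a bedGraph whose intervals align to the ``bin_size`` grid.

    Missing intervals read as 0. Off-grid intervals are rejected.
    """
    values = {
        chrom: np.zeros(-(-size // bin_size))
        for chrom, size in chrom_sizes.items()
    }
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return SignalTrack(values=values, chrom_sizes=dict(chrom_sizes),
                           bin_size=bin_size, **metadata)
    df = df[df["chrom"] != "track"]
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in values:
            lineno = int(sub.index[0]) + 1
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
        size = chrom_sizes[chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        off = (starts % bin_size != 0) | ((ends % bin_size != 0)
                                          & (ends != size))
        if off.any():
            row = sub.index[np.flatnonzero(off)[0]]
            raise ValueError(
                f"{path}:{int(row) + 1}: interval "
                f"[{df.loc[row, 'start']},{df.loc[row, 'end']}) not on "
                f"{bin_size}-bp grid")
        b0 = starts // bin_size
        b1 = -(-ends // bin_size)
        lengths = b1 - b0
        flat = (np.repeat(b0, lengths)
                + np.arange(lengths.sum())
                - np.repeat(np.cumsum(lengths) - lengths, lengths))
        values[chrom][flat] = np.repeat(sub["value"].to_numpy(dtype=float),
                                        lengths)
    return SignalTrack(values=values, chrom_sizes=dict(chrom_sizes),
                       bin_size=bin_size, **metadata)


# --------------------------------------------------------------------- peaks

def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write peaks as BED5 (chrom, start, end, name, score)."""
    df = peaks.df
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"],
        "end": df["end"],
        "name": [f"peak{i}" for i in range(len(df))],
        "score": df["score"],
    })
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format=_FLOAT_FMT)


def read_peaks(path: str | Path, factor: str = "", phase: str = "") -> PeakSet:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            score = float(fields[4]) if len(fields) >= 5 else 0.0
            rows.append((chrom, start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return PeakSet(df, factor=factor, phase=phase)


# ------------------------------------------------------------- fragment maps

def write_fragment_map(fragmap: FragmentMap, path: str | Path) -> None:
    """BED4; the name column carries the fragment index."""
    frames = []
    for chrom in sorted(fragmap.frames):
        df = fragmap.frames[chrom]
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": df["start"],
            "end": df["end"],
            "name": df["index"],
        }))
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)


def read_fragment_map(path: str | Path) -> FragmentMap:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "index"],
                     dtype={"chrom": str})
    frames = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        frames[chrom] = sub[["index", "start", "end"]]
    return FragmentMap(frames)


# --------------------------------------------------------- interaction table

_INTERACTION_COLS = ["viewpoint_id", "chrom", "frag_index", "frag_start",
                     "frag_end", "condition", "counts", "score"]


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    table.df[_INTERACTION_COLS].to_csv(path, sep="\t", index=False,
                                       float_format=_FLOAT_FMT)


def read_interaction_table(path: str | Path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _INTERACTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: interaction table missing column(s) {missing}")
    bad = ~df["condition"].isin(CAPTURE_CONDITIONS)
    if bad.any():
        lab = df.loc[bad, "condition"].iloc[0]
        raise ValueError(f"{path}: unknown condition label {lab!r} "
                         f"(column 'condition')")
    return InteractionTable(df)


# ---------------------------------------------------------- counts + samples

def write_counts(matrix: ExpressionMatrix, counts_path: str | Path,
                 samples_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    matrix.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_counts(counts_path: str | Path,
                samples_path: str | Path) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"{counts_path}: duplicated gene_id {dup!r} "
                         f"(column 'gene_id')")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return ExpressionMatrix(counts=counts, samples=samples)


# ------------------------------------------------------------------ DE table

_DE_COLS = ["contrast", "gene_id", "log2fc", "fdr"]


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_DE_COLS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing column(s) {missing}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError(f"{path}: column 'fdr' outside [0, 1]")
    return df


# ----------------------------------------------------------------- gene list

def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines()
        if line.strip()
    }


# ---------------------------------------------------------------- TSV helper

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False,
              index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=_FLOAT_FMT, na_rep=".")
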