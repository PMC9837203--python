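"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention) everywhere
internally. Signal tracks are fixed 10-bp bins; the value of a bin in a raw
track is the fragment-coverage count (number of sequenced fragments
overlapping the bin), while ``library_size`` is the number of reads, so that
reads-per-million scaling reproduces bamCompare-style normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("G1", "S", "G2")
STRANDS = ("+", "-")


@dataclass
class TSSAnnotation:
    """Strand-aware gene TSS records.

    ``df`` columns: chrom (str), tss (int, 0-based), strand ('+'/'-'),
    gene_id (str, unique).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "tss", "strand", "gene_id"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup}")
        if (self.df["tss"] < 0).any():
            raise ValueError("negative TSS coordinate")
        bad = ~self.df["strand"].isin(STRANDS)
        if bad.any():
            raise ValueError(
                f"invalid strand {self.df.loc[bad, 'strand'].iloc[0]!r}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df["gene_id"])


@dataclass
class SignalTrack:
    """Fixed-bin genomic signal for one factor/phase/condition.

    ``values`` maps chromosome name to a float/int array covering the
    chromosome from 0 in ``bin_size`` steps (last bin may be short).
    Raw tracks hold non-negative integer coverage counts; normalized tracks
    hold reals (may be negative after input subtraction).
    """

    values: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    bin_size: int = 10
    factor: str = ""
    phase: str = ""
    condition: str = ""
    library_size: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            n_bins = -(-size // self.bin_size)
            arr = self.values.get(chrom)
            if arr is None:
                raise ValueError(f"track missing chromosome {chrom}")
            if len(arr) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(arr)}"
                )

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


@dataclass
class PeakSet:
    """Sorted peak intervals (chrom, start, end, score), 0-based half-open."""

    df: pd.DataFrame
    factor: str = ""
    phase: str = ""

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"peaks missing columns: {missing}")
        if "score" not in self.df.columns:
            self.df = self.df.assign(score=0.0)
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("peak with start >= end")
        self.df = (
            self.df.sort_values(["chrom", "start", "end"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome contiguously.

    ``frames`` maps chromosome to a DataFrame with columns index/start/end
    where index runs 0..n-1 along the chromosome and fragments tile
    [0, chrom_length) exactly.
    """

    frames: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for chrom, df in self.frames.items():
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            idx = df["index"].to_numpy()
            if starts[0] != 0:
                raise ValueError(f"{chrom}: first fragment must start at 0")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"{chrom}: fragments are not contiguous")
            if not np.array_equal(idx, np.arange(len(df))):
                raise ValueError(f"{chrom}: fragment indices not 0..n-1")

    def n_fragments(self, chrom: str) -> int:
        return len(self.frames[chrom])

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment index containing genomic position ``pos``."""
        df = self.frames[chrom]
        ends = df["end"].to_numpy()
        if pos < 0 or pos >= ends[-1]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(np.searchsorted(ends, pos, side="right"))

    def interval(self, chrom: str, index: int) -> tuple[int, int]:
        row = self.frames[chrom].iloc[index]
        return int(row["start"]), int(row["end"])


CAPTURE_CONDITIONS = ("G1_WT", "G2_WT", "G1_KO", "G2_KO")


@dataclass
class InteractionTable:
    """Per-fragment capture counts and scores per viewpoint and condition.

    ``df`` columns: viewpoint_id, chrom, frag_index, frag_start, frag_end,
    condition, counts, score. Conditions are drawn from CAPTURE_CONDITIONS.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = [
            "viewpoint_id", "chrom", "frag_index", "frag_start",
            "frag_end", "condition", "counts", "score",
        ]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        bad = ~self.df["condition"].isin(CAPTURE_CONDITIONS)
        if bad.any():
            lab = self.df.loc[bad, "condition"].iloc[0]
            raise ValueError(f"unknown condition label: {lab!r}")

    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    def _index(self, column: str) -> dict:
        cache = self.__dict__.setdefault("_series_cache", {})
        if column not in cache:
            cache[column] = {
                key: pd.Series(sub[column].to_numpy(),
                               index=sub["frag_index"].to_numpy())
                for key, sub in self.df.groupby(
                    ["viewpoint_id", "condition"], sort=False)
            }
        return cache[column]

    def fragment_series(self, viewpoint_id: str, condition: str,
                        column: str = "counts") -> pd.Series:
        """Per-fragment values for one viewpoint and condition, indexed by
        fragment index (cached)."""
        series = self._index(column).get((viewpoint_id, condition))
        if series is None:
            return pd.Series(dtype=float)
        return series


@dataclass
class ExpressionMatrix:
    """Gene x sample count matrix with sample metadata.

    ``counts``: DataFrame indexed by gene_id with one column per sample.
    ``samples``: DataFrame indexed by sample name; columns depend on the
    assay (phase, genotype or treatment, timepoint, replicate).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene_id in counts: {dup}")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_where(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return [s for s in self.counts.columns if mask.get(s, False)]
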