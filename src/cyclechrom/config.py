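"""Configuration objects: simulation parameters and pipeline thresholds.

Both configs round-trip through YAML and validate on construction. Every
analysis threshold is a named, overridable key whose default is the value the
pipeline was designed around (promoter window -500..+1500 bp, 10-bp bins,
5/95 trimming percentiles, interaction score cutoff 5, metaprofile span +/-40
fragments, DE filter FC > 2 & FDR < 0.05, MA threshold 1.2, unbound control
band +/-0.2 log2 units).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _check_positive(name: str, value) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    The defaults encode the study conditions the downstream analyses assume:
    constant RING1B occupancy across the cell cycle, three-fold G2/G1
    enrichment of RYBP, CBX7 and H2AK119ub1 at target promoters (S phase at
    the geometric midpoint), two-fold higher nascent transcription of target
    genes in G1 than G2 with knockout derepression confined to S/G2, and a
    two-fold G2 boost of homotypic promoter contacts ablated in the knockout.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 7_680_000
    n_genes: int = 600
    frag_mean_len: int = 250
    group_fractions: dict = field(
        default_factory=lambda: {"vcp": 0.25, "v_only": 0.25, "unbound": 0.5}
    )
    ring1b_phase_ratio: float = 1.0
    rybp_phase_ratio: float = 3.0
    cbx7_phase_ratio: float = 3.0
    h2aub_phase_ratio: float = 3.0
    nascent_g1_over_g2: float = 2.0
    ko_derepression: dict = field(
        default_factory=lambda: {"G1": 1.0, "S": 1.5, "G2": 3.0}
    )
    capture_decay_alpha: float = 1.0
    capture_g2_boost: float = 2.0
    depth: int = 1_000_000
    # sequencing/assay geometry (fixed aspects of the emulated protocols)
    bin_size: int = 10
    fragment_length: int = 200      # ChIP fragment size; coverage = reads x flen/bin
    gene_spacing: int = 25_000
    promoter_occupancy: float = 150.0   # expected ChIP reads per bound promoter, G1
    kernel_half_width: int = 1000       # triangular occupancy kernel, bp
    nascent_target_mean: float = 100.0  # NB mean, target gene, G1, WT
    nascent_unbound_mean: float = 1500.0
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_fractions must sum to 1, got {total}")
        if set(self.group_fractions) != {"vcp", "v_only", "unbound"}:
            raise ValueError("group_fractions keys must be vcp/v_only/unbound")
        for name in ("ring1b_phase_ratio", "rybp_phase_ratio",
                     "cbx7_phase_ratio", "h2aub_phase_ratio",
                     "nascent_g1_over_g2", "capture_decay_alpha",
                     "capture_g2_boost"):
            _check_positive(name, getattr(self, name))
        for phase, mult in self.ko_derepression.items():
            if phase not in ("G1", "S", "G2"):
                raise ValueError(f"ko_derepression: unknown phase {phase!r}")
            _check_positive(f"ko_derepression[{phase}]", mult)
        for name in ("n_chrom", "chrom_length", "n_genes", "frag_mean_len",
                     "depth", "bin_size", "fragment_length", "gene_spacing"):
            _check_positive(name, getattr(self, name))
        if self.frag_mean_len < 50:
            raise ValueError("frag_mean_len must be >= 50")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineConfig:
    """Thresholds, windows and input paths for the analysis stages."""

    # windows (bp relative to TSS, gene orientation) and display parameters
    promoter_window: tuple = (-500, 1500)
    profile_span: int = 10_000
    bin_size: int = 10
    trim_low: float = 5.0
    trim_high: float = 95.0
    nascent_window: tuple = (0, 3000)
    # capture
    score_cutoff: float = 5.0
    metaprofile_span: int = 40
    # expression filters
    de_fc_cutoff: float = 2.0
    de_fdr_cutoff: float = 0.05
    ma_threshold: float = 1.2
    unbound_band: float = 0.2
    pseudocount: float = 0.5
    # randomness (GSEA permutations)
    seed: int = 0
    gsea_n_perm: int = 10_000
    # optional input paths consumed by run_pipeline
    paths: dict = field(default_factory=dict)
    # embedded simulation config (run_pipeline's simulate stage)
    simulate: dict | None = None

    def __post_init__(self) -> None:
        self.promoter_window = tuple(self.promoter_window)
        self.nascent_window = tuple(self.nascent_window)
        self.validate()

    def validate(self) -> None:
        for name in ("promoter_window", "nascent_window"):
            lo, hi = getattr(self, name)
            if hi - lo <= 0:
                raise ValueError(f"{name} must have positive length")
        if not self.trim_low < self.trim_high:
            raise ValueError("trim_low must be < trim_high")
        for name in ("profile_span", "bin_size", "metaprofile_span",
                     "de_fc_cutoff", "ma_threshold", "gsea_n_perm"):
            _check_positive(name, getattr(self, name))
        if not 0 <= self.de_fdr_cutoff <= 1:
            raise ValueError("de_fdr_cutoff must be in [0, 1]")
        if self.profile_span % self.bin_size:
            raise ValueError("profile_span must be a multiple of bin_size")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["promoter_window"] = list(self.promoter_window)
        data["nascent_window"] = list(self.nascent_window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**data)
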