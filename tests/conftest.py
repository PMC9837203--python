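"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from cyclechrom.config import SimConfig
from cyclechrom.core import SignalTrack, TSSAnnotation
from cyclechrom import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_chrom=2, chrom_length=1_280_000, n_genes=40,
                     depth=100_000)


@pytest.fixture(scope="session")
def annotation(small_config) -> TSSAnnotation:
    return sim.generate_annotation(small_config)


@pytest.fixture(scope="session")
def fragmap(small_config):
    return sim.generate_fragment_map(small_config)


@pytest.fixture(scope="session")
def truth(small_config, annotation) -> pd.DataFrame:
    return sim.assign_groups(small_config, annotation)


@pytest.fixture(scope="session")
def capture_sim(small_config, annotation, fragmap, truth):
    return sim.simulate_capture(small_config, annotation, fragmap, truth,
                                n_viewpoints=6, partners_per_viewpoint=3)


def constant_track(value: float, chrom_sizes: dict, bin_size: int = 10,
                   **meta) -> SignalTrack:
    values = {c: np.full(-(-s // bin_size), float(value))
              for c, s in chrom_sizes.items()}
    return SignalTrack(values=values, chrom_sizes=dict(chrom_sizes),
                       bin_size=bin_size, **meta)


def single_gene_annotation(chrom="chr1", tss=5_000, strand="+",
                           gene_id="g1") -> TSSAnnotation:
    return TSSAnnotation(pd.DataFrame({
        "chrom": [chrom], "tss": [tss], "strand": [strand],
        "gene_id": [gene_id]}))
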