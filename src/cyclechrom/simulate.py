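"""Synthetic genomes, tracks, peaks, capture tables and expression matrices.

The generator emulates the statistical structure the downstream analyses
assume, with known ground truth for parameter-recovery tests:

* ChIP coverage tracks with constant RING1B occupancy across G1/S/G2 and
  G2-enriched RYBP/CBX7/H2AK119ub1 at target promoters (S phase at the
  geometric midpoint), matched background-only inputs, and peak calls at the
  true target promoters.
* Nascent (4sU-like) promoter-window counts with lower target transcription
  in S/G2 than G1 in the wild type, reversed by simulated RING1B loss in
  S/G2 only.
* Fragment-level capture (3C) counts with power-law distance decay and a
  G2-boosted, knockout-ablated homotypic interaction component at designated
  partner fragments.
* An RA-response expression matrix with cluster I / II (II-A/II-B) / III
  structure and per-contrast differential-expression tables.

Every generator is a pure function of (config, seed); each output draws from
its own named child stream of the single config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SimConfig
from .core import (
    ExpressionMatrix,
    FragmentMap,
    InteractionTable,
    PeakSet,
    SignalTrack,
    TSSAnnotation,
)
from .stats import bh_fdr

PHASES = ("G1", "S", "G2")

# factor -> (bound groups, name of the SimConfig G2/G1 ratio attribute)
FACTOR_SPECS = {
    "RING1B": (("vcp", "v_only"), "ring1b_phase_ratio"),
    "RYBP": (("vcp", "v_only"), "rybp_phase_ratio"),
    "CBX7": (("vcp",), "cbx7_phase_ratio"),
    "EZH2": (("vcp",), None),  # PRC2 mark, constant across phases
    "H2AK119ub1": (("vcp", "v_only"), "h2aub_phase_ratio"),
}


def _stream(seed: int, *labels) -> np.random.Generator:
    """Named child RNG stream of the config seed (documented per output)."""
    entropy = [int(seed)] + [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def phase_multiplier(ratio: float, phase: str) -> float:
    """G1 = 1, G2 = ratio, S = geometric midpoint sqrt(ratio)."""
    return {"G1": 1.0, "S": float(np.sqrt(ratio)), "G2": float(ratio)}[phase]


# ------------------------------------------------------------------ annotation

def generate_annotation(config: SimConfig) -> TSSAnnotation:
    """Place ``n_genes`` TSSs with >= ``gene_spacing`` bp spacing.

    Genes occupy distinct spacing-sized slots; the TSS sits at a
    bin-aligned random offset inside its slot, with a margin so promoter
    windows stay inside the slot. Raises if the genome cannot hold the
    requested genes.
    """
    spacing = config.gene_spacing
    slots_per_chrom = config.chrom_length // spacing
    capacity = slots_per_chrom * config.n_chrom
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if config.n_genes > capacity:
        raise ValueError(
            f"cannot place {config.n_genes} genes with {spacing} bp spacing: "
            f"capacity {capacity}")
    rng = _stream(config.seed, "annotation")
    chosen = np.sort(rng.choice(capacity, size=config.n_genes, replace=False))
    margin = 2_000
    lo_bin = margin // config.bin_size
    hi_bin = (spacing - margin) // config.bin_size
    offsets = rng.integers(lo_bin, hi_bin, size=config.n_genes) * config.bin_size
    strands = rng.choice(["+", "-"], size=config.n_genes)
    width = len(str(config.n_genes))
    rows = []
    for i, slot in enumerate(chosen):
        chrom = config.chrom_names[slot // slots_per_chrom]
        base = (slot % slots_per_chrom) * spacing
        rows.append((chrom, int(base + offsets[i]), strands[i],
                     f"gene{str(i + 1).zfill(width)}"))
    df = pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene_id"])
    df = df.sort_values(["chrom", "tss"]).reset_index(drop=True)
    return TSSAnnotation(df)


# --------------------------------------------------------------- fragment map

def generate_fragment_map(config: SimConfig) -> FragmentMap:
    """Geometric fragment lengths tiling each chromosome exactly."""
    rng = _stream(config.seed, "fragments")
    frames = {}
    for chrom in config.chrom_names:
        length = config.chrom_length
        n_guess = int(1.3 * length / config.frag_mean_len) + 10
        lens = rng.geometric(1.0 / config.frag_mean_len, size=n_guess)
        while lens.sum() < length:
            lens = np.concatenate([lens, rng.geometric(
                1.0 / config.frag_mean_len, size=n_guess)])
        ends = np.cumsum(lens)
        cut = int(np.searchsorted(ends, length, side="left"))
        ends = ends[: cut + 1].copy()
        ends[-1] = length
        starts = np.concatenate(([0], ends[:-1]))
        keep = ends > starts  # guard the degenerate final fragment
        starts, ends = starts[keep], ends[keep]
        frames[chrom] = pd.DataFrame({
            "index": np.arange(len(starts)),
            "start": starts.astype(int),
            "end": ends.astype(int),
        })
    return FragmentMap(frames)


# ----------------------------------------------------------------- truth base

def assign_groups(config: SimConfig, annotation: TSSAnnotation) -> pd.DataFrame:
    """Ground-truth table: one row per gene with its binding group."""
    rng = _stream(config.seed, "groups")
    genes = list(annotation.gene_ids)
    order = rng.permutation(len(genes))
    n_vcp = int(round(config.group_fractions["vcp"] * len(genes)))
    n_vonly = int(round(config.group_fractions["v_only"] * len(genes)))
    labels = np.array(["unbound"] * len(genes), dtype=object)
    labels[order[:n_vcp]] = "vcp"
    labels[order[n_vcp:n_vcp + n_vonly]] = "v_only"
    return pd.DataFrame({"gene_id": genes, "group": labels})


# ----------------------------------------------------------------------- ChIP

@dataclass
class ChipSim:
    tracks: dict            # (factor, phase) -> SignalTrack (raw coverage)
    inputs: dict            # phase -> SignalTrack (raw coverage)
    peaks: dict             # (factor, phase) -> PeakSet
    truth: pd.DataFrame     # gene_id, group, occ_<factor>_<phase>


def _occupancy_kernel(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular kernel of half-width ``kernel_half_width`` centred on the
    TSS, normalized to unit mass over 10-bp bins. Returns (bin offsets,
    weights)."""
    hw = config.kernel_half_width
    n = hw // config.bin_size
    offsets = np.arange(-n, n)
    centers = offsets * config.bin_size + config.bin_size / 2
    w = np.clip(1.0 - np.abs(centers) / hw, 0.0, None)
    return offsets, w / w.sum()


def simulate_chip(config: SimConfig, annotation: TSSAnnotation,
                  factors=None) -> ChipSim:
    """Poisson coverage tracks, matched inputs, peaks and the truth table.

    Bin values are fragment-coverage counts: the expected coverage of a bin
    is the local read rate times fragment_length/bin_size, and each library's
    expected read total equals ``depth`` (the background absorbs what the
    promoter occupancy does not use), so reads-per-million scaling is
    comparable across phases.
    """
    if factors is None:
        factors = list(FACTOR_SPECS)
    unknown = [f for f in factors if f not in FACTOR_SPECS]
    if unknown:
        raise ValueError(f"unknown factors: {unknown}")
    cov_scale = config.fragment_length / config.bin_size
    n_bins = {c: -(-config.chrom_length // config.bin_size)
              for c in config.chrom_names}
    total_bins = sum(n_bins.values())
    offsets, kernel = _occupancy_kernel(config)
    truth = assign_groups(config, annotation)
    group = dict(zip(truth["gene_id"], truth["group"]))
    ann = annotation.df

    tracks, peaks = {}, {}
    for factor in factors:
        bound_groups, ratio_attr = FACTOR_SPECS[factor]
        ratio = getattr(config, ratio_attr) if ratio_attr else 1.0
        bound = ann[ann["gene_id"].map(group).isin(bound_groups)]
        for phase in PHASES:
            mult = phase_multiplier(ratio, phase)
            occ = config.promoter_occupancy * mult
            total_occ = occ * len(bound)
            if total_occ >= config.depth:
                raise ValueError(
                    f"{factor}/{phase}: occupancy reads ({total_occ:.0f}) "
                    f"exceed depth {config.depth}")
            bg_rate = (config.depth - total_occ) * cov_scale / total_bins
            rate = {c: np.full(n_bins[c], bg_rate) for c in config.chrom_names}
            for row in bound.itertuples(index=False):
                b = row.tss // config.bin_size
                idx = b + offsets
                ok = (idx >= 0) & (idx < n_bins[row.chrom])
                rate[row.chrom][idx[ok]] += occ * cov_scale * kernel[ok]
            rng = _stream(config.seed, "chip", factor, phase)
            values = {c: rng.poisson(rate[c]) for c in config.chrom_names}
            tracks[(factor, phase)] = SignalTrack(
                values=values, chrom_sizes=config.chrom_sizes,
                bin_size=config.bin_size, factor=factor, phase=phase,
                library_size=config.depth)
            truth[f"occ_{factor}_{phase}"] = [
                occ if group[g] in bound_groups else 0.0
                for g in truth["gene_id"]]
            hw = config.kernel_half_width
            pk = pd.DataFrame({
                "chrom": bound["chrom"].to_numpy(),
                "start": np.maximum(bound["tss"].to_numpy() - hw, 0),
                "end": bound["tss"].to_numpy() + hw,
                "score": occ,
            })
            peaks[(factor, phase)] = PeakSet(pk, factor=factor, phase=phase)

    inputs = {}
    bg_rate = config.depth * cov_scale / total_bins
    for phase in PHASES:
        rng = _stream(config.seed, "chip", "input", phase)
        values = {c: rng.poisson(np.full(n_bins[c], bg_rate))
                  for c in config.chrom_names}
        inputs[phase] = SignalTrack(
            values=values, chrom_sizes=config.chrom_sizes,
            bin_size=config.bin_size, factor="input", phase=phase,
            library_size=config.depth)
    return ChipSim(tracks=tracks, inputs=inputs, peaks=peaks, truth=truth)


# -------------------------------------------------------------------- nascent

def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + phi mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def nascent_rate(config: SimConfig, group: str, phase: str,
                 genotype: str) -> float:
    """Ground-truth nascent mean for one gene class / phase / genotype."""
    if group == "unbound":
        return config.nascent_unbound_mean
    mult = {"G1": 1.0,
            "S": 1.0 / np.sqrt(config.nascent_g1_over_g2),
            "G2": 1.0 / config.nascent_g1_over_g2}[phase]
    mean = config.nascent_target_mean * mult
    if genotype == "KO":
        mean *= config.ko_derepression[phase]
    return float(mean)


def simulate_nascent(config: SimConfig, annotation: TSSAnnotation,
                     truth: pd.DataFrame) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """4sU-like promoter-window counts, phases x genotypes.

    Target genes obey ``nascent_g1_over_g2`` in the wild type; the knockout
    multiplies S/G2 means by ``ko_derepression``; unbound genes are
    phase-invariant. Returns the count matrix and the truth table augmented
    with the per-condition true rates.
    """
    truth = truth.copy()
    rng = _stream(config.seed, "nascent")
    genes = truth["gene_id"].to_numpy()
    groups = truth["group"].to_numpy()
    counts = {}
    meta = {}
    for genotype in ("WT", "KO"):
        for phase in PHASES:
            name = f"{phase}_{genotype}"
            means = np.array([nascent_rate(config, g, phase, genotype)
                              for g in groups])
            counts[name] = _negative_binomial(rng, means, config.nb_dispersion)
            meta[name] = {"phase": phase, "genotype": genotype,
                          "timepoint": "0h"}
            truth[f"nascent_{phase}_{genotype}"] = means
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id")),
        samples=pd.DataFrame(meta).T.rename_axis("sample"),
    )
    return matrix, truth


# -------------------------------------------------------------------- capture

CAPTURE_CONDITIONS = ("G1_WT", "G2_WT", "G1_KO", "G2_KO")


@dataclass
class CaptureSim:
    table: InteractionTable
    atac_peaks: PeakSet
    viewpoints: pd.DataFrame   # gene_id, chrom, frag_index
    truth: pd.DataFrame        # viewpoint_id, chrom, summit, side, distance,
                               # i_lo, i_hi
    expected: pd.DataFrame     # same rows as table.df plus 'expected' column


def _condition_enrichment(config: SimConfig, condition: str,
                          enrichment: float) -> np.ndarray:
    """Partner-triplet enrichment (shoulder, core, shoulder) per condition."""
    shoulder = np.sqrt(enrichment)
    triplet = np.array([shoulder, enrichment, shoulder])
    phase, genotype = condition.split("_")
    if genotype == "KO":
        return np.ones(3)
    if phase == "G2":
        return triplet * config.capture_g2_boost
    return triplet


def simulate_capture(config: SimConfig, annotation: TSSAnnotation,
                     fragmap: FragmentMap, truth: pd.DataFrame,
                     n_viewpoints: int = 25, partners_per_viewpoint: int = 4,
                     window: int = 500, min_dist: int = 150,
                     max_dist: int = 450, enrichment: float = 3.0,
                     depth: int | None = None) -> CaptureSim:
    """Fragment-level capture counts around polycomb-target viewpoints.

    Expected counts decay as C * d^(-alpha) with fragment separation d; each
    viewpoint carries homotypic partner triplets (summit and two shoulders)
    whose expected counts are background x enrichment, multiplied by
    ``capture_g2_boost`` in G2 and reset to background in the knockout.
    Interaction scores are a monotone function of the expected enrichment,
    equal to the cutoff (5) exactly at true interaction fragments in the
    wild type. Partner distances avoid each other's mirror sites so
    distance-matched control windows stay at pure background. On genomes
    too small for the requested window, the window, partner distances and
    partner count shrink together so that every chromosome keeps at least
    two eligible viewpoints.
    """
    depth = depth or config.depth
    rng = _stream(config.seed, "capture")
    vcp_genes = set(truth.loc[truth["group"] == "vcp", "gene_id"])
    candidates = []
    for row in annotation.df.itertuples(index=False):
        if row.gene_id not in vcp_genes:
            continue
        frag = fragmap.locate(row.chrom, row.tss)
        candidates.append((row.gene_id, row.chrom, frag,
                           fragmap.n_fragments(row.chrom)))

    # the window can shrink to the largest value that still leaves >= 2
    # eligible viewpoints on every chromosome (second-best edge margin)
    margins: dict[str, list[int]] = {c: [] for c in config.chrom_names}
    for _gene, chrom, frag, n_frag in candidates:
        margins[chrom].append(min(frag, n_frag - 1 - frag))
    if any(len(m) < 2 for m in margins.values()):
        raise ValueError("need >= 2 eligible viewpoint promoters per "
                         "chromosome")
    feasible = min(sorted(m, reverse=True)[1] for m in margins.values())
    window = min(window, feasible)
    if window < 50:
        raise ValueError("need >= 2 eligible viewpoint promoters per "
                         "chromosome (viewpoints too close to chromosome "
                         "ends)")
    by_chrom = {c: [] for c in config.chrom_names}
    for gene_id, chrom, frag, n_frag in candidates:
        if window <= frag < n_frag - window:
            by_chrom[chrom].append((gene_id, chrom, frag))
    if window < max_dist + 42:
        max_dist = window - 45
        min_dist = min(min_dist, max(15, max_dist // 4))
        if max_dist <= min_dist:
            raise ValueError("chromosomes too short for capture simulation")
        partners_per_viewpoint = max(
            1, min(partners_per_viewpoint, (max_dist - min_dist) // 46))
    # round-robin across chromosomes so every chromosome keeps >= 2
    vps = []
    rank = 0
    while len(vps) < n_viewpoints:
        added = False
        for c in config.chrom_names:
            if rank < len(by_chrom[c]) and len(vps) < n_viewpoints:
                vps.append(by_chrom[c][rank])
                added = True
        if not added:
            break
        rank += 1
    if len(vps) < min(n_viewpoints, 2):
        raise ValueError("not enough eligible viewpoints")
    viewpoints = pd.DataFrame(vps, columns=["gene_id", "chrom", "frag_index"])

    alpha = config.capture_decay_alpha
    offsets = np.arange(-window, window + 1)
    decay = np.abs(offsets).astype(float)
    decay[window] = 1.0  # viewpoint fragment: same rate as d = 1
    decay = decay ** (-alpha)
    # background scale: expected background reads per condition ~ depth
    c_scale = depth / (len(vps) * decay.sum())
    if max_dist + 42 > window:
        raise ValueError("max_dist + metaprofile span must fit inside the "
                         "simulated window")
    shoulder = np.sqrt(enrichment)
    # partner triplets must stay out of every other partner's metaprofile
    # and mirrored control window (span 40 plus the triplet width)
    margin = 45

    truth_rows = []
    table_rows = []
    atac_rows = []
    # stratified distances: one partner per stratum of [min_dist, max_dist],
    # jittered within the stratum minus the exclusion margin, so any two
    # partner distances differ by > margin by construction
    p = partners_per_viewpoint
    width = (max_dist - min_dist) // p
    if width <= margin:
        raise ValueError("partner strata narrower than the exclusion margin")
    for gene_id, chrom, vp_frag in vps:
        jitter = rng.integers(0, width - margin, size=p)
        dists = [int(min_dist + k * width + jitter[k]) for k in range(p)]
        sides = rng.choice([-1, 1], size=p)
        enrich = {cond: np.ones(len(offsets)) for cond in CAPTURE_CONDITIONS}
        for d, side in zip(dists, sides):
            center = window + side * d
            for cond in CAPTURE_CONDITIONS:
                enrich[cond][center - 1: center + 2] = _condition_enrichment(
                    config, cond, enrichment)
            summit_frag = vp_frag + side * d
            truth_rows.append({
                "viewpoint_id": gene_id, "chrom": chrom,
                "summit": summit_frag, "side": int(side), "distance": d,
                "i_lo": summit_frag - 1, "i_hi": summit_frag + 1,
            })
            lo_start, _ = fragmap.interval(chrom, summit_frag - 1)
            _, hi_end = fragmap.interval(chrom, summit_frag + 1)
            atac_rows.append({"chrom": chrom, "start": lo_start,
                              "end": hi_end, "score": 1.0})
        # decoy accessible sites at pure-background fragments
        for _ in range(2):
            d = int(rng.integers(min_dist, max_dist + 1))
            side = int(rng.choice([-1, 1]))
            if any(abs(d - d0) <= margin for d0 in dists):
                continue
            frag = vp_frag + side * d
            s, e = fragmap.interval(chrom, frag)
            atac_rows.append({"chrom": chrom, "start": s, "end": e,
                              "score": 0.5})

        frag_idx = vp_frag + offsets
        starts_ends = fragmap.frames[chrom]
        f_start = starts_ends["start"].to_numpy()[frag_idx]
        f_end = starts_ends["end"].to_numpy()[frag_idx]
        for cond in CAPTURE_CONDITIONS:
            expected = c_scale * decay * enrich[cond]
            counts = rng.poisson(expected)
            e_vals = enrich[cond]
            score = np.where(
                e_vals > 1.0,
                5.0 * np.log(np.maximum(e_vals, 1.0)) / np.log(shoulder),
                0.0)
            score[window] = 0.0  # the viewpoint fragment itself
            table_rows.append(pd.DataFrame({
                "viewpoint_id": gene_id, "chrom": chrom,
                "frag_index": frag_idx, "frag_start": f_start,
                "frag_end": f_end, "condition": cond,
                "counts": counts, "score": score,
                "expected": expected,
            }))
    df = pd.concat(table_rows, ignore_index=True)
    table = InteractionTable(df.drop(columns="expected"))
    atac = PeakSet(pd.DataFrame(atac_rows), factor="ATAC")
    return CaptureSim(table=table, atac_peaks=atac, viewpoints=viewpoints,
                      truth=pd.DataFrame(truth_rows), expected=df)


# ------------------------------------------------------------ RA differentiation

RA_TREATMENTS = ("0h", "6h_UNT", "6h_IAA")


@dataclass
class RASim:
    matrix: ExpressionMatrix
    de_table: pd.DataFrame
    truth: pd.DataFrame     # truth with the ra_cluster column
    contrasts: list         # the treatment contrasts feeding the DE filter


def assign_ra_clusters(config: SimConfig, truth: pd.DataFrame,
                       cluster_sizes: dict[str, int] | None = None
                       ) -> pd.DataFrame:
    """Attach RA-response cluster labels to the truth table.

    Cluster II (IAA-derepressed; sub-clusters II-A/II-B) is drawn from
    polycomb target genes, clusters I (RA-induced) and III (RA-repressed)
    from unbound genes; the remainder is labelled none.
    """
    truth = truth.copy()
    rng = _stream(config.seed, "ra_clusters")
    targets = truth.index[truth["group"].isin(["vcp", "v_only"])].to_numpy()
    unbound = truth.index[truth["group"] == "unbound"].to_numpy()
    if cluster_sizes is None:
        cluster_sizes = {
            "II-A": len(targets) // 2,
            "II-B": len(targets) - len(targets) // 2,
            "I": len(unbound) // 3,
            "III": len(unbound) // 3,
        }
    need_t = cluster_sizes.get("II-A", 0) + cluster_sizes.get("II-B", 0)
    need_u = cluster_sizes.get("I", 0) + cluster_sizes.get("III", 0)
    if need_t > len(targets) or need_u > len(unbound):
        raise ValueError("cluster sizes exceed available genes")
    targets = rng.permutation(targets)
    unbound = rng.permutation(unbound)
    labels = pd.Series("none", index=truth.index, dtype=object)
    n_a = cluster_sizes.get("II-A", 0)
    labels[targets[:n_a]] = "II-A"
    labels[targets[n_a:need_t]] = "II-B"
    n_i = cluster_sizes.get("I", 0)
    labels[unbound[:n_i]] = "I"
    labels[unbound[n_i:need_u]] = "III"
    truth["ra_cluster"] = labels
    return truth


def _ra_mean(base: float, cluster: str, phase: str, treatment: str,
             effect: float, phase_effect: float) -> float:
    """Expected count for one gene class / phase / treatment."""
    if cluster == "I":
        return base * (effect if treatment != "0h" else 1.0)
    if cluster == "III":
        return base / (effect if treatment != "0h" else 1.0)
    if cluster in ("II-A", "II-B"):
        if treatment == "0h":
            return base
        if treatment == "6h_IAA":
            return base * np.sqrt(effect) * effect
        # 6h_UNT: partial induction; II-A additionally prefers G1
        mean = base * np.sqrt(effect)
        if cluster == "II-A":
            mean *= {"G1": phase_effect,
                     "S": np.sqrt(phase_effect),
                     "G2": 1.0}[phase]
        return mean
    return base


def simulate_ra_expression(config: SimConfig, truth: pd.DataFrame,
                           cluster_sizes: dict[str, int] | None = None,
                           n_rep: int = 3, base_mean: float = 200.0,
                           effect: float = 4.0,
                           phase_effect: float | None = None) -> RASim:
    """RA-differentiation counts (phases x 0h/6h-UNT/6h-IAA) and DE tables.

    Multiplicative structure: cluster I is RA-induced (x effect at 6 h under
    both treatments); cluster II is partially induced (x sqrt(effect) in
    6h-UNT) and amplified by IAA (x effect on top), with II-A additionally
    G1 > S > G2 in 6h-UNT (x phase_effect in G1, geometric midpoint in S;
    defaults to the same fold change as ``effect``); cluster III is
    RA-repressed (/ effect). Per-contrast log2FC/FDR tables are computed
    from the simulated replicate counts (Welch t on log2(count+1), BH
    within contrast).
    """
    if phase_effect is None:
        phase_effect = effect
    if "ra_cluster" not in truth.columns:
        truth = assign_ra_clusters(config, truth, cluster_sizes)
    rng = _stream(config.seed, "ra_expression")
    clusters = truth["ra_cluster"].to_numpy()
    genes = truth["gene_id"].to_numpy()

    counts = {}
    meta = {}
    for phase in PHASES:
        for treatment in RA_TREATMENTS:
            means = np.array([
                _ra_mean(base_mean, c, phase, treatment, effect, phase_effect)
                for c in clusters])
            for rep in range(1, n_rep + 1):
                name = f"{phase}_{treatment}_r{rep}"
                counts[name] = _negative_binomial(rng, means,
                                                  config.nb_dispersion)
                meta[name] = {"phase": phase, "treatment": treatment,
                              "timepoint": treatment.split("_")[0],
                              "replicate": rep}
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id")),
        samples=pd.DataFrame(meta).T.rename_axis("sample"),
    )

    def cols(phase, treatment):
        return [f"{phase}_{treatment}_r{r}" for r in range(1, n_rep + 1)]

    def contrast_stats(cols_a, cols_b):
        """log2FC of b over a, Welch-t p on log2(count + 1)."""
        a = np.log2(matrix.counts[cols_a].to_numpy(dtype=float) + 1.0)
        b = np.log2(matrix.counts[cols_b].to_numpy(dtype=float) + 1.0)
        log2fc = b.mean(axis=1) - a.mean(axis=1)
        _, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        return log2fc, bh_fdr(p)

    de_rows = []
    contrasts = []
    for phase in PHASES:
        for treatment in ("6h_UNT", "6h_IAA"):
            name = f"{phase}_0h_vs_{treatment}"
            contrasts.append(name)
            fc, fdr = contrast_stats(cols(phase, "0h"),
                                     cols(phase, treatment))
            de_rows.append(pd.DataFrame({
                "contrast": name, "gene_id": genes,
                "log2fc": fc, "fdr": fdr}))
    # ranking contrast: G1 over G2 at 6 h untreated
    fc, fdr = contrast_stats(cols("G2", "6h_UNT"), cols("G1", "6h_UNT"))
    de_rows.append(pd.DataFrame({
        "contrast": "G1_vs_G2_6h_UNT", "gene_id": genes,
        "log2fc": fc, "fdr": fdr}))
    de_table = pd.concat(de_rows, ignore_index=True)
    return RASim(matrix=matrix, de_table=de_table, truth=truth,
                 contrasts=contrasts)
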