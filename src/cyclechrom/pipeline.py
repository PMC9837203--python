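"""Stage orchestration: simulate -> chip -> targets -> capture -> nascent -> ra.

Each stage is a function from input paths to written TSV/BED outputs; the
``run_pipeline`` driver chains them in dependency order, writes a run log
(package version, seed, thresholds, outputs) and aborts on the first stage
error naming the stage and cause. All outputs are deterministic given the
inputs and the seed, so re-running on identical inputs reproduces files
byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import capture as cap
from . import chip
from . import expression as expr
from . import io as cio
from . import simulate as sim
from . import targets as tg
from .config import PipelineConfig, SimConfig
from .core import PHASES

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _require(paths: dict, key: str) -> Path:
    if key not in paths:
        raise FileNotFoundError(f"missing input path for {key!r}")
    p = Path(paths[key])
    if not p.exists():
        raise FileNotFoundError(f"input path does not exist: {p} ({key})")
    return p


def _read_chrom_sizes(path: Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"]))


# ------------------------------------------------------------------- simulate

def stage_simulate(sim_config: SimConfig, outdir: Path,
                   factors=None) -> dict[str, str]:
    """Generate all synthetic inputs and write them; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    annotation = sim.generate_annotation(sim_config)
    cio.write_tss_table(annotation, outdir / "annotation.bed")
    paths["annotation"] = str(outdir / "annotation.bed")

    sizes = pd.DataFrame(sorted(sim_config.chrom_sizes.items()))
    sizes.to_csv(outdir / "chrom_sizes.tsv", sep="\t", header=False,
                 index=False)
    paths["chrom_sizes"] = str(outdir / "chrom_sizes.tsv")

    fragmap = sim.generate_fragment_map(sim_config)
    cio.write_fragment_map(fragmap, outdir / "fragments.bed")
    paths["fragments"] = str(outdir / "fragments.bed")

    chip_sim = sim.simulate_chip(sim_config, annotation, factors=factors)
    track_dir = outdir / "tracks"
    track_dir.mkdir(exist_ok=True)
    lib_rows = []
    for (factor, phase), track in sorted(chip_sim.tracks.items()):
        name = f"chip_{factor}_{phase}.bedgraph"
        cio.write_bedgraph(track, track_dir / name)
        lib_rows.append((name, track.library_size))
    for phase, track in sorted(chip_sim.inputs.items()):
        name = f"input_{phase}.bedgraph"
        cio.write_bedgraph(track, track_dir / name)
        lib_rows.append((name, track.library_size))
    pd.DataFrame(lib_rows).to_csv(track_dir / "library_sizes.tsv", sep="\t",
                                  header=False, index=False)
    paths["track_dir"] = str(track_dir)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (factor, phase), pk in sorted(chip_sim.peaks.items()):
        cio.write_peaks(pk, peak_dir / f"peaks_{factor}_{phase}.bed")
    paths["peaks_dir"] = str(peak_dir)

    nascent_mat, truth = sim.simulate_nascent(sim_config, annotation,
                                              chip_sim.truth)
    cio.write_counts(nascent_mat, outdir / "nascent_counts.tsv",
                     outdir / "nascent_samples.tsv")
    paths["nascent_counts"] = str(outdir / "nascent_counts.tsv")
    paths["nascent_samples"] = str(outdir / "nascent_samples.tsv")

    capture_sim = sim.simulate_capture(sim_config, annotation, fragmap, truth)
    cio.write_interaction_table(capture_sim.table, outdir / "interactions.tsv")
    cio.write_peaks(capture_sim.atac_peaks, outdir / "atac_peaks.bed")
    cio.write_tsv(capture_sim.viewpoints, outdir / "viewpoints.tsv")
    paths["interactions"] = str(outdir / "interactions.tsv")
    paths["atac_peaks"] = str(outdir / "atac_peaks.bed")
    paths["viewpoints"] = str(outdir / "viewpoints.tsv")

    ra_sim = sim.simulate_ra_expression(sim_config, truth)
    cio.write_counts(ra_sim.matrix, outdir / "ra_counts.tsv",
                     outdir / "ra_samples.tsv")
    cio.write_de_table(ra_sim.de_table, outdir / "ra_de.tsv")
    paths["ra_counts"] = str(outdir / "ra_counts.tsv")
    paths["ra_samples"] = str(outdir / "ra_samples.tsv")
    paths["ra_de"] = str(outdir / "ra_de.tsv")

    cio.write_tsv(ra_sim.truth, outdir / "truth.tsv")
    paths["truth"] = str(outdir / "truth.tsv")
    return paths


# ----------------------------------------------------------------------- chip

def _discover_tracks(track_dir: Path) -> tuple[dict, dict]:
    chips, inputs = {}, {}
    for p in sorted(track_dir.glob("chip_*_*.bedgraph")):
        stem = p.stem[len("chip_"):]
        factor, phase = stem.rsplit("_", 1)
        chips[(factor, phase)] = p
    for p in sorted(track_dir.glob("input_*.bedgraph")):
        inputs[p.stem[len("input_"):]] = p
    return chips, inputs


def stage_chip(paths: dict, pconf: PipelineConfig, outdir: Path,
               library_sizes: dict | None = None) -> dict[str, str]:
    """Normalized promoter signal, G2 ranking, average profiles, ANOVA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = cio.read_tss_table(_require(paths, "annotation"))
    sizes = _read_chrom_sizes(_require(paths, "chrom_sizes"))
    track_dir = Path(_require(paths, "track_dir"))
    chips, inputs = _discover_tracks(track_dir)
    libs = dict(library_sizes or {})
    lib_file = track_dir / "library_sizes.tsv"
    if lib_file.exists():
        lf = pd.read_csv(lib_file, sep="\t", header=None,
                         names=["file", "reads"])
        libs.update(zip(lf["file"], lf["reads"]))

    def _load(path, **meta):
        track = cio.read_bedgraph(path, sizes, bin_size=pconf.bin_size, **meta)
        lib = libs.get(Path(path).name)
        if lib is None:
            # last resort: treat total coverage as the read count; RPM stays
            # comparable across tracks of equal fragment length
            lib = int(sum(v.sum() for v in track.values.values())) or 1
        track.library_size = int(lib)
        return track

    factors = sorted({f for f, _ in chips})
    out_paths: dict[str, str] = {}
    anova_rows = []
    profile_rows = []
    signal_frames = {}
    for factor in factors:
        promoter = {}
        for phase in PHASES:
            if (factor, phase) not in chips:
                continue
            raw = _load(chips[(factor, phase)], factor=factor, phase=phase)
            inp = _load(inputs[phase], factor="input", phase=phase)
            norm = chip.normalize_track(raw, inp)
            promoter[phase] = chip.promoter_coverage(
                norm, annotation, pconf.promoter_window)
            prof = chip.profile_matrix(norm, annotation,
                                       span=pconf.profile_span)
            curve = chip.average_profile(prof)
            profile_rows.append(pd.DataFrame({
                "factor": factor, "phase": phase,
                "position": prof.positions(), "mean": curve}))
        sig = pd.DataFrame(promoter)
        sig.index.name = "gene_id"
        signal_frames[factor] = sig
        f_stat, p = chip.profile_anova(promoter)
        anova_rows.append({"factor": factor, "F": f_stat, "pval": p})
        if "G2" in promoter and "G1" in promoter:
            sig["log2fc_G2_G1"] = chip.promoter_log2fc(
                promoter["G2"], promoter["G1"], pconf.pseudocount)
        order = chip.rank_by_reference(
            promoter, "G2" if "G2" in promoter else list(promoter)[0])
        rank_path = outdir / f"rank_{factor}.txt"
        rank_path.write_text("".join(f"{g}\n" for g in order))
        sig_path = outdir / f"promoter_signal_{factor}.tsv"
        cio.write_tsv(sig.reset_index(), sig_path)
        out_paths[f"promoter_signal_{factor}"] = str(sig_path)
        out_paths[f"rank_{factor}"] = str(rank_path)
    cio.write_tsv(pd.DataFrame(anova_rows), outdir / "anova.tsv")
    cio.write_tsv(pd.concat(profile_rows, ignore_index=True),
                  outdir / "average_profiles.tsv")
    out_paths["anova"] = str(outdir / "anova.tsv")
    out_paths["average_profiles"] = str(outdir / "average_profiles.tsv")
    return out_paths


# -------------------------------------------------------------------- targets

def stage_targets(paths: dict, pconf: PipelineConfig,
                  outdir: Path) -> dict[str, str]:
    """Per-factor target sets, PRC classes and overlap report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = cio.read_tss_table(_require(paths, "annotation"))
    peak_dir = _require(paths, "peaks_dir")
    peaks = {}
    for p in sorted(Path(peak_dir).glob("peaks_*_*.bed")):
        stem = p.stem[len("peaks_"):]
        factor, phase = stem.rsplit("_", 1)
        peaks[(factor, phase)] = cio.read_peaks(p, factor=factor, phase=phase)
    hc = (cio.read_gene_list(paths["hc_bivalent"])
          if "hc_bivalent" in paths else set())
    ts = tg.TargetSets.from_peaks(peaks, annotation,
                                  window=pconf.promoter_window,
                                  hc_bivalent=hc)
    genes = annotation.gene_ids
    flags = pd.DataFrame({"gene_id": genes})
    for name in ("ring1b_targets", "rybp_targets", "cbx7_targets",
                 "ezh2_targets", "vcp_targets", "v_only_targets"):
        member = getattr(ts, name)
        flags[name] = [int(g in member) for g in genes]
    cio.write_tsv(flags, outdir / "target_classes.tsv")

    rows = []
    if ts.hc_bivalent:
        rep = tg.overlap_fraction(ts.hc_bivalent, ts.ring1b_targets)
        rows.append({"a": "hc_bivalent", "b": "ring1b_targets",
                     "n_a": rep.n_a, "n_overlap": rep.n_intersection,
                     "pct_rounded": rep.percent_rounded,
                     "pct_display": rep.percent_truncated})
    if ts.rybp_targets:
        rep = tg.overlap_fraction(ts.rybp_targets, ts.ring1b_targets)
        rows.append({"a": "rybp_targets", "b": "ring1b_targets",
                     "n_a": rep.n_a, "n_overlap": rep.n_intersection,
                     "pct_rounded": rep.percent_rounded,
                     "pct_display": rep.percent_truncated})
    cio.write_tsv(pd.DataFrame(rows), outdir / "overlap_report.tsv")
    return {"target_classes": str(outdir / "target_classes.tsv"),
            "overlap_report": str(outdir / "overlap_report.tsv")}


# -------------------------------------------------------------------- capture

def stage_capture(paths: dict, pconf: PipelineConfig,
                  outdir: Path) -> dict[str, str]:
    """Interaction calling, metaprofiles, controls and group comparison."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cio.read_interaction_table(_require(paths, "interactions"))
    atac = cio.read_peaks(_require(paths, "atac_peaks"), factor="ATAC")
    fragmap = cio.read_fragment_map(_require(paths, "fragments"))
    viewpoints = pd.read_csv(_require(paths, "viewpoints"), sep="\t")

    interactions = cap.call_interactions(
        table, atac, fragmap, viewpoints, score_cutoff=pconf.score_cutoff)
    conditions = table.conditions()
    norms = {c: cap.normalization_from_table(table, c) for c in conditions}
    rows = []
    for inter in interactions:
        row = {"viewpoint_id": inter.viewpoint_id, "chrom": inter.chrom,
               "i_lo": inter.i_lo, "i_hi": inter.i_hi,
               "summit": inter.summit, "distance": inter.distance,
               "side": inter.side}
        for cond in conditions:
            s_counts, s_scores = cap.sum_interval_counts(
                inter, table, cond, norms[cond])
            row[f"sum_normcounts_{cond}"] = s_counts
            row[f"sum_scores_{cond}"] = s_scores
        rows.append(row)
    catalogue = pd.DataFrame(rows)
    cio.write_tsv(catalogue, outdir / "interactions_called.tsv")

    span = pconf.metaprofile_span
    meta = cap.build_metaprofile(interactions, table, fragmap,
                                 conditions=conditions, span=span)
    ctrl = cap.distance_matched_controls(interactions, table, fragmap,
                                         conditions=conditions, span=span)
    frames = []
    for cond, mp in list(meta.items()) + list(ctrl.items()):
        frames.append(pd.DataFrame({
            "condition": cond, "control": int(mp.control),
            "position": mp.positions, "mean": mp.mean, "sem": mp.sem,
            "n": mp.n}))
    cio.write_tsv(pd.concat(frames, ignore_index=True),
                  outdir / "metaprofiles.tsv")

    comp_rows = []
    for cond in conditions:
        sums = [r[f"sum_normcounts_{cond}"] for r in rows]
        ctrl_sums = cap.control_interval_sums(interactions, table, cond,
                                              norms[cond])
        if sums and ctrl_sums:
            res = cap.compare_interaction_groups(sums, ctrl_sums)
            res["condition"] = cond
            comp_rows.append(res)
    cio.write_tsv(pd.DataFrame(comp_rows), outdir / "comparison.tsv")
    return {"interactions_called": str(outdir / "interactions_called.tsv"),
            "metaprofiles": str(outdir / "metaprofiles.tsv"),
            "comparison": str(outdir / "comparison.tsv")}


# -------------------------------------------------------------------- nascent

def stage_nascent(paths: dict, pconf: PipelineConfig, outdir: Path,
                  target_classes: pd.DataFrame | None = None) -> dict[str, str]:
    """Nascent RPM, repression box statistics and MA fractions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = cio.read_counts(_require(paths, "nascent_counts"),
                             _require(paths, "nascent_samples"))
    rpm = expr.nascent_rpm(matrix)
    cio.write_tsv(rpm.reset_index(), outdir / "nascent_rpm.tsv")

    if target_classes is None and "target_classes" in paths:
        target_classes = pd.read_csv(paths["target_classes"], sep="\t")
    out = {"nascent_rpm": str(outdir / "nascent_rpm.tsv")}
    if target_classes is None:
        return out
    bound = set(target_classes.loc[
        (target_classes["ring1b_targets"] == 1)
        & (target_classes["rybp_targets"] == 1), "gene_id"])

    def wt_col(phase):
        cols = matrix.samples_where(phase=phase, genotype="WT")
        return rpm[cols].mean(axis=1)

    g1, g2 = wt_col("G1"), wt_col("G2")
    log2fc = np.log2((g1 + pconf.pseudocount) / (g2 + pconf.pseudocount))
    union = set(target_classes.loc[
        target_classes[[c for c in target_classes.columns
                        if c.endswith("_targets")]].sum(axis=1) > 0,
        "gene_id"])
    controls = tg.select_unbound_controls(rpm.index, union, log2fc,
                                          band=pconf.unbound_band)
    groups = {}
    for phase in PHASES:
        vals = wt_col(phase)
        if bound:
            groups[f"bound_{phase}"] = vals.loc[sorted(bound)].to_numpy()
        if controls:
            groups[f"control_{phase}"] = vals.loc[sorted(controls)].to_numpy()
    stats_df, pmat = expr.group_boxstats(groups)
    cio.write_tsv(stats_df.reset_index(names="group"),
                  outdir / "nascent_boxstats.tsv")
    cio.write_tsv(pmat.reset_index(names="group"),
                  outdir / "nascent_mw_pvalues.tsv")

    ma_rows = []
    for name, genes in (("bound", bound), ("control", controls)):
        if not genes:
            continue
        idx = sorted(genes)
        _, summary = expr.ma_stats(g1.loc[idx], g2.loc[idx],
                                   threshold=pconf.ma_threshold,
                                   pseudocount=pconf.pseudocount)
        summary["group"] = name
        ma_rows.append(summary)
    cio.write_tsv(pd.DataFrame(ma_rows), outdir / "ma_report.tsv")
    out.update({
        "nascent_boxstats": str(outdir / "nascent_boxstats.tsv"),
        "nascent_mw_pvalues": str(outdir / "nascent_mw_pvalues.tsv"),
        "ma_report": str(outdir / "ma_report.tsv"),
    })
    return out


# ------------------------------------------------------------------------- ra

def stage_ra(paths: dict, pconf: PipelineConfig, outdir: Path) -> dict[str, str]:
    """DE filter, TMM, geometric-mean ratios, clustering and GSEA."""
    from .stats import gsea_batch

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = cio.read_counts(_require(paths, "ra_counts"),
                             _require(paths, "ra_samples"))
    de = cio.read_de_table(_require(paths, "ra_de"))
    treatment_contrasts = [c for c in de["contrast"].unique()
                           if "0h_vs" in c]
    de_genes = expr.select_de_genes(de, fc_cutoff=pconf.de_fc_cutoff,
                                    fdr_cutoff=pconf.de_fdr_cutoff,
                                    contrasts=treatment_contrasts)
    cio.write_gene_list(de_genes, outdir / "de_genes.txt")
    if len(de_genes) < 4:
        raise PipelineError("too few differentially expressed genes to cluster")
    norm = expr.tmm_normalized(matrix.counts)
    ratios = expr.relative_to_geomean(norm.loc[sorted(de_genes)])
    labels = expr.ra_cluster_labels(ratios, matrix.samples)
    cio.write_tsv(labels.rename("cluster").rename_axis("gene_id").reset_index(),
                  outdir / "clusters.tsv")

    rank_contrast = [c for c in de["contrast"].unique() if "G1_vs_G2" in c]
    gsea_path = None
    if rank_contrast:
        sub = de[de["contrast"] == rank_contrast[0]]
        ranking = pd.Series(sub["log2fc"].to_numpy(),
                            index=sub["gene_id"].to_numpy())
        gene_sets = {}
        for lab in sorted(labels.unique()):
            members = set(labels.index[labels == lab])
            if lab.startswith("II-"):
                gene_sets.setdefault("II", set()).update(members)
            gene_sets[lab] = members
        gsea = gsea_batch(ranking, gene_sets, n_perm=pconf.gsea_n_perm,
                          seed=pconf.seed)
        cio.write_tsv(gsea, outdir / "gsea.tsv")
        gsea_path = str(outdir / "gsea.tsv")
    out = {"de_genes": str(outdir / "de_genes.txt"),
           "clusters": str(outdir / "clusters.tsv")}
    if gsea_path:
        out["gsea"] = gsea_path
    return out


# --------------------------------------------------------------------- driver

STAGES = ("simulate", "chip", "targets", "capture", "nascent", "ra")


def run_pipeline(pconf: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages in dependency order; returns the output-path report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = dict(pconf.paths)
    report: dict = {"version": __version__, "seed": pconf.seed, "stages": {}}
    sim_factors = None
    sim_dict = dict(pconf.simulate) if pconf.simulate else None
    if sim_dict is not None:
        sim_factors = sim_dict.pop("factors", None)

    def _run(stage: str, fn, *args):
        try:
            result = fn(*args)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        report["stages"][stage] = result
        return result

    if sim_dict is not None:
        sim_config = SimConfig.from_dict(sim_dict)
        produced = _run("simulate", stage_simulate, sim_config,
                        outdir / "sim", sim_factors)
        paths.update(produced)
    chip_out = _run("chip", stage_chip, paths, pconf, outdir / "chip")
    targets_out = _run("targets", stage_targets, paths, pconf,
                       outdir / "targets")
    paths.update(targets_out)
    _run("capture", stage_capture, paths, pconf, outdir / "capture")
    _run("nascent", stage_nascent, paths, pconf, outdir / "nascent")
    _run("ra", stage_ra, paths, pconf, outdir / "ra")
    report["stages"]["chip"] = chip_out

    def _relativize(obj):
        if isinstance(obj, dict):
            return {k: _relativize(v) for k, v in obj.items()}
        if isinstance(obj, str):
            try:
                return str(Path(obj).relative_to(outdir))
            except ValueError:
                return obj
        return obj

    log = {
        "version": __version__,
        "seed": pconf.seed,
        "thresholds": {
            "promoter_window": list(pconf.promoter_window),
            "profile_span": pconf.profile_span,
            "bin_size": pconf.bin_size,
            "trim_percentiles": [pconf.trim_low, pconf.trim_high],
            "nascent_window": list(pconf.nascent_window),
            "score_cutoff": pconf.score_cutoff,
            "metaprofile_span": pconf.metaprofile_span,
            "de_fc_cutoff": pconf.de_fc_cutoff,
            "de_fdr_cutoff": pconf.de_fdr_cutoff,
            "ma_threshold": pconf.ma_threshold,
            "unbound_band": pconf.unbound_band,
            "pseudocount": pconf.pseudocount,
        },
        "stages": _relativize(report["stages"]),
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return report
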