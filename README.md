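# cyclechrom

Cell-cycle-phase-resolved analysis of polycomb chromatin regulation.

Polycomb repressive complexes (PRC1/PRC2) keep developmental genes silent in
embryonic stem cells. The catalytic PRC1 subunit RING1B stays bound to its
target promoters throughout interphase, yet the repressive output of the
system — occupancy of the variant-PRC1 subunit RYBP and the canonical-PRC1
subunit CBX7, the H2AK119ub1 mark, promoter–promoter 3D contacts, and
transcriptional shut-down of nascent RNA — strengthens as cells progress
from G1 through S into G2. `cyclechrom` implements the quantitative pipeline
needed to measure that phase dependence, for anyone analysing cell-cycle
sorted (FUCCI) ChIP-seq, Capture-C, 4sU-seq and differentiation RNA-seq
data, together with a synthetic-data generator that provides ground truth
for every estimator.

## What it computes

**ChIP promoter signal per phase** (`cyclechrom.chip`). Tracks are
bamCompare-style: per-10-bp-bin coverage scaled to reads per million (RPM)
minus the matched input. Promoter signal of gene *g* in phase *p* is the
mean normalized value over the strand-aware window [−500, +1500) bp around
the TSS; phases are compared by one-way ANOVA over per-gene promoter means
and by per-gene log₂((x_G2 + c)/(x_G1 + c)) with pseudocount c = 0.5 RPM.
TSS-centred ±10 kb profile matrices support 5th/95th-percentile winsorized
heatmaps ranked by G2 signal.

**Target classes** (`cyclechrom.targets`). A promoter is a factor target if
any peak overlaps its window by ≥ 1 bp (union over phases). Classes follow
complex composition: vPRC1/cPRC1/PRC2 = RING1B ∩ RYBP ∩ CBX7 ∩ EZH2;
vPRC1-only = (RING1B ∩ RYBP) − (CBX7 ∪ EZH2); controls are unbound genes
with |log₂FC(G1/G2)| < 0.2 in nascent RNA. Overlap percentages are
reported both rounded and truncated to one decimal (the display convention
under which 1575/1678 prints as 93.8%).

**Capture-C metaprofiles** (`cyclechrom.capture`). Pooled per-DpnII-fragment
counts are scaled as normCounts = raw · nprom · 100,000 / cov (cov = reads
at captured promoters, nprom = captured promoters). Interactions are
maximal runs of consecutive fragments with interaction score ≥ 5 that
overlap ATAC-accessible regions; each is anchored at its summit (maximal
G2 normCounts), every condition is divided by the interaction's G2 summit
value, and ±40-fragment windows are flipped so positive positions point
toward the viewpoint promoter. Distance-matched controls mirror each summit
to the opposite side of the viewpoint.

**Nascent RNA and RA differentiation** (`cyclechrom.expression`).
Promoter-proximal (TSS→+3 kb) 4sU RPM, box statistics with Mann–Whitney
tests, MA up/down fractions (|FC| > 1.2), the differential-expression
filter (|FC| > 2 and FDR < 0.05, union over contrasts), TMM normalization,
expression relative to each gene's geometric mean, correlation-distance
average-linkage clustering into response clusters I/II(II-A/II-B)/III, and
preranked GSEA (ES from the weighted running sum, NES and p from seeded
gene-label permutations, BH FDR across gene sets).

**Synthetic data** (`cyclechrom.simulate`). Poisson coverage tracks with a
triangular promoter occupancy kernel (RING1B flat across phases;
RYBP/CBX7/H2AK119ub1 three-fold higher in G2, S at the geometric midpoint),
negative-binomial nascent counts (targets two-fold higher in G1 than G2,
knockout derepression confined to S/G2), fragment-level 3C counts with
power-law distance decay plus a two-fold G2-boosted, knockout-ablated
homotypic component, and an RA-response matrix with the cluster structure
above — all deterministic functions of one seed, with truth tables.

## Worked example

```python
import numpy as np
from cyclechrom import SimConfig
from cyclechrom import simulate as sim, chip

cfg = SimConfig(seed=1)          # 600 genes, 300 polycomb targets, 1e6 reads
ann = sim.generate_annotation(cfg)
cs = sim.simulate_chip(cfg, ann, factors=["RYBP"])

prom = {}
for phase in ("G1", "S", "G2"):
    norm = chip.normalize_track(cs.tracks[("RYBP", phase)], cs.inputs[phase])
    prom[phase] = chip.promoter_coverage(norm, ann, window=(-500, 1500))

truth = cs.truth.set_index("gene_id")
targets = truth.index[truth["group"].isin(["vcp", "v_only"])]
fc = chip.promoter_log2fc(prom["G2"], prom["G1"])
f_stat, p = chip.profile_anova({ph: s.loc[targets] for ph, s in prom.items()})
print(f"targets: {len(targets)}")
print(f"median log2FC(G2/G1) at targets: {fc.loc[targets].median():.3f}"
      f"  (simulated ratio 3.0 -> log2 = {np.log2(3):.3f})")
print(f"phase ANOVA at target promoters: F = {f_stat:.1f}, p = {p:.3g}")
```

prints

```
targets: 300
median log2FC(G2/G1) at targets: 1.545  (simulated ratio 3.0 -> log2 = 1.585)
phase ANOVA at target promoters: F = 193197.3, p = 0
```

The estimator recovers the simulated three-fold G2/G1 RYBP enrichment to
within 0.04 log₂ units (the small shortfall is the pseudocount's
compression), and the phase ANOVA is decisive at this effect size.

The same workflow runs from the shell:

```bash
cyclechrom run --config pipeline.yaml --outdir out/
```

where the YAML config may embed a `simulate:` block (see
`cyclechrom.config.PipelineConfig`); each stage
(`simulate | chip | targets | capture | nascent | ra`) is also callable on
its own against externally produced BED/bedGraph/TSV inputs.

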