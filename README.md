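# wsmeth

Differential DNA methylation analysis for very small two-group Infinium
microarray studies (EPIC / 450k beta values), built around the design of a
progeroid-disease case/control comparison: a handful of patients (e.g. three
Werner-syndrome whole-blood samples) against age- and sex-matched controls.
With n = 3 per group, standard moderated-statistics pipelines have little to
work with; this package implements the transparent classical alternative —
per-probe ANOVA with strict unadjusted thresholds plus a region-level test
that demands both multivariate significance and a large, spatially coherent
effect — together with everything needed to validate that machinery on
synthetic data with known ground truth.

## What it computes

**DMPs (differentially methylated positions).** Each CpG probe's beta values
are tested with a two-group one-way ANOVA (for two groups, F = t², the
pooled-variance t test). Probes with unadjusted p < 0.001 are significant;
Δβ = mean(case) − mean(control), so Δβ > 0 is hypermethylation in cases.
Summaries count directions, distinct genic regions, and large effects
(|Δβ| > 0.15); a volcano table and a sample PCA (per-probe mean-centred SVD)
support QC.

**DMRs (differentially methylated regions).** Probes in CpG islands, shores
or shelves that are associated with a gene are grouped by island unit and
scanned with step-1 sliding windows of three adjacent probes. Each window is
tested with a two-group MANOVA via Hotelling's T²:

    T² = (n₁n₂/(n₁+n₂)) · d′ S⁻¹ d,   F = T² (n₁+n₂−p−1) / (p (n₁+n₂−2))

with d the mean-difference vector, S the pooled covariance, p the window
size; F ~ F(p, n₁+n₂−p−1) exactly. A window is retained when p < 0.001 *and*
at least two adjacent probes have |Δβ| ≥ 0.3; overlapping or abutting
significant windows in one island merge into a DMR (p = min window p).

**Enrichment.** Gene lists are scored against GMT libraries by one-sided
Fisher exact tests, plus a rank-deviation z-score (how much better the term
ranks than for random gene lists of the same size, exhaustively enumerated
when feasible, otherwise seeded sampling). Terms at p < 0.05 are ranked by
the combined score c = ln(p)·z.

**Expression concordance.** Two-group pooled t tests with linear-scale fold
changes (FC = 2^Δ for log2 data), joined to methylation directions with the
canonical inverse relation (hyper ↦ down) flagged — recorded, never asserted.

**Replication.** A DMP list is intersected with another array's probe
universe and re-tested in a second dataset, counting strict (p < 0.001) and
loose (p < 0.05) replication and direction concordance.

**Synthetic data.** A generator emulates the whole study — island-clustered
manifests, bimodal beta baselines, 3v3 groups, spiked single-probe
(|Δβ| 0.15–0.45) and regional (|Δβ| = 0.35 × 3 adjacent probes) effects,
matched expression — and records every injected effect in a truth registry.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
scene (seed 42) and write their tables under `results/`:

```
$ python analysis/01_simulate.py
scene written to .../results/synthetic
  350 probes, 20 spiked DMPs, 5 spiked DMR islands, 10 spiked DE genes
$ python analysis/02_call_dmps.py
35 significant DMPs (22 hyper / 13 hypo); 35 with |Δβ| > 0.15
spiked single-probe effects recovered: 20/20
$ python analysis/03_call_dmrs.py
200 windows tested, 4 DMRs called (2 hyper)
spiked regions recovered: 4/5
DMRs on the matched null scene: 0
$ python analysis/05_expression_concordance.py
25 differentially methylated genes tested for expression; 11 differentially expressed at p < 0.05
10/11 DE-significant genes show the inverse methylation-expression relation
```

The 35 significant probes are exactly the 20 spiked single-probe effects
plus the 15 probes inside spiked regions; the dual DMR criterion recovers
4 of 5 spiked regions in this particular draw (the acceptance checks below
measure sensitivity ≈ 0.97 over 200 regions) and calls nothing on the
effect-free null scene, because two adjacent |Δβ| ≥ 0.3 cannot arise from
technical-scale noise.

The same stages are available as a CLI (`wsmeth dmp|dmr|enrich|de|concord|
compare|simulate`), and `wsmeth run --config cfg.yaml` executes the whole
workflow on user-supplied matrices (normalized betas, a sample sheet, a
manifest, optionally a GMT library / expression matrix / second dataset).

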