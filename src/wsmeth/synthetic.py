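"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a small two-group Infinium-style study: an
island-clustered probe manifest with shore/shelf relations and gene
annotations, a bimodal beta-value matrix with Gaussian within-group noise
on the beta scale (clipped to [0,1]), spiked single-probe effects and
spiked multi-probe regional effects, and a matched log2 expression matrix
whose spiked genes can be forced to agree (inversely) with the spiked
methylation directions.  Every spiked effect is recorded in a
:class:`SyntheticTruth` registry so recovery can be scored exactly.

Defaults mirror the study design the pipeline targets: 3 cases vs 3
controls, single-probe effects with |Δβ| in 0.15-0.45, regional effects
of |Δβ| = 0.35 over runs of 3 adjacent gene-associated island probes, and
within-group noise sd 0.008 (technical-noise scale for Infinium betas,
chosen so that a 3v3 design retains high power at the regional effect
size — see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .array_io import BetaMatrix, Group, ProbeAnnotation, Relation, sort_annotations

__all__ = [
    "SyntheticTruth",
    "generate_manifest",
    "generate_betas",
    "generate_expression",
    "paperlike_scene",
]

DEFAULT_WITHIN_SD = 0.008


@dataclass
class SyntheticTruth:
    """Registry of every spiked effect, keyed for direct lookup."""

    spiked_dmp_probes: dict = field(default_factory=dict)  # probe_id -> true delta
    spiked_dmr_islands: dict = field(default_factory=dict)  # island -> (probe_ids, delta)
    spiked_de_genes: dict = field(default_factory=dict)  # gene -> true log2 FC
    seed: int = 0

    @property
    def spiked_dmr_probe_ids(self) -> frozenset:
        out: set = set()
        for probe_ids, _ in self.spiked_dmr_islands.values():
            out |= set(probe_ids)
        return frozenset(out)

    def methylation_gene_directions(self, manifest: Sequence[ProbeAnnotation]) -> dict:
        """gene -> HYPER/HYPO implied by the spiked effects touching it."""
        by_probe = {a.probe_id: a for a in manifest}
        out: dict = {}
        for pid, delta in self.spiked_dmp_probes.items():
            for g in by_probe[pid].genes:
                out[g] = "HYPER" if delta > 0 else "HYPO"
        for probe_ids, delta in self.spiked_dmr_islands.values():
            for pid in probe_ids:
                for g in by_probe[pid].genes:
                    out[g] = "HYPER" if delta > 0 else "HYPO"
        return out


# island relation pattern: shelves outside shores outside the island core
def _island_relations(k: int) -> list[Relation]:
    if k >= 5:
        inner = [Relation.ISLAND] * (k - 4)
        return [Relation.N_SHELF, Relation.N_SHORE, *inner, Relation.S_SHORE, Relation.S_SHELF]
    if k == 4:
        return [Relation.N_SHORE, Relation.ISLAND, Relation.ISLAND, Relation.S_SHORE]
    return [Relation.ISLAND] * k


def generate_manifest(
    n_islands: int = 50,
    probes_per_island: int = 6,
    n_opensea: int = 50,
    gene_pool_size: int = 120,
    n_chroms: int = 3,
    gene_fraction: float = 1.0,
    opensea_gene_fraction: float = 0.3,
    probe_spacing: int = 100,
    island_gap: int = 50_000,
    seed: int = 0,
) -> list[ProbeAnnotation]:
    """Island-clustered probe annotations with interleaved open-sea probes.

    Islands are laid consecutively along ``n_chroms`` chromosomes; each
    island's probes share one island_name and carry 1-2 genes from the
    pool with probability ``gene_fraction``.  Open-sea probes sit in the
    gaps between islands.  Positions are strictly increasing within each
    chromosome.  Deterministic for a fixed seed.
    """
    if min(n_islands, probes_per_island, n_opensea, gene_pool_size, n_chroms) < 0:
        raise ValueError("all counts must be >= 0")
    rng = np.random.default_rng(seed)
    gene_pool = [f"GENE{i:04d}" for i in range(gene_pool_size)]
    cursor = {f"chr{c + 1}": 10_000 for c in range(max(n_chroms, 1))}
    probe_serial = 0
    annotations: list[ProbeAnnotation] = []

    def next_probe_id() -> str:
        nonlocal probe_serial
        probe_serial += 1
        return f"cg{probe_serial:08d}"

    opensea_per_gap = np.zeros(max(n_islands, 1), dtype=int)
    for i in range(n_opensea):
        opensea_per_gap[i % len(opensea_per_gap)] += 1

    for isl in range(n_islands):
        chrom = f"chr{isl % max(n_chroms, 1) + 1}"
        start = cursor[chrom] + island_gap
        relations = _island_relations(probes_per_island)
        positions = [start + j * probe_spacing for j in range(probes_per_island)]
        core = [p for p, r in zip(positions, relations) if r is Relation.ISLAND] or positions
        island_name = f"{chrom}:{core[0]}-{core[-1] + probe_spacing - 1}"
        n_genes = int(rng.integers(1, 3))
        island_genes = frozenset(rng.choice(gene_pool, size=n_genes, replace=False).tolist())
        for pos, rel in zip(positions, relations):
            genes = island_genes if rng.random() < gene_fraction else frozenset()
            annotations.append(
                ProbeAnnotation(
                    probe_id=next_probe_id(),
                    chrom=chrom,
                    position=pos,
                    genes=genes,
                    island_name=island_name,
                    relation=rel,
                )
            )
        cursor[chrom] = positions[-1]
        # open-sea probes in the gap after this island
        for _ in range(int(opensea_per_gap[isl]) if n_islands else 0):
            pos = cursor[chrom] + int(rng.integers(5_000, island_gap - 5_000))
            genes = (
                frozenset(rng.choice(gene_pool, size=1).tolist())
                if rng.random() < opensea_gene_fraction
                else frozenset()
            )
            annotations.append(
                ProbeAnnotation(
                    probe_id=next_probe_id(),
                    chrom=chrom,
                    position=pos,
                    genes=genes,
                    island_name="",
                    relation=Relation.OPEN_SEA,
                )
            )
            cursor[chrom] = pos
    if n_islands == 0:
        chrom = "chr1"
        for _ in range(n_opensea):
            pos = cursor[chrom] + int(rng.integers(5_000, island_gap))
            annotations.append(
                ProbeAnnotation(probe_id=next_probe_id(), chrom=chrom, position=pos)
            )
            cursor[chrom] = pos
    return sort_annotations(annotations)


def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Mixture of mostly-unmethylated and mostly-methylated probe means."""
    low = rng.random(n) < 0.55
    return np.where(low, rng.beta(2, 10, n), rng.beta(10, 2, n))


def _spike_baseline(rng: np.random.Generator, delta: float) -> float:
    """A baseline mean leaving room for a shift of ``delta`` inside [0.05, 0.95]."""
    lo, hi = (0.05, 0.95 - delta) if delta > 0 else (0.05 - delta, 0.95)
    return float(rng.uniform(lo, hi))


def _eligible_runs(manifest: Sequence[ProbeAnnotation], run_length: int) -> dict:
    """island_name -> longest run of consecutive eligible probes (>= run_length)."""
    from .dmr import _island_runs, eligible_probes

    runs = {}
    for run in _island_runs(eligible_probes(manifest)):
        island = run[0].island_name
        if len(run) >= run_length and island not in runs:
            runs[island] = run
    return runs


def generate_betas(
    manifest: Sequence[ProbeAnnotation],
    n_case: int = 3,
    n_ctrl: int = 3,
    within_sd: float = DEFAULT_WITHIN_SD,
    dmp_spikes: tuple[int, tuple[float, float]] = (20, (0.15, 0.45)),
    dmr_spikes: tuple[int, float, int] = (5, 0.35, 3),
    baseline: str = "bimodal",
    baseline_range: tuple[float, float] = (0.15, 0.85),
    seed: int = 0,
) -> tuple[BetaMatrix, SyntheticTruth]:
    """Two-group beta matrix with spiked single-probe and regional effects.

    ``dmp_spikes = (count, (lo, hi))`` draws per-probe |Δβ| uniformly in
    [lo, hi] with a random sign; ``dmr_spikes = (count, delta, run_length)``
    shifts ``run_length`` consecutive eligible probes of a CpG island by
    ±delta.  Values are clip(baseline + effect + N(0, within_sd), 0, 1);
    spiked probes get baselines that keep the shifted mean inside [0, 1].
    ``baseline`` is "bimodal" (default) or "uniform" over ``baseline_range``.
    Raises if the manifest cannot host the requested regional spikes.
    """
    rng = np.random.default_rng(seed)
    manifest = list(manifest)
    n_probes = len(manifest)
    probe_index = {a.probe_id: i for i, a in enumerate(manifest)}
    if baseline == "bimodal":
        base = _bimodal_baseline(rng, n_probes)
    elif baseline == "uniform":
        base = rng.uniform(*baseline_range, n_probes)
    else:
        raise ValueError("baseline must be 'bimodal' or 'uniform'")
    effect = np.zeros(n_probes)
    truth = SyntheticTruth(seed=seed)

    n_dmr, dmr_delta, run_length = dmr_spikes
    if n_dmr > 0:
        if abs(dmr_delta) < 0.3:
            raise ValueError("regional spikes must have |delta| >= 0.3")
        runs = _eligible_runs(manifest, run_length)
        if len(runs) < n_dmr:
            raise ValueError(
                f"manifest has only {len(runs)} islands with >= {run_length} "
                f"consecutive eligible probes; {n_dmr} requested"
            )
        chosen = rng.choice(sorted(runs), size=n_dmr, replace=False)
        for island in chosen:
            run = runs[island]
            start = int(rng.integers(0, len(run) - run_length + 1))
            probes = run[start : start + run_length]
            delta = dmr_delta * (1 if rng.random() < 0.5 else -1)
            anchor = _spike_baseline(rng, delta)
            for a in probes:
                i = probe_index[a.probe_id]
                base[i] = np.clip(anchor + rng.normal(0, 0.02), 0.05, 0.95 - abs(delta))
                effect[i] = delta
            truth.spiked_dmr_islands[island] = (tuple(a.probe_id for a in probes), delta)

    n_dmp, (lo, hi) = dmp_spikes
    if n_dmp > 0:
        # at most one single-probe spike per island, and none in spiked
        # regions, so accidental adjacent-pair "regions" cannot arise
        taken_probes = set(truth.spiked_dmr_probe_ids)
        taken_islands = set(truth.spiked_dmr_islands)
        by_probe = {a.probe_id: a for a in manifest}
        candidates = [a.probe_id for a in manifest if a.probe_id not in taken_probes]
        order = rng.permutation(len(candidates))
        placed = 0
        for idx in order:
            if placed == n_dmp:
                break
            pid = candidates[idx]
            island = by_probe[pid].island_name
            if island and island in taken_islands:
                continue
            if island:
                taken_islands.add(island)
            i = probe_index[pid]
            delta = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            base[i] = _spike_baseline(rng, delta)
            effect[i] = delta
            truth.spiked_dmp_probes[pid] = delta
            placed += 1
        if placed < n_dmp:
            raise ValueError("not enough free probes for the requested single-probe spikes")

    n = n_case + n_ctrl
    values = base[:, None] + rng.normal(0, within_sd, (n_probes, n))
    values[:, :n_case] += effect[:, None]
    values = np.clip(values, 0.0, 1.0)
    sample_ids = [f"WS{i + 1:02d}" for i in range(n_case)] + [
        f"CTR{i + 1:02d}" for i in range(n_ctrl)
    ]
    groups = {s: (Group.CASE if s.startswith("WS") else Group.CTRL) for s in sample_ids}
    matrix = BetaMatrix(
        probe_ids=[a.probe_id for a in manifest],
        sample_ids=sample_ids,
        values=values,
        groups=groups,
    )
    return matrix, truth


def generate_expression(
    gene_pool: Sequence,
    n_case: int = 10,
    n_ctrl: int = 10,
    de_spikes: tuple[int, float] = (10, 1.0),
    noise_sd: float = 0.25,
    concordance_with: SyntheticTruth | None = None,
    manifest: Sequence[ProbeAnnotation] | None = None,
    direction_agreement: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, SyntheticTruth]:
    """Log2-scale expression matrix with spiked fold changes.

    Returns (genes x samples DataFrame, sample->group mapping, truth).
    With ``concordance_with`` (and its manifest), spiked genes are drawn
    from the spiked methylation genes and their direction agrees with the
    canonical inverse methylation-expression relation (hypermethylated ->
    down-regulated) for a ``direction_agreement`` fraction of them.
    """
    rng = np.random.default_rng(seed)
    genes = [str(g).upper() for g in gene_pool]
    n_spike, log2fc = de_spikes
    truth = SyntheticTruth(seed=seed)
    shifts = {}
    if concordance_with is not None:
        if manifest is None:
            raise ValueError("concordance_with requires the matching manifest")
        meth_dirs = concordance_with.methylation_gene_directions(manifest)
        candidates = [g for g in genes if g in meth_dirs]
        chosen = rng.choice(candidates, size=min(n_spike, len(candidates)), replace=False)
        for g in chosen:
            inverse = meth_dirs[g] == "HYPER"  # hyper -> expression DOWN
            agree = rng.random() < direction_agreement
            down = inverse if agree else not inverse
            shifts[g] = -abs(log2fc) if down else abs(log2fc)
    else:
        chosen = rng.choice(genes, size=min(n_spike, len(genes)), replace=False)
        for g in chosen:
            shifts[g] = abs(log2fc) * (1 if rng.random() < 0.5 else -1)
    truth.spiked_de_genes = dict(shifts)

    sample_ids = [f"WSF{i + 1:02d}" for i in range(n_case)] + [
        f"CTRF{i + 1:02d}" for i in range(n_ctrl)
    ]
    groups = {s: (Group.CASE if s.startswith("WSF") else Group.CTRL) for s in sample_ids}
    baseline = rng.normal(8.0, 1.5, len(genes))
    values = baseline[:, None] + rng.normal(0, noise_sd, (len(genes), n_case + n_ctrl))
    for j, g in enumerate(genes):
        if g in shifts:
            values[j, :n_case] += shifts[g]
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return expr, groups, truth


def paperlike_scene(seed: int = 0, null: bool = False) -> dict:
    """The default synthetic study: 50 islands x 6 probes, 50 open-sea
    probes, 3v3 betas with 20 single-probe and 5 regional spikes, and a
    matched 10v10 expression matrix.  ``null=True`` keeps the same
    manifest and noise but injects no effects."""
    manifest = generate_manifest(seed=seed)
    spikes = dict(dmp_spikes=(0, (0.0, 0.0)), dmr_spikes=(0, 0.35, 3)) if null else {}
    matrix, truth = generate_betas(manifest, seed=seed + 1, **spikes)
    gene_pool = sorted({g for a in manifest for g in a.genes})
    expr, expr_groups, expr_truth = generate_expression(
        gene_pool,
        concordance_with=None if null else truth,
        manifest=manifest,
        seed=seed + 2,
    )
    truth.spiked_de_genes = expr_truth.spiked_de_genes
    return {
        "manifest": manifest,
        "betas": matrix,
        "truth": truth,
        "expression": expr,
        "expression_groups": expr_groups,
    }
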