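"""Region-level differential methylation by sliding-window MANOVA.

Windows of ``window_size`` (default 3) consecutive eligible probes —
gene-associated probes in CpG islands, shores or shelves, grouped by
island unit — are tested with a two-group MANOVA.  For two groups every
classical MANOVA statistic (Wilks, Pillai, Hotelling-Lawley, Roy) reduces
to Hotelling's T^2, which has an exact F transform:

    T^2 = (n1 n2 / (n1+n2)) d' S^-1 d,
    F   = T^2 (n1+n2-p-1) / (p (n1+n2-2))  ~  F(p, n1+n2-p-1)

with d the vector of group mean-beta differences and S the pooled
within-group covariance.  A window is called significant when its
non-adjusted p is strictly below ``p_threshold`` AND at least
``min_adjacent_exceeding`` mutually adjacent probes all show an absolute
group difference of at least ``min_abs_delta`` (inclusive).  Overlapping
or abutting significant windows within one island unit are merged into a
DMR whose p is the minimum member-window p.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .array_io import BetaMatrix, ProbeAnnotation, sort_annotations, _chrom_key

logger = logging.getLogger(__name__)

__all__ = [
    "DMRParams",
    "WindowResult",
    "DMRResult",
    "eligible_probes",
    "make_windows",
    "hotelling_t2",
    "call_dmrs",
    "windows_to_frame",
    "dmrs_to_frame",
]


@dataclass(frozen=True)
class DMRParams:
    window_size: int = 3
    p_threshold: float = 0.001
    min_abs_delta: float = 0.3
    min_adjacent_exceeding: int = 2

    def __post_init__(self):
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.min_adjacent_exceeding > self.window_size:
            raise ValueError("min_adjacent_exceeding cannot exceed window_size")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class WindowResult:
    probe_ids: tuple  # ordered by position
    island_name: str
    chrom: str
    positions: tuple
    T2: float
    F_stat: float
    p_value: float
    deltas: tuple  # per-probe case - ctrl mean differences
    singular: bool = False  # pooled covariance needed a pseudoinverse


@dataclass(frozen=True)
class DMRResult:
    chrom: str
    start: int
    end: int
    probe_ids: tuple
    genes: frozenset
    island_name: str
    relations: tuple
    p_value: float  # minimum member-window p
    direction: str  # HYPER / HYPO / MIXED
    n_windows: int = 1


def eligible_probes(annotations: Iterable[ProbeAnnotation]) -> list[ProbeAnnotation]:
    """Gene-associated probes in CpG-rich regions, sorted by (chrom, position)."""
    return sort_annotations(a for a in annotations if a.cpg_rich and a.genes)


def _island_runs(eligible: Sequence[ProbeAnnotation]):
    """Runs of consecutive eligible probes sharing (chrom, island_name)."""
    for (_, _), run in itertools.groupby(eligible, key=lambda a: (a.chrom, a.island_name)):
        yield list(run)


def make_windows(
    eligible: Sequence[ProbeAnnotation], params: DMRParams = DMRParams()
) -> list[tuple[ProbeAnnotation, ...]]:
    """Step-1 sliding windows of ``window_size`` probes within an island unit.

    Island units with fewer than ``window_size`` eligible probes yield no
    windows; windows never span two island units.
    """
    w = params.window_size
    windows = []
    for run in _island_runs(eligible):
        for i in range(len(run) - w + 1):
            windows.append(tuple(run[i : i + w]))
    return windows


def hotelling_t2(
    window_betas: np.ndarray,
    groups: Sequence,
    probes: Sequence[ProbeAnnotation] | None = None,
    island_name: str = "",
) -> WindowResult:
    """Two-group Hotelling T^2 test on one window.

    ``window_betas`` is (window_size x n_samples); ``groups`` labels each
    column CASE/CTRL (any truthy case mask also accepted).  Requires
    n1 + n2 >= window_size + 2 so that the F transform is defined.  A
    singular pooled covariance falls back to a pseudoinverse (relative
    tolerance 1e-10) and is flagged.
    """
    X = np.asarray(window_betas, dtype=float)
    p_dim, n = X.shape
    mask = np.array([str(g).upper().endswith("CASE") if isinstance(g, str) else bool(g) for g in groups])
    if mask.size != n:
        raise ValueError("groups length does not match number of samples")
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 + n2 < p_dim + 2 or min(n1, n2) < 2:
        raise ValueError(
            f"Hotelling T^2 with {p_dim} probes needs at least {p_dim + 2} samples "
            f"(and >=2 per group); got {n1}+{n2}"
        )
    case, ctrl = X[:, mask], X[:, ~mask]
    d = case.mean(axis=1) - ctrl.mean(axis=1)
    S1 = np.atleast_2d(np.cov(case))
    S2 = np.atleast_2d(np.cov(ctrl))
    S = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    singular = False
    try:
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        singular = True
        logger.warning("singular pooled covariance in window %s; using pseudoinverse", island_name)
        sol = np.linalg.pinv(S, rcond=1e-10) @ d
    T2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    T2 = max(T2, 0.0)
    df2 = n1 + n2 - p_dim - 1
    F = T2 * df2 / (p_dim * (n1 + n2 - 2))
    p_value = float(stats.f.sf(F, p_dim, df2)) if T2 > 0 else 1.0
    if probes is not None:
        probe_ids = tuple(a.probe_id for a in probes)
        positions = tuple(a.position for a in probes)
        chrom = probes[0].chrom
        island_name = island_name or probes[0].island_name
    else:
        probe_ids = tuple(f"p{i}" for i in range(p_dim))
        positions = tuple(range(p_dim))
        chrom = ""
    return WindowResult(
        probe_ids=probe_ids,
        island_name=island_name,
        chrom=chrom,
        positions=positions,
        T2=T2,
        F_stat=float(F),
        p_value=p_value,
        deltas=tuple(float(x) for x in d),
        singular=singular,
    )


def _has_adjacent_run(deltas: Sequence[float], min_abs: float, run_len: int) -> bool:
    """True when ``run_len`` consecutive deltas all have |delta| >= min_abs."""
    count = 0
    for d in deltas:
        count = count + 1 if abs(d) >= min_abs else 0
        if count >= run_len:
            return True
    return False


def window_significant(window: WindowResult, params: DMRParams) -> bool:
    """The dual criterion: p strictly below threshold AND an adjacent
    run of ``min_adjacent_exceeding`` probes with |delta| >= min_abs_delta."""
    return window.p_value < params.p_threshold and _has_adjacent_run(
        window.deltas, params.min_abs_delta, params.min_adjacent_exceeding
    )


def call_dmrs(
    matrix: BetaMatrix,
    annotations: Iterable[ProbeAnnotation],
    params: DMRParams = DMRParams(),
) -> tuple[list[WindowResult], list[DMRResult]]:
    """Run the sliding-window test and merge significant windows into DMRs."""
    mat = matrix.drop_incomplete()
    present = set(mat.probe_ids)
    index = {p: i for i, p in enumerate(mat.probe_ids)}
    eligible = [a for a in eligible_probes(annotations) if a.probe_id in present]
    groups = [mat.groups[s] for s in mat.sample_ids]
    ann_by_id = {a.probe_id: a for a in eligible}

    w = params.window_size
    window_results: list[WindowResult] = []
    dmrs: list[DMRResult] = []
    for run in _island_runs(eligible):
        # significant windows in this island unit, with their start index
        sig_here: list[tuple[int, WindowResult]] = []
        for i in range(len(run) - w + 1):
            probes = run[i : i + w]
            betas = mat.values[[index[a.probe_id] for a in probes]]
            res = hotelling_t2(betas, groups, probes=probes)
            window_results.append(res)
            if window_significant(res, params):
                sig_here.append((i, res))
        # merge windows that overlap or abut (start index gap <= window size)
        cluster: list[WindowResult] = []
        last_end = -2
        for i, res in sig_here:
            if cluster and i > last_end + 1:
                dmrs.append(_merge_cluster(cluster, ann_by_id, params))
                cluster = []
            cluster.append(res)
            last_end = i + w - 1
        if cluster:
            dmrs.append(_merge_cluster(cluster, ann_by_id, params))
    dmrs.sort(key=lambda d: (_chrom_key(d.chrom), d.start))
    return window_results, dmrs


def _merge_cluster(
    cluster: list[WindowResult], ann_by_id: dict, params: DMRParams
) -> DMRResult:
    probe_ids: list = []
    deltas: dict = {}
    for w in cluster:
        for pid, d in zip(w.probe_ids, w.deltas):
            if pid not in deltas:
                probe_ids.append(pid)
                deltas[pid] = d
    probe_ids.sort(key=lambda p: ann_by_id[p].position)
    genes: set = set()
    relations: list = []
    for pid in probe_ids:
        genes |= ann_by_id[pid].genes
        rel = ann_by_id[pid].relation.value
        if rel not in relations:
            relations.append(rel)
    exceeding = [deltas[p] for p in probe_ids if abs(deltas[p]) >= params.min_abs_delta]
    if exceeding and all(d > 0 for d in exceeding):
        direction = "HYPER"
    elif exceeding and all(d < 0 for d in exceeding):
        direction = "HYPO"
    else:
        direction = "MIXED"
    positions = [ann_by_id[p].position for p in probe_ids]
    return DMRResult(
        chrom=cluster[0].chrom,
        start=min(positions),
        end=max(positions),
        probe_ids=tuple(probe_ids),
        genes=frozenset(genes),
        island_name=cluster[0].island_name,
        relations=tuple(relations),
        p_value=min(w.p_value for w in cluster),
        direction=direction,
        n_windows=len(cluster),
    )


def windows_to_frame(windows: Sequence[WindowResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.positions[0] for w in windows],
            "end": [w.positions[-1] for w in windows],
            "island_name": [w.island_name for w in windows],
            "probe_ids": [";".join(w.probe_ids) for w in windows],
            "T2": [w.T2 for w in windows],
            "F_stat": [w.F_stat for w in windows],
            "p_value": [w.p_value for w in windows],
            "deltas": [";".join(f"{d:.6g}" for d in w.deltas) for w in windows],
            "singular": [w.singular for w in windows],
        }
    )


def dmrs_to_frame(dmrs: Sequence[DMRResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "island_name": [d.island_name for d in dmrs],
            "relations": [";".join(d.relations) for d in dmrs],
            "genes": [";".join(sorted(d.genes)) for d in dmrs],
            "probe_ids": [";".join(d.probe_ids) for d in dmrs],
            "n_probes": [len(d.probe_ids) for d in dmrs],
            "n_windows": [d.n_windows for d in dmrs],
            "p_value": [d.p_value for d in dmrs],
            "direction": [d.direction for d in dmrs],
        }
    )
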