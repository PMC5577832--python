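"""Single-probe differential methylation (DMPs).

Each CpG probe is tested with a two-group one-way ANOVA on beta values
(equivalent, for two groups, to the pooled-variance two-sample t test:
F = t^2).  Probes with non-adjusted p below the threshold (default 0.001,
strict) are flagged significant; effect size is the difference of group
mean betas (case minus control), so HYPER means higher methylation in
cases.  No multiple-testing correction enters the primary call — a BH
q-value column is emitted for convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import BetaMatrix, ProbeAnnotation

__all__ = [
    "DMPResult",
    "DMPSummary",
    "probe_anova",
    "call_dmps",
    "summarize_dmps",
    "sample_pca",
    "volcano_table",
    "dmps_to_frame",
]


def probe_anova(case_values: Sequence[float], ctrl_values: Sequence[float]) -> tuple[float, float]:
    """One-way two-group ANOVA on one probe's betas -> (F, p).

    p comes from the F distribution with df (1, n1+n2-2).  A probe with
    zero total variance returns (0, 1); zero within-group variance with
    distinct means returns (inf, 0).
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("probe_anova requires at least 2 values per group")
    if np.isnan(case).any() or np.isnan(ctrl).any():
        raise ValueError("probe_anova does not accept missing values")
    F, p = _anova_matrix(case[None, :], ctrl[None, :])
    return float(F[0]), float(p[0])


def _anova_matrix(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-group ANOVA over rows of (probes x samples) blocks."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    ssw = ((case - m1[:, None]) ** 2).sum(axis=1) + ((ctrl - m2[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / df2)
    # zero total variance -> no evidence; zero within variance only -> F=inf
    F = np.where((ssb == 0) & (ssw == 0), 0.0, F)
    F = np.where((ssw == 0) & (ssb > 0), np.inf, F)
    p = stats.f.sf(F, 1, df2)
    p = np.where(F == 0.0, 1.0, p)
    return F, p


@dataclass(frozen=True)
class DMPResult:
    probe_id: str
    p_value: float
    mean_case: float
    mean_ctrl: float
    delta: float  # mean_case - mean_ctrl
    significant: bool
    q_value: float
    annotation: ProbeAnnotation | None = None

    @property
    def direction(self) -> str:
        if self.delta > 0:
            return "HYPER"
        if self.delta < 0:
            return "HYPO"
        return "NONE"


def call_dmps(
    matrix: BetaMatrix,
    annotations: Iterable[ProbeAnnotation] | Mapping[str, ProbeAnnotation] | None = None,
    p_threshold: float = 0.001,
) -> list[DMPResult]:
    """Test every complete probe; significance is strict p < p_threshold.

    Probes absent from the annotation set are kept with ``annotation=None``
    (their count is implicit in the result).  Probes with missing betas are
    excluded via :meth:`BetaMatrix.drop_incomplete`.
    """
    if annotations is None:
        ann_map: Mapping[str, ProbeAnnotation] = {}
    elif isinstance(annotations, Mapping):
        ann_map = annotations
    else:
        ann_map = {a.probe_id: a for a in annotations}
    mat = matrix.drop_incomplete()
    case, ctrl = mat.group_split()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("call_dmps requires at least 2 samples per group")
    F, p = _anova_matrix(case, ctrl)
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    delta = m1 - m2
    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0)) if len(p) else np.array([])
    return [
        DMPResult(
            probe_id=pid,
            p_value=float(p[i]),
            mean_case=float(m1[i]),
            mean_ctrl=float(m2[i]),
            delta=float(delta[i]),
            significant=bool(p[i] < p_threshold),
            q_value=float(q[i]),
            annotation=ann_map.get(pid),
        )
        for i, pid in enumerate(mat.probe_ids)
    ]


@dataclass(frozen=True)
class DMPSummary:
    n_significant: int
    n_hyper: int
    n_hypo: int
    n_hyper_genic_regions: int
    n_hypo_genic_regions: int
    n_hyper_large_effect: int
    n_hypo_large_effect: int
    p_threshold: float
    effect_threshold: float


def summarize_dmps(
    dmps: Sequence[DMPResult],
    p_threshold: float = 0.001,
    effect_threshold: float = 0.15,
    genic_count: str = "genes",
) -> DMPSummary:
    """Direction, genic-region and large-effect counts for significant probes.

    ``genic_count="genes"`` counts distinct gene symbols (multi-gene probe
    annotations are split); ``"strings"`` counts distinct unsplit annotation
    strings.  Large effect means |delta| strictly greater than the threshold.
    """
    if genic_count not in ("genes", "strings"):
        raise ValueError("genic_count must be 'genes' or 'strings'")
    sig = [d for d in dmps if d.p_value < p_threshold]
    hyper = [d for d in sig if d.delta > 0]
    hypo = [d for d in sig if d.delta < 0]

    def genic(records: list[DMPResult]) -> int:
        units: set = set()
        for d in records:
            if d.annotation is None or not d.annotation.genes:
                continue
            if genic_count == "genes":
                units |= d.annotation.genes
            else:
                units.add(";".join(sorted(d.annotation.genes)))
        return len(units)

    return DMPSummary(
        n_significant=len(sig),
        n_hyper=len(hyper),
        n_hypo=len(hypo),
        n_hyper_genic_regions=genic(hyper),
        n_hypo_genic_regions=genic(hypo),
        n_hyper_large_effect=sum(abs(d.delta) > effect_threshold for d in hyper),
        n_hypo_large_effect=sum(abs(d.delta) > effect_threshold for d in hypo),
        p_threshold=p_threshold,
        effect_threshold=effect_threshold,
    )


def sample_pca(matrix: BetaMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over probes after per-probe mean centering.

    Returns (coordinates DataFrame: samples x components, variance-explained
    fractions of the retained components; the full decomposition's fractions
    sum to 1).
    """
    mat = matrix.drop_incomplete()
    n_samples = len(mat.sample_ids)
    if n_samples < 2:
        raise ValueError("sample_pca requires at least 2 samples")
    max_rank = n_samples - 1
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds n_samples-1={max_rank}")
    X = mat.values.T  # samples x probes
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :n_components] * s[:n_components]
    total = float((s**2).sum())
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    df = pd.DataFrame(
        coords,
        index=pd.Index(mat.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return df, frac


def volcano_table(dmps: Sequence[DMPResult], p_threshold: float = 0.001) -> pd.DataFrame:
    """Per-probe (delta, -log10 p, significant) records for a volcano plot."""
    return pd.DataFrame(
        {
            "probe_id": [d.probe_id for d in dmps],
            "delta": [d.delta for d in dmps],
            "neg_log10_p": [-np.log10(max(d.p_value, 1e-300)) for d in dmps],
            "significant": [d.p_value < p_threshold for d in dmps],
        }
    )


def dmps_to_frame(dmps: Sequence[DMPResult]) -> pd.DataFrame:
    """Flatten DMP results (with annotation columns) into a DataFrame."""
    rows = []
    for d in dmps:
        a = d.annotation
        rows.append(
            {
                "probe_id": d.probe_id,
                "chrom": a.chrom if a else "",
                "position": a.position if a else -1,
                "genes": ";".join(sorted(a.genes)) if a else "",
                "island_name": a.island_name if a else "",
                "relation": a.relation.value if a else "",
                "mean_case": d.mean_case,
                "mean_ctrl": d.mean_ctrl,
                "delta": d.delta,
                "p_value": d.p_value,
                "q_value": d.q_value,
                "direction": d.direction,
                "significant": d.significant,
            }
        )
    return pd.DataFrame(rows)
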