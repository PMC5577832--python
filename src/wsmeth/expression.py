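"""Two-group differential expression and methylation-expression concordance.

Expression is compared with a two-sided pooled-variance Student t test.
Fold change is reported on the linear scale: for log2 data
FC = 2^(mean_case - mean_ctrl); for linear data FC = mean_case/mean_ctrl.
The concordance table joins methylation directions (HYPER/HYPO) with
expression directions (UP/DOWN); the flag records the canonical inverse
relationship (HYPER with DOWN, or HYPO with UP) and carries no causal
claim — discordant pairs are reported as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import Group

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionResult",
    "de_ttest",
    "detect_scale",
    "differential_expression",
    "concordance_table",
]


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    fold_change: float  # case/control ratio, linear scale
    t_p_value: float
    mean_case: float
    mean_ctrl: float

    @property
    def direction(self) -> str:
        return "UP" if self.fold_change > 1 else "DOWN"


def de_ttest(
    case_values: Sequence[float],
    ctrl_values: Sequence[float],
    scale: str = "log2",
    gene: str = "",
) -> ExpressionResult:
    """Pooled-variance two-sample t test plus linear-scale fold change."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("de_ttest requires at least 2 values per group")
    m1, m2 = float(case.mean()), float(ctrl.mean())
    if scale == "log2":
        fc = float(2.0 ** (m1 - m2))
    elif scale == "linear":
        if m2 == 0:
            raise ValueError(f"gene {gene!r}: control mean is 0, fold change undefined")
        if m1 <= 0 or m2 < 0:
            raise ValueError(f"gene {gene!r}: linear-scale means must be positive")
        fc = m1 / m2
    else:
        raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")
    # for two groups this p is identical to the one-way ANOVA p (F = t^2)
    p = float(stats.ttest_ind(case, ctrl, equal_var=True).pvalue)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if m1 == m2 else 0.0
    return ExpressionResult(gene=gene, fold_change=fc, t_p_value=p, mean_case=m1, mean_ctrl=m2)


def detect_scale(values: np.ndarray) -> str:
    """Heuristic: non-negative values mostly within [0, 20] look like log2."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return "log2"
    if v.min() >= 0 and np.mean(v <= 20) >= 0.99:
        return "log2"
    return "linear"


def differential_expression(
    expr: pd.DataFrame,
    groups: Mapping,
    genes: Iterable | None = None,
    scale: str = "auto",
    collapse: str = "iqr",
) -> pd.DataFrame:
    """Per-gene t test + fold change over an expression matrix.

    ``expr`` is genes x samples (index = gene symbol, possibly repeated);
    ``groups`` maps sample id -> CASE/CTRL.  When a symbol maps to several
    rows, the row with the largest inter-quartile range is used
    (``collapse="iqr"``) or rows are averaged (``collapse="mean"``).
    """
    if collapse not in ("iqr", "mean"):
        raise ValueError("collapse must be 'iqr' or 'mean'")
    expr = expr.copy()
    expr.index = expr.index.astype(str).str.upper()
    samples = [s for s in expr.columns if s in groups]
    if len(samples) < len(expr.columns):
        logger.warning(
            "differential_expression: %d samples without group labels ignored",
            len(expr.columns) - len(samples),
        )
    expr = expr[samples]
    case_cols = [s for s in samples if Group(groups[s]) is Group.CASE]
    ctrl_cols = [s for s in samples if Group(groups[s]) is Group.CTRL]
    if scale == "auto":
        scale = detect_scale(expr.to_numpy())
        logger.info("differential_expression: auto-detected %s scale", scale)
    wanted = (
        [str(g).upper() for g in genes] if genes is not None else list(dict.fromkeys(expr.index))
    )
    rows = []
    for gene in wanted:
        if gene not in expr.index:
            continue
        block = expr.loc[[gene]]
        if len(block) > 1:
            if collapse == "iqr":
                iqr = block.quantile(0.75, axis=1) - block.quantile(0.25, axis=1)
                values = block.iloc[[int(np.argmax(iqr.to_numpy()))]].iloc[0]
            else:
                values = block.mean(axis=0)
        else:
            values = block.iloc[0]
        res = de_ttest(values[case_cols], values[ctrl_cols], scale=scale, gene=gene)
        rows.append(
            {
                "gene": gene,
                "fold_change": res.fold_change,
                "p_value": res.t_p_value,
                "mean_case": res.mean_case,
                "mean_ctrl": res.mean_ctrl,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p_value", "mean_case", "mean_ctrl", "direction"])


def concordance_table(
    meth_directions: Mapping,
    de_results: pd.DataFrame,
    de_p: float = 0.05,
) -> pd.DataFrame:
    """Inner-join methylation directions with expression results.

    ``meth_directions`` maps gene symbol -> HYPER/HYPO.  ``concordant``
    flags the canonical inverse methylation-expression relation
    (HYPER & DOWN or HYPO & UP); ``de_significant`` is strict p < de_p.
    Genes absent from the expression table are counted in the log.
    """
    meth = {str(g).upper(): str(d).upper() for g, d in meth_directions.items()}
    if de_results.empty:
        logger.warning("concordance_table: empty expression table, empty join")
        return pd.DataFrame(
            columns=["gene", "meth_direction", "fold_change", "p_value", "de_direction", "de_significant", "concordant"]
        )
    de = de_results.copy()
    de["gene"] = de["gene"].astype(str).str.upper()
    de = de.set_index("gene")
    rows, missing = [], 0
    for gene, mdir in meth.items():
        if gene not in de.index:
            missing += 1
            continue
        rec = de.loc[gene]
        de_dir = str(rec["direction"])
        rows.append(
            {
                "gene": gene,
                "meth_direction": mdir,
                "fold_change": float(rec["fold_change"]),
                "p_value": float(rec["p_value"]),
                "de_direction": de_dir,
                "de_significant": bool(rec["p_value"] < de_p),
                "concordant": (mdir == "HYPER" and de_dir == "DOWN")
                or (mdir == "HYPO" and de_dir == "UP"),
            }
        )
    if missing:
        logger.info("concordance_table: %d methylation genes absent from expression data", missing)
    return pd.DataFrame(
        rows,
        columns=["gene", "meth_direction", "fold_change", "p_value", "de_direction", "de_significant", "concordant"],
    )
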