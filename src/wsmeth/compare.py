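"""Cross-platform / cross-dataset replication of a DMP list.

A DMP list from one array design (e.g. EPIC) is intersected with another
design's probe universe (e.g. 450k), re-tested by per-probe ANOVA in a
second two-group dataset, and counted at a strict (p < 0.001) and a loose
(p < 0.05) tier; direction concordance (sign of the second-dataset delta
vs the reference delta) is tabulated among loose-tier replicated probes.
A per-probe case/control variance-ratio column from the second dataset is
reported but never acted upon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .array_io import BetaMatrix
from .dmp import _anova_matrix

logger = logging.getLogger(__name__)

__all__ = ["ReplicationReport", "intersect_universe", "replicate"]


@dataclass
class ReplicationReport:
    n_input: int
    n_in_universe: int
    n_replicated_strict: int  # p < 0.001
    n_replicated_loose: int  # p < 0.05
    n_concordant_direction: int  # among loose-replicated
    records: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def __post_init__(self):
        ok = (
            0
            <= self.n_replicated_strict
            <= self.n_replicated_loose
            <= self.n_in_universe
            <= self.n_input
        ) and self.n_concordant_direction <= self.n_replicated_loose
        if not ok:
            raise ValueError("replication counts violate ordering invariants")


def intersect_universe(dmp_probe_ids: Sequence, universe_probe_ids: Iterable) -> list:
    """Order-preserving intersection of a DMP list with a probe universe."""
    universe = set(universe_probe_ids)
    return [p for p in dmp_probe_ids if p in universe]


def replicate(
    subset: Sequence,
    other_betas: BetaMatrix,
    reference_deltas: Mapping,
    strict_p: float = 0.001,
    loose_p: float = 0.05,
    n_input: int | None = None,
) -> ReplicationReport:
    """Re-test ``subset`` probes in a second dataset and count replication.

    ``reference_deltas`` maps probe id -> delta from the discovery dataset;
    concordance means the second-dataset delta has the same sign.  Probes
    absent from ``other_betas`` are dropped and counted.  ``n_input``
    defaults to len(subset) (pass the original pre-intersection count when
    the universe intersection happened upstream).
    """
    mat = other_betas.drop_incomplete()
    case, ctrl = mat.group_split()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("replication dataset needs at least 2 samples per group")
    present = mat.subset(subset)
    n_missing = len(subset) - len(present.probe_ids)
    if n_missing:
        logger.info("replicate: %d probes absent from the second dataset", n_missing)
    case2, ctrl2 = present.group_split()
    if len(present.probe_ids):
        _, p = _anova_matrix(case2, ctrl2)
        delta2 = case2.mean(axis=1) - ctrl2.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_ratio = case2.var(axis=1, ddof=1) / ctrl2.var(axis=1, ddof=1)
    else:
        p = delta2 = var_ratio = np.array([])
    ref = np.array([reference_deltas.get(pid, np.nan) for pid in present.probe_ids])
    loose = p < loose_p
    concordant = loose & (np.sign(delta2) == np.sign(ref))
    records = pd.DataFrame(
        {
            "probe_id": present.probe_ids,
            "p_value": p,
            "delta": delta2,
            "reference_delta": ref,
            "replicated_strict": p < strict_p,
            "replicated_loose": loose,
            "concordant": concordant,
            "variance_ratio_case_ctrl": var_ratio,
        }
    )
    return ReplicationReport(
        n_input=n_input if n_input is not None else len(subset),
        n_in_universe=len(subset),
        n_replicated_strict=int((p < strict_p).sum()),
        n_replicated_loose=int(loose.sum()),
        n_concordant_direction=int(concordant.sum()),
        records=records,
    )
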