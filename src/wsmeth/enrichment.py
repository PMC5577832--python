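"""Gene-set enrichment with a Fisher-p x rank-z combined score.

For each library term the overlap with the input gene list is scored by a
one-sided Fisher exact test against a background universe (by default the
union of all library genes).  A second, rank-based component measures how
much better a term ranks for the observed list than for random gene lists
of the same size: terms are ranked by Fisher p for many random input sets,
and z = (observed_rank - mean_null_rank) / sd_null_rank, so negative z
means better than expected.  The reported combined score is

    c = ln(p) * z

(natural log; ln(p) <= 0, so strongly enriched terms get large positive
c).  Results are filtered at p < p_cut and sorted by descending |c|.
The exact null is enumerated automatically whenever the number of possible
input sets is small; otherwise the null is sampled with a seeded RNG, so a
fixed seed makes the whole ranking bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .array_io import GeneSetLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "fisher_overlap",
    "rank_zscore",
    "enrich",
    "enrichment_to_frame",
]

#: enumerate the exact null when C(|background|, input_size) is at most this
EXHAUSTIVE_LIMIT = 100_000


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_k: int
    term_size_K: int
    input_size: int
    p_value: float
    z: float
    combined_score: float
    overlapping_genes: frozenset


def _fisher_p(k: int, n_input: int, K: int, N: int) -> float:
    """One-sided (greater) Fisher p = P(X >= k), X ~ Hypergeom(N, K, n_input)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n_input))


def fisher_overlap(
    input_genes: Iterable, term_genes: Iterable, background: Iterable
) -> tuple[int, int, float]:
    """Overlap test of an input list against one term -> (k, K, p).

    Genes outside the background are dropped (and counted in the log)
    before the 2x2 table is formed.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("empty background universe")
    inp = frozenset(input_genes)
    term = frozenset(term_genes)
    dropped = len(inp - bg) + len(term - bg)
    if dropped:
        logger.debug("fisher_overlap: %d genes outside background dropped", dropped)
    inp &= bg
    term &= bg
    k = len(inp & term)
    return k, len(term), _fisher_p(k, len(inp), len(term), len(bg))


def _term_ranks(library: GeneSetLibrary, pvals: dict) -> dict:
    """Ordinal ranks 1..T by ascending p, ties broken by term_id."""
    order = sorted(library.terms, key=lambda t: (pvals[t], t))
    return {t: r for r, t in enumerate(order, start=1)}


def _rank_stats_for_set(library: GeneSetLibrary, gene_set: frozenset, bg: frozenset) -> dict:
    pvals = {
        t: _fisher_p(len(gene_set & genes), len(gene_set), len(genes & bg), len(bg))
        for t, (_, genes) in library.terms.items()
    }
    return _term_ranks(library, pvals)


def rank_zscore(
    library: GeneSetLibrary,
    input_size: int,
    observed_ranks: dict,
    background: Iterable | None = None,
    n_null: int = 1000,
    seed: int | None = None,
) -> dict:
    """Per-term z-score of the observed rank against the random-list null.

    Draws ``n_null`` uniform gene sets of ``input_size`` from the
    background (exhaustive enumeration replaces sampling when feasible),
    ranks every term by Fisher p for each draw, and standardises the
    observed rank: z = (observed - mean) / sd.  A term whose null rank is
    constant (sd = 0) gets z = 0 with a warning.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    bg = frozenset(background) if background is not None else library.all_genes
    if input_size > len(bg):
        raise ValueError(f"input_size {input_size} exceeds background size {len(bg)}")
    bg_list = sorted(bg)
    n_sets = math.comb(len(bg_list), input_size)
    terms = list(library.terms)
    if n_sets <= EXHAUSTIVE_LIMIT:
        draws = [frozenset(c) for c in combinations(bg_list, input_size)]
    else:
        rng = np.random.default_rng(seed)
        draws = [
            frozenset(rng.choice(len(bg_list), size=input_size, replace=False).tolist())
            for _ in range(n_null)
        ]
        draws = [frozenset(bg_list[i] for i in idx) for idx in draws]
    rank_rows = np.empty((len(draws), len(terms)))
    for row, gene_set in enumerate(draws):
        r = _rank_stats_for_set(library, gene_set, bg)
        rank_rows[row] = [r[t] for t in terms]
    mu = rank_rows.mean(axis=0)
    sd = rank_rows.std(axis=0, ddof=0)
    out = {}
    for j, t in enumerate(terms):
        if sd[j] == 0:
            if len(terms) > 1:
                logger.warning("rank_zscore: term %s has constant null rank; z set to 0", t)
            out[t] = 0.0
        else:
            out[t] = float((observed_ranks[t] - mu[j]) / sd[j])
    return out


def enrich(
    gene_list: Iterable,
    library: GeneSetLibrary,
    background: Iterable | None = None,
    p_cut: float = 0.05,
    n_null: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Rank library terms for a gene list by the combined score.

    Returns terms with Fisher p strictly below ``p_cut``, sorted by
    descending |c| (c = ln(p) * z), ties by ascending p then term_id.
    """
    bg = frozenset(background) if background is not None else library.all_genes
    inp = frozenset(str(g).upper() for g in gene_list) & bg
    if not inp:
        logger.warning("enrich: gene list empty after background intersection")
        return []
    pvals, overlaps = {}, {}
    for term_id, (_, genes) in library.terms.items():
        k, K, p = fisher_overlap(inp, genes, bg)
        pvals[term_id] = p
        overlaps[term_id] = (k, K, inp & genes)
    observed_ranks = _term_ranks(library, pvals)
    z = rank_zscore(
        library, len(inp), observed_ranks, background=bg, n_null=n_null, seed=seed
    )
    results = []
    for term_id, (name, _) in library.terms.items():
        p = pvals[term_id]
        if not (p < p_cut):
            continue
        k, K, genes_overlap = overlaps[term_id]
        c = math.log(p) * z[term_id]
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=name,
                overlap_k=k,
                term_size_K=K,
                input_size=len(inp),
                p_value=p,
                z=z[term_id],
                combined_score=c,
                overlapping_genes=frozenset(genes_overlap),
            )
        )
    results.sort(key=lambda r: (-abs(r.combined_score), r.p_value, r.term_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "overlap": [f"{r.overlap_k}/{r.term_size_K}" for r in results],
            "p_value": [r.p_value for r in results],
            "z": [r.z for r in results],
            "combined_score": [r.combined_score for r in results],
            "overlapping_genes": [",".join(sorted(r.overlapping_genes)) for r in results],
        }
    )
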