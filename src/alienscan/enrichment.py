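"""GO-term enrichment of the candidate set by one-sided Fisher's exact test.

For each GO term annotated to at least one candidate, a 2×2 table is built
(candidates with/without the term vs. background genes with/without it) and
the over-representation tail probability computed with Fisher's exact test.
P-values are corrected across terms with the Benjamini–Hochberg step-up
procedure; terms with FDR q ≤ alpha are flagged enriched.

This is a flat per-term test (topGO-classic-equivalent); no GO-graph
weighting or ancestor propagation is applied — input annotations are taken
as given. The background is the set of annotated non-candidate genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("alienscan")

__all__ = ["EnrichmentResult", "fisher_exact_greater", "benjamini_hochberg", "enrich"]


@dataclass
class EnrichmentResult:
    """One GO term's 2×2 enrichment outcome.

    a/b: candidates with/without the term; c/d: background genes
    with/without it.
    """

    term: str
    a: int
    b: int
    c: int
    d: int
    p: float
    fdr_q: float
    enriched: bool


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher's exact p for a 2×2 table."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    candidate_ids: Iterable[str],
    annotations: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-term enrichment of candidates vs. annotated background genes.

    Terms present only in the background are not reported. Results are
    sorted by (q, p, term); ``enriched`` flags q ≤ alpha.
    """
    candidates = set(candidate_ids)
    annotated = set(annotations)
    cand_annotated = candidates & annotated
    background = annotated - candidates
    if not cand_annotated:
        logger.warning("no annotated candidate genes; enrichment skipped")
        return []

    terms = sorted({t for g in cand_annotated for t in annotations[g]})
    n_cand = len(cand_annotated)
    n_bg = len(background)
    results = []
    for term in terms:
        a = sum(1 for g in cand_annotated if term in annotations[g])
        c = sum(1 for g in background if term in annotations[g])
        p = fisher_exact_greater(a, n_cand - a, c, n_bg - c)
        results.append(EnrichmentResult(term, a, n_cand - a, c, n_bg - c, p, 1.0, False))

    qs = benjamini_hochberg([r.p for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)
        r.enriched = r.fdr_q <= alpha
    results.sort(key=lambda r: (r.fdr_q, r.p, r.term))
    return results
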