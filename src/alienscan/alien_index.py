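"""Alien Index scoring and three-way classification of genes.

The Alien Index (AI) of a gene contrasts how well it aligns to metazoan
versus non-metazoan sequences:

    AI = log10(best metazoan E-value + 1e-200)
       - log10(best non-metazoan E-value + 1e-200)

A side with no hits contributes E = 1, so a gene whose only strong hits are
non-metazoan scores highly positive. With the 1e-200 pseudocount and base-10
logs the score lives in [-200, 200] and reads as "orders of magnitude of
E-value separation". Genes scoring >= 45 are classified FOREIGN, [0, 45)
INDETERMINATE, and < 0 METAZOAN.

Classification alone is not enough: a gene only becomes an HGT candidate
when its single best (lowest-E) informative hit also falls in a donor
lineage (bacteria, archaea, unicellular algae or fungi) — the taxon
prefilter. Hits to the focal species or to other choanoflagellates are
ignored throughout, as they carry no donor signal.

The natural log is available via ``log_base`` for cross-checking against
other Alien Index implementations; base 10 is the default, under which the
printed pseudocount yields the clean ±200 range.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import HomologyHit
from .taxonomy import AiSide, LineageCategory, LineageMap, ai_partition, is_potential_donor

logger = logging.getLogger("alienscan")

__all__ = [
    "AiClass",
    "AlienIndexRecord",
    "best_evalues",
    "alien_index",
    "classify_ai",
    "screen_genome",
    "group_hits_by_gene",
    "records_to_frame",
    "frame_to_records",
]

DEFAULT_PSEUDOCOUNT = 1e-200
DEFAULT_FOREIGN_THRESHOLD = 45.0


class AiClass(str, enum.Enum):
    FOREIGN = "FOREIGN"
    INDETERMINATE = "INDETERMINATE"
    METAZOAN = "METAZOAN"


@dataclass
class AlienIndexRecord:
    """Per-gene Alien Index result.

    ``best_hit_category`` is the lineage category of the overall lowest-E
    non-excluded hit (None when the gene has no informative hits);
    ``passed_taxon_filter`` records whether that category is a potential
    donor lineage. The candidate set is
    ``passed_taxon_filter and ai_class is FOREIGN``.
    """

    gene_id: str
    best_metazoan_E: float
    best_nonmetazoan_E: float
    best_hit_category: LineageCategory | None
    ai: float
    ai_class: AiClass
    passed_taxon_filter: bool

    @property
    def is_candidate(self) -> bool:
        return self.passed_taxon_filter and self.ai_class is AiClass.FOREIGN


def _capped_evalue(e: float) -> float:
    # An E-value above 1 must not outrank "no hit" (side floor = 1).
    return min(e, 1.0)


def best_evalues(
    hits: Sequence[HomologyHit], lmap: LineageMap
) -> tuple[float, float, LineageCategory | None]:
    """Best (minimum) E-value per Alien Index side for one gene's hits.

    Hits on the EXCLUDED side (self / choanoflagellate) are ignored both for
    the side minima and for the best-hit category. A side with no hits gets
    E = 1. The best-hit category is that of the minimum-E informative hit,
    ties broken by higher bitscore, then lexicographic subject id.
    """
    if hits:
        queries = {h.query_id for h in hits}
        if len(queries) > 1:
            raise ValueError(f"hits span multiple queries: {sorted(queries)}")

    best_meta = 1.0
    best_nonmeta = 1.0
    best_overall: HomologyHit | None = None
    best_overall_cat: LineageCategory | None = None
    for hit in hits:
        cat = lmap.categorize(hit.subject_taxid)
        side = ai_partition(cat)
        if side is AiSide.EXCLUDED:
            continue
        e = _capped_evalue(hit.evalue)
        if side is AiSide.METAZOAN_SIDE:
            best_meta = min(best_meta, e)
        else:
            best_nonmeta = min(best_nonmeta, e)
        if best_overall is None or (e, -hit.bitscore, hit.subject_id) < (
            _capped_evalue(best_overall.evalue),
            -best_overall.bitscore,
            best_overall.subject_id,
        ):
            best_overall = hit
            best_overall_cat = cat
    return best_meta, best_nonmeta, best_overall_cat


def alien_index(
    best_metazoan_E: float,
    best_nonmetazoan_E: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = 10,
) -> float:
    """Alien Index score from the two side-best E-values.

    ``log(bm + pseudocount) - log(bn + pseudocount)`` in the configured base
    (10 or *e*). Antisymmetric in its arguments; monotone non-decreasing in
    the metazoan E-value and non-increasing in the non-metazoan one.
    """
    if best_metazoan_E < 0 or best_nonmetazoan_E < 0:
        raise ValueError("E-values must be non-negative")
    if log_base == 10:
        return math.log10(best_metazoan_E + pseudocount) - math.log10(
            best_nonmetazoan_E + pseudocount
        )
    if log_base in (math.e, "e"):
        return math.log(best_metazoan_E + pseudocount) - math.log(
            best_nonmetazoan_E + pseudocount
        )
    raise ValueError(f"unsupported log base {log_base!r}")


def classify_ai(ai: float, foreign_threshold: float = DEFAULT_FOREIGN_THRESHOLD) -> AiClass:
    """Three-band classification: >= threshold FOREIGN, [0, threshold)
    INDETERMINATE, < 0 METAZOAN. FOREIGN wins the boundary at exactly the
    threshold."""
    if ai >= foreign_threshold:
        return AiClass.FOREIGN
    if ai >= 0:
        return AiClass.INDETERMINATE
    return AiClass.METAZOAN


def group_hits_by_gene(hits: Iterable[HomologyHit]) -> dict[str, list[HomologyHit]]:
    grouped: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def screen_genome(
    hits_by_gene: Mapping[str, Sequence[HomologyHit]],
    lmap: LineageMap,
    gene_ids: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = 10,
    foreign_threshold: float = DEFAULT_FOREIGN_THRESHOLD,
) -> list[AlienIndexRecord]:
    """Score every gene in the genome and apply the donor-taxon prefilter.

    Genes with no hits at all (or only excluded hits) get (1, 1) side
    E-values, AI = 0 and class INDETERMINATE — these are the
    "focal-species-specific" bucket, never candidates. Genes present in the
    hit table but absent from ``gene_ids`` are still scored, with a warning.
    """
    extra = sorted(set(hits_by_gene) - set(gene_ids))
    if extra:
        logger.warning(
            "%d genes in the hit table are absent from the genome list (e.g. %s)",
            len(extra),
            extra[:3],
        )
    records: list[AlienIndexRecord] = []
    for gene_id in list(gene_ids) + extra:
        gene_hits = hits_by_gene.get(gene_id, ())
        bm, bn, cat = best_evalues(gene_hits, lmap)
        ai = alien_index(bm, bn, pseudocount=pseudocount, log_base=log_base)
        records.append(
            AlienIndexRecord(
                gene_id=gene_id,
                best_metazoan_E=bm,
                best_nonmetazoan_E=bn,
                best_hit_category=cat,
                ai=ai,
                ai_class=classify_ai(ai, foreign_threshold),
                passed_taxon_filter=cat is not None and is_potential_donor(cat),
            )
        )
    return records


def records_to_frame(records: Sequence[AlienIndexRecord]):
    """Tabular view of AI records (round-trips through the TSV writer)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "best_metazoan_E": [r.best_metazoan_E for r in records],
            "best_nonmetazoan_E": [r.best_nonmetazoan_E for r in records],
            "best_hit_category": [
                r.best_hit_category.value if r.best_hit_category else "NONE"
                for r in records
            ],
            "ai": [r.ai for r in records],
            "ai_class": [r.ai_class.value for r in records],
            "passed_taxon_filter": [r.passed_taxon_filter for r in records],
            "is_candidate": [r.is_candidate for r in records],
        }
    )


def frame_to_records(df) -> list[AlienIndexRecord]:
    records = []
    for row in df.itertuples(index=False):
        cat = None if row.best_hit_category == "NONE" else LineageCategory(row.best_hit_category)
        records.append(
            AlienIndexRecord(
                gene_id=str(row.gene_id),
                best_metazoan_E=float(row.best_metazoan_E),
                best_nonmetazoan_E=float(row.best_nonmetazoan_E),
                best_hit_category=cat,
                ai=float(row.ai),
                ai_class=AiClass(row.ai_class),
                passed_taxon_filter=bool(row.passed_taxon_filter),
            )
        )
    return records
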