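"""Per-gene architecture statistics and candidate-vs-background comparison.

Recently transferred genes tend to carry donor-like sequence signatures;
genes acquired long ago ameliorate toward the host. Four per-gene features
are profiled:

* CDS length (nt);
* GC3 — fraction of G/C at synonymous third codon positions (Met, Trp and
  stop codons excluded, matching the GC3s convention; an all-positions
  variant is available);
* CBI — codon bias index, (Nopt − Nrand) / (Ntot − Nrand), where Nopt is
  the number of codons using an "optimal" synonym, Ntot the number of
  codons of amino acids with ≥ 2 synonyms, and Nrand the count expected
  under uniform synonymous usage. CBI is 1 when only optimal codons are
  used and ~0 under random usage;
* intron count (exons − 1 from the gene model).

Optimal codons are derived from a reference gene set by synonymous-usage
argmax (most frequent synonym per amino acid, ties keeping all tied
codons). Candidate and background feature distributions are compared with
the Kruskal–Wallis rank test (tie-corrected, chi-square approximation),
which for two groups is the standard rank-sum comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .io_formats import GeneModel, STOP_CODONS

logger = logging.getLogger("alienscan")

__all__ = [
    "OptimalCodonSet",
    "GroupComparison",
    "gc3",
    "cbi",
    "derive_optimal_codons",
    "kruskal_wallis",
    "architecture_table",
    "architecture_report",
    "SYNONYM_SETS",
]


def _standard_synonym_sets() -> dict[str, frozenset[str]]:
    """Amino acid → synonymous codon set from the standard genetic code."""
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, set[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, set()).add(codon)
    return {aa: frozenset(codons) for aa, codons in by_aa.items()}


SYNONYM_SETS = _standard_synonym_sets()
_CODON_TO_AA = {
    codon: aa for aa, codons in SYNONYM_SETS.items() for codon in codons
}
#: Amino acids with ≥ 2 synonymous codons (CBI-eligible).
ELIGIBLE_AA = frozenset(aa for aa, codons in SYNONYM_SETS.items() if len(codons) >= 2)
#: Codons excluded from GC3 under the synonymous convention.
_GC3_EXCLUDED = frozenset({"ATG", "TGG"}) | STOP_CODONS


@dataclass
class OptimalCodonSet:
    """Per-amino-acid optimal codon sets (proper, non-empty subsets).

    Amino acids absent from the mapping are excluded from CBI eligibility
    (the reference set contained no codon of that amino acid).
    """

    optimal: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for aa, codons in self.optimal.items():
            syn = SYNONYM_SETS.get(aa)
            if syn is None or aa not in ELIGIBLE_AA:
                raise ValueError(f"{aa!r} is not a CBI-eligible amino acid")
            if not codons or not codons <= syn:
                raise ValueError(f"optimal set for {aa} must be a non-empty subset of its synonyms")
            if codons == syn:
                raise ValueError(f"optimal set for {aa} must be a proper subset")


@dataclass
class GroupComparison:
    """Kruskal–Wallis comparison of one feature across groups."""

    statistic_name: str
    H: float
    df: int
    p_value: float
    group_medians: dict[str, float]
    group_sizes: dict[str, int]


def _codons(sequence: str) -> list[str]:
    """Complete codons of an upper-cased CDS, trailing partial codon and a
    terminal stop dropped."""
    seq = sequence.upper()
    usable = len(seq) - len(seq) % 3
    codons = [seq[i : i + 3] for i in range(0, usable, 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons.pop()
    return codons


def gc3(cds_sequence: str, synonymous: bool = True) -> float | None:
    """GC fraction at third codon positions.

    With ``synonymous=True`` (default, the GC3s convention) codons for Met
    and Trp and stop codons are not counted; codons containing N are always
    dropped. Returns None when no countable codon remains.
    """
    countable = 0
    gc = 0
    for codon in _codons(cds_sequence):
        if "N" in codon:
            continue
        if synonymous and codon in _GC3_EXCLUDED:
            continue
        countable += 1
        if codon[2] in "GC":
            gc += 1
    if countable == 0:
        return None
    return gc / countable


def cbi(cds_sequence: str, optimal: OptimalCodonSet) -> float | None:
    """Codon bias index of one CDS against an optimal-codon set.

    CBI = (Nopt − Nrand) / (Ntot − Nrand) with Nrand = Σ_aa n_aa·k_aa/s_aa
    (k_aa optimal codons among s_aa synonyms). Returns None when the gene
    has no codons of eligible amino acids or the denominator degenerates.
    """
    n_tot = 0
    n_opt = 0
    n_rand = 0.0
    for codon in _codons(cds_sequence):
        aa = _CODON_TO_AA.get(codon)
        if aa is None or aa not in optimal.optimal:
            continue
        opt_set = optimal.optimal[aa]
        n_tot += 1
        if codon in opt_set:
            n_opt += 1
        n_rand += len(opt_set) / len(SYNONYM_SETS[aa])
    if n_tot == 0 or math.isclose(n_tot, n_rand):
        return None
    return (n_opt - n_rand) / (n_tot - n_rand)


def derive_optimal_codons(reference_genes: Sequence[GeneModel]) -> OptimalCodonSet:
    """Optimal codon per eligible amino acid by usage argmax over a
    reference set (ties keep all tied codons; a full tie across all
    synonyms, or an absent amino acid, drops the amino acid from
    eligibility)."""
    if len(reference_genes) < 10:
        raise ValueError("need at least 10 reference genes to derive optimal codons")
    counts: dict[str, int] = {}
    for gene in reference_genes:
        for codon in _codons(gene.cds_sequence):
            if codon in _CODON_TO_AA:
                counts[codon] = counts.get(codon, 0) + 1
    optimal: dict[str, frozenset[str]] = {}
    for aa in sorted(ELIGIBLE_AA):
        syn = SYNONYM_SETS[aa]
        aa_counts = {c: counts.get(c, 0) for c in syn}
        total = sum(aa_counts.values())
        if total == 0:
            logger.warning("amino acid %s absent from reference set; excluded from CBI", aa)
            continue
        top = max(aa_counts.values())
        winners = frozenset(c for c, n in aa_counts.items() if n == top)
        if winners == syn:
            logger.warning("all synonyms of %s tied in reference set; excluded from CBI", aa)
            continue
        optimal[aa] = winners
    return OptimalCodonSet(optimal=optimal)


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal–Wallis H test across ≥ 2 non-empty groups.

    Mid-ranks for ties, the standard tie correction, and an upper
    chi-square tail with df = groups − 1. When every pooled value is tied
    the statistic is defined as 0 with p = 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(list(groups.values()))
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    df = len(groups) - 1
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    sizes = {k: len(v) for k, v in groups.items()}

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n**3 - n) if n > 1 else 0.0
    if correction == 0.0:  # all pooled values identical
        return GroupComparison("kruskal_wallis", 0.0, df, 1.0, medians, sizes)

    h = 12.0 / (n * (n + 1))
    offset = 0
    rank_sum_sq = 0.0
    for v in groups.values():
        r = ranks[offset : offset + len(v)]
        offset += len(v)
        rank_sum_sq += r.sum() ** 2 / len(v)
    h = (h * rank_sum_sq - 3 * (n + 1)) / correction
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df))
    return GroupComparison("kruskal_wallis", float(h), df, p, medians, sizes)


def architecture_table(
    genes: Sequence[GeneModel],
    candidate_ids: Iterable[str],
    optimal: OptimalCodonSet | None = None,
    gc3_synonymous: bool = True,
) -> pd.DataFrame:
    """Per-gene feature table: cds_length, gc3, cbi, intron_count,
    is_candidate. Genes whose GC3/CBI is undefined carry NaN there.

    Optimal codons default to a derivation over all genes with sequence.
    """
    with_seq = [g for g in genes if g.cds_sequence]
    if optimal is None:
        optimal = derive_optimal_codons(with_seq)
    candidates = set(candidate_ids)
    rows = []
    for g in genes:
        g3 = gc3(g.cds_sequence, synonymous=gc3_synonymous) if g.cds_sequence else None
        cb = cbi(g.cds_sequence, optimal) if g.cds_sequence else None
        rows.append(
            {
                "gene_id": g.gene_id,
                "cds_length": g.cds_length,
                "gc3": np.nan if g3 is None else g3,
                "cbi": np.nan if cb is None else cb,
                "intron_count": g.intron_count,
                "is_candidate": g.gene_id in candidates,
            }
        )
    return pd.DataFrame(rows)


FEATURES = ("cds_length", "gc3", "cbi", "intron_count")


def architecture_report(
    table: pd.DataFrame,
    background: str = "noncandidate",
) -> dict[str, GroupComparison]:
    """Candidate-vs-background Kruskal–Wallis comparison per feature.

    ``background`` selects the comparison group: "noncandidate" (default)
    or "all" (the full genome, candidates included). Genes with a missing
    feature value are excluded from that feature's test. With fewer than
    two candidates the tests are skipped with a warning.
    """
    if background not in {"noncandidate", "all"}:
        raise ValueError("background must be 'noncandidate' or 'all'")
    cand = table[table["is_candidate"]]
    if len(cand) < 2:
        logger.warning("fewer than 2 candidate genes; architecture tests skipped")
        return {}
    bg = table if background == "all" else table[~table["is_candidate"]]
    comparisons: dict[str, GroupComparison] = {}
    for feature in FEATURES:
        cv = cand[feature].dropna().to_numpy()
        bv = bg[feature].dropna().to_numpy()
        if len(cv) < 2 or len(bv) < 2:
            logger.warning("feature %s: too few defined values; test skipped", feature)
            continue
        cmp = kruskal_wallis({"candidate": cv, "background": bv})
        cmp.statistic_name = feature
        comparisons[feature] = cmp
    return comparisons
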