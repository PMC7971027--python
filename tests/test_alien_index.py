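import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alienscan.alien_index import (
    AiClass,
    alien_index,
    best_evalues,
    classify_ai,
    group_hits_by_gene,
    screen_genome,
)
from alienscan.io_formats import HomologyHit
from alienscan.taxonomy import LineageCategory, LineageMap, ai_partition, AiSide, is_potential_donor


def ai_oracle(bm, bn, digits=50):
    """Arbitrary-precision evaluation of log10(bm+1e-200) - log10(bn+1e-200)."""
    import sympy

    pc = sympy.Rational(1, 10) ** 200
    expr = sympy.log(sympy.Float(bm, digits) + pc, 10) - sympy.log(
        sympy.Float(bn, digits) + pc, 10
    )
    return float(expr.evalf(digits))


LMAP = LineageMap(
    entries={
        562: LineageCategory.BACTERIA,
        9606: LineageCategory.METAZOA,
        81824: LineageCategory.CHOANOFLAGELLATA,
        946362: LineageCategory.SELF,
        4932: LineageCategory.UNICELLULAR_FUNGUS,
    }
)


def hit(taxid, evalue, query="g1", subject=None, bitscore=100.0):
    return HomologyHit(query, subject or f"s{taxid}_{evalue}", taxid, evalue, bitscore)


class TestAlienIndexFormula:
    @pytest.mark.parametrize(
        "bm,bn,expected",
        [
            (1e-50, 1e-50, 0.0),
            (1.0, 1e-45, 45.0),
            (0.0, 0.0, 0.0),
            (1.0, 0.0, 200.0),
        ],
    )
    def test_frozen_values_match_arbitrary_precision(self, bm, bn, expected):
        value = alien_index(bm, bn)
        assert value == pytest.approx(expected, abs=1e-9)
        assert value == pytest.approx(ai_oracle(bm, bn), abs=1e-9)

    def test_natural_log_base(self):
        assert alien_index(1.0, 1e-45, log_base=math.e) == pytest.approx(
            45.0 * math.log(10), abs=1e-9
        )

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            alien_index(-1e-3, 1e-5)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        b=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert alien_index(a, b) == pytest.approx(-alien_index(b, a), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        b=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        b2=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    def test_monotone_in_each_argument(self, a, b, b2):
        lo, hi = min(b, b2), max(b, b2)
        # non-increasing in the non-metazoan E, non-decreasing in the metazoan E
        assert alien_index(a, lo) >= alien_index(a, hi) - 1e-12
        assert alien_index(lo, a) <= alien_index(hi, a) + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "ai,expected",
        [
            (45.0, AiClass.FOREIGN),
            (200.0, AiClass.FOREIGN),
            (44.999999, AiClass.INDETERMINATE),
            (10.0, AiClass.INDETERMINATE),
            (0.0, AiClass.INDETERMINATE),
            (-3.0, AiClass.METAZOAN),
            (-200.0, AiClass.METAZOAN),
        ],
    )
    def test_three_band_rule(self, ai, expected):
        assert classify_ai(ai) is expected

    def test_custom_threshold(self):
        assert classify_ai(30.0, foreign_threshold=30.0) is AiClass.FOREIGN


class TestBestEvalues:
    def test_minima_per_side(self):
        bm, bn, cat = best_evalues([hit(562, 1e-80), hit(9606, 1e-20)], LMAP)
        assert (bm, bn, cat) == (1e-20, 1e-80, LineageCategory.BACTERIA)

    def test_choanoflagellate_hits_excluded(self):
        bm, bn, cat = best_evalues([hit(81824, 1e-90), hit(9606, 1e-20)], LMAP)
        assert (bm, bn, cat) == (1e-20, 1.0, LineageCategory.METAZOA)

    def test_self_hits_excluded(self):
        bm, bn, cat = best_evalues([hit(946362, 0.0), hit(562, 1e-30)], LMAP)
        assert (bm, bn, cat) == (1.0, 1e-30, LineageCategory.BACTERIA)

    def test_no_hits_floors_both_sides(self):
        assert best_evalues([], LMAP) == (1.0, 1.0, None)

    def test_evalue_above_one_capped(self):
        bm, bn, _ = best_evalues([hit(9606, 3.0)], LMAP)
        assert bm == 1.0

    def test_tie_broken_by_higher_bitscore(self):
        hits = [
            hit(9606, 1e-30, subject="a", bitscore=50.0),
            hit(562, 1e-30, subject="b", bitscore=90.0),
        ]
        assert best_evalues(hits, LMAP)[2] is LineageCategory.BACTERIA

    def test_multiple_queries_rejected(self):
        with pytest.raises(ValueError, match="multiple queries"):
            best_evalues([hit(562, 1e-9, query="g1"), hit(562, 1e-9, query="g2")], LMAP)


def brute_force_candidates(hits, lmap, gene_ids, threshold=45.0):
    """Independent re-derivation of the candidate set: scan every hit per
    gene without grouping, side minima by partition, AI by direct formula."""
    candidates = set()
    for gene in gene_ids:
        gene_hits = [h for h in hits if h.query_id == gene]
        bm = bn = 1.0
        best = None
        for h in gene_hits:
            cat = lmap.categorize(h.subject_taxid)
            side = ai_partition(cat)
            if side is AiSide.EXCLUDED:
                continue
            e = min(h.evalue, 1.0)
            if side is AiSide.METAZOAN_SIDE:
                bm = min(bm, e)
            else:
                bn = min(bn, e)
            key = (e, -h.bitscore, h.subject_id)
            if best is None or key < best[0]:
                best = (key, cat)
        ai = math.log10(bm + 1e-200) - math.log10(bn + 1e-200)
        if best is not None and is_potential_donor(best[1]) and ai >= threshold:
            candidates.add(gene)
    return candidates


class TestScreenGenome:
    def test_bacterial_best_hit_becomes_candidate(self):
        hits = {"g1": [hit(562, 1e-60), hit(9606, 1e-4)]}
        (rec,) = screen_genome(hits, LMAP, ["g1"])
        assert rec.passed_taxon_filter
        assert rec.ai == pytest.approx(56.0, abs=1e-6)
        assert rec.ai_class is AiClass.FOREIGN
        assert rec.is_candidate

    def test_metazoan_best_hit_never_candidate(self):
        hits = {"g1": [hit(9606, 1e-90), hit(562, 1e-10)]}
        (rec,) = screen_genome(hits, LMAP, ["g1"])
        assert not rec.passed_taxon_filter and not rec.is_candidate

    def test_no_hits_indeterminate(self):
        (rec,) = screen_genome({}, LMAP, ["g1"])
        assert rec.best_metazoan_E == rec.best_nonmetazoan_E == 1.0
        assert rec.ai == 0.0
        assert rec.ai_class is AiClass.INDETERMINATE
        assert not rec.is_candidate

    def test_hit_for_unknown_gene_still_scored(self, caplog):
        hits = {"ghost": [hit(562, 1e-60, query="ghost")]}
        records = screen_genome(hits, LMAP, ["g1"])
        assert {r.gene_id for r in records} == {"g1", "ghost"}
        assert any("absent from the genome" in r.message for r in caplog.records)

    def test_candidates_subset_of_donor_affiliated(self):
        rng = np.random.default_rng(11)
        taxids = list(LMAP.entries)
        hits = []
        genes = [f"g{i}" for i in range(20)]
        for g in genes:
            for _ in range(rng.integers(0, 8)):
                hits.append(
                    hit(
                        int(rng.choice(taxids)),
                        float(10.0 ** rng.uniform(-120, 0)),
                        query=g,
                        subject=f"s{rng.integers(1e6)}",
                        bitscore=float(rng.uniform(30, 300)),
                    )
                )
        records = screen_genome(group_hits_by_gene(hits), LMAP, genes)
        donor_affiliated = {r.gene_id for r in records if r.passed_taxon_filter}
        assert {r.gene_id for r in records if r.is_candidate} <= donor_affiliated

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        taxids = list(LMAP.entries)
        genes = [f"g{i}" for i in range(rng.integers(5, 21))]
        hits = []
        for g in genes:
            for _ in range(rng.integers(0, 51)):
                hits.append(
                    hit(
                        int(rng.choice(taxids)),
                        float(10.0 ** rng.uniform(-120, 1)),
                        query=g,
                        subject=f"s{rng.integers(10**6)}",
                        bitscore=float(rng.uniform(30, 300)),
                    )
                )
        records = screen_genome(group_hits_by_gene(hits), LMAP, genes)
        assert {r.gene_id for r in records if r.is_candidate} == brute_force_candidates(
            hits, LMAP, genes
        )
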