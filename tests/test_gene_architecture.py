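import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alienscan.gene_architecture import (
    ELIGIBLE_AA,
    SYNONYM_SETS,
    OptimalCodonSet,
    architecture_report,
    architecture_table,
    cbi,
    derive_optimal_codons,
    gc3,
    kruskal_wallis,
)
from alienscan.io_formats import GeneModel


class TestGc3:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGCCC", 1.0),            # Gly, Pro: both thirds G/C
            ("AAATTT", 0.0),            # Lys, Phe: both thirds A/T
            ("ATGAAATAA", 0.0),         # ATG excluded, TAA stop dropped, AAA counts
            ("GGGAAA", 0.5),
        ],
    )
    def test_hand_counts(self, seq, expected):
        assert gc3(seq) == pytest.approx(expected)

    def test_case_and_terminal_stop_invariance(self):
        assert gc3("gggccc") == gc3("GGGCCC") == gc3("GGGCCCTAA")

    def test_codons_with_n_dropped(self):
        assert gc3("GGNAAA") == 0.0  # GGN dropped, AAA counted

    def test_trailing_partial_codon_dropped(self):
        assert gc3("GGGCC") == 1.0

    def test_no_countable_codon_is_missing(self):
        assert gc3("ATGTGG") is None
        assert gc3("NNN") is None

    def test_all_positions_variant_counts_met_and_trp(self):
        # ATG and TGG both end in G: naive GC3 = 1, synonymous = None
        assert gc3("ATGTGG", synonymous=False) == 1.0


LYS_OPTIMAL = OptimalCodonSet({"K": frozenset({"AAG"})})


class TestCbi:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAGAAGAAGAAG", 1.0),      # 4/4 optimal: (4-2)/(4-2)
            ("AAGAAGAAAAAA", 0.0),      # 2/4: (2-2)/(4-2)
            ("AAAAAAAAAAAA", -1.0),     # 0/4: (0-2)/(4-2)
        ],
    )
    def test_hand_evaluations(self, seq, expected):
        assert cbi(seq, LYS_OPTIMAL) == pytest.approx(expected)

    def test_ineligible_codons_ignored(self):
        # Met/Trp and amino acids outside the optimal table contribute nothing
        assert cbi("ATGAAGAAGAAGAAGTGG", LYS_OPTIMAL) == pytest.approx(1.0)

    def test_no_eligible_codon_is_missing(self):
        assert cbi("ATGTGG", LYS_OPTIMAL) is None

    def test_at_most_one(self):
        rng = np.random.default_rng(0)
        codons = rng.choice(["AAA", "AAG", "GGG", "GGC"], size=200)
        optimal = OptimalCodonSet(
            {"K": frozenset({"AAG"}), "G": frozenset({"GGC"})}
        )
        value = cbi("".join(codons), optimal)
        assert value is not None and value <= 1.0

    def test_near_zero_under_uniform_synonymous_usage(self):
        # 1e5 codons drawn uniformly within each amino acid's synonym set
        rng = np.random.default_rng(42)
        aas = sorted(ELIGIBLE_AA)
        optimal = OptimalCodonSet(
            {aa: frozenset({sorted(SYNONYM_SETS[aa])[0]}) for aa in aas}
        )
        codons = []
        for _ in range(100_000):
            aa = aas[rng.integers(len(aas))]
            syn = sorted(SYNONYM_SETS[aa])
            codons.append(syn[rng.integers(len(syn))])
        assert abs(cbi("".join(codons), optimal)) < 0.02


class TestOptimalCodons:
    def test_argmax_rule(self):
        genes = [GeneModel(f"g{i}", "AAG" * 7 + "AAA" * 3) for i in range(10)]
        opt = derive_optimal_codons(genes)
        assert opt.optimal["K"] == frozenset({"AAG"})

    def test_exact_tie_keeps_all_tied_codons(self):
        # Gly: GGA and GGC tied on top among 4 synonyms -> both optimal
        genes = [GeneModel(f"g{i}", "GGAGGC" * 3 + "GGG") for i in range(10)]
        opt = derive_optimal_codons(genes)
        assert opt.optimal["G"] == frozenset({"GGA", "GGC"})

    def test_full_tie_equivalent_to_all_optimal(self):
        # A 50/50 tie across ALL of Lys's synonyms makes every Lys codon
        # optimal, which contributes zero to both CBI numerator and
        # denominator; the amino acid is dropped, with identical CBI.
        genes = [GeneModel(f"g{i}", "AAGAAA" * 5 + "GGAGGA" * 3 + "GGC" * 2) for i in range(10)]
        opt = derive_optimal_codons(genes)
        assert "K" not in opt.optimal
        with_k = OptimalCodonSet({**opt.optimal, "K": frozenset({"AAA"})})
        seq = "GGAGGAGGC"  # no Lys: CBI identical whether K is eligible or not
        assert cbi(seq, opt) == cbi(seq, with_k)

    def test_absent_amino_acid_excluded(self, caplog):
        genes = [GeneModel(f"g{i}", "AAGAAA" * 5) for i in range(10)]
        opt = derive_optimal_codons(genes)
        assert "C" not in opt.optimal  # no Cys codons in the reference

    def test_too_few_reference_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            derive_optimal_codons([GeneModel("g1", "AAG")])

    def test_improper_optimal_set_rejected(self):
        with pytest.raises(ValueError, match="proper subset"):
            OptimalCodonSet({"K": frozenset({"AAA", "AAG"})})


class TestKruskalWallis:
    def test_hand_ranked_fixture(self):
        cmp = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert cmp.H == pytest.approx(3.857, abs=5e-4)
        assert cmp.df == 1

    def test_identical_groups_degenerate(self):
        cmp = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert cmp.H == 0.0 and cmp.p_value == 1.0

    def test_invariant_under_within_group_permutation(self):
        a, b, c = [3, 1, 4, 1, 5], [9, 2, 6], [5, 3, 5]
        h1 = kruskal_wallis({"a": a, "b": b, "c": c}).H
        h2 = kruskal_wallis({"a": a[::-1], "b": b[::-1], "c": c[::-1]}).H
        assert h1 == pytest.approx(h2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reference_implementation_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = int(rng.integers(2, 5))
        groups = {
            f"g{i}": rng.integers(0, 10, size=int(rng.integers(3, 51))).astype(float)
            for i in range(n_groups)
        }
        ours = kruskal_wallis(groups)
        ref = stats.kruskal(*groups.values())
        assert ours.H == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1, 2, 3]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": []})


def _table(candidate_gc3, background_gc3):
    n_c, n_b = len(candidate_gc3), len(background_gc3)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_c + n_b)],
            "cds_length": [900] * (n_c + n_b),
            "gc3": list(candidate_gc3) + list(background_gc3),
            "cbi": [0.1] * (n_c + n_b),
            "intron_count": [5] * (n_c + n_b),
            "is_candidate": [True] * n_c + [False] * n_b,
        }
    )


class TestArchitectureReport:
    def test_shifted_candidates_detected(self):
        rng = np.random.default_rng(3)
        table = _table(rng.normal(0.82, 0.05, 100), rng.normal(0.72, 0.05, 1000))
        report = architecture_report(table)
        gc3_cmp = report["gc3"]
        assert gc3_cmp.group_medians["candidate"] > gc3_cmp.group_medians["background"]
        assert gc3_cmp.p_value < 1e-3

    def test_null_pvalues_roughly_uniform(self):
        # candidates drawn from the background distribution: p ~ U(0,1)
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            table = _table(rng.normal(0.7, 0.05, 30), rng.normal(0.7, 0.05, 120))
            pvals.append(architecture_report(table)["gc3"].p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_candidate_skipped_with_warning(self, caplog):
        table = _table([0.8], [0.7, 0.71, 0.72])
        assert architecture_report(table) == {}
        assert any("skipped" in r.message for r in caplog.records)

    def test_background_all_includes_candidates(self):
        table = _table([0.9, 0.91], [0.7, 0.71, 0.72])
        rep_all = architecture_report(table, background="all")
        assert rep_all["gc3"].group_sizes["background"] == 5

    def test_table_from_gene_models(self, default_bundle):
        genes = default_bundle.genes[:50]
        table = architecture_table(genes, candidate_ids=[genes[0].gene_id])
        assert len(table) == 50
        assert table["is_candidate"].sum() == 1
        assert (table["cds_length"] % 3 == 0).all()
        assert table["gc3"].between(0, 1).all()
        assert (table["cbi"] <= 1 + 1e-12).all()
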