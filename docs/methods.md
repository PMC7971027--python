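# Methods

## The screening model

The pipeline treats horizontal-gene-transfer detection as a best-hit
contrast problem. For a gene *g* with homology hits filtered at E ≤ 10⁻⁵,
every hit subject is mapped to a lineage category and assigned to one side
of the Alien Index contrast: metazoan hits on one side, all
non-choanozoan lineages (bacteria, archaea, unicellular algae, unicellular
fungi, other eukaryotes) on the other. Hits to the focal species itself or
to other choanoflagellates are excluded from both sides: they are expected
for any gene regardless of origin and carry no donor signal (including
self-hits would drive AI toward 0 for every gene). Then

AI(g) = log₁₀(E_met + 10⁻²⁰⁰) − log₁₀(E_non + 10⁻²⁰⁰),

with E_met / E_non the side minima and a side with no hits contributing
E = 1. The pseudocount bounds the score to [−200, 200] and the base-10 log
makes AI read as "orders of magnitude by which the best non-metazoan hit
beats the best metazoan one". The source formula writes "log" without a
base; base 10 is the default here because the printed pseudocount then
yields the clean ±200 range and the 45 threshold reads as 45 orders of
magnitude; natural log is available via `log_base` for cross-checking
against other Alien Index implementations.

Classification: AI ≥ 45 → foreign; 0 ≤ AI < 45 → indeterminate; AI < 0 →
metazoan. The published band definitions overlap at exactly 45
("≥ 45 foreign" and "0 ≤ AI ≤ 45 indeterminate"); foreign takes precedence
because it is stated first and with "≥". E-values above 1 are capped at 1
on load so that a weak hit can never outrank "no hit".

A gene is an *AI candidate* only if it is foreign **and** its overall
best (lowest-E) informative hit falls in a donor lineage (bacteria,
archaea, unicellular algae, unicellular fungi); ties on E are broken by
higher bitscore, then lexicographic subject id. Genes with no informative
hits get (1, 1), AI = 0, indeterminate — the "focal-species-specific"
bucket, reported separately.

## Ortholog-distribution filter

OrthoMCL-style groups are reduced to a panel-group span per gene (the
union of memberships when a gene sits in several groups, with a warning).
The stratum call is an any-member rule: any fungal / filasterean / other
eukaryote member → eukaryote-wide; else any metazoan member → choanozoan
stem (Urchoanozoan); else any non-focal choanoflagellate →
choanoflagellate-only; else focal-only. Only the middle two strata are
retained: a eukaryote-wide distribution makes vertical descent (or a far
older transfer) the more parsimonious history, and orphans carry no
distributional evidence (`include_orphans` restores them for sensitivity
analyses). The any-member rule is strict — one contaminant metazoan
member promotes a gene out of choanoflagellate-only — which is one
defensible operationalization of "gained on the choanozoan stem"; the
group file, not the code, decides membership.

Conservation across choanoflagellate families is called from the same
members: all families (both craspedid clades + loricates), both craspedid
clades, clade 1 only, or focal only.

## Architecture statistics

* **GC3** follows the synonymous (GC3s) convention: complete codons only,
  terminal stop dropped, codons containing N dropped, Met (ATG), Trp (TGG)
  and stop codons excluded. `synonymous=False` gives the naive
  all-third-position variant; which one the source analysis used is not
  stated, so both exist and the synonymous form is the default.
* **CBI** = (Nopt − Nrand)/(Ntot − Nrand) over amino acids with ≥ 2
  synonymous codons, Nrand = Σ n_aa·(k_aa/s_aa). CBI = 1 iff only optimal
  codons are used; ≈ 0 under uniform synonymous usage (checked by
  simulation at 10⁵ codons).
* **Optimal codons** are derived by per-amino-acid usage argmax over a
  reference set (default: the whole genome). The original
  correspondence-analysis procedure (CodonW) is not reproducible from its
  description; the argmax rule is deterministic and preserves CBI's
  contract. Ties keep all tied codons; an amino acid whose synonyms all
  tie, or which is absent from the reference, is dropped from eligibility
  — numerically identical to declaring all its codons optimal, since such
  an amino acid adds equally to Nopt, Nrand and Ntot.
* **Kruskal–Wallis** is implemented directly (mid-ranks, the standard tie
  correction, chi-square upper tail with df = groups − 1) so that
  `scipy.stats.kruskal` remains an independent oracle in the tests; when
  every pooled value is tied the statistic is defined as H = 0, p = 1.
  With two groups this is the usual rank-sum comparison; no continuity
  correction. The default background is the non-candidate genes
  (`background="all"` compares against the whole genome, since published
  "overall" medians are ambiguous about including candidates).

## Expression and enrichment

A stage counts as expressed at TPM ≥ 1 — a conventional detectability
cut-off, exposed as `tpm_threshold`, because the underlying studies never
state theirs. Categories: all stages / some / none; raising the threshold
is monotone (stages can only be lost).

Enrichment is a flat one-sided Fisher's exact test per GO term present in
≥ 1 annotated candidate, against annotated non-candidate genes, with
Benjamini–Hochberg step-up FDR (q ≤ 0.05). No GO-graph weighting or
ancestor propagation is applied; annotations are taken as given.

## The synthetic generator

`SimulationScenario` defaults define the study conditions:

| parameter | default | why |
| --- | --- | --- |
| n_genes | 1000 | desk-scale stand-in for an ~11.7k-gene genome |
| alien_fraction | 0.05 | ~175/... retained of a few-percent candidate load |
| alien_urchoanozoan_fraction | 0.2 | ≈ the 36:139 animal-shared : choano-only split |
| orphan_fraction | 0.25 | a large species-specific bucket, as real genomes show |
| host / alien GC3 | 0.72 / 0.82 (sd 0.05) | GC-rich host; aliens shifted +0.10 upward |
| CDS length median | 1404 / 1737 nt (log10 sd 0.25) | host vs candidate medians |
| intron count | NB(mean 5, size 2) | median ≈ 4–5 introns, ~8% intron-less genes |
| evalue_separation | 60 orders | every planted alien scores AI ≥ 45 by construction |
| expression_probs | 0.89/0.09/0.02 | ≈ the 156/16/3 all/some/none split |
| conservation_probs | 0.49/0.38/0.13 | ≈ the 86/66/19 family-coverage split |
| spiked GO term | GO:0099999 at 80% vs 5% | one strongly enriched function |

The intron distribution cannot match a median of exactly 5 and ~8.8%
intron-less genes simultaneously with a two-parameter negative binomial;
NB(5, 2) favors the intron-less fraction and lands the median at 4–5.

Sequences are drawn codon by codon: first two bases uniform, third base
G/C with probability equal to the gene's GC3 target, restricted so that
internal stop, ATG and TGG codons never occur — within each allowed
prefix the G/C probability is preserved, so the realized synonymous GC3
is an unbiased estimate of the target (verified: sample mean within
3·sd/√n). Hits are sampled directly on the log10 E-value scale; the
planted separation between a gene's two sides is therefore exact, and no
alignment is simulated. What the generator does **not** emulate: real
homology-score correlation between related subjects, database taxon bias,
contaminated ortholog groups, GC-content/expression covariation, and
compositional amelioration over time. Passing recovery tests therefore
demonstrates the pipeline's logic, not its real-data error rates.

`recovery_report` scores a candidate set against the planted truth
(sensitivity = recovered/planted, precision = recovered/called). Under the
default scenario recovery is exact; under a hard scenario (10-order
separation, overlapping GC3) it is reported, not asserted.

## Numerical and degenerate-input choices

* TSV writers use `%.17g` and readers `float_precision="round_trip"`, so
  every writer→reader round-trip is bit-exact.
* GFF3 coordinates stay 1-based inclusive end to end; intron count is
  exons − 1; overlapping exons and unresolvable Parents are hard errors.
* Multi-taxid `staxids` cells resolve to the first id (warned); unknown
  taxids fall to a configurable default category (warned, counted).
* Fewer than two candidates, or a feature with fewer than two defined
  values per group, skips that architecture test with a warning.
* The run report embeds config, version and input SHA-256s, is serialized
  with sorted keys, and asserts the count nesting chain before writing;
  identical inputs give byte-identical reports.

## Problem sizes

Tests and the acceptance script run the full pipeline at 1000 genes
(~3300 hits) plus a 1000-gene null genome, 400-replicate null calibration
of the rank test, a 100-dataset cross-check against the reference
Kruskal–Wallis implementation, and exhaustive Fisher verification for all
2×2 tables with row margins ≤ 30 — sizes chosen so the whole suite
completes in well under a minute each while still exercising every gate.

## Known limitations

* Alien Index inherits the biases of its database: under-represented
  lineages and ancient, ameliorated transfers depress sensitivity; genes
  retained in metazoans after a stem transfer are invisible by design.
* The donor prefilter keys on the single best hit; a one-hit database
  artifact can flip it (the distribution filter is the backstop).
* The enrichment test is per-term and ignores GO-term dependence beyond
  BH's rank correction.
* CBI's optimal-codon derivation is reference-set dependent; with a
  biased reference the index shifts globally (candidate-vs-background
  contrasts are unaffected to first order).
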