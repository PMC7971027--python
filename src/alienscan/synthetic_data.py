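"""Synthetic input bundles with planted alien genes and known ground truth.

The generator emits every file the pipeline consumes — CDS FASTA, GFF3 gene
models, a tabular hit table, a taxid→lineage map, ortholog groups, a taxon
panel, a stage TPM matrix and GO annotations — from a single seeded
scenario, so every stage is testable end to end without downloads.

What it emulates
----------------
* a GC-rich host gene background (per-gene GC3 targets drawn around a host
  mean) with log-normal CDS lengths and negative-binomial intron counts;
* a minority of planted "alien" genes with donor-like codon composition
  (higher GC3), donor-category best hits, and best non-metazoan E-values
  many orders of magnitude below their best metazoan E-values;
* ortholog groups consistent with each gene's planted history: genes
  planted as choanozoan-stem gains span choanoflagellates plus metazoans,
  choanoflagellate-lineage gains span only choanoflagellate taxa, and host
  genes span wider eukaryotes;
* stage-structured TPM values and GO annotations with one term spiked
  among the alien genes.

Hits are generated directly on the log10 E-value scale (uniform within the
scenario windows); no sequence evolution or alignment is simulated, which
makes the metazoan/non-metazoan separation a single interpretable knob.
Sequences are drawn codon by codon with the third position biased to the
gene's GC3 target; internal stop, Met and Trp codons are excluded by
construction so the realized synonymous GC3 is unbiased for the target.
Every gene starts ATG and ends TAA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    HomologyHit,
    OrthologGroup,
    write_cds_fasta,
    write_go_annotations,
    write_hit_table,
    write_orthomcl_groups,
    write_tpm_matrix,
)
from .phylostrat import PanelGroup, TaxonPanel, write_taxon_panel
from .taxonomy import LineageCategory, LineageMap, write_lineage_map

logger = logging.getLogger("alienscan")

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "SimulationBundle",
    "RecoveryReport",
    "simulate",
    "write_bundle",
    "write_gff3",
    "recovery_report",
    "SPIKED_GO_TERM",
]

#: Ground-truth labels.
HOST = "HOST"
HOST_ORPHAN = "HOST_ORPHAN"
ALIEN_URCHOANOZOAN = "ALIEN_URCHOANOZOAN"
ALIEN_CHOANO_ONLY = "ALIEN_CHOANO_ONLY"
ALIEN_LABELS = (ALIEN_URCHOANOZOAN, ALIEN_CHOANO_ONLY)

#: GO term spiked among planted alien genes.
SPIKED_GO_TERM = "GO:0099999"

#: Representative taxids per lineage category (real NCBI ids for flavor;
#: the lineage map emitted with the bundle is authoritative).
TAXIDS: dict[LineageCategory, tuple[int, ...]] = {
    LineageCategory.METAZOA: (9606, 7227, 7955),
    LineageCategory.CHOANOFLAGELLATA: (81824,),
    LineageCategory.BACTERIA: (562, 1423, 287),
    LineageCategory.ARCHAEA: (2287, 2190),
    LineageCategory.UNICELLULAR_ALGA: (3055, 2850),
    LineageCategory.UNICELLULAR_FUNGUS: (4932, 5207),
    LineageCategory.OTHER_EUKARYOTE: (5755, 3702),
    LineageCategory.SELF: (946362,),
}

#: Donor-category mix of planted alien best hits (bacteria-dominated, then
#: unicellular algae and fungi, a sliver of archaea).
DONOR_MIX: tuple[tuple[LineageCategory, float], ...] = (
    (LineageCategory.BACTERIA, 0.60),
    (LineageCategory.UNICELLULAR_ALGA, 0.27),
    (LineageCategory.UNICELLULAR_FUNGUS, 0.08),
    (LineageCategory.ARCHAEA, 0.05),
)

#: Synthetic taxon panel: focal species plus one other clade-1 craspedid,
#: two clade-2 craspedids, two loricates, and outgroups.
PANEL_GROUPS: dict[str, PanelGroup] = {
    "sros": PanelGroup.CHOANO_CLADE1_CRASPEDID,
    "mbre": PanelGroup.CHOANO_CLADE1_CRASPEDID,
    "shel": PanelGroup.CHOANO_CLADE2_CRASPEDID,
    "smac": PanelGroup.CHOANO_CLADE2_CRASPEDID,
    "dgra": PanelGroup.CHOANO_LORICATE,
    "sdip": PanelGroup.CHOANO_LORICATE,
    "hsap": PanelGroup.METAZOA,
    "nvec": PanelGroup.METAZOA,
    "scer": PanelGroup.FUNGI,
    "cowc": PanelGroup.FILASTEREA,
    "atha": PanelGroup.OTHER_EUKARYOTE,
}
FOCAL_TAXON = "sros"


@dataclass
class SimulationScenario:
    """All knobs of one synthetic genome, fully determined by ``seed``.

    Defaults emulate the focal study system: ~5% planted aliens split 20/80
    between choanozoan-stem and choanoflagellate-lineage gains, host median
    CDS 1404 nt vs. alien 1737 nt, ~5 introns per gene with ~8% intron-less
    genes, a GC-rich background (host GC3 0.72) with aliens shifted +0.10,
    and a 60-order-of-magnitude E-value separation between each gene's two
    Alien Index sides.
    """

    n_genes: int = 1000
    alien_fraction: float = 0.05
    alien_urchoanozoan_fraction: float = 0.2
    orphan_fraction: float = 0.25
    host_gc3_mean: float = 0.72
    host_gc3_sd: float = 0.05
    alien_gc3_mean: float = 0.82
    alien_gc3_sd: float = 0.05
    host_log10E_meta: tuple[float, float] = (-180.0, -30.0)
    alien_log10E_nonmeta: tuple[float, float] = (-180.0, -80.0)
    evalue_separation: float = 60.0
    intron_mean: float = 5.0
    intron_size: float = 2.0
    cds_length_median: float = 1404.0
    alien_cds_length_median: float = 1737.0
    cds_length_log10_sd: float = 0.25
    stage_names: tuple[str, ...] = ("thecate", "swimming", "chain", "rosette")
    expression_probs: tuple[float, float, float] = (0.89, 0.09, 0.02)
    conservation_probs: tuple[float, float, float] = (0.49, 0.38, 0.13)
    go_annotation_rate: float = 0.65
    n_go_terms: int = 40
    spiked_term_alien_rate: float = 0.8
    spiked_term_host_rate: float = 0.05
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.alien_fraction < 1:
            raise ValueError("alien_fraction must lie in [0, 1)")
        if not 0 <= self.orphan_fraction < 1:
            raise ValueError("orphan_fraction must lie in [0, 1)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if abs(sum(self.expression_probs) - 1) > 1e-9:
            raise ValueError("expression_probs must sum to 1")


@dataclass
class GroundTruth:
    """Planted label and donor category per gene."""

    labels: dict[str, str]
    donor_category: dict[str, LineageCategory]

    def alien_genes(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab in ALIEN_LABELS]


@dataclass
class SimulationBundle:
    """In-memory synthetic input set plus its ground truth."""

    scenario: SimulationScenario
    genes: list[GeneModel]
    hits: list[HomologyHit]
    lineage_map: LineageMap
    groups: list[OrthologGroup]
    panel: TaxonPanel
    tpm: ExpressionMatrix
    go_annotations: dict[str, set[str]]
    truth: GroundTruth


@dataclass
class RecoveryReport:
    """Recovery of planted aliens by the pipeline's candidate set."""

    tp: int
    fp: int
    fn: int
    n_planted: int
    n_candidates: int
    sensitivity: float | None
    precision: float | None


# ---------------------------------------------------------------------------
# sequence generation

_BASES = np.array(list("ACGT"))


def _random_cds(rng: np.random.Generator, n_codons: int, gc3_target: float) -> str:
    """One CDS: ATG + internal codons + TAA, third positions G/C with
    probability ``gc3_target``.

    Internal stop, ATG and TGG codons never occur: after drawing the first
    two bases, the third is restricted to the synonymously free choices
    (TA*/TG* → {C, T}; AT* → {A, C, T}) with P(G or C) = gc3_target in every
    case, so the realized synonymous GC3 is unbiased for the target.
    """
    k = max(n_codons - 2, 1)
    pre = _BASES[rng.integers(0, 4, size=(k, 2))]
    r = rng.random(k) < gc3_target
    half = rng.integers(0, 2, size=k)
    third = np.where(r, np.where(half == 0, "G", "C"), np.where(half == 0, "A", "T"))
    ta = (pre[:, 0] == "T") & (pre[:, 1] == "A")
    tg = (pre[:, 0] == "T") & (pre[:, 1] == "G")
    at = (pre[:, 0] == "A") & (pre[:, 1] == "T")
    constrained = ta | tg
    third[constrained & r] = "C"
    third[constrained & ~r] = "T"
    third[at & r] = "C"
    codons = np.char.add(np.char.add(pre[:, 0], pre[:, 1]), third)
    return "ATG" + "".join(codons.tolist()) + "TAA"


def _exon_intervals(
    rng: np.random.Generator, cds_length: int, n_introns: int
) -> tuple[tuple[int, int], ...]:
    """Split ``cds_length`` into n_introns + 1 exons on a private contig,
    separated by introns of 50–500 nt; exon lengths sum to the CDS length."""
    n_exons = n_introns + 1
    if n_exons > cds_length:
        n_exons = cds_length
    if n_exons == 1:
        return ((1, cds_length),)
    cuts = np.sort(rng.choice(np.arange(1, cds_length), size=n_exons - 1, replace=False))
    lengths = np.diff(np.concatenate(([0], cuts, [cds_length])))
    intron_lens = rng.integers(50, 501, size=n_exons - 1)
    intervals = []
    pos = 1
    for i, length in enumerate(lengths):
        intervals.append((pos, pos + int(length) - 1))
        pos += int(length)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return tuple(intervals)


# ---------------------------------------------------------------------------
# the generator


def _bitscore(log10_e: float, rng: np.random.Generator) -> float:
    # Rough monotone map from alignment strength to a plausible bitscore.
    return round(30.0 + 2.5 * (-log10_e) + rng.uniform(0, 10), 1)


def simulate(scenario: SimulationScenario) -> SimulationBundle:
    """Generate a full synthetic input bundle with known ground truth.

    Deterministic: the same scenario (including its seed) always yields an
    identical bundle.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_genes
    n_alien = int(round(n * scenario.alien_fraction))
    n_urch = int(round(n_alien * scenario.alien_urchoanozoan_fraction))
    n_orphan = int(round((n - n_alien) * scenario.orphan_fraction))

    width = max(4, len(str(n)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]
    labels: dict[str, str] = {}
    order = rng.permutation(n)
    for rank, idx in enumerate(order):
        if rank < n_urch:
            labels[gene_ids[idx]] = ALIEN_URCHOANOZOAN
        elif rank < n_alien:
            labels[gene_ids[idx]] = ALIEN_CHOANO_ONLY
        elif rank < n_alien + n_orphan:
            labels[gene_ids[idx]] = HOST_ORPHAN
        else:
            labels[gene_ids[idx]] = HOST
    labels = {g: labels[g] for g in gene_ids}  # restore id order

    # --- sequences and gene models -------------------------------------
    genes: list[GeneModel] = []
    for gene_id in gene_ids:
        alien = labels[gene_id] in ALIEN_LABELS
        gc3_mu = scenario.alien_gc3_mean if alien else scenario.host_gc3_mean
        gc3_sd = scenario.alien_gc3_sd if alien else scenario.host_gc3_sd
        gc3_target = float(np.clip(rng.normal(gc3_mu, gc3_sd), 0.05, 0.95))
        median = scenario.alien_cds_length_median if alien else scenario.cds_length_median
        length = 10 ** rng.normal(np.log10(median), scenario.cds_length_log10_sd)
        n_codons = max(4, int(round(length / 3)))
        seq = _random_cds(rng, n_codons, gc3_target)
        p_zero = scenario.intron_size / (scenario.intron_size + scenario.intron_mean)
        n_introns = int(rng.negative_binomial(scenario.intron_size, p_zero))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                cds_sequence=seq,
                exon_intervals=_exon_intervals(rng, len(seq), n_introns),
            )
        )

    # --- lineage map -----------------------------------------------------
    entries = {
        taxid: cat for cat, taxids in TAXIDS.items() for taxid in taxids
    }
    lineage_map = LineageMap(entries=dict(sorted(entries.items())))

    # --- hit table -------------------------------------------------------
    donor_cats, donor_w = zip(*DONOR_MIX)
    hits: list[HomologyHit] = []
    donor_category: dict[str, LineageCategory] = {}
    log10_threshold = -5.0
    for gene_id in gene_ids:
        label = labels[gene_id]
        if label == HOST_ORPHAN:
            continue
        if label == HOST:
            best_meta = rng.uniform(*scenario.host_log10E_meta)
            _emit_side(hits, rng, gene_id, LineageCategory.METAZOA, best_meta, n_extra=2)
            worse = best_meta + scenario.evalue_separation
            if worse <= log10_threshold:
                _emit_side(hits, rng, gene_id, LineageCategory.OTHER_EUKARYOTE, worse, n_extra=0)
        else:
            cat = donor_cats[int(rng.choice(len(donor_cats), p=np.array(donor_w) / sum(donor_w)))]
            donor_category[gene_id] = cat
            best_nonmeta = rng.uniform(*scenario.alien_log10E_nonmeta)
            _emit_side(hits, rng, gene_id, cat, best_nonmeta, n_extra=2)
            worse = best_nonmeta + scenario.evalue_separation
            if worse <= log10_threshold:
                _emit_side(hits, rng, gene_id, LineageCategory.METAZOA, worse, n_extra=0)
        # uninformative choanoflagellate hit (excluded from both AI sides)
        if rng.random() < 0.5:
            choano = rng.uniform(-150, -10)
            _emit_side(hits, rng, gene_id, LineageCategory.CHOANOFLAGELLATA, choano, n_extra=0)

    # --- ortholog groups -------------------------------------------------
    groups: list[OrthologGroup] = []
    cons_probs = np.array(scenario.conservation_probs)
    cons_probs = cons_probs / cons_probs.sum()
    for gene_id in gene_ids:
        label = labels[gene_id]
        if label == HOST_ORPHAN:
            continue
        members: list[tuple[str, str]] = [(FOCAL_TAXON, gene_id)]
        if label == HOST:
            members.append(("hsap", f"hs_{gene_id}"))
            members.append(("mbre", f"mb_{gene_id}"))
            if rng.random() < 0.7:
                members.append(("atha", f"at_{gene_id}"))  # eukaryote-wide
        else:
            span = int(rng.choice(3, p=cons_probs))
            members.append(("mbre", f"mb_{gene_id}"))  # clade 1, non-focal
            if span <= 1:
                members.append(("shel", f"sh_{gene_id}"))
            if span == 0:
                members.append(("dgra", f"dg_{gene_id}"))
            if label == ALIEN_URCHOANOZOAN:
                members.append(("hsap", f"hs_{gene_id}"))
        groups.append(OrthologGroup(group_id=f"OG_{gene_id}", members=tuple(members)))

    panel = TaxonPanel(groups=dict(PANEL_GROUPS), focal_taxon=FOCAL_TAXON)

    # --- TPM matrix ------------------------------------------------------
    n_stages = len(scenario.stage_names)
    tpm_rows = np.empty((n, n_stages))
    for i, gene_id in enumerate(gene_ids):
        cat = int(rng.choice(3, p=scenario.expression_probs))
        if cat == 0:
            expressed = np.ones(n_stages, dtype=bool)
        elif cat == 1:
            k = int(rng.integers(1, n_stages))
            expressed = np.zeros(n_stages, dtype=bool)
            expressed[rng.choice(n_stages, size=k, replace=False)] = True
        else:
            expressed = np.zeros(n_stages, dtype=bool)
        on = 10 ** rng.uniform(0.05, 2.5, size=n_stages)
        off = 10 ** rng.uniform(-3.0, -0.05, size=n_stages)
        tpm_rows[i] = np.where(expressed, on, off)
    tpm = ExpressionMatrix(
        tpm=pd.DataFrame(
            np.round(tpm_rows, 4), index=gene_ids, columns=list(scenario.stage_names)
        )
    )

    # --- GO annotations --------------------------------------------------
    term_pool = [f"GO:{i:07d}" for i in range(1, scenario.n_go_terms + 1)]
    go_annotations: dict[str, set[str]] = {}
    for gene_id in gene_ids:
        if rng.random() >= scenario.go_annotation_rate:
            continue
        k = int(rng.integers(1, 5))
        terms = set(
            term_pool[j] for j in rng.choice(len(term_pool), size=k, replace=False)
        )
        spike_rate = (
            scenario.spiked_term_alien_rate
            if labels[gene_id] in ALIEN_LABELS
            else scenario.spiked_term_host_rate
        )
        if rng.random() < spike_rate:
            terms.add(SPIKED_GO_TERM)
        go_annotations[gene_id] = terms

    truth = GroundTruth(labels=labels, donor_category=donor_category)
    return SimulationBundle(
        scenario=scenario,
        genes=genes,
        hits=hits,
        lineage_map=lineage_map,
        groups=groups,
        panel=panel,
        tpm=tpm,
        go_annotations=go_annotations,
        truth=truth,
    )


def _emit_side(
    hits: list[HomologyHit],
    rng: np.random.Generator,
    gene_id: str,
    cat: LineageCategory,
    best_log10_e: float,
    n_extra: int,
) -> None:
    """Emit the side's best hit plus ``n_extra`` strictly worse ones (all
    within the load-time E-value threshold)."""
    taxids = TAXIDS[cat]
    exps = [best_log10_e]
    for _ in range(n_extra):
        worse = best_log10_e + rng.uniform(3, 15)
        if worse <= -5.0:
            exps.append(worse)
    for j, exp in enumerate(exps):
        taxid = int(taxids[int(rng.integers(0, len(taxids)))])
        hits.append(
            HomologyHit(
                query_id=gene_id,
                subject_id=f"{cat.value.lower()}_{taxid}_{gene_id}_{j}",
                subject_taxid=taxid,
                evalue=float(10.0**exp),
                bitscore=_bitscore(exp, rng),
            )
        )


# ---------------------------------------------------------------------------
# writers


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features, each gene on its own contig."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            contig = f"{g.gene_id}_ctg"
            start = g.exon_intervals[0][0]
            end = g.exon_intervals[-1][1]
            fh.write(
                f"{contig}\talienscan\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{contig}\talienscan\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exon_intervals, start=1):
                fh.write(
                    f"{contig}\talienscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{k};Parent={mrna_id}\n"
                )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\tdonor_category\n")
        for gene_id, label in truth.labels.items():
            donor = truth.donor_category.get(gene_id)
            fh.write(f"{gene_id}\t{label}\t{donor.value if donor else 'NONE'}\n")


def write_bundle(bundle: SimulationBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in the pipeline's input formats.

    Returns the path of each emitted file, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds_fasta": outdir / "cds.fasta",
        "gff3": outdir / "models.gff3",
        "hits": outdir / "hits.tsv",
        "lineage": outdir / "lineage.tsv",
        "groups": outdir / "groups.txt",
        "panel": outdir / "panel.tsv",
        "tpm": outdir / "tpm.tsv",
        "go": outdir / "go.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_cds_fasta(bundle.genes, paths["cds_fasta"])
    write_gff3(bundle.genes, paths["gff3"])
    write_hit_table(bundle.hits, paths["hits"])
    write_lineage_map(bundle.lineage_map, paths["lineage"])
    write_orthomcl_groups(bundle.groups, paths["groups"])
    write_taxon_panel(bundle.panel, paths["panel"])
    write_tpm_matrix(bundle.tpm, paths["tpm"])
    write_go_annotations(bundle.go_annotations, paths["go"])
    write_truth(bundle.truth, paths["truth"])
    return paths


def recovery_report(truth: GroundTruth, candidate_ids: Sequence[str]) -> RecoveryReport:
    """Sensitivity/precision of a candidate set against the planted aliens."""
    planted = set(truth.alien_genes())
    candidates = set(candidate_ids)
    tp = len(planted & candidates)
    fp = len(candidates - planted)
    fn = len(planted - candidates)
    sensitivity = tp / len(planted) if planted else None
    precision = tp / len(candidates) if candidates else None
    return RecoveryReport(
        tp=tp,
        fp=fp,
        fn=fn,
        n_planted=len(planted),
        n_candidates=len(candidates),
        sensitivity=sensitivity,
        precision=precision,
    )
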