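"""Readers and writers for every external file the pipeline touches.

All other modules operate on the in-memory types defined here: FASTA CDS
sets become :class:`GeneModel` lists, tabular homology hits become
:class:`HomologyHit` lists (E-value-filtered at load time), OrthoMCL-style
group files become :class:`OrthologGroup` lists, and TPM / GO tables become
:class:`ExpressionMatrix` / gene→term-set mappings.

Conventions
-----------
* GFF3 coordinates are 1-based inclusive and stay that way internally.
* Hit tables are DIAMOND/BLAST outfmt-6-like TSV with at least the columns
  ``qseqid sseqid staxids evalue bitscore``; a semicolon-separated staxids
  cell resolves to its first taxid (with a warning).
* Every writer's output is parseable by its reader with field equality
  (round-trip safety), so result tables can be re-ingested by later stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("alienscan")

__all__ = [
    "GeneModel",
    "HomologyHit",
    "OrthologGroup",
    "ExpressionMatrix",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_gff3_gene_models",
    "read_hit_table",
    "write_hit_table",
    "read_orthomcl_groups",
    "write_orthomcl_groups",
    "read_tpm_matrix",
    "write_tpm_matrix",
    "read_go_annotations",
    "write_go_annotations",
    "read_results_tsv",
    "write_results_tsv",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGTN")


@dataclass
class GeneModel:
    """One protein-coding gene: spliced CDS plus (optional) exon structure.

    ``exon_intervals`` are 1-based inclusive genomic (start, end) pairs as in
    GFF3, sorted and non-overlapping. The intron count is derived: a gene
    with *k* exons has *k − 1* introns. ``sequence_missing`` marks genes
    present in a GFF3 but absent from the CDS FASTA.
    """

    gene_id: str
    cds_sequence: str = ""
    exon_intervals: tuple[tuple[int, int], ...] = ()
    strand: str = "+"
    sequence_missing: bool = False

    def __post_init__(self) -> None:
        ivs = tuple((int(a), int(b)) for a, b in self.exon_intervals)
        if any(b < a for a, b in ivs):
            raise ValueError(f"{self.gene_id}: exon end before start")
        if list(ivs) != sorted(ivs, key=lambda iv: iv[0]):
            raise ValueError(f"{self.gene_id}: exon intervals not sorted by start")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exon intervals")
        self.exon_intervals = ivs

    @property
    def intron_count(self) -> int:
        return max(len(self.exon_intervals) - 1, 0)

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def is_complete_cds(self) -> bool:
        s = self.cds_sequence
        return (
            len(s) >= 6
            and len(s) % 3 == 0
            and s.startswith("ATG")
            and s[-3:] in STOP_CODONS
        )


@dataclass(frozen=True)
class HomologyHit:
    """One query→subject alignment row from a tabular homology search."""

    query_id: str
    subject_id: str
    subject_taxid: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.subject_taxid <= 0:
            raise ValueError(f"{self.query_id}: taxid must be positive")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative E-value")
        if self.bitscore <= 0:
            raise ValueError(f"{self.query_id}: bitscore must be positive")


@dataclass
class OrthologGroup:
    """A gene family across a taxon panel: (taxon_code, gene_id) members."""

    group_id: str
    members: tuple[tuple[str, str], ...]

    @property
    def taxon_codes(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.members)

    def gene_ids_for(self, taxon_code: str) -> list[str]:
        return [g for t, g in self.members if t == taxon_code]


@dataclass
class ExpressionMatrix:
    """Gene × life-stage TPM matrix (non-negative)."""

    tpm: pd.DataFrame  # index: gene ids, columns: stage names

    def __post_init__(self) -> None:
        if self.tpm.columns.duplicated().any():
            raise ValueError("duplicate stage names in TPM matrix")
        if self.tpm.index.duplicated().any():
            raise ValueError("duplicate gene ids in TPM matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM value")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def stage_names(self) -> list[str]:
        return list(self.tpm.columns)


# ---------------------------------------------------------------------------
# FASTA


def read_cds_fasta(path: str | Path) -> list[GeneModel]:
    """Read a CDS FASTA into sequence-only gene models.

    The gene id is the first whitespace-delimited token of each header;
    sequences are upper-cased and must be over the A/C/G/T/N alphabet.
    Duplicate ids and invalid characters are hard errors.
    """
    models: list[GeneModel] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seen.add(gene_id)
        seq = str(record.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in _VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"{path}: gene {gene_id!r}: invalid base {seq[bad]!r} at position {bad}"
            )
        models.append(GeneModel(gene_id=gene_id, cds_sequence=seq))
    return models


def write_cds_fasta(models: Iterable[GeneModel], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.gene_id}\n")
            for i in range(0, len(m.cds_sequence), width):
                fh.write(m.cds_sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_gene_models(
    path: str | Path, cds_by_id: Mapping[str, str]
) -> list[GeneModel]:
    """Read gene models with exon structure from a GFF3 file.

    One :class:`GeneModel` per mRNA; the gene id is the mRNA's parent gene
    ID when present, else the mRNA ID. Exon features are preferred; CDS
    features substitute when a transcript has no exon rows. Unresolvable
    Parent attributes and overlapping exons are hard errors. Genes absent
    from ``cds_by_id`` come back with an empty sequence, flagged.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise ValueError(
                    f"{path}: feature {feat.id!r} has unresolvable Parent {parent_id!r}"
                )

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = list(db.children(mrna, featuretype="exon", order_by="start"))
        if not exons:
            exons = list(db.children(mrna, featuretype="CDS", order_by="start"))
        intervals = tuple((e.start, e.end) for e in exons)
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        seq = cds_by_id.get(gene_id, "")
        missing = gene_id not in cds_by_id
        if missing:
            logger.warning("gene %s present in GFF3 but absent from CDS set", gene_id)
        models.append(
            GeneModel(
                gene_id=gene_id,
                cds_sequence=seq.upper(),
                exon_intervals=intervals,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                sequence_missing=missing,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Hit tables

_HIT_COLUMNS = ["query_id", "subject_id", "subject_taxid", "evalue", "bitscore"]


def _parse_taxid_cell(cell: str, lineno: int, path: str | Path) -> int:
    """First taxid of a possibly semicolon-separated staxids cell."""
    text = str(cell)
    if ";" in text:
        logger.warning(
            "%s:%d: multiple taxids %r; using the first", path, lineno, text
        )
        text = text.split(";", 1)[0]
    try:
        return int(float(text))
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-numeric taxid {cell!r}") from exc


def read_hit_table(path: str | Path, evalue_threshold: float = 1e-5) -> list[HomologyHit]:
    """Read an outfmt-6-like TSV hit table, dropping rows above the E-value cut.

    Expected columns (header optional, auto-detected):
    qseqid, sseqid, staxids, evalue, bitscore. Row order is preserved;
    the number of dropped rows is logged.
    """
    hits: list[HomologyHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 tab-separated columns")
            if lineno == 1:
                try:
                    float(fields[3])
                except ValueError:
                    continue  # header row
            taxid = _parse_taxid_cell(fields[2], lineno, path)
            try:
                evalue = float(fields[3])
                bitscore = float(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore"
                ) from exc
            if evalue > evalue_threshold:
                dropped += 1
                continue
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_taxid=taxid,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    if dropped:
        logger.info(
            "%s: dropped %d hit rows above E-value threshold %g", path, dropped, evalue_threshold
        )
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("qseqid\tsseqid\tstaxids\tevalue\tbitscore\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.subject_taxid}\t{h.evalue:.6g}\t{h.bitscore:.6g}\n"
            )


# ---------------------------------------------------------------------------
# OrthoMCL groups


def read_orthomcl_groups(path: str | Path) -> list[OrthologGroup]:
    """Parse an OrthoMCL group file: ``GROUPID: taxon|gene taxon|gene ...``.

    Duplicate members are deduplicated with a warning; empty groups are kept
    with a warning; a member token without ``|`` is a hard error.
    """
    groups: list[OrthologGroup] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing 'GROUPID:' prefix")
            group_id, _, rest = line.partition(":")
            group_id = group_id.strip()
            members: list[tuple[str, str]] = []
            seen: set[tuple[str, str]] = set()
            for token in rest.split():
                if "|" not in token:
                    raise ValueError(
                        f"{path}:{lineno}: malformed member token {token!r} (no '|')"
                    )
                taxon, _, gene = token.partition("|")
                member = (taxon, gene)
                if member in seen:
                    logger.warning(
                        "%s:%d: duplicate member %s|%s deduplicated", path, lineno, taxon, gene
                    )
                    continue
                seen.add(member)
                members.append(member)
            if not members:
                logger.warning("%s:%d: empty ortholog group %s", path, lineno, group_id)
            groups.append(OrthologGroup(group_id=group_id, members=tuple(members)))
    return groups


def write_orthomcl_groups(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            tokens = " ".join(f"{t}|{gid}" for t, gid in g.members)
            fh.write(f"{g.group_id}: {tokens}".rstrip() + "\n")


# ---------------------------------------------------------------------------
# TPM matrices, GO annotations, generic result tables


def read_tpm_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TPM TSV (gene_id + one column per stage). Negative values error."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged or missing TPM entries")
    return ExpressionMatrix(tpm=df.astype(float))


def write_tpm_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.tpm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_go_annotations(
    path: str | Path, known_genes: set[str] | None = None
) -> dict[str, set[str]]:
    """Read a gene→GO TSV (gene_id, comma-separated ``GO:NNNNNNN`` ids).

    Rows for genes outside ``known_genes`` (when given) are kept with a
    warning. Syntactically invalid GO ids are hard errors.
    """
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"gene_id", "gene"}:
                continue
            gene_id = fields[0]
            terms: set[str] = set()
            if len(fields) > 1 and fields[1].strip():
                for term in fields[1].split(","):
                    term = term.strip()
                    if not (
                        term.startswith("GO:") and len(term) == 10 and term[3:].isdigit()
                    ):
                        raise ValueError(f"{path}:{lineno}: invalid GO id {term!r}")
                    terms.add(term)
            if known_genes is not None and gene_id not in known_genes:
                logger.warning(
                    "%s:%d: GO row for gene %s absent from genome; kept", path, lineno, gene_id
                )
            annotations.setdefault(gene_id, set()).update(terms)
    return annotations


def write_go_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_terms\n")
        for gene_id in sorted(annotations):
            fh.write(f"{gene_id}\t{','.join(sorted(annotations[gene_id]))}\n")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    """Read back any result table written by :func:`write_results_tsv`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged rows or missing values in result table")
    return df


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with full float round-trip precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
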