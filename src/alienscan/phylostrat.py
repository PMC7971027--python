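"""Ortholog-distribution filtering of Alien Index candidates.

A gene that scores FOREIGN by Alien Index may still be an ancient eukaryotic
gene patchily lost elsewhere. This module assigns each gene a phylogenetic
stratum from its ortholog-group membership across a taxon panel:

* EUKARYOTE_WIDE — orthologs in fungi, filastereans or other eukaryotes;
* URCHOANOZOAN — orthologs reach metazoans but no wider eukaryotes
  (consistent with a gain on the choanozoan stem);
* CHOANOFLAGELLATE_ONLY — orthologs confined to choanoflagellates;
* FOCAL_ONLY — no detected orthologs outside the focal species.

Only URCHOANOZOAN and CHOANOFLAGELLATE_ONLY genes are retained as
candidates: a EUKARYOTE_WIDE distribution makes a vertical history (or an
older transfer) more parsimonious, while orphans carry no distributional
evidence at all (an ``include_orphans`` flag restores them for sensitivity
analyses).

For retained genes a conservation level across choanoflagellate families is
also called (all families / both craspedid clades / clade 1 only / focal
only), mirroring the clade structure of the choanoflagellate tree: two
craspedid clades plus the loricates.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alien_index import AlienIndexRecord
from .io_formats import OrthologGroup

logger = logging.getLogger("alienscan")

__all__ = [
    "PanelGroup",
    "TaxonPanel",
    "read_taxon_panel",
    "write_taxon_panel",
    "Stratum",
    "Conservation",
    "DistributionCall",
    "call_stratum",
    "call_conservation",
    "call_distribution",
    "retained_candidates",
]


class PanelGroup(str, enum.Enum):
    CHOANO_CLADE1_CRASPEDID = "CHOANO_CLADE1_CRASPEDID"
    CHOANO_CLADE2_CRASPEDID = "CHOANO_CLADE2_CRASPEDID"
    CHOANO_LORICATE = "CHOANO_LORICATE"
    METAZOA = "METAZOA"
    FUNGI = "FUNGI"
    FILASTEREA = "FILASTEREA"
    OTHER_EUKARYOTE = "OTHER_EUKARYOTE"


_CHOANO_GROUPS = frozenset(
    {
        PanelGroup.CHOANO_CLADE1_CRASPEDID,
        PanelGroup.CHOANO_CLADE2_CRASPEDID,
        PanelGroup.CHOANO_LORICATE,
    }
)
_WIDER_EUKARYOTE_GROUPS = frozenset(
    {PanelGroup.FUNGI, PanelGroup.FILASTEREA, PanelGroup.OTHER_EUKARYOTE}
)


@dataclass
class TaxonPanel:
    """Taxon-code → panel-group mapping plus the focal taxon code."""

    groups: dict[str, PanelGroup]
    focal_taxon: str

    def __post_init__(self) -> None:
        if self.focal_taxon not in self.groups:
            raise ValueError(f"focal taxon {self.focal_taxon!r} not in panel")
        if self.groups[self.focal_taxon] is not PanelGroup.CHOANO_CLADE1_CRASPEDID:
            raise ValueError("focal taxon must be a clade-1 craspedid")

    def group_of(self, taxon_code: str) -> PanelGroup:
        try:
            return self.groups[taxon_code]
        except KeyError as exc:
            raise ValueError(f"unknown taxon code {taxon_code!r}") from exc


class Stratum(str, enum.Enum):
    EUKARYOTE_WIDE = "EUKARYOTE_WIDE"
    URCHOANOZOAN = "URCHOANOZOAN"
    CHOANOFLAGELLATE_ONLY = "CHOANOFLAGELLATE_ONLY"
    FOCAL_ONLY = "FOCAL_ONLY"


#: Strata consistent with a gain on the choanozoan stem or within
#: choanoflagellates — the ones retained by the distribution filter.
RETAINED_STRATA = frozenset({Stratum.URCHOANOZOAN, Stratum.CHOANOFLAGELLATE_ONLY})


class Conservation(str, enum.Enum):
    ALL_FAMILIES = "ALL_FAMILIES"
    BOTH_CRASPEDID_CLADES = "BOTH_CRASPEDID_CLADES"
    CLADE1_ONLY = "CLADE1_ONLY"
    FOCAL_ONLY = "FOCAL_ONLY"
    NOT_APPLICABLE = "NOT_APPLICABLE"


@dataclass
class DistributionCall:
    gene_id: str
    stratum: Stratum
    conservation: Conservation

    def __post_init__(self) -> None:
        if self.stratum is Stratum.FOCAL_ONLY and self.conservation not in (
            Conservation.FOCAL_ONLY,
            Conservation.NOT_APPLICABLE,
        ):
            raise ValueError("FOCAL_ONLY stratum implies FOCAL_ONLY conservation")


def read_taxon_panel(path: str | Path) -> TaxonPanel:
    """Read a panel TSV: taxon_code, panel_group, is_focal (0/1)."""
    groups: dict[str, PanelGroup] = {}
    focal: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"taxon_code", "taxon"}:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            code = fields[0]
            try:
                group = PanelGroup(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unknown panel group {fields[1]!r}") from exc
            groups[code] = group
            if fields[2].strip() in {"1", "true", "True"}:
                if focal is not None:
                    raise ValueError(f"{path}:{lineno}: multiple focal taxa")
                focal = code
    if focal is None:
        raise ValueError(f"{path}: no focal taxon declared")
    return TaxonPanel(groups=groups, focal_taxon=focal)


def write_taxon_panel(panel: TaxonPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_code\tpanel_group\tis_focal\n")
        for code in sorted(panel.groups):
            focal = 1 if code == panel.focal_taxon else 0
            fh.write(f"{code}\t{panel.groups[code].value}\t{focal}\n")


def _member_groups(
    gene_id: str, groups: Sequence[OrthologGroup], panel: TaxonPanel
) -> set[PanelGroup]:
    """Panel groups spanned by the gene's ortholog-group co-members.

    Multi-group membership (possible in OrthoMCL output) is resolved by
    taking the union of memberships, with a warning.
    """
    if len(groups) > 1:
        logger.warning(
            "gene %s belongs to %d ortholog groups; memberships unioned",
            gene_id,
            len(groups),
        )
    spanned: set[PanelGroup] = set()
    for group in groups:
        for taxon_code, _ in group.members:
            spanned.add(panel.group_of(taxon_code))
    return spanned


def call_stratum(
    gene_id: str, groups: Sequence[OrthologGroup], panel: TaxonPanel
) -> Stratum:
    """Phylogenetic stratum from ortholog-group taxon span (any-member rule).

    Any member in a wider-eukaryote group forces EUKARYOTE_WIDE; else any
    metazoan member gives URCHOANOZOAN; else any non-focal choanoflagellate
    gives CHOANOFLAGELLATE_ONLY; else FOCAL_ONLY.
    """
    spanned = _member_groups(gene_id, groups, panel)
    if spanned & _WIDER_EUKARYOTE_GROUPS:
        return Stratum.EUKARYOTE_WIDE
    if PanelGroup.METAZOA in spanned:
        return Stratum.URCHOANOZOAN
    nonfocal_choano = any(
        taxon != panel.focal_taxon and panel.group_of(taxon) in _CHOANO_GROUPS
        for group in groups
        for taxon, _ in group.members
    )
    if nonfocal_choano:
        return Stratum.CHOANOFLAGELLATE_ONLY
    return Stratum.FOCAL_ONLY


def call_conservation(
    members: Iterable[tuple[str, str]], panel: TaxonPanel
) -> Conservation:
    """Conservation across choanoflagellate families from member taxa.

    ALL_FAMILIES requires clade-1 craspedids, clade-2 craspedids and
    loricates; BOTH_CRASPEDID_CLADES both craspedid clades without
    loricates; CLADE1_ONLY clade 1 (incl. the focal species) only.
    """
    choano_groups = {
        panel.group_of(taxon)
        for taxon, _ in members
        if panel.group_of(taxon) in _CHOANO_GROUPS
    }
    has_nonfocal = any(
        taxon != panel.focal_taxon and panel.group_of(taxon) in _CHOANO_GROUPS
        for taxon, _ in members
    )
    craspedid = {
        PanelGroup.CHOANO_CLADE1_CRASPEDID,
        PanelGroup.CHOANO_CLADE2_CRASPEDID,
    }
    if craspedid <= choano_groups and PanelGroup.CHOANO_LORICATE in choano_groups:
        return Conservation.ALL_FAMILIES
    if craspedid <= choano_groups:
        return Conservation.BOTH_CRASPEDID_CLADES
    if has_nonfocal:
        return Conservation.CLADE1_ONLY
    return Conservation.FOCAL_ONLY


def call_distribution(
    gene_ids: Sequence[str],
    groups: Sequence[OrthologGroup],
    panel: TaxonPanel,
) -> list[DistributionCall]:
    """One :class:`DistributionCall` per gene in ``gene_ids``.

    Genes are matched to groups through the focal taxon's members; a gene in
    no group is FOCAL_ONLY.
    """
    by_gene: dict[str, list[OrthologGroup]] = {}
    for group in groups:
        for taxon_code, member_gene in group.members:
            if taxon_code == panel.focal_taxon:
                by_gene.setdefault(member_gene, []).append(group)

    calls: list[DistributionCall] = []
    for gene_id in gene_ids:
        gene_groups = by_gene.get(gene_id, [])
        stratum = call_stratum(gene_id, gene_groups, panel)
        if stratum in RETAINED_STRATA:
            members = [m for g in gene_groups for m in g.members]
            conservation = call_conservation(members, panel)
        elif stratum is Stratum.FOCAL_ONLY:
            conservation = Conservation.FOCAL_ONLY
        else:
            conservation = Conservation.NOT_APPLICABLE
        calls.append(DistributionCall(gene_id=gene_id, stratum=stratum, conservation=conservation))
    return calls


def retained_candidates(
    ai_records: Sequence[AlienIndexRecord],
    distribution_calls: Sequence[DistributionCall],
    include_orphans: bool = False,
) -> list[str]:
    """Gene ids passing all three gates: taxon prefilter, FOREIGN Alien
    Index class, and a retained phylogenetic stratum.

    ``include_orphans`` additionally retains FOCAL_ONLY genes (no detected
    orthologs), for sensitivity analyses.
    """
    ai_genes = {r.gene_id for r in ai_records}
    call_genes = {c.gene_id for c in distribution_calls}
    if ai_genes != call_genes:
        missing = ai_genes ^ call_genes
        raise ValueError(
            f"AI records and distribution calls cover different gene universes "
            f"({len(missing)} mismatched, e.g. {sorted(missing)[:3]})"
        )
    strata = {c.gene_id: c.stratum for c in distribution_calls}
    keep = set(RETAINED_STRATA) | ({Stratum.FOCAL_ONLY} if include_orphans else set())
    retained = [r.gene_id for r in ai_records if r.is_candidate and strata[r.gene_id] in keep]
    n_orphan = sum(
        1 for r in ai_records if r.is_candidate and strata[r.gene_id] is Stratum.FOCAL_ONLY
    )
    if n_orphan and not include_orphans:
        logger.info("%d FOREIGN orphan genes (no orthologs) excluded from the retained set", n_orphan)
    return retained
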