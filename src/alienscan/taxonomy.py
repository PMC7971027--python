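"""Lineage categories for homology-hit subjects.

Every subject taxon id in a hit table is mapped to one of a small set of
donor/recipient categories. Downstream, two predicates matter:

* :func:`is_potential_donor` — whether a gene whose single best hit falls in
  a category is a plausible horizontal-transfer candidate (prokaryotes,
  unicellular algae, unicellular fungi);
* :func:`ai_partition` — which side of the Alien Index contrast a hit
  contributes to (metazoan vs. non-metazoan, with the focal species and its
  fellow choanoflagellates excluded from both sides, since neither carries
  donor signal).

The taxid → category mapping is a user-supplied flat TSV rather than a live
walk of the NCBI taxonomy: it is reproducible, works offline, and the
synthetic generator can emit one. Note that group membership (e.g. which
stramenopiles count as "unicellular algae") is decided entirely by the
mapping file, not by code.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("alienscan")

__all__ = [
    "LineageCategory",
    "AiSide",
    "LineageMap",
    "read_lineage_map",
    "write_lineage_map",
    "categorize",
    "is_potential_donor",
    "ai_partition",
]


class LineageCategory(str, enum.Enum):
    """Donor/recipient lineage category of a hit subject."""

    METAZOA = "METAZOA"
    CHOANOFLAGELLATA = "CHOANOFLAGELLATA"
    BACTERIA = "BACTERIA"
    ARCHAEA = "ARCHAEA"
    UNICELLULAR_ALGA = "UNICELLULAR_ALGA"
    UNICELLULAR_FUNGUS = "UNICELLULAR_FUNGUS"
    OTHER_EUKARYOTE = "OTHER_EUKARYOTE"
    SELF = "SELF"


#: Categories whose best-hit affiliation marks a gene as a potential HGT.
DONOR_CATEGORIES = frozenset(
    {
        LineageCategory.BACTERIA,
        LineageCategory.ARCHAEA,
        LineageCategory.UNICELLULAR_ALGA,
        LineageCategory.UNICELLULAR_FUNGUS,
    }
)


class AiSide(str, enum.Enum):
    """Side of the Alien Index contrast a hit contributes to."""

    METAZOAN_SIDE = "METAZOAN_SIDE"
    NONMETAZOAN_SIDE = "NONMETAZOAN_SIDE"
    EXCLUDED = "EXCLUDED"


@dataclass
class LineageMap:
    """Taxid → :class:`LineageCategory` lookup with a configurable default.

    Unknown taxids resolve to ``default`` (OTHER_EUKARYOTE unless
    overridden); the number of unknown lookups is counted and reported once
    via :meth:`log_unknowns`.
    """

    entries: dict[int, LineageCategory]
    default: LineageCategory = LineageCategory.OTHER_EUKARYOTE
    _unknown_seen: set[int] = field(default_factory=set, repr=False)

    def categorize(self, taxid: int) -> LineageCategory:
        try:
            return self.entries[taxid]
        except KeyError:
            if taxid not in self._unknown_seen:
                self._unknown_seen.add(taxid)
                logger.warning(
                    "taxid %d absent from lineage map; defaulting to %s",
                    taxid,
                    self.default.value,
                )
            return self.default

    def log_unknowns(self) -> int:
        n = len(self._unknown_seen)
        if n:
            logger.warning("%d distinct taxids resolved to the default category", n)
        return n


def read_lineage_map(
    path: str | Path, default: LineageCategory = LineageCategory.OTHER_EUKARYOTE
) -> LineageMap:
    """Load a two-column TSV (taxid, category name) into a :class:`LineageMap`.

    Category names must be the exact enum spellings. A header line is
    tolerated (detected by a non-numeric first field).
    """
    entries: dict[int, LineageCategory] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and not fields[0].isdigit():
                continue  # header
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer taxid {fields[0]!r}") from exc
            if taxid <= 0:
                raise ValueError(f"{path}:{lineno}: taxid must be positive")
            try:
                cat = LineageCategory(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unknown lineage category {fields[1]!r}"
                ) from exc
            if taxid in entries and entries[taxid] is not cat:
                raise ValueError(f"{path}:{lineno}: taxid {taxid} mapped to two categories")
            entries[taxid] = cat
    return LineageMap(entries=entries, default=default)


def write_lineage_map(lmap: LineageMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tcategory\n")
        for taxid in sorted(lmap.entries):
            fh.write(f"{taxid}\t{lmap.entries[taxid].value}\n")


def categorize(taxid: int, lmap: LineageMap) -> LineageCategory:
    """Deterministic category lookup; unknown taxids get the map default."""
    return lmap.categorize(taxid)


def is_potential_donor(cat: LineageCategory) -> bool:
    """True iff a best hit in ``cat`` flags the gene as a potential HGT.

    Donor lineages are bacteria, archaea, unicellular algae and unicellular
    fungi; metazoans and choanoflagellates are recipient-side lineages.
    """
    return cat in DONOR_CATEGORIES


def ai_partition(cat: LineageCategory) -> AiSide:
    """Assign a lineage category to one side of the Alien Index contrast.

    Metazoan hits form one side and every non-choanozoan lineage the other;
    hits to the focal species itself or to other choanoflagellates are
    excluded from both sides.
    """
    if cat is LineageCategory.METAZOA:
        return AiSide.METAZOAN_SIDE
    if cat in (LineageCategory.CHOANOFLAGELLATA, LineageCategory.SELF):
        return AiSide.EXCLUDED
    return AiSide.NONMETAZOAN_SIDE
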