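"""KGML (KEGG Markup Language) parsing and information-defect detection.

KGML describes a KEGG pathway map as ``entry`` elements (nodes with graphics),
``reaction`` elements (substrate/product/catalyst references) and ``relation``
elements (notably ``maplink`` relations pointing at other pathway maps).

Graphics ``x``/``y`` attributes are interpreted as *element centers* in a
y-down pixel frame (the KEGG drawing convention); every downstream stage of
this package uses that same frame.  The targeted dialect is the 0.7.x KGML
schema family; unknown elements and attributes are ignored with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from lxml import etree

logger = logging.getLogger(__name__)


class EntryType(str, Enum):
    GENE = "gene"
    ORTHOLOG = "ortholog"
    ENZYME = "enzyme"
    COMPOUND = "compound"
    MAP = "map"
    GROUP = "group"


class Reversibility(str, Enum):
    REVERSIBLE = "reversible"
    IRREVERSIBLE = "irreversible"
    UNKNOWN = "unknown"


class RelationType(str, Enum):
    MAPLINK = "maplink"
    OTHER = "other"


class AmbiguityReason(str, Enum):
    MISSING_REVERSIBILITY = "missing_reversibility"
    MISSING_ROLE = "missing_role"
    MISSING_PARTICIPANTS = "missing_participants"


# closest-enum fallback for entry types outside the 0.7.x metabolic vocabulary
_ENTRY_TYPE_ALIASES = {
    "genes": EntryType.GENE,
    "protein": EntryType.GENE,
    "rna": EntryType.GENE,
    "molecule": EntryType.COMPOUND,
    "chemical": EntryType.COMPOUND,
    "pathway": EntryType.MAP,
    "brite": EntryType.MAP,
}

CATALYST_TYPES = (EntryType.GENE, EntryType.ORTHOLOG, EntryType.ENZYME)


@dataclass
class KgmlEntry:
    entry_id: str
    kegg_names: list[str]
    entry_type: EntryType
    label: str = ""
    center: Optional[tuple[float, float]] = None
    size: Optional[tuple[float, float]] = None
    component_ids: list[str] = field(default_factory=list)
    reaction_names: list[str] = field(default_factory=list)

    @property
    def has_position(self) -> bool:
        return self.center is not None


@dataclass
class KgmlReaction:
    reaction_id: str
    name: str
    reversibility: Reversibility
    substrate_refs: list[str] = field(default_factory=list)
    product_refs: list[str] = field(default_factory=list)
    catalyst_refs: list[str] = field(default_factory=list)
    # participants whose substrate/product role could not be resolved
    roleless_refs: list[str] = field(default_factory=list)


@dataclass
class KgmlRelation:
    entry1: str
    entry2: str
    relation_type: RelationType
    subtype_name: str = ""
    via_compound: Optional[str] = None


@dataclass
class KgmlPathway:
    name: str = ""
    title: str = ""
    entries: list[KgmlEntry] = field(default_factory=list)
    reactions: list[KgmlReaction] = field(default_factory=list)
    relations: list[KgmlRelation] = field(default_factory=list)

    def entry_by_id(self, entry_id: str) -> KgmlEntry:
        return self._index()[entry_id]

    def _index(self) -> dict[str, KgmlEntry]:
        return {e.entry_id: e for e in self.entries}


@dataclass(frozen=True)
class AmbiguityFlag:
    target: str  # reaction id (defects the detector recognizes live on reactions)
    reason: AmbiguityReason


class KgmlParseError(ValueError):
    pass


def _parse_entry_type(raw: str) -> EntryType:
    try:
        return EntryType(raw)
    except ValueError:
        inferred = _ENTRY_TYPE_ALIASES.get(raw, EntryType.GROUP)
        logger.warning("unknown entry type %r, treating as %s", raw, inferred.value)
        return inferred


def parse_kgml(xml_text: str | bytes) -> KgmlPathway:
    """Parse KGML text into a :class:`KgmlPathway`.

    Entries lacking graphics are retained position-less and afterwards given a
    synthetic position at the centroid of their reaction partners so that the
    layout stage always has a desired position.  Duplicate entry ids keep the
    later entry (warning logged).
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed KGML XML: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlParseError(f"expected <pathway> root element, got <{root.tag}>")

    pathway = KgmlPathway(name=root.get("name", ""), title=root.get("title", ""))

    seen: dict[str, int] = {}
    for el in root.findall("entry"):
        entry_id = el.get("id", "")
        names = el.get("name", "").split()
        entry_type = _parse_entry_type(el.get("type", "group"))
        reaction_names = el.get("reaction", "").split()
        component_ids = [c.get("id", "") for c in el.findall("component")]
        center = size = None
        label = names[0] if names else entry_id
        g = el.find("graphics")
        if g is not None:
            label = g.get("name", label).split(",")[0].strip() or label
            if g.get("x") is not None and g.get("y") is not None:
                w = float(g.get("width", "8"))
                h = float(g.get("height", "8"))
                if w <= 0 or h <= 0:
                    raise KgmlParseError(
                        f"entry {entry_id}: non-positive graphics size {w}x{h}"
                    )
                center = (float(g.get("x")), float(g.get("y")))
                size = (w, h)
        entry = KgmlEntry(
            entry_id=entry_id,
            kegg_names=names,
            entry_type=entry_type,
            label=label,
            center=center,
            size=size,
            component_ids=component_ids,
            reaction_names=reaction_names,
        )
        if entry_id in seen:
            logger.warning("duplicate entry id %s: later entry wins", entry_id)
            pathway.entries[seen[entry_id]] = entry
        else:
            seen[entry_id] = len(pathway.entries)
            pathway.entries.append(entry)

    for el in root.findall("reaction"):
        rid = el.get("id") or el.get("name", "")
        rtype = el.get("type")
        if rtype == "reversible":
            rev = Reversibility.REVERSIBLE
        elif rtype == "irreversible":
            rev = Reversibility.IRREVERSIBLE
        else:
            # absent attribute is an ambiguity, never silently defaulted
            rev = Reversibility.UNKNOWN
        reaction = KgmlReaction(reaction_id=rid, name=el.get("name", ""), reversibility=rev)
        for child in el:
            ref = child.get("id") or child.get("name", "")
            if child.tag == "substrate":
                reaction.substrate_refs.append(ref)
            elif child.tag == "product":
                reaction.product_refs.append(ref)
            else:
                logger.warning(
                    "reaction %s: participant <%s> without resolvable role", rid, child.tag
                )
                reaction.roleless_refs.append(ref)
        pathway.reactions.append(reaction)

    index = pathway._index()
    for r in pathway.reactions:
        wanted = {r.name, r.reaction_id}
        r.catalyst_refs = [
            e.entry_id
            for e in pathway.entries
            if e.entry_type in CATALYST_TYPES and wanted.intersection(e.reaction_names)
        ]

    for el in root.findall("relation"):
        raw = el.get("type", "")
        rtype = RelationType.MAPLINK if raw == "maplink" else RelationType.OTHER
        via = None
        subtype_name = ""
        sub = el.find("subtype")
        if sub is not None:
            subtype_name = sub.get("name", "")
            if subtype_name == "compound":
                via = sub.get("value")
        pathway.relations.append(
            KgmlRelation(
                entry1=el.get("entry1", ""),
                entry2=el.get("entry2", ""),
                relation_type=rtype,
                subtype_name=subtype_name,
                via_compound=via,
            )
        )

    _check_references(pathway, index)
    _assign_missing_positions(pathway, index)
    return pathway


def _check_references(pathway: KgmlPathway, index: dict[str, KgmlEntry]) -> None:
    for r in pathway.reactions:
        for ref in r.substrate_refs + r.product_refs:
            if ref not in index:
                raise KgmlParseError(
                    f"reaction {r.reaction_id} references missing entry {ref}"
                )
    for rel in pathway.relations:
        for ref in (rel.entry1, rel.entry2):
            if ref not in index:
                raise KgmlParseError(f"relation references missing entry {ref}")


def _assign_missing_positions(pathway: KgmlPathway, index: dict[str, KgmlEntry]) -> None:
    """Give position-less entries a synthetic center at the centroid of their
    reaction/relation partners (fallback: origin)."""
    neighbors: dict[str, set[str]] = {e.entry_id: set() for e in pathway.entries}
    for r in pathway.reactions:
        participants = r.substrate_refs + r.product_refs + r.catalyst_refs
        for a in participants:
            for b in participants:
                if a != b and a in neighbors:
                    neighbors[a].add(b)
    for rel in pathway.relations:
        if rel.entry1 in neighbors:
            neighbors[rel.entry1].add(rel.entry2)
        if rel.entry2 in neighbors:
            neighbors[rel.entry2].add(rel.entry1)

    for e in pathway.entries:
        if e.center is not None:
            continue
        pts = [
            index[n].center
            for n in sorted(neighbors.get(e.entry_id, ()))
            if n in index and index[n].center is not None
        ]
        if pts:
            e.center = (
                sum(p[0] for p in pts) / len(pts),
                sum(p[1] for p in pts) / len(pts),
            )
        else:
            e.center = (0.0, 0.0)
        if e.size is None:
            e.size = (8.0, 8.0) if e.entry_type == EntryType.COMPOUND else (46.0, 17.0)
        logger.warning(
            "entry %s lacks graphics; synthetic position %s assigned", e.entry_id, e.center
        )


def detect_ambiguities(pathway: KgmlPathway) -> list[AmbiguityFlag]:
    """Flag the KGML information defects that preclude an unambiguous translation.

    One flag per defect: unknown reaction reversibility, a participant without
    a resolvable substrate/product role, and reactions missing substrates or
    products entirely.  The detector never raises on content.
    """
    flags: list[AmbiguityFlag] = []
    for r in pathway.reactions:
        if r.reversibility is Reversibility.UNKNOWN:
            flags.append(AmbiguityFlag(r.reaction_id, AmbiguityReason.MISSING_REVERSIBILITY))
        if r.roleless_refs:
            flags.append(AmbiguityFlag(r.reaction_id, AmbiguityReason.MISSING_ROLE))
        if not r.substrate_refs or not r.product_refs:
            flags.append(AmbiguityFlag(r.reaction_id, AmbiguityReason.MISSING_PARTICIPANTS))
    return flags
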