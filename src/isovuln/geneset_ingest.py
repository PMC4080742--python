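"""Isoenzyme gene-set construction.

Gene sets group the genes whose products catalyze the same biochemical
reaction (isoenzymes).  Loss of one member shifts the catalytic load onto
the others, which is the premise of the collateral-lethality calls made
downstream.  Sets are harvested from three kinds of inputs:

* BioPAX Level 3 OWL documents (pathway databases such as Reactome and
  HumanCyc export these) -- one set per biochemical reaction, built from
  the HGNC symbols of its catalytic controllers;
* EC-number tables (one row per EC number / human gene pair, the shape of
  a KEGG Enzyme export) -- one set per EC number;
* GMT files, the tab-delimited gene-set exchange dialect.

Catalogs pooled from several resources are merged composition-wise with a
declared resource priority, then filtered by set size and by drug
targetability of the member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

log = logging.getLogger(__name__)

#: Recognized gene-set resources, in no particular order.  Merge priority is
#: supplied separately by the caller.
KNOWN_SOURCES = ("KEGG", "REACTOME", "HUMANCYC", "USER")

#: Default resource priority used when merging pooled catalogs: KEGG Enzyme
#: first, then Reactome, then HumanCyc; user-supplied sets last.
DEFAULT_PRIORITY = ("KEGG", "REACTOME", "HUMANCYC", "USER")

BP_NS = "http://www.biopax.org/release/biopax-level3.owl#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"


class BiopaxParseError(ValueError):
    """Raised when a BioPAX document is not well-formed XML."""


class GmtFormatError(ValueError):
    """Raised for malformed GMT lines."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    No alias resolution is attempted; inputs are expected to carry
    HGNC-style symbols already.
    """
    return symbol.strip().upper()


def _dedup_normalized(genes: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in genes:
        s = normalize_symbol(g)
        if s:
            seen.setdefault(s, None)
    return tuple(seen)


@dataclass(frozen=True)
class GeneSet:
    """A named group of isoenzyme gene symbols with provenance metadata.

    ``genes`` is ordered, deduplicated and case-normalized at construction;
    ``source`` must be one of :data:`KNOWN_SOURCES`.
    """

    set_id: str
    genes: tuple[str, ...]
    source: str
    reaction_name: str = ""
    pathway_name: str = ""

    def __post_init__(self) -> None:
        genes = _dedup_normalized(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.set_id!r} has no genes")
        if self.source not in KNOWN_SOURCES:
            raise ValueError(
                f"gene set {self.set_id!r}: unknown source {self.source!r}"
            )
        object.__setattr__(self, "genes", genes)

    @property
    def composition(self) -> frozenset[str]:
        """Unordered gene composition, the merge key across resources."""
        return frozenset(self.genes)


@dataclass
class GeneSetCatalog:
    """A collection of gene sets plus per-set provenance.

    After :func:`merge_catalogs` no two sets share an unordered gene
    composition; after :func:`filter_catalog` every set satisfies the
    active size and targetability filters.
    """

    sets: list[GeneSet] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set_id(s) in catalog: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def by_id(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


# ---------------------------------------------------------------------------
# BioPAX Level 3 extraction
# ---------------------------------------------------------------------------
#
# Only six BioPAX classes are interpreted: BiochemicalReaction,
# Catalysis/Control, Protein, ProteinReference, Complex and the Xref
# hierarchy.  Everything else in the document is ignored.  The walk is:
# reaction <- controlled <- Catalysis/Control -> controller -> Protein
# (or Complex of Proteins) -> entityReference -> ProteinReference -> xref
# -> Xref with an HGNC db field, whose id is taken as the gene symbol.

_CONTROL_TAGS = {f"{{{BP_NS}}}Catalysis", f"{{{BP_NS}}}Control"}
_XREF_LOCAL = ("UnificationXref", "RelationshipXref", "PublicationXref", "Xref")


def _rdf_id(elem) -> str | None:
    for attr in ("ID", "about"):
        v = elem.get(f"{{{RDF_NS}}}{attr}")
        if v is not None:
            return v.lstrip("#")
    return None


def _resource(elem) -> str | None:
    v = elem.get(f"{{{RDF_NS}}}resource")
    return v.lstrip("#") if v is not None else None


def _bp_text(elem, prop: str) -> str | None:
    child = elem.find(f"{{{BP_NS}}}{prop}")
    if child is not None and child.text:
        return child.text.strip()
    return None


def _byte_offset(data: bytes, line: int, column: int) -> int:
    lines = data.split(b"\n")
    return sum(len(l) + 1 for l in lines[: max(line - 1, 0)]) + column


def parse_biopax_isoenzymes(
    source: str | Path | bytes, resource_label: str = "REACTOME"
) -> list[GeneSet]:
    """Extract one isoenzyme gene set per catalyzed biochemical reaction.

    Parameters
    ----------
    source
        Path to a BioPAX Level 3 OWL (RDF/XML) file, or its raw bytes.
    resource_label
        Which resource the document came from (``REACTOME`` or
        ``HUMANCYC``); recorded on every emitted set.

    Returns
    -------
    One :class:`GeneSet` per ``BiochemicalReaction`` that has at least one
    ``Catalysis``/``Control`` controller resolving to at least one HGNC
    symbol.  Complex controllers contribute the symbols of all member
    proteins.  Reactions with no controller, or whose controllers resolve
    to no symbol, are skipped.  Dangling internal references are logged as
    warnings and skipped.

    Raises
    ------
    BiopaxParseError
        If the document is not well-formed XML; the message names the
        approximate byte offset of the failure.
    """
    if isinstance(source, bytes):
        data = source
        origin = "<bytes>"
    else:
        data = Path(source).read_bytes()
        origin = str(source)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        offset = _byte_offset(data, line, col)
        raise BiopaxParseError(
            f"malformed XML in {origin} at byte offset {offset} "
            f"(line {line}, column {col}): {exc.msg}"
        ) from exc

    index: dict[str, etree._Element] = {}
    for elem in root.iter():
        eid = _rdf_id(elem)
        if eid is not None:
            index[eid] = elem

    def resolve(ref: str | None, context: str):
        if ref is None:
            return None
        elem = index.get(ref)
        if elem is None:
            log.warning("biopax: dangling reference %r in %s; skipped", ref, context)
        return elem

    def is_xref(elem) -> bool:
        tag = etree.QName(elem).localname
        return tag in _XREF_LOCAL

    def xref_symbols(entity) -> list[str]:
        symbols: list[str] = []
        for xref_ref in entity.findall(f"{{{BP_NS}}}xref"):
            xref = resolve(_resource(xref_ref), f"xref of {_rdf_id(entity)}")
            if xref is None or not is_xref(xref):
                continue
            db = _bp_text(xref, "db") or ""
            if "HGNC" in db.upper():
                sym = _bp_text(xref, "id")
                if sym:
                    symbols.append(sym)
        return symbols

    def entity_symbols(entity, seen: frozenset[str]) -> list[str]:
        """Symbols of a controller entity (Protein or Complex); other
        entity classes are outside the interpreted subset and yield none."""
        eid = _rdf_id(entity) or "<anonymous>"
        if eid in seen:  # defensive: cyclic complex membership
            return []
        tag = etree.QName(entity).localname
        symbols: list[str] = []
        if tag == "Protein":
            symbols.extend(xref_symbols(entity))
            er = resolve(
                _resource(entity.find(f"{{{BP_NS}}}entityReference"))
                if entity.find(f"{{{BP_NS}}}entityReference") is not None
                else None,
                f"entityReference of {eid}",
            )
            if er is not None:
                symbols.extend(xref_symbols(er))
        elif tag == "Complex":
            for comp_ref in entity.findall(f"{{{BP_NS}}}component"):
                comp = resolve(_resource(comp_ref), f"component of {eid}")
                if comp is not None:
                    symbols.extend(entity_symbols(comp, seen | {eid}))
        return symbols

    # reaction id -> controller entities, in document order of the controls
    controllers: dict[str, list[etree._Element]] = {}
    for elem in root.iter():
        if elem.tag not in _CONTROL_TAGS:
            continue
        ctrl_id = _rdf_id(elem) or "<anonymous control>"
        controlled = resolve(
            _resource(elem.find(f"{{{BP_NS}}}controlled"))
            if elem.find(f"{{{BP_NS}}}controlled") is not None
            else None,
            f"controlled of {ctrl_id}",
        )
        if controlled is None:
            continue
        if etree.QName(controlled).localname != "BiochemicalReaction":
            continue
        rxn_id = _rdf_id(controlled)
        if rxn_id is None:
            continue
        for ctl_ref in elem.findall(f"{{{BP_NS}}}controller"):
            entity = resolve(_resource(ctl_ref), f"controller of {ctrl_id}")
            if entity is not None:
                controllers.setdefault(rxn_id, []).append(entity)

    # reaction id -> enclosing pathway display name (best effort)
    pathway_of: dict[str, str] = {}
    for elem in root.iter(f"{{{BP_NS}}}Pathway"):
        pname = _bp_text(elem, "displayName") or _bp_text(elem, "name") or ""
        if not pname:
            continue
        for comp_ref in elem.findall(f"{{{BP_NS}}}pathwayComponent"):
            comp = resolve(_resource(comp_ref), "pathwayComponent")
            if comp is None:
                continue
            if comp.tag in _CONTROL_TAGS:
                inner = comp.find(f"{{{BP_NS}}}controlled")
                comp = resolve(
                    _resource(inner) if inner is not None else None,
                    "pathwayComponent control",
                )
                if comp is None:
                    continue
            cid = _rdf_id(comp)
            if cid is not None:
                pathway_of.setdefault(cid, pname)

    sets: list[GeneSet] = []
    for elem in root.iter(f"{{{BP_NS}}}BiochemicalReaction"):
        rxn_id = _rdf_id(elem)
        if rxn_id is None or rxn_id not in controllers:
            continue
        symbols: list[str] = []
        for entity in controllers[rxn_id]:
            symbols.extend(entity_symbols(entity, frozenset()))
        genes = _dedup_normalized(symbols)
        if not genes:
            log.warning(
                "biopax: reaction %s has controllers but no HGNC symbols; skipped",
                rxn_id,
            )
            continue
        sets.append(
            GeneSet(
                set_id=f"{resource_label}:{rxn_id}",
                genes=genes,
                source=resource_label,
                reaction_name=_bp_text(elem, "displayName")
                or _bp_text(elem, "name")
                or "",
                pathway_name=pathway_of.get(rxn_id, ""),
            )
        )
    log.info("biopax: %d gene sets extracted from %s", len(sets), origin)
    return sets


# ---------------------------------------------------------------------------
# EC-number tables
# ---------------------------------------------------------------------------

def parse_ec_table(path: str | Path, resource_label: str = "KEGG") -> list[GeneSet]:
    """Build one gene set per EC number from a 2-3 column TSV.

    Columns are ``ec_number``, ``gene_symbol`` and optionally
    ``enzyme_name`` (a header row with these names is recognized and
    skipped).  The enzyme name, when present, becomes the reaction name;
    otherwise the EC number itself is used.  Rows with an empty gene
    symbol are dropped with a warning.
    """
    groups: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in ("ec_number", "ec"):
                continue
            ec = fields[0].strip()
            symbol = fields[1].strip() if len(fields) > 1 else ""
            if not symbol:
                log.warning("%s:%d: empty gene symbol; row dropped", path, lineno)
                continue
            groups.setdefault(ec, []).append(symbol)
            if len(fields) > 2 and fields[2].strip():
                names.setdefault(ec, fields[2].strip())
    sets = [
        GeneSet(
            set_id=f"{resource_label}:{ec}",
            genes=_dedup_normalized(genes),
            source=resource_label,
            reaction_name=names.get(ec, ec),
        )
        for ec, genes in groups.items()
    ]
    log.info("ec-table: %d gene sets from %s", len(sets), path)
    return sets


# ---------------------------------------------------------------------------
# GMT round trip
# ---------------------------------------------------------------------------
#
# Standard GMT: name TAB description TAB gene TAB gene...  The description
# field carries "source|reaction_name|pathway_name"; a description without
# pipes is taken as a plain reaction name with source USER.

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (metadata packed in the description)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected at least 3 (name, description, genes...)"
                )
            name, desc = fields[0], fields[1]
            if "|" in desc:
                parts = (desc.split("|") + ["", "", ""])[:3]
                source, reaction_name, pathway_name = parts
            else:
                source, reaction_name, pathway_name = "USER", desc, ""
            sets.append(
                GeneSet(
                    set_id=name,
                    genes=_dedup_normalized(fields[2:]),
                    source=source or "USER",
                    reaction_name=reaction_name,
                    pathway_name=pathway_name,
                )
            )
    return sets


def write_gmt(sets: Iterable[GeneSet] | GeneSetCatalog, path: str | Path) -> None:
    """Write gene sets as GMT; ``read_gmt(write_gmt(x)) == x`` up to type."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            desc = f"{s.source}|{s.reaction_name}|{s.pathway_name}"
            fh.write("\t".join([s.set_id, desc, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Merging and filtering
# ---------------------------------------------------------------------------

def merge_catalogs(
    catalogs: Sequence[Iterable[GeneSet]],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    provenance: Mapping[str, str] | None = None,
) -> GeneSetCatalog:
    """Pool gene sets from several resources, collapsing duplicates.

    Sets with identical unordered gene composition collapse to a single
    survivor: the copy from the highest-priority source (the survivor's
    metadata, including reaction name, wins).  Sets with distinct
    compositions are all kept, even when they overlap.  First-seen order
    of compositions is preserved, which makes the merge idempotent and
    deterministic.

    Parameters
    ----------
    catalogs
        Lists of gene sets, e.g. one list per parsed resource file.
    priority
        Resource order, highest priority first; must cover every source
        present in the inputs.
    provenance
        Optional ``set_id -> origin file`` mapping; defaults to the
        surviving set's source label.
    """
    rank = {src: i for i, src in enumerate(priority)}
    chosen: dict[frozenset[str], GeneSet] = {}
    order: list[frozenset[str]] = []
    n_in = 0
    for catalog in catalogs:
        for s in catalog:
            n_in += 1
            if s.source not in rank:
                raise ValueError(
                    f"source {s.source!r} of set {s.set_id!r} not in priority "
                    f"list {list(priority)}"
                )
            key = s.composition
            if key not in chosen:
                chosen[key] = s
                order.append(key)
            elif rank[s.source] < rank[chosen[key].source]:
                chosen[key] = s
    sets = [chosen[k] for k in order]
    prov = {
        s.set_id: (provenance or {}).get(s.set_id, s.source) for s in sets
    }
    log.info("merge: %d input sets pooled into %d unique compositions", n_in, len(sets))
    return GeneSetCatalog(sets=sets, provenance=prov)


def filter_catalog(
    catalog: GeneSetCatalog,
    targetable_genes: frozenset[str] | set[str],
    max_set_size: int = 5,
) -> GeneSetCatalog:
    """Apply the size and targetability filters to a merged catalog.

    A set is retained iff it has at most ``max_set_size`` genes (boundary
    inclusive: a 5-gene set passes the default) and at least one member is
    targetable by some drug (any drug, not only selective ones).  Removal
    counts by reason are logged.
    """
    targetable = {normalize_symbol(g) for g in targetable_genes}
    kept: list[GeneSet] = []
    removed_size = removed_untargetable = 0
    for s in catalog.sets:
        if len(s.genes) > max_set_size:
            removed_size += 1
            continue
        if not any(g in targetable for g in s.genes):
            removed_untargetable += 1
            continue
        kept.append(s)
    log.info(
        "filter: kept=%d removed_size=%d removed_untargetable=%d (max_set_size=%d)",
        len(kept),
        removed_size,
        removed_untargetable,
        max_set_size,
    )
    return GeneSetCatalog(
        sets=kept,
        provenance={s.set_id: catalog.provenance.get(s.set_id, s.source) for s in kept},
    )
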