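"""Readers and writers for pathway gene-set formats.

Three on-disk formats are supported, all reduced to the same in-memory
representation (:class:`Pathway` / :class:`PathwayDatabase`):

* **KGML** — the XML format of individual KEGG pathway maps.  One file is
  one pathway; gene entries carry organism-prefixed accessions
  (``hsa:7157``) in their ``name`` attribute and display symbols in the
  nested ``graphics`` element.
* **BioPAX Level 3** — the OWL/RDF pathway-exchange standard (Reactome
  exports L3).  One file may contain many pathways; member proteins are
  reached by walking ``pathwayComponent`` chains through interactions and
  complexes.
* **GMT** — the plain tab-separated gene-set exchange format
  (``name<TAB>description<TAB>gene...``).

Identifier normalization is deliberately simple and deterministic: symbols
are uppercased, KGML ``org:digits`` tokens become ``ENTREZ:<digits>``, and
BioPAX unification xrefs become ``DB:ID``.  No cross-namespace mapping is
attempted; a pathway may therefore carry several identifiers for one
biological gene, and overlap counting treats identifier strings as-is.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Union

from lxml import etree

from .errors import EmptyQueryError, FormatError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "Pathway",
    "PathwayDatabase",
    "normalize_gene_id",
    "parse_kgml",
    "parse_biopax",
    "read_gmt",
    "write_gmt",
    "load_query",
]

Readable = Union[str, "os.PathLike[str]", IO[str], IO[bytes]]

#: KGML token of the form ``org:digits`` (e.g. ``hsa:7157``).
_ORG_DIGITS = re.compile(r"^[A-Za-z]+:(\d+)$")


class Source(str, Enum):
    """Provenance of a parsed pathway."""

    BIOPAX = "BIOPAX"
    KGML = "KGML"
    GMT = "GMT"
    SYNTHETIC = "SYNTHETIC"


def normalize_gene_id(raw: str) -> str:
    """Normalize one gene/protein identifier.

    Whitespace is stripped and the identifier uppercased so that exact
    string equality is a meaningful overlap test.  Returns ``""`` for
    whitespace-only input (callers drop such tokens).
    """
    return raw.strip().upper()


def _normalize_kgml_token(token: str) -> str:
    """KGML ``name`` tokens of the form ``org:digits`` denote Entrez ids."""
    m = _ORG_DIGITS.match(token)
    if m:
        return f"ENTREZ:{m.group(1)}"
    return normalize_gene_id(token)


@dataclass(frozen=True)
class Pathway:
    """One named pathway and its member gene set."""

    pathway_id: str
    name: str
    genes: frozenset[str]
    organism: str = ""
    source: Source = Source.SYNTHETIC

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise FormatError("pathway_id must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class PathwayDatabase:
    """An ordered collection of pathways plus the background universe.

    The universe defaults to the union of all member gene sets — the only
    self-contained, reproducible choice of background population — and may
    be overridden with a user-supplied list via :meth:`with_background`.
    """

    pathways: list[Pathway]
    universe: frozenset[str] = field(default_factory=frozenset)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise FormatError(f"duplicate pathway_id: {p.pathway_id!r}")
            seen.add(p.pathway_id)
        member_union = frozenset().union(*(p.genes for p in self.pathways)) \
            if self.pathways else frozenset()
        if not self.universe:
            self.universe = member_union
        elif not member_union <= self.universe:
            missing = sorted(member_union - self.universe)[:5]
            raise FormatError(
                "universe must contain every pathway gene; missing e.g. "
                + ", ".join(missing)
            )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def with_background(self, background: Iterable[str]) -> "PathwayDatabase":
        """Return a copy whose universe is the normalized background list
        united with all member genes (so Eq.-style preconditions hold)."""
        bg = {normalize_gene_id(g) for g in background}
        bg.discard("")
        union = frozenset().union(*(p.genes for p in self.pathways)) \
            if self.pathways else frozenset()
        return PathwayDatabase(
            pathways=list(self.pathways),
            universe=frozenset(bg) | union,
            provenance=self.provenance + " +background",
        )

    @staticmethod
    def merge(databases: Iterable["PathwayDatabase"]) -> "PathwayDatabase":
        """Merge several databases into one shared-universe collection.

        Duplicate pathway ids across inputs are an error (re-raised by the
        constructor's uniqueness check).
        """
        dbs = list(databases)
        pathways = [p for db in dbs for p in db.pathways]
        universe = frozenset().union(*(db.universe for db in dbs)) \
            if dbs else frozenset()
        prov = "; ".join(db.provenance for db in dbs if db.provenance)
        return PathwayDatabase(pathways=pathways, universe=universe,
                               provenance=prov)


# ---------------------------------------------------------------------------
# stream plumbing


def _as_bytes(stream: Readable) -> bytes:
    if hasattr(stream, "read"):
        data = stream.read()
        return data.encode("utf-8") if isinstance(data, str) else data
    with open(stream, "rb") as fh:
        return fh.read()


def _as_text(stream: Readable) -> str:
    return _as_bytes(stream).decode("utf-8")


# ---------------------------------------------------------------------------
# KGML


def parse_kgml(stream: Readable) -> PathwayDatabase:
    """Parse one KGML file into a single-pathway database.

    The gene set is the union, over ``entry`` elements with
    ``type="gene"``, of every space-separated token of the entry ``name``
    attribute (``org:digits`` tokens normalized to ``ENTREZ:<digits>``)
    and the first comma-separated token of each nested ``graphics``
    ``name`` attribute (uppercased, trailing ``...`` stripped).  Entries of
    type ``compound``, ``map``, ``group`` and ``ortholog`` contribute
    nothing — only genes/proteins are enriched.
    """
    data = _as_bytes(stream)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed KGML XML: {exc}") from exc
    if root.tag != "pathway":
        raise FormatError(
            f"expected root element 'pathway', found {root.tag!r}"
        )
    genes: set[str] = set()
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            continue
        for token in (entry.get("name") or "").split():
            norm = _normalize_kgml_token(token)
            if norm:
                genes.add(norm)
        for graphics in entry.iter("graphics"):
            gname = graphics.get("name")
            if not gname:
                continue
            first = gname.split(",")[0].strip()
            if first.endswith("..."):
                first = first[:-3]
            norm = normalize_gene_id(first)
            if norm:
                genes.add(norm)
    pathway = Pathway(
        pathway_id=root.get("name") or "unnamed",
        name=root.get("title") or root.get("name") or "unnamed",
        organism=root.get("org") or "",
        source=Source.KGML,
        genes=frozenset(genes),
    )
    return PathwayDatabase(pathways=[pathway], provenance="KGML")


# ---------------------------------------------------------------------------
# BioPAX Level 3

BP = "http://www.biopax.org/release/biopax-level3.owl#"
_BP_L2 = "http://www.biopax.org/release/biopax-level2.owl#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

#: properties traversed from a pathway/interaction toward physical entities
_TRAVERSE_PROPS = (
    "pathwayComponent", "pathwayOrder", "stepProcess", "stepConversion",
    "left", "right", "controller", "controlled", "participant",
    "product", "template", "component", "memberPhysicalEntity",
)
#: physical entity classes whose references are gene products
_GENE_CLASSES = {"Protein", "Rna", "Dna", "RnaRegion", "DnaRegion"}


def parse_biopax(stream: Readable) -> PathwayDatabase:
    """Parse a BioPAX Level-3 RDF/XML document.

    Every ``bp:Pathway`` instance becomes one :class:`Pathway`; nested
    sub-pathways contribute their genes to the parent *and* appear as
    entries of their own (matching hierarchical Reactome exports).  From
    each pathway the graph is walked transitively through component,
    participant and complex-membership properties down to Protein/Rna/Dna
    physical entities; for each such entity we emit the ``displayName`` of
    its ``entityReference`` (uppercased) and every unification xref as
    ``DB:ID``.  Small molecules are excluded.  Traversal carries a
    visited-set so cyclic graphs terminate.
    """
    import rdflib

    data = _as_bytes(stream)
    if _BP_L2.encode() in data:
        raise FormatError("unsupported BioPAX level: only Level 3 is supported")
    graph = rdflib.Graph()
    try:
        graph.parse(data=data, format="xml")
    except Exception as exc:  # rdflib raises various SAX/xml errors
        raise ParseError(f"unparseable RDF/XML: {exc}") from exc

    bp = rdflib.Namespace(BP)
    rdf_type = rdflib.RDF.type

    pathway_nodes = list(graph.subjects(rdf_type, bp.Pathway))
    if not pathway_nodes:
        raise FormatError("document contains no BioPAX Level-3 Pathway instances")

    # document order: first byte offset of each pathway node's identifier
    order = _document_order(data, pathway_nodes)
    pathway_nodes.sort(key=lambda n: (order.get(str(n), 1 << 60), str(n)))

    def node_class(node) -> str | None:
        for t in graph.objects(node, rdf_type):
            ts = str(t)
            if ts.startswith(BP):
                return ts[len(BP):]
        return None

    def entity_identifiers(node) -> set[str]:
        """displayName of the entityReference + unification xrefs, for one
        gene-product physical entity."""
        out: set[str] = set()
        for ref in graph.objects(node, bp.entityReference):
            for dn in graph.objects(ref, bp.displayName):
                norm = normalize_gene_id(str(dn))
                if norm:
                    out.add(norm)
            for xref in graph.objects(ref, bp.xref):
                if node_class(xref) != "UnificationXref":
                    continue
                dbs = [str(v) for v in graph.objects(xref, bp.db)]
                ids = [str(v) for v in graph.objects(xref, bp.id)]
                if dbs and ids:
                    out.add(normalize_gene_id(f"{dbs[0]}:{ids[0]}"))
        return out

    def collect(node, visited: set) -> set[str]:
        if node in visited:
            return set()
        visited.add(node)
        cls = node_class(node)
        if cls == "SmallMolecule":
            return set()
        genes: set[str] = set()
        if cls in _GENE_CLASSES:
            genes |= entity_identifiers(node)
        for prop in _TRAVERSE_PROPS:
            for child in graph.objects(node, bp[prop]):
                genes |= collect(child, visited)
        return genes

    def display_name(node, fallback: str) -> str:
        for prop in (bp.displayName, bp.name, bp.standardName):
            for v in graph.objects(node, prop):
                return str(v)
        return fallback

    pathways = []
    for node in pathway_nodes:
        pid = _uri_fragment(str(node))
        org = ""
        for o in graph.objects(node, bp.organism):
            org = display_name(o, str(o))
        pathways.append(Pathway(
            pathway_id=pid,
            name=display_name(node, pid),
            organism=org,
            source=Source.BIOPAX,
            genes=frozenset(collect(node, set())),
        ))
    return PathwayDatabase(pathways=pathways, provenance="BioPAX L3")


def _uri_fragment(uri: str) -> str:
    if "#" in uri:
        frag = uri.rsplit("#", 1)[1]
        if frag:
            return frag
    return uri.rstrip("/").rsplit("/", 1)[-1] or uri


def _document_order(data: bytes, nodes) -> dict[str, int]:
    """First byte offset of each node identifier in the raw document."""
    text = data.decode("utf-8", errors="replace")
    offsets: dict[str, int] = {}
    for node in nodes:
        frag = _uri_fragment(str(node))
        best = -1
        for needle in (f'rdf:ID="{frag}"', f'rdf:about="#{frag}"',
                       f'rdf:about="{node}"'):
            pos = text.find(needle)
            if pos != -1 and (best == -1 or pos < best):
                best = pos
        offsets[str(node)] = best if best != -1 else 1 << 60
    return offsets


# ---------------------------------------------------------------------------
# GMT


def read_gmt(stream: Readable) -> PathwayDatabase:
    """Read a GMT file: ``name<TAB>description<TAB>gene<TAB>gene...``

    Identifiers are normalized on read; duplicate genes within a line
    collapse to one (gene sets are sets).
    """
    pathways = []
    for lineno, line in enumerate(_as_text(stream).splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"GMT line {lineno}: expected at least 2 tab-separated "
                f"fields, found {len(fields)}"
            )
        name, description, *genes = fields
        normalized = {normalize_gene_id(g) for g in genes}
        normalized.discard("")
        pathways.append(Pathway(
            pathway_id=name,
            name=description or name,
            source=Source.GMT,
            genes=frozenset(normalized),
        ))
    return PathwayDatabase(pathways=pathways, provenance="GMT")


def write_gmt(db: PathwayDatabase, stream: Readable | None = None) -> str:
    """Serialize a database to GMT text (lossless for ids and gene sets).

    Returns the text; if *stream* is given the text is also written to it
    (a path or a text file object).
    """
    lines = []
    for p in db.pathways:
        lines.append("\t".join([p.pathway_id, p.name, *sorted(p.genes)]))
    text = "\n".join(lines) + ("\n" if lines else "")
    if stream is not None:
        if hasattr(stream, "write"):
            stream.write(text)
        else:
            with open(stream, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# query lists


def load_query(stream: Readable) -> list[str]:
    """Load a plain-text query list, one identifier per line.

    Blank lines and ``#`` comments are ignored; identifiers are normalized
    and de-duplicated preserving first-occurrence order.  The number of
    dropped duplicates is logged.
    """
    seen: dict[str, None] = {}
    duplicates = 0
    for line in _as_text(stream).splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        norm = normalize_gene_id(stripped)
        if norm in seen:
            duplicates += 1
        else:
            seen[norm] = None
    if duplicates:
        logger.info("query list: dropped %d duplicate identifier(s)", duplicates)
    if not seen:
        raise EmptyQueryError("empty query: no identifiers after filtering")
    return list(seen)
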