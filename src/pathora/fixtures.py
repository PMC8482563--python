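"""Synthetic pathway databases and query lists with planted enrichment.

Real enrichment inputs are large downloads (KEGG/Reactome exports, cancer
gene lists); this module generates small, fully in-memory stand-ins whose
statistical behaviour is known by construction, so that every parser and
the whole enrichment pipeline can be exercised deterministically:

* :func:`generate_database` draws pathways of configurable size from a
  synthetic gene universe (``G000001`` ...), with a tunable expected
  fraction of genes shared between pathways, and can serialize the result
  to per-pathway KGML files, one GMT file and one minimal-but-valid
  BioPAX Level-3 file (Pathway → BiochemicalReaction → Protein →
  ProteinReference), all parseable by :mod:`pathora.pathway_io`.
* :func:`generate_query` draws a query list that is either uniform over
  the universe (a true null for the hypergeometric test) or deliberately
  biased toward chosen pathways ("planted" enrichment), so that recovery
  at top rank can be verified.

All randomness flows through one seeded generator per call; the same
spec and seed always reproduce the same bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .errors import SpecError
from .pathway_io import Pathway, PathwayDatabase, Source, write_gmt

__all__ = [
    "SyntheticSpec",
    "generate_database",
    "generate_query",
    "write_kgml",
    "write_kgml_dir",
    "write_biopax",
    "write_fixture_tree",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fixture.

    Defaults describe the standard test condition used throughout the
    suite: 50 pathways of 10–50 genes over a universe of 1000, with ~5%
    expected gene sharing between pathways and a query of 30 genes.
    """

    n_pathways: int = 50
    size_range: tuple[int, int] = (10, 50)
    universe_size: int = 1000
    overlap_rate: float = 0.05
    planted: tuple[tuple[str, float], ...] = ()
    query_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise SpecError(f"invalid size_range {self.size_range}")
        if hi > self.universe_size:
            raise SpecError(
                f"size_range max {hi} exceeds universe_size "
                f"{self.universe_size}")
        if not (0.0 <= self.overlap_rate <= 1.0):
            raise SpecError("overlap_rate must be in [0, 1]")
        if self.query_size > self.universe_size:
            raise SpecError("query_size exceeds universe_size")
        total = sum(f for _, f in self.planted)
        if total > 1.0 + 1e-9:
            raise SpecError(f"planted signal fractions sum to {total} > 1")
        object.__setattr__(self, "planted", tuple(
            (str(pid), float(f)) for pid, f in self.planted))


def _gene_names(universe_size: int) -> list[str]:
    width = max(6, len(str(universe_size)))
    return [f"G{i:0{width}d}" for i in range(1, universe_size + 1)]


def generate_database(spec: SyntheticSpec) -> PathwayDatabase:
    """Draw a synthetic pathway database, deterministic for fixed seed.

    Pathway sizes are uniform over ``size_range``.  For pathway *i*, a
    ``round(overlap_rate * size)`` share of its genes is drawn from genes
    already used by earlier pathways (when any exist) and the remainder
    from still-unused genes, so the expected pairwise sharing tracks
    ``overlap_rate``; with ``overlap_rate = 0`` and a universe at least as
    large as the total demand, pathways are pairwise disjoint by
    construction.  The full universe (including genes in no pathway) is
    attached as the database background.
    """
    rng = np.random.default_rng([spec.seed, 0])
    genes = np.array(_gene_names(spec.universe_size))
    lo, hi = spec.size_range

    used_mask = np.zeros(spec.universe_size, dtype=bool)
    pathways: list[Pathway] = []
    for i in range(1, spec.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        used_idx = np.flatnonzero(used_mask)
        fresh_idx = np.flatnonzero(~used_mask)
        n_shared = min(round(spec.overlap_rate * size), used_idx.size)
        n_fresh = size - n_shared
        if n_fresh > fresh_idx.size:
            # fresh genes exhausted: top up from used genes instead
            n_fresh = fresh_idx.size
            n_shared = min(size - n_fresh, used_idx.size)
        chosen = []
        if n_shared:
            chosen.append(rng.choice(used_idx, size=n_shared, replace=False))
        if n_fresh:
            chosen.append(rng.choice(fresh_idx, size=n_fresh, replace=False))
        idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
        used_mask[idx] = True
        pathways.append(Pathway(
            pathway_id=f"P{i}", name=f"Synthetic pathway {i}",
            organism="syn", source=Source.SYNTHETIC,
            genes=frozenset(genes[idx].tolist()),
        ))
    return PathwayDatabase(
        pathways=pathways,
        universe=frozenset(genes.tolist()),
        provenance=f"synthetic seed={spec.seed}",
    )


def generate_query(db: PathwayDatabase, spec: SyntheticSpec) -> list[str]:
    """Draw a query list with the spec's planted enrichment signal.

    For each planted ``(pathway_id, fraction)``, ``ceil(fraction *
    query_size)`` genes are sampled without replacement from that pathway
    (capped at the pathway's size — a pathway cannot contribute more
    distinct genes than it has); the remainder is uniform over the
    universe minus the genes already chosen.  Planted genes come first in
    the emitted list.
    """
    rng = np.random.default_rng([spec.seed, 1])
    chosen: list[str] = []
    chosen_set: set[str] = set()
    for pid, fraction in spec.planted:
        try:
            pathway = db[pid]
        except KeyError:
            raise SpecError(f"planted pathway id {pid!r} not in database") \
                from None
        want = math.ceil(fraction * spec.query_size)
        pool = sorted(pathway.genes - chosen_set)
        take = min(want, len(pool), spec.query_size - len(chosen))
        if take:
            picked = rng.choice(len(pool), size=take, replace=False)
            for j in sorted(picked):
                chosen.append(pool[j])
            chosen_set.update(chosen)
    remainder = spec.query_size - len(chosen)
    if remainder > 0:
        pool = sorted(db.universe - chosen_set)
        picked = rng.choice(len(pool), size=remainder, replace=False)
        for j in sorted(picked):
            chosen.append(pool[j])
    return chosen


# ---------------------------------------------------------------------------
# serialization


def write_kgml(pathway: Pathway) -> str:
    """Render one pathway as a KGML document (one ``entry`` per gene)."""
    root = etree.Element("pathway", name=pathway.pathway_id,
                         title=pathway.name, org=pathway.organism or "syn")
    for i, gene in enumerate(sorted(pathway.genes), start=1):
        entry = etree.SubElement(root, "entry", id=str(i), name=gene,
                                 type="gene")
        etree.SubElement(entry, "graphics", name=gene)
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def write_kgml_dir(db: PathwayDatabase, out_dir: str | Path) -> list[Path]:
    """Write one KGML file per pathway into *out_dir*; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in db.pathways:
        path = out / f"{p.pathway_id}.xml"
        path.write_text(write_kgml(p), encoding="utf-8")
        paths.append(path)
    return paths


_BIOPAX_HEADER = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
    '         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"\n'
    '         xml:base="http://pathora.example/synthetic#">\n'
)


def write_biopax(db: PathwayDatabase) -> str:
    """Render the whole database as a minimal BioPAX Level-3 document.

    Each pathway becomes ``bp:Pathway`` → one ``bp:BiochemicalReaction``
    whose ``bp:left`` participants are ``bp:Protein`` entities with
    ``bp:ProteinReference``/``displayName`` per gene.  This exercises the
    parser's transitive traversal, not the full Reactome vocabulary.
    """
    from xml.sax.saxutils import escape, quoteattr

    parts = [_BIOPAX_HEADER]
    for p in db.pathways:
        pid = p.pathway_id
        parts.append(f'  <bp:Pathway rdf:ID="{pid}">\n'
                     f'    <bp:displayName>{escape(p.name)}</bp:displayName>\n'
                     f'    <bp:pathwayComponent rdf:resource="#{pid}_rxn"/>\n'
                     f'  </bp:Pathway>\n')
        lefts = "".join(
            f'    <bp:left rdf:resource="#{pid}_pe{j}"/>\n'
            for j in range(len(p.genes)))
        parts.append(f'  <bp:BiochemicalReaction rdf:ID="{pid}_rxn">\n'
                     f'{lefts}  </bp:BiochemicalReaction>\n')
        for j, gene in enumerate(sorted(p.genes)):
            parts.append(
                f'  <bp:Protein rdf:ID="{pid}_pe{j}">\n'
                f'    <bp:entityReference rdf:resource="#{pid}_ref{j}"/>\n'
                f'  </bp:Protein>\n'
                f'  <bp:ProteinReference rdf:ID="{pid}_ref{j}">\n'
                f'    <bp:displayName>{escape(gene)}</bp:displayName>\n'
                f'  </bp:ProteinReference>\n')
    parts.append('</rdf:RDF>\n')
    return "".join(parts)


def write_fixture_tree(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Generate and serialize a full fixture set under *out_dir*.

    Writes ``kgml/<pathway_id>.xml`` per pathway, ``pathways.gmt``,
    ``pathways.owl`` (BioPAX L3) and ``query.txt``; returns a manifest of
    paths plus the in-memory database and query.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = generate_database(spec)
    query = generate_query(db, spec)
    kgml_paths = write_kgml_dir(db, out / "kgml")
    gmt_path = out / "pathways.gmt"
    write_gmt(db, gmt_path)
    owl_path = out / "pathways.owl"
    owl_path.write_text(write_biopax(db), encoding="utf-8")
    query_path = out / "query.txt"
    query_path.write_text("\n".join(query) + "\n", encoding="utf-8")
    return {"db": db, "query": query, "kgml": kgml_paths,
            "gmt": gmt_path, "biopax": owl_path, "query_path": query_path}
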