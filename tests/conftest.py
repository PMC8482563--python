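"""Shared fixtures: small hand-written KGML/BioPAX/GMT documents and the
brute-force hypergeometric enumeration oracle used against the analytic
tail."""

from itertools import combinations

import pytest

# One KGML pathway with two gene entries, one pathway cross-link ("map")
# and one compound; only the gene entries may contribute identifiers.
KGML_FIXTURE = """<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:hsa05200" org="hsa" number="05200" title="Pathways in cancer">
  <entry id="1" name="hsa:7157" type="gene">
    <graphics name="TP53, P53" type="rectangle"/>
  </entry>
  <entry id="2" name="hsa:1029" type="gene">
    <graphics name="CDKN2A"/>
  </entry>
  <entry id="3" name="path:hsa04110" type="map">
    <graphics name="Cell cycle"/>
  </entry>
  <entry id="4" name="cpd:C00076" type="compound">
    <graphics name="Calcium"/>
  </entry>
</pathway>
"""

KGML_EMPTY = """<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:hsa00001" org="hsa" title="Empty map"/>
"""

# Minimal BioPAX Level 3: one pathway -> one reaction with two proteins
# (one carrying a unification xref) and one small molecule (excluded).
BIOPAX_FIXTURE = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"
         xml:base="http://example.org/test#">
  <bp:Pathway rdf:ID="PW1">
    <bp:displayName>Toy signalling</bp:displayName>
    <bp:pathwayComponent rdf:resource="#RX1"/>
  </bp:Pathway>
  <bp:BiochemicalReaction rdf:ID="RX1">
    <bp:left rdf:resource="#PE1"/>
    <bp:left rdf:resource="#PE2"/>
    <bp:right rdf:resource="#SM1"/>
  </bp:BiochemicalReaction>
  <bp:Protein rdf:ID="PE1">
    <bp:entityReference rdf:resource="#PR1"/>
  </bp:Protein>
  <bp:Protein rdf:ID="PE2">
    <bp:entityReference rdf:resource="#PR2"/>
  </bp:Protein>
  <bp:SmallMolecule rdf:ID="SM1">
    <bp:entityReference rdf:resource="#SMR1"/>
  </bp:SmallMolecule>
  <bp:ProteinReference rdf:ID="PR1">
    <bp:displayName>Abc1</bp:displayName>
    <bp:xref rdf:resource="#UX1"/>
  </bp:ProteinReference>
  <bp:ProteinReference rdf:ID="PR2">
    <bp:displayName>XYZ2</bp:displayName>
  </bp:ProteinReference>
  <bp:SmallMoleculeReference rdf:ID="SMR1">
    <bp:displayName>ATP</bp:displayName>
  </bp:SmallMoleculeReference>
  <bp:UnificationXref rdf:ID="UX1">
    <bp:db>UniProt</bp:db>
    <bp:id>P12345</bp:id>
  </bp:UnificationXref>
</rdf:RDF>
"""

# Parent pathway embedding a sub-pathway, with a component cycle
# (child points back to parent) to exercise the visited-set.
BIOPAX_NESTED_CYCLIC = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"
         xml:base="http://example.org/test#">
  <bp:Pathway rdf:ID="PARENT">
    <bp:displayName>Parent</bp:displayName>
    <bp:pathwayComponent rdf:resource="#CHILD"/>
    <bp:pathwayComponent rdf:resource="#RXP"/>
  </bp:Pathway>
  <bp:Pathway rdf:ID="CHILD">
    <bp:displayName>Child</bp:displayName>
    <bp:pathwayComponent rdf:resource="#RXC"/>
    <bp:pathwayComponent rdf:resource="#PARENT"/>
  </bp:Pathway>
  <bp:BiochemicalReaction rdf:ID="RXP">
    <bp:left rdf:resource="#PEP"/>
  </bp:BiochemicalReaction>
  <bp:BiochemicalReaction rdf:ID="RXC">
    <bp:participant rdf:resource="#CX1"/>
  </bp:BiochemicalReaction>
  <bp:Protein rdf:ID="PEP">
    <bp:entityReference rdf:resource="#PRP"/>
  </bp:Protein>
  <bp:Complex rdf:ID="CX1">
    <bp:component rdf:resource="#PEC"/>
  </bp:Complex>
  <bp:Protein rdf:ID="PEC">
    <bp:entityReference rdf:resource="#PRC"/>
  </bp:Protein>
  <bp:ProteinReference rdf:ID="PRP">
    <bp:displayName>PARENTGENE</bp:displayName>
  </bp:ProteinReference>
  <bp:ProteinReference rdf:ID="PRC">
    <bp:displayName>CHILDGENE</bp:displayName>
  </bp:ProteinReference>
</rdf:RDF>
"""

BIOPAX_EMPTY_PATHWAY = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"
         xml:base="http://example.org/test#">
  <bp:Pathway rdf:ID="LONELY">
    <bp:displayName>No components</bp:displayName>
  </bp:Pathway>
</rdf:RDF>
"""

BIOPAX_LEVEL2 = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bp="http://www.biopax.org/release/biopax-level2.owl#">
  <bp:pathway rdf:ID="OLD"/>
</rdf:RDF>
"""


def hypergeom_tail_by_enumeration(k: int, m: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element universe
    whose first m elements are marked.  Independent of any closed form."""
    hits = total = 0
    marked = set(range(m))
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


@pytest.fixture
def toy_db():
    """Three disjoint pathways over a 10-gene universe (A..J)."""
    from pathora import Pathway, PathwayDatabase, Source

    return PathwayDatabase(pathways=[
        Pathway("P1", "First", frozenset("ABCD"), source=Source.GMT),
        Pathway("P2", "Second", frozenset("EFG"), source=Source.GMT),
        Pathway("P3", "Third", frozenset("HIJ"), source=Source.GMT),
    ])
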