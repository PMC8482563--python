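# Methods

## Model and assumptions

`pathora` implements classical over-representation analysis (ORA): for a
query list of genes/proteins and each pathway in a database, the overlap
count is referred to the hypergeometric distribution and the one-sided
upper tail `P(X >= k)` is reported as the enrichment p-value.  The null
model assumes the query is a uniform draw without replacement from a
fixed background universe; the test uses only set membership — no pathway
topology, no gene ranking, no expression magnitudes.

Two modelling choices deserve emphasis because the literature often
leaves them implicit:

* **Background universe.**  The population `N` the test draws from is, by
  default, the union of all gene identifiers in the loaded database.
  This is the only background that is reproducible from the inputs alone;
  any other choice (whole genome, array content) must be supplied
  explicitly via `EnrichmentConfig.background` / `--background`, and is
  then united with the member genes so the test's preconditions always
  hold.  Query genes absent from the universe are dropped from `n`
  (counted and reported) rather than inflating the draw count: counting
  unmatched identifiers in `n` would deflate every p-value with no
  statistical justification.
* **Identifier matching.**  Identifiers are compared as normalized
  strings: uppercased symbols, KGML `org:digits` tokens as
  `ENTREZ:<digits>`, BioPAX unification xrefs as `DB:ID`.  No
  cross-namespace mapping is attempted, so a pathway may legitimately
  carry both a symbol and an accession for one biological gene.  Overlap
  statistics are therefore statistics over identifier strings; users who
  need symbol↔accession unification must pre-map their inputs.

## Multiple-testing correction

Raw p-values across the `N_tests` eligible pathways (those meeting
`min_pathway_size`, default 1 — an empty gene set cannot be tested) are
adjusted two ways and both columns always reported:

* **Benjamini–Hochberg step-up FDR**: the i-th smallest p maps to
  `p_(i) * N_tests / i`; a cumulative minimum from the largest rank down
  enforces monotonicity, values are capped at 1 and returned in input
  order.  Ties share the adjusted value of their rank position.  The
  implementation is cross-checked against
  `statsmodels.stats.multitest.multipletests(method="fdr_bh")` in the
  test suite.
* **Bonferroni**: `min(1, p * N_tests)`, the adjusted-p form of dividing
  the significance level by the number of tests.

For every record `p_fdr <= p_bonf <= 1`, and the significance filter
(default: raw column at α = 0.005, switchable to either corrected column)
is monotone in α.  Ranking is by raw p ascending with lexicographic
pathway-id tie-break, so "top k" views are deterministic.

## Numerical choices

The tail is computed with `scipy.stats.hypergeom.sf`; if that underflows
to zero while the support is non-empty, the tail is recomputed as
`logsumexp` over `logpmf`, so values down to ~1e-300 survive.  True tails
below the smallest double (~5e-324) are unrepresentable and reported as
0; adjusted values are exact multiples of the raw value until the cap.
Argument bounds (`0 <= m,n <= N`, `max(0, m+n-N) <= k <= min(m,n)`) are
validated and violations raise a domain error naming the constraint.

## Parsing

* **KGML**: one file is one pathway.  Only entries with `type="gene"`
  contribute; `compound`, `map`, `group` and `ortholog` entries are
  ignored (group members are genes already listed as their own entries).
  Each gene entry contributes every space-separated `name` token plus the
  first comma-separated token of each nested `graphics` name (trailing
  `...` stripped — KEGG truncates long label lists that way).
* **BioPAX**: Level 3 only; Level 2 documents are rejected with a clear
  error rather than half-parsed.  Each `bp:Pathway` instance becomes one
  pathway; the RDF graph is walked transitively through
  `pathwayComponent`, step/order properties, interaction participants
  (`left`, `right`, `controller`, `controlled`, `participant`,
  `product`, `template`) and `Complex` components down to
  Protein/Rna/Dna entities, with a visited-set so cyclic graphs
  terminate.  Small molecules are excluded — ATP in a reaction is not
  evidence a gene list hits the pathway.  Sub-pathways contribute their
  genes to the parent *and* appear as their own entries, matching
  hierarchical Reactome exports.  Because RDF is unordered, pathway order
  is recovered from each node's first occurrence in the document bytes,
  keeping parsing deterministic.
* **GMT**: read/write round-trips pathway ids and gene sets losslessly;
  identifiers are normalized on read.

## Similarity indices

Two enrichment results are compared on their significant pathway-**id**
sets (names are whitespace/case fragile).  Reported per pair: NP1, NP2,
union, intersection, Jaccard `|∩|/|∪|` and meet-min `|∩|/min(|P1|,|P2|)`.
Invariants enforced and property-tested: inclusion–exclusion
`U = NP1 + NP2 − I`, `0 ≤ JI ≤ mi ≤ 1`, `JI = 1` iff equality, `mi = 1`
iff containment, full symmetry.  Comparing two empty significant sets is
an error (0/0 has no meaningful index value), not a sentinel.  Indices
are returned as fractions in [0,1]; percent rendering is presentation
only.

## Synthetic data

The `fixtures` module emulates, at desk scale, the shape of a real
enrichment study: a database of 50 pathways of 10–50 genes over a
1000-gene universe with ~5% expected gene sharing between pathways, and a
30-gene query — either uniform over the universe (an exact null for the
test, since the query is then a draw without replacement) or planted,
with `ceil(fraction * query_size)` genes taken from a chosen pathway
(capped at the pathway's size, which a without-replacement draw cannot
exceed).  Gene identifiers are `G000001…`; all randomness flows through
one seeded generator per call, so fixed spec + seed reproduce identical
databases, queries and serialized bytes.  Databases serialize to
per-pathway KGML, one GMT and one minimal-but-valid BioPAX L3 document
(Pathway → BiochemicalReaction → Protein → ProteinReference), each of
which parses back to identical gene sets.

What the generator does **not** emulate: real KEGG/Reactome pathway-size
distributions, hierarchical pathway nesting, multi-namespace identifiers
per gene, or annotation bias.  Passing recovery tests on these fixtures
therefore demonstrates the pipeline's statistical and mechanical
correctness, not that any particular biological enrichment claim holds on
real data — for that the database version and background choice dominate.

A note on calibration: the hypergeometric tail is a *discrete* test, so
its attained level sits below the nominal α — with this generator's
dimensions the attained level at α = 0.005 averages about 0.002 across
pathway sizes 10–50, and observed null rejection rates track that value.
The guarantee a conservative test provides is one-sided (the rejection
rate does not *exceed* α), and that is the property the suite enforces;
a two-sided band centred on α is not achievable for discrete tests at
these dimensions and the corresponding strict check is expected to fail,
documented as such.

## Problem sizes used in the checks

Worked-example arithmetic: 291 simultaneous tests.  Oracle sweep: every
valid (k, m, n, N) with N ≤ 12 (1820 tuples) against exhaustive subset
enumeration.  Null calibration: 200 seeded runs (10,000 pathway tests).
Planted recovery: 100 seeded runs at signal fraction 0.5.  Round-trips:
20 seeded databases × 10 pathways × 2 formats.  Index laws: 1000 random
set pairs.

## Known limitations

* No GSEA-style ranked statistics and no topology-aware scores; ORA only.
* No identifier-mapping service; heterogeneous inputs must share a
  namespace to overlap.
* BioPAX parsing targets the core Level-3 traversal vocabulary; exotic
  constructs (generic entity references, stoichiometry-dependent
  semantics) are ignored for membership purposes.
* The FDR adjustment assumes the usual BH setting; no dependency-robust
  (Benjamini–Yekutieli) variant is exposed.
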