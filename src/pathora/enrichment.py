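"""Hypergeometric over-representation analysis with multiple-testing control.

The statistical core: given a query list of :math:`n` genes drawn from a
universe of :math:`N` genes, and a pathway containing :math:`m` of those
genes, the overlap :math:`k` under the null of random draws follows the
hypergeometric distribution, and the enrichment p-value is the upper tail

.. math::

    p = P(X \\ge k) = \\sum_{i=k}^{\\min(m,n)}
        \\frac{\\binom{m}{i}\\binom{N-m}{n-i}}{\\binom{N}{n}}.

Per-pathway p-values are corrected for multiple testing with the
Benjamini–Hochberg step-up FDR procedure (:func:`fdr_adjust`) and the
Bonferroni adjustment (:func:`bonferroni_adjust`), both reported alongside
the raw value.  The default significance protocol thresholds the raw
p-value at 0.005.

The module is organised statsmodels-style:
:class:`OverRepresentationAnalysis` is the model (query + database +
config); its :meth:`~OverRepresentationAnalysis.fit` returns an
:class:`EnrichmentResults` carrying the ranked records, diagnostics, a
``summary()`` table and TSV round-trip I/O.  :func:`enrich` is the
one-call convenience wrapper.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import DomainError, EmptyQueryError, FormatError
from .pathway_io import PathwayDatabase, normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "Column",
    "EnrichmentConfig",
    "EnrichmentRecord",
    "EnrichmentResults",
    "OverRepresentationAnalysis",
    "hypergeom_pvalue",
    "bonferroni_adjust",
    "fdr_adjust",
    "enrich",
]

#: exact TSV column order of the result table
TSV_COLUMNS = ["pathway_id", "name", "m", "k", "p_raw", "p_fdr", "p_bonf",
               "overlap_genes"]


class Column(str, Enum):
    """Which p-value column the significance threshold applies to."""

    RAW = "raw"
    FDR = "fdr"
    BONFERRONI = "bonferroni"


@dataclass(frozen=True)
class EnrichmentConfig:
    """Protocol parameters for one enrichment run.

    Parameters
    ----------
    alpha : float
        Significance threshold on the selected p-value column; the
        default 0.005 follows the published protocol.
    column : Column
        Column thresholded by :meth:`EnrichmentResults.significant`
        (default raw; the corrected columns are always reported).
    min_pathway_size : int
        Pathways with fewer genes in the universe are excluded from
        testing (and from the number of tests N).  An empty gene set
        cannot be tested, hence the default 1.
    background : frozenset[str] | None
        Optional explicit universe override; ``None`` means the union of
        all database gene sets.
    """

    alpha: float = 0.005
    column: Column = Column.RAW
    min_pathway_size: int = 1
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.min_pathway_size < 1:
            raise DomainError("min_pathway_size must be >= 1")
        object.__setattr__(self, "column", Column(self.column))


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-pathway test result.

    ``m`` is the pathway size within the universe, ``k`` the overlap with
    the query, ``p_raw`` the hypergeometric upper-tail probability,
    ``p_fdr``/``p_bonf`` the corrected values (capped at 1).
    """

    pathway_id: str
    name: str
    m: int
    k: int
    p_raw: float
    p_fdr: float
    p_bonf: float
    overlap_genes: frozenset[str]

    def value(self, column: Column) -> float:
        return {Column.RAW: self.p_raw, Column.FDR: self.p_fdr,
                Column.BONFERRONI: self.p_bonf}[Column(column)]


# ---------------------------------------------------------------------------
# statistics


def _check_args(k: int, m: int, n: int, N: int) -> None:
    if N < 0:
        raise DomainError(f"universe size N must be >= 0, got {N}")
    if not 0 <= m <= N:
        raise DomainError(f"pathway size m must satisfy 0 <= m <= N: m={m}, N={N}")
    if not 0 <= n <= N:
        raise DomainError(f"query size n must satisfy 0 <= n <= N: n={n}, N={N}")
    lo, hi = max(0, m + n - N), min(m, n)
    if not lo <= k <= hi:
        raise DomainError(
            f"overlap k must satisfy max(0, m+n-N) <= k <= min(m, n): "
            f"k={k}, bounds=[{lo}, {hi}]"
        )


def hypergeom_pvalue(k: int, m: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts the query genes landing in a pathway of size *m* when
    *n* genes are drawn without replacement from a universe of size *N*.
    Computed through the scipy survival function with a log-space
    fallback, so extreme tails (1e-150 and below) do not underflow to 0.
    """
    _check_args(k, m, n, N)
    if k <= max(0, m + n - N):
        return 1.0
    p = float(hypergeom.sf(k - 1, N, m, n))
    if p == 0.0:
        # true tail is positive on the support; recover it in log space
        support = np.arange(k, min(m, n) + 1)
        p = float(np.exp(logsumexp(hypergeom.logpmf(support, N, m, n))))
    return min(1.0, max(0.0, p))


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value ``min(1, p * n_tests)``.

    Equivalent to comparing the raw p against the α/k corrected
    significance level, reported on the p-value scale.
    """
    if n_tests < 1:
        raise DomainError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must be in [0, 1], got {p}")
    return min(1.0, p * n_tests)


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    The i-th smallest p maps to ``p_(i) * N / i``; monotonicity is then
    enforced by a cumulative minimum from the largest rank downward, the
    result capped at 1 and returned in the original order (ties share the
    value of their rank position after the cumulative minimum).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DomainError("fdr_adjust requires a non-empty list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("all p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    n = p.size
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n, dtype=float)
    out[order] = adjusted
    return out.tolist()


# ---------------------------------------------------------------------------
# model / results


class OverRepresentationAnalysis:
    """Over-representation model for a query list against a pathway database.

    Parameters
    ----------
    query : sequence of str
        Gene/protein identifiers of interest (normalized on input).
    database : PathwayDatabase
        Pathway collection; its universe (or ``config.background``) is the
        population the hypergeometric test draws from.
    config : EnrichmentConfig, optional

    Examples
    --------
    >>> from pathora import OverRepresentationAnalysis, read_gmt
    >>> db = read_gmt("pathways.gmt")            # doctest: +SKIP
    >>> res = OverRepresentationAnalysis(["TP53", "BRCA1"], db).fit()  # doctest: +SKIP
    >>> res.summary().head()                     # doctest: +SKIP
    """

    def __init__(self, query: Iterable[str], database: PathwayDatabase,
                 config: EnrichmentConfig | None = None) -> None:
        self.config = config or EnrichmentConfig()
        if self.config.background is not None:
            database = database.with_background(self.config.background)
        self.database = database
        seen: dict[str, None] = {}
        for g in query:
            norm = normalize_gene_id(g)
            if norm:
                seen.setdefault(norm, None)
        if not seen:
            raise EmptyQueryError("empty query")
        self.query: list[str] = list(seen)

    @classmethod
    def from_files(cls, query_path, database_paths,
                   config: EnrichmentConfig | None = None
                   ) -> "OverRepresentationAnalysis":
        """Build the model straight from a query file and pathway files
        (format auto-detected per file; see :func:`pathora.cli.load_database`)."""
        from .cli import load_database
        from .pathway_io import load_query
        db = load_database(database_paths)
        return cls(load_query(query_path), db, config)

    def fit(self) -> "EnrichmentResults":
        """Run the test for every eligible pathway and return ranked results."""
        cfg = self.config
        universe = self.database.universe
        N = len(universe)
        query_in = [g for g in self.query if g in universe]
        dropped = len(self.query) - len(query_in)
        if dropped:
            logger.info("enrich: dropped %d query gene(s) absent from the "
                        "universe", dropped)
        if not query_in:
            raise EmptyQueryError("query disjoint from universe")
        qset = frozenset(query_in)
        n = len(qset)

        eligible = []
        for p in self.database.pathways:
            genes = p.genes & universe
            if len(genes) >= cfg.min_pathway_size:
                eligible.append((p, genes))
        if not eligible:
            raise FormatError(
                f"no pathway meets min_pathway_size={cfg.min_pathway_size}")
        n_tests = len(eligible)

        raw = []
        for p, genes in eligible:
            overlap = genes & qset
            raw.append((p, genes, overlap,
                        hypergeom_pvalue(len(overlap), len(genes), n, N)))
        fdr = fdr_adjust([r[3] for r in raw])
        records = [
            EnrichmentRecord(
                pathway_id=p.pathway_id, name=p.name,
                m=len(genes), k=len(overlap),
                p_raw=p_raw, p_fdr=p_fdr,
                p_bonf=bonferroni_adjust(p_raw, n_tests),
                overlap_genes=frozenset(overlap),
            )
            for (p, genes, overlap, p_raw), p_fdr in zip(raw, fdr)
        ]
        records.sort(key=lambda r: (r.p_raw, r.pathway_id))
        return EnrichmentResults(
            records=records, n=n, N_tests=n_tests, universe_size=N,
            config=cfg, dropped_query_genes=dropped,
        )


@dataclass
class EnrichmentResults:
    """Ranked enrichment table plus run diagnostics.

    ``records`` is ordered by raw p-value ascending, ties broken by
    pathway id, so the "top 10" of the reporting protocol is simply the
    head of the table.
    """

    records: list[EnrichmentRecord]
    n: int
    N_tests: int
    universe_size: int
    config: EnrichmentConfig
    dropped_query_genes: int = 0

    def significant(self, alpha: float | None = None,
                    column: Column | None = None) -> list[EnrichmentRecord]:
        """Records whose selected p-value column is <= alpha."""
        alpha = self.config.alpha if alpha is None else alpha
        column = self.config.column if column is None else Column(column)
        return [r for r in self.records if r.value(column) <= alpha]

    def significant_ids(self, alpha: float | None = None,
                        column: Column | None = None) -> frozenset[str]:
        return frozenset(r.pathway_id for r in
                         self.significant(alpha=alpha, column=column))

    def top(self, k: int = 10) -> list[EnrichmentRecord]:
        """Head of the ranked table (the protocol's top-10 view)."""
        return self.records[:k]

    def summary(self) -> pd.DataFrame:
        """The full result table as a DataFrame (one row per pathway)."""
        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.records],
                "name": [r.name for r in self.records],
                "m": [r.m for r in self.records],
                "k": [r.k for r in self.records],
                "p_raw": [r.p_raw for r in self.records],
                "p_fdr": [r.p_fdr for r in self.records],
                "p_bonf": [r.p_bonf for r in self.records],
                "overlap_genes": [";".join(sorted(r.overlap_genes))
                                  for r in self.records],
            },
            columns=TSV_COLUMNS,
        )

    def to_tsv(self, stream=None) -> str:
        """Serialize to TSV (header + one row per record; p-values in
        scientific notation with 6 significant digits)."""
        df = self.summary()
        for col in ("p_raw", "p_fdr", "p_bonf"):
            df[col] = df[col].map(lambda v: f"{v:.6e}")
        text = df.to_csv(sep="\t", index=False)
        if stream is not None:
            if hasattr(stream, "write"):
                stream.write(text)
            else:
                with open(stream, "w", encoding="utf-8") as fh:
                    fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, stream, config: EnrichmentConfig | None = None
                 ) -> "EnrichmentResults":
        """Load a previously saved result table.

        Diagnostics that the TSV does not carry (query size, universe
        size) are reconstructed as far as possible; N_tests is the row
        count.
        """
        if hasattr(stream, "read"):
            df = pd.read_csv(stream, sep="\t", dtype={"pathway_id": str,
                                                      "name": str})
        else:
            df = pd.read_csv(str(stream), sep="\t", dtype={"pathway_id": str,
                                                           "name": str})
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                "enrichment TSV is missing column(s): " + ", ".join(missing))
        records = []
        for row in df.itertuples(index=False):
            genes = getattr(row, "overlap_genes")
            geneset = frozenset(str(genes).split(";")) \
                if isinstance(genes, str) and genes else frozenset()
            records.append(EnrichmentRecord(
                pathway_id=str(row.pathway_id), name=str(row.name),
                m=int(row.m), k=int(row.k),
                p_raw=float(row.p_raw), p_fdr=float(row.p_fdr),
                p_bonf=float(row.p_bonf), overlap_genes=geneset,
            ))
        records.sort(key=lambda r: (r.p_raw, r.pathway_id))
        n = max((r.k for r in records), default=0)
        return cls(records=records, n=n, N_tests=len(records),
                   universe_size=0, config=config or EnrichmentConfig())


def enrich(query: Iterable[str], db: PathwayDatabase,
           config: EnrichmentConfig | None = None) -> EnrichmentResults:
    """One-call over-representation analysis (model + fit)."""
    return OverRepresentationAnalysis(query, db, config).fit()
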