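"""Over-representation analysis against user-supplied term-gene tables.

For a query gene list of size n drawn from a universe of N genes, a term
annotating K universe genes with k of them in the query gets the exact
hypergeometric upper tail p = P(X >= k), one-sided for over-representation,
followed by Benjamini-Hochberg adjustment across all tested terms. The
default universe is the set of genes actually tested for differential
expression, not the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_TERM_SIZE = 2  # smaller terms give uninformative p-values and are skipped


@dataclass(frozen=True)
class TermSet:
    term_id: str
    term_name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    source: str
    overlap_count: int  # k
    term_size: int  # K, within the universe
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    fdr: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: Iterable[str],
    terms: Sequence[TermSet],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Exact hypergeometric over-representation test per term, BH-adjusted.

    Query genes outside the universe are dropped with a warning; term genes
    outside the universe are ignored; terms with fewer than two universe
    genes are skipped. Results are sorted by p ascending, ties by term id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    stray = query - universe_set
    if stray:
        logger.warning("%d query gene(s) outside the universe dropped", len(stray))
        query &= universe_set

    N, n = len(universe_set), len(query)
    tested: list[tuple[TermSet, int, int, float, tuple[str, ...]]] = []
    for term in terms:
        term_in_universe = term.genes & universe_set
        if len(term_in_universe) < len(term.genes):
            logger.warning(
                "term %s: %d gene(s) outside universe ignored",
                term.term_id,
                len(term.genes) - len(term_in_universe),
            )
        K = len(term_in_universe)
        if K < MIN_TERM_SIZE:
            logger.warning("term %s skipped: only %d universe gene(s)", term.term_id, K)
            continue
        overlap = tuple(sorted(term_in_universe & query))
        p = hypergeom_upper_tail(len(overlap), N, K, n)
        tested.append((term, K, len(overlap), p, overlap))

    if not tested:
        return []
    _, fdrs, _, _ = multipletests([t[3] for t in tested], method="fdr_bh")
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            source=term.source,
            overlap_count=k,
            term_size=K,
            query_size=n,
            universe_size=N,
            p_value=p,
            fdr=float(fdr),
            overlap_genes=overlap,
        )
        for (term, K, k, p, overlap), fdr in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def read_term_table(path: str | Path) -> list[TermSet]:
    """Read a term-gene TSV (term_id, term_name, source, gene_id; one row
    per pair) or a GMT file (term, description, genes...)."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        terms = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms.append(TermSet(parts[0], parts[0], parts[1] or "GMT", frozenset(parts[2:])))
        return terms
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "source", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"term table missing column(s): {sorted(required - set(df.columns))}")
    terms = []
    for (term_id, term_name, source), group in df.groupby(
        ["term_id", "term_name", "source"], sort=True
    ):
        terms.append(TermSet(term_id, term_name, source, frozenset(group["gene_id"])))
    return terms


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "source": r.source,
            "overlap_count": r.overlap_count,
            "term_size": r.term_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "overlap_genes": ";".join(r.overlap_genes),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "source",
            "overlap_count",
            "term_size",
            "query_size",
            "universe_size",
            "p_value",
            "fdr",
            "overlap_genes",
        ],
    )
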