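"""Over-representation search of query gene lists against gene-set collections.

For a query of size *q* drawn from a background universe of size *N*, the
number of query genes falling inside a candidate set of scale *K* follows a
hypergeometric null. The one-sided over-representation p-value is
``P(X >= hits)`` — the upper tail of Fisher's exact test on the 2x2
membership table. Results are filtered by a hit floor and a p-value
threshold, adjusted for multiple testing with Benjamini-Hochberg, and
ranked by decreasing hits (then increasing p, then set id), mirroring how
disease gene-set search tables are conventionally presented.

The *disease-profile* search first collects the genes of all name-matching
sets from designated disease sources (e.g. OMIM- or GAD-like catalogs) into
a profile, then queries every other source with that profile, excluding the
disease sources themselves from the results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import (
    EmptyQueryError,
    GeneSet,
    GeneSetCollection,
    QueryGeneList,
    name_search,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "EmptyProfileError",
    "count_hits",
    "fisher_pvalue",
    "bh_fdr",
    "search_by_genes",
    "disease_profile_search",
    "results_to_frame",
    "write_results",
]

DEFAULT_MIN_HITS = 2
DEFAULT_P_THRESHOLD = 0.05


class EmptyProfileError(ValueError):
    """No disease set matched the search term, so no profile could be built."""


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    source: str
    organism: str
    hits: int
    set_scale: int
    query_size: int
    universe_size: int
    p_value: float
    fdr: float
    rank: int


def count_hits(query: QueryGeneList, gene_set: GeneSet) -> int:
    """Number of query genes present in the gene set."""
    return len(set(query.symbols) & gene_set.genes)


def fisher_pvalue(
    hits: int, query_size: int, set_scale: int, universe_size: int
) -> float:
    """One-sided over-representation p-value ``P(X >= hits)``.

    X ~ Hypergeometric(universe_size, set_scale, query_size): the overlap
    obtained by drawing ``query_size`` genes uniformly without replacement
    from a universe in which ``set_scale`` genes are marked.
    """
    if universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    if not (0 <= hits <= min(query_size, set_scale)):
        raise ValueError(
            f"hits={hits} inconsistent with query_size={query_size}, "
            f"set_scale={set_scale}"
        )
    if query_size > universe_size or set_scale > universe_size:
        raise ValueError("query_size and set_scale must not exceed universe_size")
    if hits == 0:
        return 1.0
    # sf(k) = P(X > k), so P(X >= hits) = sf(hits - 1)
    return float(hypergeom.sf(hits - 1, universe_size, set_scale, query_size))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    if len(p_values) == 0:
        raise ValueError("p_values must be non-empty")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(x) for x in adj]


def _resolve_universe(
    collections: Sequence[GeneSetCollection], universe_size: int | str
) -> int:
    if universe_size == "auto":
        union: set[str] = set()
        for coll in collections:
            union |= coll.universe
        return len(union)
    n = int(universe_size)
    if n < 1:
        raise ValueError("universe_size must be >= 1")
    return n


def search_by_genes(
    query: QueryGeneList,
    collections: Sequence[GeneSetCollection],
    min_hits: int = DEFAULT_MIN_HITS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    universe_size: int | str = "auto",
    exclude_sources: Sequence[str] = (),
) -> list[EnrichmentResult]:
    """Rank gene sets by over-representation of the query genes.

    Sources in ``exclude_sources`` are removed before testing. The test
    family for FDR adjustment is the post-exclusion sets passing the hit
    floor; the p-value threshold is applied after adjustment is computed.
    Query genes absent from the combined universe still count toward
    query_size but are reported through the logging contract.
    """
    if not collections:
        raise ValueError("at least one collection required")
    if len(query) == 0:
        raise EmptyQueryError("query gene list is empty")
    excluded = set(exclude_sources)
    universe_n = _resolve_universe(collections, universe_size)
    if universe_n < len(query):
        raise ValueError(
            f"universe size {universe_n} smaller than query size {len(query)}"
        )
    query_genes = set(query.symbols)
    combined: set[str] = set()
    for coll in collections:
        combined |= coll.universe
    absent = query_genes - combined
    if absent:
        logger.warning(
            "%d of %d query genes absent from the collection universe",
            len(absent), len(query_genes),
        )

    candidates: list[tuple[GeneSet, int]] = []
    for coll in collections:
        for s in coll.sets:
            if s.source in excluded:
                continue
            h = len(query_genes & s.genes)
            if h >= min_hits:
                candidates.append((s, h))
    if not candidates:
        return []

    pvals = [
        fisher_pvalue(h, len(query), s.scale, universe_n) for s, h in candidates
    ]
    fdrs = bh_fdr(pvals)
    rows = [
        (s, h, p, f)
        for (s, h), p, f in zip(candidates, pvals, fdrs)
        if p < p_threshold
    ]
    rows.sort(key=lambda r: (-r[1], r[2], r[0].set_id))
    return [
        EnrichmentResult(
            set_id=s.set_id,
            name=s.name,
            source=s.source,
            organism=s.organism,
            hits=h,
            set_scale=s.scale,
            query_size=len(query),
            universe_size=universe_n,
            p_value=p,
            fdr=f,
            rank=i,
        )
        for i, (s, h, p, f) in enumerate(rows, start=1)
    ]


def disease_profile_search(
    term: str,
    disease_sources: Sequence[str],
    collections: Sequence[GeneSetCollection],
    min_hits: int = DEFAULT_MIN_HITS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    universe_size: int | str = "auto",
) -> tuple[QueryGeneList, list[EnrichmentResult]]:
    """Two-stage disease search: build a gene profile, then query with it.

    The profile is the union of the genes of every set whose name matches
    ``term`` within the designated disease sources. Those sources are then
    excluded from the enrichment results (they defined the query, so
    testing them would be circular).
    """
    wanted = set(disease_sources)
    matches = [s for s in name_search(term, collections) if s.source in wanted]
    if not matches:
        raise EmptyProfileError(
            f"no gene set matching {term!r} in sources {sorted(wanted)}"
        )
    seen: set[str] = set()
    profile_syms: list[str] = []
    for s in matches:  # name_search order: scale desc, id asc — deterministic
        for g in sorted(s.genes):
            if g not in seen:
                seen.add(g)
                profile_syms.append(g)
    profile = QueryGeneList(symbols=tuple(profile_syms), label=f"profile:{term}")
    results = search_by_genes(
        profile,
        collections,
        min_hits=min_hits,
        p_threshold=p_threshold,
        universe_size=universe_size,
        exclude_sources=list(wanted),
    )
    return profile, results


def results_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            (
                r.set_id, r.name, r.source, r.organism, r.hits, r.set_scale,
                r.p_value, r.fdr, r.rank,
            )
            for r in results
        ],
        columns=[
            "set_id", "name", "source", "organism", "hits", "set_scale",
            "p_value", "fdr", "rank",
        ],
    )


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as CSV."""
    results_to_frame(results).to_csv(path, index=False)
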