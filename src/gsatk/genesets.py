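"""Core gene-set domain types and file I/O.

A *gene set* is a named, source-annotated group of official gene symbols —
a disease gene list, a pathway, an expression signature, a microRNA target
list, or a network module. Collections of gene sets are carried in the GMT
dialect (one set per tab-separated line: id, description, members) or in a
long membership table (one row per set/gene pair) that additionally carries
source and organism annotations, which GMT cannot.

Symbols are normalized on ingestion: whitespace-trimmed, uppercased,
empties dropped, duplicates collapsed keeping first occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "QueryGeneList",
    "GmtParseError",
    "EmptyCollectionError",
    "EmptyQueryError",
    "normalize_symbol",
    "normalize_symbols",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_membership_table",
    "write_membership_table",
    "read_symbol_map",
    "apply_symbol_map",
    "source_overlap_matrix",
    "name_search",
]


class GmtParseError(ValueError):
    """A GMT line could not be parsed (fewer than 3 tab-separated fields)."""


class EmptyCollectionError(ValueError):
    """No usable gene set could be read from the input."""


class EmptyQueryError(ValueError):
    """A query gene list contained no usable symbols."""


def normalize_symbol(symbol: str) -> str:
    """Trim and uppercase a gene symbol."""
    return symbol.strip().upper()


def normalize_symbols(symbols: Iterable[str]) -> list[str]:
    """Normalize symbols, dropping empties and duplicates, keeping first occurrence."""
    seen: set[str] = set()
    out: list[str] = []
    for raw in symbols:
        sym = normalize_symbol(raw)
        if sym and sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


@dataclass(frozen=True)
class GeneSet:
    """An identified set of unique, uppercase gene symbols.

    Parameters
    ----------
    set_id : unique opaque identifier within a collection.
    name : free-text label (searched by :func:`name_search`).
    source : data-source tag, e.g. ``"KEGG"`` or ``"user"``.
    organism : free-text organism label.
    genes : frozen set of normalized gene symbols; must be non-empty.
    """

    set_id: str
    name: str
    genes: frozenset[str]
    source: str = "user"
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        for g in self.genes:
            if not g or g != g.strip().upper():
                raise ValueError(
                    f"gene set {self.set_id!r}: symbol {g!r} is not normalized"
                )

    @property
    def scale(self) -> int:
        """Number of member gene symbols (the set's *scale*)."""
        return len(self.genes)

    @staticmethod
    def from_symbols(
        set_id: str,
        name: str,
        symbols: Iterable[str],
        source: str = "user",
        organism: str = "",
    ) -> "GeneSet":
        """Build a gene set from raw symbols, normalizing them first."""
        return GeneSet(
            set_id=set_id,
            name=name,
            genes=frozenset(normalize_symbols(symbols)),
            source=source,
            organism=organism,
        )


@dataclass
class GeneSetCollection:
    """An ordered list of gene sets plus the derived gene universe."""

    collection_id: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set_ids in collection: {dupes}")

    @property
    def universe(self) -> frozenset[str]:
        """Union of the member genes of all sets, recomputed on access."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


@dataclass(frozen=True)
class QueryGeneList:
    """An ordered, de-duplicated list of normalized query symbols."""

    symbols: tuple[str, ...]
    label: str = "query"

    def __post_init__(self) -> None:
        # Emptiness is rejected at the ingestion/search boundary, not here,
        # so that filters may legitimately produce an empty selection.
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"query {self.label!r} has duplicate symbols")

    @staticmethod
    def from_symbols(symbols: Iterable[str], label: str = "query") -> "QueryGeneList":
        norm = normalize_symbols(symbols)
        if not norm:
            raise EmptyQueryError(f"query {label!r} has no usable symbols")
        return QueryGeneList(symbols=tuple(norm), label=label)

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# File I/O


def read_gmt(
    path: str | Path,
    source: str = "user",
    organism: str = "",
    collection_id: str | None = None,
) -> GeneSetCollection:
    """Read a GMT file (one gene set per line: id TAB description TAB genes...).

    Genes are normalized; empty tokens are dropped; sets left empty after
    normalization are dropped with a warning. Raises
    :class:`GmtParseError` for a line with fewer than 3 fields and
    :class:`EmptyCollectionError` when no usable set remains.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    n_genes_read = 0
    n_dupes = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name = fields[0].strip(), fields[1].strip()
            raw_genes = fields[2:]
            n_genes_read += sum(1 for g in raw_genes if g.strip())
            genes = normalize_symbols(raw_genes)
            n_dupes += sum(1 for g in raw_genes if g.strip()) - len(genes)
            if not genes:
                logger.warning(
                    "%s: line %d: set %r empty after normalization, dropped",
                    path, lineno, set_id,
                )
                continue
            sets.append(
                GeneSet(set_id=set_id, name=name, genes=frozenset(genes),
                        source=source, organism=organism)
            )
    if not sets:
        raise EmptyCollectionError(f"{path}: no usable gene sets")
    coll = GeneSetCollection(collection_id=collection_id or path.stem, sets=sets)
    logger.info(
        "read %d sets, %d gene tokens (%d duplicates collapsed) from %s",
        len(sets), n_genes_read, n_dupes, path,
    )
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes sorted for byte-stable output."""
    path = Path(path)
    with path.open("w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def read_gene_list(path: str | Path, label: str | None = None) -> QueryGeneList:
    """Read a newline-delimited gene list (one symbol per line)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    return QueryGeneList.from_symbols(lines, label=label or path.stem)


_MEMBERSHIP_COLUMNS = ["set_id", "name", "source", "organism", "gene"]


def read_membership_table(
    path: str | Path, collection_id: str | None = None
) -> GeneSetCollection:
    """Read the long membership dialect: one row per (set, gene) pair.

    Tab- or comma-separated with header columns
    ``set_id, name, source, organism, gene``. Set order follows first
    appearance; per-set name/source/organism come from the first row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _MEMBERSHIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sets: list[GeneSet] = []
    for set_id, grp in df.groupby("set_id", sort=False):
        genes = normalize_symbols(grp["gene"].fillna(""))
        if not genes:
            logger.warning("%s: set %r empty after normalization, dropped", path, set_id)
            continue
        first = grp.iloc[0]
        sets.append(
            GeneSet(
                set_id=str(set_id),
                name=str(first["name"]),
                genes=frozenset(genes),
                source=str(first["source"]),
                organism="" if pd.isna(first["organism"]) else str(first["organism"]),
            )
        )
    if not sets:
        raise EmptyCollectionError(f"{path}: no usable gene sets")
    return GeneSetCollection(collection_id=collection_id or path.stem, sets=sets)


def write_membership_table(collection: GeneSetCollection, path: str | Path) -> None:
    rows = [
        (s.set_id, s.name, s.source, s.organism, g)
        for s in collection.sets
        for g in sorted(s.genes)
    ]
    pd.DataFrame(rows, columns=_MEMBERSHIP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_symbol_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (alias, official symbol) into a mapping."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        alias, official = normalize_symbol(fields[0]), normalize_symbol(fields[1])
        if alias and official:
            mapping[alias] = official
    return mapping


def apply_symbol_map(
    collection: GeneSetCollection, mapping: Mapping[str, str]
) -> GeneSetCollection:
    """Replace aliases by official symbols; unmapped symbols pass through.

    Post-mapping duplicates within a set collapse (e.g. an alias mapping
    onto a symbol the set already contains). The number of unmapped symbols
    is reported through the logging contract, never raised.
    """
    norm_map = {normalize_symbol(k): normalize_symbol(v) for k, v in mapping.items()}
    unmapped: set[str] = set()
    new_sets: list[GeneSet] = []
    for s in collection.sets:
        genes: set[str] = set()
        for g in s.genes:
            if g in norm_map:
                genes.add(norm_map[g])
            else:
                unmapped.add(g)
                genes.add(g)
        new_sets.append(
            GeneSet(set_id=s.set_id, name=s.name, genes=frozenset(genes),
                    source=s.source, organism=s.organism)
        )
    if norm_map:
        logger.info(
            "symbol mapping: %d distinct symbols passed through unmapped",
            len(unmapped),
        )
    return GeneSetCollection(collection_id=collection.collection_id, sets=new_sets)


# ---------------------------------------------------------------------------
# Collection-level statistics and search


def source_overlap_matrix(collections: Sequence[GeneSetCollection]) -> pd.DataFrame:
    """Pairwise gene-overlap counts between collection universes.

    The diagonal holds each collection's universe size; off-diagonal cell
    (i, j) holds ``|universe_i ∩ universe_j|``. Symmetric by construction.
    """
    if not collections:
        raise ValueError("at least one collection required")
    ids = [c.collection_id for c in collections]
    universes = [c.universe for c in collections]
    n = len(collections)
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        mat[i][i] = len(universes[i])
        for j in range(i + 1, n):
            ov = len(universes[i] & universes[j])
            mat[i][j] = mat[j][i] = ov
    return pd.DataFrame(mat, index=ids, columns=ids)


def name_search(
    term: str, collections: Sequence[GeneSetCollection]
) -> list[GeneSet]:
    """Case-insensitive substring search over gene-set names.

    Results are ordered by decreasing scale, ties broken by set_id.
    """
    if not term or not term.strip():
        raise ValueError("search term must be non-empty")
    needle = term.strip().lower()
    hits = [
        s
        for coll in collections
        for s in coll.sets
        if needle in s.name.lower()
    ]
    hits.sort(key=lambda s: (-s.scale, s.set_id))
    return hits
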