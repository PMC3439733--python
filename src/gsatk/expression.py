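"""Differential gene-set expression from per-gene fold changes.

A gene set's differential expression statistic, NORM_ABS_FC, is a modified
p-norm of the absolute fold changes of its *available* genes (those present
in the expression table):

.. math::

    \\mathrm{NORM\\_ABS\\_FC}
        = \\Big( \\tfrac{1}{n} \\sum_{i=1}^{n} x_i^{\\,p} \\Big)^{1/p},
        \\qquad x_i = |\\mathrm{FC}_i|

The 1/n inside the root makes the statistic a generalized (power) mean, so
it is bounded by min(x) and max(x), equals the arithmetic mean at p = 1,
and approaches max(x) as p grows. The default p = 6 accentuates the most
differential genes in a set without collapsing onto the single maximum.

Fold changes are consumed as given; a flag allows interpreting the column
as log2 fold changes (|log2FC|) instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet, QueryGeneList, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "NormParams",
    "read_expression",
    "norm_abs_fc",
    "top_differential_genes",
    "prioritize_sets",
]

DEFAULT_NORM_P = 6.0


@dataclass(frozen=True)
class NormParams:
    """Order of the power mean; p >= 1, default 6."""

    p: float = DEFAULT_NORM_P

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"norm order p must be >= 1, got {self.p}")


class ExpressionTable:
    """Per-gene fold change table: one row per symbol, with |FC| and optional p.

    Wraps a DataFrame indexed by normalized gene symbol with columns
    ``fc``, ``abs_fc`` and optionally ``p_value``.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise ValueError("expression table is empty")
        if frame.index.has_duplicates:
            raise ValueError("expression table has duplicate gene symbols")
        if "fc" not in frame.columns:
            raise ValueError("expression table needs an 'fc' column")
        frame = frame.copy()
        frame["abs_fc"] = frame["fc"].abs()
        self.frame = frame

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    @property
    def has_pvalues(self) -> bool:
        return "p_value" in self.frame.columns

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def from_records(
        records: Sequence[tuple], with_pvalues: bool = True
    ) -> "ExpressionTable":
        """Build from (gene, fc[, p_value]) tuples, applying the max-|FC| dedupe rule."""
        cols = ["gene", "fc"] + (["p_value"] if with_pvalues else [])
        df = pd.DataFrame(records, columns=cols)
        return _finalize_expression(df)

    def write(self, path: str | Path) -> None:
        out = self.frame.reset_index(names="gene")
        out.to_csv(path, sep="\t", index=False)


def _finalize_expression(df: pd.DataFrame) -> ExpressionTable:
    """Normalize symbols, drop NA fold changes, collapse duplicates by max |FC|."""
    df = df.copy()
    df["gene"] = df["gene"].astype(str).map(normalize_symbol)
    df = df[df["gene"] != ""]
    n_na = int(df["fc"].isna().sum())
    if n_na:
        logger.warning("dropped %d rows with missing fold change", n_na)
        df = df.dropna(subset=["fc"])
    if df.empty:
        raise ValueError("no usable expression rows")
    df["abs_fc"] = df["fc"].abs()
    # Duplicate symbols (e.g. several probes for one gene): keep max |FC|.
    df = df.sort_values(["abs_fc", "gene"], kind="mergesort")
    df = df.drop_duplicates(subset="gene", keep="last")
    df = df.sort_values("gene", kind="mergesort").set_index("gene")
    return ExpressionTable(df[[c for c in ("fc", "p_value") if c in df.columns]])


def read_expression(
    path: str | Path,
    gene_col: str = "gene",
    fc_col: str = "fc",
    p_col: str | None = "p_value",
    log2: bool = False,
) -> ExpressionTable:
    """Read a delimited fold-change table (TSV or CSV, sniffed).

    Duplicate gene symbols keep the row with maximal |FC| — the rule used
    when several probes map to one gene. Rows with missing fold change are
    dropped with a warning. ``log2=True`` converts log2 ratios back to
    linear fold changes (2**|log2FC| with the original sign) before |FC|.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in [gene_col, fc_col] + ([p_col] if p_col else []):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = pd.DataFrame({"gene": df[gene_col]})
    fc = pd.to_numeric(df[fc_col], errors="coerce")
    if log2:
        fc = np.sign(fc) * np.power(2.0, fc.abs())
    out["fc"] = fc
    if p_col:
        out["p_value"] = pd.to_numeric(df[p_col], errors="coerce")
    return _finalize_expression(out)


def norm_abs_fc(
    gene_set: GeneSet,
    expr: ExpressionTable,
    params: NormParams | None = None,
) -> float | None:
    """Power-mean of |FC| over the set's measured genes; None when none measured.

    Stabilized by factoring out the maximum before exponentiation so large
    fold changes at p = 6 do not overflow.
    """
    params = params or NormParams()
    avail = sorted(gene_set.genes & expr.genes)
    if not avail:
        return None
    x = expr.frame.loc[avail, "abs_fc"].to_numpy(dtype=float)
    m = float(x.max())
    if m == 0.0:
        return 0.0
    return m * float(np.mean((x / m) ** params.p) ** (1.0 / params.p))


def top_differential_genes(
    expr: ExpressionTable,
    n: int = 100,
    p_threshold: float = 0.05,
) -> QueryGeneList:
    """Top-n genes by |FC| among those significant at the p threshold.

    Ties in |FC| break by symbol. Fewer than n survivors (including zero)
    returns all of them with a warning.
    """
    if not expr.has_pvalues:
        raise ValueError("expression table has no p_value column")
    df = expr.frame
    surv = df[df["p_value"] < p_threshold]
    if len(surv) < n:
        logger.warning(
            "only %d genes pass p < %g (requested %d)", len(surv), p_threshold, n
        )
    # index is the gene symbol; sort by (-abs_fc, symbol)
    order = sorted(
        surv.index, key=lambda g: (-float(surv.loc[g, "abs_fc"]), g)
    )
    chosen = order[:n]
    return QueryGeneList(symbols=tuple(chosen), label=f"top{n}_abs_fc")


def prioritize_sets(
    sets: Sequence[GeneSet],
    expr: ExpressionTable,
    params: NormParams | None = None,
) -> pd.DataFrame:
    """Rank gene sets by NORM_ABS_FC, undefined scores last.

    Returns a DataFrame with columns (set_id, name, scale, source,
    norm_abs_fc, rank); norm_abs_fc is NaN for sets with no measured genes,
    which sort after all defined scores. Ties break by set_id.
    """
    if not sets:
        raise ValueError("at least one gene set required")
    params = params or NormParams()
    rows = []
    for s in sets:
        score = norm_abs_fc(s, expr, params)
        rows.append((s.set_id, s.name, s.scale, s.source,
                     np.nan if score is None else score))
    df = pd.DataFrame(
        rows, columns=["set_id", "name", "scale", "source", "norm_abs_fc"]
    )
    df["_defined"] = df["norm_abs_fc"].notna()
    df = df.sort_values(
        ["_defined", "norm_abs_fc", "set_id"],
        ascending=[False, False, True],
        kind="mergesort",
        na_position="last",
    ).drop(columns="_defined")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
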