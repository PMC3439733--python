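"""Gene-set similarity scoring and all-pairs association computation.

The similarity of two gene sets :math:`P_i, P_j` is a weighted blend of the
Jaccard coefficient and the cover (overlap) coefficient:

.. math::

    S_{i,j} = \\alpha \\, S_L + (1 - \\alpha) \\, S_R
            = \\alpha \\frac{|P_i \\cap P_j|}{|P_i \\cup P_j|}
            + (1 - \\alpha) \\frac{|P_i \\cap P_j|}{\\min(|P_i|, |P_j|)}

with weight :math:`\\alpha \\in [0, 1]` (default 0.8). The cover term makes
the score high when a large set contains a small one, which plain Jaccard
penalizes. Since ``min(|P_i|,|P_j|) <= |P_i ∪ P_j|`` we always have
``S_L <= S_R``, so the blended score is non-increasing in alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "SimilarityParams",
    "SimilarityEdge",
    "similarity",
    "pairwise_similarity",
    "overlapping_pairs",
    "alpha_sensitivity",
    "AlphaScanResult",
    "write_edges",
    "similarity_matrix",
]

DEFAULT_ALPHA = 0.8
DEFAULT_MIN_SCORE = 0.1


@dataclass(frozen=True)
class SimilarityParams:
    """Weight coefficient for blending Jaccard and cover terms."""

    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class SimilarityEdge:
    """A scored, undirected association between two gene sets."""

    set_i: str
    set_j: str
    overlap: int
    union_size: int
    s_l: float
    s_r: float
    score: float


def _edge(
    id_a: str, size_a: int, id_b: str, size_b: int, overlap: int, alpha: float
) -> SimilarityEdge:
    union = size_a + size_b - overlap
    s_l = overlap / union
    s_r = overlap / min(size_a, size_b)
    return SimilarityEdge(
        set_i=id_a,
        set_j=id_b,
        overlap=overlap,
        union_size=union,
        s_l=s_l,
        s_r=s_r,
        score=alpha * s_l + (1.0 - alpha) * s_r,
    )


def similarity(
    set_a: GeneSet, set_b: GeneSet, params: SimilarityParams | None = None
) -> SimilarityEdge:
    """Score a single pair of distinct gene sets.

    Raises ``ValueError`` when the two ids coincide: the score is defined
    only for distinct sets (i != j).
    """
    params = params or SimilarityParams()
    if set_a.set_id == set_b.set_id:
        raise ValueError(f"similarity undefined for identical ids ({set_a.set_id!r})")
    overlap = len(set_a.genes & set_b.genes)
    return _edge(set_a.set_id, set_a.scale, set_b.set_id, set_b.scale,
                 overlap, params.alpha)


def overlapping_pairs(sets: Sequence[GeneSet]) -> list[tuple[int, int, int]]:
    """All unordered index pairs with at least one shared gene.

    Uses an inverted gene→set index so that memory stays proportional to
    the number of overlapping pairs, not to n².
    """
    index: dict[str, list[int]] = {}
    for i, s in enumerate(sets):
        for g in s.genes:
            index.setdefault(g, []).append(i)
    out: list[tuple[int, int, int]] = []
    for i, s in enumerate(sets):
        counts: dict[int, int] = {}
        for g in s.genes:
            for j in index[g]:
                if j > i:
                    counts[j] = counts.get(j, 0) + 1
        for j, ov in counts.items():
            out.append((i, j, ov))
    return out


def pairwise_similarity(
    collection: GeneSetCollection | Sequence[GeneSet],
    params: SimilarityParams | None = None,
    min_score: float = 0.0,
) -> list[SimilarityEdge]:
    """Every unordered pair with overlap >= 1 and score >= min_score.

    Zero-overlap pairs are never emitted: an association requires shared
    genes. Output is deterministically ordered by (set_i, set_j) ids, each
    edge oriented with the lexicographically smaller id first.
    """
    params = params or SimilarityParams()
    sets = list(collection)
    if len(sets) < 2:
        raise ValueError("pairwise similarity requires at least 2 sets")
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    edges: list[SimilarityEdge] = []
    for i, j, ov in overlapping_pairs(sets):
        a, b = sets[i], sets[j]
        if a.set_id > b.set_id:
            a, b = b, a
        e = _edge(a.set_id, a.scale, b.set_id, b.scale, ov, params.alpha)
        if e.score >= min_score:
            edges.append(e)
    edges.sort(key=lambda e: (e.set_i, e.set_j))
    return edges


@dataclass
class AlphaScanResult:
    """Histogram and moment summary of pairwise scores across alpha values."""

    histogram: pd.DataFrame  # columns: alpha, bin_low, bin_high, count
    summary: pd.DataFrame  # columns: alpha, n_pairs, mean, skewness

    def write(self, path: str | Path) -> None:
        self.histogram.to_csv(path, sep="\t", index=False)


def alpha_sensitivity(
    collection: GeneSetCollection | Sequence[GeneSet],
    alphas: Sequence[float],
    bins: int = 20,
) -> AlphaScanResult:
    """Distribution of all pairwise scores (overlap >= 1) per alpha value.

    For each alpha the scores of every overlapping pair are histogrammed
    over [0, 1] with the stated bin count, and sample skewness is reported.
    Small alpha weights the cover term and inflates scores (right-shifted
    mass); large alpha weights Jaccard and deflates them.
    """
    if not alphas:
        raise ValueError("alphas must be non-empty")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    sets = list(collection)
    if len(sets) < 2:
        raise ValueError("alpha scan requires at least 2 sets")
    pairs = overlapping_pairs(sets)
    s_l = np.array([ov / (sets[i].scale + sets[j].scale - ov) for i, j, ov in pairs])
    s_r = np.array([ov / min(sets[i].scale, sets[j].scale) for i, j, ov in pairs])
    edges_grid = np.linspace(0.0, 1.0, bins + 1)
    hist_rows = []
    summary_rows = []
    for alpha in alphas:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        scores = alpha * s_l + (1.0 - alpha) * s_r
        counts, _ = np.histogram(scores, bins=edges_grid)
        for lo, hi, c in zip(edges_grid[:-1], edges_grid[1:], counts):
            hist_rows.append((alpha, lo, hi, int(c)))
        skew = float(stats.skew(scores)) if scores.size > 2 else float("nan")
        summary_rows.append((alpha, scores.size, float(scores.mean()), skew))
    return AlphaScanResult(
        histogram=pd.DataFrame(
            hist_rows, columns=["alpha", "bin_low", "bin_high", "count"]
        ),
        summary=pd.DataFrame(
            summary_rows, columns=["alpha", "n_pairs", "mean", "skewness"]
        ),
    )


def write_edges(edges: Sequence[SimilarityEdge], path: str | Path) -> None:
    """Write an edge list as TSV (set_i, set_j, overlap, union_size, s_l, s_r, score)."""
    df = pd.DataFrame(
        [
            (e.set_i, e.set_j, e.overlap, e.union_size, e.s_l, e.s_r, e.score)
            for e in edges
        ],
        columns=["set_i", "set_j", "overlap", "union_size", "s_l", "s_r", "score"],
    )
    df.to_csv(path, sep="\t", index=False)


def similarity_matrix(
    collection: GeneSetCollection | Sequence[GeneSet],
    params: SimilarityParams | None = None,
) -> pd.DataFrame:
    """Dense square score matrix for small collections (heat-map export).

    Diagonal is 1 by convention; zero-overlap pairs score 0.
    """
    params = params or SimilarityParams()
    sets = list(collection)
    ids = [s.set_id for s in sets]
    n = len(sets)
    mat = np.eye(n)
    for i, j, ov in overlapping_pairs(sets):
        e = _edge(sets[i].set_id, sets[i].scale, sets[j].set_id, sets[j].scale,
                  ov, params.alpha)
        mat[i, j] = mat[j, i] = e.score
    return pd.DataFrame(mat, index=ids, columns=ids)
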