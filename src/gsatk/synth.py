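"""Seeded synthetic gene-set collections and expression tables.

Real gene-set databases are snapshots of many curated sources and cannot be
redistributed, so every downstream analysis here is exercised on synthetic
collections with controlled structure:

* **scales** are drawn from a truncated discrete power law, mimicking the
  many-small/few-large regime of integrated gene-set databases;
* **membership** follows one of three overlap models — ``independent``
  (uniform sampling, overlap governed by chance), ``nested-chain`` (each
  set a superset of the previous, maximizing cover-coefficient structure),
  or ``block-community`` (sets within a block share a planted core);
* **expression** gives every universe gene a log-normal |FC| (median 1.2,
  σ chosen so roughly 5% of genes exceed |FC| = 2 — a typical microarray
  fold-change marginal) with a random sign and a uniform p-value, while
  genes of designated *target* sets get |FC| multiplied by an effect size
  and p-values below 0.05 — a planted differential signal whose recovery
  downstream is checkable by construction.

All randomness flows from the spec's single integer seed through named
sub-streams, and every sampling step operates on sorted sequences, so a
given spec reproduces byte-identical outputs across platforms and
processes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import ExpressionTable
from .genesets import GeneSet, GeneSetCollection, QueryGeneList, write_gmt

__all__ = [
    "ScaleLaw",
    "SignalSpec",
    "SynthSpec",
    "generate_collection",
    "generate_expression",
    "generate_query",
    "write_fixtures",
]

# σ such that P(|FC| > 2) ≈ 0.05 for median-1.2 log-normal background:
# (ln 2 − ln 1.2) / z_0.95
_BACKGROUND_SIGMA = (math.log(2.0) - math.log(1.2)) / 1.6448536269514722


@dataclass(frozen=True)
class ScaleLaw:
    """Truncated discrete power law for gene-set scales: P(s) ∝ s^(−exponent)."""

    exponent: float = 2.0
    min_scale: int = 5
    max_scale: int = 500

    def __post_init__(self) -> None:
        if self.min_scale < 1 or self.max_scale < self.min_scale:
            raise ValueError("require 1 <= min_scale <= max_scale")


@dataclass(frozen=True)
class SignalSpec:
    """Planted differential signal for target gene sets."""

    target_ids: tuple[str, ...] = ()
    effect_size: float = 3.0
    background_median: float = 1.2
    background_sigma: float = _BACKGROUND_SIGMA
    target_p_max: float = 0.05


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    universe_size: int = 1000
    n_sets: int = 200
    scale_law: ScaleLaw = field(default_factory=ScaleLaw)
    overlap_model: str = "independent"  # independent | nested-chain | block-community
    n_blocks: int = 10  # block-community only
    core_fraction: float = 0.5  # block-community: share of min_scale planted as core
    signal: SignalSpec = field(default_factory=SignalSpec)

    def __post_init__(self) -> None:
        if self.scale_law.max_scale > self.universe_size:
            raise ValueError(
                f"max_scale {self.scale_law.max_scale} exceeds universe "
                f"{self.universe_size}"
            )
        if self.overlap_model not in (
            "independent", "nested-chain", "block-community"
        ):
            raise ValueError(f"unknown overlap model {self.overlap_model!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "SynthSpec":
        d = json.loads(text)
        d["scale_law"] = ScaleLaw(**d["scale_law"])
        sig = d["signal"]
        sig["target_ids"] = tuple(sig["target_ids"])
        d["signal"] = SignalSpec(**sig)
        return SynthSpec(**d)


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), stream])


def _symbols(universe_size: int) -> list[str]:
    return [f"G{i:06d}" for i in range(universe_size)]


def _draw_scales(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.scale_law
    support = np.arange(law.min_scale, law.max_scale + 1)
    probs = support.astype(float) ** (-law.exponent)
    probs /= probs.sum()
    return rng.choice(support, size=spec.n_sets, p=probs)


def generate_collection(spec: SynthSpec) -> GeneSetCollection:
    """Generate ``n_sets`` synthetic gene sets over a synthetic universe."""
    rng = _rng(spec, 0)
    universe = _symbols(spec.universe_size)
    scales = _draw_scales(spec, rng)
    sets: list[GeneSet] = []

    if spec.overlap_model == "independent":
        for i, scale in enumerate(scales):
            idx = rng.choice(spec.universe_size, size=int(scale), replace=False)
            sets.append(_make_set(i, [universe[k] for k in sorted(idx)]))

    elif spec.overlap_model == "nested-chain":
        scales = np.sort(scales)
        current: list[int] = []
        remaining = list(range(spec.universe_size))
        for i, scale in enumerate(scales):
            need = int(scale) - len(current)
            if need > 0:
                pick = rng.choice(len(remaining), size=need, replace=False)
                chosen = [remaining[k] for k in sorted(pick)]
                current = sorted(current + chosen)
                keep = set(chosen)
                remaining = [r for r in remaining if r not in keep]
            sets.append(_make_set(i, [universe[k] for k in current]))

    else:  # block-community
        core_size = max(1, int(spec.core_fraction * spec.scale_law.min_scale))
        cores: list[list[int]] = []
        for _ in range(spec.n_blocks):
            idx = rng.choice(spec.universe_size, size=core_size, replace=False)
            cores.append(sorted(int(k) for k in idx))
        for i, scale in enumerate(scales):
            core = cores[i % spec.n_blocks]
            pool = [k for k in range(spec.universe_size) if k not in set(core)]
            fill_n = max(0, int(scale) - len(core))
            pick = rng.choice(len(pool), size=fill_n, replace=False)
            members = sorted(core + [pool[k] for k in pick])
            sets.append(
                _make_set(i, [universe[k] for k in members],
                          block=i % spec.n_blocks)
            )

    return GeneSetCollection(collection_id=f"synth_seed{spec.seed}", sets=sets)


def _make_set(i: int, genes: list[str], block: int | None = None) -> GeneSet:
    name = f"Synthetic set {i}" + (f" (block {block})" if block is not None else "")
    return GeneSet(
        set_id=f"SET{i:04d}", name=name, genes=frozenset(genes), source="synth"
    )


def generate_expression(
    spec: SynthSpec, collection: GeneSetCollection
) -> ExpressionTable:
    """Per-gene fold-change table for the whole universe, with planted signal."""
    targets = set(spec.signal.target_ids)
    known = {s.set_id for s in collection}
    unknown = targets - known
    if unknown:
        raise ValueError(f"unknown target set ids: {sorted(unknown)}")
    target_genes: set[str] = set()
    for s in collection:
        if s.set_id in targets:
            target_genes |= s.genes

    rng = _rng(spec, 1)
    genes = _symbols(spec.universe_size)
    sig = spec.signal
    abs_fc = np.exp(
        rng.normal(math.log(sig.background_median), sig.background_sigma,
                   size=len(genes))
    )
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    pvals = rng.uniform(0.0, 1.0, size=len(genes))
    target_p = rng.uniform(0.0, sig.target_p_max, size=len(genes))
    records = []
    for k, g in enumerate(genes):
        if g in target_genes:
            fc = signs[k] * abs_fc[k] * sig.effect_size
            p = target_p[k]
        else:
            fc = signs[k] * abs_fc[k]
            p = pvals[k]
        records.append((g, float(fc), float(p)))
    return ExpressionTable.from_records(records)


def generate_query(
    spec: SynthSpec,
    collection: GeneSetCollection,
    target: str,
    k_inside: int,
    k_outside: int,
) -> QueryGeneList:
    """k_inside genes from the target set plus k_outside from outside it."""
    tset = collection.get(target)
    inside_pool = sorted(tset.genes)
    outside_pool = sorted(set(_symbols(spec.universe_size)) - tset.genes)
    if k_inside > len(inside_pool):
        raise ValueError(
            f"k_inside={k_inside} exceeds target scale {len(inside_pool)}"
        )
    if k_outside > len(outside_pool):
        raise ValueError(
            f"k_outside={k_outside} exceeds outside pool {len(outside_pool)}"
        )
    rng = _rng(spec, 2)
    picks: list[str] = []
    if k_inside:
        idx = rng.choice(len(inside_pool), size=k_inside, replace=False)
        picks += [inside_pool[i] for i in sorted(idx)]
    if k_outside:
        idx = rng.choice(len(outside_pool), size=k_outside, replace=False)
        picks += [outside_pool[i] for i in sorted(idx)]
    return QueryGeneList(symbols=tuple(picks), label=f"query_{target}")


def write_fixtures(spec: SynthSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a spec as re-readable fixture files (GMT, TSV, JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coll = generate_collection(spec)
    expr = generate_expression(spec, coll)
    paths = {
        "spec": out / "synth_spec.json",
        "gmt": out / "collection.gmt",
        "expression": out / "expression.tsv",
    }
    paths["spec"].write_text(spec.to_json() + "\n")
    write_gmt(coll, paths["gmt"])
    expr.write(paths["expression"])
    return paths
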