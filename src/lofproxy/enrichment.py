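"""Preranked gene-set enrichment (weighted KS running sum) and ORA.

The enrichment score walks the ranked list: set members ("hits") increment
the running sum by their weighted score share, non-members decrement by
1/(N-K).  ES is the extremum of the running sum (sign retained).
Significance comes from a gene-sampling permutation null: random same-size
sets drawn from the ranked universe.  Over-representation analysis uses
the upper-tail hypergeometric distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corr import adjust_by
from .dataio import ExpressionMatrix
from .stratify import StrataAssignment

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "ORAResult",
    "read_gmt",
    "write_gmt",
    "rank_by_contrast",
    "rank_by_log2fc",
    "gsea_es",
    "gsea_pvalue",
    "gsea_collection",
    "ora_test",
    "write_enrichment",
    "write_ora",
]

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500


# --------------------------------------------------------------------------
# GMT format
# --------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT collection: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected name, description, members")
            name = parts[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na") if descriptions else "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


# --------------------------------------------------------------------------
# Ranked lists
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedList:
    """Genes ordered descending by a signed score (log2FC of group means)."""

    genes: tuple[str, ...]
    scores: np.ndarray  # aligned with genes, non-increasing
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float], label: str = "") -> "RankedList":
        # descending score, ties broken by gene id for determinism
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            genes=tuple(g for g, _ in items),
            scores=np.array([s for _, s in items], dtype=float),
            label=label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores}, index=pd.Index(self.genes, name="gene")
        )


def rank_by_contrast(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    label: str = "",
) -> RankedList:
    """Score each gene by mean(group A) - mean(group B), descending."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both contrast groups must be non-empty")
    mean_a = matrix.values.loc[list(group_a)].mean(axis=0)
    mean_b = matrix.values.loc[list(group_b)].mean(axis=0)
    return RankedList.from_scores((mean_a - mean_b).to_dict(), label=label)


def rank_by_log2fc(matrix: ExpressionMatrix, strata: StrataAssignment) -> RankedList:
    """LOW-minus-HIGH log2 fold-change ranking over stratum means."""
    low, high = strata.low_samples, strata.high_samples
    if not low or not high:
        raise ValueError("empty stratum: cannot rank LOW - HIGH contrast")
    return rank_by_contrast(matrix, low, high, label="LOW-HIGH")


# --------------------------------------------------------------------------
# GSEA
# --------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    p_adj: float
    leading_edge: list[str] = field(default_factory=list)
    set_size: int = 0


def _hit_increments(scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float) -> np.ndarray:
    w = np.abs(scores[hit_mask]) ** weight_exponent
    total = w.sum()
    if total == 0:
        # all hit scores are zero: degrade gracefully to equal weights
        return np.full(hit_mask.sum(), 1.0 / hit_mask.sum())
    return w / total


def gsea_es(
    ranked: RankedList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[str]]:
    """Enrichment score and leading edge for one gene set.

    ES is the running-sum value of maximum magnitude (first occurrence on
    magnitude ties).  The leading edge holds set members at or before the
    extremum for positive ES, and at or after it for negative ES.
    """
    members = set(gene_set)
    n = len(ranked)
    hit_mask = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if k == n:
        raise ValueError("gene set covers the whole ranked universe")
    steps = np.full(n, -1.0 / (n - k))
    steps[hit_mask] = _hit_increments(ranked.scores, hit_mask, weight_exponent)
    running = np.cumsum(steps)
    i_star = int(np.argmax(np.abs(running)))
    es = float(np.clip(running[i_star], -1.0, 1.0))  # absorb cumsum float drift
    if es >= 0:
        edge_idx = np.nonzero(hit_mask[: i_star + 1])[0]
    else:
        edge_idx = np.nonzero(hit_mask[i_star:])[0] + i_star
    leading_edge = [ranked.genes[i] for i in edge_idx]
    return es, leading_edge


def _null_es(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """Vectorized null ES for random same-size sets from the universe."""
    n = scores.size
    # random K-subsets via argpartition of uniform keys (one row per perm)
    keys = rng.random((n_perm, n))
    hit_idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    steps = np.full((n_perm, n), -1.0 / (n - set_size))
    wvals = np.abs(scores) ** weight_exponent
    hw = wvals[hit_idx]
    totals = hw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(totals > 0, hw / totals, 1.0 / set_size)
    rows = np.repeat(np.arange(n_perm), set_size)
    steps[rows, hit_idx.ravel()] = weights.ravel()
    running = np.cumsum(steps, axis=1)
    extremum = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), extremum]


def gsea_pvalue(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    name: str = "",
) -> EnrichmentResult:
    """Permutation p-value and NES for one gene set (gene-sampling null).

    p uses the plus-one estimator over same-sign null draws; NES divides
    ES by the mean |null ES| of matching sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = [g for g in gene_set if g in set(ranked.genes)]
    es, leading_edge = gsea_es(ranked, members, weight_exponent)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.scores, len(members), n_perm, rng, weight_exponent)
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        warnings.warn(
            f"degenerate permutation null for set {name or 'unnamed'!r}: "
            "all null ES of opposite sign",
            stacklevel=2,
        )
        p = 1.0 / (1.0 + n_perm)
        nes = np.sign(es) * np.inf if es != 0 else 0.0
    else:
        exceed = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1.0 + exceed) / (1.0 + n_same)
        mean_mag = float(np.abs(null[same_sign]).mean())
        nes = es / mean_mag if mean_mag > 0 else 0.0
    return EnrichmentResult(
        name=name,
        es=es,
        nes=float(nes),
        p=float(p),
        p_adj=float("nan"),
        leading_edge=leading_edge,
        set_size=len(members),
    )


def gsea_collection(
    ranked: RankedList,
    collection: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[EnrichmentResult]:
    """Score every set in a collection; BY-adjust p across scored sets."""
    universe = set(ranked.genes)
    results: list[EnrichmentResult] = []
    rng = np.random.default_rng(seed)
    for name, members in collection.items():
        overlap = sorted(universe.intersection(members))
        if not (min_size <= len(overlap) <= max_size) or len(overlap) == len(universe):
            continue
        sub_seed = int(rng.integers(0, 2**32))
        results.append(
            gsea_pvalue(
                ranked,
                overlap,
                n_perm=n_perm,
                seed=sub_seed,
                weight_exponent=weight_exponent,
                name=name,
            )
        )
    if results:
        adjusted = adjust_by([r.p for r in results])
        results = [replace(r, p_adj=float(a)) for r, a in zip(results, adjusted)]
    return results


# --------------------------------------------------------------------------
# ORA
# --------------------------------------------------------------------------

@dataclass
class ORAResult:
    name: str
    k: int  # overlap of hits with the set
    K: int  # set size within the universe
    n: int  # hit-list size
    N: int  # universe size
    p: float
    p_adj: float
    ratio: float  # k*N / (n*K)


def ora_test(
    hits: Iterable[str],
    universe: Iterable[str],
    collection: Mapping[str, Sequence[str]],
) -> list[ORAResult]:
    """Upper-tail hypergeometric over-representation per set, BY across sets."""
    hit_set = set(hits)
    uni = set(universe)
    offenders = sorted(hit_set - uni)
    if offenders:
        raise ValueError(f"hits not contained in universe: {offenders[:10]}")
    n = len(hit_set)
    N = len(uni)
    results: list[ORAResult] = []
    for name, members in collection.items():
        in_universe = uni.intersection(members)
        K = len(in_universe)
        if K == 0:
            continue
        k = len(hit_set & in_universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        ratio = (k * N) / (n * K) if n > 0 else float("nan")
        results.append(ORAResult(name, k, K, n, N, p, float("nan"), ratio))
    if results:
        adjusted = adjust_by([r.p for r in results])
        for r, a in zip(results, adjusted):
            r.p_adj = float(a)
    return results


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "set": r.name,
                "es": r.es,
                "nes": r.nes,
                "p": r.p,
                "p_adj": r.p_adj,
                "set_size": r.set_size,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ora(results: Sequence[ORAResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "set": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
                "enrichment_ratio": r.ratio,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
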