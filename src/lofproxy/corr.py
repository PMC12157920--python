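"""Genome-wide Pearson correlation screen against a focal gene.

Correlations are two-sided Pearson product-moment tests with p-values from
the t distribution on n-2 degrees of freedom; multiple testing is handled
with the Benjamini-Yekutieli step-up, which is valid under arbitrary
dependence between genes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix

__all__ = [
    "correlate_focal",
    "adjust_by",
    "screen_significant",
    "panel_sign_summary",
    "pairwise_independence",
    "write_correlations",
]

FLAG_OK = ""
FLAG_FOCAL = "focal"
FLAG_ZERO_VARIANCE = "zero_variance"

_TINY_P = np.finfo(float).tiny


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df; clamped to (0, 1]."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return np.clip(p, _TINY_P, 1.0)


def correlate_focal(
    matrix: ExpressionMatrix,
    focal: str,
    targets: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Correlate every target gene with the focal profile.

    Returns a DataFrame indexed by gene with columns ``r``, ``n``, ``p``,
    ``p_adj`` and ``flag``.  Zero-variance genes get NaN statistics and are
    excluded from the BY adjustment (so m counts testable genes only); the
    focal gene itself is reported (r = 1) but flagged and likewise excluded
    from adjustment.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError("insufficient samples for correlation (need n >= 4)")
    genes = list(targets) if targets is not None else matrix.genes
    missing = [g for g in genes if g not in matrix.values.columns]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:10]}")
    x = matrix.gene(focal).to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"focal gene {focal!r} has zero variance")
    ymat = matrix.values[genes].to_numpy(dtype=float)

    xc = x - x.mean()
    yc = ymat - ymat.mean(axis=0, keepdims=True)
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    zero_var = sy == 0
    r[zero_var] = np.nan

    p = np.full(len(genes), np.nan)
    ok = ~zero_var
    p[ok] = _pearson_p(r[ok], n)

    flags = np.full(len(genes), FLAG_OK, dtype=object)
    flags[zero_var] = FLAG_ZERO_VARIANCE
    is_focal = np.array([g == focal for g in genes])
    flags[is_focal & ~zero_var] = FLAG_FOCAL

    p_adj = np.full(len(genes), np.nan)
    adjustable = ok & ~is_focal
    if adjustable.any():
        p_adj[adjustable] = adjust_by(p[adjustable])

    return pd.DataFrame(
        {"r": r, "n": n, "p": p, "p_adj": p_adj, "flag": flags},
        index=pd.Index(genes, name="gene"),
    )


def adjust_by(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment, input order preserved.

    With p sorted ascending, p_adj(i) = min_{j>=i} min(1, m*c(m)*p(j)/j)
    where c(m) is the m-th harmonic number.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def screen_significant(
    records: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = False
) -> tuple[list[str], int]:
    """Genes passing the significance threshold (raw p by default)."""
    if records.empty:
        raise ValueError("no correlation records to screen")
    col = "p_adj" if use_adjusted else "p"
    mask = (records[col] < alpha) & (records["flag"] == FLAG_OK)
    genes = records.index[mask].tolist()
    return genes, len(genes)


def panel_sign_summary(
    records: pd.DataFrame, panel: Iterable[str]
) -> tuple[int, int, int]:
    """(n_negative, n_positive, n_missing) correlation signs over a gene panel."""
    n_neg = n_pos = n_missing = 0
    for gene in panel:
        if gene not in records.index or not np.isfinite(records.loc[gene, "r"]):
            n_missing += 1
        elif records.loc[gene, "r"] < 0:
            n_neg += 1
        else:
            n_pos += 1
    return n_neg, n_pos, n_missing


def pairwise_independence(
    matrix: ExpressionMatrix, gene_a: str, gene_b: str
) -> pd.Series:
    """Single-pair Pearson correlation record (r, n, p)."""
    n = matrix.n_samples
    if n < 4:
        raise ValueError("insufficient samples for correlation (need n >= 4)")
    a = matrix.gene(gene_a).to_numpy(dtype=float)
    b = matrix.gene(gene_b).to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return pd.Series(
            {"r": np.nan, "n": n, "p": np.nan, "flag": FLAG_ZERO_VARIANCE},
            name=f"{gene_a}~{gene_b}",
        )
    res = stats.pearsonr(a, b)
    p = max(float(res.pvalue), _TINY_P)
    return pd.Series(
        {"r": float(res.statistic), "n": n, "p": p, "flag": FLAG_OK},
        name=f"{gene_a}~{gene_b}",
    )


def write_correlations(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
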