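"""Transcription-factor correlation-shift analysis.

For each TF we compute its Pearson correlation against a pathway-average
expression profile separately within the HIGH and LOW strata.  The shift
delta_r = r_low - r_high is tested with the Fisher z two-sample comparison
of independent correlations; a strain-resampling bootstrap is available as
a sensitivity check.  TF differential expression between groups uses
Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corr import adjust_by
from .dataio import ExpressionMatrix
from .stratify import StrataAssignment

__all__ = [
    "pathway_average",
    "tf_stratum_correlations",
    "shift_test",
    "bootstrap_shift_test",
    "tf_shift_analysis",
    "tf_differential_expression",
    "summarize_shifts",
    "overlap_tfs",
    "stars_for_p",
]

DIRECTION_NEGATIVE = "negative"
DIRECTION_POSITIVE = "positive"
DIRECTION_NS = "ns"


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pathway_average(
    matrix: ExpressionMatrix, gene_set: Iterable[str]
) -> tuple[pd.Series, int]:
    """Per-sample arithmetic mean over the set genes present in the matrix.

    Returns (profile, n_present); raises if no set gene is present.
    """
    present = [g for g in gene_set if g in matrix.values.columns]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    profile = matrix.values[list(dict.fromkeys(present))].mean(axis=1)
    profile.name = "pathway_average"
    return profile, len(set(present))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def tf_stratum_correlations(
    matrix: ExpressionMatrix,
    tf_list: Sequence[str],
    profile: pd.Series,
    strata: StrataAssignment,
) -> pd.DataFrame:
    """Per-TF Pearson r against the profile within each stratum.

    TFs absent from the matrix are kept in the output with ``present=False``
    and NaN correlations rather than silently dropped.
    """
    high, low = strata.high_samples, strata.low_samples
    if len(high) < 4 or len(low) < 4:
        raise ValueError(
            f"stratum too small for correlation (n_high={len(high)}, n_low={len(low)})"
        )
    prof_high = profile.loc[high].to_numpy(dtype=float)
    prof_low = profile.loc[low].to_numpy(dtype=float)
    rows = []
    for tf in tf_list:
        if tf not in matrix.values.columns:
            rows.append({"tf": tf, "r_high": np.nan, "r_low": np.nan, "present": False})
            continue
        v = matrix.gene(tf)
        rows.append(
            {
                "tf": tf,
                "r_high": _pearson(v.loc[high].to_numpy(dtype=float), prof_high),
                "r_low": _pearson(v.loc[low].to_numpy(dtype=float), prof_low),
                "present": True,
            }
        )
    return pd.DataFrame(rows).set_index("tf")


class ShiftResult(NamedTuple):
    delta_r: float
    p_shift: float
    stars: str
    statistic: float


def shift_test(
    r_high: float,
    n_high: int,
    r_low: float,
    n_low: int,
    clamp: bool = False,
) -> ShiftResult:
    """Fisher z comparison of two independent correlations.

    statistic = (atanh(r_low) - atanh(r_high)) / sqrt(1/(n_low-3) + 1/(n_high-3)),
    two-sided normal p.  |r| = 1 is rejected unless ``clamp=True``, which
    clamps to 1 - 1e-6 before transforming.
    """
    if n_high < 4 or n_low < 4:
        raise ValueError("each stratum needs n >= 4 for the shift test")
    rh, rl = float(r_high), float(r_low)
    if max(abs(rh), abs(rl)) >= 1.0:
        if not clamp:
            raise ValueError(
                "|r| = 1 gives an infinite Fisher z; rerun with clamp=True "
                "to clamp at |r| = 1 - 1e-6"
            )
        rh = float(np.clip(rh, -1 + 1e-6, 1 - 1e-6))
        rl = float(np.clip(rl, -1 + 1e-6, 1 - 1e-6))
    se = np.sqrt(1.0 / (n_low - 3) + 1.0 / (n_high - 3))
    z = (np.arctanh(rl) - np.arctanh(rh)) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ShiftResult(rl - rh, p, stars_for_p(p), float(z))


def bootstrap_shift_test(
    tf_high: np.ndarray,
    profile_high: np.ndarray,
    tf_low: np.ndarray,
    profile_low: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ShiftResult:
    """Strain-resampling bootstrap alternative to the Fisher z shift test.

    Resamples samples within each stratum with replacement, recomputes
    delta_r, and reports a plus-one two-sided sign-crossing p-value.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    nh, nl = len(tf_high), len(tf_low)
    observed = _pearson(tf_low, profile_low) - _pearson(tf_high, profile_high)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        ih = rng.integers(0, nh, nh)
        il = rng.integers(0, nl, nl)
        deltas[b] = _pearson(tf_low[il], profile_low[il]) - _pearson(
            tf_high[ih], profile_high[ih]
        )
    deltas = deltas[np.isfinite(deltas)]
    if observed >= 0:
        crossing = int((deltas <= 0).sum())
    else:
        crossing = int((deltas >= 0).sum())
    p = min(1.0, 2.0 * (1 + crossing) / (1 + len(deltas)))
    return ShiftResult(float(observed), p, stars_for_p(p), float("nan"))


def tf_shift_analysis(
    matrix: ExpressionMatrix,
    tf_list: Sequence[str],
    gene_set: Iterable[str],
    strata: StrataAssignment,
    clamp: bool = False,
    profile_mode: str = "average-profile",
) -> pd.DataFrame:
    """Full per-TF shift table: r_high, r_low, delta_r, p_shift, stars.

    ``profile_mode='average-profile'`` correlates each TF with the
    pathway-average profile (default); ``'mean-of-correlations'`` instead
    averages the TF's per-gene correlations over the set within each
    stratum (no shift p-value is defined for that mode's average).
    """
    n_high, n_low = len(strata.high_samples), len(strata.low_samples)
    if profile_mode == "average-profile":
        profile, _ = pathway_average(matrix, gene_set)
        cors = tf_stratum_correlations(matrix, tf_list, profile, strata)
    elif profile_mode == "mean-of-correlations":
        cors = _mean_of_correlations(matrix, tf_list, gene_set, strata)
    else:
        raise ValueError(f"unknown profile_mode {profile_mode!r}")
    rows = []
    for tf, row in cors.iterrows():
        if not row["present"] or not np.isfinite(row["r_high"]) or not np.isfinite(row["r_low"]):
            rows.append(
                {
                    "tf": tf,
                    "r_high": row["r_high"],
                    "r_low": row["r_low"],
                    "delta_r": np.nan,
                    "p_shift": np.nan,
                    "stars": "",
                    "n_high": n_high,
                    "n_low": n_low,
                    "present": bool(row["present"]),
                }
            )
            continue
        res = shift_test(row["r_high"], n_high, row["r_low"], n_low, clamp=clamp)
        rows.append(
            {
                "tf": tf,
                "r_high": row["r_high"],
                "r_low": row["r_low"],
                "delta_r": res.delta_r,
                "p_shift": res.p_shift,
                "stars": res.stars,
                "n_high": n_high,
                "n_low": n_low,
                "present": True,
            }
        )
    return pd.DataFrame(rows).set_index("tf")


def _mean_of_correlations(
    matrix: ExpressionMatrix,
    tf_list: Sequence[str],
    gene_set: Iterable[str],
    strata: StrataAssignment,
) -> pd.DataFrame:
    present_genes = [g for g in gene_set if g in matrix.values.columns]
    if not present_genes:
        raise ValueError("no gene of the set is present in the matrix")
    high, low = strata.high_samples, strata.low_samples
    rows = []
    for tf in tf_list:
        if tf not in matrix.values.columns:
            rows.append({"tf": tf, "r_high": np.nan, "r_low": np.nan, "present": False})
            continue
        v = matrix.gene(tf)
        r_h = np.nanmean(
            [
                _pearson(
                    v.loc[high].to_numpy(float),
                    matrix.gene(g).loc[high].to_numpy(float),
                )
                for g in present_genes
            ]
        )
        r_l = np.nanmean(
            [
                _pearson(
                    v.loc[low].to_numpy(float),
                    matrix.gene(g).loc[low].to_numpy(float),
                )
                for g in present_genes
            ]
        )
        rows.append({"tf": tf, "r_high": r_h, "r_low": r_l, "present": True})
    return pd.DataFrame(rows).set_index("tf")


def tf_differential_expression(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    tf_list: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per TF; log2FC = mean(group A) - mean(group B).

    Group A is the LOW stratum or KO genotype, group B the HIGH stratum or
    WT.  ``direction`` is 'enriched'/'depleted' by sign when raw p < alpha,
    else 'ns'; BY-adjusted p is reported alongside.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    rows = []
    for tf in tf_list:
        if tf not in matrix.values.columns:
            rows.append(
                {"tf": tf, "log2fc": np.nan, "t": np.nan, "p": np.nan,
                 "direction": "missing"}
            )
            continue
        a = matrix.gene(tf).loc[list(group_a)].to_numpy(dtype=float)
        b = matrix.gene(tf).loc[list(group_b)].to_numpy(dtype=float)
        log2fc = float(a.mean() - b.mean())
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t_stat = float(res.statistic)
            p = float(res.pvalue)
            if not np.isfinite(p):
                p = 1.0
        p = min(max(p, np.finfo(float).tiny), 1.0)
        if p >= alpha:
            direction = DIRECTION_NS
        else:
            direction = "enriched" if log2fc > 0 else "depleted"
        rows.append({"tf": tf, "log2fc": log2fc, "t": t_stat, "p": p, "direction": direction})
    df = pd.DataFrame(rows).set_index("tf")
    testable = df["p"].notna()
    df["p_adj"] = np.nan
    if testable.any():
        df.loc[testable, "p_adj"] = adjust_by(df.loc[testable, "p"].to_numpy())
    return df[["log2fc", "t", "p", "p_adj", "direction"]]


def summarize_shifts(records: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int, int]:
    """(n_significant, n_negative, n_positive) over p_shift < alpha."""
    sig = records[(records["p_shift"] < alpha) & records["p_shift"].notna()]
    n_neg = int((sig["delta_r"] < 0).sum())
    n_pos = int((sig["delta_r"] > 0).sum())
    return len(sig), n_neg, n_pos


def shift_directions(records: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Direction labels for significant shifts: tf -> 'negative'/'positive'."""
    out: dict[str, str] = {}
    sig = records[(records["p_shift"] < alpha) & records["p_shift"].notna()]
    for tf, row in sig.iterrows():
        if row["delta_r"] < 0:
            out[tf] = DIRECTION_NEGATIVE
        elif row["delta_r"] > 0:
            out[tf] = DIRECTION_POSITIVE
    return out


def deg_directions(records: pd.DataFrame) -> dict[str, str]:
    """Direction labels for significant differential expression."""
    mapping = {"depleted": DIRECTION_NEGATIVE, "enriched": DIRECTION_POSITIVE}
    return {
        tf: mapping[row["direction"]]
        for tf, row in records.iterrows()
        if row["direction"] in mapping
    }


def overlap_tfs(
    directions_a: Mapping[str, str], directions_b: Mapping[str, str]
) -> list[str]:
    """Direction-concordant TF intersection, lexicographically ordered."""
    return sorted(
        tf
        for tf, d in directions_a.items()
        if tf in directions_b and directions_b[tf] == d
    )


def write_shift_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index_label="tf", float_format="%.6g")
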