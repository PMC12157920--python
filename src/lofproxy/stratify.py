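"""Focal-gene ranking, fold difference, percentiles, and HIGH/LOW strata."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix

__all__ = [
    "StrataAssignment",
    "PRESETS",
    "rank_focal",
    "fold_difference",
    "percentile_rank",
    "assign_strata",
    "write_strata",
]

# group-size presets encoding published stratification counts verbatim
PRESETS: dict[str, tuple[int, int]] = {
    "paper-chow": (12, 12),
    "paper-hfd": (11, 10),
}

HIGH, LOW, MID = "HIGH", "LOW", "MID"


@dataclass(frozen=True)
class StrataAssignment:
    """Per-sample HIGH/LOW/MID labels from a focal-gene ranking."""

    labels: pd.Series  # index: sample id, values in {HIGH, LOW, MID}
    focal: str
    n_high: int
    n_low: int
    ranking: tuple[str, ...]  # samples ascending by focal expression

    @property
    def high_samples(self) -> list[str]:
        return [s for s in self.ranking if self.labels[s] == HIGH]

    @property
    def low_samples(self) -> list[str]:
        return [s for s in self.ranking if self.labels[s] == LOW]

    @property
    def mid_samples(self) -> list[str]:
        return [s for s in self.ranking if self.labels[s] == MID]


def rank_focal(matrix: ExpressionMatrix, focal: str) -> list[str]:
    """Samples sorted ascending by focal expression; ties break by sample id."""
    values = matrix.gene(focal)
    return sorted(matrix.samples, key=lambda s: (values[s], s))


def fold_difference(matrix: ExpressionMatrix, focal: str) -> float:
    """Linear fold span of a log2-scale column: 2**(max - min)."""
    v = matrix.gene(focal).to_numpy(dtype=float)
    return float(2.0 ** (np.max(v) - np.min(v)))


class PercentileRank(NamedTuple):
    raw: float
    reported: int


def percentile_rank(ranking: list[str] | tuple[str, ...], sample: str) -> PercentileRank:
    """Percentile of ``sample`` in the ascending ranking.

    Raw value is 100*(rank-1)/(n-1); the reported value rounds half-up to
    the nearest integer.  A single-sample ranking reports 0.
    """
    if sample not in ranking:
        raise KeyError(f"sample {sample!r} not in ranking")
    n = len(ranking)
    if n == 1:
        return PercentileRank(0.0, 0)
    rank = list(ranking).index(sample) + 1
    raw = 100.0 * (rank - 1) / (n - 1)
    return PercentileRank(raw, int(math.floor(raw + 0.5)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_strata(
    ranking: list[str] | tuple[str, ...],
    n_high: int | None = None,
    n_low: int | None = None,
    preset: str | None = None,
    fraction: float | None = None,
    focal: str = "",
) -> StrataAssignment:
    """Label the top ``n_high`` samples HIGH, bottom ``n_low`` LOW, rest MID.

    Group sizes can come from explicit counts, a named preset
    (``paper-chow`` -> (12, 12), ``paper-hfd`` -> (11, 10)), or a fraction
    of n rounded half-up (``fraction=0.25`` gives quartiles).
    """
    n = len(ranking)
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        n_high, n_low = PRESETS[preset]
    elif fraction is not None:
        if not 0 < fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        n_high = n_low = _round_half_up(fraction * n)
    if n_high is None or n_low is None:
        raise ValueError("provide n_high/n_low, a preset, or a fraction")
    if n_high < 0 or n_low < 0:
        raise ValueError("group sizes must be non-negative")
    if n_high + n_low > n:
        raise ValueError(
            f"overlapping strata: n_high + n_low = {n_high + n_low} > n = {n}"
        )
    ranking = tuple(ranking)
    labels = pd.Series(MID, index=pd.Index(ranking, name="sample"), dtype=object)
    if n_low:
        labels.iloc[:n_low] = LOW
    if n_high:
        labels.iloc[n - n_high:] = HIGH
    return StrataAssignment(
        labels=labels, focal=focal, n_high=n_high, n_low=n_low, ranking=ranking
    )


def write_strata(
    strata: StrataAssignment, matrix: ExpressionMatrix, path: str | Path
) -> None:
    """Serialize as TSV: sample, label, focal value, rank, percentile."""
    focal_values = matrix.gene(strata.focal) if strata.focal else None
    rows = []
    for rank, sample in enumerate(strata.ranking, start=1):
        pr = percentile_rank(strata.ranking, sample)
        rows.append(
            {
                "sample": sample,
                "label": strata.labels[sample],
                "focal_value": float(focal_values[sample]) if focal_values is not None else float("nan"),
                "rank": rank,
                "percentile": pr.reported,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
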