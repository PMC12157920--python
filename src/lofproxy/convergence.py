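"""Cross-contrast convergence reporting.

Classifies significant pathways as shared or unique across contrasts
(panel low-vs-high, knockout-vs-wildtype, diet arms) and measures
within-set rank concordance between contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, RankedList

__all__ = ["ConvergenceReport", "classify_overlap", "gene_rank_concordance"]

COMMON_ALL = "common-all"


@dataclass
class ConvergenceReport:
    classification: dict[str, str]  # pathway -> common-all / common-pair:<..> / unique:<..>
    significant: dict[str, list[str]]  # contrast label -> significant pathway names
    directions: dict[str, dict[str, int]]  # pathway -> contrast -> sign(NES)
    discordant: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classification": self.classification,
            "significant": self.significant,
            "directions": self.directions,
            "discordant": self.discordant,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway": name,
                "classification": cls,
                "contrasts": ",".join(
                    sorted(c for c, sig in self.significant.items() if name in sig)
                ),
                "discordant": name in self.discordant,
            }
            for name, cls in sorted(self.classification.items())
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_overlap(
    results_by_contrast: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
    provenance: dict | None = None,
) -> ConvergenceReport:
    """Set-membership classification of significant pathways across contrasts.

    A pathway significant (BY-adjusted p < alpha) in every contrast is
    ``common-all``; in a proper subset of >= 2 contrasts,
    ``common-pair:<label+label>``; in exactly one, ``unique:<label>``.
    Shared pathways whose NES signs disagree are flagged as discordant,
    never merged away.
    """
    if len(results_by_contrast) < 2:
        raise ValueError("need at least two contrasts to classify overlap")
    labels = list(results_by_contrast)
    significant: dict[str, list[str]] = {}
    directions: dict[str, dict[str, int]] = {}
    for label, results in results_by_contrast.items():
        names = [r.name for r in results]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate pathway names in contrast {label!r}: {sorted(dup)}")
        sig = [r.name for r in results if np.isfinite(r.p_adj) and r.p_adj < alpha]
        significant[label] = sorted(sig)
        for r in results:
            if r.name in sig:
                directions.setdefault(r.name, {})[label] = int(np.sign(r.es))
    classification: dict[str, str] = {}
    discordant: list[str] = []
    for name, per_contrast in directions.items():
        members = sorted(per_contrast)
        if len(members) == len(labels):
            classification[name] = COMMON_ALL
        elif len(members) == 1:
            classification[name] = f"unique:{members[0]}"
        else:
            classification[name] = "common-pair:" + "+".join(members)
        if len({s for s in per_contrast.values() if s != 0}) > 1:
            discordant.append(name)
    return ConvergenceReport(
        classification=classification,
        significant=significant,
        directions=directions,
        discordant=sorted(discordant),
        provenance=provenance or {},
    )


def gene_rank_concordance(
    ranked_a: RankedList, ranked_b: RankedList, gene_set: Iterable[str]
) -> float:
    """Spearman rho of within-set contrast scores over shared set genes."""
    members = set(gene_set)
    scores_a = {g: s for g, s in zip(ranked_a.genes, ranked_a.scores) if g in members}
    scores_b = {g: s for g, s in zip(ranked_b.genes, ranked_b.scores) if g in members}
    shared = sorted(set(scores_a) & set(scores_b))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared set genes for rank concordance, got {len(shared)}"
        )
    a = np.array([scores_a[g] for g in shared])
    b = np.array([scores_b[g] for g in shared])
    rho = stats.spearmanr(a, b).statistic
    return float(rho)
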