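"""Tabular I/O, probe selection, and cross-platform renormalization.

Expression matrices are tab-separated text: first column holds sample ids,
the header row holds gene symbols, and values are log2-scale expression.
Sample metadata is a second TSV with columns ``sample``, ``strain``,
``diet`` and ``genotype``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "NormalizationError",
    "ProbeSelectionError",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_probe_table",
    "select_probe",
    "renormalize",
    "read_gene_list",
    "write_gene_list",
]

DIET_VALUES = frozenset({"CD", "HFD", "NA"})
GENOTYPE_VALUES = frozenset({"WT", "KO", "NA"})


class ParseError(ValueError):
    """A tabular input file is malformed."""


class NormalizationError(ValueError):
    """The matrix cannot be renormalized (e.g. zero global variance)."""


class ProbeSelectionError(ValueError):
    """No probe satisfies the selection criteria."""


def _default_meta(sample_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": list(sample_ids),
            "diet": "NA",
            "genotype": "NA",
        },
        index=pd.Index(sample_ids, name="sample"),
    )


@dataclass
class ExpressionMatrix:
    """Samples x genes log2 expression values plus per-sample metadata.

    ``values`` is indexed by sample id with gene symbols as columns.
    ``sample_meta`` is indexed by sample id with columns ``strain``,
    ``diet`` (CD/HFD/NA) and ``genotype`` (WT/KO/NA).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = _default_meta(list(self.values.index))
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at sample {idx[bad[0]]!r}, gene {cols[bad[1]]!r}"
            )
        if not self.sample_meta.index.equals(idx):
            missing = idx.difference(self.sample_meta.index).tolist()
            if missing:
                raise ParseError(f"samples missing from metadata: {missing}")
            self.sample_meta = self.sample_meta.loc[idx]

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.columns:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values[gene_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(sample_ids)],
            self.sample_meta.loc[list(sample_ids)],
        )


def read_matrix(
    path: str | Path,
    metadata_path: str | Path | None = None,
    orientation: str = "samples-rows",
) -> ExpressionMatrix:
    """Read an expression TSV; ``orientation='genes-rows'`` transposes.

    Raises :class:`ParseError` on duplicate ids, non-numeric cells, or
    ragged rows, naming the offending row/column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        ids = header[1:]
        seen: set[str] = set()
        for ident in ids:
            if ident in seen:
                raise ParseError(f"duplicate column id {ident!r} in {path.name}")
            seen.add(ident)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if len(line.rstrip("\n").split("\t")) != n_cols:
                raise ParseError(f"ragged row at line {lineno} of {path.name}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate row ids in {path.name}: {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"non-numeric value in column {col!r}, row {row!r} of {path.name}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "genes-rows":
        df = df.T
    elif orientation != "samples-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    meta = read_metadata(metadata_path) if metadata_path is not None else None
    return ExpressionMatrix(df.astype(float), meta)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (10 significant digits, round-trip < 1e-5)."""
    matrix.values.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the literal string "NA" is a valid category here
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "strain", "diet", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise ParseError("duplicate sample ids in metadata")
    bad_diet = set(df["diet"]) - DIET_VALUES
    if bad_diet:
        raise ParseError(f"invalid diet values: {sorted(bad_diet)}")
    bad_geno = set(df["genotype"]) - GENOTYPE_VALUES
    if bad_geno:
        raise ParseError(f"invalid genotype values: {sorted(bad_geno)}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, gene, cross_hyb, then sample columns."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str})
    required = {"probe_id", "gene", "cross_hyb"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"probe table missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ParseError("duplicate probe ids in probe table")
    df["cross_hyb"] = df["cross_hyb"].astype(bool)
    return df.set_index("probe_id")


def select_probe(
    probes: pd.DataFrame, gene: str, normality_alpha: float = 0.05
) -> str:
    """Pick one probe for ``gene``: unflagged, normal-looking, widest range.

    Among probes with ``cross_hyb == False``, keep those whose per-sample
    values pass a Shapiro-Wilk normality check at ``normality_alpha`` and
    return the one with the largest dynamic range (max - min, log2 units);
    ties break lexicographically on probe id.  If no unflagged probe passes
    normality, the widest-range unflagged probe is returned with a warning.
    """
    sub = probes[probes["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} has no probes")
    unflagged = sub[~sub["cross_hyb"]]
    if unflagged.empty:
        raise ProbeSelectionError(
            f"all probes for {gene!r} are flagged for cross-hybridization"
        )
    value_cols = [c for c in probes.columns if c not in ("gene", "cross_hyb")]
    ranges: dict[str, float] = {}
    normal_ok: dict[str, bool] = {}
    for probe_id, row in unflagged.iterrows():
        vals = row[value_cols].to_numpy(dtype=float)
        ranges[probe_id] = float(np.max(vals) - np.min(vals))
        if np.ptp(vals) == 0 or len(vals) < 3:
            normal_ok[probe_id] = False
        else:
            normal_ok[probe_id] = stats.shapiro(vals).pvalue >= normality_alpha
    candidates = [p for p in ranges if normal_ok[p]]
    if not candidates:
        warnings.warn(
            f"no probe for {gene!r} passes normality at alpha={normality_alpha}; "
            "falling back to widest-range unflagged probe",
            stacklevel=2,
        )
        candidates = list(ranges)
    # widest range wins; ties broken by probe id for determinism
    return min(candidates, key=lambda p: (-ranges[p], p))


def renormalize(
    matrix: ExpressionMatrix,
    target_mean: float = 8.0,
    target_sd: float = 2.0,
    per_gene: bool = False,
) -> ExpressionMatrix:
    """Global z-score over all cells, then rescale to ``target_mean``/``target_sd``.

    The default mode pools every cell of the matrix into one distribution,
    so all pairwise correlations are preserved exactly (affine map).
    ``per_gene=True`` z-scores each gene column independently instead.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if per_gene:
        mu = arr.mean(axis=0, keepdims=True)
        sd = arr.std(axis=0, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise NormalizationError("per-gene normalization: constant gene column")
    else:
        mu = arr.mean()
        sd = arr.std(ddof=0)
        if sd == 0:
            raise NormalizationError("matrix has zero global variance")
    out = (arr - mu) / sd * target_sd + target_mean
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.sample_meta.copy(),
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list: one symbol per line, blanks and '#' lines skipped."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
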