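"""Strain-panel and knockout expression simulators with planted structure.

The generator plants four kinds of genes and records them in a truth
table so every downstream stage has a recoverable ground truth:

* one focal gene whose log2 values are evenly spaced across strains,
  spanning ``log2(focal_fold_range)``;
* module genes linearly coupled to the focal gene
  (``baseline + sign * beta * (focal - mean(focal)) + noise``);
* TF genes whose correlation with a module-average profile is planted
  per stratum by mixing the stratum's pathway-average signal with
  independent noise at the variance ratio implied by the target r;
* null genes, i.i.d. Normal(baseline_mean, baseline_sd).

Every component draws from its own seed substream keyed off the master
seed, so adding genes or arms never perturbs existing columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, write_gene_list, write_matrix, write_metadata
from .enrichment import write_gmt

__all__ = [
    "ModuleSpec",
    "TFSpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_panel",
    "simulate_ko",
    "planted_strata",
    "beta_for_target_r",
    "focal_sd",
    "default_config",
    "write_dataset",
]

_ARM_CODES = {"CD": 0, "HFD": 1, "KO": 2}


@dataclass(frozen=True)
class ModuleSpec:
    """A gene module coupled to the focal gene.

    ``beta`` is the log2 change per log2-unit of focal expression and
    ``sign`` is +1 or -1.  ``in_ko=False`` exempts the module from the
    knockout shift (useful to plant panel-unique pathways).
    """

    name: str
    size: int
    beta: float
    sign: int
    in_ko: bool = True


@dataclass(frozen=True)
class TFSpec:
    """A TF with per-stratum target correlations to the pathway average.

    ``ko_shift`` is the log2 expression shift applied in knockout samples.
    """

    name: str
    r_high: float
    r_low: float
    ko_shift: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_strains: int = 40
    n_genes: int = 5000
    focal_fold_range: float = 3.22
    module_specs: tuple[ModuleSpec, ...] = ()
    tf_specs: tuple[TFSpec, ...] = ()
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    ko_replicates: int = 3
    ko_effect: float = 1.0
    diet_interaction: float = 1.0
    tf_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 8:
            raise ValueError("n_strains must be >= 8")
        if self.focal_fold_range <= 1:
            raise ValueError("focal_fold_range must be > 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        names = [m.name for m in self.module_specs]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        tf_names = [t.name for t in self.tf_specs]
        if len(set(tf_names)) != len(tf_names):
            raise ValueError("TF names must be unique")
        for m in self.module_specs:
            if m.sign not in (+1, -1):
                raise ValueError(f"module {m.name!r}: sign must be +1 or -1")
            if m.size < 1:
                raise ValueError(f"module {m.name!r}: size must be >= 1")
        for t in self.tf_specs:
            for r in (t.r_high, t.r_low):
                if abs(r) >= 1:
                    raise ValueError(
                        f"TF {t.name!r}: infeasible r_target {r} (need |r| < 1)"
                    )
                if abs(r * self.diet_interaction) >= 1:
                    raise ValueError(
                        f"TF {t.name!r}: diet_interaction makes |r_target| >= 1"
                    )
        reserved = sum(m.size for m in self.module_specs) + len(self.tf_specs) + 1
        if self.n_genes < reserved:
            raise ValueError(
                f"n_genes = {self.n_genes} < {reserved} planted genes (modules + TFs + focal)"
            )

    @property
    def n_null(self) -> int:
        return self.n_genes - 1 - sum(m.size for m in self.module_specs) - len(self.tf_specs)


@dataclass
class TruthTable:
    """Ground truth of the planted structure; partitions the gene universe."""

    focal_gene: str
    module_membership: dict[str, str]  # gene -> module name
    coupling_signs: dict[str, int]  # module -> +1/-1
    module_betas: dict[str, float]
    tf_coupling: dict[str, tuple[float, float]]  # tf -> (r_high, r_low)
    tf_ko_shift: dict[str, float]
    null_genes: set[str]

    def __post_init__(self) -> None:
        groups = [
            {self.focal_gene},
            set(self.module_membership),
            set(self.tf_coupling),
            set(self.null_genes),
        ]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            raise ValueError("gene groups in the truth table overlap")

    @property
    def all_genes(self) -> set[str]:
        return (
            {self.focal_gene}
            | set(self.module_membership)
            | set(self.tf_coupling)
            | set(self.null_genes)
        )

    def module_genes(self, module: str) -> list[str]:
        return sorted(g for g, m in self.module_membership.items() if m == module)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "focal_gene": self.focal_gene,
            "module_membership": self.module_membership,
            "coupling_signs": self.coupling_signs,
            "module_betas": self.module_betas,
            "tf_coupling": {k: list(v) for k, v in self.tf_coupling.items()},
            "tf_ko_shift": self.tf_ko_shift,
            "null_genes": sorted(self.null_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        return cls(
            focal_gene=d["focal_gene"],
            module_membership=d["module_membership"],
            coupling_signs={k: int(v) for k, v in d["coupling_signs"].items()},
            module_betas={k: float(v) for k, v in d["module_betas"].items()},
            tf_coupling={k: (float(v[0]), float(v[1])) for k, v in d["tf_coupling"].items()},
            tf_ko_shift={k: float(v) for k, v in d["tf_ko_shift"].items()},
            null_genes=set(d["null_genes"]),
        )


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def focal_values(config: SimulationConfig) -> np.ndarray:
    """Evenly spaced log2 focal values, ascending with strain index."""
    span = math.log2(config.focal_fold_range)
    lo = config.baseline_mean - span / 2
    return lo + span * np.arange(config.n_strains) / (config.n_strains - 1)


def focal_sd(config: SimulationConfig) -> float:
    """Population SD of the evenly spaced focal column."""
    return float(np.std(focal_values(config)))


def beta_for_target_r(
    target_r: float, noise_sd: float, config: SimulationConfig
) -> float:
    """Coupling coefficient giving asymptotic Pearson r = target_r.

    Inverts r = beta*sd_f / sqrt(beta^2*sd_f^2 + noise_sd^2).
    """
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must satisfy 0 < |r| < 1")
    sd_f = focal_sd(config)
    return abs(target_r) / math.sqrt(1 - target_r**2) * noise_sd / sd_f


def planted_strata(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """(low_strains, high_strains): bottom/top quartile by planted focal order."""
    strains = _strain_ids(config)
    q = _round_half_up(0.25 * config.n_strains)
    return strains[:q], strains[-q:]


def _strain_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i:03d}" for i in range(1, config.n_strains + 1)]


def _gene_layout(config: SimulationConfig) -> dict[str, list[str]]:
    layout: dict[str, list[str]] = {"focal": ["focal"]}
    for m in config.module_specs:
        layout[m.name] = [f"{m.name}_{i:04d}" for i in range(1, m.size + 1)]
    layout["__tf__"] = [t.name for t in config.tf_specs]
    layout["__null__"] = [f"null_{i:05d}" for i in range(1, config.n_null + 1)]
    return layout


def build_truth(config: SimulationConfig) -> TruthTable:
    layout = _gene_layout(config)
    membership = {
        g: m.name for m in config.module_specs for g in layout[m.name]
    }
    return TruthTable(
        focal_gene="focal",
        module_membership=membership,
        coupling_signs={m.name: m.sign for m in config.module_specs},
        module_betas={m.name: m.beta for m in config.module_specs},
        tf_coupling={t.name: (t.r_high, t.r_low) for t in config.tf_specs},
        tf_ko_shift={t.name: t.ko_shift for t in config.tf_specs},
        null_genes=set(layout["__null__"]),
    )


def _module_baselines(config: SimulationConfig, module_index: int, size: int) -> np.ndarray:
    rng = _rng(config.seed, 1, module_index, 0)
    return rng.normal(config.baseline_mean, config.baseline_sd, size)


def _tf_baselines(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config.seed, 2, 0)
    return rng.normal(config.baseline_mean, config.baseline_sd, len(config.tf_specs))


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------

def simulate_panel(
    config: SimulationConfig, arm: str = "CD"
) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate one strain-panel arm (``CD`` or ``HFD``).

    The HFD arm reuses the same strain ids and planted focal spacing but
    redraws all noise from arm-specific substreams and multiplies each
    TF's target correlations by ``diet_interaction``.
    """
    if arm not in ("CD", "HFD"):
        raise ValueError(f"arm must be 'CD' or 'HFD', got {arm!r}")
    arm_code = _ARM_CODES[arm]
    n = config.n_strains
    strains = _strain_ids(config)
    layout = _gene_layout(config)
    truth = build_truth(config)

    columns: dict[str, np.ndarray] = {}
    focal = focal_values(config)
    columns["focal"] = focal
    centered = focal - focal.mean()

    # module genes: baseline + sign * beta * centered focal + noise
    for mi, m in enumerate(config.module_specs):
        baselines = _module_baselines(config, mi, m.size)
        noise = _rng(config.seed, 1, mi, 1, arm_code).normal(
            0.0, config.noise_sd, (m.size, n)
        )
        block = baselines[:, None] + m.sign * m.beta * centered[None, :] + noise
        for gi, g in enumerate(layout[m.name]):
            columns[g] = block[gi]

    # pathway-average profile used to plant TF couplings (first module)
    low_ids, high_ids = planted_strata(config)
    low_idx = np.array([strains.index(s) for s in low_ids])
    high_idx = np.array([strains.index(s) for s in high_ids])
    if config.tf_specs:
        if not config.module_specs:
            raise ValueError("TF coupling requires at least one module")
        first = config.module_specs[0]
        pathway = np.mean(
            [columns[g] for g in layout[first.name]], axis=0
        )
        tf_baselines = _tf_baselines(config)
        for ti, t in enumerate(config.tf_specs):
            rng = _rng(config.seed, 2, 1, ti, arm_code)
            dev = rng.normal(0.0, 1.0, n)  # MID samples keep pure noise
            for idx, r_target in ((high_idx, t.r_high), (low_idx, t.r_low)):
                r_eff = r_target * (config.diet_interaction if arm == "HFD" else 1.0)
                seg = pathway[idx]
                sd = seg.std()
                z = (seg - seg.mean()) / sd if sd > 0 else np.zeros(len(idx))
                dev[idx] = r_eff * z + math.sqrt(1 - r_eff**2) * rng.normal(
                    0.0, 1.0, len(idx)
                )
            columns[t.name] = tf_baselines[ti] + config.tf_scale * dev

    # null block: row-major fill so the prefix is stable as n_genes grows
    null_block = _rng(config.seed, 3, arm_code).normal(
        config.baseline_mean, config.baseline_sd, (config.n_null, n)
    )
    for gi, g in enumerate(layout["__null__"]):
        columns[g] = null_block[gi]

    gene_order = (
        layout["focal"]
        + [g for m in config.module_specs for g in layout[m.name]]
        + layout["__tf__"]
        + layout["__null__"]
    )
    values = pd.DataFrame(
        {g: columns[g] for g in gene_order}, index=pd.Index(strains, name="sample")
    )
    meta = pd.DataFrame(
        {"strain": strains, "diet": arm, "genotype": "NA"},
        index=pd.Index(strains, name="sample"),
    )
    return ExpressionMatrix(values, meta), truth


def simulate_ko(config: SimulationConfig, truth: TruthTable) -> ExpressionMatrix:
    """Simulate the small-n knockout arm (WT vs KO, ``ko_replicates`` each).

    The focal gene is silenced in KO (panel minimum minus 1 log2 unit);
    module genes move opposite their focal coupling by ``ko_effect`` so the
    knockout mimics the low-expression end of the panel; TF genes shift by
    their ``ko_shift``; null genes are untouched.
    """
    if config.ko_replicates < 2:
        raise ValueError("ko_replicates must be >= 2")
    k = config.ko_replicates
    samples = [f"WT{i}" for i in range(1, k + 1)] + [f"KO{i}" for i in range(1, k + 1)]
    is_ko = np.array([s.startswith("KO") for s in samples])
    n = 2 * k
    layout = _gene_layout(config)

    columns: dict[str, np.ndarray] = {}
    span = math.log2(config.focal_fold_range)
    panel_min = config.baseline_mean - span / 2
    wt_rng = _rng(config.seed, 4, 0)
    focal = config.baseline_mean + wt_rng.normal(0.0, config.noise_sd, n)
    focal[is_ko] = panel_min - 1.0
    columns["focal"] = focal

    for mi, m in enumerate(config.module_specs):
        baselines = _module_baselines(config, mi, m.size)
        noise = _rng(config.seed, 1, mi, 1, _ARM_CODES["KO"]).normal(
            0.0, config.noise_sd, (m.size, n)
        )
        block = baselines[:, None] + noise
        if m.in_ko:
            block[:, is_ko] -= m.sign * config.ko_effect
        for gi, g in enumerate(layout[m.name]):
            columns[g] = block[gi]

    tf_baselines = _tf_baselines(config)
    for ti, t in enumerate(config.tf_specs):
        rng = _rng(config.seed, 2, 1, ti, _ARM_CODES["KO"])
        vals = tf_baselines[ti] + rng.normal(0.0, config.noise_sd, n)
        vals[is_ko] += t.ko_shift
        columns[t.name] = vals

    null_block = _rng(config.seed, 3, _ARM_CODES["KO"]).normal(
        config.baseline_mean, config.baseline_sd, (config.n_null, n)
    )
    for gi, g in enumerate(layout["__null__"]):
        columns[g] = null_block[gi]

    gene_order = (
        layout["focal"]
        + [g for m in config.module_specs for g in layout[m.name]]
        + layout["__tf__"]
        + layout["__null__"]
    )
    values = pd.DataFrame(
        {g: columns[g] for g in gene_order}, index=pd.Index(samples, name="sample")
    )
    meta = pd.DataFrame(
        {
            "strain": "B6",
            "diet": "CD",
            "genotype": ["KO" if ko else "WT" for ko in is_ko],
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values, meta)


# --------------------------------------------------------------------------
# default demo configuration
# --------------------------------------------------------------------------

def default_config(seed: int = 0, n_genes: int = 5000) -> SimulationConfig:
    """Demo configuration with planted modules and TFs at recoverable effect sizes.

    Two focal-coupled modules (81 and 89 genes, planted |r| ~ 0.6, negative
    coupling so their genes rise as focal expression falls), two
    knockout-only modules, seven direction-concordant TFs (negative shift,
    depleted in KO), two discordant TFs, and six null TFs.
    """
    base = SimulationConfig(n_strains=40, focal_fold_range=3.22, noise_sd=0.5, seed=seed)
    beta = beta_for_target_r(0.6, base.noise_sd, base)
    modules = (
        ModuleSpec("mod_ribo", 81, beta, -1),
        ModuleSpec("mod_oxphos", 89, beta, -1),
        ModuleSpec("mod_ko_only_a", 30, 0.0, +1),
        ModuleSpec("mod_ko_only_b", 30, 0.0, -1),
    )
    tfs = tuple(
        TFSpec(f"tf_conc{i}", 0.8, -0.8, -4.0) for i in range(1, 8)
    ) + (
        TFSpec("tf_disc1", -0.8, 0.8, -4.0),
        TFSpec("tf_disc2", 0.8, -0.8, 4.0),
    ) + tuple(TFSpec(f"tf_null{i}", 0.0, 0.0, 0.0) for i in range(1, 7))
    return SimulationConfig(
        n_strains=40,
        n_genes=n_genes,
        focal_fold_range=3.22,
        module_specs=modules,
        tf_specs=tfs,
        noise_sd=0.5,
        ko_replicates=3,
        ko_effect=1.0,
        diet_interaction=0.5,
        seed=seed,
    )


def write_dataset(
    config: SimulationConfig,
    out_dir: str | Path,
    arms: Sequence[str] = ("cd",),
) -> dict[str, Path]:
    """Simulate and write matrices, metadata, truth table, GMT and TF list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)
    paths: dict[str, Path] = {}
    for arm in arms:
        arm_u = arm.upper()
        if arm_u == "KO":
            matrix = simulate_ko(config, truth)
        else:
            matrix, _ = simulate_panel(config, arm=arm_u)
        mat_path = out / f"expression_{arm.lower()}.tsv"
        meta_path = out / f"metadata_{arm.lower()}.tsv"
        write_matrix(matrix, mat_path)
        write_metadata(matrix.sample_meta, meta_path)
        paths[f"matrix_{arm.lower()}"] = mat_path
        paths[f"metadata_{arm.lower()}"] = meta_path
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    gmt_path = out / "gene_sets.gmt"
    write_gmt(
        {m.name: truth.module_genes(m.name) for m in config.module_specs}, gmt_path
    )
    paths["gmt"] = gmt_path
    tf_path = out / "tf_list.txt"
    write_gene_list([t.name for t in config.tf_specs], tf_path)
    paths["tf_list"] = tf_path
    return paths
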