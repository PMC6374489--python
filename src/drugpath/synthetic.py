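"""Synthetic screens, target maps, gene-set collections and size populations.

Every downstream stage is testable against known ground truth.  The screen
generator emulates the study design the pipeline was built for: 3 stem-cell
groups x 3 cell lines x 3 technical replicates, 81 inhibitors plus vehicle
and untreated controls at a single concentration, 10 summary parameters per
well, filled onto 96-well plates with fixed control positions, with
plate- and cell-line-structured multiplicative noise on top of per-well
measurement noise.  Effects are planted as mean shifts expressed in z-units
(multiples of the per-process measurement noise) restricted to the affected
groups.

The size-population generator produces paired (birth volume, division
volume) samples under the three classic size-control rules:

* timer: V_div = k * V_birth       (fixed growth time, exponential growth)
* adder: V_div = V_birth + dV      (fixed added volume)
* sizer: V_div = V*                (fixed division size)

With ``noise_sd = 0`` every generator is a deterministic function of its
configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_types import (
    CONTROL_KINDS,
    DEFAULT_GROUPS,
    PROCESSES,
    GeneSetCollection,
    ScreenDataset,
    TargetMap,
)

# Per-process baseline (mean, unit noise scale) on the normalized scale.
# The realised per-well noise sd is noise_sd * unit_sd, so noise_sd is a
# dimensionless dial shared by all processes and effect sizes stated in
# z-units translate to raw shifts of effect * noise_sd * unit_sd.
BASELINES: dict[str, tuple[float, float]] = {
    "survival": (1.0, 0.15),
    "apoptosis_fraction": (0.05, 0.02),
    "g1_fraction": (0.40, 0.03),
    "s_fraction": (0.30, 0.03),
    "g2m_fraction": (0.20, 0.03),
    "size_all": (50_000.0, 2_500.0),
    "size_g1": (45_000.0, 2_500.0),
    "size_s": (50_000.0, 2_500.0),
    "size_g2m": (55_000.0, 2_500.0),
    "size_apoptotic": (30_000.0, 2_000.0),
}

#: Default control wells placed at the head of every plate (>= 4 per plate).
DEFAULT_CONTROLS_PER_KIND = 2


@dataclass(frozen=True)
class PlantedEffect:
    """A group-restricted mean shift on one (inhibitor, process) cell."""

    inhibitor: str
    process: str
    groups: tuple[str, ...]
    effect_size: float  # in z-units (multiples of per-process noise sd)

    def __post_init__(self):
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass
class ScreenSimConfig:
    n_inhibitors: int = 81
    n_cell_lines_per_group: int = 3
    n_replicates: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 0.3
    cell_line_sd: float = 0.05  # lognormal sd of per-line baseline factor
    plate_sd: float = 0.05  # lognormal sd of per-plate factor
    plate_capacity: int = 96
    controls_per_kind: int = DEFAULT_CONTROLS_PER_KIND
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.controls_per_kind < 1:
            raise ValueError("need >= 1 control well of each kind per plate")
        if self.plate_capacity <= len(self.control_layout):
            raise ValueError("plate capacity too small for control layout")

    @property
    def control_layout(self) -> tuple[str, ...]:
        return ("untreated",) * self.controls_per_kind + (
            "vehicle",
        ) * self.controls_per_kind

    @property
    def inhibitors(self) -> list[str]:
        width = len(str(self.n_inhibitors))
        return [f"inh_{i + 1:0{width}d}" for i in range(self.n_inhibitors)]

    @property
    def cell_lines(self) -> list[tuple[str, str]]:
        """(cell line, group) pairs in generation order."""
        out = []
        for g in self.groups:
            for i in range(self.n_cell_lines_per_group):
                out.append((f"{g}_L{i + 1}", g))
        return out


def _well_label(index: int) -> str:
    row, col = divmod(index, 12)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def generate_screen(cfg: ScreenSimConfig) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a screen; returns the dataset and the planted-truth table.

    Controls and non-planted inhibitors are drawn from the per-process
    baseline; planted inhibitors are shifted by ``effect_size`` z-units in
    the affected groups only.  Identical seeds yield identical output.
    """
    inhibitors = cfg.inhibitors
    known = set(inhibitors)
    for eff in cfg.planted_effects:
        if eff.inhibitor not in known:
            raise ValueError(f"planted effect references unknown inhibitor {eff.inhibitor!r}")
        if eff.process not in PROCESSES:
            raise ValueError(f"planted effect references unknown process {eff.process!r}")
        for g in eff.groups:
            if g not in cfg.groups:
                raise ValueError(f"planted effect references unknown group {g!r}")

    rng = np.random.default_rng(cfg.seed)
    stochastic = cfg.noise_sd > 0

    # Effect sizes are stated in z-units of the *normalized* population.
    # Dividing by the noisy per-plate control mean (n_ctrl vehicle wells)
    # inflates the normalized-scale sd to noise_sd*unit_sd*sqrt(1+1/n_ctrl),
    # so the injected raw shift carries the same factor to deliver the
    # stated z-shift after normalization.
    n_ctrl = cfg.controls_per_kind
    z_unit_factor = float(np.sqrt(1.0 + 1.0 / n_ctrl))

    # shift lookup: (inhibitor, process, group) -> raw shift
    shift: dict[tuple[str, str, str], float] = {}
    for eff in cfg.planted_effects:
        _mean, unit_sd = BASELINES[eff.process]
        for g in eff.groups:
            shift[(eff.inhibitor, eff.process, g)] = (
                eff.effect_size * cfg.noise_sd * unit_sd * z_unit_factor
            )

    control_layout = cfg.control_layout
    conditions_per_plate = cfg.plate_capacity - len(control_layout)
    rows: list[dict] = []
    for cell_line, group in cfg.cell_lines:
        # per-line baseline factor (line-to-line variation; removed by
        # per-plate normalization since plates hold a single line)
        line_factor = {
            p: float(np.exp(rng.normal(0.0, cfg.cell_line_sd))) if stochastic else 1.0
            for p in PROCESSES
        }
        for rep in range(1, cfg.n_replicates + 1):
            for chunk_start in range(0, cfg.n_inhibitors, conditions_per_plate):
                chunk = inhibitors[chunk_start : chunk_start + conditions_per_plate]
                plate_no = chunk_start // conditions_per_plate + 1
                plate_id = f"P_{cell_line}_r{rep}_{plate_no}"
                plate_factor = {
                    p: float(np.exp(rng.normal(0.0, cfg.plate_sd))) if stochastic else 1.0
                    for p in PROCESSES
                }
                plate_conditions = list(control_layout) + chunk
                for widx, cond in enumerate(plate_conditions):
                    row = {
                        "plate_id": plate_id,
                        "well": _well_label(widx),
                        "cell_line": cell_line,
                        "group": group,
                        "replicate": rep,
                        "condition": cond,
                    }
                    for p in PROCESSES:
                        mean, unit_sd = BASELINES[p]
                        val = mean + shift.get((cond, p, group), 0.0)
                        if stochastic:
                            val += cfg.noise_sd * unit_sd * rng.normal()
                        val *= line_factor[p] * plate_factor[p]
                        row[p] = val
                    rows.append(row)

    wells = pd.DataFrame(rows)
    wells = _enforce_fraction_invariants(wells)

    ds = ScreenDataset(
        wells=wells,
        conditions=inhibitors,
        groups=list(cfg.groups),
        metadata={
            "concentration_uM": 5.0,
            "treatment_duration_h": 24.0,
            "seed": cfg.seed,
            "noise_sd": cfg.noise_sd,
        },
    )
    truth = pd.DataFrame(
        [
            {
                "inhibitor": e.inhibitor,
                "process": e.process,
                "group": g,
                "effect_size": e.effect_size,
            }
            for e in cfg.planted_effects
            for g in e.groups
        ],
        columns=["inhibitor", "process", "group", "effect_size"],
    )
    return ds, truth


def _enforce_fraction_invariants(wells: pd.DataFrame) -> pd.DataFrame:
    """Clip fractions to [0, 1] and rescale the cell-cycle trio to sum <= 1.

    With the default noise this almost never triggers (>5 sigma); it keeps
    extreme draws from violating measurement constraints.
    """
    wells = wells.copy()
    for c in ("apoptosis_fraction", "g1_fraction", "s_fraction", "g2m_fraction"):
        wells[c] = wells[c].clip(lower=0.0, upper=1.0)
    trio = wells[["g1_fraction", "s_fraction", "g2m_fraction"]].sum(axis=1)
    over = trio > 1.0
    if over.any():
        scale = 1.0 / trio[over]
        for c in ("g1_fraction", "s_fraction", "g2m_fraction"):
            wells.loc[over, c] = wells.loc[over, c] * scale
    for c in ("size_all", "size_g1", "size_s", "size_g2m", "size_apoptotic", "survival"):
        wells[c] = wells[c].clip(lower=1e-9)
    return wells


# ---------------------------------------------------------------------------
# size-control populations
# ---------------------------------------------------------------------------

SIZE_MODELS = ("timer", "adder", "sizer")


@dataclass
class SizeSimConfig:
    model: str
    n: int
    birth_volume_range: tuple[float, float] = (1.0, 3.0)
    growth_param: float = 2.0  # timer fold-change k / adder dV / sizer V*
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in SIZE_MODELS:
            raise ValueError(f"unknown size model {self.model!r}")
        lo, hi = self.birth_volume_range
        if not lo > 0 or hi < lo:
            raise ValueError("birth volume range must satisfy 0 < lo <= hi")
        if self.model == "timer" and not self.growth_param > 1:
            raise ValueError("timer fold-change k must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_size_population(
    cfg: SizeSimConfig, births: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (birth volumes, division volumes) under the chosen rule."""
    rng = np.random.default_rng(cfg.seed)
    if births is None:
        lo, hi = cfg.birth_volume_range
        births = rng.uniform(lo, hi, size=cfg.n)
    else:
        births = np.asarray(births, dtype=float)
    if cfg.model == "timer":
        divisions = cfg.growth_param * births
    elif cfg.model == "adder":
        divisions = births + cfg.growth_param
    else:  # sizer
        divisions = np.full_like(births, cfg.growth_param)
    if cfg.noise_sd > 0:
        divisions = divisions + rng.normal(0.0, cfg.noise_sd, size=births.shape)
    return births, divisions


# ---------------------------------------------------------------------------
# target maps and gene-set collections
# ---------------------------------------------------------------------------

def _gene_universe(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def generate_fixtures(
    n_genes: int,
    n_sets: int,
    n_inhibitors: int,
    targets_per_inhibitor: int,
    seed: int,
    set_size_range: tuple[int, int] = (5, 20),
    concentration_range_uM: tuple[float, float] = (0.1, 5.0),
) -> tuple[TargetMap, GeneSetCollection]:
    """Random target map + gene-set collection over a shared gene universe."""
    if not n_genes >= n_sets >= 1:
        raise ValueError("need n_genes >= n_sets >= 1")
    if targets_per_inhibitor > n_genes:
        raise ValueError("targets_per_inhibitor exceeds gene universe")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_universe(n_genes))

    width = len(str(n_inhibitors))
    entries: dict[str, list[tuple[str, float]]] = {}
    lo_c, hi_c = concentration_range_uM
    for i in range(n_inhibitors):
        picked = rng.choice(genes, size=targets_per_inhibitor, replace=False)
        concs = rng.uniform(lo_c, hi_c, size=targets_per_inhibitor)
        entries[f"inh_{i + 1:0{width}d}"] = [
            (str(g), float(c)) for g, c in zip(sorted(picked), concs)
        ]
    tmap = TargetMap(entries)

    lo_s, hi_s = set_size_range
    lo_s = max(1, min(lo_s, n_genes))
    hi_s = max(lo_s, min(hi_s, n_genes))
    sets: dict[str, tuple[str, list[str]]] = {}
    for j in range(n_sets):
        size = int(rng.integers(lo_s, hi_s + 1))
        members = sorted(str(g) for g in rng.choice(genes, size=size, replace=False))
        sets[f"SET_{j + 1:03d}"] = (f"synthetic set {j + 1}", members)
    return tmap, GeneSetCollection(sets)


def planted_gene_set(
    tmap: TargetMap,
    inhibitors: list[str],
    ceiling_uM: float = 5.0,
    name: str = "PLANTED_SET",
) -> tuple[str, tuple[str, list[str]]]:
    """A gene set built from the eligible targets of selected inhibitors.

    Used to verify end-to-end recovery: if the inhibitors carry planted
    group-differential effects, this set should enrich toward the affected
    group after ranking and GSEA.
    """
    members = sorted(
        {g for inh in inhibitors for g in tmap.targets_within(inh, ceiling_uM)}
    )
    if not members:
        raise ValueError("selected inhibitors have no eligible targets")
    return name, ("targets of planted-effect inhibitors", members)


def config_to_dict(cfg) -> dict:
    """JSON/YAML-serializable view of a simulation config."""
    d = dataclasses.asdict(cfg)
    if "planted_effects" in d:
        d["planted_effects"] = [
            {
                "inhibitor": e["inhibitor"],
                "process": e["process"],
                "groups": list(e["groups"]),
                "effect_size": e["effect_size"],
            }
            for e in d["planted_effects"]
        ]
    return d
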