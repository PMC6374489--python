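"""Domain model shared by every pipeline stage.

A screen is stored as a wide, long-format table: one row per well, one
column per homeostatic process.  The ten processes form a closed default
vocabulary (extendable via :data:`PROCESSES` hooks in readers): per-well
survival (cell count relative to control), the apoptotic fraction, the
three cell-cycle phase fractions, and five FSC-A size readouts (all cells,
per-phase, and apoptotic cells).  Fractions are stored in [0, 1]; readers
convert percent columns on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The ten homeostatic processes measured per well, in canonical order.
PROCESSES: tuple[str, ...] = (
    "survival",
    "apoptosis_fraction",
    "g1_fraction",
    "s_fraction",
    "g2m_fraction",
    "size_all",
    "size_g1",
    "size_s",
    "size_g2m",
    "size_apoptotic",
)

FRACTION_PROCESSES: tuple[str, ...] = (
    "apoptosis_fraction",
    "g1_fraction",
    "s_fraction",
    "g2m_fraction",
)

SIZE_PROCESSES: tuple[str, ...] = (
    "size_all",
    "size_g1",
    "size_s",
    "size_g2m",
    "size_apoptotic",
)

#: Fraction process -> size process that must be positive when the fraction is.
_FRACTION_TO_SIZE: dict[str, str] = {
    "g1_fraction": "size_g1",
    "s_fraction": "size_s",
    "g2m_fraction": "size_g2m",
    "apoptosis_fraction": "size_apoptotic",
}

#: Control condition labels.  "vehicle" is the DMSO carrier control.
CONTROL_KINDS: tuple[str, ...] = ("untreated", "vehicle")

DEFAULT_GROUPS: tuple[str, ...] = ("ESC", "IPSC", "AFSC")

#: Columns identifying a well, in interchange-file order.
WELL_ID_COLUMNS: tuple[str, ...] = (
    "plate_id",
    "well",
    "cell_line",
    "group",
    "replicate",
    "condition",
)

CYCLE_SUM_TOLERANCE = 1e-6


@dataclass(frozen=True)
class WellMeasurement:
    """A single well's summary measurements of the ten processes."""

    plate_id: str
    well: str
    cell_line: str
    group: str
    replicate: int
    condition: str
    parameters: Mapping[str, float]

    @property
    def is_control(self) -> bool:
        return self.condition in CONTROL_KINDS

    def violations(self) -> list[str]:
        """Invariant violations for this well (empty list = valid)."""
        out: list[str] = []
        tag = f"{self.plate_id}/{self.well}"
        if self.replicate < 1:
            out.append(f"{tag}: replicate must be >= 1, got {self.replicate}")
        for name in FRACTION_PROCESSES:
            v = self.parameters.get(name)
            if v is not None and not (0.0 <= v <= 1.0):
                out.append(f"{tag}: {name}={v} outside [0, 1]")
        cyc = sum(
            self.parameters.get(k, 0.0)
            for k in ("g1_fraction", "s_fraction", "g2m_fraction")
        )
        if cyc > 1.0 + CYCLE_SUM_TOLERANCE:
            out.append(f"{tag}: cell-cycle fractions sum to {cyc:.6g} > 1")
        for frac, size in _FRACTION_TO_SIZE.items():
            f = self.parameters.get(frac)
            s = self.parameters.get(size)
            if f is not None and s is not None and f > 0 and not s > 0:
                out.append(f"{tag}: {size}={s} must be > 0 when {frac} > 0")
        for name in SIZE_PROCESSES + ("survival",):
            v = self.parameters.get(name)
            if v is not None and v < 0:
                out.append(f"{tag}: {name}={v} negative")
        return out


@dataclass
class ScreenDataset:
    """A full screen: wells table + ordered condition/group bookkeeping.

    ``wells`` has one row per well with the identifier columns of
    :data:`WELL_ID_COLUMNS` followed by one column per process.
    """

    wells: pd.DataFrame
    conditions: list[str]
    groups: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in WELL_ID_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"wells table missing columns: {missing}")

    @property
    def processes(self) -> list[str]:
        return [p for p in PROCESSES if p in self.wells.columns] + [
            c
            for c in self.wells.columns
            if c not in WELL_ID_COLUMNS and c not in PROCESSES
        ]

    def control_wells(self, kind: str | None = None) -> pd.DataFrame:
        kinds = CONTROL_KINDS if kind is None else (kind,)
        return self.wells[self.wells["condition"].isin(kinds)]

    def inhibitor_wells(self) -> pd.DataFrame:
        return self.wells[~self.wells["condition"].isin(CONTROL_KINDS)]

    def iter_wells(self) -> Iterable[WellMeasurement]:
        procs = self.processes
        for row in self.wells.itertuples(index=False):
            d = row._asdict()
            yield WellMeasurement(
                plate_id=str(d["plate_id"]),
                well=str(d["well"]),
                cell_line=str(d["cell_line"]),
                group=str(d["group"]),
                replicate=int(d["replicate"]),
                condition=str(d["condition"]),
                parameters={p: d[p] for p in procs if p in d},
            )


def validate_dataset(ds: ScreenDataset) -> list[str]:
    """Collect invariant violations; an empty list means the dataset is valid.

    Checks per-well invariants, uniqueness of (cell_line, replicate,
    condition) per plate, and the presence of at least one control well of
    each kind on every plate.
    """
    violations: list[str] = []
    for w in ds.iter_wells():
        violations.extend(w.violations())

    # uniqueness applies to inhibitor conditions; replicate control wells of
    # the same kind on a plate are expected (>= 2 per kind by design)
    inhib = ds.wells[~ds.wells["condition"].isin(CONTROL_KINDS)]
    dup = inhib.duplicated(
        subset=["plate_id", "cell_line", "replicate", "condition"], keep=False
    )
    if dup.any():
        for _, r in inhib[dup].iterrows():
            violations.append(
                f"{r['plate_id']}/{r['well']}: duplicate "
                f"(cell_line={r['cell_line']}, replicate={r['replicate']}, "
                f"condition={r['condition']}) on plate {r['plate_id']}"
            )

    for plate, sub in ds.wells.groupby("plate_id", sort=False):
        for kind in CONTROL_KINDS:
            if not (sub["condition"] == kind).any():
                violations.append(f"no {kind} control on plate {plate}")
    return violations


@dataclass
class TargetMap:
    """Inhibitor -> validated targets with maximal effective concentration.

    ``entries`` maps an inhibitor name to a list of
    ``(gene_symbol, max_effective_uM)`` pairs.  Gene symbols are upper-cased
    and whitespace-stripped at construction; no alias resolution is done.
    """

    entries: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        clean: dict[str, list[tuple[str, float]]] = {}
        for inh, targets in self.entries.items():
            rows = []
            for gene, conc in targets:
                g = str(gene).strip().upper()
                if not g:
                    raise ValueError(f"empty gene symbol for inhibitor {inh!r}")
                if not conc > 0:
                    raise ValueError(
                        f"non-positive concentration {conc} for {inh!r}/{g}"
                    )
                rows.append((g, float(conc)))
            clean[str(inh)] = rows
        self.entries = clean

    def targets_within(self, inhibitor: str, ceiling_uM: float) -> list[str]:
        """Target genes of ``inhibitor`` effective at <= ``ceiling_uM``."""
        return [g for g, c in self.entries.get(inhibitor, []) if c <= ceiling_uM]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (inh, g, c)
            for inh, targets in self.entries.items()
            for g, c in targets
        ]
        return pd.DataFrame(rows, columns=["inhibitor", "gene", "max_uM"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TargetMap":
        entries: dict[str, list[tuple[str, float]]] = {}
        for r in df.itertuples(index=False):
            entries.setdefault(str(r.inhibitor), []).append(
                (str(r.gene), float(r.max_uM))
            )
        return cls(entries)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def sizes(self) -> dict[str, int]:
        return {n: len(g) for n, (_d, g) in self.sets.items()}

    def universe(self) -> set[str]:
        out: set[str] = set()
        for _d, genes in self.sets.values():
            out.update(genes)
        return out


def sample_label(cell_line: str, replicate: int) -> str:
    """Canonical flat label for a (cell line, replicate) sample column."""
    return f"{cell_line}|r{int(replicate)}"


def split_sample_label(label: str) -> tuple[str, int]:
    cell_line, rep = label.rsplit("|r", 1)
    return cell_line, int(rep)
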