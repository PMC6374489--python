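"""Readers and writers for the tabular interchange formats.

Screen tables are UTF-8 TSV, one row per well (wide: one column per
process).  Fractions are stored in [0, 1]; columns suffixed ``_pct`` or a
``percent=True`` flag are converted on read.  Gene sets use GMT
(name TAB description TAB genes...), ranked lists use RNK (gene TAB
metric, descending), target maps a three-column TSV
(inhibitor, gene, max_uM).  z and delta-z matrices are written one TSV per
process with condition rows and sample columns plus a provenance sidecar
JSON recording the standardization constants.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_types import (
    FRACTION_PROCESSES,
    WELL_ID_COLUMNS,
    GeneSetCollection,
    ScreenDataset,
    TargetMap,
)
from .normalization import DeltaZMatrix, ZScoreMatrix
from .target_expansion import RankedGeneList


# -- screen tables ----------------------------------------------------------

def write_screen_table(ds: ScreenDataset, path) -> None:
    cols = list(WELL_ID_COLUMNS) + ds.processes
    ds.wells[cols].to_csv(path, sep="\t", index=False)


def read_screen_table(
    path,
    conditions: list[str] | None = None,
    groups: list[str] | None = None,
    percent: bool = False,
) -> ScreenDataset:
    wells = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if percent:
        for c in FRACTION_PROCESSES:
            if c in wells.columns:
                wells[c] = wells[c] / 100.0
    from .core_types import CONTROL_KINDS

    if conditions is None:
        conditions = [
            c for c in wells["condition"].drop_duplicates() if c not in CONTROL_KINDS
        ]
    if groups is None:
        groups = list(wells["group"].drop_duplicates())
    return ScreenDataset(wells=wells, conditions=conditions, groups=groups)


# -- target maps ------------------------------------------------------------

def write_target_map(tmap: TargetMap, path) -> None:
    tmap.to_frame().to_csv(path, sep="\t", index=False)


def read_target_map(path) -> TargetMap:
    df = pd.read_csv(path, sep="\t")
    required = {"inhibitor", "gene", "max_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"target map must have columns {sorted(required)}")
    return TargetMap.from_frame(df)


# -- GMT --------------------------------------------------------------------

def read_gmt(path) -> tuple[GeneSetCollection, list[str]]:
    """Parse a GMT file; returns the collection and dedup warnings."""
    warnings: list[str] = []
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
        name, desc, *genes = fields
        genes = [g.strip().upper() for g in genes if g.strip()]
        seen: list[str] = []
        for g in genes:
            if g in seen:
                warnings.append(f"{path}:{lineno}: duplicate gene {g!r} in {name!r} dropped")
            else:
                seen.append(g)
        sets[name] = (desc, seen)
    return GeneSetCollection(sets), warnings


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc, genes = collection.sets[name]
            fh.write("\t".join([name, desc, *genes]) + "\n")


# -- RNK --------------------------------------------------------------------

def write_rnk(rl: RankedGeneList, path) -> None:
    """Two-column gene TAB metric, descending, full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene, metric in zip(rl.genes, rl.metrics):
            fh.write(f"{gene}\t{float(metric)!r}\n")


def read_rnk(path, comparison: str = "", process: str = "") -> RankedGeneList:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: RNK line needs 2 fields")
            rows.append((parts[0], float(parts[1])))
    if not rows:
        raise ValueError(f"empty RNK file: {path}")
    table = pd.DataFrame(rows, columns=["gene", "metric"])
    return RankedGeneList(table=table, comparison=comparison, process=process)


# -- z / delta-z matrices ---------------------------------------------------

def write_z_matrices(z: ZScoreMatrix | DeltaZMatrix, outdir, prefix: str = "z") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for process, mat in z.data.items():
        mat.to_csv(outdir / f"{prefix}_{process}.tsv", sep="\t", index_label="condition")
    sidecar: dict = {"samples": z.samples.reset_index().to_dict("records")}
    if isinstance(z, ZScoreMatrix):
        sidecar["scope"] = z.scope
        sidecar["provenance"] = {
            p: prov.reset_index().to_dict("records") for p, prov in z.provenance.items()
        }
    else:
        sidecar["control_condition"] = z.control_condition
    with open(outdir / f"{prefix}_provenance.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_z_matrices(outdir, prefix: str = "z") -> ZScoreMatrix:
    outdir = Path(outdir)
    with open(outdir / f"{prefix}_provenance.json", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    samples = pd.DataFrame(sidecar["samples"]).set_index("sample")
    data = {}
    provenance = {}
    for f in sorted(outdir.glob(f"{prefix}_*.tsv")):
        process = f.stem[len(prefix) + 1 :]
        data[process] = pd.read_csv(
            f, sep="\t", index_col="condition", float_precision="round_trip"
        )
    for p, rows in sidecar.get("provenance", {}).items():
        provenance[p] = pd.DataFrame(rows).set_index("scope_key")
    return ZScoreMatrix(
        data=data,
        samples=samples,
        provenance=provenance,
        scope=sidecar.get("scope", "cell_line"),
    )


# -- misc -------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
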