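"""Plate normalization, z-score transformation, and delta-z formation.

Raw well values are first divided by the same-plate control mean for each
process (so control wells normalize to ~1 on average), then standardized to
z = (x - mu) / sigma where mu and sigma are taken over all values of one
process within a scoping population, and finally converted to delta-z by
subtracting the control condition's z-score sample-wise.

The default scoping population is one cell line's plate series (all
conditions x all replicates of that line for one process); per-group and
global scoping are available.  sigma uses the sample (n-1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_types import (
    CONTROL_KINDS,
    ScreenDataset,
    sample_label,
)

Z_SCOPES = ("cell_line", "group", "global")


@dataclass
class ZScoreMatrix:
    """Per-process condition x sample matrices of z-scores.

    ``data`` maps process -> DataFrame with condition rows (inhibitors and
    controls) and sample columns labelled ``cell_line|r<replicate>``.
    ``samples`` carries one row per sample column: cell_line, replicate,
    group.  ``provenance`` maps process -> DataFrame (scope key rows, mu and
    sigma columns) recording the standardization constants.
    """

    data: dict[str, pd.DataFrame]
    samples: pd.DataFrame
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)
    scope: str = "cell_line"

    @property
    def processes(self) -> list[str]:
        return list(self.data)

    @property
    def conditions(self) -> list[str]:
        first = next(iter(self.data.values()))
        return list(first.index)

    def inhibitor_conditions(self) -> list[str]:
        return [c for c in self.conditions if c not in CONTROL_KINDS]


@dataclass
class DeltaZMatrix:
    """Inhibitor-only condition x sample matrices of delta-z scores."""

    data: dict[str, pd.DataFrame]
    samples: pd.DataFrame
    control_condition: str = "vehicle"

    @property
    def processes(self) -> list[str]:
        return list(self.data)


def normalize_to_controls(
    ds: ScreenDataset, control_kind: str = "vehicle"
) -> ScreenDataset:
    """Divide each well's parameters by the same-plate control mean.

    Plates hold a single cell line in the reference design; grouping is by
    (plate, cell line) so mixed plates are still normalized within-line.
    """
    if control_kind not in CONTROL_KINDS:
        raise ValueError(f"unknown control kind {control_kind!r}")
    processes = ds.processes
    wells = ds.wells.copy()
    key = ["plate_id", "cell_line"]
    ctrl_means = (
        wells[wells["condition"] == control_kind].groupby(key)[processes].mean()
    )
    plates = wells[key].drop_duplicates()
    missing = plates[
        ~pd.MultiIndex.from_frame(plates).isin(ctrl_means.index)
    ]
    if len(missing):
        plate, line = missing.iloc[0]
        raise ValueError(f"no {control_kind} control on plate {plate} for {line}")
    bad = (ctrl_means == 0) | ~np.isfinite(ctrl_means)
    if bad.to_numpy().any():
        loc = np.argwhere(bad.to_numpy())[0]
        plate = ctrl_means.index[loc[0]]
        proc = ctrl_means.columns[loc[1]]
        raise ValueError(f"control mean for process {proc!r} on plate {plate} is not positive")
    denom = ctrl_means.loc[pd.MultiIndex.from_frame(wells[key])].to_numpy()
    wells[processes] = wells[processes].to_numpy() / denom
    out = ScreenDataset(
        wells=wells,
        conditions=list(ds.conditions),
        groups=list(ds.groups),
        metadata={**ds.metadata, "normalized_to": control_kind},
    )
    return out


def _pivot(ds: ScreenDataset, process: str) -> pd.DataFrame:
    """Condition x sample matrix of one process (control wells averaged)."""
    w = ds.wells
    tab = w.pivot_table(
        index="condition",
        columns=["cell_line", "replicate"],
        values=process,
        aggfunc="mean",
    )
    tab.columns = [sample_label(cl, rep) for cl, rep in tab.columns]
    order = [c for c in ds.conditions if c in tab.index] + [
        k for k in CONTROL_KINDS if k in tab.index
    ]
    return tab.loc[order]


def _sample_table(ds: ScreenDataset) -> pd.DataFrame:
    s = (
        ds.wells[["cell_line", "replicate", "group"]]
        .drop_duplicates()
        .sort_values(["cell_line", "replicate"])
        .reset_index(drop=True)
    )
    s["sample"] = [sample_label(cl, r) for cl, r in zip(s["cell_line"], s["replicate"])]
    return s.set_index("sample")


def zscore(ds: ScreenDataset, scope: str = "cell_line") -> ZScoreMatrix:
    """Standardize normalized values per process over the scoping population.

    scope:
      * ``cell_line`` (default) — mu, sigma over all conditions x replicates
        of one cell line, per process;
      * ``group`` — pooled over the cell lines of one group;
      * ``global`` — pooled over every sample.
    """
    if scope not in Z_SCOPES:
        raise ValueError(f"unknown z-score scope {scope!r}")
    samples = _sample_table(ds)
    data: dict[str, pd.DataFrame] = {}
    provenance: dict[str, pd.DataFrame] = {}
    for p in ds.processes:
        mat = _pivot(ds, p)
        mat = mat[[c for c in samples.index if c in mat.columns]]
        z = pd.DataFrame(index=mat.index, columns=mat.columns, dtype=float)
        prov_rows = []
        if scope == "cell_line":
            keys = samples.groupby("cell_line").groups
        elif scope == "group":
            keys = samples.groupby("group").groups
        else:
            keys = {"global": samples.index}
        for key, cols in keys.items():
            cols = [c for c in cols if c in mat.columns]
            block = mat[cols].to_numpy(dtype=float)
            vals = block[np.isfinite(block)]
            if np.unique(vals).size < 2:
                raise ValueError(
                    f"process {p!r}, scope {key!r}: need >= 2 distinct values"
                )
            mu = float(vals.mean())
            sigma = float(vals.std(ddof=1))
            if sigma == 0:
                raise ValueError(f"process {p!r}, scope {key!r}: zero variance")
            z[cols] = (mat[cols] - mu) / sigma
            prov_rows.append({"scope_key": str(key), "mu": mu, "sigma": sigma})
        data[p] = z
        provenance[p] = pd.DataFrame(prov_rows).set_index("scope_key")
    return ZScoreMatrix(data=data, samples=samples, provenance=provenance, scope=scope)


def zscore_values(values) -> np.ndarray:
    """z-standardize a plain vector (sample sd); raises on zero sigma."""
    x = np.asarray(values, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValueError("need >= 2 distinct values")
    sigma = x.std(ddof=1)
    if sigma == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sigma


def delta_z(z: ZScoreMatrix, control_condition: str = "vehicle") -> DeltaZMatrix:
    """Subtract the control condition's z-scores sample-wise.

    The result is restricted to inhibitor conditions; by construction the
    delta-z of the chosen control itself is identically zero.
    """
    out: dict[str, pd.DataFrame] = {}
    for p, mat in z.data.items():
        if control_condition not in mat.index:
            raise ValueError(
                f"control condition {control_condition!r} missing for process {p!r}"
            )
        ctrl = mat.loc[control_condition]
        inhib = [c for c in mat.index if c not in CONTROL_KINDS]
        out[p] = mat.loc[inhib].sub(ctrl, axis=1)
    return DeltaZMatrix(data=out, samples=z.samples, control_condition=control_condition)
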