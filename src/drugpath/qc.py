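"""Numeric screen quality control on z-scores.

Three views of assay reliability: concordance of technical replicates
(Pearson r of z-scores between replicate pairs over all conditions),
intra-plate variability (median and SEM of z per sample), and inter-plate
alignment (per-plate z medians and the largest pairwise median gap).

Pass thresholds are configuration values — replicate r >= 0.8 and maximum
|median difference| <= 0.5 by default — since the original analysis reports
only qualitative concordance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core_types import ScreenDataset, sample_label
from .normalization import ZScoreMatrix


@dataclass
class QCThresholds:
    min_replicate_r: float = 0.8
    max_interplate_median_diff: float = 0.5


@dataclass
class QCReport:
    replicate_correlations: pd.DataFrame
    intraplate: pd.DataFrame
    interplate: pd.DataFrame
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def replicate_pass(self) -> bool:
        r = self.replicate_correlations["pearson_r"].dropna()
        return bool((r >= self.thresholds.min_replicate_r).all()) if len(r) else False

    @property
    def interplate_pass(self) -> bool:
        d = self.interplate["max_abs_median_diff"].dropna()
        return bool((d <= self.thresholds.max_interplate_median_diff).all())

    def to_dict(self) -> dict:
        return {
            "replicate_correlations": self.replicate_correlations.to_dict("records"),
            "intraplate": self.intraplate.to_dict("records"),
            "interplate": self.interplate.to_dict("records"),
            "thresholds": {
                "min_replicate_r": self.thresholds.min_replicate_r,
                "max_interplate_median_diff": self.thresholds.max_interplate_median_diff,
            },
            "replicate_pass": self.replicate_pass,
            "interplate_pass": self.interplate_pass,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary_text(self) -> str:
        lines = ["Screen quality control"]
        r = self.replicate_correlations["pearson_r"].dropna()
        if len(r):
            lines.append(
                f"  replicate concordance: r in [{r.min():.3f}, {r.max():.3f}], "
                f"median {r.median():.3f} "
                f"({'PASS' if self.replicate_pass else 'FAIL'} at "
                f"r >= {self.thresholds.min_replicate_r})"
            )
        d = self.interplate["max_abs_median_diff"].dropna()
        if len(d):
            lines.append(
                f"  interplate alignment: max |median diff| {d.max():.3f} "
                f"({'PASS' if self.interplate_pass else 'FAIL'} at "
                f"<= {self.thresholds.max_interplate_median_diff})"
            )
        lines.append(f"  samples profiled: {len(self.intraplate)}")
        return "\n".join(lines)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN (missing) for constant vectors rather than 0."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def replicate_concordance(z: ZScoreMatrix) -> pd.DataFrame:
    """Pearson r between all replicate pairs per cell line and process."""
    rows = []
    reps_per_line = z.samples.groupby("cell_line")["replicate"].unique()
    for process, mat in z.data.items():
        for cell_line, reps in reps_per_line.items():
            reps = sorted(int(r) for r in reps)
            if len(reps) < 2:
                raise ValueError(f"cell line {cell_line!r} has < 2 replicates")
            for ra, rb in combinations(reps, 2):
                ca, cb = sample_label(cell_line, ra), sample_label(cell_line, rb)
                r = _pearson(mat[ca].to_numpy(), mat[cb].to_numpy())
                rows.append(
                    {
                        "process": process,
                        "cell_line": cell_line,
                        "replicate_a": ra,
                        "replicate_b": rb,
                        "pearson_r": r,
                        "n_conditions": int(mat[[ca, cb]].notna().all(axis=1).sum()),
                    }
                )
    return pd.DataFrame(rows)


def intraplate_stats(z: ZScoreMatrix) -> pd.DataFrame:
    """Median and SEM of z-scores per sample (cell line x replicate)."""
    rows = []
    for process, mat in z.data.items():
        for col in mat.columns:
            v = mat[col].dropna().to_numpy()
            if len(v) < 2:
                raise ValueError(f"sample {col!r} has < 2 values for {process!r}")
            rows.append(
                {
                    "process": process,
                    "sample": col,
                    "cell_line": z.samples.loc[col, "cell_line"],
                    "replicate": int(z.samples.loc[col, "replicate"]),
                    "median_z": float(np.median(v)),
                    "sem_z": float(np.std(v, ddof=1) / np.sqrt(len(v))),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def plate_assignment(ds: ScreenDataset) -> pd.DataFrame:
    """(condition, sample) -> plate lookup extracted from a dataset."""
    a = ds.wells[["plate_id", "condition", "cell_line", "replicate"]].drop_duplicates()
    a = a.copy()
    a["sample"] = [
        sample_label(cl, r) for cl, r in zip(a["cell_line"], a["replicate"])
    ]
    return a[["plate_id", "condition", "sample"]]


def interplate_stats(
    z: ZScoreMatrix,
    assignment: pd.DataFrame,
    max_median_diff: float = 0.5,
) -> pd.DataFrame:
    """Per-plate z medians and the maximum pairwise median gap per process."""
    plates = assignment["plate_id"].unique()
    if len(plates) < 2:
        raise ValueError("need >= 2 plates for inter-plate statistics")
    rows = []
    for process, mat in z.data.items():
        long = mat.reset_index(names="condition").melt(
            id_vars="condition", var_name="sample", value_name="z"
        )
        merged = long.merge(assignment, on=["condition", "sample"], how="inner")
        med = merged.groupby("plate_id")["z"].median()
        gap = float(med.max() - med.min()) if len(med) > 1 else float("nan")
        for plate, m in med.items():
            rows.append(
                {
                    "process": process,
                    "plate_id": plate,
                    "median_z": float(m),
                    "max_abs_median_diff": gap,
                    "pass": bool(gap <= max_median_diff),
                }
            )
    return pd.DataFrame(rows)


def qc_report(
    z: ZScoreMatrix,
    assignment: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    thresholds = thresholds or QCThresholds()
    return QCReport(
        replicate_correlations=replicate_concordance(z),
        intraplate=intraplate_stats(z),
        interplate=interplate_stats(
            z, assignment, thresholds.max_interplate_median_diff
        ),
        thresholds=thresholds,
    )
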