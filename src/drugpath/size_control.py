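"""Cell-size-control analysis: sphere geometry, added size, model slopes.

Per-phase FSC-A readouts are converted to radius, volume and surface area
under the assumption that cells in suspension are spherical.  The readout
convention decides the mapping (default "area": FSC-A proportional to the
cross-sectional area, r = sqrt(readout / pi); alternatives treat the
readout as a diameter or as a volume).  For a sphere SA/V = 3/r exactly.

'Added size' dV = V_G2 - V_G1 regressed on birth volume V_G1 classifies
the size-control strategy: slope +1 is a perfect timer (fixed fold-growth),
0 a perfect adder (fixed added volume), -1 a perfect sizer (fixed division
volume).  A qualifier grades distance from the nearest ideal slope
(<= 0.1 perfect, <= 0.25 near, else moderate).  Sizer-like populations also
show larger added-size variance than adders under equal birth spread, which
an F ratio test quantifies.  Treatment-induced shrinkage is read out as an
increase of the G1-phase SA/V ratio relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SPHERE_CONVENTIONS = ("area", "diameter", "volume")

QUALIFIER_BANDS = ((0.1, "perfect"), (0.25, "near"))
MODEL_SLOPES = (("adder", 0.0), ("sizer", -1.0), ("timer", 1.0))


def sphere_from_readout(readout, convention: str = "area"):
    """(radius, volume, surface area) of spheres from a size readout.

    * ``area``: readout is a cross-sectional area, r = sqrt(readout / pi)
    * ``diameter``: readout is a diameter, r = readout / 2
    * ``volume``: readout is a volume, r = (3 readout / 4 pi)^(1/3)
    """
    x = np.asarray(readout, dtype=float)
    if np.any(x <= 0):
        raise ValueError("size readouts must be positive")
    if convention == "area":
        r = np.sqrt(x / np.pi)
    elif convention == "diameter":
        r = x / 2.0
    elif convention == "volume":
        r = (3.0 * x / (4.0 * np.pi)) ** (1.0 / 3.0)
    else:
        raise ValueError(f"unknown sphere convention {convention!r}")
    volume = (4.0 / 3.0) * np.pi * r**3
    surface = 4.0 * np.pi * r**2
    return r, volume, surface


def size_records(
    sizes: pd.DataFrame, convention: str = "area"
) -> tuple[pd.DataFrame, list[str]]:
    """Derive per-condition sphere geometry and added sizes.

    ``sizes`` needs columns condition, group, size_g1, size_g2m (per-phase
    readouts, e.g. per-condition well means).  Rows missing a phase are
    skipped and reported in the second return value.
    """
    required = {"condition", "group", "size_g1", "size_g2m"}
    missing_cols = required - set(sizes.columns)
    if missing_cols:
        raise ValueError(f"sizes table missing columns: {sorted(missing_cols)}")
    skipped: list[str] = []
    ok = sizes["size_g1"].notna() & sizes["size_g2m"].notna()
    for row in sizes[~ok].itertuples(index=False):
        skipped.append(f"{row.condition}/{row.group}: missing phase size")
    rec = sizes[ok].copy().reset_index(drop=True)
    for phase, col in (("g1", "size_g1"), ("g2", "size_g2m")):
        r, v, sa = sphere_from_readout(rec[col].to_numpy(), convention)
        rec[f"radius_{phase}"] = r
        rec[f"volume_{phase}"] = v
        rec[f"surface_{phase}"] = sa
        rec[f"sav_{phase}"] = sa / v
    rec["delta_v"] = rec["volume_g2"] - rec["volume_g1"]
    rec["delta_sa"] = rec["surface_g2"] - rec["surface_g1"]
    return rec, skipped


def added_size(records: pd.DataFrame) -> pd.DataFrame:
    """Added volume and surface per (condition, group)."""
    return records[["condition", "group", "delta_v", "delta_sa"]].copy()


@dataclass
class SizeModelFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    classification: str
    qualifier: str
    added_variance: float
    r_value: float
    n: int


def _classify(slope: float) -> tuple[str, str]:
    best_name, best_dist = None, np.inf
    for name, ideal in MODEL_SLOPES:
        d = abs(slope - ideal)
        if d < best_dist:  # strict: evaluation order breaks exact ties
            best_name, best_dist = name, d
    for band, label in QUALIFIER_BANDS:
        if best_dist <= band:
            return best_name, label
    return best_name, "moderate"


def fit_size_model(
    birth_volumes, added_volumes, confidence: float = 0.95
) -> SizeModelFit:
    """OLS of added volume on birth volume + slope-based classification."""
    x = np.asarray(birth_volumes, dtype=float)
    y = np.asarray(added_volumes, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 conditions to fit a size model")
    if np.std(x) == 0:
        raise ValueError("birth volumes have zero variance")
    fit = stats.linregress(x, y)
    if fit.stderr > 0:
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=x.size - 2)
        ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    else:
        ci = (fit.slope, fit.slope)
    classification, qualifier = _classify(fit.slope)
    return SizeModelFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci=(float(ci[0]), float(ci[1])),
        classification=classification,
        qualifier=qualifier,
        added_variance=float(np.var(y, ddof=1)),
        r_value=float(fit.rvalue),
        n=int(x.size),
    )


def birth_division_correlation(
    birth_sizes, division_sizes, doubling_tolerance: float = 0.25
) -> dict:
    """OLS slope and Pearson r of division size on birth size.

    ``normal_doubling`` flags a slope within ``doubling_tolerance`` of +1
    on the readout scale (regular growth through the cycle).
    """
    x = np.asarray(birth_sizes, dtype=float)
    y = np.asarray(division_sizes, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 conditions")
    if np.std(x) == 0:
        raise ValueError("birth sizes have zero variance")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r": float(fit.rvalue),
        "normal_doubling": bool(abs(fit.slope - 1.0) <= doubling_tolerance),
        "n": int(x.size),
    }


def added_size_variance(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group added-size variances with two-sided variance-ratio tests."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    variances = {}
    counts = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 added sizes")
        variances[name] = float(np.var(v, ddof=1))
        counts[name] = v.size
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if variances[b] == 0:
                raise ValueError(f"zero variance in denominator group {b!r}")
            f_stat = variances[a] / variances[b]
            dfa, dfb = counts[a] - 1, counts[b] - 1
            cdf = stats.f.cdf(f_stat, dfa, dfb)
            p = 2.0 * min(cdf, 1.0 - cdf)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "var_a": variances[a],
                    "var_b": variances[b],
                    "f_statistic": f_stat,
                    "p": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


def sav_shift(
    records: pd.DataFrame,
    treated_conditions,
    control_conditions,
) -> pd.DataFrame:
    """Per-group change in mean G1 SA/V between treated and control arms.

    Shift = mean(SA/V | treated) - mean(SA/V | control); Welch's t-test
    quantifies the contrast when both arms have >= 2 records.
    """
    treated_conditions = set(treated_conditions)
    control_conditions = set(control_conditions)
    rows = []
    for group, sub in records.groupby("group", sort=True):
        tr = sub[sub["condition"].isin(treated_conditions)]["sav_g1"].to_numpy()
        ct = sub[sub["condition"].isin(control_conditions)]["sav_g1"].to_numpy()
        if tr.size == 0 or ct.size == 0:
            raise ValueError(f"group {group!r} is missing a treatment arm")
        if tr.size >= 2 and ct.size >= 2:
            t, p = stats.ttest_ind(tr, ct, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "group": group,
                "mean_sav_treated": float(tr.mean()),
                "mean_sav_control": float(ct.mean()),
                "shift": float(tr.mean() - ct.mean()),
                "ratio": float(tr.mean() / ct.mean()),
                "t": float(t) if np.isfinite(t) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "n_treated": int(tr.size),
                "n_control": int(ct.size),
            }
        )
    return pd.DataFrame(rows)
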