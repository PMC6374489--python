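"""Statistical discrimination of effective vs non-effective inhibitors.

For every inhibitor, process, and unordered pair of stem-cell groups a
two-sample t-test compares the groups' z-scores (Welch by default; a
pooled-variance variant mirrors classic pairwise testing).  p-values are
Benjamini-Hochberg adjusted within one (process, group pair) family across
inhibitors, and a condition is a hit when the adjusted p falls below alpha
(default 0.01) AND at least one group's mean z-score clears the noise
cutoff (default |z| >= 2) in an eligible direction.  For the apoptosis
readout only increases (z above noise) are eligible, since a decrease in
apoptotic cells below the already-low baseline is not a scorable response.

ESC and IPSC samples may be consolidated into a single "ESC/IPSC" group
prior to testing, matching the two-population comparison the downstream
enrichment stage expects.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import DeltaZMatrix, ZScoreMatrix

DEFAULT_ALPHA = 0.01
DEFAULT_NOISE_CUTOFF = 2.0

#: process -> eligible hit direction ("above", "below", or "both")
DEFAULT_DIRECTION_POLICY: dict[str, str] = {"apoptosis_fraction": "above"}

_VALID_DIRECTIONS = ("above", "below", "both")


def consolidate_groups(
    samples: pd.DataFrame,
    merge: tuple[str, ...] = ("ESC", "IPSC"),
    name: str = "ESC/IPSC",
) -> pd.DataFrame:
    """Relabel the given groups as one consolidated group."""
    out = samples.copy()
    out.loc[out["group"].isin(merge), "group"] = name
    return out


def group_tests(
    z: ZScoreMatrix,
    samples: pd.DataFrame | None = None,
    equal_var: bool = False,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sample t-tests per (inhibitor, process, unordered group pair).

    ``equal_var=False`` (default) runs Welch's test; ``True`` the
    pooled-variance test.  Zero variance in both groups leaves the test
    undefined (NaN p, reported missing rather than 0 or 1).  ``group_order``
    fixes which group of a pair is reported first (hence the sign of
    downstream metric differences); default is order of appearance.
    """
    samples = z.samples if samples is None else samples
    if group_order is None:
        groups = list(dict.fromkeys(samples["group"]))
    else:
        present = set(samples["group"])
        groups = [g for g in group_order if g in present]
        groups += [g for g in dict.fromkeys(samples["group"]) if g not in groups]
    cols_by_group = {
        g: [s for s in samples.index[samples["group"] == g]] for g in groups
    }
    for g, cols in cols_by_group.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    frames = []
    inhibitors = z.inhibitor_conditions()
    for process, mat in z.data.items():
        sub = mat.loc[inhibitors]
        for ga, gb in combinations(groups, 2):
            a = sub[cols_by_group[ga]].to_numpy(dtype=float)
            b = sub[cols_by_group[gb]].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                # scipy warns on constant inputs; those rows are discarded below
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
            # both groups constant -> test undefined, report missing
            degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
            t = np.where(degenerate, np.nan, t)
            p = np.where(degenerate, np.nan, p)
            frames.append(
                pd.DataFrame(
                    {
                        "condition": inhibitors,
                        "process": process,
                        "group_a": ga,
                        "group_b": gb,
                        "mean_z_a": a.mean(axis=1),
                        "mean_z_b": b.mean(axis=1),
                        "t": t,
                        "p": p,
                        "n_a": a.shape[1],
                        "n_b": b.shape[1],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving, clipped at 1; NaN entries are passed through and do
    not count toward the family size.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def call_hits(
    tests: pd.DataFrame,
    dz: DeltaZMatrix | None = None,
    alpha: float = DEFAULT_ALPHA,
    noise_cutoff: float = DEFAULT_NOISE_CUTOFF,
    direction_policy: dict[str, str] | None = None,
    adjust_scope: str = "per_comparison",
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag hits from test results, BH adjustment, and the noise cutoff.

    ``adjust_scope='per_comparison'`` (default) applies BH within one
    (process, group pair) family across inhibitors; ``'global'`` adjusts
    over all rows at once.  When a delta-z matrix is supplied each row also
    carries the group mean delta-z values used downstream as rank metrics.
    """
    policy = dict(DEFAULT_DIRECTION_POLICY)
    if direction_policy:
        known = set(tests["process"])
        for proc, d in direction_policy.items():
            if proc not in known:
                raise ValueError(f"direction policy names unknown process {proc!r}")
            if d not in _VALID_DIRECTIONS:
                raise ValueError(f"invalid direction {d!r} for process {proc!r}")
            policy[proc] = d

    out = tests.copy()
    if adjust_scope == "per_comparison":
        out["p_adj"] = np.nan
        for _, idx in out.groupby(["process", "group_a", "group_b"]).groups.items():
            out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"])
    elif adjust_scope == "global":
        out["p_adj"] = bh_adjust(out["p"])
    else:
        raise ValueError(f"unknown adjust scope {adjust_scope!r}")

    mza = out["mean_z_a"].to_numpy()
    mzb = out["mean_z_b"].to_numpy()
    directions = np.array(
        [policy.get(p, "both") for p in out["process"]], dtype=object
    )

    def eligible(mz: np.ndarray) -> np.ndarray:
        above = mz >= noise_cutoff
        below = mz <= -noise_cutoff
        both = np.abs(mz) >= noise_cutoff
        return np.where(
            directions == "above", above, np.where(directions == "below", below, both)
        ).astype(bool)

    passes_noise = eligible(mza) | eligible(mzb)
    significant = out["p_adj"].to_numpy() < alpha
    out["passes_noise"] = passes_noise
    out["hit"] = significant & passes_noise
    out["noise_filtered"] = significant & ~passes_noise

    # direction of the dominant (largest |mean z|) group response
    dominant = np.where(np.abs(mza) >= np.abs(mzb), mza, mzb)
    out["direction"] = np.where(dominant >= 0, "above", "below")
    out.loc[~out["hit"], "direction"] = ""

    if dz is not None:
        sample_table = dz.samples if samples is None else samples
        for suffix, col in (("a", "group_a"), ("b", "group_b")):
            out[f"delta_z_{suffix}"] = _group_mean_dz(out, dz, col, sample_table)
    return out


def _group_mean_dz(
    table: pd.DataFrame,
    dz: DeltaZMatrix,
    group_col: str,
    samples: pd.DataFrame,
) -> np.ndarray:
    cols_by_group = {
        g: list(samples.index[samples["group"] == g])
        for g in dict.fromkeys(table[group_col])
    }
    vals = np.full(len(table), np.nan)
    for (process, group), idx in table.groupby(
        ["process", group_col]
    ).groups.items():
        cols = cols_by_group.get(group, [])
        if not cols:
            continue
        mat = dz.data[process][cols].mean(axis=1)
        vals[table.index.get_indexer(idx)] = (
            mat.reindex(table.loc[idx, "condition"]).to_numpy()
        )
    return vals


def hit_summary(hits: pd.DataFrame) -> dict:
    """Counts of effective vs non-effective inhibitors per process/comparison."""
    out: dict = {}
    for (process, ga, gb), sub in hits.groupby(["process", "group_a", "group_b"]):
        out[f"{process}:{ga} vs {gb}"] = {
            "effective": int(sub["hit"].sum()),
            "noise_filtered": int(sub["noise_filtered"].sum()),
            "non_effective": int((~sub["hit"]).sum()),
            "tested": int(len(sub)),
        }
    return out
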