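"""Pre-ranked gene-set enrichment analysis (weighted running-sum statistic).

Given a ranked gene list with signed metrics and a gene-set collection, the
enrichment score (ES) of a set is the extremum of a running sum walked down
the list: meeting a set member ("hit") increments the sum by the member's
|metric|^p share of the total in-set weight (p = 1, the classic weighted
scheme, by default), and every non-member ("miss") decrements it by
1/(N - Nh).  A positive ES means the set concentrates at the head of the
list (first group of the comparison), a negative ES at the tail (second
group).  The leading edge collects the members at or before (ES > 0) or
strictly after (ES < 0) the extremum.

Significance comes from a gene-label permutation null: set membership is
redrawn uniformly over the ranked universe preserving set size (the
standard null for pre-ranked mode, where no sample-level phenotypes exist).
ES values are normalized to NES by the mean magnitude of same-sign null ES,
nominal p is the same-sign tail fraction, and FDR q follows the canonical
NES-ratio procedure over the pooled normalized null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .target_expansion import RankedGeneList

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_FDR_ALPHA = 0.25
DEFAULT_WEIGHT_EXPONENT = 1.0
DEFAULT_MIN_SET_SIZE = 3
DEFAULT_MAX_SET_SIZE = 500


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the FDR-passing subset."""

    table: pd.DataFrame
    passing: pd.DataFrame
    skipped: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _running_sum(
    hit_mask: np.ndarray, abs_metric_p: np.ndarray
) -> np.ndarray:
    """Running enrichment sum over the ranked universe."""
    n = hit_mask.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the universe")
    weights = abs_metric_p[hit_mask]
    total = weights.sum()
    steps = np.empty(n, dtype=float)
    if total > 0:
        steps[hit_mask] = weights / total
    else:  # all in-set metrics zero: fall back to equal hit mass
        steps[hit_mask] = 1.0 / n_hit
    steps[~hit_mask] = -1.0 / (n - n_hit)
    return np.cumsum(steps)


def _extremum(running: np.ndarray) -> tuple[float, int]:
    idx = int(np.argmax(np.abs(running)))  # first occurrence on ties
    return float(running[idx]), idx


def enrichment_score(
    rl: RankedGeneList,
    gene_set,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> tuple[float, np.ndarray, list[str]]:
    """(ES, running sum, leading-edge genes) for one gene set.

    Raises if the set misses the universe entirely or covers it completely.
    """
    genes = rl.genes
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    absm = np.abs(rl.metrics) ** weight_exponent
    running = _running_sum(hit_mask, absm)
    es, idx = _extremum(running)
    if es > 0:
        lead = [g for i, g in enumerate(genes) if hit_mask[i] and i <= idx]
    elif es < 0:
        lead = [g for i, g in enumerate(genes) if hit_mask[i] and i > idx]
    else:
        lead = []
    return es, running, lead


def permutation_null(
    rl: RankedGeneList,
    set_sizes: dict[str, int],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> dict[str, np.ndarray]:
    """Gene-permutation null ES distributions, one array per set.

    Membership is redrawn uniformly without replacement from the universe,
    preserving each set's size.  Reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(rl)
    absm = np.abs(rl.metrics) ** weight_exponent
    rng = np.random.default_rng(seed)
    nulls: dict[str, np.ndarray] = {}
    for name in sorted(set_sizes):
        size = set_sizes[name]
        out = np.empty(n_perm)
        for k in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=size, replace=False)] = True
            out[k], _ = _extremum(_running_sum(mask, absm))
        nulls[name] = out
    return nulls


def normalize_and_fdr(
    observed: pd.DataFrame, nulls: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Attach NES, nominal p, and FDR q to an observed ES table.

    NES divides ES by the mean magnitude of same-sign null ES of the same
    set.  Nominal p is the same-sign null tail fraction (an observed ES more
    extreme than every null is stored as p = 0 with ``p_underflow`` set).
    FDR q compares the same-sign tail share of the pooled normalized null
    with the corresponding share of observed NES values, clipped to [0, 1].
    """
    out = observed.copy()
    nes = np.full(len(out), np.nan)
    p_nom = np.full(len(out), np.nan)
    underflow = np.zeros(len(out), dtype=bool)
    flags = [""] * len(out)

    pos_means: dict[str, float] = {}
    neg_means: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for name, null in nulls.items():
        pos = null[null > 0]
        neg = null[null < 0]
        pos_means[name] = pos.mean() if pos.size else np.nan
        neg_means[name] = np.abs(neg).mean() if neg.size else np.nan
        parts = []
        if pos.size and np.isfinite(pos_means[name]):
            parts.append(pos / pos_means[name])
        if neg.size and np.isfinite(neg_means[name]):
            parts.append(neg / neg_means[name])
        if parts:
            null_nes_pool.append(np.concatenate(parts))
    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])

    for i, row in enumerate(out.itertuples(index=False)):
        name, es = row.name, row.es
        null = nulls.get(name)
        if null is None:
            flags[i] = "no_null"
            continue
        if es == 0:
            nes[i], p_nom[i] = 0.0, 1.0
            continue
        if es > 0:
            same = null[null > 0]
            denom = pos_means[name]
        else:
            same = null[null < 0]
            denom = neg_means[name]
        if same.size == 0 or not np.isfinite(denom):
            flags[i] = "no_same_sign_null"
            continue
        nes[i] = es / denom if es > 0 else -abs(es) / denom
        tail = (same >= es).sum() if es > 0 else (same <= es).sum()
        p_nom[i] = tail / same.size
        if tail == 0:
            underflow[i] = True

    out["nes"] = nes
    out["p_nominal"] = p_nom
    out["p_underflow"] = underflow

    obs_nes = out["nes"].to_numpy()
    q = np.full(len(out), np.nan)
    for i, v in enumerate(obs_nes):
        if not np.isfinite(v):
            continue
        if v == 0:
            q[i] = 1.0
            continue
        if v > 0:
            null_frac = (
                (pooled >= v).sum() / max((pooled > 0).sum(), 1)
                if pooled.size
                else np.nan
            )
            obs_pos = obs_nes[np.isfinite(obs_nes) & (obs_nes > 0)]
            obs_frac = (obs_pos >= v).sum() / obs_pos.size
        else:
            null_frac = (
                (pooled <= v).sum() / max((pooled < 0).sum(), 1)
                if pooled.size
                else np.nan
            )
            obs_neg = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
            obs_frac = (obs_neg <= v).sum() / obs_neg.size
        if np.isfinite(null_frac) and obs_frac > 0:
            q[i] = min(null_frac / obs_frac, 1.0)
    out["fdr_q"] = q
    out["flag"] = flags
    return out


def run_gsea(
    rl: RankedGeneList,
    collection,
    alpha_fdr: float = DEFAULT_FDR_ALPHA,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> EnrichmentResult:
    """Score a gene-set collection against a ranked list.

    Sets are restricted to the ranked universe and size-filtered
    (default 3..500 members after intersection); the full per-set table and
    the FDR < ``alpha_fdr`` subset are both returned.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(rl.genes)
    rows = []
    members_by_set: dict[str, list[str]] = {}
    leading: dict[str, list[str]] = {}
    skipped: list[str] = []
    for name in sorted(collection.sets):
        _desc, genes = collection.sets[name]
        members = sorted(universe.intersection(genes))
        if not members:
            skipped.append(f"{name}: no overlap with ranked universe")
            continue
        if len(members) == len(universe):
            skipped.append(f"{name}: covers the whole universe")
            continue
        if not (min_size <= len(members) <= max_size):
            skipped.append(f"{name}: size {len(members)} outside [{min_size}, {max_size}]")
            continue
        es, _running, lead = enrichment_score(rl, members, weight_exponent)
        members_by_set[name] = members
        leading[name] = lead
        rows.append({"name": name, "size": len(members), "es": es})
    if not rows:
        table = pd.DataFrame(
            columns=["name", "size", "es", "nes", "p_nominal", "fdr_q"]
        )
        return EnrichmentResult(table=table, passing=table, skipped=skipped)

    observed = pd.DataFrame(rows)
    nulls = permutation_null(
        rl,
        {r["name"]: r["size"] for r in rows},
        n_perm=n_perm,
        seed=seed,
        weight_exponent=weight_exponent,
    )
    table = normalize_and_fdr(observed, nulls)
    table["sign"] = np.sign(table["es"]).astype(int)
    table["leading_edge"] = [",".join(leading[n]) for n in table["name"]]
    table["members"] = [",".join(members_by_set[n]) for n in table["name"]]
    passing = table[table["fdr_q"] < alpha_fdr].reset_index(drop=True)
    return EnrichmentResult(
        table=table,
        passing=passing,
        skipped=skipped,
        params={
            "alpha_fdr": alpha_fdr,
            "n_perm": n_perm,
            "seed": seed,
            "weight_exponent": weight_exponent,
            "min_size": min_size,
            "max_size": max_size,
        },
    )
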