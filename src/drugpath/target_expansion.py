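"""Consolidate effective inhibitors with their validated targets.

Each effective inhibitor fans out to all of its validated target genes with
maximal effective concentration at or below the ceiling (default 5 uM).
Each gene inherits the inhibitor's signed rank metric — by default the
difference of group mean delta-z values of the comparison (first group
minus second group), so positive metrics mean "stronger response in the
first group".  When several inhibitors share a target the contributions are
collapsed by a configurable rule; the default keeps the signed value of the
largest magnitude.  The result is a hybrid gene/delta-z ranked list in
descending metric order, ready for pre-ranked enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_types import TargetMap

DEFAULT_CONCENTRATION_CEILING_UM = 5.0

AGGREGATION_RULES = ("signed_max", "mean", "sum")
METRIC_MODES = ("difference", "group_a")


@dataclass
class RankedGeneList:
    """Ordered (gene, metric) pairs with full contribution provenance."""

    table: pd.DataFrame  # columns: gene, metric; sorted by metric desc
    provenance: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    comparison: str = ""
    process: str = ""

    def __post_init__(self):
        t = self.table
        if t["gene"].duplicated().any():
            raise ValueError("ranked list contains duplicate genes")
        if not np.isfinite(t["metric"]).all():
            raise ValueError("ranked list metrics must be finite")
        expected = t.sort_values(
            ["metric", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        if not (
            expected["gene"].tolist() == t["gene"].tolist()
            and np.array_equal(expected["metric"].to_numpy(), t["metric"].to_numpy())
        ):
            self.table = expected

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def metrics(self) -> np.ndarray:
        return self.table["metric"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


def expand_hits(
    hits: pd.DataFrame,
    tmap: TargetMap,
    ceiling_uM: float = DEFAULT_CONCENTRATION_CEILING_UM,
    metric: str = "difference",
) -> tuple[dict[str, list[tuple[str, float]]], list[str]]:
    """Map target genes to (inhibitor, metric) contributions of the hits.

    ``hits`` must be restricted to one process and one comparison and
    contain only hit rows with delta-z columns.  Effective inhibitors absent
    from the target map are excluded with a warning record (second return
    value).  Targets above the concentration ceiling are dropped.
    """
    if metric not in METRIC_MODES:
        raise ValueError(f"unknown metric mode {metric!r}")
    if len(hits):
        if hits["process"].nunique() > 1:
            raise ValueError("hits span multiple processes; restrict to one")
        if hits[["group_a", "group_b"]].drop_duplicates().shape[0] > 1:
            raise ValueError("hits span multiple comparisons; restrict to one")

    gene_map: dict[str, list[tuple[str, float]]] = {}
    warnings: list[str] = []
    for row in hits.itertuples(index=False):
        inh = row.condition
        if metric == "difference":
            value = float(row.delta_z_a - row.delta_z_b)
        else:
            value = float(row.delta_z_a)
        genes = tmap.targets_within(inh, ceiling_uM)
        if inh not in tmap.entries:
            warnings.append(f"effective inhibitor {inh!r} missing from target map")
            continue
        if not genes:
            warnings.append(
                f"effective inhibitor {inh!r} has no targets at <= {ceiling_uM} uM"
            )
            continue
        for g in genes:
            gene_map.setdefault(g, []).append((inh, value))
    return gene_map, warnings


def _collapse(contribs: list[tuple[str, float]], rule: str) -> float:
    vals = np.array([v for _, v in contribs], dtype=float)
    if rule == "mean":
        return float(vals.mean())
    if rule == "sum":
        return float(vals.sum())
    # signed_max: value of the largest |metric|; ties prefer the positive
    # sign, then the lexicographically first inhibitor
    ranked = sorted(
        contribs, key=lambda iv: (-abs(iv[1]), -np.sign(iv[1]), iv[0])
    )
    return float(ranked[0][1])


def aggregate_to_ranked_list(
    gene_map: dict[str, list[tuple[str, float]]],
    rule: str = "signed_max",
    comparison: str = "",
    process: str = "",
) -> RankedGeneList:
    """Collapse per-gene contributions into one metric and order the list.

    Genes are sorted by metric descending with lexicographic gene-symbol
    tie-break, making the output invariant to input ordering.
    """
    if rule not in AGGREGATION_RULES:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    if not gene_map:
        raise ValueError("empty gene map: no effective inhibitors to rank")
    rows = [(g, _collapse(contribs, rule)) for g, contribs in gene_map.items()]
    table = (
        pd.DataFrame(rows, columns=["gene", "metric"])
        .sort_values(["metric", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return RankedGeneList(
        table=table,
        provenance={g: sorted(c) for g, c in gene_map.items()},
        comparison=comparison,
        process=process,
    )
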