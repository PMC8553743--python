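"""Network-level summaries of the HC-selected edge set.

Selected edges are classified into the six within/between-network categories
(DMN, ASN, LECN within; DMN-ASN, ASN-LECN, LECN-DMN between), split by the
sign of their worry association, and aggregated into a signed weighted
degree centrality: for each region, the sum of worry-standardized
coefficients of selected edges touching it, kept separate for positive and
negative associations to avoid cancellation.  These tables are the inputs a
chord diagram or brain map would render; rendering itself is out of scope.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import EdgeIndex

logger = logging.getLogger(__name__)

WITHIN_LABELS = ("DMN", "ASN", "LECN")
BETWEEN_LABELS = {
    frozenset({"DMN", "ASN"}): "DMN-ASN",
    frozenset({"ASN", "LECN"}): "ASN-LECN",
    frozenset({"LECN", "DMN"}): "LECN-DMN",
}
CATEGORY_ORDER = ["DMN", "ASN", "LECN", "DMN-ASN", "ASN-LECN", "LECN-DMN"]


def _edge_networks(selected, annotation: pd.DataFrame):
    index = EdgeIndex(len(annotation))
    node_net = annotation.sort_values("node_id")["network"].to_numpy()
    i, j = index.endpoints(selected.edge_ids)
    return i, j, node_net[i], node_net[j]


def edge_category(net_a: str, net_b: str) -> str:
    """Within-network label if the endpoints share a network, else the fixed
    unordered between-network label (endpoint order never matters)."""
    if net_a == net_b:
        if net_a not in WITHIN_LABELS:
            raise ValueError(f"unknown network {net_a!r}")
        return net_a
    key = frozenset({net_a, net_b})
    if key not in BETWEEN_LABELS:
        raise ValueError(f"unknown network pair {net_a!r}, {net_b!r}")
    return BETWEEN_LABELS[key]


def classify_edges(selected, annotation: pd.DataFrame) -> pd.DataFrame:
    """Count selected edges per network category and worry-association sign.

    Returns a 6-row frame (category, positive, negative); the 12 cells sum
    to the selected-set size.  Zero-coefficient edges count as positive with
    a warning.
    """
    counts = pd.DataFrame(0, index=CATEGORY_ORDER, columns=["positive", "negative"])
    if len(selected) == 0:
        return counts.rename_axis("category").reset_index()
    _, _, nets_i, nets_j = _edge_networks(selected, annotation)
    n_zero = int(np.sum(selected.sign == 0))
    if n_zero:
        logger.warning("%d selected edge(s) with zero coefficient counted as positive", n_zero)
    for a, b, s in zip(nets_i, nets_j, selected.sign):
        cat = edge_category(a, b)
        counts.loc[cat, "negative" if s < 0 else "positive"] += 1
    return counts.rename_axis("category").reset_index()


def signed_degree_centrality(
    selected, annotation: pd.DataFrame, level: str = "region_group"
) -> pd.DataFrame:
    """Signed weighted degree centrality of the selected edges.

    Each selected edge contributes its worry-standardized coefficient w to
    both endpoints: to the positive stratum if w > 0, else to the negative
    stratum.  ``level`` aggregates at 'node' or 'region_group'.
    """
    if level not in ("node", "region_group"):
        raise ValueError("level must be 'node' or 'region_group'")
    ann = annotation.sort_values("node_id").reset_index(drop=True)
    m = len(ann)
    pos = np.zeros(m)
    neg = np.zeros(m)
    if len(selected):
        index = EdgeIndex(m)
        i, j = index.endpoints(selected.edge_ids)
        w = selected.beta_std
        for arr in (i, j):
            np.add.at(pos, arr, np.where(w > 0, w, 0.0))
            np.add.at(neg, arr, np.where(w < 0, w, 0.0))
    if level == "node":
        regions = ann["node_id"].astype(str)
        df = pd.DataFrame({"region": regions, "positive_sum": pos, "negative_sum": neg})
    else:
        df = (
            pd.DataFrame({"region": ann["region_group"], "positive_sum": pos, "negative_sum": neg})
            .groupby("region", sort=True, as_index=False)
            .sum()
        )
    return df


def export_summary(
    selected,
    counts: pd.DataFrame,
    centrality: pd.DataFrame,
    annotation: pd.DataFrame,
    out_dir,
    decision=None,
) -> dict:
    """Write the plotting-ready summary bundle.

    Emits edges.csv (per-edge endpoints, networks, groups, effect, sign, p),
    table2.csv (category x sign counts), centrality.csv and summary.json.
    Rows are canonically ordered and floats fixed to 6 significant digits so
    re-exports of identical inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = annotation.sort_values("node_id").reset_index(drop=True)
    if len(selected):
        i, j, nets_i, nets_j = _edge_networks(selected, ann)
        groups = ann["region_group"].to_numpy()
        cats = [edge_category(a, b) for a, b in zip(nets_i, nets_j)]
        edges = pd.DataFrame(
            {
                "edge_id": selected.edge_ids,
                "node_i": i,
                "node_j": j,
                "network_i": nets_i,
                "network_j": nets_j,
                "region_group_i": groups[i],
                "region_group_j": groups[j],
                "beta_std": selected.beta_std,
                "sign": selected.sign,
                "p": selected.p,
                "category": cats,
            }
        ).sort_values(["category", "edge_id"], kind="stable")
    else:
        edges = pd.DataFrame(
            columns=[
                "edge_id", "node_i", "node_j", "network_i", "network_j",
                "region_group_i", "region_group_j", "beta_std", "sign", "p",
                "category",
            ]
        )
    edges.to_csv(out / "edges.csv", index=False, float_format="%.6g")
    counts.to_csv(out / "table2.csv", index=False)
    centrality.sort_values("region", kind="stable").to_csv(
        out / "centrality.csv", index=False, float_format="%.6g"
    )
    summary = {
        "n_selected": int(len(selected)),
        "i_star": int(selected.i_star) if len(selected) else 0,
        "category_totals": {
            row["category"]: {"positive": int(row["positive"]), "negative": int(row["negative"])}
            for _, row in counts.iterrows()
        },
    }
    if decision is not None:
        summary["hc_max"] = decision.hc_max
        summary["reject"] = decision.reject
        summary["threshold"] = decision.threshold
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
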