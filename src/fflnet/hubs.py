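"""Degree-based hub identification with per-class cutoffs.

Hubs are the highest-degree nodes of each molecular class.  The default
cutoff rule takes the top fraction (20%) of each class by degree with
ties included: the cutoff is the smallest observed degree d such that
the nodes of the class with degree ≥ d number at most fraction × class
size.  Because ties are included, a class whose degrees are all equal
yields no hubs rather than an arbitrary subset.  A manual mode lets the
caller impose fixed per-class cutoffs (e.g. the published 22/26/7 for
genes, miRNAs and TFs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import NodeClass

__all__ = ["HubReport", "hub_cutoffs", "identify_hubs"]


@dataclass
class HubReport:
    cutoffs: dict[NodeClass, int]
    hubs: pd.DataFrame  # columns: node_class, node, degree, cutoff

    def hub_nodes(self, cls: NodeClass | None = None) -> list[str]:
        df = self.hubs
        if cls is not None:
            df = df[df["node_class"] == cls.value]
        return df["node"].tolist()


def hub_cutoffs(
    degrees: pd.DataFrame,
    method: str = "top_fraction",
    fraction: float = 0.20,
    manual: Mapping[NodeClass, int] | None = None,
) -> dict[NodeClass, int]:
    """Per-class degree cutoff, by top-fraction rule or manual values.

    ``degrees`` is a degree table (columns node, node_class, degree).
    top_fraction: smallest observed degree whose ≥-d node count stays
    within fraction × class size (ties included); if no observed degree
    qualifies, the cutoff is max degree + 1 (no hubs in that class).
    manual: caller-supplied cutoffs, passed through for classes present.
    """
    if method == "manual":
        if manual is None:
            raise ValueError("manual method requires cutoffs")
        return dict(manual)
    if method != "top_fraction":
        raise ValueError(f"unknown method {method!r}")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")

    out: dict[NodeClass, int] = {}
    for cls in NodeClass:
        sub = degrees.loc[degrees["node_class"] == cls.value, "degree"]
        if sub.empty:
            continue
        budget = fraction * len(sub)
        cutoff = None
        for d in sorted(sub.unique()):
            if (sub >= d).sum() <= budget:
                cutoff = int(d)
                break
        out[cls] = cutoff if cutoff is not None else int(sub.max()) + 1
    return out


def identify_hubs(degrees: pd.DataFrame, cutoffs: Mapping[NodeClass, int]) -> HubReport:
    """Report every node meeting its class cutoff, sorted by class then
    descending degree (node id breaks ties deterministically)."""
    present = {NodeClass(c) for c in degrees["node_class"].unique()}
    missing = present - set(cutoffs)
    if missing:
        raise ValueError(f"no cutoff for class(es): {sorted(c.value for c in missing)}")

    rows = []
    for cls in NodeClass:
        if cls not in cutoffs:
            continue
        cut = cutoffs[cls]
        sub = degrees[(degrees["node_class"] == cls.value) & (degrees["degree"] >= cut)]
        sub = sub.sort_values(["degree", "node"], ascending=[False, True])
        for rowt in sub.itertuples(index=False):
            rows.append(
                {"node_class": cls.value, "node": rowt.node, "degree": int(rowt.degree), "cutoff": cut}
            )
    report = pd.DataFrame(rows, columns=["node_class", "node", "degree", "cutoff"])
    return HubReport(cutoffs=dict(cutoffs), hubs=report)
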