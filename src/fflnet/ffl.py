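"""Enumeration and exclusive classification of miRNA–TF–gene feed-forward loops.

A 3-node FFL here is a (miRNA, TF, gene) triple in which both regulators
target the gene and the two regulators are themselves linked.  Three
mutually exclusive categories exist, distinguished by the direction(s) of
the TF–miRNA arm:

* **miRNA-FFL** — the miRNA represses both the TF and the gene, and the
  TF regulates the gene (edges miRNA→TF, miRNA→gene, TF→gene).
* **TF-FFL** — the TF regulates both the miRNA and the gene, and the
  miRNA represses the gene (edges TF→miRNA, TF→gene, miRNA→gene).
* **composite-FFL** — reciprocal TF↔miRNA regulation on top of both
  regulators targeting the gene (all four edges; 4-edge motif).

Exclusivity is resolved by promotion: a triple carrying both TF→miRNA
and miRNA→TF is composite only, never counted in the other two classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import EdgeType, RegulatoryEdge

__all__ = [
    "FFLCategory",
    "FFL",
    "classify_triple",
    "enumerate_ffls",
    "ffl_summary",
    "write_ffl_table",
    "read_ffl_table",
]


class FFLCategory(enum.Enum):
    MIRNA_FFL = "MIRNA_FFL"
    TF_FFL = "TF_FFL"
    COMPOSITE_FFL = "COMPOSITE_FFL"


@dataclass(frozen=True)
class FFL:
    """One classified 3-node motif with its constituent edges attached."""

    mirna: str
    tf: str
    gene: str
    category: FFLCategory
    edges: tuple[RegulatoryEdge, ...]

    def __post_init__(self) -> None:
        want = 4 if self.category is FFLCategory.COMPOSITE_FFL else 3
        if len(self.edges) != want:
            raise ValueError(
                f"{self.category.value} must carry {want} edges, got {len(self.edges)}"
            )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.mirna, self.tf, self.gene)


def classify_triple(
    has_tf_mirna: bool,
    has_mirna_tf: bool,
    has_tf_gene: bool,
    has_mirna_gene: bool,
) -> FFLCategory | None:
    """Classify a fixed (miRNA, TF, gene) triple from its edge-presence flags.

    Both regulators must target the gene for any category; the TF–miRNA
    arm then decides: reciprocal → composite, miRNA→TF only → miRNA-FFL,
    TF→miRNA only → TF-FFL, neither → no FFL.  Total function.
    """
    if not (has_tf_gene and has_mirna_gene):
        return None
    if has_tf_mirna and has_mirna_tf:
        return FFLCategory.COMPOSITE_FFL
    if has_mirna_tf:
        return FFLCategory.MIRNA_FFL
    if has_tf_mirna:
        return FFLCategory.TF_FFL
    return None


_CATEGORY_ORDER = {c: i for i, c in enumerate(FFLCategory)}


def enumerate_ffls(edges: Iterable[RegulatoryEdge]) -> list[FFL]:
    """Find every classifiable (miRNA, TF, gene) triple, each exactly once.

    Enumeration walks the miRNA–TF arms (the rarest edge types) and
    intersects the two regulators' target-gene sets, so the cost is
    O(arms × shared targets) rather than a full triple product.  Output
    is deterministic: sorted by category, then miRNA, TF, gene.
    """
    by_type: dict[EdgeType, dict[tuple[str, str], RegulatoryEdge]] = {t: {} for t in EdgeType}
    for e in edges:
        by_type[e.edge_type][(e.source, e.target)] = e

    tf_targets: dict[str, set[str]] = {}
    for tf, g in by_type[EdgeType.TF_GENE]:
        tf_targets.setdefault(tf, set()).add(g)
    mirna_targets: dict[str, set[str]] = {}
    for m, g in by_type[EdgeType.MIRNA_GENE]:
        mirna_targets.setdefault(m, set()).add(g)

    arm_pairs = {(m, tf) for m, tf in by_type[EdgeType.MIRNA_TF]}
    arm_pairs |= {(m, tf) for tf, m in by_type[EdgeType.TF_MIRNA]}

    out: list[FFL] = []
    for m, tf in arm_pairs:
        has_mt = (m, tf) in by_type[EdgeType.MIRNA_TF]
        has_tm = (tf, m) in by_type[EdgeType.TF_MIRNA]
        shared = mirna_targets.get(m, set()) & tf_targets.get(tf, set())
        for g in shared:
            category = classify_triple(has_tm, has_mt, True, True)
            assert category is not None
            constituent = [
                by_type[EdgeType.MIRNA_GENE][(m, g)],
                by_type[EdgeType.TF_GENE][(tf, g)],
            ]
            if has_mt:
                constituent.append(by_type[EdgeType.MIRNA_TF][(m, tf)])
            if has_tm:
                constituent.append(by_type[EdgeType.TF_MIRNA][(tf, m)])
            out.append(
                FFL(mirna=m, tf=tf, gene=g, category=category, edges=tuple(constituent))
            )
    out.sort(key=lambda f: (_CATEGORY_ORDER[f.category], f.mirna, f.tf, f.gene))
    return out


def ffl_summary(ffls: Sequence[FFL]) -> pd.DataFrame:
    """Per-category motif summary: FFL, node and merged-link counts.

    Link counts are over the *union* of constituent edges per category
    (an edge shared by many FFLs counts once); a Total row summarises
    the union across all categories.
    """
    rows = []
    order = list(FFLCategory) + [None]  # None = grand total
    for cat in order:
        subset = [f for f in ffls if cat is None or f.category is cat]
        edge_union = {e for f in subset for e in f.edges}
        genes = {f.gene for f in subset}
        mirnas = {f.mirna for f in subset}
        tfs = {f.tf for f in subset}
        row = {
            "category": "Total" if cat is None else cat.value,
            "n_ffls": len(subset),
            "n_genes": len(genes),
            "n_mirnas": len(mirnas),
            "n_tfs": len(tfs),
            "n_nodes": len(genes | mirnas | tfs),
            "n_links": len(edge_union),
        }
        for t in EdgeType:
            row[f"links_{t.value}"] = sum(1 for e in edge_union if e.edge_type is t)
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def _edge_token(e: RegulatoryEdge) -> str:
    return f"{e.source}>{e.target}:{e.edge_type.value}"


def write_ffl_table(ffls: Sequence[FFL], path: str | Path) -> None:
    """Write FFLs as TSV: category, mirna, tf, gene, semicolon-joined edges."""
    rows = [
        {
            "category": f.category.value,
            "mirna": f.mirna,
            "tf": f.tf,
            "gene": f.gene,
            "edge_list": ";".join(_edge_token(e) for e in sorted(f.edges, key=lambda e: e.key)),
        }
        for f in ffls
    ]
    pd.DataFrame(rows, columns=["category", "mirna", "tf", "gene", "edge_list"]).to_csv(
        path, sep="\t", index=False
    )


def read_ffl_table(path: str | Path) -> list[FFL]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for rowt in df.itertuples(index=False):
        edges = []
        for token in rowt.edge_list.split(";"):
            st, et = token.rsplit(":", 1)
            src, tgt = st.split(">")
            edges.append(RegulatoryEdge(src, tgt, EdgeType(et)))
        out.append(
            FFL(
                mirna=rowt.mirna,
                tf=rowt.tf,
                gene=rowt.gene,
                category=FFLCategory(rowt.category),
                edges=tuple(edges),
            )
        )
    return out
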