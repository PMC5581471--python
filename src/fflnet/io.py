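"""Readers, writers and score prefilters for typed regulatory edge lists.

The pipeline consumes four kinds of predicted regulations — miRNA→gene,
miRNA→TF, TF→gene and TF→miRNA — as tab-separated edge lists, plus
expression matrices (features × samples) and a clinical table.  Edges may
carry the prediction scores emitted by the upstream target-prediction
tools (TargetScan total context score, miRanda S and ΔG, Match core and
matrix scores); those scores are used here only as documented prefilter
columns, never recomputed.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NodeClass",
    "EdgeType",
    "RegulatoryEdge",
    "NodeRoster",
    "ExpressionMatrix",
    "SCORE_COLUMNS",
    "read_edge_list",
    "prefilter_edges",
    "read_expression_matrix",
    "read_clinical_table",
    "write_network",
    "read_network_tsv",
    "edges_to_frame",
]


class NodeClass(enum.Enum):
    """Molecular class of a network node."""

    GENE = "GENE"
    MIRNA = "MIRNA"
    TF = "TF"


class EdgeType(enum.Enum):
    """The four predicted regulation types.

    miRNA-sourced edges are repressive; TF-sourced edges are activating
    or repressive (the sign is decided at the correlation-filter stage).
    """

    MIRNA_GENE = "MIRNA_GENE"
    MIRNA_TF = "MIRNA_TF"
    TF_GENE = "TF_GENE"
    TF_MIRNA = "TF_MIRNA"

    @property
    def source_class(self) -> NodeClass:
        return NodeClass.MIRNA if self.name.startswith("MIRNA") else NodeClass.TF

    @property
    def target_class(self) -> NodeClass:
        return {
            EdgeType.MIRNA_GENE: NodeClass.GENE,
            EdgeType.MIRNA_TF: NodeClass.TF,
            EdgeType.TF_GENE: NodeClass.GENE,
            EdgeType.TF_MIRNA: NodeClass.MIRNA,
        }[self]


#: Recognised prediction-score columns and how duplicates are collapsed
#: (higher is better for all except the miRanda folding energy ΔG).
SCORE_COLUMNS: tuple[str, ...] = (
    "context_score",
    "miranda_S",
    "miranda_dG",
    "match_core",
    "match_matrix",
)
_SCORE_BEST = {
    "context_score": max,
    "miranda_S": max,
    "miranda_dG": min,
    "match_core": max,
    "match_matrix": max,
}


@dataclass(frozen=True)
class RegulatoryEdge:
    """One typed, directed predicted regulation.

    Identity (equality/hash) is on (source, target, edge_type); scores are
    carried along but do not distinguish edges.
    """

    source: str
    target: str
    edge_type: EdgeType
    scores: Mapping[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-regulation not allowed: {self.source}")
        unknown = set(self.scores) - set(SCORE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown score column(s): {sorted(unknown)}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.edge_type.value)

    def __repr__(self) -> str:  # compact, scores elided when absent
        s = f", scores={dict(self.scores)}" if self.scores else ""
        return f"RegulatoryEdge({self.source}>{self.target}:{self.edge_type.value}{s})"


class NodeRoster:
    """The node universe: disjoint gene / miRNA / TF symbol sets.

    Gene and TF matching is exact and case-sensitive; miRNA names are
    matched case-insensitively (miRBase-style capitalisation varies
    across sources) and reported with the roster's spelling.  A symbol
    appearing in more than one class is rejected outright.
    """

    def __init__(
        self,
        genes: Iterable[str],
        mirnas: Iterable[str],
        tfs: Iterable[str],
    ) -> None:
        self.genes = frozenset(genes)
        self.tfs = frozenset(tfs)
        mirna_list = list(mirnas)
        self._mirna_canonical = {m.lower(): m for m in mirna_list}
        self.mirnas = frozenset(self._mirna_canonical.values())

        overlap = (self.genes & self.tfs) | (self.genes & self.mirnas) | (self.tfs & self.mirnas)
        mirna_lc = set(self._mirna_canonical)
        overlap |= {s for s in self.genes | self.tfs if s.lower() in mirna_lc}
        if overlap:
            raise ValueError(
                f"ambiguous roster: symbol(s) in more than one class: {sorted(overlap)[:5]}"
            )

    def class_of(self, symbol: str) -> NodeClass | None:
        if symbol in self.genes:
            return NodeClass.GENE
        if symbol in self.tfs:
            return NodeClass.TF
        if symbol.lower() in self._mirna_canonical:
            return NodeClass.MIRNA
        return None

    def canonical(self, symbol: str) -> str:
        """Roster spelling for a symbol (only miRNAs are case-folded)."""
        return self._mirna_canonical.get(symbol.lower(), symbol)


@dataclass
class ExpressionMatrix:
    """Features × samples real-valued expression for one assay."""

    data: pd.DataFrame  # rows = features, columns = samples
    assay: str  # "MRNA" or "MIRNA"

    def __post_init__(self) -> None:
        if self.assay not in ("MRNA", "MIRNA"):
            raise ValueError(f"assay must be MRNA or MIRNA, got {self.assay!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifier(s): {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def row(self, feature: str) -> pd.Series | None:
        if feature in self.data.index:
            return self.data.loc[feature]
        return None


def _merge_scores(a: Mapping[str, float], b: Mapping[str, float]) -> dict[str, float]:
    out = dict(a)
    for name, val in b.items():
        out[name] = _SCORE_BEST[name](out[name], val) if name in out else val
    return out


def read_edge_list(
    path: str | Path,
    edge_type: EdgeType,
    roster: NodeRoster,
) -> set[RegulatoryEdge]:
    """Read one typed edge-list TSV into a validated, deduplicated edge set.

    The file must have a header with ``source`` and ``target`` columns and
    may carry any subset of :data:`SCORE_COLUMNS`.  Rows whose source or
    target is unknown to the roster are dropped (counted and logged);
    a node known to the roster but of the wrong class for ``edge_type``
    is a hard error.  Duplicate (source, target) rows are collapsed,
    keeping the best value per score column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    score_cols = [c for c in df.columns if c in SCORE_COLUMNS]

    merged: dict[tuple[str, str], dict[str, float]] = {}
    rejected = 0
    for rowt in df.itertuples(index=False):
        src, tgt = roster.canonical(rowt.source), roster.canonical(rowt.target)
        src_cls, tgt_cls = roster.class_of(src), roster.class_of(tgt)
        if src_cls is None or tgt_cls is None:
            rejected += 1
            continue
        if src_cls is not edge_type.source_class or tgt_cls is not edge_type.target_class:
            raise ValueError(
                f"{path}: class mismatch for edge {src}>{tgt}: "
                f"({src_cls.value}, {tgt_cls.value}) incompatible with {edge_type.value}"
            )
        scores = {
            c: float(getattr(rowt, c))
            for c in score_cols
            if not _is_missing(getattr(rowt, c))
        }
        k = (src, tgt)
        merged[k] = _merge_scores(merged[k], scores) if k in merged else scores
    if rejected:
        logger.warning("%s: rejected %d row(s) with unknown node symbols", path, rejected)
    return {
        RegulatoryEdge(s, t, edge_type, scores=sc) for (s, t), sc in merged.items()
    }


def _is_missing(v: object) -> bool:
    try:
        return v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v)
    except (TypeError, ValueError):
        return False


# Published prefilter operators: strict inequalities as quoted for the
# TargetScan and miRanda scores, >= for the bounded Match scores.
_THRESHOLD_OPS = {
    "context_score": lambda v, t: v > t,
    "miranda_S": lambda v, t: v > t,
    "miranda_dG": lambda v, t: v < t,
    "match_core": lambda v, t: v >= t,
    "match_matrix": lambda v, t: v >= t,
}

#: The study's published score thresholds, usable as-is with
#: :func:`prefilter_edges`.
PUBLISHED_THRESHOLDS: dict[str, float] = {
    "context_score": -0.30,
    "miranda_S": 90.0,
    "miranda_dG": -17.0,
    "match_core": 1.00,
    "match_matrix": 0.95,
}


def prefilter_edges(
    edges: Iterable[RegulatoryEdge],
    thresholds: Mapping[str, float],
    missing_score: str = "pass",
    context_direction: str = "higher",
) -> set[RegulatoryEdge]:
    """Keep edges satisfying every provided score threshold.

    ``thresholds`` maps score names to cut-off values; the comparison
    operator per score is fixed (strictly greater for ``context_score``
    and ``miranda_S``, strictly less for ``miranda_dG``, at-least for the
    Match core/matrix scores).  An edge missing a thresholded score
    passes or fails per ``missing_score`` ("pass" or "fail"; default
    pass, because the prediction sources are unioned, not intersected).

    ``context_direction`` selects whether the context-score rule reads
    "higher than" (the published wording) or "lower than" (the reading
    under which more-negative scores, i.e. stronger predicted repression,
    are retained).
    """
    unknown = set(thresholds) - set(SCORE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown threshold name(s): {sorted(unknown)}")
    if missing_score not in ("pass", "fail"):
        raise ValueError("missing_score must be 'pass' or 'fail'")
    if context_direction not in ("higher", "lower"):
        raise ValueError("context_direction must be 'higher' or 'lower'")

    def keep(edge: RegulatoryEdge) -> bool:
        for name, cut in thresholds.items():
            if name not in edge.scores:
                if missing_score == "fail":
                    return False
                continue
            op = _THRESHOLD_OPS[name]
            if name == "context_score" and context_direction == "lower":
                if not edge.scores[name] < cut:
                    return False
            elif not op(edge.scores[name], cut):
                return False
        return True

    return {e for e in edges if keep(e)}


def read_expression_matrix(path: str | Path, assay: str) -> ExpressionMatrix:
    """Read a features-in-rows, samples-in-columns expression TSV.

    Non-numeric cells become missing values (excluded pairwise from
    correlations downstream); a duplicated feature identifier is a hard
    error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(data=df, assay=assay)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns ``sample``, ``time_days``, ``event``.

    Returns a frame indexed by sample with non-negative times and 0/1
    event indicators (1 = death observed, 0 = censored).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time_days", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    df = df.set_index("sample")
    df["time_days"] = pd.to_numeric(df["time_days"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time_days"] < 0).any():
        raise ValueError("negative survival time")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def edges_to_frame(edges: Iterable[RegulatoryEdge]) -> pd.DataFrame:
    """Flat table of edges: source, target, edge_type plus score columns."""
    rows = []
    for e in sorted(edges, key=lambda e: e.key):
        row: dict[str, object] = {
            "source": e.source,
            "target": e.target,
            "edge_type": e.edge_type.value,
        }
        row.update({c: e.scores.get(c) for c in SCORE_COLUMNS})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["source", "target", "edge_type", *SCORE_COLUMNS])
    return df.dropna(axis=1, how="all") if len(df) else df[["source", "target", "edge_type"]]


def write_network(network, path: str | Path, fmt: str) -> None:
    """Export a network as SIF, GraphML or flat TSV.

    SIF lines are ``source <EDGE_TYPE> target`` (Cytoscape interaction
    labels equal the edge-type labels); GraphML carries node class and
    undirected degree as node attributes; the TSV is the
    :func:`edges_to_frame` layout and round-trips losslessly through
    :func:`read_network_tsv`.
    """
    path = Path(path)
    edges = sorted(network.edges, key=lambda e: e.key)
    if not edges:
        raise ValueError("refusing to write an empty network")
    fmt = fmt.upper()
    if fmt == "SIF":
        lines = [f"{e.source}\t{e.edge_type.value}\t{e.target}" for e in edges]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "GRAPHML":
        g = nx.DiGraph()
        degree: dict[str, int] = {}
        for e in edges:
            degree[e.source] = degree.get(e.source, 0) + 1
            degree[e.target] = degree.get(e.target, 0) + 1
        for node, cls in network.nodes.items():
            g.add_node(node, node_class=cls.value, degree=degree.get(node, 0))
        for e in edges:
            g.add_edge(e.source, e.target, edge_type=e.edge_type.value)
        nx.write_graphml(g, path)
    elif fmt == "TSV":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network_tsv(path: str | Path) -> set[RegulatoryEdge]:
    """Read back a flat edge TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    out: set[RegulatoryEdge] = set()
    score_cols = [c for c in df.columns if c in SCORE_COLUMNS]
    for rowt in df.itertuples(index=False):
        scores = {
            c: float(getattr(rowt, c))
            for c in score_cols
            if not _is_missing(getattr(rowt, c))
        }
        out.add(
            RegulatoryEdge(rowt.source, rowt.target, EdgeType(rowt.edge_type), scores=scores)
        )
    return out
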