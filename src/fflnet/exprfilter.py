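"""Co-expression filtering of predicted regulatory edges.

Each candidate edge is scored by the Pearson correlation of its two
endpoints' expression across shared tumour samples, tested one-tailed
(miRNA-sourced edges must be negatively correlated — repression; TF-
sourced edges may go either way, tested in the observed direction),
adjusted for multiple testing by Benjamini–Hochberg within each edge-type
family, and kept when it clears both a fixed |r| floor and the adjusted-p
threshold.  An FFL is *significant* when every one of its constituent
edges passes.

The default |r| floors (0.14 for TF→gene at n = 264; 0.15 for the
miRNA-involving types at n = 243) are exactly the smallest correlations
reaching one-tailed p < 0.01 at those sample sizes — see
:func:`critical_r`, which reproduces them analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ffl import FFL
from .io import EdgeType, ExpressionMatrix, NodeClass, RegulatoryEdge

__all__ = [
    "EdgeRule",
    "ThresholdPolicy",
    "CorrelationResult",
    "critical_r",
    "pearson_r",
    "one_tailed_p",
    "bh_adjust",
    "significant_pairs",
    "extract_significant_ffls",
    "results_to_frame",
]


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Smallest |r| with one-tailed Pearson significance ``p < alpha`` at n.

    Inverts the t-transform t = r·sqrt((n−2)/(1−r²)): with
    t* = t_{1−α, n−2}, the critical correlation is t*/sqrt(n−2+t*²).
    At n = 264 this rounds to 0.14 and at n = 243 to 0.15.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    t_crit = stats.t.isf(alpha, df)
    return float(t_crit / math.sqrt(df + t_crit**2))


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int, str | None]:
    """Pairwise-complete product-moment correlation.

    Returns ``(r, n_used, reason)`` where reason is None on success, or
    one of ``"n<3"`` / ``"zero variance"`` when r is undefined (r is NaN
    then).  Samples missing either value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        return (float("nan"), n, "n<3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), n, "zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return (max(-1.0, min(1.0, r)), n, None)


def one_tailed_p(r: float, n_used: int, direction: str) -> float:
    """One-tailed p for a Pearson r via the t-transform with n−2 df.

    ``direction`` is ``"negative"`` (tests r < 0; the repression rule for
    miRNA-sourced edges) or ``"observed-sign"`` (tests in the direction
    of the observed r; the sign-free rule for TF-sourced edges).  r = ±1
    underflows to the smallest positive float rather than 0.
    """
    if n_used < 3:
        raise ValueError("need n_used >= 3")
    if direction not in ("negative", "observed-sign"):
        raise ValueError(f"unknown direction {direction!r}")
    df = n_used - 2
    if abs(r) >= 1.0:
        return 5e-324  # smallest subnormal; p in (0, 1]
    t = r * math.sqrt(df / (1.0 - r * r))
    if direction == "negative":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(stats.t.sf(abs(t), df))
    return max(p, 5e-324)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EdgeRule:
    """Significance rule for one edge type."""

    min_abs_r: float
    sign: str  # "negative" or "either"
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.sign not in ("negative", "either"):
            raise ValueError(f"sign must be 'negative' or 'either', got {self.sign!r}")

    @property
    def direction(self) -> str:
        return "negative" if self.sign == "negative" else "observed-sign"

    def sign_ok(self, r: float) -> bool:
        return r < 0 if self.sign == "negative" else True


def _default_rules() -> dict[EdgeType, EdgeRule]:
    return {
        EdgeType.TF_GENE: EdgeRule(min_abs_r=0.14, sign="either"),
        EdgeType.MIRNA_GENE: EdgeRule(min_abs_r=0.15, sign="negative"),
        EdgeType.TF_MIRNA: EdgeRule(min_abs_r=0.15, sign="either"),
        EdgeType.MIRNA_TF: EdgeRule(min_abs_r=0.15, sign="negative"),
    }


@dataclass
class ThresholdPolicy:
    """Per-edge-type correlation rules plus the FDR family scope.

    Defaults reproduce the study's published rules: |r| ≥ 0.14 either
    sign for TF→gene; r ≤ −0.15 for miRNA→gene and miRNA→TF; |r| ≥ 0.15
    either sign for TF→miRNA; adjusted one-tailed p < 0.01 everywhere.
    ``family`` selects whether BH runs within each edge type separately
    (default, matching the per-type thresholds) or globally.
    """

    rules: dict[EdgeType, EdgeRule] = field(default_factory=_default_rules)
    family: str = "per_edge_type"

    def __post_init__(self) -> None:
        if self.family not in ("per_edge_type", "global"):
            raise ValueError("family must be 'per_edge_type' or 'global'")


@dataclass
class CorrelationResult:
    """Per-edge correlation outcome."""

    edge: RegulatoryEdge
    r: float
    n_used: int
    p_one_tailed: float
    q: float
    significant: bool
    reason: str | None = None  # set when r/p undefined or endpoint unmeasured


def _endpoint_row(
    symbol: str, cls: NodeClass, mrna: ExpressionMatrix, mirna: ExpressionMatrix
) -> pd.Series | None:
    return (mirna if cls is NodeClass.MIRNA else mrna).row(symbol)


def significant_pairs(
    edges: Iterable[RegulatoryEdge],
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    policy: ThresholdPolicy | None = None,
) -> list[CorrelationResult]:
    """Correlate and test every candidate edge against expression data.

    Sample alignment follows the assays: TF→gene edges use the mRNA
    matrix's samples; any edge involving a miRNA uses the intersection of
    the two assays' sample sets (this is what gives the two different
    reference sample sizes, e.g. 264 vs 243).  Edges with an endpoint
    absent from its matrix are reported with reason ``"unmeasured"`` and
    excluded from the BH families.
    """
    policy = policy or ThresholdPolicy()
    edges = list(edges)
    if not edges:
        return []

    shared = mrna.samples.intersection(mirna.samples)

    results: list[CorrelationResult] = []
    testable_idx: list[int] = []
    for e in edges:
        rule = policy.rules[e.edge_type]
        src_row = _endpoint_row(e.source, e.edge_type.source_class, mrna, mirna)
        tgt_row = _endpoint_row(e.target, e.edge_type.target_class, mrna, mirna)
        if src_row is None or tgt_row is None:
            results.append(
                CorrelationResult(e, float("nan"), 0, float("nan"), float("nan"), False, "unmeasured")
            )
            continue
        samples = mrna.samples if e.edge_type is EdgeType.TF_GENE else shared
        r, n_used, reason = pearson_r(
            src_row.reindex(samples).to_numpy(), tgt_row.reindex(samples).to_numpy()
        )
        if reason is not None:
            results.append(
                CorrelationResult(e, r, n_used, float("nan"), float("nan"), False, reason)
            )
            continue
        p = one_tailed_p(r, n_used, rule.direction)
        results.append(CorrelationResult(e, r, n_used, p, float("nan"), False, None))
        testable_idx.append(len(results) - 1)

    if not testable_idx:
        raise ValueError("no candidate edge has matched expression for both endpoints")

    # BH adjustment within families, then apply sign + floor + alpha rules.
    if policy.family == "global":
        families: dict[object, list[int]] = {"all": testable_idx}
    else:
        families = {}
        for i in testable_idx:
            families.setdefault(results[i].edge.edge_type, []).append(i)
    for idx in families.values():
        qvals = bh_adjust([results[i].p_one_tailed for i in idx])
        for i, q in zip(idx, qvals):
            results[i].q = float(q)

    for i in testable_idx:
        res = results[i]
        rule = policy.rules[res.edge.edge_type]
        res.significant = (
            rule.sign_ok(res.r)
            and abs(res.r) >= rule.min_abs_r
            and res.q < rule.alpha
        )
    return results


def extract_significant_ffls(
    ffls: Sequence[FFL], results: Sequence[CorrelationResult]
) -> list[FFL]:
    """Keep FFLs *all* of whose constituent edges passed the filter.

    The requirement is conservation in both the prediction data and the
    expression data: one failing edge (of the 3 or 4) drops the motif.
    Category labels are unchanged.
    """
    passed = {res.edge.key for res in results if res.significant}
    return [f for f in ffls if all(e.key in passed for e in f.edges)]


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Correlation report: source, target, edge_type, r, n, p, q, significant, reason."""
    rows = [
        {
            "source": res.edge.source,
            "target": res.edge.target,
            "edge_type": res.edge.edge_type.value,
            "r": res.r,
            "n": res.n_used,
            "p": res.p_one_tailed,
            "q": res.q,
            "significant": res.significant,
            "reason": res.reason or "",
        }
        for res in results
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "r", "n", "p", "q", "significant", "reason"]
    )
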