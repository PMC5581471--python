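"""Synthetic regulomes, expression matrices and survival data with known truth.

The generator emulates the study's inputs at desk scale: typed edge
lists in which FFLs of each category are planted by construction among
random decoy edges (a rejection step keeps decoys from forming
accidental motifs, so planted counts are exact); two Gaussian expression
matrices in which true regulator–target pairs carry a configured Pearson
correlation — negative for miRNA-sourced regulation, configurable sign
for TF-sourced — realised through shared latent factors so one node can
serve many pairs; and exponential survival times whose hazard depends on
one designated component's expression, with independent uniform
censoring calibrated to a target censoring fraction.

Defaults mirror the study's conditions: 264 mRNA samples with a
243-sample overlap carrying the miRNA assay, |r| = 0.5 on true pairs,
5 planted FFLs per category among 200 decoy edges, log hazard ratio 1.5
with 30% censoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ffl import FFL, FFLCategory, write_ffl_table
from .io import EdgeType, ExpressionMatrix, NodeClass, NodeRoster, RegulatoryEdge, edges_to_frame

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_regulome",
    "simulate_expression",
    "simulate_survival",
    "simulate_study",
    "write_study",
]


def _default_planted() -> dict[FFLCategory, int]:
    return {FFLCategory.MIRNA_FFL: 5, FFLCategory.TF_FFL: 5, FFLCategory.COMPOSITE_FFL: 5}


def _default_decoys() -> dict[EdgeType, int]:
    return {t: 50 for t in EdgeType}


def _default_true_r() -> dict[EdgeType, float]:
    return {
        EdgeType.MIRNA_GENE: -0.5,
        EdgeType.MIRNA_TF: -0.5,
        EdgeType.TF_GENE: 0.5,
        EdgeType.TF_MIRNA: 0.5,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 60
    n_mirnas: int = 25
    n_tfs: int = 25
    planted: dict[FFLCategory, int] = field(default_factory=_default_planted)
    #: extra miRNA-FFLs all sharing one miRNA (fresh TF/gene pairs), so a
    #: single high-degree hub exists by construction; 0 = flat topology
    hub_extra_ffls: int = 0
    decoys: dict[EdgeType, int] = field(default_factory=_default_decoys)
    true_r: dict[EdgeType, float] = field(default_factory=_default_true_r)
    coexpressed_fraction: float = 1.0
    n_samples_mrna: int = 264
    n_samples_mirna: int = 243
    n_overlap: int = 243
    # survival generator
    survival_component: str | None = None  # default: a planted miRNA
    log_hr: float = 1.5
    censoring_rate: float = 0.30
    hazard_model: str = "threshold"  # "threshold" (change-point) or "linear"
    threshold_percentile: float = 60.0
    baseline_hazard: float = 1.0 / 1000.0  # per day; median survival ~700 d
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (EdgeType.MIRNA_GENE, EdgeType.MIRNA_TF):
            if self.true_r[t] >= 0:
                raise ValueError(f"true r for {t.value} must be negative (repression)")
        for r in self.true_r.values():
            if not abs(r) < 1:
                raise ValueError("|true r| must be < 1")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.hazard_model not in ("threshold", "linear"):
            raise ValueError("hazard_model must be 'threshold' or 'linear'")
        if not (0 <= self.n_overlap <= min(self.n_samples_mrna, self.n_samples_mirna)):
            raise ValueError("overlap exceeds an assay's sample count")
        if any(v < 0 for v in self.planted.values()) or any(v < 0 for v in self.decoys.values()):
            raise ValueError("counts must be >= 0")


@dataclass
class GroundTruth:
    """Bookkeeping of what was planted, for sharp downstream assertions."""

    roster: NodeRoster
    planted_ffls: list[FFL]
    coexpressed: list[bool]  # aligned with planted_ffls
    true_pair_r: dict[frozenset, float]  # unordered node pair -> correlation
    hub_component: str | None = None  # the designated high-degree miRNA, if any
    survival_component: str | None = None
    survival_threshold: float | None = None  # expression value at the change point
    log_hr: float | None = None

    @property
    def coexpressed_ffls(self) -> list[FFL]:
        return [f for f, c in zip(self.planted_ffls, self.coexpressed) if c]


def _make_roster(config: SimulationConfig) -> NodeRoster:
    genes = [f"GENE{i:03d}" for i in range(1, config.n_genes + 1)]
    mirnas = [f"hsa-miR-{i}" for i in range(1, config.n_mirnas + 1)]
    tfs = [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]
    return NodeRoster(genes, mirnas, tfs)


class _EdgeIndex:
    """Incremental edge index with an accidental-FFL check."""

    def __init__(self) -> None:
        self.pairs: dict[EdgeType, set[tuple[str, str]]] = {t: set() for t in EdgeType}
        self.mirna_targets: dict[str, set[str]] = {}
        self.tf_targets: dict[str, set[str]] = {}
        self.arms_by_tf: dict[str, set[str]] = {}  # TF -> miRNAs linked either way
        self.arms_by_mirna: dict[str, set[str]] = {}

    def add(self, e: RegulatoryEdge) -> None:
        self.pairs[e.edge_type].add((e.source, e.target))
        if e.edge_type is EdgeType.MIRNA_GENE:
            self.mirna_targets.setdefault(e.source, set()).add(e.target)
        elif e.edge_type is EdgeType.TF_GENE:
            self.tf_targets.setdefault(e.source, set()).add(e.target)
        elif e.edge_type is EdgeType.MIRNA_TF:
            self.arms_by_mirna.setdefault(e.source, set()).add(e.target)
            self.arms_by_tf.setdefault(e.target, set()).add(e.source)
        else:  # TF_MIRNA
            self.arms_by_tf.setdefault(e.source, set()).add(e.target)
            self.arms_by_mirna.setdefault(e.target, set()).add(e.source)

    def has(self, e: RegulatoryEdge) -> bool:
        return (e.source, e.target) in self.pairs[e.edge_type]

    def would_change_ffls(self, e: RegulatoryEdge) -> bool:
        """Would adding this edge create a new classifiable triple or
        promote an existing one to a different category?"""
        t = e.edge_type
        if t is EdgeType.TF_GENE:
            tf, g = e.source, e.target
            return any(
                g in self.mirna_targets.get(m, ()) for m in self.arms_by_tf.get(tf, ())
            )
        if t is EdgeType.MIRNA_GENE:
            m, g = e.source, e.target
            return any(
                g in self.tf_targets.get(tf, ()) for tf in self.arms_by_mirna.get(m, ())
            )
        # TF–miRNA arm edges: any shared target creates or promotes
        if t is EdgeType.MIRNA_TF:
            m, tf = e.source, e.target
        else:
            tf, m = e.source, e.target
        shared = self.mirna_targets.get(m, set()) & self.tf_targets.get(tf, set())
        return bool(shared)


_FFL_EDGE_TYPES = {
    FFLCategory.MIRNA_FFL: (EdgeType.MIRNA_TF, EdgeType.MIRNA_GENE, EdgeType.TF_GENE),
    FFLCategory.TF_FFL: (EdgeType.TF_MIRNA, EdgeType.MIRNA_GENE, EdgeType.TF_GENE),
    FFLCategory.COMPOSITE_FFL: (
        EdgeType.MIRNA_TF,
        EdgeType.TF_MIRNA,
        EdgeType.MIRNA_GENE,
        EdgeType.TF_GENE,
    ),
}


def _motif_edges(m: str, tf: str, g: str, cat: FFLCategory) -> tuple[RegulatoryEdge, ...]:
    mk = {
        EdgeType.MIRNA_TF: RegulatoryEdge(m, tf, EdgeType.MIRNA_TF),
        EdgeType.TF_MIRNA: RegulatoryEdge(tf, m, EdgeType.TF_MIRNA),
        EdgeType.MIRNA_GENE: RegulatoryEdge(m, g, EdgeType.MIRNA_GENE),
        EdgeType.TF_GENE: RegulatoryEdge(tf, g, EdgeType.TF_GENE),
    }
    return tuple(mk[t] for t in _FFL_EDGE_TYPES[cat])


def simulate_regulome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[set[RegulatoryEdge], GroundTruth]:
    """Plant the configured FFLs on fresh node triples, then sprinkle
    decoy edges that provably form no additional motif.

    Planted triples are node-disjoint, so every planted FFL keeps its
    intended category and the planted counts are exact.  Decoys are
    rejection-sampled; an infeasible configuration raises after bounded
    retries.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roster = _make_roster(config)
    n_planted = sum(config.planted.values())
    if n_planted > min(config.n_genes, config.n_mirnas, config.n_tfs):
        raise ValueError("rosters too small to host the planted FFLs on disjoint triples")

    genes = sorted(roster.genes)
    mirnas = sorted(roster.mirnas, key=lambda s: (len(s), s))
    tfs = sorted(roster.tfs)
    index = _EdgeIndex()
    planted: list[FFL] = []
    slot = 0
    for cat in FFLCategory:
        for _ in range(config.planted.get(cat, 0)):
            m, tf, g = mirnas[slot], tfs[slot], genes[slot]
            slot += 1
            edges = _motif_edges(m, tf, g, cat)
            for e in edges:
                index.add(e)
            planted.append(FFL(mirna=m, tf=tf, gene=g, category=cat, edges=edges))

    hub_component: str | None = None
    if config.hub_extra_ffls > 0:
        if slot + config.hub_extra_ffls > min(config.n_genes, config.n_tfs):
            raise ValueError("rosters too small for the requested hub FFLs")
        hub_component = planted[0].mirna if planted else mirnas[0]
        for _ in range(config.hub_extra_ffls):
            tf, g = tfs[slot], genes[slot]
            slot += 1
            edges = _motif_edges(hub_component, tf, g, FFLCategory.MIRNA_FFL)
            for e in edges:
                index.add(e)
            planted.append(
                FFL(mirna=hub_component, tf=tf, gene=g, category=FFLCategory.MIRNA_FFL, edges=edges)
            )

    all_edges = {e for f in planted for e in f.edges}
    src_pool = {
        EdgeType.MIRNA_GENE: (mirnas, genes),
        EdgeType.MIRNA_TF: (mirnas, tfs),
        EdgeType.TF_GENE: (tfs, genes),
        EdgeType.TF_MIRNA: (tfs, mirnas),
    }
    for etype in EdgeType:
        want = config.decoys.get(etype, 0)
        sources, targets = src_pool[etype]
        placed, tries = 0, 0
        max_tries = 1000 * max(1, want)
        while placed < want:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {want} decoy {etype.value} edges without "
                    f"creating accidental FFLs (placed {placed})"
                )
            s = sources[rng.integers(len(sources))]
            t = targets[rng.integers(len(targets))]
            cand = RegulatoryEdge(s, t, etype)
            if index.has(cand) or index.would_change_ffls(cand):
                continue
            index.add(cand)
            all_edges.add(cand)
            placed += 1

    n_co = int(round(config.coexpressed_fraction * len(planted)))
    co_idx = set(rng.choice(len(planted), size=n_co, replace=False)) if planted else set()
    coexpressed = [i in co_idx for i in range(len(planted))]

    true_pair_r: dict[frozenset, float] = {}
    for f, co in zip(planted, coexpressed):
        if not co:
            continue
        for e in f.edges:
            pair = frozenset((e.source, e.target))
            r = config.true_r[e.edge_type]
            # reciprocal TF<->miRNA edges share one pair; the repression
            # constraint (negative r) binds
            if pair in true_pair_r:
                r = min(true_pair_r[pair], r)
            true_pair_r[pair] = r

    truth = GroundTruth(
        roster=roster,
        planted_ffls=planted,
        coexpressed=coexpressed,
        true_pair_r=true_pair_r,
        hub_component=hub_component,
        log_hr=config.log_hr,
    )
    return all_edges, truth


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw Gaussian expression in which each true pair has its configured
    Pearson correlation, via shared latent factors.

    Every true pair (u, v) with correlation r gets a latent standard-
    normal factor; each endpoint loads it with sqrt(|r|) (one side signed
    by sign(r)) and tops up with independent noise to unit variance, so
    corr(u, v) = r exactly while a node can serve several pairs.  When a
    node's factor loadings would exceed unit variance they are rescaled
    and the realised correlations shrink (many-partner hubs).  Decoy
    pairs share no factor and are asymptotically uncorrelated.  The two
    assays overlap in ``n_overlap`` samples.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n_total = config.n_samples_mrna + config.n_samples_mirna - config.n_overlap
    samples = [f"S{i:04d}" for i in range(1, n_total + 1)]
    mrna_samples = samples[: config.n_samples_mrna]
    mirna_samples = samples[config.n_samples_mrna - config.n_overlap :]

    pairs = sorted(truth.true_pair_r.items(), key=lambda kv: sorted(kv[0]))
    factors = rng.standard_normal((len(pairs), n_total))

    # loadings per node: list of (factor index, signed loading)
    loadings: dict[str, list[tuple[int, float]]] = {}
    for k, (pair, r) in enumerate(pairs):
        u, v = sorted(pair)
        b = np.sqrt(abs(r))
        loadings.setdefault(u, []).append((k, b * np.sign(r)))
        loadings.setdefault(v, []).append((k, b))

    roster = truth.roster
    all_nodes = sorted(roster.genes) + sorted(roster.tfs) + sorted(roster.mirnas)
    values: dict[str, np.ndarray] = {}
    for node in all_nodes:
        load = loadings.get(node, [])
        ssq = sum(b * b for _, b in load)
        scale = 1.0 if ssq <= 1.0 else 1.0 / np.sqrt(ssq)
        x = np.zeros(n_total)
        for k, b in load:
            x += b * scale * factors[k]
        noise_var = max(0.0, 1.0 - ssq * scale * scale)
        if noise_var > 0:
            x = x + np.sqrt(noise_var) * rng.standard_normal(n_total)
        values[node] = x

    frame = pd.DataFrame(values, index=samples).T
    mrna_features = sorted(roster.genes) + sorted(roster.tfs)
    mirna_features = sorted(roster.mirnas)
    mrna = ExpressionMatrix(frame.loc[mrna_features, mrna_samples].copy(), assay="MRNA")
    mirna = ExpressionMatrix(frame.loc[mirna_features, mirna_samples].copy(), assay="MIRNA")
    return mrna, mirna


def simulate_survival(
    expression: pd.Series,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Exponential survival driven by one component's expression.

    Under the ``threshold`` hazard model, samples whose expression
    exceeds the ``threshold_percentile`` of the observed values carry a
    hazard multiplied by exp(log_hr) — a planted change point that a
    cutpoint scan can recover.  Under ``linear``, the log hazard is
    baseline + log_hr × standardised expression.  Censoring is
    independent Uniform(0, c) with c calibrated so the expected censored
    fraction equals ``censoring_rate``.

    Returns the clinical table (sample, time_days, event — indexed by
    sample) and the planted threshold expression value (None for the
    linear model).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    x = expression.dropna().to_numpy(dtype=float)
    idx = expression.dropna().index
    threshold: float | None = None
    if config.hazard_model == "threshold":
        threshold = float(np.percentile(x, config.threshold_percentile))
        log_rel = config.log_hr * (x > threshold).astype(float)
    else:
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        log_rel = config.log_hr * z
    lam = config.baseline_hazard * np.exp(log_rel)
    t_event = rng.exponential(1.0 / lam)

    if config.censoring_rate > 0:
        def expected_censored(c: float) -> float:
            lc = lam * c
            return float(np.mean((1.0 - np.exp(-lc)) / lc))

        lo, hi = 1e-9, 1e12
        c_max = brentq(lambda c: expected_censored(c) - config.censoring_rate, lo, hi)
        t_cens = rng.uniform(0.0, c_max, size=lam.size)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(lam.size, dtype=int)
        time = t_event

    clinical = pd.DataFrame({"time_days": time, "event": event}, index=pd.Index(idx, name="sample"))
    return clinical, threshold


@dataclass
class SimulatedStudy:
    """A full synthetic study: inputs for every pipeline stage plus truth."""

    config: SimulationConfig
    edges: set[RegulatoryEdge]
    truth: GroundTruth
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    clinical: pd.DataFrame


def simulate_study(config: SimulationConfig, seed: int | None = None) -> SimulatedStudy:
    """Regulome + expression + survival in one deterministic draw."""
    seed = config.seed if seed is None else seed
    edges, truth = simulate_regulome(config, seed)
    mrna, mirna = simulate_expression(truth, config, seed)
    component = config.survival_component
    if component is None:
        component = truth.planted_ffls[0].mirna if truth.planted_ffls else None
    clinical = pd.DataFrame(columns=["time_days", "event"])
    if component is not None:
        row = mirna.row(component)
        if row is None:
            row = mrna.row(component)
        if row is None:
            raise ValueError(f"survival component {component!r} not in any matrix")
        clinical, threshold = simulate_survival(row, config, seed)
        truth.survival_component = component
        truth.survival_threshold = threshold
    return SimulatedStudy(
        config=config, edges=edges, truth=truth, mrna=mrna, mirna=mirna, clinical=clinical
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit the study as the TSV dialects the io module reads, plus a
    ground-truth JSON; returns the written paths keyed by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for etype in EdgeType:
        sub = [e for e in study.edges if e.edge_type is etype]
        p = outdir / f"edges_{etype.value.lower()}.tsv"
        edges_to_frame(sub)[["source", "target"]].to_csv(p, sep="\t", index=False)
        paths[f"edges_{etype.value}"] = p
    p = outdir / "expression_mrna.tsv"
    study.mrna.data.to_csv(p, sep="\t", index_label="feature")
    paths["expression_mrna"] = p
    p = outdir / "expression_mirna.tsv"
    study.mirna.data.to_csv(p, sep="\t", index_label="feature")
    paths["expression_mirna"] = p
    p = outdir / "clinical.tsv"
    study.clinical.reset_index().to_csv(p, sep="\t", index=False)
    paths["clinical"] = p
    p = outdir / "planted_ffls.tsv"
    write_ffl_table(study.truth.planted_ffls, p)
    paths["planted_ffls"] = p
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(_truth_json(study), indent=2, sort_keys=True))
    paths["ground_truth"] = p
    return paths


def _truth_json(study: SimulatedStudy) -> dict:
    t = study.truth
    return {
        "config": {
            k: (v if not isinstance(v, dict) else {getattr(kk, "value", kk): vv for kk, vv in v.items()})
            for k, v in dataclasses.asdict(study.config).items()
        },
        "planted_ffls": [
            {"category": f.category.value, "mirna": f.mirna, "tf": f.tf, "gene": f.gene}
            for f in t.planted_ffls
        ],
        "coexpressed": t.coexpressed,
        "hub_component": t.hub_component,
        "true_pairs": [
            {"pair": sorted(pair), "r": r} for pair, r in sorted(
                t.true_pair_r.items(), key=lambda kv: sorted(kv[0])
            )
        ],
        "survival": {
            "component": t.survival_component,
            "threshold": t.survival_threshold,
            "log_hr": t.log_hr,
        },
    }
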