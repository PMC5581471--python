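import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fflnet.io import EdgeType, NodeRoster, RegulatoryEdge

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def roster() -> NodeRoster:
    return NodeRoster(
        genes=[f"G{i}" for i in range(1, 21)],
        mirnas=[f"hsa-miR-{i}" for i in range(1, 11)],
        tfs=[f"T{i}" for i in range(1, 11)],
    )


def random_typed_edges(rng: np.random.Generator, n_mirnas=8, n_tfs=8, n_genes=15, density=0.2):
    """Random typed digraph over small rosters: each possible typed edge
    is present independently with the given density."""
    mirnas = [f"hsa-miR-{i}" for i in range(1, n_mirnas + 1)]
    tfs = [f"T{i}" for i in range(1, n_tfs + 1)]
    genes = [f"G{i}" for i in range(1, n_genes + 1)]
    edges = set()
    pools = {
        EdgeType.MIRNA_GENE: (mirnas, genes),
        EdgeType.MIRNA_TF: (mirnas, tfs),
        EdgeType.TF_GENE: (tfs, genes),
        EdgeType.TF_MIRNA: (tfs, mirnas),
    }
    for etype, (sources, targets) in pools.items():
        for s in sources:
            for t in targets:
                if rng.random() < density:
                    edges.add(RegulatoryEdge(s, t, etype))
    return edges, mirnas, tfs, genes


def brute_force_ffl_scan(edges, mirnas, tfs, genes):
    """Exhaustive miRNA x TF x gene triple scan oracle (independent of
    the production enumeration): returns {(m, tf, g): category_value}."""
    present = {(e.source, e.target, e.edge_type) for e in edges}
    out = {}
    for m in mirnas:
        for tf in tfs:
            for g in genes:
                has_tm = (tf, m, EdgeType.TF_MIRNA) in present
                has_mt = (m, tf, EdgeType.MIRNA_TF) in present
                has_tg = (tf, g, EdgeType.TF_GENE) in present
                has_mg = (m, g, EdgeType.MIRNA_GENE) in present
                if not (has_tg and has_mg):
                    continue
                if has_tm and has_mt:
                    out[(m, tf, g)] = "COMPOSITE_FFL"
                elif has_mt:
                    out[(m, tf, g)] = "MIRNA_FFL"
                elif has_tm:
                    out[(m, tf, g)] = "TF_FFL"
    return out
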