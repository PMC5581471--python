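import json

import numpy as np
import pandas as pd
import pytest

from fflnet.exprfilter import pearson_r
from fflnet.ffl import FFLCategory, enumerate_ffls
from fflnet.io import EdgeType
from fflnet.synth import (
    SimulationConfig,
    simulate_expression,
    simulate_regulome,
    simulate_study,
    simulate_survival,
    write_study,
)


class TestRegulome:
    def test_empty_config_gives_empty_edge_sets(self):
        cfg = SimulationConfig(
            planted={c: 0 for c in FFLCategory}, decoys={t: 0 for t in EdgeType}
        )
        edges, truth = simulate_regulome(cfg)
        assert edges == set() and truth.planted_ffls == []

    def test_enumeration_recovers_exactly_the_planted_ffls(self):
        cfg = SimulationConfig(seed=12)
        edges, truth = simulate_regulome(cfg)
        found = {(f.triple, f.category) for f in enumerate_ffls(edges)}
        planted = {(f.triple, f.category) for f in truth.planted_ffls}
        assert found == planted  # decoys created no accidental motif

    def test_decoy_counts_exact(self):
        cfg = SimulationConfig(seed=12)
        edges, truth = simulate_regulome(cfg)
        planted_edges = {e for f in truth.planted_ffls for e in f.edges}
        decoys = edges - planted_edges
        for t in EdgeType:
            assert sum(1 for e in decoys if e.edge_type is t) == cfg.decoys[t]

    def test_same_seed_identical_output(self):
        a, _ = simulate_regulome(SimulationConfig(seed=99))
        b, _ = simulate_regulome(SimulationConfig(seed=99))
        assert a == b

    def test_infeasible_roster_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_regulome(SimulationConfig(n_genes=3, n_mirnas=3, n_tfs=3))

    def test_positive_repression_correlation_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SimulationConfig(
                true_r={
                    EdgeType.MIRNA_GENE: +0.5,
                    EdgeType.MIRNA_TF: -0.5,
                    EdgeType.TF_GENE: 0.5,
                    EdgeType.TF_MIRNA: 0.5,
                }
            )


class TestExpression:
    def test_planted_pair_correlation_near_target(self):
        cfg = SimulationConfig(seed=21)
        edges, truth = simulate_regulome(cfg)
        mrna, mirna = simulate_expression(truth, cfg)
        shared = mrna.samples.intersection(mirna.samples)
        # check one planted miRNA->gene edge per planted FFL
        devs = []
        for f in truth.coexpressed_ffls:
            x = mirna.row(f.mirna).reindex(shared).to_numpy()
            y = mrna.row(f.gene).reindex(shared).to_numpy()
            r, n, _ = pearson_r(x, y)
            assert n == cfg.n_overlap
            devs.append(r - cfg.true_r[EdgeType.MIRNA_GENE])
        assert np.max(np.abs(devs)) < 0.15

    def test_decoy_pairs_uncorrelated(self):
        cfg = SimulationConfig(seed=22)
        edges, truth = simulate_regulome(cfg)
        mrna, mirna = simulate_expression(truth, cfg)
        planted_pairs = set(truth.true_pair_r)
        shared = mrna.samples.intersection(mirna.samples)
        rs = []
        for e in edges:
            if frozenset((e.source, e.target)) in planted_pairs:
                continue
            if e.edge_type is not EdgeType.MIRNA_GENE:
                continue
            r, _, _ = pearson_r(
                mirna.row(e.source).reindex(shared).to_numpy(),
                mrna.row(e.target).reindex(shared).to_numpy(),
            )
            rs.append(r)
        assert np.mean(np.abs(np.asarray(rs)) < 0.15) > 0.9

    def test_sample_overlap_as_configured(self):
        cfg = SimulationConfig(seed=23)
        _, truth = simulate_regulome(cfg)
        mrna, mirna = simulate_expression(truth, cfg)
        assert len(mrna.samples) == 264
        assert len(mirna.samples) == 243
        assert len(mrna.samples.intersection(mirna.samples)) == 243

    def test_minimal_n_still_runs(self):
        cfg = SimulationConfig(seed=24, n_samples_mrna=3, n_samples_mirna=3, n_overlap=3)
        _, truth = simulate_regulome(cfg)
        mrna, mirna = simulate_expression(truth, cfg)
        assert mrna.data.shape[1] == 3


class TestSurvival:
    def test_no_censoring_all_events_observed(self):
        cfg = SimulationConfig(seed=31, censoring_rate=0.0)
        expr = pd.Series(
            np.random.default_rng(0).standard_normal(100),
            index=[f"S{i}" for i in range(100)],
        )
        clinical, thr = simulate_survival(expr, cfg)
        assert (clinical["event"] == 1).all()
        assert thr is not None

    def test_censoring_rate_calibrated(self):
        cfg = SimulationConfig(seed=32, censoring_rate=0.30)
        expr = pd.Series(
            np.random.default_rng(1).standard_normal(2000),
            index=[f"S{i}" for i in range(2000)],
        )
        clinical, _ = simulate_survival(expr, cfg)
        assert np.mean(clinical["event"] == 0) == pytest.approx(0.30, abs=0.05)

    def test_linear_model_has_no_threshold(self):
        cfg = SimulationConfig(seed=33, hazard_model="linear")
        expr = pd.Series(
            np.random.default_rng(2).standard_normal(50),
            index=[f"S{i}" for i in range(50)],
        )
        _, thr = simulate_survival(expr, cfg)
        assert thr is None


class TestStudyFiles:
    def test_written_files_round_trip_through_io(self, tmp_path):
        from fflnet.io import (
            NodeRoster,
            read_clinical_table,
            read_edge_list,
            read_expression_matrix,
        )

        study = simulate_study(SimulationConfig(seed=41))
        paths = write_study(study, tmp_path)
        roster = study.truth.roster
        back = set()
        for t in EdgeType:
            back |= read_edge_list(paths[f"edges_{t.value}"], t, roster)
        assert back == study.edges
        mrna = read_expression_matrix(paths["expression_mrna"], "MRNA")
        pd.testing.assert_frame_equal(
            mrna.data, study.mrna.data.rename_axis("feature"), check_exact=False
        )
        clin = read_clinical_table(paths["clinical"])
        assert len(clin) == len(study.clinical)
        truth = json.loads(paths["ground_truth"].read_text())
        assert len(truth["planted_ffls"]) == len(study.truth.planted_ffls)

    def test_same_seed_identical_files(self, tmp_path):
        a = write_study(simulate_study(SimulationConfig(seed=7)), tmp_path / "a")
        b = write_study(simulate_study(SimulationConfig(seed=7)), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
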