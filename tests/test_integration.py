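"""Filter-chain semantics and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crosstalk import (
    CooccurrenceResult,
    DifferentialLR,
    IntegratedHit,
    LRDatabase,
    LRRecord,
    PipelineConfig,
    PlantedLR,
    QCThresholds,
    apply_cooccurrence_filter,
    build_hits,
    hits_to_frame,
    join_common_hits,
    make_lr_database,
    run_pipeline,
    simulate_paired,
)
from crosstalk.preprocess import NormalizedMatrix

from conftest import small_sim_config


def _cooc(cluster_id, rows):
    """rows: (type_a, type_b, classification)."""
    table = pd.DataFrame(
        [
            (a, b, 10, 5, 5, 3, 0.5, 0.5, cls)
            for a, b, cls in rows
        ],
        columns=["type_a", "type_b", "N", "N1", "N2", "j", "p_gt", "p_lt",
                 "classification"],
    )
    return CooccurrenceResult(cluster_id=cluster_id, table=table)


def _diff(rows, comparison=("h", "d")):
    """rows: (source, target, pair_id, l_lnfc, r_lnfc, direction)."""
    table = pd.DataFrame(
        [(s, t, p, l, r, 0.001, 0.001, d) for s, t, p, l, r, d in rows],
        columns=["source_type", "target_type", "pair_id", "ligand_lnFC",
                 "receptor_lnFC", "ligand_padj", "receptor_padj", "direction"],
    )
    return DifferentialLR(comparison=comparison, table=table)


def _spots_norm(values, gene_ids, sample_id=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame(
        {
            "sample_id": sample_id or ["sl1"] * n,
            "condition": ["d"] * n,
            "x": np.zeros(n),
            "y": np.zeros(n),
        }
    )
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        gene_ids=list(gene_ids),
        unit_ids=[f"sp{i}" for i in range(n)],
        meta=meta,
    )


class TestCooccurrenceFilter:
    def test_union_keeps_pair_positive_in_any_selected_cluster(self):
        diff = _diff([("A", "B", "p1", 0.5, 0.5, "up")])
        c1 = _cooc(1, [("A", "B", "random")])
        c2 = _cooc(2, [("A", "B", "positive")])
        out = apply_cooccurrence_filter(diff, [c1, c2], [1, 2], "union")
        assert len(out.table) == 1
        out = apply_cooccurrence_filter(diff, [c1, c2], [1, 2], "intersection")
        assert len(out.table) == 0

    def test_non_positive_pair_dropped(self):
        diff = _diff([("A", "B", "p1", 0.5, 0.5, "up")])
        c1 = _cooc(1, [("A", "B", "negative")])
        out = apply_cooccurrence_filter(diff, [c1], [1])
        assert len(out.table) == 0

    def test_autocrine_always_kept(self):
        diff = _diff([("A", "A", "auto", 0.5, 0.5, "up")])
        c1 = _cooc(1, [("A", "B", "negative")])
        out = apply_cooccurrence_filter(diff, [c1], [1])
        assert list(out.table["pair_id"]) == ["auto"]

    def test_type_absent_from_spatial_dropped_with_warning(self, caplog):
        diff = _diff([("A", "GHOST", "p1", 0.5, 0.5, "up")])
        c1 = _cooc(1, [("A", "B", "positive")])
        with caplog.at_level("WARNING"):
            out = apply_cooccurrence_filter(diff, [c1], [1])
        assert len(out.table) == 0
        assert any("GHOST" in r.message for r in caplog.records)

    def test_unselected_cluster_does_not_count(self):
        diff = _diff([("A", "B", "p1", 0.5, 0.5, "up")])
        c1 = _cooc(1, [("A", "B", "random")])
        c2 = _cooc(2, [("A", "B", "positive")])
        out = apply_cooccurrence_filter(diff, [c1, c2], [1])
        assert len(out.table) == 0

    def test_missing_cooccurrence_result_is_error(self):
        diff = _diff([("A", "B", "p1", 0.5, 0.5, "up")])
        with pytest.raises(ValueError):
            apply_cooccurrence_filter(diff, [_cooc(1, [])], [1, 7])


class TestBuildHits:
    def _base(self):
        diff = _diff(
            [
                ("A", "B", "L1_R1", 0.9, 0.2, "up"),
                ("A", "B", "L2_R2", 0.3, 0.2, "up"),
            ]
        )
        db = LRDatabase(
            [
                LRRecord("L1_R1", "L1", ("R1",), "p"),
                LRRecord("L2_R2", "L2", ("R2",), "p"),
            ]
        )
        cooc = [_cooc(1, [("A", "B", "positive")])]
        return diff, db, cooc

    def test_ranked_by_total_abs_lnfc(self):
        diff, db, cooc = self._base()
        spots = _spots_norm([[1.0, 1, 1, 1]], ["L1", "R1", "L2", "R2"])
        hits = build_hits(diff, spots, db, cooc, [1])
        assert [h.pair_id for h in hits] == ["L1_R1", "L2_R2"]
        assert hits[0].supporting_clusters == (1,)
        assert hits[0].cooccurrence_class == "positive"

    def test_tie_breaks_by_pair_id(self):
        diff = _diff(
            [
                ("A", "B", "zzz", 0.5, 0.5, "up"),
                ("A", "B", "aaa", 0.6, 0.4, "up"),
            ]
        )
        db = LRDatabase(
            [
                LRRecord("zzz", "L1", ("R1",), "p"),
                LRRecord("aaa", "L2", ("R2",), "p"),
            ]
        )
        spots = _spots_norm([[1.0, 1, 1, 1]], ["L1", "R1", "L2", "R2"])
        hits = build_hits(diff, spots, db, [_cooc(1, [("A", "B", "positive")])], [1])
        assert [h.pair_id for h in hits] == ["aaa", "zzz"]

    def test_ligand_absent_flag_demotes_not_excludes(self):
        diff, db, cooc = self._base()
        spots = _spots_norm([[1.0, 1]], ["L2", "R2"])  # L1/R1 missing
        hits = build_hits(diff, spots, db, cooc, [1])
        flagged = {h.pair_id: h.evidence_flags for h in hits}
        assert "ligand-absent-from-panel" in flagged["L1_R1"]
        assert flagged["L2_R2"] == ()
        # strict mode drops the flagged hit
        strict = build_hits(diff, spots, db, cooc, [1], strict_spatial=True)
        assert [h.pair_id for h in strict] == ["L2_R2"]

    def test_marker_correlation_and_missing_marker_flag(self):
        diff, db, cooc = self._base()
        vals = np.array(
            [[1.0, 1, 1, 1, 2.0], [2.0, 3, 1, 1, 4.0], [3.0, 5, 1, 1, 6.0]]
        )
        spots = _spots_norm(vals, ["L1", "R1", "L2", "R2", "MK"])
        hits = build_hits(diff, spots, db, cooc, [1], marker_genes=["MK", "NOPE"])
        h = {x.pair_id: x for x in hits}["L1_R1"]
        # min(L1,R1) = (1,2,3); MK = (2,4,6): perfect correlation
        assert h.marker_correlation["MK"] == pytest.approx(1.0)
        assert "marker-absent-from-panel:NOPE" in h.evidence_flags

    def test_empty_differential_gives_empty_hits_frame(self):
        diff = _diff([])
        spots = _spots_norm([[1.0]], ["G"])
        hits = build_hits(diff, spots, LRDatabase([]), [_cooc(1, [])], [1])
        assert hits == []
        frame = hits_to_frame(hits)
        assert len(frame) == 0
        assert "pair_id" in frame.columns


class TestJoinCommonHits:
    def test_direction_agreement_annotation(self):
        a = pd.DataFrame(
            {"pair_id": ["p1", "p2"], "direction": ["up", "down"]}
        )
        b = pd.DataFrame(
            {"pair_id": ["p2", "p3"], "direction": ["up"] * 2}
        )
        j = join_common_hits(a, b)
        assert list(j["pair_id"]) == ["p2"]
        assert list(j["direction_agrees"]) == [False]


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    cfg_sim = small_sim_config(
        seed=4,
        n_samples_per_condition=1,
        n_spots_per_sample=196,
        planted_lr=(
            PlantedLR("LR_up", "G0100", ("G0101",), "type_1", "type_2",
                      "disease", 0.8, 0.8),
        ),
        colocalized_pairs=(("type_1", "type_2"),),
    )
    cells, spots, truth = simulate_paired(cfg_sim)
    db = make_lr_database(cfg_sim, n_decoys=10)
    config = PipelineConfig(
        comparisons=[("healthy", "disease")],
        diseased_conditions=["disease"],
        cell_types_of_interest=["type_1"],
        marker_genes=["G0000"],
        qc=QCThresholds(
            min_counts=100, min_genes=50, min_log10_genes_over_log10_counts=0.0
        ),
        k_range=(1, 8),
        seed=7,
    )
    out = tmp_path_factory.mktemp("run1")
    hits, manifest, artifacts = run_pipeline(config, cells, spots, db, outdir=out)
    return config, cells, spots, db, out, hits, manifest, artifacts


class TestRunPipeline:
    def test_planted_pair_survives_to_hits(self, pipeline_run):
        *_, hits, manifest, artifacts = pipeline_run
        assert any(h.pair_id == "LR_up" and h.direction == "up" for h in hits)

    def test_artifacts_and_outputs_written(self, pipeline_run):
        config, cells, spots, db, out, hits, manifest, artifacts = pipeline_run
        for f in ["qc_cells.tsv", "qc_spots.tsv", "abundance.tsv", "wss.tsv",
                  "clusters.tsv", "cooccurrence.tsv", "hits.tsv",
                  "summary.json", "manifest.json",
                  "differential_healthy_vs_disease.tsv"]:
            assert (out / f).exists(), f
        assert manifest.stages[0] == "qc" and manifest.stages[-1] == "done"
        assert len(artifacts["hits_frame"]) == len(hits)

    def test_rerun_is_byte_identical(self, pipeline_run, tmp_path):
        config, cells, spots, db, out, *_ = pipeline_run
        run_pipeline(config, cells, spots, db, outdir=tmp_path)
        assert (tmp_path / "hits.tsv").read_bytes() == (out / "hits.tsv").read_bytes()
        assert (
            (tmp_path / "summary.json").read_text()
            == (out / "summary.json").read_text()
        )

    def test_config_without_comparisons_is_error(self, pipeline_run):
        _, cells, spots, db, *_ = pipeline_run
        with pytest.raises(ValueError, match="comparison"):
            run_pipeline(PipelineConfig(), cells, spots, db)

    def test_bad_combine_rule_is_error(self):
        cfg = PipelineConfig(
            comparisons=[("h", "d")], diseased_conditions=["d"],
            combine_rule="sometimes",
        )
        with pytest.raises(ValueError, match="combine_rule"):
            cfg.validate()
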