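"""Ligand-receptor communication scoring and differential L-R analysis.

Per condition, the communication strength of a ligand-receptor pair between
a source and a target cell type is computed from group-summarized
expression: a cell type's expression level of a gene is the Tukey trimean
(Q1 + 2*Q2 + Q3)/4 of its normalized values (quartiles by linear
interpolation); a multi-subunit receptor's level is the geometric mean of
its subunit levels and is zero when any subunit is absent (a complex
missing a subunit cannot signal). The interaction score is the saturating
mass-action form

    score = L * R / (Kh + L * R),   Kh > 0,

bounded in [0, 1). Significance comes from a label-permutation null: cell
type labels are shuffled within the condition, scores recomputed, and the
add-one p-value (#{perm >= obs} + 1) / (n_perm + 1) reported. These are the
documented defaults of the standard communication-inference toolkit,
reimplemented directly.

Differential L-R analysis compares two conditions within the expressing
cell type gene by gene: two-sided Wilcoxon rank-sum on normalized values,
natural-log fold change of de-logged means (ln of mean expm1 + epsilon),
Benjamini-Hochberg adjustment scoped per cell type, then the filter chain:
|lnFC| >= 0.1 for ligand and receptor, both adjusted p < 0.05, and the
same direction of regulation for ligand and receptor (mixed signs are
excluded). A receptor complex passes only if every subunit passes with the
same sign; its lnFC is the subunit mean. The fold-change reference is the
second-named condition over the first, so "healthy vs disease" reports
positive lnFC for genes up in disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .io_formats import LRDatabase
from .preprocess import NormalizedMatrix

__all__ = [
    "CommunicationConfig",
    "CommunicationResult",
    "DifferentialLR",
    "trimean",
    "complex_level",
    "score_interaction",
    "score_communication",
    "permutation_test",
    "differential_lr",
    "run_comparisons",
]

LNFC_EPS = 1e-9


@dataclass(frozen=True)
class CommunicationConfig:
    hill_constant: float = 0.5
    n_permutations: int = 100
    significance_alpha: float = 0.05
    min_cells_per_type: int = 10
    lnfc_threshold: float = 0.1
    padj_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.hill_constant <= 0:
            raise ValueError("hill_constant must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class CommunicationResult:
    condition: str
    table: pd.DataFrame  # source_type, target_type, pair_id, ligand_level,
    #                      receptor_level, score, p_value

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t["p_value"] < alpha) & (t["score"] > 0)].reset_index(drop=True)


@dataclass
class DifferentialLR:
    comparison: tuple[str, str]
    table: pd.DataFrame  # source_type, target_type, pair_id, ligand_lnFC,
    #                      receptor_lnFC, ligand_padj, receptor_padj, direction


def trimean(values: np.ndarray) -> float:
    """Tukey trimean (Q1 + 2*Q2 + Q3)/4, quartiles by linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimean of empty array")
    q1, q2, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float((q1 + 2 * q2 + q3) / 4)


def complex_level(subunit_levels) -> float:
    """Geometric mean of subunit levels; zero if any subunit is zero."""
    levels = np.asarray(list(subunit_levels), dtype=float)
    if levels.size == 0:
        raise ValueError("complex with no subunits")
    if np.any(levels <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(levels))))


def score_interaction(L: float, R: float, config: CommunicationConfig) -> float:
    """Saturating mass-action score L*R / (Kh + L*R), in [0, 1)."""
    if L < 0 or R < 0:
        raise ValueError("expression levels must be nonnegative")
    lr = L * R
    return lr / (config.hill_constant + lr)


def _dense_expression(cells: NormalizedMatrix, genes: list[str]) -> np.ndarray:
    """Cells x genes dense block for the genes present; absent genes are
    columns of zeros (a gene not in the panel is simply not expressed)."""
    col_of = {g: j for j, g in enumerate(cells.gene_ids)}
    out = np.zeros((cells.values.shape[0], len(genes)))
    have = [(i, col_of[g]) for i, g in enumerate(genes) if g in col_of]
    if have:
        dst, src = zip(*have)
        block = np.asarray(sp.csr_matrix(cells.values)[:, list(src)].todense())
        out[:, list(dst)] = block
    return out


def _group_levels(E: np.ndarray, labels: np.ndarray, types: list[str]) -> np.ndarray:
    """Trimean of each column of E within each label group: (n_types, n_genes)."""
    out = np.zeros((len(types), E.shape[1]))
    for t_i, t in enumerate(types):
        block = E[labels == t]
        q1, q2, q3 = np.percentile(block, [25, 50, 75], axis=0, method="linear")
        out[t_i] = (q1 + 2 * q2 + q3) / 4
    return out


def _scores_from_levels(levels, types, db, config):
    """All (source, target, pair) scores from a (n_types, n_genes) level table."""
    rows = []
    gene_pos = {g: i for i, g in enumerate(db.all_genes)}
    for rec in db:
        lig_col = gene_pos[rec.ligand]
        sub_cols = [gene_pos[s] for s in rec.receptor_subunits]
        for s_i, s_t in enumerate(types):
            L = levels[s_i, lig_col]
            for t_i, t_t in enumerate(types):
                R = complex_level(levels[t_i, sub_cols])
                rows.append((s_t, t_t, rec.pair_id, L, R, score_interaction(L, R, config)))
    return rows


def score_communication(
    cells: NormalizedMatrix,
    db: LRDatabase,
    config: CommunicationConfig = CommunicationConfig(),
    seed: int = 0,
    conditions=None,
) -> dict:
    """Per-condition communication scores with permutation p-values.

    Returns ``{condition: CommunicationResult}``. Cell types with fewer
    than ``min_cells_per_type`` cells in a condition are excluded from that
    condition's scoring. One label permutation per round re-scores every
    (source, target, pair) triple simultaneously, so all triples share the
    same permutation null draws.
    """
    rng = np.random.default_rng(seed)
    genes = db.all_genes
    E_all = _dense_expression(cells, genes)
    cond_arr = cells.meta["condition"].to_numpy()
    type_arr = cells.meta["cell_type"].to_numpy()
    if conditions is None:
        conditions = list(pd.unique(cond_arr))
    results = {}
    for cond in conditions:
        in_c = cond_arr == cond
        E = E_all[in_c]
        labels = type_arr[in_c]
        counts = pd.Series(labels).value_counts()
        types = sorted(counts[counts >= config.min_cells_per_type].index)
        if not types:
            results[cond] = CommunicationResult(
                condition=cond,
                table=pd.DataFrame(
                    columns=["source_type", "target_type", "pair_id",
                             "ligand_level", "receptor_level", "score", "p_value"]
                ),
            )
            continue
        keep = np.isin(labels, types)
        E, labels = E[keep], labels[keep]
        obs_levels = _group_levels(E, labels, types)
        obs_rows = _scores_from_levels(obs_levels, types, db, config)
        obs_scores = np.array([r[5] for r in obs_rows])
        exceed = np.zeros(len(obs_rows), dtype=int)
        for _ in range(config.n_permutations):
            perm = rng.permutation(labels)
            lv = _group_levels(E, perm, types)
            ps = np.array([r[5] for r in _scores_from_levels(lv, types, db, config)])
            exceed += ps >= obs_scores
        pvals = (exceed + 1) / (config.n_permutations + 1)
        table = pd.DataFrame(
            obs_rows,
            columns=["source_type", "target_type", "pair_id",
                     "ligand_level", "receptor_level", "score"],
        )
        table["p_value"] = pvals
        results[cond] = CommunicationResult(condition=cond, table=table)
    return results


def permutation_test(
    cells: NormalizedMatrix,
    pair,
    source_type: str,
    target_type: str,
    config: CommunicationConfig = CommunicationConfig(),
    seed: int = 0,
    condition=None,
) -> float:
    """Permutation p-value for a single (source, target, pair) triple."""
    cond_arr = cells.meta["condition"].to_numpy()
    type_arr = cells.meta["cell_type"].to_numpy()
    mask = np.ones(len(cond_arr), dtype=bool) if condition is None else cond_arr == condition
    genes = [pair.ligand, *pair.receptor_subunits]
    E = _dense_expression(cells, genes)[mask]
    labels = type_arr[mask]
    for t in (source_type, target_type):
        if (labels == t).sum() < config.min_cells_per_type:
            raise ValueError(f"cell type {t} has too few cells")

    def _score(lbl):
        L = trimean(E[lbl == source_type, 0])
        R = complex_level(
            [trimean(E[lbl == target_type, j]) for j in range(1, E.shape[1])]
        )
        return score_interaction(L, R, config)

    obs = _score(labels)
    rng = np.random.default_rng(seed)
    exceed = sum(
        _score(rng.permutation(labels)) >= obs for _ in range(config.n_permutations)
    )
    return (exceed + 1) / (config.n_permutations + 1)


def _condition_mask(cond_arr: np.ndarray, name, pooled: dict | None):
    members = pooled.get(name, [name]) if pooled else [name]
    return np.isin(cond_arr, members)


def _gene_stats(E_a: np.ndarray, E_b: np.ndarray):
    """Wilcoxon rank-sum p and lnFC (B over A) for one gene's value vectors."""
    if np.all(E_a == E_a[0]) and np.all(E_b == E_b[0]) and E_a[0] == E_b[0]:
        p = 1.0
    else:
        p = float(ranksums(E_a, E_b).pvalue)
    mean_a = float(np.mean(np.expm1(E_a)))
    mean_b = float(np.mean(np.expm1(E_b)))
    lnfc = float(np.log(mean_b + LNFC_EPS) - np.log(mean_a + LNFC_EPS))
    return p, lnfc


def differential_lr(
    cells: NormalizedMatrix,
    comparison: tuple[str, str],
    significant_interactions: pd.DataFrame,
    db: LRDatabase,
    config: CommunicationConfig = CommunicationConfig(),
    pooled_conditions: dict | None = None,
) -> DifferentialLR:
    """Directional differential L-R analysis between two conditions.

    ``significant_interactions`` must have columns source_type, target_type,
    pair_id (typically the union of per-condition significant communication
    rows). lnFC is second condition over first. Only rows where ligand and
    every receptor subunit pass |lnFC| >= threshold and adjusted p <
    threshold with one shared sign are kept.
    """
    cond_a, cond_b = comparison
    cond_arr = cells.meta["condition"].to_numpy()
    type_arr = cells.meta["cell_type"].to_numpy()
    for name in comparison:
        if not _condition_mask(cond_arr, name, pooled_conditions).any():
            raise ValueError(f"condition {name!r} has no cells")
    mask_a = _condition_mask(cond_arr, cond_a, pooled_conditions)
    mask_b = _condition_mask(cond_arr, cond_b, pooled_conditions)

    inter = significant_interactions[["source_type", "target_type", "pair_id"]].drop_duplicates()
    # collect the (cell_type, gene) tests needed
    needed: set = set()
    for row in inter.itertuples(index=False):
        rec = db[row.pair_id]
        needed.add((row.source_type, rec.ligand))
        for s in rec.receptor_subunits:
            needed.add((row.target_type, s))

    by_type: dict = {}
    for t, g in sorted(needed):
        by_type.setdefault(t, []).append(g)

    stats: dict = {}  # (type, gene) -> (p, lnfc)
    padj: dict = {}  # (type, gene) -> BH-adjusted p within the type
    for t, genes in by_type.items():
        E = _dense_expression(cells, genes)
        rows_a = E[mask_a & (type_arr == t)]
        rows_b = E[mask_b & (type_arr == t)]
        if len(rows_a) == 0 or len(rows_b) == 0:
            for g in genes:
                stats[(t, g)] = (1.0, 0.0)
            continue
        pvals = []
        for j, g in enumerate(genes):
            p, lnfc = _gene_stats(rows_a[:, j], rows_b[:, j])
            stats[(t, g)] = (p, lnfc)
            pvals.append(p)
        adj = multipletests(pvals, method="fdr_bh")[1]
        for g, a in zip(genes, adj):
            padj[(t, g)] = float(a)

    out_rows = []
    thr, pthr = config.lnfc_threshold, config.padj_threshold
    for row in inter.itertuples(index=False):
        rec = db[row.pair_id]
        key_l = (row.source_type, rec.ligand)
        if key_l not in padj:
            continue
        _, l_lnfc = stats[key_l]
        l_padj = padj[key_l]
        if abs(l_lnfc) < thr or l_padj >= pthr or l_lnfc == 0:
            continue
        sign = np.sign(l_lnfc)
        sub_lnfc, sub_padj, ok = [], [], True
        for s in rec.receptor_subunits:
            key_r = (row.target_type, s)
            if key_r not in padj:
                ok = False
                break
            _, r_lnfc = stats[key_r]
            r_padj = padj[key_r]
            if abs(r_lnfc) < thr or r_padj >= pthr or np.sign(r_lnfc) != sign:
                ok = False
                break
            sub_lnfc.append(r_lnfc)
            sub_padj.append(r_padj)
        if not ok:
            continue
        out_rows.append(
            (
                row.source_type,
                row.target_type,
                row.pair_id,
                l_lnfc,
                float(np.mean(sub_lnfc)),
                l_padj,
                float(np.max(sub_padj)),
                "up" if sign > 0 else "down",
            )
        )
    table = pd.DataFrame(
        out_rows,
        columns=["source_type", "target_type", "pair_id", "ligand_lnFC",
                 "receptor_lnFC", "ligand_padj", "receptor_padj", "direction"],
    )
    return DifferentialLR(comparison=comparison, table=table)


def run_comparisons(
    cells: NormalizedMatrix,
    comparisons: list[tuple[str, str]],
    db: LRDatabase,
    config: CommunicationConfig = CommunicationConfig(),
    seed: int = 0,
    pooled_conditions: dict | None = None,
    communication: dict | None = None,
):
    """Differential L-R tables for every listed condition comparison.

    Communication significance is computed once per plain condition (pooled
    conditions reuse their members' results); the significant set for a
    comparison is the union over its two conditions ("significant in at
    least one compared condition"). Returns ``(tables, summary)`` where
    ``summary`` has one row per comparison with up/down interaction counts.
    """
    cond_arr = cells.meta["condition"].to_numpy()
    pooled = pooled_conditions or {}
    known = set(pd.unique(cond_arr)) | set(pooled)
    plain: list = []
    for a, b in comparisons:
        for name in (a, b):
            if name not in known:
                raise ValueError(f"unknown condition {name!r} in comparisons")
            for member in pooled.get(name, [name]):
                if member not in plain:
                    plain.append(member)
    if communication is None:
        communication = score_communication(
            cells, db, config, seed=seed, conditions=plain
        )

    def _sig(name):
        frames = [
            communication[m].significant(config.significance_alpha)
            for m in pooled.get(name, [name])
        ]
        return pd.concat(frames, ignore_index=True)

    tables = {}
    summary_rows = []
    for a, b in comparisons:
        sig = pd.concat([_sig(a), _sig(b)], ignore_index=True)
        diff = differential_lr(
            cells, (a, b), sig, db, config, pooled_conditions=pooled
        )
        tables[(a, b)] = diff
        n_up = int((diff.table["direction"] == "up").sum())
        n_down = int((diff.table["direction"] == "down").sum())
        summary_rows.append((f"{a} vs {b}", n_up, n_down))
    summary = pd.DataFrame(summary_rows, columns=["comparison", "n_up", "n_down"])
    return tables, summary
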