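"""The combined target-discovery filter chain.

Candidate ligand-receptor interactions come from the single-cell side
(per-condition communication significance followed by directional
differential analysis); the spatial side then filters and annotates them:

1. co-occurrence filter — keep interactions whose source and target cell
   types positively co-occur in at least one selected compositional cluster
   (union rule; an intersection rule is available). Self-pairs are always
   kept: autocrine signaling needs no co-occurrence evidence.
2. co-expression annotation — map each surviving pair onto the slides with
   the minimum-principle score and correlate it with disease markers.
   Failures here (e.g. a ligand absent from the spatial panel) demote a hit
   with an evidence flag rather than excluding it: probe dropout is a
   finding, and a hit with single-cell plus co-occurrence support remains a
   hit. A strict mode that drops flagged hits is provided.

Hits are ranked by total absolute log fold change (|ligand lnFC| +
|receptor lnFC|), ties broken by pair id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communication import CommunicationConfig, DifferentialLR, run_comparisons
from .composition import (
    CompositionClustering,
    CooccurrenceResult,
    cluster_compositions,
    cooccurrence,
    select_clusters,
)
from .deconvolution import DeconvolutionConfig, build_signatures, deconvolve
from .io_formats import (
    CellMatrix,
    LRDatabase,
    RunManifest,
    SpotMatrix,
    write_table,
)
from .preprocess import QCThresholds, normalize, qc_filter
from .spatial_coexpression import (
    MissingGeneError,
    pair_coexpression_for_hit,
    spatial_correlation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IntegratedHit",
    "PipelineConfig",
    "apply_cooccurrence_filter",
    "build_hits",
    "run_pipeline",
]


@dataclass
class IntegratedHit:
    comparison: tuple[str, str]
    source_type: str
    target_type: str
    pair_id: str
    direction: str
    ligand_lnFC: float
    receptor_lnFC: float
    cooccurrence_class: str
    supporting_clusters: tuple[int, ...]
    coexpressed_fraction: dict  # slide -> fraction, empty when flagged
    marker_correlation: dict  # marker -> median r (all slides)
    evidence_flags: tuple[str, ...] = ()

    @property
    def rank_key(self):
        return (-(abs(self.ligand_lnFC) + abs(self.receptor_lnFC)), self.pair_id)


@dataclass
class PipelineConfig:
    """Composite configuration for the end-to-end run."""

    comparisons: list = field(default_factory=list)  # [(cond_a, cond_b), ...]
    diseased_conditions: list = field(default_factory=list)
    cell_types_of_interest: list = field(default_factory=list)
    marker_genes: list = field(default_factory=list)
    qc: QCThresholds = field(default_factory=QCThresholds)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    communication: CommunicationConfig = field(default_factory=CommunicationConfig)
    pooled_conditions: dict = field(default_factory=dict)
    k_range: tuple = (1, 15)
    selected_k: int | None = None
    manual_clusters: list | None = None
    n_select_clusters: int = 2
    presence_threshold: float = 0.05
    cooccurrence_alpha: float = 0.05
    combine_rule: str = "union"
    coexpression_threshold: float = 0.0
    strict_spatial: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.comparisons:
            raise ValueError("pipeline config needs at least one comparison")
        if self.combine_rule not in ("union", "intersection"):
            raise ValueError("combine_rule must be 'union' or 'intersection'")
        if self.manual_clusters is None and not self.diseased_conditions:
            raise ValueError(
                "automatic cluster selection needs diseased_conditions"
            )


def apply_cooccurrence_filter(
    diff: DifferentialLR,
    cooc_results: list[CooccurrenceResult],
    selected_clusters: list[int],
    combine_rule: str = "union",
) -> DifferentialLR:
    """Keep interactions between positively co-occurring cell types.

    Union rule: positive in at least one selected cluster. Intersection
    rule: positive in all of them. Self-pairs always pass. Interactions
    naming a cell type absent from the spatial cell-type set are dropped
    with a warning (the spatial data cannot support them either way).
    """
    by_cluster = {c.cluster_id: c for c in cooc_results}
    missing = [c for c in selected_clusters if c not in by_cluster]
    if missing:
        raise ValueError(f"no co-occurrence result for clusters {missing}")
    pos_sets = [by_cluster[c].positive_pairs() for c in selected_clusters]
    spatial_types = set()
    for c in selected_clusters:
        t = by_cluster[c].table
        spatial_types |= set(t["type_a"]) | set(t["type_b"])

    keep_rows = []
    for row in diff.table.itertuples(index=False):
        if row.source_type == row.target_type:
            keep_rows.append(True)
            continue
        if row.source_type not in spatial_types or row.target_type not in spatial_types:
            logger.warning(
                "dropping %s (%s -> %s): cell type absent from spatial data",
                row.pair_id, row.source_type, row.target_type,
            )
            keep_rows.append(False)
            continue
        pair = frozenset((row.source_type, row.target_type))
        hits = [pair in s for s in pos_sets]
        keep_rows.append(any(hits) if combine_rule == "union" else all(hits))
    return DifferentialLR(
        comparison=diff.comparison,
        table=diff.table[np.array(keep_rows, dtype=bool)].reset_index(drop=True),
    )


def _cooccurrence_support(row, cooc_results, selected_clusters):
    if row.source_type == row.target_type:
        return "positive", tuple(selected_clusters)
    pair = frozenset((row.source_type, row.target_type))
    support = tuple(
        c.cluster_id
        for c in cooc_results
        if c.cluster_id in selected_clusters and pair in c.positive_pairs()
    )
    return ("positive" if support else "not-positive"), support


def build_hits(
    filtered: DifferentialLR,
    spots_norm,
    db: LRDatabase,
    cooc_results: list[CooccurrenceResult],
    selected_clusters: list[int],
    marker_genes=(),
    coexpression_threshold: float = 0.0,
    strict_spatial: bool = False,
) -> list[IntegratedHit]:
    """Annotate surviving interactions with spatial evidence and rank them."""
    hits = []
    for row in filtered.table.itertuples(index=False):
        rec = db[row.pair_id]
        flags: list[str] = []
        coex_frac: dict = {}
        marker_r: dict = {}
        try:
            cmap = pair_coexpression_for_hit(spots_norm, rec, coexpression_threshold)
        except MissingGeneError as e:
            for g in e.genes:
                if g == rec.ligand:
                    flags.append("ligand-absent-from-panel")
                else:
                    flags.append(f"receptor-subunit-absent-from-panel:{g}")
            cmap = None
        if cmap is not None:
            frac = cmap.coexpressed_fraction_per_slide()
            coex_frac = dict(zip(frac["sample_id"], frac["coexpressed_fraction"]))
            for marker in marker_genes:
                try:
                    mv = spots_norm.gene_vector(marker)
                except KeyError:
                    flags.append(f"marker-absent-from-panel:{marker}")
                    continue
                corr = spatial_correlation(spots_norm, cmap.score, mv, grouping="all")
                marker_r[marker] = float(corr.by_group.iloc[0]["median_r"])
        cls, support = _cooccurrence_support(row, cooc_results, selected_clusters)
        hits.append(
            IntegratedHit(
                comparison=filtered.comparison,
                source_type=row.source_type,
                target_type=row.target_type,
                pair_id=row.pair_id,
                direction=row.direction,
                ligand_lnFC=float(row.ligand_lnFC),
                receptor_lnFC=float(row.receptor_lnFC),
                cooccurrence_class=cls,
                supporting_clusters=support,
                coexpressed_fraction=coex_frac,
                marker_correlation=marker_r,
                evidence_flags=tuple(flags),
            )
        )
    if strict_spatial:
        hits = [h for h in hits if not h.evidence_flags]
    hits.sort(key=lambda h: h.rank_key)
    return hits


def hits_to_frame(hits: list[IntegratedHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "comparison": f"{h.comparison[0]} vs {h.comparison[1]}",
                "source_type": h.source_type,
                "target_type": h.target_type,
                "pair_id": h.pair_id,
                "direction": h.direction,
                "ligand_lnFC": h.ligand_lnFC,
                "receptor_lnFC": h.receptor_lnFC,
                "cooccurrence_class": h.cooccurrence_class,
                "supporting_clusters": ";".join(map(str, h.supporting_clusters)),
                "coexpressed_fraction": ";".join(
                    f"{k}={v:.6g}" for k, v in sorted(h.coexpressed_fraction.items())
                ),
                "marker_correlation": ";".join(
                    f"{k}={v:.6g}" for k, v in sorted(h.marker_correlation.items())
                ),
                "evidence_flags": ";".join(h.evidence_flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "source_type", "target_type", "pair_id", "direction",
            "ligand_lnFC", "receptor_lnFC", "cooccurrence_class",
            "supporting_clusters", "coexpressed_fraction", "marker_correlation",
            "evidence_flags",
        ],
    )


def run_pipeline(
    config: PipelineConfig,
    cells: CellMatrix,
    spots: SpotMatrix,
    db: LRDatabase,
    outdir=None,
):
    """Execute the full chain: QC -> normalize -> communication ->
    deconvolution -> compositional clustering -> co-occurrence ->
    differential L-R -> co-occurrence filter -> co-expression -> hits.

    Deterministic given ``config.seed``. When ``outdir`` is given each
    stage writes its TSV there and a manifest is written at the end.
    Returns ``(hits, manifest, artifacts)`` where ``artifacts`` is a dict
    of intermediate results keyed by stage name.
    """
    from pathlib import Path

    config.validate()
    manifest = RunManifest(seed=config.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        manifest.record_stage(name)
        if out is not None:
            manifest.write(out / "manifest.json")

    cells_f, cell_qc = qc_filter(cells, config.qc)
    spots_f, spot_qc = qc_filter(spots, config.qc)
    if out is not None:
        write_table(cell_qc, out / "qc_cells.tsv")
        write_table(spot_qc, out / "qc_spots.tsv")
    _stage("qc")

    cells_n = normalize(cells_f)
    spots_n = normalize(spots_f)
    _stage("normalize")

    sig = build_signatures(cells_f, spots_f.gene_ids)
    abundance, deconv_report = deconvolve(spots_f, sig, config.deconvolution)
    if out is not None:
        write_table(abundance.to_frame(), out / "abundance.tsv")
        write_table(deconv_report, out / "deconvolution_report.tsv")
    _stage("deconvolve")

    clustering = cluster_compositions(
        abundance,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        seed=config.seed,
        selected_k=config.selected_k,
    )
    if out is not None:
        write_table(
            pd.DataFrame(
                {"k": list(clustering.wss), "wss": list(clustering.wss.values())}
            ),
            out / "wss.tsv",
        )
        write_table(
            pd.DataFrame(
                {"spot_id": clustering.spot_ids, "cluster": clustering.labels}
            ),
            out / "clusters.tsv",
        )
    _stage("compose")

    selected = select_clusters(
        clustering,
        abundance,
        diseased_conditions=config.diseased_conditions,
        cell_types_of_interest=config.cell_types_of_interest or None,
        n_select=config.n_select_clusters,
        manual=config.manual_clusters,
    )
    cooc_results = [
        cooccurrence(
            abundance, clustering, c, config.presence_threshold, config.cooccurrence_alpha
        )
        for c in selected
    ]
    if out is not None:
        write_table(
            pd.concat(
                [r.table.assign(cluster=r.cluster_id) for r in cooc_results],
                ignore_index=True,
            ),
            out / "cooccurrence.tsv",
        )
    _stage("cooccur")

    diff_tables, summary = run_comparisons(
        cells_n,
        config.comparisons,
        db,
        config.communication,
        seed=config.seed,
        pooled_conditions=config.pooled_conditions,
    )
    if out is not None:
        write_table(summary, out / "differential_summary.tsv")
        for (a, b), d in diff_tables.items():
            write_table(d.table, out / f"differential_{a}_vs_{b}.tsv")
    _stage("differential")

    all_hits: list[IntegratedHit] = []
    for comp, diff in diff_tables.items():
        filtered = apply_cooccurrence_filter(
            diff, cooc_results, selected, config.combine_rule
        )
        all_hits.extend(
            build_hits(
                filtered,
                spots_n,
                db,
                cooc_results,
                selected,
                marker_genes=config.marker_genes,
                coexpression_threshold=config.coexpression_threshold,
                strict_spatial=config.strict_spatial,
            )
        )
    _stage("integrate")

    hits_df = hits_to_frame(all_hits)
    if out is not None:
        write_table(hits_df, out / "hits.tsv")
        summary_json = {
            "comparisons": summary.to_dict(orient="records"),
            "selected_clusters": [int(c) for c in selected],
            "selected_k": clustering.selected_k,
            "n_hits": len(all_hits),
        }
        import json

        (out / "summary.json").write_text(json.dumps(summary_json, indent=2))
    _stage("done")

    artifacts = {
        "cells_norm": cells_n,
        "spots_norm": spots_n,
        "abundance": abundance,
        "clustering": clustering,
        "selected_clusters": selected,
        "cooccurrence": cooc_results,
        "differential": diff_tables,
        "summary": summary,
        "hits_frame": hits_df,
    }
    return all_hits, manifest, artifacts


def join_common_hits(hits_a: pd.DataFrame, hits_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-tissue comparison: join two runs' hit tables on pair_id.

    Annotates whether the direction of regulation agrees between the two
    runs (e.g. a pair up in one tissue and down in the other).
    """
    merged = hits_a.merge(hits_b, on="pair_id", suffixes=("_a", "_b"))
    merged["direction_agrees"] = merged["direction_a"] == merged["direction_b"]
    return merged
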