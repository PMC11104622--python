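"""Minimum-principle spatial co-expression and marker correlation.

A spot's co-expression of a gene set is the minimum of the genes'
normalized expression there — the expression shared by the whole set is at
least that minimum. Scores below a noise threshold t are reported as zero.
For two-gene sets each spot is also assigned a display channel: none,
gene1-only, gene2-only, or co-expressed. A gene counts as present at a spot
when its value is >= t and strictly positive, so an unexpressed gene never
reads as co-expressed at the default t = 0.

Colocalization with disease markers is quantified by the Pearson
correlation between two per-spot vectors computed within each slide
(sample) separately, aggregated by the median across slides, overall and
per condition. A slide where either vector is constant has no defined
correlation and is excluded from aggregation.

A gene missing from the spot panel is an explicit error naming the gene:
probe absence is a finding, not a silent skip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_formats import LRRecord
from .preprocess import NormalizedMatrix

__all__ = [
    "MissingGeneError",
    "CoexpressionMap",
    "SpatialCorrelation",
    "min_coexpression",
    "pair_coexpression_for_hit",
    "spatial_correlation",
]


class MissingGeneError(KeyError):
    """A requested gene is absent from the spot gene panel."""

    def __init__(self, genes):
        self.genes = list(genes)
        super().__init__(f"genes absent from the spot panel: {self.genes}")


@dataclass
class CoexpressionMap:
    gene_set: list[str]
    score: np.ndarray  # per-spot, thresholded (values < t reported as 0)
    threshold: float
    channel: np.ndarray | None  # per-spot label for 2-gene sets, else None
    spot_ids: list[str]
    meta: pd.DataFrame

    def coexpressed_fraction_per_slide(self) -> pd.DataFrame:
        """Fraction of each slide's spots where the whole set is present."""
        # score is already thresholded: co-expressed spots are exactly those
        # with a positive reported score (whole set present above threshold)
        co = self.score > 0
        df = pd.DataFrame({"sample_id": self.meta["sample_id"], "co": co})
        out = df.groupby("sample_id")["co"].mean().rename("coexpressed_fraction")
        return out.reset_index()


@dataclass
class SpatialCorrelation:
    per_slide: pd.DataFrame  # sample_id, condition, r (NaN where undefined)
    by_group: pd.DataFrame  # group ("all" or a condition), median_r, n_slides


def _expression_block(spots: NormalizedMatrix, genes) -> np.ndarray:
    missing = [g for g in genes if g not in spots.gene_ids]
    if missing:
        raise MissingGeneError(missing)
    cols = [spots.gene_ids.index(g) for g in genes]
    return np.asarray(spots.values[:, cols].todense())


def min_coexpression(
    spots: NormalizedMatrix, gene_set, threshold: float = 0.0
) -> CoexpressionMap:
    """Per-spot minimum-principle co-expression of ``gene_set``."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    E = _expression_block(spots, gene_set)
    raw = E.min(axis=1)
    score = np.where(raw < threshold, 0.0, raw)
    channel = None
    if len(gene_set) == 2:
        present = (E >= threshold) & (E > 0)
        channel = np.select(
            [
                present[:, 0] & present[:, 1],
                present[:, 0] & ~present[:, 1],
                ~present[:, 0] & present[:, 1],
            ],
            ["co-expressed", "gene1-only", "gene2-only"],
            default="none",
        )
    return CoexpressionMap(
        gene_set=gene_set,
        score=score,
        threshold=threshold,
        channel=channel,
        spot_ids=list(spots.unit_ids),
        meta=spots.meta,
    )


def pair_coexpression_for_hit(
    spots: NormalizedMatrix, lr_pair: LRRecord, threshold: float = 0.0
) -> CoexpressionMap:
    """Co-expression map of a ligand with all its receptor subunits."""
    gene_set = [lr_pair.ligand, *lr_pair.receptor_subunits]
    return min_coexpression(spots, gene_set, threshold)


def spatial_correlation(
    spots: NormalizedMatrix,
    vector_a: np.ndarray,
    vector_b: np.ndarray,
    grouping: str = "by-condition",
) -> SpatialCorrelation:
    """Per-slide Pearson correlation of two per-spot vectors.

    ``grouping``: "all" aggregates over every slide only; "by-condition"
    additionally aggregates within each condition. Aggregation is the
    median r across the group's slides with defined correlation.
    """
    a = np.asarray(vector_a, dtype=float)
    b = np.asarray(vector_b, dtype=float)
    n = len(spots.unit_ids)
    if a.shape != (n,) or b.shape != (n,):
        raise ValueError("vectors must have one value per spot")
    samples = spots.meta["sample_id"].to_numpy()
    conds = spots.meta["condition"].to_numpy()
    rows = []
    for s in pd.unique(samples):
        m = samples == s
        cond = conds[m][0]
        if np.ptp(a[m]) == 0 or np.ptp(b[m]) == 0 or m.sum() < 2:
            rows.append((s, cond, np.nan))
            continue
        r = float(pearsonr(a[m], b[m]).statistic)
        rows.append((s, cond, r))
    per_slide = pd.DataFrame(rows, columns=["sample_id", "condition", "r"])

    groups = [("all", per_slide)]
    if grouping == "by-condition":
        for c in pd.unique(per_slide["condition"]):
            groups.append((c, per_slide[per_slide["condition"] == c]))
    elif grouping != "all":
        raise ValueError("grouping must be 'all' or 'by-condition'")
    agg_rows = []
    for name, sub in groups:
        defined = sub["r"].dropna()
        agg_rows.append(
            (name, float(defined.median()) if len(defined) else np.nan, len(defined))
        )
    by_group = pd.DataFrame(agg_rows, columns=["group", "median_r", "n_slides"])
    return SpatialCorrelation(per_slide=per_slide, by_group=by_group)
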