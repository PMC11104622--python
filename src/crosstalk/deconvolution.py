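"""Spot deconvolution by regularized nonnegative least squares.

Estimates a nonnegative cell-type abundance vector per spot from cell-type
expression signatures built on the gene intersection of the two modalities.
This is a deterministic stand-in for Bayesian spot deconvolution that keeps
its inputs (a single-cell reference, shared genes) and outputs (spot x
cell-type abundances): per spot we solve

    min_{a >= 0}  ||y - S a||^2 + lambda ||a - abar||^2

where y is the spot's counts rescaled to ``expected_cells_per_spot`` cells'
worth of counts, S the signature matrix, and abar a uniform prior vector
summing to ``expected_cells_per_spot``. The expected-cells prior (default
n = 8) sets the abundance scale; the detection-sensitivity convention
alpha = 20 maps to lambda = 1/alpha (weaker regularization for higher
sensitivity) — a documented convention, not a claim about any Bayesian
model's internals.

The problem is strictly convex for lambda > 0 and solved exactly via NNLS
on the Tikhonov-augmented system [S; sqrt(lambda) I], [y; sqrt(lambda) abar].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .io_formats import CellMatrix, SpotMatrix

__all__ = [
    "SignatureMatrix",
    "AbundanceMatrix",
    "DeconvolutionConfig",
    "build_signatures",
    "deconvolve",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    expected_cells_per_spot: float = 8.0
    detection_sensitivity: float = 20.0  # lambda = 1 / detection_sensitivity
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.expected_cells_per_spot <= 0:
            raise ValueError("expected_cells_per_spot must be positive")
        if self.detection_sensitivity < 0:
            raise ValueError("detection_sensitivity must be nonnegative")

    @property
    def regularization_weight(self) -> float:
        if self.detection_sensitivity == 0:
            return 0.0
        return 1.0 / self.detection_sensitivity


@dataclass
class SignatureMatrix:
    """Mean expression per gene per cell type on the shared gene set."""

    values: np.ndarray  # (n_genes, n_types)
    gene_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("signature shape does not match labels")
        if self.values.min() < 0:
            raise ValueError("signatures must be nonnegative")


@dataclass
class AbundanceMatrix:
    """Nonnegative spot x cell-type abundances with spot metadata."""

    values: np.ndarray  # (n_spots, n_types)
    spot_ids: list[str]
    cell_types: list[str]
    meta: pd.DataFrame  # sample_id, condition, x, y per spot

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-12:
            raise ValueError("abundances must be nonnegative")
        self.values = np.maximum(self.values, 0.0)

    def proportions(self) -> np.ndarray:
        """Rows scaled to sum 1 (rows with zero sum stay zero)."""
        tot = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, self.values / tot, 0.0)
        return p

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.cell_types)
        df.insert(0, "spot_id", self.spot_ids)
        return pd.concat([df, self.meta.reset_index(drop=True)], axis=1)


def build_signatures(cells: CellMatrix, spot_genes) -> SignatureMatrix:
    """Per-type mean raw counts restricted to the shared gene set.

    Raw counts are used (matching a count-likelihood deconvolution model);
    each signature column is on the scale of one cell's counts.
    """
    shared = [g for g in cells.gene_ids if g in set(spot_genes)]
    if not shared:
        raise ValueError("empty gene intersection between cells and spots")
    col_of = {g: j for j, g in enumerate(cells.gene_ids)}
    cols = [col_of[g] for g in shared]
    counts = sp.csr_matrix(cells.counts)[:, cols]
    if cells.n_cells == 0:
        raise ValueError("reference has no cells (did QC remove everything?)")
    types = sorted(set(cells.cell_type))
    sig = np.zeros((len(shared), len(types)))
    for t_i, t in enumerate(types):
        mask = cells.cell_type == t
        if not mask.any():
            raise ValueError(f"cell type {t} has no cells")
        sig[:, t_i] = np.asarray(counts[mask].mean(axis=0)).ravel()
    return SignatureMatrix(values=sig, gene_ids=shared, cell_types=types)


def _solve_spot(S: np.ndarray, y: np.ndarray, lam: float, abar: np.ndarray, max_iter: int):
    if lam > 0:
        A = np.vstack([S, np.sqrt(lam) * np.eye(S.shape[1])])
        b = np.concatenate([y, np.sqrt(lam) * abar])
    else:
        A, b = S, y
    try:
        a, _ = scipy.optimize.nnls(A, b, maxiter=max_iter)
        converged = True
    except RuntimeError:
        a, _ = scipy.optimize.nnls(A, b, maxiter=10 * max_iter)
        converged = False
    return a, converged


def deconvolve(
    spots: SpotMatrix,
    signatures: SignatureMatrix,
    config: DeconvolutionConfig = DeconvolutionConfig(),
):
    """Estimate cell-type abundances for every spot.

    Returns ``(AbundanceMatrix, report)``; the report flags spots whose
    solver did not converge within the iteration cap (their abundances are
    still returned) and spots with no counts on the shared genes, which
    carry no information and are assigned the uniform prior.
    """
    col_of = {g: j for j, g in enumerate(spots.gene_ids)}
    missing = [g for g in signatures.gene_ids if g not in col_of]
    if missing:
        raise ValueError(f"signature genes absent from spots: {missing[:5]}")
    cols = [col_of[g] for g in signatures.gene_ids]
    Y = np.asarray(sp.csr_matrix(spots.counts)[:, cols].todense(), dtype=float)

    S = signatures.values
    n_types = S.shape[1]
    n_exp = config.expected_cells_per_spot
    lam = config.regularization_weight
    abar = np.full(n_types, n_exp / n_types)
    # a spot holding n_exp average cells would total n_exp * mean column mass
    target_total = n_exp * S.sum(axis=0).mean()

    A = np.zeros((spots.n_spots, n_types))
    flags = []
    for i in range(spots.n_spots):
        y = Y[i]
        tot = y.sum()
        if tot == 0:
            A[i] = abar  # no data: the prior is the estimate
            flags.append("no_counts")
            continue
        y = y * (target_total / tot)
        a, converged = _solve_spot(S, y, lam, abar, config.max_iter)
        A[i] = a
        flags.append("" if converged else "not_converged")

    meta = pd.DataFrame(
        {
            "sample_id": spots.sample_id,
            "condition": spots.condition,
            "x": spots.xy[:, 0],
            "y": spots.xy[:, 1],
        }
    )
    report = pd.DataFrame({"spot_id": spots.spot_ids, "flag": flags})
    abundance = AbundanceMatrix(
        values=A,
        spot_ids=list(spots.spot_ids),
        cell_types=list(signatures.cell_types),
        meta=meta,
    )
    return abundance, report
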