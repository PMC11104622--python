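"""Readers, writers and in-memory containers for every external format.

The pipeline exchanges data through four container types:

* :class:`CellMatrix` — cell x gene counts with per-cell type/condition/sample
  labels (the single-cell/single-nucleus side).
* :class:`SpotMatrix` — spot x gene counts with 2-D array coordinates and
  per-spot sample/condition (the spatial side).
* :class:`LRDatabase` — ligand-receptor interaction records, where a receptor
  may be a multi-subunit complex (e.g. ITGAV-ITGB1).
* :class:`RunManifest` — a JSON record of config, seed and stage provenance.

On disk, count matrices use the 10x-style triplet layout: a Matrix Market
``.mtx`` file plus ``features.tsv`` and ``barcodes.tsv``. The matrix may be
stored genes-in-rows (10x convention, the default) or units-in-rows; the
orientation is a flag, never guessed. Gene order always follows the features
file — readers never reorder.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CellMatrix",
    "SpotMatrix",
    "LRDatabase",
    "LRRecord",
    "RunManifest",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_spot_matrix",
    "write_spot_matrix",
    "read_lr_database",
    "write_lr_database",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dup[:5]}")


@dataclass
class CellMatrix:
    """Sparse cell x gene counts with per-cell annotation.

    ``counts`` is CSR with cells as rows. Labels are numpy object/str arrays
    aligned with ``cell_ids``.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: np.ndarray
    condition: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts contain negative entries")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell barcodes")
        for name in ("cell_type", "condition", "sample_id"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise FormatError(f"{name} must have one value per cell")
            setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, mask: np.ndarray) -> "CellMatrix":
        """Return a new matrix restricted to cells where ``mask`` is True."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_type=self.cell_type[idx],
            condition=self.condition[idx],
            sample_id=self.sample_id[idx],
        )


@dataclass
class SpotMatrix:
    """Sparse spot x gene counts with 2-D coordinates.

    Coordinates are abstract array units, origin top-left, y increasing
    downward; only relative positions matter to any computation here.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    spot_ids: list[str]
    xy: np.ndarray  # (n_spots, 2) float
    sample_id: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, g = self.counts.shape
        if n != len(self.spot_ids) or g != len(self.gene_ids):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts contain negative entries")
        _check_unique(self.gene_ids, "gene ids")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (n, 2) or not np.all(np.isfinite(self.xy)):
            raise FormatError("xy must be finite with shape (n_spots, 2)")
        for name in ("sample_id", "condition"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise FormatError(f"{name} must have one value per spot")
            setattr(self, name, arr)
        # spot ids unique within a sample; one condition per sample
        key = pd.DataFrame({"sample": self.sample_id, "spot": self.spot_ids})
        if key.duplicated().any():
            raise FormatError("duplicate spot barcodes within a sample")
        cond_per_sample = (
            pd.DataFrame({"sample": self.sample_id, "cond": self.condition})
            .groupby("sample")["cond"]
            .nunique()
        )
        bad = cond_per_sample[cond_per_sample > 1]
        if len(bad):
            raise FormatError(
                f"samples with more than one condition: {list(bad.index)}"
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, mask: np.ndarray) -> "SpotMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpotMatrix(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            spot_ids=[self.spot_ids[i] for i in idx],
            xy=self.xy[idx],
            sample_id=self.sample_id[idx],
            condition=self.condition[idx],
        )


@dataclass(frozen=True)
class LRRecord:
    pair_id: str
    ligand: str
    receptor_subunits: tuple[str, ...]
    pathway: str = ""

    def __post_init__(self) -> None:
        if not self.receptor_subunits:
            raise FormatError(f"pair {self.pair_id}: empty receptor subunit list")

    @property
    def genes(self) -> tuple[str, ...]:
        return (self.ligand,) + self.receptor_subunits


@dataclass
class LRDatabase:
    """An ordered collection of ligand-receptor interaction records."""

    records: list[LRRecord]

    def __post_init__(self) -> None:
        _check_unique([r.pair_id for r in self.records], "pair ids")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, pair_id: str) -> LRRecord:
        for r in self.records:
            if r.pair_id == pair_id:
                return r
        raise KeyError(pair_id)

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            for g in r.genes:
                if g not in out:
                    out.append(g)
        return out


@dataclass
class RunManifest:
    """Provenance record written atomically at the end of each stage."""

    config: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)
    seed: int | None = None
    versions: dict = field(default_factory=dict)

    def record_stage(self, name: str) -> None:
        self.stages.append(name)

    def checksum_file(self, label: str, path: str | Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[label] = h

    def write(self, path: str | Path) -> None:
        """Atomic write: temp file in the target directory, then rename."""
        path = Path(path)
        payload = json.dumps(
            {
                "config": self.config,
                "stages": self.stages,
                "input_checksums": self.input_checksums,
                "seed": self.seed,
                "versions": self.versions,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


# ---------------------------------------------------------------------------
# triplet matrix helpers


def _read_triplet(matrix_path, features_path, barcodes_path, genes_in_rows):
    mat = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if genes_in_rows:
        mat = mat.T
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix shape {mat.shape} inconsistent with {len(barcodes)} "
            f"barcodes x {len(genes)} features"
        )
    return mat, genes, barcodes


def _write_triplet(counts, gene_ids, unit_ids, outdir, genes_in_rows=True):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = counts.T if genes_in_rows else counts
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(mat))
    pd.Series(gene_ids).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(unit_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_cell_matrix(
    matrix_path,
    features_path,
    barcodes_path,
    metadata_path,
    genes_in_rows: bool = True,
) -> CellMatrix:
    """Read a 10x-style triplet count matrix plus a cell metadata table.

    The metadata TSV must have columns ``barcode``, ``cell_type``,
    ``condition``, ``sample_id``. Every barcode in the matrix must appear in
    the metadata; cells absent from metadata are rejected, not dropped.
    """
    counts, genes, barcodes = _read_triplet(
        matrix_path, features_path, barcodes_path, genes_in_rows
    )
    _check_unique(barcodes, "cell barcodes")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"barcode", "cell_type", "condition", "sample_id"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata missing columns: {sorted(missing_cols)}")
    _check_unique(meta["barcode"], "metadata barcodes")
    meta = meta.set_index("barcode")
    absent = [b for b in barcodes if b not in meta.index]
    if absent:
        raise FormatError(f"barcodes missing from metadata: {absent[:5]}")
    meta = meta.loc[barcodes]
    return CellMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=barcodes,
        cell_type=meta["cell_type"].to_numpy(dtype=object),
        condition=meta["condition"].to_numpy(dtype=object),
        sample_id=meta["sample_id"].to_numpy(dtype=object),
    )


def write_cell_matrix(cm: CellMatrix, outdir, genes_in_rows: bool = True) -> None:
    _write_triplet(cm.counts, cm.gene_ids, cm.cell_ids, outdir, genes_in_rows)
    pd.DataFrame(
        {
            "barcode": cm.cell_ids,
            "cell_type": cm.cell_type,
            "condition": cm.condition,
            "sample_id": cm.sample_id,
        }
    ).to_csv(Path(outdir) / "metadata.tsv", sep="\t", index=False)


def read_spot_matrix(
    matrix_path,
    features_path,
    barcodes_path,
    positions_path,
    sample_meta_path,
    genes_in_rows: bool = True,
) -> SpotMatrix:
    """Read a spatial triplet matrix with spot coordinates.

    ``positions_path`` is a CSV with columns ``barcode,x,y`` and an optional
    ``sample_id`` column; when absent, the sample-meta file must list exactly
    one sample, which every spot is assigned to. ``sample_meta_path`` is a
    TSV mapping ``sample_id`` to ``condition``.

    Position rows for barcodes not present in the matrix are ignored with a
    warning; a matrix barcode without coordinates is an error.
    """
    counts, genes, barcodes = _read_triplet(
        matrix_path, features_path, barcodes_path, genes_in_rows
    )
    pos = pd.read_csv(positions_path, dtype={"barcode": str})
    if not {"barcode", "x", "y"} <= set(pos.columns):
        raise FormatError("positions CSV must have columns barcode,x,y")
    smeta = pd.read_csv(sample_meta_path, sep="\t", dtype=str)
    if not {"sample_id", "condition"} <= set(smeta.columns):
        raise FormatError("sample meta must have columns sample_id, condition")
    cond_of = dict(zip(smeta["sample_id"], smeta["condition"]))

    if "sample_id" not in pos.columns:
        if len(cond_of) != 1:
            raise FormatError(
                "positions CSV has no sample_id column and sample meta lists "
                f"{len(cond_of)} samples; cannot assign spots to samples"
            )
        pos = pos.assign(sample_id=next(iter(cond_of)))

    extra = set(pos["barcode"]) - set(barcodes)
    if extra:
        logger.warning(
            "positions file has %d barcodes absent from the matrix; ignored",
            len(extra),
        )
    pos = pos.set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise FormatError(f"spots without coordinates: {missing[:5]}")
    pos = pos.loc[barcodes]
    sample = pos["sample_id"].to_numpy(dtype=object)
    unknown = sorted(set(sample) - set(cond_of))
    if unknown:
        raise FormatError(f"samples missing from sample meta: {unknown}")
    return SpotMatrix(
        counts=counts,
        gene_ids=genes,
        spot_ids=barcodes,
        xy=pos[["x", "y"]].to_numpy(dtype=float),
        sample_id=sample,
        condition=np.array([cond_of[s] for s in sample], dtype=object),
    )


def write_spot_matrix(sm: SpotMatrix, outdir, genes_in_rows: bool = True) -> None:
    _write_triplet(sm.counts, sm.gene_ids, sm.spot_ids, outdir, genes_in_rows)
    outdir = Path(outdir)
    pd.DataFrame(
        {
            "barcode": sm.spot_ids,
            "x": sm.xy[:, 0],
            "y": sm.xy[:, 1],
            "sample_id": sm.sample_id,
        }
    ).to_csv(outdir / "positions.csv", index=False)
    (
        pd.DataFrame({"sample_id": sm.sample_id, "condition": sm.condition})
        .drop_duplicates()
        .to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    )


def read_lr_database(tsv_path, subunit_sep: str = ";") -> LRDatabase:
    """Read a ligand-receptor database TSV.

    Columns: ``pair_id``, ``ligand``, ``receptor`` (subunits joined by
    ``subunit_sep``), ``pathway`` (optional, free text). Subunit order is
    preserved.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    required = {"pair_id", "ligand", "receptor"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"L-R database missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        subunits = tuple(s.strip() for s in row.receptor.split(subunit_sep) if s.strip())
        if not subunits:
            raise FormatError(f"pair {row.pair_id}: empty receptor field")
        records.append(
            LRRecord(
                pair_id=row.pair_id.strip(),
                ligand=row.ligand.strip(),
                receptor_subunits=subunits,
                pathway=getattr(row, "pathway", ""),
            )
        )
    return LRDatabase(records)


def write_lr_database(db: LRDatabase, tsv_path, subunit_sep: str = ";") -> None:
    pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in db],
            "ligand": [r.ligand for r in db],
            "receptor": [subunit_sep.join(r.receptor_subunits) for r in db],
            "pathway": [r.pathway for r in db],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV with 6 significant digits for floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
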