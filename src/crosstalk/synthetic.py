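"""Paired synthetic single-cell + spatial datasets with known ground truth.

The generator emulates the structure of a paired snRNA-seq / Visium study:

* Cell programs: log-normal baseline gene means shared across cell types,
  with a block of marker genes elevated per type. Condition-dependent
  ligand-receptor programs are planted by multiplying the ligand mean in the
  source type and the receptor-subunit means in the target type by
  exp(ln-fold-change) in the affected condition only.
* Cells: negative-binomial counts with a single dispersion shared across
  genes (var = mu + mu^2 / dispersion) and log-normal library sizes.
* Spots: each sample is a square grid partitioned into spatially contiguous
  archetype blocks. A spot draws its cell-type composition from its
  archetype's Dirichlet, draws ~Poisson(8) latent cells (truncated >= 1),
  and its counts are the sum of those cells' negative-binomial draws —
  generative mixing, matching the physical model of a 55 um capture spot
  that pools roughly 8-15 cells.
* Co-localization ground truth: pairs listed in ``colocalized_pairs`` share
  a high-concentration archetype; pairs in ``segregated_pairs`` dominate
  disjoint archetypes and never co-dominate any.

Planted effect sizes default to the |ln-FC| 0.1-1.1 range observed for
dysregulated L-R pairs in kidney/liver fibro-inflammatory disease; real
effect-size distributions are unknown, so this range is a stated assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io_formats import CellMatrix, LRDatabase, LRRecord, SpotMatrix

__all__ = [
    "PlantedLR",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cell_programs",
    "simulate_cells",
    "simulate_spots",
    "simulate_paired",
    "make_lr_database",
]


class ConfigError(ValueError):
    """Raised for invalid or internally inconsistent simulation configs."""


@dataclass(frozen=True)
class PlantedLR:
    """A condition-dependent ligand-receptor program to plant.

    ``ligand_lnfc`` / ``receptor_lnfc`` are natural-log fold changes applied
    in ``condition`` (relative to all other conditions) to the ligand in the
    source type and to every receptor subunit in the target type.
    """

    pair_id: str
    ligand: str
    receptor_subunits: tuple[str, ...]
    source_type: str
    target_type: str
    condition: str
    ligand_lnfc: float
    receptor_lnfc: float


@dataclass(frozen=True)
class SimulationConfig:
    n_cell_types: int = 5
    n_genes: int = 200
    n_cells_per_type_per_condition: int = 150
    conditions: tuple[str, ...] = ("healthy", "disease")
    cells_per_spot_mean: float = 8.0
    n_spots_per_sample: int = 196
    n_samples_per_condition: int = 2
    n_archetypes: int = 3
    dirichlet_concentration_high: float = 24.0
    dirichlet_concentration_mid: float = 2.0
    dirichlet_concentration_low: float = 0.9
    colocalized_pairs: tuple[tuple[str, str], ...] = ()
    segregated_pairs: tuple[tuple[str, str], ...] = ()
    planted_lr: tuple[PlantedLR, ...] = ()
    coloc_intensity_sigma: float = 1.0
    seg_anticorr_sigma: float = 1.2
    nb_dispersion: float = 2.0
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.25
    marker_genes_per_type: int = 10
    marker_fold: float = 8.0
    planted_gene_baseline_fold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_spot_mean <= 0:
            raise ConfigError("cells_per_spot_mean must be positive")
        if self.library_size_mean <= 0:
            raise ConfigError("library_size_mean must be positive")
        if min(self.dirichlet_concentration_high, self.dirichlet_concentration_low) <= 0:
            raise ConfigError("Dirichlet concentrations must be positive")
        if len(self.conditions) < 2:
            raise ConfigError("at least two conditions are required")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        coloc = {frozenset(p) for p in self.colocalized_pairs}
        segr = {frozenset(p) for p in self.segregated_pairs}
        if coloc & segr:
            raise ConfigError("a pair cannot be both colocalized and segregated")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(f"type_{i + 1}" for i in range(self.n_cell_types))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i:04d}" for i in range(self.n_genes))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    # means[type][condition] -> (n_genes,) relative expression program
    means: dict
    planted: tuple[PlantedLR, ...]
    cell_types: tuple[str, ...]
    gene_ids: tuple[str, ...]
    # filled by simulate_spots
    composition: np.ndarray | None = None  # (n_spots, n_types), rows sum to 1
    cells_per_spot: np.ndarray | None = None  # latent cell count per spot
    archetype: np.ndarray | None = None  # archetype label per spot
    archetype_concentration: np.ndarray | None = None  # (n_arch, n_types)


def _gene_index(config: SimulationConfig) -> dict:
    return {g: i for i, g in enumerate(config.gene_ids)}


def simulate_cell_programs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Build per-type, per-condition mean expression programs.

    The baseline is log-normal across genes and shared by all types; each
    type gets a disjoint marker block multiplied by ``marker_fold``. Genes
    participating in a planted pair get an elevated baseline in their
    expressing type (ligands and receptors are expressed by their cell
    types) before the condition effect is applied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gidx = _gene_index(config)
    types = config.cell_types

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    means: dict = {}
    marker_block = config.marker_genes_per_type
    if marker_block * config.n_cell_types > config.n_genes:
        raise ConfigError("not enough genes for the requested marker blocks")
    for t_i, t in enumerate(types):
        prog = baseline.copy()
        lo = t_i * marker_block
        prog[lo : lo + marker_block] *= config.marker_fold
        means[t] = {c: prog.copy() for c in config.conditions}

    # validate planted effects: the same (gene, type, condition) may not carry
    # two different multiplicative effects; identical replants merge.
    applied: dict = {}

    def _apply(gene: str, cell_type: str, condition: str, lnfc: float) -> None:
        if gene not in gidx:
            raise ConfigError(f"planted gene {gene} not in the gene panel")
        if cell_type not in means:
            raise ConfigError(f"planted cell type {cell_type} unknown")
        if condition not in config.conditions:
            raise ConfigError(f"planted condition {condition} unknown")
        key = (gene, cell_type, condition)
        if key in applied:
            if applied[key] != lnfc:
                raise ConfigError(
                    f"gene {gene} planted twice in {cell_type}/{condition} "
                    f"with conflicting effects {applied[key]} vs {lnfc}"
                )
            return  # identical replant: single multiplicative effect
        applied[key] = lnfc
        j = gidx[gene]
        means[cell_type][condition][j] *= float(np.exp(lnfc))

    boosted: set = set()
    for p in config.planted_lr:
        # ligands/receptors are expressed by their types: raise the baseline
        # once per (gene, type) across all conditions before the effect
        for gene, cell_type in [(p.ligand, p.source_type)] + [
            (s, p.target_type) for s in p.receptor_subunits
        ]:
            if gene not in gidx:
                raise ConfigError(f"planted gene {gene} not in the gene panel")
            if (gene, cell_type) not in boosted:
                boosted.add((gene, cell_type))
                j = gidx[gene]
                for c in config.conditions:
                    means[cell_type][c][j] *= config.planted_gene_baseline_fold
        _apply(p.ligand, p.source_type, p.condition, p.ligand_lnfc)
        for s in p.receptor_subunits:
            _apply(s, p.target_type, p.condition, p.receptor_lnfc)

    return GroundTruth(
        means=means,
        planted=tuple(config.planted_lr),
        cell_types=types,
        gene_ids=config.gene_ids,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + mu^2/dispersion."""
    mu = np.asarray(mu, dtype=float)
    p = dispersion / (dispersion + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        out[pos] = rng.negative_binomial(dispersion, p[pos])
    return out


def simulate_cells(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> CellMatrix:
    """Draw the single-cell count matrix from the ground-truth programs."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    cell_type, condition, sample_id, cell_ids = [], [], [], []
    n_per = config.n_cells_per_type_per_condition
    log_lib_mu = np.log(config.library_size_mean) - config.library_size_sigma**2 / 2
    k = 0
    for cond in config.conditions:
        for t in truth.cell_types:
            prog = truth.means[t][cond]
            rel = prog / prog.sum()
            libs = rng.lognormal(log_lib_mu, config.library_size_sigma, size=n_per)
            for lib in libs:
                rows.append(_nb_draw(rng, rel * lib, config.nb_dispersion))
                cell_type.append(t)
                condition.append(cond)
                sample_id.append(f"sc_{cond}")
                cell_ids.append(f"cell_{k:06d}")
                k += 1
    counts = sp.csr_matrix(np.vstack(rows))
    return CellMatrix(
        counts=counts,
        gene_ids=list(truth.gene_ids),
        cell_ids=cell_ids,
        cell_type=np.array(cell_type, dtype=object),
        condition=np.array(condition, dtype=object),
        sample_id=np.array(sample_id, dtype=object),
    )


def build_archetype_concentrations(config: SimulationConfig) -> np.ndarray:
    """Dirichlet concentration vectors encoding the co-localization truth.

    Archetype 0 is the shared home of every colocalized pair, where both
    members sit at the *mid* concentration: they are recurrent minor
    components of that neighborhood, whose spot-to-spot presence is then
    made to co-vary by a shared intensity factor (see simulate_spots), while
    the neighborhood's identity is carried by a dominant unconstrained
    type. Each member of a segregated pair dominates its own archetype and
    is held at the low concentration everywhere else, so segregated types
    never co-dominate. Types untouched by constraints are spread
    round-robin over archetypes.
    """
    types = list(config.cell_types)
    t_idx = {t: i for i, t in enumerate(types)}
    for a, b in list(config.colocalized_pairs) + list(config.segregated_pairs):
        for t in (a, b):
            if t not in t_idx:
                raise ConfigError(f"constraint references unknown cell type {t}")

    seg_types = [t for pair in config.segregated_pairs for t in pair]
    n_needed = (1 if config.colocalized_pairs else 0) + len(set(seg_types))
    if config.n_archetypes < max(n_needed, 1):
        raise ConfigError(
            f"{config.n_archetypes} archetypes cannot satisfy the "
            f"co-localization constraints (need >= {n_needed})"
        )

    lo, hi = config.dirichlet_concentration_low, config.dirichlet_concentration_high
    mid = config.dirichlet_concentration_mid
    conc = np.full((config.n_archetypes, len(types)), lo)
    next_free = 0
    if config.colocalized_pairs:
        for a, b in config.colocalized_pairs:
            conc[0, t_idx[a]] = mid
            conc[0, t_idx[b]] = mid
        next_free = 1
    seg_home: dict = {}
    for a, b in config.segregated_pairs:
        for t in (a, b):
            if t not in seg_home:
                seg_home[t] = next_free
                conc[next_free, t_idx[t]] = hi
                next_free += 1
    constrained = {t for p in config.colocalized_pairs for t in p} | set(seg_home)
    free_types = [t for t in types if t not in constrained]
    for i, t in enumerate(free_types):
        arch = i % config.n_archetypes
        # keep free types out of segregated homes they would contaminate? no:
        # free types carry no constraint, any archetype may host them
        conc[arch, t_idx[t]] = hi
    return conc


def simulate_spots(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> SpotMatrix:
    """Draw the spatial count matrix and complete the ground truth.

    Each sample is a ceil(sqrt(n))-sided grid; archetypes are contiguous
    vertical strips of columns, making co-occurrence ground truth
    unambiguous. The realized per-spot composition (fraction of latent cells
    of each type) is stored in ``truth.composition``.

    Colocalized pairs share archetype 0 and, within it, a per-spot shared
    intensity factor exp(N(0, coloc_intensity_sigma)) multiplying both
    types' Dirichlet concentrations. Presence of the two types therefore
    rises and falls together across the neighborhood's spots — the signal
    the presence/absence co-occurrence model detects. Without it, a
    homogeneous Dirichlet neighborhood leaves the pair conditionally
    independent given its presence marginals and no enrichment exists.
    Symmetrically, each segregated pair receives an anti-correlated factor
    (one member scaled by exp(N(0, seg_anticorr_sigma)), the other by its
    reciprocal) in every archetype, so their co-presence falls below the
    independence expectation everywhere.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    conc = build_archetype_concentrations(config)
    truth.archetype_concentration = conc
    types = list(truth.cell_types)
    t_idx = {t: i for i, t in enumerate(types)}
    # colocalized pairs are homed in archetype 0 (see build_archetype_concentrations)
    coloc_cols = sorted(
        {t_idx[t] for pair in config.colocalized_pairs for t in pair}
    )
    seg_pairs_idx = [
        (t_idx[a], t_idx[b]) for a, b in config.segregated_pairs
    ]
    side = int(np.ceil(np.sqrt(config.n_spots_per_sample)))

    all_rows = []
    spot_ids, xy, sample_ids, conditions = [], [], [], []
    comp_rows, arch_labels, n_cells_list = [], [], []
    spot_i = 0
    for cond in config.conditions:
        for s in range(config.n_samples_per_condition):
            sname = f"{cond}_s{s + 1}"
            for k in range(config.n_spots_per_sample):
                row, col = divmod(k, side)
                arch = min(
                    int(col * config.n_archetypes / side), config.n_archetypes - 1
                )
                spot_conc = conc[arch].copy()
                modified = False
                if arch == 0 and coloc_cols and config.coloc_intensity_sigma > 0:
                    g = float(
                        np.exp(rng.normal(0.0, config.coloc_intensity_sigma))
                    )
                    spot_conc[coloc_cols] *= g
                    modified = True
                if config.seg_anticorr_sigma > 0:
                    for ia, ib in seg_pairs_idx:
                        h = float(
                            np.exp(rng.normal(0.0, config.seg_anticorr_sigma))
                        )
                        spot_conc[ia] *= h
                        spot_conc[ib] /= h
                        modified = True
                if modified:
                    # the niche trades dominant-type mass for the fluctuating
                    # types: absorb the concentration change into the
                    # archetype's dominant type so the total stays constant
                    # and unrelated types' expected shares do not co-vary
                    # (a compositional closure artifact otherwise couples
                    # every minor type to every factor)
                    dom = int(np.argmax(conc[arch]))
                    others = spot_conc.sum() - spot_conc[dom]
                    spot_conc[dom] = max(
                        conc[arch].sum() - others,
                        config.dirichlet_concentration_low,
                    )
                p = rng.dirichlet(spot_conc)
                n_cells = 0
                while n_cells < 1:
                    n_cells = rng.poisson(config.cells_per_spot_mean)
                type_counts = rng.multinomial(n_cells, p)
                spot_counts = np.zeros(config.n_genes, dtype=np.int64)
                log_lib_mu = (
                    np.log(config.library_size_mean)
                    - config.library_size_sigma**2 / 2
                )
                for t_i, m in enumerate(type_counts):
                    if m == 0:
                        continue
                    prog = truth.means[types[t_i]][cond]
                    rel = prog / prog.sum()
                    libs = rng.lognormal(
                        log_lib_mu, config.library_size_sigma, size=m
                    )
                    for lib in libs:
                        spot_counts += _nb_draw(rng, rel * lib, config.nb_dispersion)
                all_rows.append(spot_counts)
                spot_ids.append(f"spot_{spot_i:06d}")
                xy.append((float(col), float(row)))
                sample_ids.append(sname)
                conditions.append(cond)
                comp_rows.append(type_counts / n_cells)
                arch_labels.append(arch)
                n_cells_list.append(n_cells)
                spot_i += 1

    truth.composition = np.array(comp_rows)
    truth.cells_per_spot = np.array(n_cells_list)
    truth.archetype = np.array(arch_labels)
    return SpotMatrix(
        counts=sp.csr_matrix(np.vstack(all_rows)),
        gene_ids=list(truth.gene_ids),
        spot_ids=spot_ids,
        xy=np.array(xy),
        sample_id=np.array(sample_ids, dtype=object),
        condition=np.array(conditions, dtype=object),
    )


def simulate_paired(config: SimulationConfig):
    """Generate the full paired dataset: (cells, spots, truth).

    All randomness derives from ``config.seed``; repeated calls with the
    same config are bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_cell_programs(config, rng)
    cells = simulate_cells(config, truth, rng)
    spots = simulate_spots(config, truth, rng)
    return cells, spots, truth


def make_lr_database(
    config: SimulationConfig, n_decoys: int = 20, rng: np.random.Generator | None = None
) -> LRDatabase:
    """An L-R database holding the planted pairs plus decoy pairs.

    Decoys pair genes untouched by planting or marker blocks, so under the
    null they behave like any background gene.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    records = [
        LRRecord(
            pair_id=p.pair_id,
            ligand=p.ligand,
            receptor_subunits=p.receptor_subunits,
            pathway="planted",
        )
        for p in config.planted_lr
    ]
    used = {g for p in config.planted_lr for g in (p.ligand, *p.receptor_subunits)}
    marker_end = config.marker_genes_per_type * config.n_cell_types
    free = [g for g in config.gene_ids[marker_end:] if g not in used]
    if len(free) < 2 * n_decoys:
        raise ConfigError("not enough free genes for the requested decoys")
    picks = rng.choice(len(free), size=2 * n_decoys, replace=False)
    for d in range(n_decoys):
        lig = free[picks[2 * d]]
        rec = free[picks[2 * d + 1]]
        records.append(
            LRRecord(
                pair_id=f"decoy_{d:03d}",
                ligand=lig,
                receptor_subunits=(rec,),
                pathway="decoy",
            )
        )
    return LRDatabase(records)
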