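"""Seeded generators emulating the statistical structure of the study data.

Four generators stand in for the deposited cohorts:

* :func:`generate_bulk_regions` — per-patient bulk profiles for five surgical
  compartments (Core, Rim, Invasive margin, 5ALA+, 5ALA-) with
  compartment-specific transcriptional-program activation on the log2 scale,
  patient random effects, and Gaussian noise, back-transformed to TPM.
* :func:`generate_single_cells` — negative-binomial single-cell counts over
  discrete states, with Chr7-gain/Chr10-loss expression shifts planted in a
  myeloid-like aneuploid (MLA) subset.
* :func:`generate_spatial_grid` — a spot grid (default 32 x 33) with a
  necrotic core, cellular tumor (CT), non-tumor (NT) tissue, a
  two-spot-thick 5ALA-enriched arc at the CT/NT boundary, a 5ALA pocket
  inside the CT, and an immune-reactive rim; tumor-bearing regions carry
  Chr7+/Chr10- expression shifts (half strength on the invasive arc, where
  tumor purity is lower).
* :func:`generate_survival_cohort` — primary/recurrent survival arms with a
  score-survival Gaussian copula active in the recurrent arm only.

Every generator is bit-reproducible under a fixed seed and returns its
ground truth alongside the data; no pipeline stage reads the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    ConfigError,
    ExpressionMatrix,
    GenePositionTable,
    GeneSet,
    GeneSetCollection,
    SurvivalCohort,
)
from .spatial import SpatialGrid

__all__ = [
    "PROGRAMS",
    "COMPARTMENTS",
    "ProgramEffectTable",
    "default_program_effects",
    "generate_bulk_regions",
    "CellStateSpec",
    "default_cell_states",
    "default_gene_positions",
    "generate_single_cells",
    "NicheLayout",
    "generate_spatial_grid",
    "generate_survival_cohort",
]

PROGRAMS = (
    "MES", "InfWound", "GPM", "MTC", "Developmental",
    "TNF", "InfResponse", "Hypoxia", "Proliferation", "Neuronal",
)
COMPARTMENTS = ("Core", "Rim", "Inv", "5ALA_pos", "5ALA_neg")


@dataclass
class ProgramEffectTable:
    """Mean log2 shift per (program, compartment)."""

    shifts: pd.DataFrame  # programs x compartments

    def __post_init__(self) -> None:
        missing_p = set(PROGRAMS) - set(self.shifts.index)
        missing_c = set(COMPARTMENTS) - set(self.shifts.columns)
        if missing_p or missing_c:
            raise ConfigError(
                f"effect table incomplete: missing programs {sorted(missing_p)}, "
                f"compartments {sorted(missing_c)}"
            )
        if not np.isfinite(self.shifts.to_numpy()).all():
            raise ConfigError("effect table contains non-finite shifts")


def default_program_effects() -> ProgramEffectTable:
    """Default planted contrasts.

    The 5ALA+ compartment activates the six signature programs (MES,
    inflammatory wound response, GPM, MTC, TNF, inflammatory response); the
    Core is hypoxic/glycolytic with the Developmental stem program; the Rim
    proliferates; the invasive margin and 5ALA- fraction are dominated by
    neuronal background.
    """
    shifts = pd.DataFrame(0.0, index=list(PROGRAMS), columns=list(COMPARTMENTS))
    for prog in ("MES", "InfWound", "GPM", "MTC", "TNF", "InfResponse"):
        shifts.loc[prog, "5ALA_pos"] = 1.0
    shifts.loc["Hypoxia", "Core"] = 1.0
    shifts.loc["GPM", "Core"] = 0.5
    shifts.loc["Developmental", "Core"] = 1.0
    shifts.loc["Proliferation", "Core"] = 0.5
    shifts.loc["Proliferation", "Rim"] = 1.0
    shifts.loc["Developmental", "Rim"] = 0.5
    shifts.loc["Neuronal", "Inv"] = 1.0
    shifts.loc["Neuronal", "5ALA_neg"] = 1.0
    return ProgramEffectTable(shifts)


def generate_bulk_regions(
    n_patients: int = 10,
    n_genes: int = 3000,
    effects: ProgramEffectTable | None = None,
    noise_sd: float = 0.5,
    genes_per_program: int = 30,
    patient_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneSetCollection]:
    """Bulk TPM profiles for 5 compartments x n_patients.

    log2 expression = baseline + program shift + patient random effect +
    N(0, noise_sd), back-transformed to TPM.  Returns the matrix, a sample
    annotation table (patient, compartment), and the planted program gene
    sets as ground truth.
    """
    if n_patients < 2:
        raise ConfigError("need at least 2 patients")
    total_program_genes = genes_per_program * len(PROGRAMS)
    if n_genes < 10 * total_program_genes:
        raise ConfigError(
            f"n_genes ({n_genes}) must be >= 10x planted program genes ({total_program_genes})"
        )
    effects = effects or default_program_effects()
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    program_sets = []
    program_of = {}
    for pi, prog in enumerate(PROGRAMS):
        members = genes[pi * genes_per_program:(pi + 1) * genes_per_program]
        program_sets.append(GeneSet(prog, f"planted {prog} program", tuple(members)))
        for g in members:
            program_of[g] = prog

    baseline = rng.uniform(1.0, 7.0, size=n_genes)
    samples, ann = [], []
    cols = {}
    patient_effect = rng.normal(0.0, patient_sd, size=(n_patients, n_genes))
    shift_per_gene = np.zeros((len(COMPARTMENTS), n_genes))
    for ci, comp in enumerate(COMPARTMENTS):
        for gi, g in enumerate(genes):
            prog = program_of.get(g)
            if prog is not None:
                shift_per_gene[ci, gi] = effects.shifts.loc[prog, comp]
    for p in range(n_patients):
        for ci, comp in enumerate(COMPARTMENTS):
            x = baseline + shift_per_gene[ci] + patient_effect[p] + rng.normal(0, noise_sd, n_genes)
            sid = f"P{p:02d}_{comp}"
            cols[sid] = np.maximum(2.0**x - 1.0, 0.0)
            ann.append({"sample_id": sid, "patient": f"P{p:02d}", "compartment": comp})
    values = pd.DataFrame(cols, index=genes)
    annotations = pd.DataFrame(ann).set_index("sample_id")
    return ExpressionMatrix(values, "tpm"), annotations, GeneSetCollection(program_sets)


# ---------------------------------------------------------------------------
# Single cells


@dataclass
class CellStateSpec:
    """One discrete cell state: markers, abundance, planted CNV."""

    name: str
    markers: tuple[str, ...]
    proportion: float
    cnv: dict = field(default_factory=dict)  # chromosome -> log2 shift
    marker_fold_log2: float = 2.0


def default_gene_positions(n_genes: int = 3000) -> GenePositionTable:
    """Evenly spread genes over chr1..chr22 in contiguous genomic blocks."""
    chroms = [f"chr{i}" for i in range(1, 23)]
    per = n_genes // len(chroms)
    rows = []
    gi = 0
    for chrom in chroms:
        count = per + (1 if chroms.index(chrom) < n_genes % len(chroms) else 0)
        for j in range(count):
            rows.append({"gene_id": f"G{gi:05d}", "chromosome": chrom,
                         "start": 1 + j * 1000, "order_index": j + 1})
            gi += 1
    return GenePositionTable(pd.DataFrame(rows).set_index("gene_id"))


def default_cell_states(positions: GenePositionTable, markers_per_state: int = 25,
                        mla_fraction: float = 0.05) -> list[CellStateSpec]:
    """Eight states: six malignant programs, diploid myeloid, and the MLA subset.

    Marker genes are drawn round-robin from chr1-chr6 so that no marker
    program contaminates the chr7/chr10 CNV readout.
    """
    pool = [g for c in ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6")
            for g in positions.genes_on(c)]
    names = ["MES1", "MES2", "AC", "OPC", "NPC1", "NPC2",
             "myeloid_diploid", "myeloid_like_aneuploid"]
    base = (1.0 - mla_fraction - 0.20) / 6  # malignant states share the remainder
    props = [base] * 6 + [0.20, mla_fraction]
    states = []
    for i, (name, prop) in enumerate(zip(names, props)):
        markers = tuple(pool[i * markers_per_state:(i + 1) * markers_per_state])
        cnv = {"chr7": 0.5, "chr10": -0.5} if name == "myeloid_like_aneuploid" else {}
        states.append(CellStateSpec(name, markers, prop, cnv))
    return states


def generate_single_cells(
    n_cells: int = 2000,
    states: list[CellStateSpec] | None = None,
    positions: GenePositionTable | None = None,
    nb_dispersion: float = 0.4,
    mean_scale: float = 4.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Negative-binomial single-cell counts with planted states and CNV.

    Returns (counts matrix, per-cell annotations with state and planted
    cluster id, ground-truth ploidy labels).
    """
    if n_cells < 50:
        raise ConfigError("need at least 50 cells")
    positions = positions or default_gene_positions()
    states = states if states is not None else default_cell_states(positions)
    all_markers = [g for s in states for g in s.markers]
    if len(set(all_markers)) != len(all_markers):
        raise ConfigError("marker sets overlap between states")
    props = np.array([s.proportion for s in states])
    if not np.isclose(props.sum(), 1.0):
        raise ConfigError(f"state proportions sum to {props.sum():.3f}, expected 1")
    for s in states:
        if s.cnv and not (s.cnv.get("chr7", 0) > 0 and s.cnv.get("chr10", 0) < 0):
            raise ConfigError(f"aneuploid state {s.name!r} must shift chr7 up and chr10 down")

    rng = np.random.default_rng(seed)
    genes = positions.gene_ids
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    chrom = positions.table["chromosome"]

    base_mu = rng.gamma(shape=2.0, scale=mean_scale / 2.0, size=n_genes)
    state_mu = np.tile(base_mu, (len(states), 1))
    for si, s in enumerate(states):
        for g in s.markers:
            state_mu[si, gene_index[g]] *= 2.0**s.marker_fold_log2
        for chrom_name, shift in s.cnv.items():
            on = (chrom == chrom_name).to_numpy()
            state_mu[si, on] *= 2.0**shift

    assignment = rng.choice(len(states), size=n_cells, p=props)
    mu = state_mu[assignment]  # cells x genes
    if nb_dispersion > 0:
        lam = rng.gamma(shape=1.0 / nb_dispersion, scale=nb_dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float).T  # genes x cells

    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    em = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=cell_ids), "counts")
    ann = pd.DataFrame({
        "state": [states[i].name for i in assignment],
        "cluster": assignment,
    }, index=cell_ids)
    ann.index.name = "cell"
    ploidy = pd.Series(
        ["aneuploid" if states[i].cnv else "diploid" for i in assignment],
        index=cell_ids, name="ploidy",
    )
    return em, ann, ploidy


# ---------------------------------------------------------------------------
# Spatial grid


@dataclass
class NicheLayout:
    """Geometry of the planted tissue niches, in grid units."""

    necrotic_radius: float = 4.0
    ct_radius: float = 10.0
    boundary_thickness: float = 2.0
    arc_degrees: tuple[float, float] = (-60.0, 60.0)  # 5ALA-INV arc at the CT/NT interface
    pocket_center_offset: tuple[float, float] = (0.0, 7.0)  # 5ALA-CT pocket, relative to center
    pocket_radius: float = 2.0
    include_ala_niches: bool = True

    def __post_init__(self) -> None:
        if self.necrotic_radius >= self.ct_radius:
            raise ConfigError("necrotic core must lie inside the cellular tumor")
        px, py = self.pocket_center_offset
        pocket_d = float(np.hypot(px, py))
        if self.include_ala_niches and not (
            self.necrotic_radius + self.pocket_radius < pocket_d < self.ct_radius - self.pocket_radius / 2
        ):
            raise ConfigError("5ALA-CT pocket overlaps the necrotic core or leaves the CT")


SPATIAL_PROGRAMS = ("ALA_SIG", "IMMUNE", "HYPOXIA", "NEURONAL", "PROLIF")
_SPATIAL_SET_SIZES = {"ALA_SIG": 40, "IMMUNE": 40, "HYPOXIA": 30, "NEURONAL": 30, "PROLIF": 30}

# mean log2 shift of each program per region
_REGION_EFFECTS = {
    "necrotic": {"HYPOXIA": 1.5},
    "ct": {"PROLIF": 1.0, "HYPOXIA": 0.5},
    "ala_ct": {"ALA_SIG": 1.5, "IMMUNE": 1.0, "PROLIF": 0.5},
    "ala_inv": {"ALA_SIG": 1.5, "IMMUNE": 1.0},
    "immune_rim": {"IMMUNE": 1.5},
    "nt": {"NEURONAL": 1.0},
}
# planted chr7/chr10 log2 shifts per region (tumor content)
_REGION_CNV = {
    "ct": ("full", 0.5),
    "ala_ct": ("full", 0.5),
    "ala_inv": ("half", 0.25),
}


def generate_spatial_grid(
    width: int = 32,
    height: int = 33,
    layout: NicheLayout | None = None,
    n_genes: int = 1200,
    noise_sd: float = 0.3,
    coloc_sd: float = 0.5,
    seed: int = 0,
) -> tuple[SpatialGrid, GeneSetCollection, GenePositionTable]:
    """Spot grid with planted niches, program expression and tumor CNV.

    Every spot belongs to exactly one region (mask names: necrotic, ct,
    ala_ct, ala_inv, immune_rim, nt).  Tumor-bearing regions carry
    Chr7+/Chr10- expression shifts, at half strength on the invasive arc.
    Inside the 5ALA niches a shared per-spot latent factor couples the
    ALA_SIG and IMMUNE programs (planted co-localization).
    Returns (grid with ground-truth masks, planted program sets, positions).
    """
    if width < 8 or height < 8:
        raise ConfigError("grid must be at least 8 x 8")
    layout = layout or NicheLayout()
    rng = np.random.default_rng(seed)

    positions = default_gene_positions(n_genes)
    genes = positions.gene_ids
    chrom = positions.table["chromosome"]
    # program genes from chr1-chr6 blocks, clear of the chr7/chr10 readout
    pool = [g for c in ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6")
            for g in positions.genes_on(c)]
    sets, cursor, members = [], 0, {}
    for name in SPATIAL_PROGRAMS:
        size = _SPATIAL_SET_SIZES[name]
        sel = tuple(pool[cursor:cursor + size])
        cursor += size
        sets.append(GeneSet(name, f"planted spatial {name} program", sel))
        members[name] = sel
    collection = GeneSetCollection(sets)

    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    d = np.hypot(xs - cx, ys - cy)
    ang = np.degrees(np.arctan2(ys - cy, xs - cx))

    region = np.full(xs.size, "nt", dtype=object)
    band = (d > layout.ct_radius) & (d <= layout.ct_radius + layout.boundary_thickness)
    lo, hi = layout.arc_degrees
    region[band] = "immune_rim"
    region[d <= layout.ct_radius] = "ct"
    region[d <= layout.necrotic_radius] = "necrotic"
    if layout.include_ala_niches:
        region[band & (ang >= lo) & (ang <= hi)] = "ala_inv"
        px, py = cx + layout.pocket_center_offset[0], cy + layout.pocket_center_offset[1]
        pocket = np.hypot(xs - px, ys - py) <= layout.pocket_radius
        if (pocket & (d <= layout.necrotic_radius)).any():
            raise ConfigError("5ALA-CT pocket overlaps the necrotic core")
        region[pocket & (region == "ct")] = "ala_ct"

    spot_ids = [f"S{x:02d}x{y:02d}" for x, y in zip(xs, ys)]
    baseline = rng.uniform(2.0, 6.0, size=n_genes)
    member_idx = {name: positions.table.index.get_indexer(m) for name, m in members.items()}
    chr7 = (chrom == "chr7").to_numpy()
    chr10 = (chrom == "chr10").to_numpy()

    logx = np.tile(baseline, (xs.size, 1))
    for ri, reg in enumerate(region):
        for prog, shift in _REGION_EFFECTS[reg].items():
            logx[ri, member_idx[prog]] += shift
        cnvspec = _REGION_CNV.get(reg)
        if cnvspec is not None:
            logx[ri, chr7] += cnvspec[1]
            logx[ri, chr10] -= cnvspec[1]
        if reg in ("ala_inv", "ala_ct"):
            u = rng.normal(0.0, coloc_sd)
            logx[ri, member_idx["ALA_SIG"]] += u
            logx[ri, member_idx["IMMUNE"]] += u
    logx[region == "necrotic"] -= 1.0  # necrosis: globally depressed expression
    logx += rng.normal(0.0, noise_sd, size=logx.shape)

    tpm = np.maximum(2.0**logx - 1.0, 0.0).T  # genes x spots
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=spot_ids), "tpm")
    spots = pd.DataFrame({"x": xs, "y": ys}, index=pd.Index(spot_ids, name="spot_id"))
    masks = {reg: set(np.array(spot_ids)[region == reg]) for reg in np.unique(region)}
    grid = SpatialGrid(spots=spots, expression=expr, masks=masks)
    return grid, collection, positions


# ---------------------------------------------------------------------------
# Survival cohorts


def generate_survival_cohort(
    n_primary: int = 30,
    n_recurrent: int = 30,
    rho_recurrent: float = -0.9,
    median_os_months: float = 12.0,
    censor_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[SurvivalCohort, pd.Series]:
    """Primary/recurrent arms with a planted score-survival association.

    Scores and survival couple through a Gaussian copula at
    ``rho_recurrent`` in the recurrent arm and are independent in the
    primary arm.  Event times are exponential (median ``median_os_months``)
    with independent exponential censoring at ``censor_fraction``.
    Returns the cohort and the per-sample true score.
    """
    if not -1.0 <= rho_recurrent <= 0.0:
        raise ConfigError("rho_recurrent must lie in [-1, 0]")
    if min(n_primary, n_recurrent) < 10:
        raise ConfigError("need at least 10 samples per arm")
    rng = np.random.default_rng(seed)
    rate = np.log(2.0) / median_os_months
    censor_rate = rate * censor_fraction / (1.0 - censor_fraction)

    rows, scores = [], {}
    for stage, n, rho in (("primary", n_primary, 0.0), ("recurrent", n_recurrent, rho_recurrent)):
        z1 = rng.normal(size=n)
        z2 = rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(size=n)
        u = np.clip(_norm_cdf(z2), 1e-12, 1 - 1e-12)
        t_event = -np.log(1.0 - u) / rate
        t_cens = rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0 else np.full(n, np.inf)
        os_months = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        age = rng.normal(60.0, 10.0, size=n)
        sex = rng.choice(["F", "M"], size=n)
        for i in range(n):
            sid = f"{stage[:3].upper()}{i:03d}"
            rows.append({"sample_id": sid, "os_months": max(os_months[i], 1e-3),
                         "event": int(event[i]), "age": age[i], "sex": sex[i], "stage": stage})
            scores[sid] = z1[i]
    table = pd.DataFrame(rows).set_index("sample_id")
    cohort = SurvivalCohort(table)
    return cohort, pd.Series(scores, name="true_score")


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(z)
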