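"""Shared domain types, file formats and configuration.

Every pipeline stage exchanges data through the containers defined here:
an :class:`ExpressionMatrix` (genes x samples/cells/spots with an explicit
scale), gene sets (GMT), a genomic gene-position table (BED-like), and a
survival cohort table.  Readers validate invariants eagerly and name the
offending record; every reader/writer pair round-trips exactly on valid
files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("margin_profiler")

VALID_SCALES = ("tpm", "log2_tpm_plus1", "counts")
VALID_STAGES = ("primary", "recurrent")
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


class FormatError(ValueError):
    """A file or container violates the format contract."""


class ConfigError(ValueError):
    """A configuration or parameter table is incomplete or inconsistent."""


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``scale`` is one of ``tpm`` (linear TPM), ``log2_tpm_plus1`` or
    ``counts``.  Ids must be unique, values finite and non-negative; counts
    must be integral.
    """

    values: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise FormatError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if self.scale == "counts" and arr.size and not np.allclose(arr, np.round(arr)):
            raise FormatError("counts scale requires integer values")

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(TPM + 1) view of a TPM matrix (identity on log2)."""
        if self.scale == "log2_tpm_plus1":
            return self
        if self.scale == "tpm":
            return ExpressionMatrix(np.log2(self.values + 1.0), "log2_tpm_plus1")
        raise FormatError("counts must be normalized before log transform (use counts_to_log2)")

    def counts_to_log2(self, scale_factor: float = 1e4) -> "ExpressionMatrix":
        """Depth-normalize counts per cell to ``scale_factor`` and log2(x+1)."""
        if self.scale != "counts":
            raise FormatError("counts_to_log2 requires a counts matrix")
        depth = self.values.sum(axis=0)
        if (depth == 0).any():
            bad = depth.index[depth == 0][0]
            raise FormatError(f"sample {bad!r} has zero total counts")
        norm = self.values / depth * scale_factor
        return ExpressionMatrix(np.log2(norm + 1.0), "log2_tpm_plus1")

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.scale)


def read_expression_matrix(path: str | Path, scale: str = "tpm") -> ExpressionMatrix:
    """Read a gene-major TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate gene row {dup!r}")
    try:
        num = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path.name}: non-numeric value {cell!r} at gene {gene!r}, sample {col!r}"
                    ) from None
        raise
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    num.index.name = None
    return ExpressionMatrix(num, scale)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_matrix_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path, scale: str = "counts"
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix with row (gene) / column sidecar files."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path))
    genes = [ln.strip().split("\t")[0] for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    samples = [ln.strip().split("\t")[0] for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    if dense.shape != (len(genes), len(samples)):
        raise FormatError(
            f"matrix shape {dense.shape} does not match sidecars ({len(genes)} genes, {len(samples)} samples)"
        )
    return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=samples), scale)


# ---------------------------------------------------------------------------
# Gene sets


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = next(n for i, n in enumerate(names) if n in names[:i])
            raise FormatError(f"duplicate gene-set name {dup!r}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene...`` per line.

    Duplicate genes within a line are dropped with a warning; duplicate set
    names are an error.
    """
    sets: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{Path(path).name}:{i}: GMT line has {len(fields)} fields, expected >= 3")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) != len(genes):
            warnings.warn(f"GMT set {name!r}: {len(genes) - len(uniq)} duplicate genes dropped")
        sets.append(GeneSet(name, desc, tuple(uniq)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Gene positions


@dataclass
class GenePositionTable:
    """Genomic order of genes: chromosome, 1-based start, and a per-chromosome
    order index used by the CNV moving average."""

    table: pd.DataFrame  # index gene_id; columns chromosome, start, order_index

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "start", "order_index"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"gene position table missing columns {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate gene {dup!r} in position table")
        bad_chrom = set(t["chromosome"]) - set(CHROMOSOMES)
        if bad_chrom:
            raise FormatError(f"unknown chromosome(s) {sorted(bad_chrom)}")
        if (t["start"] < 1).any():
            bad = t.index[t["start"] < 1][0]
            raise FormatError(f"gene {bad!r}: start must be >= 1")
        for chrom, sub in t.groupby("chromosome", sort=False):
            oi = sub["order_index"].to_numpy()
            if not (np.diff(oi) > 0).all():
                raise FormatError(f"order_index not strictly increasing on {chrom}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def chromosomes(self) -> list[str]:
        return [c for c in CHROMOSOMES if c in set(self.table["chromosome"])]

    def genes_on(self, chrom: str) -> list[str]:
        sub = self.table[self.table["chromosome"] == chrom].sort_values("order_index")
        return list(sub.index)


def read_position_table(path: str | Path) -> GenePositionTable:
    """Read a BED-like TSV: chrom, start, end, gene (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "gene_id"], dtype={"gene_id": str})
    df = df.set_index("gene_id")
    out = df[["chromosome", "start"]].copy()
    out["start"] = out["start"].astype(int) + 1  # BED is 0-based half-open
    order = []
    for chrom, sub in out.groupby("chromosome", sort=False):
        ranks = sub["start"].rank(method="first").astype(int)
        order.append(ranks)
    out["order_index"] = pd.concat(order)
    return GenePositionTable(out)


def write_position_table(positions: GenePositionTable, path: str | Path) -> None:
    t = positions.table
    bed = pd.DataFrame({
        "chromosome": t["chromosome"],
        "start": t["start"] - 1,
        "end": t["start"],  # 1-bp features; only order matters downstream
        "gene_id": t.index,
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Survival cohort


@dataclass
class SurvivalCohort:
    """Overall survival table with stage (primary/recurrent) and covariates."""

    table: pd.DataFrame  # index sample_id; os_months, event, stage + covariates

    REQUIRED = ("os_months", "event", "stage")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"survival table missing column {missing[0]!r}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if (t["os_months"] <= 0).any():
            bad = t.index[t["os_months"] <= 0][0]
            raise FormatError(f"sample {bad!r}: os_months must be > 0")
        if not t["event"].isin([0, 1]).all():
            bad = t.index[~t["event"].isin([0, 1])][0]
            raise FormatError(f"sample {bad!r}: event must be 0 or 1")
        bad_stage = set(t["stage"]) - set(VALID_STAGES)
        if bad_stage:
            raise FormatError(f"unknown stage(s) {sorted(bad_stage)}; expected {VALID_STAGES}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, stage: str) -> "SurvivalCohort":
        return SurvivalCohort(self.table[self.table["stage"] == stage].copy())

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]


def read_survival_table(path: str | Path) -> SurvivalCohort:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError("survival table missing column 'sample_id'")
    df = df.set_index("sample_id")
    return SurvivalCohort(df)


def write_survival_table(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Spot tables (delegates container to the spatial module)


def read_spot_table(path: str | Path, expression: ExpressionMatrix | None = None):
    """Read a spot table (spot_id, x, y [+ per-gene columns]) into a SpatialGrid.

    Expression may be embedded as additional columns (genes x spots after
    transposition) or supplied as a sidecar matrix whose sample ids are
    spot ids.
    """
    from .spatial import SpatialGrid  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"spot table missing column {col!r}")
    df = df.set_index("spot_id")
    coords = df[["x", "y"]].astype(int)
    dup = coords.duplicated()
    if dup.any():
        x, y = coords[dup].iloc[0]
        raise FormatError(f"two spots at the same position ({x}, {y})")
    gene_cols = [c for c in df.columns if c not in ("x", "y")]
    if expression is None and gene_cols:
        expression = ExpressionMatrix(df[gene_cols].T.astype(float), "tpm")
    return SpatialGrid(spots=coords, expression=expression)


def write_spot_table(grid, path: str | Path, embed_expression: bool = True) -> None:
    df = grid.spots.copy()
    if embed_expression and grid.expression is not None:
        df = df.join(grid.expression.values.T)
    df.to_csv(path, sep="\t", index_label="spot_id")


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass
class AnalysisConfig:
    """Run-wide knobs: seed, resampling depths and per-stage thresholds."""

    seed: int = 0
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    alpha_fdr: float = 0.05
    thresholds: dict = field(default_factory=lambda: {
        "gsea_min_size": 5,
        "gsea_max_size": 2000,
        "ucell_r_max": 1500,
        "ploidy_tau": 0.1,
        "cnv_window": 101,
        "cnv_clamp": 3.0,
        "eisa_min_mean_log2": 5.0,
        "eisa_post_delta": 1.0,
        "gw_bandwidth": 5.0,
    })

    def __post_init__(self) -> None:
        if self.n_permutations < 1 or self.n_bootstraps < 1:
            raise ConfigError("resampling counts must be >= 1")
        if not 0 < self.alpha_fdr < 1:
            raise ConfigError("alpha_fdr must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = cls()
        thresholds = {**base.thresholds, **raw.pop("thresholds", {})}
        return cls(**{**{k: raw[k] for k in raw}, "thresholds": thresholds})

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "n_bootstraps": self.n_bootstraps,
            "alpha_fdr": self.alpha_fdr,
            "thresholds": dict(self.thresholds),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
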