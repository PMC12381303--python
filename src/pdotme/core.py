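"""Shared data model, file I/O and normalization.

The central container is :class:`ExpressionMatrix`: a sparse gene-by-cell
count matrix carrying a per-gene annotation table (symbol, chromosome,
start coordinate — needed for expression-based copy-number inference) and a
per-cell metadata table (patient of origin, exosome treatment arm,
compartment and cluster labels).  Matrices are oriented genes x cells,
matching the MatrixMarket triplet layout produced by droplet pipelines.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("pdotme")

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "AnalysisConfig",
    "FormatError",
    "ValidationError",
    "read_mtx",
    "write_mtx",
    "read_table",
    "normalize_log1p",
    "read_gmt",
    "write_gmt",
    "estimate_cells_per_organoid",
    "chromosome_sort_key",
    "genomic_gene_order",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Inputs violate a documented precondition or invariant."""


# --------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells counts plus aligned gene/cell annotation.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes as rows.
    gene_table
        One row per gene: ``gene_id``, ``symbol`` and, when available,
        ``chromosome`` and ``start_bp`` (1-based).  Genes lacking valid
        coordinates are retained but unusable for CNV inference.
    cell_table
        One row per cell: ``cell_id`` plus categorical metadata columns
        (``patient``, ``treatment``, optionally ``compartment``/``cluster``).
        Missing metadata columns default to a single level ``"all"``.
    normalized
        Log-normalized layer, filled lazily by :func:`normalize_log1p`.
    """

    counts: sp.spmatrix
    gene_table: pd.DataFrame
    cell_table: pd.DataFrame
    normalized: sp.spmatrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.gene_table):
            raise ValidationError(
                f"gene_table has {len(self.gene_table)} rows but matrix has "
                f"{self.counts.shape[0]} gene rows"
            )
        if self.counts.shape[1] != len(self.cell_table):
            raise ValidationError(
                f"cell_table has {len(self.cell_table)} rows but matrix has "
                f"{self.counts.shape[1]} cell columns"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        self.gene_table = self.gene_table.reset_index(drop=True)
        self.cell_table = self.cell_table.reset_index(drop=True)
        for tbl, col in ((self.gene_table, "gene_id"), (self.cell_table, "cell_id")):
            if col not in tbl.columns:
                raise ValidationError(f"missing required column {col!r}")
            if tbl[col].duplicated().any():
                dupes = tbl.loc[tbl[col].duplicated(), col].head(3).tolist()
                raise ValidationError(f"duplicate {col} values, e.g. {dupes}")
        if "symbol" not in self.gene_table.columns:
            self.gene_table["symbol"] = self.gene_table["gene_id"]
        for col in ("patient", "treatment"):
            if col not in self.cell_table.columns:
                self.cell_table[col] = "all"

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_table["gene_id"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_table["cell_id"].to_numpy()

    def has_coordinates(self) -> np.ndarray:
        """Boolean mask of genes with a usable chromosome/start annotation."""
        if "chromosome" not in self.gene_table.columns or "start_bp" not in self.gene_table.columns:
            return np.zeros(self.n_genes, dtype=bool)
        chrom_ok = self.gene_table["chromosome"].notna() & (
            self.gene_table["chromosome"].astype(str) != ""
        )
        start = pd.to_numeric(self.gene_table["start_bp"], errors="coerce")
        return (chrom_ok & start.notna() & (start >= 0)).to_numpy()

    def dense_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValidationError("normalized layer absent; call normalize_log1p first")
        return np.asarray(self.normalized.todense())

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            gene_table=self.gene_table.copy(),
            cell_table=self.cell_table.iloc[idx].reset_index(drop=True),
            normalized=None if self.normalized is None else sp.csr_matrix(self.normalized)[:, idx],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): ordered, duplicate-free symbol lists."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


_GRID_DEFAULT = (-1.0, 3.0, 0.1)


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline in one place.

    Defaults: 101-gene CNV smoothing window clipped at +/-3 log2 units; the
    top 5% most genomically unstable cells define each patient's tumor CNV
    profile; the tumor-calling threshold grid spans SD multipliers -1..3 in
    steps of 0.1; module scores use 24 expression bins with 100 control
    genes per set gene; GSEA uses 50,000 permutations; BH-adjusted p cutoff
    0.05; organoid particles below 300 um^2 (single cells) are discarded.
    """

    seed: int = 0
    cnv_window: int = 101
    cnv_clip: float = 3.0
    top_fraction: float = 0.05
    grid_range: tuple[float, float, float] = _GRID_DEFAULT
    n_bins: int = 24
    n_ctrl: int = 100
    nperm: int = 50_000
    fdr_alpha: float = 0.05
    min_area_um2: float = 300.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.cnv_window < 3 or self.cnv_window % 2 == 0:
            raise ValidationError("cnv_window must be odd and >= 3")
        if not (0 < self.top_fraction <= 1):
            raise ValidationError("top_fraction must lie in (0, 1]")
        if self.cnv_clip <= 0 or self.n_bins < 2 or self.n_ctrl < 1 or self.nperm < 1:
            raise ValidationError("numeric config field out of range")
        if not (0 < self.fdr_alpha < 1):
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.min_area_um2 < 0 or self.pixel_size_um <= 0:
            raise ValidationError("area/pixel-size fields must be positive")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.grid_range
        n = int(round((hi - lo) / step))
        return np.round(lo + step * np.arange(n + 1), 10)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, Mapping):  # nested sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in flat.items() if k in known}
        if "grid_range" in kwargs:
            kwargs["grid_range"] = tuple(kwargs["grid_range"])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# I/O


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV metadata/results table."""
    return pd.read_csv(path, sep="\t", **kwargs)


def _read_features(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    cols = ["gene_id", "symbol", "chromosome", "start_bp"]
    df = df.iloc[:, : len(cols)]
    df.columns = cols[: df.shape[1]]
    if "symbol" not in df.columns:
        df["symbol"] = df["gene_id"]
    if "start_bp" in df.columns:
        df["start_bp"] = pd.to_numeric(df["start_bp"], errors="coerce")
    return df


def read_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    cell_meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a 10x-style MTX triplet (matrix, features TSV, barcodes TSV).

    The features file carries ``gene_id<TAB>symbol[<TAB>chromosome<TAB>start_bp]``;
    barcodes one cell id per line.  An optional cell-metadata TSV (keyed by
    ``cell_id``) is joined onto the barcodes.
    """
    matrix_path, features_path, barcodes_path = (
        Path(matrix_path), Path(features_path), Path(barcodes_path))
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"{matrix_path}: not a readable MatrixMarket file ({exc})")
    mat = sp.csr_matrix(mat)
    genes = _read_features(features_path)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    cells = pd.DataFrame({"cell_id": barcodes.iloc[:, 0]})
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix declares "
            f"{mat.shape[0]} gene rows"
        )
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"{barcodes_path}: {len(cells)} barcodes but matrix declares "
            f"{mat.shape[1]} cell columns"
        )
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValidationError(f"{matrix_path}: non-integer count entries")
    if cell_meta_path is not None:
        meta = read_table(cell_meta_path, dtype={"cell_id": str})
        if "cell_id" not in meta.columns:
            raise FormatError(f"{cell_meta_path}: missing cell_id column")
        cells = cells.merge(meta, on="cell_id", how="left")
    n_missing = int((~ExpressionMatrix(mat, genes, cells).has_coordinates()).sum())
    if n_missing:
        logger.info("read_mtx: %d genes lack coordinates (unusable for CNV)", n_missing)
    return ExpressionMatrix(counts=mat, gene_table=genes, cell_table=cells)


def write_mtx(expr: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write the MTX triplet (and the cell metadata TSV) for round-tripping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(expr.counts), field="integer")
    cols = [c for c in ("gene_id", "symbol", "chromosome", "start_bp") if c in expr.gene_table]
    expr.gene_table[cols].to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    expr.cell_table[["cell_id"]].to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    expr.cell_table.to_csv(out / "cell_meta.tsv", sep="\t", index=False)


def normalize_log1p(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and log-transform counts in place.

    ``normalized[g, c] = log(1 + scale * counts[g, c] / total_counts[c])``.
    Cells with zero total counts are rejected.
    """
    totals = np.asarray(expr.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        bad = expr.cell_ids[totals == 0].tolist()
        raise ValidationError(f"cells with zero total counts: {bad}")
    norm = sp.csc_matrix(expr.counts, dtype=float)
    norm.data = norm.data * (scale / np.repeat(totals, np.diff(norm.indptr)))
    np.log1p(norm.data, out=norm.data)
    expr.normalized = sp.csr_matrix(norm)
    return expr


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: set[str] = set()
            uniq = []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                uniq.append(g)
            if len(uniq) != len(genes):
                logger.warning("read_gmt: duplicate genes in set %r deduplicated", name)
            if not uniq:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def estimate_cells_per_organoid(diameter_um: float, cell_diameter_um: float) -> int:
    """Cells per organoid assuming both organoid and cell are spheres.

    The sphere-volume ratio reduces to the cubed diameter ratio; the result
    is floored to a whole cell count.  Used to normalize exosome dosing to
    particles per cell.
    """
    if diameter_um <= 0 or cell_diameter_um <= 0:
        raise ValidationError("diameters must be positive")
    if cell_diameter_um > diameter_um:
        raise ValidationError("cell diameter exceeds organoid diameter")
    return math.floor((diameter_um / cell_diameter_um) ** 3)


# --------------------------------------------------------------------------
# genomic ordering

_CHR_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def chromosome_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome order: chr1..chr22, chrX, chrY, then others."""
    name = _CHR_RE.match(str(chrom)).group(2)
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


def genomic_gene_order(gene_table: pd.DataFrame) -> np.ndarray:
    """Indices of coordinate-bearing genes sorted by (chromosome, start)."""
    start = pd.to_numeric(gene_table["start_bp"], errors="coerce")
    ok = gene_table["chromosome"].notna() & start.notna()
    idx = np.flatnonzero(ok.to_numpy())
    keys = [
        (chromosome_sort_key(gene_table["chromosome"].iat[i]), float(start.iat[i]), i)
        for i in idx
    ]
    keys.sort()
    return np.array([k[-1] for k in keys], dtype=int)
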