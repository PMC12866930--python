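"""Core containers, file I/O, preprocessing, configuration and seeding.

The canonical in-memory carrier is :class:`ExpressionMatrix`: a dense
cells-by-genes array of nonnegative finite values with unique string
identifiers on both axes.  Files may be dense CSV/TSV (header row = gene
ids, first column = cell ids) or Matrix Market with plain-text sidecar id
files; gzip is handled transparently by pandas / scipy.

Preprocessing follows the scImpute convention that the downstream
Gamma-Normal dropout model relies on: per-cell library-size normalization
to the median library, then x -> log(x + 1.01).  Raw zeros all map to the
constant "zero level" log(1.01), which is strictly positive so the Gamma
component of the mixture has support there.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("scdropgan")

#: pseudocount of the shifted-log transform
PSEUDOCOUNT = 1.01
#: preprocessed value that raw zeros map to
ZERO_LEVEL = float(np.log(PSEUDOCOUNT))
#: tolerance for "is at zero level" comparisons
ZERO_TOL = 1e-9


class MatrixFormatError(ValueError):
    """Raised when an input file violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """Dense cells x genes matrix of nonnegative finite expression values."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("expression values must be 2-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("non-finite expression value encountered")
        if np.any(self.values < 0):
            raise MatrixFormatError("negative expression value encountered")
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise MatrixFormatError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise MatrixFormatError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise MatrixFormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != g:
            raise MatrixFormatError("duplicate gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.cell_ids),
                                list(self.gene_ids))

    def zero_level_mask(self, zero_level: float = 0.0) -> np.ndarray:
        """Boolean mask of entries at the given zero level (default: raw 0)."""
        return np.abs(self.values - zero_level) < ZERO_TOL


@dataclass
class CellLabels:
    """One label per cell; ``source`` records provided vs pre-clustered."""

    labels: np.ndarray
    source: str = "provided"  # "provided" | "preclustered"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.source not in ("provided", "preclustered"):
            raise ValueError(f"unknown label source {self.source!r}")

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def codes(self) -> np.ndarray:
        """Labels as integer codes 0..k-1 (sorted unique order)."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes


@dataclass
class RunConfig:
    """All knobs of the end-to-end pipeline, with field-default values."""

    seed: int = 0
    # preprocessing
    pseudocount: float = PSEUDOCOUNT
    target_sum: float | None = None      # None -> median library size
    # dropout identification
    rho: float = 0.5
    k_max: int = 8
    em_max_iter: int = 100
    em_tol: float = 1e-6
    em_restarts: int = 3
    # generator architecture
    hidden_dims: tuple = (512, 256)
    latent_dim: int = 32
    n_components: int | None = None      # None -> number of labels
    prior: str = "gmm"                   # "gmm" | "standard_normal"
    # discriminator architecture
    embed_dims: tuple = (256, 128)
    head_hidden: int = 64
    proj_dim: int = 64
    tau_cell: float = 0.5
    tau_type: float = 0.1
    # training schedule
    pretrain_epochs: int = 30
    warmup_epochs: int = 10
    joint_epochs: int = 10
    batch_size: int = 128
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-3
    lambda_adv: float = 1.0
    lambda_cell: float = 1.0
    lambda_type: float = 1.0
    # ablation switches (dropping a head zeroes its loss everywhere)
    use_adv: bool = True
    use_cell: bool = True
    use_type: bool = True

    def __post_init__(self):
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        for name in ("lambda_adv", "lambda_cell", "lambda_type"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict):   # nested sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hidden_dims", "embed_dims"):
            if key in flat:
                flat[key] = tuple(flat[key])
        return cls(**flat)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# seeding

_STREAMS = ("simulation", "kmeans", "em", "network", "shuffle", "noise", "mask")


def seed_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """Derive independent named generators from one master seed.

    Each pipeline stage consumes its own stream so components are
    independently reproducible.
    """
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


def derive_seed(master_seed: int, purpose: str) -> int:
    """A deterministic 31-bit integer sub-seed for a named purpose."""
    h = hashlib.sha256(f"{master_seed}:{purpose}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# readers / writers

def _read_dense(path: Path) -> pd.DataFrame:
    sep = "\t" if ".tsv" in path.name else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: no data columns found")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric entry ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise MatrixFormatError(f"{path}: non-finite expression value")
    if np.any(values < 0):
        raise MatrixFormatError(f"{path}: negative expression value")
    return df


def _sidecar_names(path: Path, kind: str) -> Path:
    # x.mtx -> x.rows.txt / x.cols.txt (also accepts .mtx.gz)
    stem = path.name
    for suffix in (".mtx.gz", ".mtx"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(f"{stem}.{kind}.txt")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_matrix(path, orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Read a dense CSV/TSV or Matrix Market file into an ExpressionMatrix.

    ``orientation='genes_by_cells'`` transposes on read so the in-memory
    layout is always cells in rows.
    """
    path = Path(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    if ".mtx" in path.suffixes or path.name.endswith(".mtx"):
        mat = scipy.io.mmread(str(path))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                            dtype=np.float64)
        rows = _read_lines(_sidecar_names(path, "rows"))
        cols = _read_lines(_sidecar_names(path, "cols"))
        if len(rows) != values.shape[0] or len(cols) != values.shape[1]:
            raise MatrixFormatError(f"{path}: sidecar id counts do not match matrix")
        if np.any(values < 0):
            raise MatrixFormatError(f"{path}: negative expression value")
        row_ids, col_ids = rows, cols
    else:
        df = _read_dense(path)
        values = df.to_numpy(dtype=np.float64)
        row_ids, col_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids)


def write_matrix(m: ExpressionMatrix, path, format: str = "csv") -> None:
    """Write to dense CSV/TSV or Matrix Market (+ sidecar id files)."""
    path = Path(path)
    if format == "csv":
        sep = "\t" if ".tsv" in path.name else ","
        df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path, sep=sep, float_format="%.9g")
    elif format == "mtx":
        sparse = scipy.sparse.csr_matrix(m.values)
        scipy.io.mmwrite(str(path), sparse, precision=9)
        _sidecar_names(path, "rows").write_text("\n".join(m.cell_ids) + "\n")
        _sidecar_names(path, "cols").write_text("\n".join(m.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path, cell_ids: list[str] | None = None) -> CellLabels:
    """One label per line (or two tab-separated columns: cell id, label)."""
    lines = _read_lines(Path(path))
    if lines and "\t" in lines[0]:
        mapping = dict(line.split("\t", 1) for line in lines)
        if cell_ids is None:
            labels = list(mapping.values())
        else:
            labels = [mapping[c] for c in cell_ids]
    else:
        labels = lines
    return CellLabels(np.asarray(labels), source="provided")


def write_labels(labels: CellLabels, path) -> None:
    Path(path).write_text("\n".join(str(x) for x in labels.labels) + "\n")


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(raw: ExpressionMatrix, cfg: RunConfig | None = None) -> ExpressionMatrix:
    """Library-size normalize to a common target sum, then shifted log.

    Each cell is scaled to ``target_sum`` (default: the median library
    size), then x -> log(x + pseudocount).  Zeros map exactly to the
    constant ``log(pseudocount)`` and the within-cell rank order of values
    is preserved.
    """
    cfg = cfg or RunConfig()
    libs = raw.values.sum(axis=1)
    empty = np.flatnonzero(libs == 0)
    if empty.size:
        raise ValueError(
            f"cell(s) with total count 0 cannot be normalized: "
            f"{[raw.cell_ids[i] for i in empty[:5]]}")
    target = cfg.target_sum if cfg.target_sum is not None else float(np.median(libs))
    scaled = raw.values * (target / libs)[:, None]
    return ExpressionMatrix(np.log(scaled + cfg.pseudocount),
                            list(raw.cell_ids), list(raw.gene_ids))


def zero_level(cfg: RunConfig | None = None) -> float:
    """Preprocessed value that raw zeros map to."""
    return float(np.log((cfg or RunConfig()).pseudocount))


# ---------------------------------------------------------------------------
# run manifest

def write_manifest(path, cfg: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
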