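"""Expression/coordinate containers and readers for standard SC formats.

Two containers organise everything downstream: :class:`ExpressionProfile`
(cells x genes with ids and optional cell-type labels) and
:class:`SpatialDataset` (a profile plus 2-D coordinates and a platform tag).
Readers cover h5ad (via anndata), MTX directories (matrix.mtx +
features.tsv + barcodes.tsv) and plain CSV; writers mirror them so
round-trips are lossless.

Normalization is deliberately simple: per-cell library-size scaling to a
target total (the median library by default) followed by natural log1p.
Pre-normalized input is accepted by flagging ``is_lognorm``; re-normalizing
an already log-normalized profile is rejected rather than silently applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("single_cell", "spot")


class ValidationError(ValueError):
    """Raised when an input matrix violates a container invariant."""


class FormatError(IOError):
    """Raised when a file cannot be parsed in the requested format."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    values, counts = np.unique(ids, return_counts=True)
    dup = values[counts > 1]
    if dup.size:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dup[:10]))}")


@dataclass
class ExpressionProfile:
    """A cells x genes matrix of non-negative expression values.

    Parameters
    ----------
    values
        Dense float matrix, raw counts or log-normalized values.
    gene_ids, cell_ids
        Ordered unique identifiers matching the matrix axes.
    cell_types
        Optional per-cell label array.
    is_lognorm
        True once :func:`log_normalize` (or an upstream tool) has been
        applied; guards against double normalization.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_types: Optional[np.ndarray] = None
    is_lognorm: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values contain NaN/inf")
        if (self.values < 0).any():
            raise ValidationError("expression values contain negative entries")
        if self.cell_types is not None:
            self.cell_types = np.asarray(self.cell_types, dtype=object)
            if len(self.cell_types) != n_cells:
                raise ValidationError("cell_types length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionProfile":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"genes not present: {missing[:10]}")
        cols = np.array([idx[g] for g in gene_ids])
        return replace(
            self,
            values=self.values[:, cols],
            gene_ids=np.asarray(list(gene_ids), dtype=object),
        )


@dataclass
class SpatialDataset:
    """An :class:`ExpressionProfile` with 2-D spatial coordinates."""

    profile: ExpressionProfile
    coords: np.ndarray
    platform: str = "single_cell"
    sim_config: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n_cells, 2) matrix")
        if self.coords.shape[0] != self.profile.n_cells:
            raise ValidationError("coords row count does not match profile")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain NaN/inf")
        if self.platform not in PLATFORMS:
            raise ValidationError(f"platform must be one of {PLATFORMS}")

    @property
    def n_cells(self) -> int:
        return self.profile.n_cells


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_COORD_KEYS = ("x", "y")
_CELL_TYPE_KEY = "cell_type"


def load_dataset(path, format: str, coord_keys: Optional[Tuple[str, str]] = None,
                 platform: str = "single_cell"):
    """Load an expression dataset from ``path``.

    Returns a :class:`SpatialDataset` when coordinates are found, otherwise
    an :class:`ExpressionProfile`. ``coord_keys`` names the two coordinate
    columns (CSV / obs) or the obsm slot (h5ad, first element).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if format == "csv":
        profile, coords = _load_csv(path, coord_keys or _DEFAULT_COORD_KEYS)
    elif format == "mtx_dir":
        profile, coords = _load_mtx_dir(path, coord_keys or _DEFAULT_COORD_KEYS)
    elif format == "h5ad":
        profile, coords = _load_h5ad(path, coord_keys)
    else:
        raise FormatError(f"unknown format {format!r}")
    if coords is None:
        return profile
    return SpatialDataset(profile=profile, coords=coords, platform=platform)


def _load_csv(path: Path, coord_keys):
    # pandas silently renames duplicate header fields; check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    _check_unique(np.asarray(header, object), "gene ids")
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    cx, cy = coord_keys
    coords = None
    if cx in df.columns and cy in df.columns:
        coords = df[[cx, cy]].to_numpy(float)
        df = df.drop(columns=[cx, cy])
    cell_types = None
    if _CELL_TYPE_KEY in df.columns:
        cell_types = df[_CELL_TYPE_KEY].to_numpy(object)
        df = df.drop(columns=[_CELL_TYPE_KEY])
    profile = ExpressionProfile(
        values=df.to_numpy(float),
        gene_ids=df.columns.to_numpy(object),
        cell_ids=df.index.to_numpy(object),
        cell_types=cell_types,
    )
    return profile, coords


def _load_mtx_dir(path: Path, coord_keys):
    from scipy.io import mmread

    mtx = path / "matrix.mtx"
    feats = path / "features.tsv"
    bars = path / "barcodes.tsv"
    for f in (mtx, feats, bars):
        if not f.exists():
            raise FormatError(f"MTX directory {path} is missing {f.name}")
    try:
        # genes x cells on disk, per 10x convention
        values = np.asarray(mmread(mtx).todense()).T
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    gene_ids = pd.read_csv(feats, sep="\t", header=None)[0].to_numpy(object)
    bar_df = pd.read_csv(bars, sep="\t", header=None)
    cell_ids = bar_df[0].to_numpy(object)
    coords = None
    coords_file = path / "coords.csv"
    if coords_file.exists():
        cdf = pd.read_csv(coords_file, index_col=0)
        cx, cy = coord_keys
        coords = cdf.loc[cell_ids, [cx, cy]].to_numpy(float)
    cell_types = None
    types_file = path / "cell_types.tsv"
    if types_file.exists():
        cell_types = pd.read_csv(types_file, sep="\t", header=None)[0].to_numpy(object)
    profile = ExpressionProfile(values, gene_ids, cell_ids, cell_types=cell_types)
    return profile, coords


def _load_h5ad(path: Path, coord_keys):
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read h5ad {path}: {exc}") from exc
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = np.asarray(X.todense())
    cell_types = None
    if _CELL_TYPE_KEY in adata.obs:
        cell_types = adata.obs[_CELL_TYPE_KEY].to_numpy(object)
    profile = ExpressionProfile(
        values=X.astype(float),
        gene_ids=adata.var_names.to_numpy(object),
        cell_ids=adata.obs_names.to_numpy(object),
        cell_types=cell_types,
        is_lognorm=bool(adata.uns.get("is_lognorm", False)),
    )
    coords = None
    slot = coord_keys[0] if coord_keys else "spatial"
    if slot in adata.obsm:
        coords = np.asarray(adata.obsm[slot], float)[:, :2]
    elif coord_keys and all(k in adata.obs for k in coord_keys):
        coords = adata.obs[list(coord_keys)].to_numpy(float)
    elif "spatial" in adata.obsm:
        coords = np.asarray(adata.obsm["spatial"], float)[:, :2]
    return profile, coords


def save_csv(obj, path) -> None:
    """Write a profile or dataset to a single CSV (cells as rows)."""
    profile = obj.profile if isinstance(obj, SpatialDataset) else obj
    df = pd.DataFrame(profile.values, index=profile.cell_ids, columns=profile.gene_ids)
    if isinstance(obj, SpatialDataset):
        df["x"] = obj.coords[:, 0]
        df["y"] = obj.coords[:, 1]
    if profile.cell_types is not None:
        df[_CELL_TYPE_KEY] = profile.cell_types
    df.to_csv(path)


def save_h5ad(obj, path) -> None:
    import anndata as ad

    profile = obj.profile if isinstance(obj, SpatialDataset) else obj
    adata = ad.AnnData(
        X=profile.values.copy(),
        obs=pd.DataFrame(index=profile.cell_ids.astype(str)),
        var=pd.DataFrame(index=profile.gene_ids.astype(str)),
    )
    if profile.cell_types is not None:
        adata.obs[_CELL_TYPE_KEY] = profile.cell_types.astype(str)
    adata.uns["is_lognorm"] = profile.is_lognorm
    if isinstance(obj, SpatialDataset):
        adata.obsm["spatial"] = obj.coords.copy()
        adata.uns["platform"] = obj.platform
    adata.write_h5ad(path)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def log_normalize(profile: ExpressionProfile, target_sum="median") -> ExpressionProfile:
    """Scale each cell to a common library size, then apply log1p.

    ``target_sum`` is either a positive number or ``"median"`` (the median
    library size across cells). Cells with zero total counts are an error.
    """
    if profile.is_lognorm:
        raise ValidationError("profile is already log-normalized")
    totals = profile.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(map(str, profile.cell_ids[zero[:10]]))
        raise ValidationError(f"cells with zero total counts: {names}")
    if target_sum == "median":
        target = float(np.median(totals))
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValidationError("target_sum must be positive")
    scaled = profile.values * (target / totals)[:, None]
    return replace(profile, values=np.log1p(scaled), is_lognorm=True)


def align_genes(sc: ExpressionProfile, st: ExpressionProfile):
    """Restrict both profiles to their shared genes, in the ST gene order."""
    sc_set = set(sc.gene_ids)
    shared = [g for g in st.gene_ids if g in sc_set]
    if not shared:
        raise ValidationError("no genes shared between the two profiles")
    logger.info("gene intersection: %d genes", len(shared))
    return sc.subset_genes(shared), st.subset_genes(shared)


def select_hvg(profile: ExpressionProfile, n_top: int) -> ExpressionProfile:
    """Keep the ``n_top`` most dispersed genes (variance of log values).

    Raw-count input is log1p-transformed for the ranking only; the returned
    profile keeps the original values. Gene order is preserved.
    """
    if n_top > profile.n_genes:
        raise ValidationError(
            f"n_top={n_top} exceeds the {profile.n_genes} available genes"
        )
    vals = profile.values if profile.is_lognorm else np.log1p(profile.values)
    dispersion = vals.var(axis=0)
    keep = np.sort(np.argsort(-dispersion, kind="stable")[:n_top])
    return replace(
        profile,
        values=profile.values[:, keep],
        gene_ids=profile.gene_ids[keep],
    )
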