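"""Shared file I/O: images, count matrices, masks, run records.

Internal conventions: RGB images are HxWx3 uint8 in [0, 255]; IF stacks are
channels x H x W float arrays; count matrices are genes x cells. 16-bit
images are linearly rescaled to the 8-bit range with a logged warning;
alpha channels are dropped.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .sc import CountMatrix, DEFAULT_MITO_PREFIX

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_counts",
    "write_counts",
    "write_mask_png",
    "run_record",
]


def _to_uint8(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        warnings.warn(f"{path.name}: 16-bit image rescaled linearly to [0, 255]", stacklevel=3)
        return (arr.astype(np.float64) / 257.0).round().clip(0, 255).astype(np.uint8)
    raise ValueError(f"{path.name}: unsupported image dtype {arr.dtype}; expected uint8 or uint16")


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG as an RGB image (HxWx3 uint8).

    Multi-page TIFFs should go through :func:`read_stack` instead.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn(f"{path.name}: alpha channel dropped", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path.name}: expected an RGB image, got shape {arr.shape}")
    return _to_uint8(arr, path)


def write_image(path: str | Path, img: np.ndarray) -> None:
    path = Path(path)
    img = np.asarray(img, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a channels x H x W float stack."""
    path = Path(path)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a multi-page single-plane TIFF, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a channels x H x W stack as a multi-page float32 TIFF."""
    stack = np.asarray(stack, dtype=np.float32)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_counts(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    mito_genes=None,
) -> CountMatrix:
    """Read a genes x cells count matrix.

    ``path`` is either a MatrixMarket .mtx file (then ``genes_path`` and
    ``cells_path`` name one-label-per-line text files) or a dense CSV with
    gene names in the first column and cell identifiers as the header.
    Mitochondrial genes come from ``mito_genes`` if given, otherwise from
    the name prefix (case-insensitive, default ``mt-``).
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input needs genes_path and cells_path label files")
        mat = spio.mmread(path)
        counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        if len(genes) != counts.shape[0]:
            raise ValueError(f"gene file has {len(genes)} names but the matrix has {counts.shape[0]} rows")
        if len(cells) != counts.shape[1]:
            raise ValueError(f"cell file has {len(cells)} names but the matrix has {counts.shape[1]} columns")
    else:
        df = pd.read_csv(path, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        counts = df.to_numpy()
    if mito_genes is None:
        mito = frozenset(g for g in genes if g.lower().startswith(mito_prefix.lower()))
    else:
        mito = frozenset(mito_genes)
    return CountMatrix(list(genes), list(cells), counts, mito)


def write_counts(matrix: CountMatrix, out_dir: str | Path, stem: str = "counts", fmt: str = "mtx") -> list[Path]:
    """Write a CountMatrix as MTX + label files, or as a dense CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mtx = out_dir / f"{stem}.mtx"
        spio.mmwrite(mtx, sparse.coo_matrix(matrix.counts))
        genes = out_dir / f"{stem}.genes.txt"
        cells = out_dir / f"{stem}.cells.txt"
        genes.write_text("\n".join(matrix.genes) + "\n")
        cells.write_text("\n".join(matrix.cells) + "\n")
        return [mtx, genes, cells]
    if fmt == "csv":
        csv = out_dir / f"{stem}.csv"
        pd.DataFrame(matrix.counts, index=matrix.genes, columns=matrix.cells).to_csv(csv)
        return [csv]
    raise ValueError(f"unknown counts format {fmt!r}; use 'mtx' or 'csv'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_record(
    command: str,
    config_text: str = "",
    inputs: list[str | Path] | None = None,
    timings: dict[str, float] | None = None,
    warnings_seen: list[str] | None = None,
) -> dict:
    """Provenance record emitted alongside every CLI run."""
    from . import __version__

    return {
        "tool": "fibroquant",
        "version": __version__,
        "command": command,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "input_sha256": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).is_file()},
        "timings_s": timings or {},
        "warnings": warnings_seen or [],
    }


def write_run_record(record: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_record.json"
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
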