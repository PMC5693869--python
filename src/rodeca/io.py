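"""On-disk formats: TIFF stacks for cubes and maps, CSV for spectra and
abundances, JSON manifests for run metadata.

A cube directory contains ``data.tif`` (L pages, float32), ``mask.tif``
(int32 labels; 0 marks pixels absent from the pixel map) and
``channels.csv``.  Round-trips are lossless for float32 data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    AbundanceMatrix,
    ChannelSet,
    EndmemberMatrix,
    HyperspectralCube,
    cube_from_stack,
    maps_from_matrix,
)

__all__ = [
    "write_cube",
    "read_cube",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_abundance_csv",
    "read_abundance_csv",
    "write_manifest",
    "read_manifest",
    "file_checksum",
]


def write_cube(cube: HyperspectralCube, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if cube.canvas_shape is None:
        raise ValueError("cube has no canvas shape; cannot render TIFF pages")
    pages = maps_from_matrix(
        cube.values.astype(np.float32), cube.pixel_map, cube.canvas_shape
    )
    tifffile.imwrite(d / "data.tif", np.stack(pages).astype(np.float32))
    mask = np.zeros(cube.canvas_shape, dtype=np.int32)
    mask[cube.pixel_map[:, 1], cube.pixel_map[:, 2]] = 1
    tifffile.imwrite(d / "mask.tif", mask)
    if cube.channel_set is not None:
        cube.channel_set.write_csv(d / "channels.csv")
    return d


def read_cube(directory) -> HyperspectralCube:
    d = Path(directory)
    data = tifffile.imread(d / "data.tif").astype(float)
    mask = tifffile.imread(d / "mask.tif")
    channels = None
    if (d / "channels.csv").exists():
        channels = ChannelSet.read_csv(d / "channels.csv")
    return cube_from_stack(list(data), channel_set=channels, mask=mask)


def write_spectra_csv(M: EndmemberMatrix, path) -> None:
    names = M.names or [f"endmember_{j + 1}" for j in range(M.n_endmembers)]
    df = pd.DataFrame(M.spectra, columns=names)
    df.insert(0, "index", np.arange(1, M.n_channels + 1))
    df.to_csv(path, index=False)


def read_spectra_csv(path, expect: list[str] | None = None) -> EndmemberMatrix:
    df = pd.read_csv(path, comment="#")
    if "index" not in df.columns:
        raise ValueError("spectra CSV is missing the 'index' column")
    names = [c for c in df.columns if c != "index"]
    if expect is not None:
        missing = [c for c in expect if c not in names]
        if missing:
            raise ValueError(f"spectra CSV is missing column(s): {missing}")
        names = expect
    return EndmemberMatrix(df[names].to_numpy(dtype=float), names=names)


def write_abundance_csv(ab: AbundanceMatrix, path) -> None:
    names = ab.names or [f"endmember_{j + 1}" for j in range(ab.n_endmembers)]
    df = pd.DataFrame(ab.fractions.T.astype(np.float32), columns=names)
    if ab.pixel_map is not None:
        df.insert(0, "col", ab.pixel_map[:, 2])
        df.insert(0, "row", ab.pixel_map[:, 1])
        df.insert(0, "image", ab.pixel_map[:, 0])
    df.to_csv(path, index=False)


def read_abundance_csv(path) -> AbundanceMatrix:
    df = pd.read_csv(path, comment="#")
    coord_cols = [c for c in ("image", "row", "col") if c in df.columns]
    names = [c for c in df.columns if c not in coord_cols]
    pixel_map = None
    if len(coord_cols) == 3:
        pixel_map = df[["image", "row", "col"]].to_numpy(dtype=np.int64)
    return AbundanceMatrix(
        fractions=df[names].to_numpy(dtype=float).T,
        pixel_map=pixel_map,
        names=names,
    )


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
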