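"""Linear-mixing-model data types and image-stack <-> pixel-matrix reshaping.

The linear mixing model (LMM) writes every observed pixel spectrum as a
convex combination of a small number ``p`` of pure-constituent spectra
("endmembers"):

    y = M s + n,      s >= 0,  columns of s sum to 1,

with ``y`` the L x N matrix of pixel spectra (L spectral channels, N pixels),
``M`` the L x p endmember matrix, ``s`` the p x N abundance matrix and ``n``
sensor noise.  All downstream stages (pre-processing, subspace
identification, unmixing, evaluation) operate on these containers.

Pixel columns are ordered by a deterministic row-major scan of the
(optionally masked) image so that runs are reproducible bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "ChannelSet",
    "HyperspectralCube",
    "EndmemberMatrix",
    "AbundanceMatrix",
    "CameraSettings",
    "cube_from_stack",
    "maps_from_matrix",
]


@dataclass(frozen=True)
class Channel:
    """One spectral channel: an excitation band observed through a filter cube.

    ``qe`` is the camera quantum efficiency in this channel (fraction in
    (0, 1]); ``f`` is the calibration-fluid spectrum value used for
    flat-fielding and must be strictly positive (the calibration fluid is
    chosen to have non-zero response in every channel).
    """

    index: int
    ex_nm: float
    bandwidth_nm: float
    filter_id: str
    qe: float
    f: float


class ChannelSet:
    """Ordered collection of the L spectral channels of an acquisition."""

    def __init__(self, channels: Sequence[Channel]):
        channels = list(channels)
        if len(channels) < 1:
            raise ValueError("ChannelSet requires at least one channel")
        indices = [c.index for c in channels]
        if indices != list(range(1, len(channels) + 1)):
            raise ValueError(
                "channel indices must be unique and contiguous starting at 1, "
                f"got {indices}"
            )
        for c in channels:
            if not (0.0 < c.qe <= 1.0):
                raise ValueError(f"channel {c.index}: QE must be in (0, 1], got {c.qe}")
            if c.f <= 0.0:
                raise ValueError(
                    f"channel {c.index}: calibration value f must be > 0, got {c.f}"
                )
        self.channels = channels

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    def __getitem__(self, i: int) -> Channel:
        return self.channels[i]

    @property
    def ex_nm(self) -> np.ndarray:
        return np.array([c.ex_nm for c in self.channels])

    @property
    def qe(self) -> np.ndarray:
        return np.array([c.qe for c in self.channels])

    @property
    def f(self) -> np.ndarray:
        return np.array([c.f for c in self.channels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [c.index for c in self.channels],
                "ex_nm": [c.ex_nm for c in self.channels],
                "bandwidth_nm": [c.bandwidth_nm for c in self.channels],
                "filter_id": [c.filter_id for c in self.channels],
                "qe": [c.qe for c in self.channels],
                "f": [c.f for c in self.channels],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChannelSet":
        required = {"index", "ex_nm", "bandwidth_nm", "filter_id", "qe", "f"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"channel table missing columns: {sorted(missing)}")
        rows = df.sort_values("index").itertuples(index=False)
        return cls(
            [
                Channel(
                    index=int(r.index),
                    ex_nm=float(r.ex_nm),
                    bandwidth_nm=float(r.bandwidth_nm),
                    filter_id=str(r.filter_id),
                    qe=float(r.qe),
                    f=float(r.f),
                )
                for r in rows
            ]
        )

    @classmethod
    def read_csv(cls, path) -> "ChannelSet":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class HyperspectralCube:
    """L x N matrix of pixel spectra plus the map back to image coordinates.

    ``pixel_map`` has shape (N, 3) with integer rows (image_id, row, col);
    it is a bijection onto the pixel columns so 2-D abundance maps can be
    reconstructed after unmixing.
    """

    values: np.ndarray
    pixel_map: np.ndarray
    channel_set: ChannelSet | None = None
    canvas_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_map = np.asarray(self.pixel_map, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (L, N) array")
        if self.pixel_map.shape != (self.values.shape[1], 3):
            raise ValueError(
                f"pixel_map shape {self.pixel_map.shape} does not match "
                f"N={self.values.shape[1]} pixels"
            )
        if self.values.shape[1] < 1:
            raise ValueError("cube must contain at least one pixel")
        coords = {tuple(r) for r in self.pixel_map}
        if len(coords) != self.pixel_map.shape[0]:
            raise ValueError("pixel_map contains duplicate coordinates")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")


@dataclass
class EndmemberMatrix:
    """L x p matrix whose columns are endmember (pure fluorophore) spectra."""

    spectra: np.ndarray
    names: list[str] | None = None

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (L, p) array")
        if self.names is not None and len(self.names) != self.spectra.shape[1]:
            raise ValueError("names length must equal the number of endmembers")

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[1]

    def normalized(self) -> "EndmemberMatrix":
        """Clip negatives to zero and scale every column to maximum 1."""
        m = np.clip(self.spectra, 0.0, None)
        peak = m.max(axis=0)
        if np.any(peak <= 0):
            raise ValueError("cannot normalize an all-non-positive endmember column")
        return EndmemberMatrix(m / peak, names=self.names)


@dataclass
class AbundanceMatrix:
    """p x N abundance fractions; every column lies on the probability simplex."""

    fractions: np.ndarray
    pixel_map: np.ndarray | None = None
    names: list[str] | None = None
    canvas_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2:
            raise ValueError("fractions must be a 2-D (p, N) array")

    @property
    def n_endmembers(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.fractions.shape[1]

    def validate_simplex(self, atol: float = 1e-9) -> None:
        if np.any(self.fractions < -atol):
            raise ValueError("abundances contain negative entries")
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("abundance columns do not sum to 1")


@dataclass
class CameraSettings:
    """EMCCD acquisition parameters used for photon-per-second equalization.

    ``em_gain``, ``t_exp`` and ``qe`` may be scalars (shared by all channels)
    or per-channel arrays of length L.
    """

    bias_offset: float = 100.0
    sensitivity: float = 0.89
    em_gain: np.ndarray | float = 100.0
    t_exp: np.ndarray | float = 1.0
    qe: np.ndarray | float = 0.5

    def __post_init__(self):
        self.em_gain = np.atleast_1d(np.asarray(self.em_gain, dtype=float))
        self.t_exp = np.atleast_1d(np.asarray(self.t_exp, dtype=float))
        self.qe = np.atleast_1d(np.asarray(self.qe, dtype=float))
        if np.any(self.em_gain < 1.0):
            raise ValueError("EM gain must be >= 1")
        if np.any(self.t_exp <= 0.0):
            raise ValueError("exposure time must be > 0")
        if self.sensitivity <= 0.0:
            raise ValueError("sensitivity must be > 0")
        if np.any(self.qe <= 0.0):
            raise ValueError("QE must be > 0")

    def per_channel(self, attr: str, k: int) -> float:
        arr = getattr(self, attr)
        return float(arr[k % len(arr)] if len(arr) > 1 else arr[0])


def cube_from_stack(
    images: Sequence[np.ndarray],
    channel_set: ChannelSet | None = None,
    mask: np.ndarray | None = None,
    image_id: int = 0,
) -> HyperspectralCube:
    """Flatten a per-channel image stack into an (L, N) pixel-spectrum matrix.

    Pixels are scanned row-major; when ``mask`` (an integer label image,
    0 = background) is given, only pixels with a non-zero label are kept.
    The (image_id, row, col) of every retained pixel is recorded so that
    abundance maps can be rendered back onto the original canvas.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if len(images) == 0:
        raise ValueError("empty image stack")
    shape = images[0].shape
    for k, im in enumerate(images):
        if im.ndim != 2 or im.shape != shape:
            raise ValueError(
                f"channel {k + 1}: image shape {im.shape} differs from "
                f"channel 1 shape {shape}"
            )
    if channel_set is not None and len(channel_set) != len(images):
        raise ValueError(
            f"stack has {len(images)} channels but channel set has {len(channel_set)}"
        )
    if mask is None:
        keep = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} differs from image shape {shape}")
        keep = mask > 0
    rows, cols = np.nonzero(keep)  # np.nonzero scans row-major
    if rows.size == 0:
        raise ValueError("mask selects no pixels")
    values = np.stack([im[rows, cols] for im in images], axis=0)
    pixel_map = np.column_stack(
        [np.full(rows.size, image_id, dtype=np.int64), rows, cols]
    )
    return HyperspectralCube(
        values=values,
        pixel_map=pixel_map,
        channel_set=channel_set,
        canvas_shape=shape,
    )


def maps_from_matrix(
    values: np.ndarray,
    pixel_map: np.ndarray,
    canvas_shape: tuple[int, int],
    fill: float = 0.0,
) -> list[np.ndarray]:
    """Render each row of a (p, N) or (L, N) matrix onto a 2-D canvas.

    Unmapped canvas pixels carry ``fill`` (default 0: the physically neutral
    value for an abundance map).
    """
    values = np.asarray(values, dtype=float)
    pixel_map = np.asarray(pixel_map, dtype=np.int64)
    if values.ndim != 2:
        raise ValueError("values must be 2-D")
    if pixel_map.shape[0] != values.shape[1]:
        raise ValueError("pixel_map does not cover all matrix columns")
    h, w = canvas_shape
    if pixel_map.shape[0] > 0:
        rows, cols = pixel_map[:, 1], pixel_map[:, 2]
        if rows.min(initial=0) < 0 or cols.min(initial=0) < 0 or np.any(rows >= h) or np.any(cols >= w):
            raise ValueError("pixel coordinate outside the canvas")
    out = []
    for band in values:
        canvas = np.full((h, w), fill, dtype=float)
        if pixel_map.shape[0] > 0:
            canvas[pixel_map[:, 1], pixel_map[:, 2]] = band
        out.append(canvas)
    return out
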