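"""Calibrated pre-processing of raw autofluorescence channel images.

Weak cellular autofluorescence sits close to the camera noise floor, so
quantitative unmixing needs the raw digital counts turned into
camera-independent, background-free, flat-fielded intensities first.
The chain implemented here:

1. *Equalization* to photons per pixel per second (PPS): subtract the
   camera bias offset, convert counts to electrons with the sensitivity,
   undo electron-multiplication gain, quantum efficiency and exposure.
2. *Dark correction*: subtract the average of the shutter-open and
   shutter-closed dark frames (removes unresponsive/blocked pixels).
3. *Despiking*: replace isolated spikes or dips (EMCCD gain-register
   artifacts) detected by a robust median/MAD criterion with the median
   of their 8-connected neighbours.
4. *Background subtraction and flattening*: subtract the smoothed water
   background B and divide by the smoothed calibration-fluid image
   (C_raw - B), multiplying by the calibration-fluid spectrum value f(k)
   so channels are mutually comparable:

       y(k, i) = f(k) * (y_raw(k, i) - B(k, i)) / (C_raw(k, i) - B(k, i))

5. *Wavelet smoothing*: stationary wavelet transform, BayesShrink soft
   thresholding of the detail bands.

Pixels where the calibration response is not above background are flagged
undetectable and dropped from the pixel map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .core import CameraSettings, ChannelSet, HyperspectralCube, cube_from_stack

__all__ = [
    "ReferenceImages",
    "PreprocessConfig",
    "equalize_to_pps",
    "dark_correct",
    "despike",
    "wavelet_smooth",
    "background_flatten",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class ReferenceImages:
    """Per-channel reference frames acquired at the start of a session.

    Each field is a list of L 2-D arrays in digital counts: two dark
    frames (shutter open / closed), two water frames (background
    autofluorescence of the dish) and two calibration-fluid frames
    (NADH + riboflavin mixture with non-zero response in every channel).
    """

    dark_open: list[np.ndarray]
    dark_closed: list[np.ndarray]
    water_1: list[np.ndarray]
    water_2: list[np.ndarray]
    calibration_1: list[np.ndarray]
    calibration_2: list[np.ndarray]

    def validate(self, shape: tuple[int, int], n_channels: int) -> None:
        for name in (
            "dark_open",
            "dark_closed",
            "water_1",
            "water_2",
            "calibration_1",
            "calibration_2",
        ):
            frames = getattr(self, name)
            if len(frames) != n_channels:
                raise ValueError(f"{name}: expected {n_channels} frames, got {len(frames)}")
            for k, f in enumerate(frames):
                if np.asarray(f).shape != shape:
                    raise ValueError(
                        f"{name} channel {k + 1}: shape {np.asarray(f).shape} != {shape}"
                    )


@dataclass
class PreprocessConfig:
    despike_window: int = 3
    despike_z: float = 5.0
    wavelet: str = "sym4"
    wavelet_levels: int = 3
    denom_guard: float = 1e-6  # x channel max, Eq-5 denominator threshold


def equalize_to_pps(
    raw: np.ndarray,
    settings: CameraSettings,
    channel: int,
) -> tuple[np.ndarray, int]:
    """Digital counts -> photons per pixel per second for channel ``channel``.

    Returns the PPS image and the number of pixels clamped at zero after
    bias subtraction (sub-bias values carry no signal).
    """
    raw = np.asarray(raw, dtype=float)
    g = settings.per_channel("em_gain", channel)
    t = settings.per_channel("t_exp", channel)
    qe = settings.per_channel("qe", channel)
    if t <= 0:
        raise ValueError("exposure time must be > 0")
    if qe <= 0:
        raise ValueError("QE must be > 0")
    electrons = (raw - settings.bias_offset) * settings.sensitivity
    clamped = int(np.sum(electrons < 0))
    if clamped:
        log.info("channel %d: clamped %d sub-bias pixels", channel + 1, clamped)
    electrons = np.maximum(electrons, 0.0)
    return electrons / (g * qe * t), clamped


def dark_correct(
    image: np.ndarray,
    dark_open: np.ndarray,
    dark_closed: np.ndarray,
) -> np.ndarray:
    """Subtract the average of the two dark frames, clamped at zero."""
    out = np.asarray(image, float) - 0.5 * (
        np.asarray(dark_open, float) + np.asarray(dark_closed, float)
    )
    return np.maximum(out, 0.0)


def despike(image: np.ndarray, window: int = 3, z_threshold: float = 5.0) -> np.ndarray:
    """Replace isolated spikes/dips by the median of their 8 neighbours.

    A pixel is an outlier when |value - local median| exceeds
    ``z_threshold`` local MADs within the scanning window (MAD floored at
    a small epsilon so constant regions with a single spike still
    trigger).  Border pixels use the neighbours available inside the
    image.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    img = np.asarray(image, float)
    med = ndimage.median_filter(img, size=window, mode="nearest")
    mad = ndimage.median_filter(np.abs(img - med), size=window, mode="nearest")
    eps = 1e-12 * max(1.0, float(np.abs(img).max()))
    outliers = np.abs(img - med) > z_threshold * np.maximum(mad, eps)
    if not np.any(outliers):
        return img.copy()
    footprint = np.ones((3, 3), bool)
    footprint[1, 1] = False  # the centre is the suspect
    neighbour_med = ndimage.median_filter(img, footprint=footprint, mode="nearest")
    out = img.copy()
    out[outliers] = neighbour_med[outliers]
    return out


def _bayes_threshold(detail: np.ndarray, sigma: float) -> float:
    """BayesShrink threshold sigma^2 / sigma_x for one detail band."""
    var = float(np.mean(detail**2))
    sigma_x = np.sqrt(max(var - sigma**2, 1e-30))
    return sigma**2 / sigma_x


def wavelet_smooth(
    image: np.ndarray,
    wavelet: str = "sym4",
    levels: int = 3,
    threshold_rule: str = "bayes",
) -> np.ndarray:
    """Stationary wavelet denoising with soft thresholding.

    The image is mirror-padded to a multiple of 2**levels, decomposed
    with the stationary (undecimated) wavelet transform, the detail
    coefficients soft-thresholded (BayesShrink per band, with the noise
    scale taken from the finest diagonal band's median absolute
    deviation) and reconstructed.  Deterministic for fixed inputs.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    block = 2**levels
    if min(img.shape) <= block:
        raise ValueError(f"image sides must exceed 2^levels = {block}")
    pad_r = (-img.shape[0]) % block
    pad_c = (-img.shape[1]) % block
    padded = np.pad(img, ((0, pad_r), (0, pad_c)), mode="symmetric")
    coeffs = pywt.swt2(padded, wavelet, level=levels, norm=True, trim_approx=True)
    # coeffs = [approx, (cH_n, cV_n, cD_n), ...] coarse -> fine
    finest_diag = coeffs[-1][2]
    sigma = float(np.median(np.abs(finest_diag)) / 0.6745)
    out = [coeffs[0]]
    for cH, cV, cD in coeffs[1:]:
        bands = []
        for band in (cH, cV, cD):
            if sigma <= 0:
                bands.append(band)
                continue
            if threshold_rule == "bayes":
                t = _bayes_threshold(band, sigma)
            elif threshold_rule == "universal":
                t = sigma * np.sqrt(2.0 * np.log(band.size))
            else:
                raise ValueError(f"unknown threshold rule {threshold_rule!r}")
            bands.append(pywt.threshold(band, t, mode="soft"))
        out.append(tuple(bands))
    rec = pywt.iswt2(out, wavelet, norm=True)
    return rec[: img.shape[0], : img.shape[1]]


def background_flatten(
    y_raw: np.ndarray,
    B: np.ndarray,
    C_raw: np.ndarray,
    f_k: float,
    guard: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Background subtraction and illumination flattening for one channel.

    Returns ``(y, detectable)``: the corrected image
    ``f_k * (y_raw - B) / (C_raw - B)`` and a boolean mask of pixels whose
    calibration response exceeds the background by more than
    ``guard * max(C_raw - B)`` (the rest are undetectable: no calibration
    light reached them and the ratio is meaningless).
    """
    if f_k <= 0:
        raise ValueError("calibration spectrum value f(k) must be > 0")
    y_raw = np.asarray(y_raw, float)
    B = np.asarray(B, float)
    C_raw = np.asarray(C_raw, float)
    denom = C_raw - B
    thresh = guard * max(float(denom.max()), 1e-300)
    detectable = denom > thresh
    y = np.zeros_like(y_raw)
    y[detectable] = f_k * (y_raw[detectable] - B[detectable]) / denom[detectable]
    return y, detectable


def preprocess_pipeline(
    stack: list[np.ndarray],
    references: ReferenceImages,
    settings: CameraSettings,
    channel_set: ChannelSet,
    config: PreprocessConfig | None = None,
    mask: np.ndarray | None = None,
) -> HyperspectralCube:
    """Full per-channel chain: equalize -> dark -> despike -> flatten -> smooth.

    Reference frames go through the same equalization/dark treatment; the
    water background ``B`` and calibration image ``C_raw`` are smoothed
    with the same wavelet filter before entering the flattening ratio.
    Undetectable pixels (calibration response not above background) are
    excluded from the output pixel map.
    """
    config = config or PreprocessConfig()
    L = len(channel_set)
    if len(stack) != L:
        raise ValueError(f"stack has {len(stack)} channels, channel set has {L}")
    shape = np.asarray(stack[0]).shape
    references.validate(shape, L)

    corrected: list[np.ndarray] = []
    detectable_all = np.ones(shape, dtype=bool)
    for k, ch in enumerate(channel_set):
        sample, n_clamped = equalize_to_pps(stack[k], settings, k)
        water = [
            equalize_to_pps(w[k], settings, k)[0]
            for w in (references.water_1, references.water_2)
        ]
        calib = [
            equalize_to_pps(cimg[k], settings, k)[0]
            for cimg in (references.calibration_1, references.calibration_2)
        ]
        dark_o = np.asarray(references.dark_open[k], float)
        dark_c = np.asarray(references.dark_closed[k], float)
        # darks stay in digital counts; equalize them the same way so the
        # subtraction happens in PPS units
        dark_o = equalize_to_pps(dark_o, settings, k)[0]
        dark_c = equalize_to_pps(dark_c, settings, k)[0]

        sample = dark_correct(sample, dark_o, dark_c)
        water = [dark_correct(w, dark_o, dark_c) for w in water]
        calib = [dark_correct(cimg, dark_o, dark_c) for cimg in calib]

        sample = despike(sample, config.despike_window, config.despike_z)

        B = wavelet_smooth(
            0.5 * (water[0] + water[1]), config.wavelet, config.wavelet_levels
        )
        C_raw = wavelet_smooth(
            0.5 * (calib[0] + calib[1]), config.wavelet, config.wavelet_levels
        )
        flat, detectable = background_flatten(
            sample, B, C_raw, ch.f, guard=config.denom_guard
        )
        detectable_all &= detectable

        smooth = wavelet_smooth(flat, config.wavelet, config.wavelet_levels)
        corrected.append(smooth)
        log.info(
            "channel %d: %d clamped, %d undetectable",
            k + 1,
            n_clamped,
            int((~detectable).sum()),
        )

    keep = detectable_all if mask is None else (np.asarray(mask) > 0) & detectable_all
    label = keep.astype(np.int32)
    return cube_from_stack(corrected, channel_set=channel_set, mask=label)
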