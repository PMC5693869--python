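"""Artificial hyperspectral autofluorescence datasets (cases A-D).

Each case is a 24 x 25 pixel scene mixing four cellular fluorophores under
the linear mixing model.  The abundance maps are laid out as vertical
stripes, one dominant fluorophore per stripe (peak fraction drawn uniformly
in [0.80, 0.85], the remainder split Dirichlet-uniformly among the other
three), plus case-specific spatial-overlap blocks where two (or four)
fluorophores each take roughly half (or a quarter) of the signal:

* case A - four disjoint stripes, no overlap block (free NADH, FAD,
  porphyrin, Cyt c);
* case B - FAD and porphyrin overlap in columns 11-16 at ~50 % each;
* case C - additionally free NADH and Cyt c overlap in rows 11-16;
* case D - the spectrally similar pair free/bound NADH replaces FAD, with
  bound NADH and porphyrin overlapping in columns 11-16.

White Gaussian noise is added at a prescribed SNR; the SNR convention is
global, 10*log10(mean(x^2) / sigma^2) with one sigma for the whole cube.
The shipped fluorophore spectra are synthetic stand-ins with the
qualitative shapes of the named fluorophores (see ``data/``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, ChannelSet, EndmemberMatrix, HyperspectralCube

__all__ = [
    "FLUOROPHORES",
    "CaseDesign",
    "OverlapBlock",
    "NoiseSpec",
    "case_design",
    "default_channel_set",
    "fixture_spectra",
    "generate_case_abundance",
    "mix",
    "add_noise",
    "simulate_case",
]

#: names available in the fixture spectra library
FLUOROPHORES = ("free NADH", "bound NADH", "FAD", "porphyrin", "Cyt c", "lipofuscin")

GRID_SHAPE = (24, 25)
DOMINANT_BAND = (0.80, 0.85)
OVERLAP_JITTER = 0.045  # "around 50%": each partner drawn within +/- ~0.05


def _data_path(name: str):
    return importlib.resources.files("rodeca.data") / name


def default_channel_set() -> ChannelSet:
    """The shipped 18-channel stand-in metadata table."""
    with importlib.resources.as_file(_data_path("channels_synthetic.csv")) as p:
        return ChannelSet.read_csv(p)


@dataclass(frozen=True)
class OverlapBlock:
    """A rectangular region where the named fluorophores share the signal."""

    rows: tuple[int, int]  # half-open 0-based row range
    cols: tuple[int, int]  # half-open 0-based col range
    names: tuple[str, ...]
    fraction: float  # target fraction per named fluorophore


@dataclass(frozen=True)
class CaseDesign:
    case_id: str
    fluorophores: tuple[str, str, str, str]
    stripes: tuple[tuple[int, int], ...]  # half-open column ranges, one per fluorophore
    overlap_blocks: tuple[OverlapBlock, ...] = ()
    shape: tuple[int, int] = GRID_SHAPE
    dominant_band: tuple[float, float] = DOMINANT_BAND

    def __post_init__(self):
        cover = sorted(self.stripes)
        if cover[0][0] != 0 or cover[-1][1] != self.shape[1]:
            raise ValueError("stripe layout does not cover the grid columns")
        for (a0, a1), (b0, b1) in zip(cover, cover[1:]):
            if a1 != b0:
                raise ValueError("stripe layout leaves a gap or overlap in columns")


_CASE_A_FLUORS = ("free NADH", "FAD", "porphyrin", "Cyt c")
_CASE_D_FLUORS = ("free NADH", "bound NADH", "porphyrin", "Cyt c")
_STRIPES = ((0, 6), (6, 12), (12, 19), (19, 25))
# columns 11-16 (1-based, inclusive) -> 0-based half-open (10, 16)
_COL_BLOCK = (10, 16)
_ROW_BLOCK = (10, 16)


def case_design(case_id: str) -> CaseDesign:
    """The four published artificial-data layouts."""
    case_id = case_id.upper()
    if case_id == "A":
        return CaseDesign("A", _CASE_A_FLUORS, _STRIPES)
    if case_id == "B":
        return CaseDesign(
            "B",
            _CASE_A_FLUORS,
            _STRIPES,
            (OverlapBlock((0, 24), _COL_BLOCK, ("FAD", "porphyrin"), 0.5),),
        )
    if case_id == "C":
        # two half-half blocks crossing; their intersection shares among all four
        return CaseDesign(
            "C",
            _CASE_A_FLUORS,
            _STRIPES,
            (
                OverlapBlock((0, 24), _COL_BLOCK, ("FAD", "porphyrin"), 0.5),
                OverlapBlock(_ROW_BLOCK, (0, 25), ("free NADH", "Cyt c"), 0.5),
                OverlapBlock(_ROW_BLOCK, _COL_BLOCK, _CASE_A_FLUORS, 0.25),
            ),
        )
    if case_id == "D":
        return CaseDesign(
            "D",
            _CASE_D_FLUORS,
            _STRIPES,
            (OverlapBlock((0, 24), _COL_BLOCK, ("bound NADH", "porphyrin"), 0.5),),
        )
    raise ValueError(f"unknown case {case_id!r}; available: A, B, C, D")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a given global SNR (dB)."""

    snr_db: float
    seed: int = 0

    def __post_init__(self):
        if np.isnan(self.snr_db) or self.snr_db == -np.inf:
            raise ValueError("snr_db must be finite or +inf (noiseless)")


def _dirichlet_split(rng: np.ndarray, n: int, k: int) -> np.ndarray:
    """n columns of a flat Dirichlet(1,..,1) over k parts, shape (k, n)."""
    g = rng.standard_exponential((k, n))
    return g / g.sum(axis=0)


def generate_case_abundance(design: CaseDesign, seed: int | np.random.Generator = 0) -> AbundanceMatrix:
    """Draw a random abundance map following the case layout.

    Every pixel of a stripe gives its dominant fluorophore a fraction
    uniform in the dominant band; overlap blocks give each named
    fluorophore ``fraction`` +/- a small jitter.  Columns are renormalized
    to sum exactly to 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = design.shape
    p = len(design.fluorophores)
    idx = {name: j for j, name in enumerate(design.fluorophores)}
    frac = np.zeros((p, h, w))

    lo, hi = design.dominant_band
    for j, (c0, c1) in enumerate(design.stripes):
        n = h * (c1 - c0)
        dom = rng.uniform(lo, hi, size=n)
        rest = _dirichlet_split(rng, n, p - 1) * (1.0 - dom)
        block = np.empty((p, n))
        block[j] = dom
        others = [jj for jj in range(p) if jj != j]
        block[others] = rest
        frac[:, :, c0:c1] = block.reshape(p, h, c1 - c0)

    for blk in design.overlap_blocks:
        (r0, r1), (c0, c1) = blk.rows, blk.cols
        n = (r1 - r0) * (c1 - c0)
        named = [idx[name] for name in blk.names]
        others = [jj for jj in range(p) if jj not in named]
        jit = min(OVERLAP_JITTER, blk.fraction * 0.5)
        k = len(named)
        shares = rng.uniform(blk.fraction - jit, blk.fraction + jit, size=(k, n))
        # rejection step: keep a small positive remainder for the unnamed
        # fluorophores without pushing any share out of its band
        for _ in range(200):
            bad = shares.sum(axis=0) > 0.98
            if not bad.any():
                break
            shares[:, bad] = rng.uniform(
                blk.fraction - jit, blk.fraction + jit, size=(k, int(bad.sum()))
            )
        rem = 1.0 - shares.sum(axis=0)
        block = np.zeros((p, n))
        block[named] = shares
        if others:
            block[others] = _dirichlet_split(rng, n, len(others)) * rem
        else:
            block[named] += rem / len(named)
        frac[:, r0:r1, c0:c1] = block.reshape(p, r1 - r0, c1 - c0)

    flat = frac.reshape(p, h * w)
    flat = flat / flat.sum(axis=0)
    rows, cols = np.divmod(np.arange(h * w), w)
    pixel_map = np.column_stack([np.zeros(h * w, dtype=np.int64), rows, cols])
    return AbundanceMatrix(
        fractions=flat,
        pixel_map=pixel_map,
        names=list(design.fluorophores),
        canvas_shape=design.shape,
    )


def fixture_spectra(
    names: tuple[str, ...] | list[str],
    channel_set: ChannelSet | None = None,
) -> EndmemberMatrix:
    """Stand-in normalized channel spectra for the named fluorophores.

    The shipped library is synthetic: smooth excitation/emission profiles
    with the qualitative shapes of the named cellular fluorophores, sampled
    on the 18 stand-in channels, per-column normalized to maximum 1.
    """
    with importlib.resources.as_file(_data_path("fixture_spectra_synthetic.csv")) as p:
        table = pd.read_csv(p, comment="#")
    unknown = [n for n in names if n not in table.columns]
    if unknown:
        raise ValueError(
            f"unknown fluorophore(s) {unknown}; available: {list(FLUOROPHORES)}"
        )
    m = table[list(names)].to_numpy(dtype=float)
    return EndmemberMatrix(m, names=list(names))


def mix(M: EndmemberMatrix, s: AbundanceMatrix, channel_set: ChannelSet | None = None) -> HyperspectralCube:
    """Noiseless linear mixture x = M s."""
    if M.n_endmembers != s.n_endmembers:
        raise ValueError(
            f"endmember count mismatch: M has {M.n_endmembers}, s has {s.n_endmembers}"
        )
    values = M.spectra @ s.fractions
    pixel_map = s.pixel_map
    if pixel_map is None:
        n = values.shape[1]
        pixel_map = np.column_stack(
            [np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64), np.arange(n)]
        )
    return HyperspectralCube(
        values=values,
        pixel_map=pixel_map,
        channel_set=channel_set,
        canvas_shape=s.canvas_shape,
    )


def add_noise(cube: HyperspectralCube, spec: NoiseSpec) -> HyperspectralCube:
    """y = x + n with i.i.d. zero-mean Gaussian noise at the requested SNR.

    sigma solves 10*log10(mean(x^2) / sigma^2) = snr_db with one global
    sigma over the whole cube; ``snr_db = +inf`` returns the input
    unchanged.  Same seed, same cube -> bit-identical output.
    """
    cube.validate_finite()
    if spec.snr_db == np.inf:
        return HyperspectralCube(
            values=cube.values.copy(),
            pixel_map=cube.pixel_map.copy(),
            channel_set=cube.channel_set,
            canvas_shape=cube.canvas_shape,
        )
    power = float(np.mean(cube.values**2))
    sigma = np.sqrt(power / 10.0 ** (spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, sigma, size=cube.values.shape)
    return HyperspectralCube(
        values=cube.values + noise,
        pixel_map=cube.pixel_map.copy(),
        channel_set=cube.channel_set,
        canvas_shape=cube.canvas_shape,
    )


def simulate_case(
    case_id: str,
    snr_db: float,
    seed: int,
) -> tuple[HyperspectralCube, EndmemberMatrix, AbundanceMatrix]:
    """Generate one complete artificial dataset: (noisy cube, true M, true s).

    The abundance draw and the noise draw use independent streams derived
    from ``seed`` so the same scene can be re-noised reproducibly.
    """
    ss = np.random.SeedSequence(seed)
    s_ab, s_noise = ss.spawn(2)
    design = case_design(case_id)
    channels = default_channel_set()
    s_true = generate_case_abundance(design, np.random.default_rng(s_ab))
    M_true = fixture_spectra(design.fluorophores, channels)
    clean = mix(M_true, s_true, channels)
    noisy = add_noise(clean, NoiseSpec(snr_db=snr_db, seed=int(s_noise.generate_state(1)[0] % (2**31))))
    return noisy, M_true, s_true
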