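"""Signal-subspace identification by minimum error (HySime).

Hyperspectral channel images are strongly correlated, so the noiseless
signal lives in a low-dimensional subspace of the L-dimensional channel
space.  HySime proceeds in two steps:

1. *Noise estimation*: each channel is regressed on all the others
   (ordinary least squares); because the signal is near-perfectly
   predictable across channels while the noise is independent, the
   regression residuals estimate the per-channel noise.
2. *Subspace selection*: the signal correlation matrix (observation
   correlation minus noise correlation) is diagonalised and eigenvectors
   are admitted into the signal subspace while doing so lowers the
   estimated mean-squared error between the unknown noiseless signal and
   its projection, i.e. while the signal power along an eigenvector
   exceeds twice its noise power.

The selected dimension equals the number of mixture endmembers p (the
affine hull of p spectra not through the origin spans p linear
dimensions), and the orthonormal basis E supplies the reduced p x N
representation used by the unmixing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HyperspectralCube

__all__ = ["SubspaceModel", "estimate_noise", "hysime", "project", "back_project"]


@dataclass
class SubspaceModel:
    p: int
    basis: np.ndarray  # (L, p), orthonormal columns
    noise_variance: np.ndarray  # per-channel sigma_k^2
    mse_curve: np.ndarray  # estimated MSE for candidate sizes 0..L
    eigenvalues: np.ndarray | None = None

    def __post_init__(self):
        E = np.asarray(self.basis, dtype=float)
        if E.ndim != 2 or E.shape[1] != self.p:
            raise ValueError("basis must be (L, p)")
        if self.p >= E.shape[0]:
            raise ValueError("p must be smaller than the number of channels")
        g = E.T @ E
        if not np.allclose(g, np.eye(self.p), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")
        if np.any(np.asarray(self.noise_variance) < 0):
            raise ValueError("noise variances must be non-negative")


def estimate_noise(cube: HyperspectralCube | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel noise via multiple regression.

    Returns ``(residuals, Rn)``: the (L, N) noise estimate (band k minus
    its least-squares prediction from all other bands) and its (L, L)
    sample correlation matrix.
    """
    Y = cube.values if isinstance(cube, HyperspectralCube) else np.asarray(cube, float)
    L, N = Y.shape
    if L < 3:
        raise ValueError("noise estimation needs at least 3 channels")
    if N <= L:
        raise ValueError("noise estimation needs more pixels than channels")
    R = Y @ Y.T / N
    # small ridge keeps the inverse stable for near-noiseless low-rank data
    ridge = 1e-10 * np.trace(R) / L
    Rinv = np.linalg.inv(R + ridge * np.eye(L))
    # residual of regressing band k on the others, via the inverse-correlation
    # identity: resid_k = (Rinv @ Y)[k] / Rinv[k, k]
    resid = np.empty_like(Y)
    infl = np.empty(L)
    for k in range(L):
        w = Rinv[k] / Rinv[k, k]
        w[k] = 0.0
        resid[k] = Y[k] + w @ Y
        # errors-in-variables inflation: the residual contains the channel's
        # own noise plus the projected noise of the regressors,
        # Var(resid_k) ~ sigma^2 (1 + ||beta_k||^2)
        infl[k] = 1.0 + (w @ w)
    Rn = resid @ resid.T / N
    d = 1.0 / np.sqrt(infl)
    Rn = Rn * np.outer(d, d)
    return resid, Rn


def hysime(
    cube: HyperspectralCube | np.ndarray,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
    max_p: int | None = None,
) -> SubspaceModel:
    """Select the signal subspace minimizing the estimated projection MSE.

    Ties in the MSE curve break toward smaller p (parsimony); p is capped
    at L-1.
    """
    Y = cube.values if isinstance(cube, HyperspectralCube) else np.asarray(cube, float)
    L, N = Y.shape
    if noise is None:
        noise = estimate_noise(Y)
    resid, Rn = noise
    if resid.shape != Y.shape:
        raise ValueError("noise estimate does not match the cube")
    X = Y - resid
    Ry = Y @ Y.T / N
    Rx = X @ X.T / N
    Rx = (Rx + Rx.T) / 2.0
    evals, evecs = np.linalg.eigh(Rx)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # per-eigenvector observation and noise powers
    py = np.einsum("ji,jk,ki->i", evecs, Ry, evecs)
    pn = np.einsum("ji,jk,ki->i", evecs, Rn, evecs)
    # floor at numerical precision so exactly-low-rank (noiseless) data does
    # not admit machine-epsilon eigenvectors
    floor = 1e-12 * np.trace(Ry) / L
    pn = np.maximum(pn, floor)
    # including eigenvector i trades its excluded signal power py_i for a
    # projection-noise cost 2*pn_i; rank candidates by that trade-off
    cost = 2.0 * pn - py
    order2 = np.argsort(cost, kind="stable")
    mse_curve = np.empty(L + 1)
    for k in range(L + 1):
        mse_curve[k] = py[order2[k:]].sum() + 2.0 * pn[order2[:k]].sum()
    cap = min(L - 1, max_p if max_p is not None else L - 1)
    p = int(np.argmin(mse_curve[: cap + 1]))  # first occurrence: ties -> smaller p
    p = max(p, 1)
    return SubspaceModel(
        p=p,
        basis=evecs[:, order2[:p]],
        noise_variance=np.diag(Rn).copy(),
        mse_curve=mse_curve,
        eigenvalues=evals,
    )


def project(cube: HyperspectralCube | np.ndarray, model: SubspaceModel) -> np.ndarray:
    """Orthogonal projection of pixel spectra onto the signal subspace.

    Returns the (p, N) reduced coordinates ``E^T y``.
    """
    Y = cube.values if isinstance(cube, HyperspectralCube) else np.asarray(cube, float)
    return model.basis.T @ Y


def back_project(y_sub: np.ndarray, model: SubspaceModel) -> np.ndarray:
    """Lift reduced coordinates back to the L-dimensional channel space."""
    return model.basis @ np.asarray(y_sub, float)
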