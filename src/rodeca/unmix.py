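"""Unmixing core: SISAL initialization and Dirichlet-mixture GEM (RoDECA).

Given the p x N subspace representation of the pixel spectra, the
endmember simplex is estimated in two stages:

1. **SISAL** - minimum-volume simplex fitting.  With ``Q = A^-1`` and the
   sum-to-one constraint folded into ``Q`` (rows of ``Q`` summing to the
   unique vector ``c`` with ``c^T y = 1`` on the data's affine hull), SISAL
   minimizes ``-log|det Q| + tau * sum hinge(Q y)`` where
   ``hinge(z) = max(0, -z)`` softly penalizes negative abundances.  The
   optimization uses variable splitting and an augmented Lagrangian whose
   penalty weight doubles on a fixed schedule, started from a VCA draw.
   SISAL needs no pure pixels, which autofluorescence data do not offer.
   The hinge weight is noise-adaptive: with heavier noise the simplex
   facets should cut through the smeared boundary of the point cloud
   instead of enclosing it, which a stiff hinge would force.

2. **Dirichlet-mixture GEM** - the abundances ``s = W y`` are modeled as a
   mixture of Dirichlet densities (automatically non-negative and
   sum-to-one), and the mixture together with ``W`` is estimated by a
   generalized EM: responsibilities in the E-step, then coordinate ascent
   over the mixture weights, the Dirichlet parameters (weighted Minka
   fixed-point updates, concentration-capped against the classic
   delta-degeneracy of mixture likelihoods) and ``W`` (constrained
   quasi-Newton on the observed-data objective).  Negative abundances are
   charged their Gaussian noise log-likelihood (a quadratic hinge scaled
   by the per-component noise variance), and the ``W`` update is confined
   to a trust region whose radius scales with the statistical uncertainty
   of the initial simplex - at high SNR the minimum-volume geometry is
   trusted, under heavy noise the statistical refinement may move more.
   Every update is accepted only if it does not decrease the objective,
   so the objective trace is non-decreasing on every run.

The final endmembers are lifted back to channel space, clipped to be
non-negative and normalized to a per-column maximum of 1; abundances are
Euclidean-projected onto the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, polygamma, psi

from .core import AbundanceMatrix, EndmemberMatrix, HyperspectralCube
from .subspace import SubspaceModel, back_project, estimate_noise, hysime, project

__all__ = [
    "SisalConfig",
    "EmConfig",
    "UnmixConfig",
    "DirichletMixture",
    "UnmixResult",
    "vca",
    "sisal",
    "rodeca_em",
    "recover_endmembers",
    "compute_abundance",
    "simplex_project",
    "unmix",
]

# ---------------------------------------------------------------------------
# configuration


@dataclass
class SisalConfig:
    """Settings of the minimum-volume simplex stage.

    ``tau`` is the maximum hinge weight; when ``adapt_tau`` is on, the
    effective weight is ``min(tau, tau_scale / sigma_rel)`` with
    ``sigma_rel`` the estimated noise-to-signal amplitude ratio of the
    cube, so facets relax as the boundary of the point cloud blurs.
    """

    tau: float = 1.0
    max_iter: int = 80  # outer augmented-Lagrangian iterations
    tol: float = 1e-8
    seed: int = 0
    mu0: float = 1.0  # initial AL penalty (at unit data RMS); doubles every 10 iters
    mu_max: float = 1e4  # cap on the AL penalty (ADMM converges at fixed mu)
    adapt_tau: bool = True
    tau_scale: float = 0.02

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class EmConfig:
    """Settings of the Dirichlet-mixture GEM stage."""

    kappa_max: int = 4  # initial number of Dirichlet modes
    max_iter: int = 200
    tol: float = 1e-6  # relative objective change
    seed: int = 0
    theta_floor: float = 1.02  # keeps the Dirichlet boundary non-singular
    alpha0_cap: float = 50.0  # per-mode concentration cap (anti-degeneracy)
    delta: float = 1e-3  # log-density floor below delta
    trust: float = 0.2  # W trust radius in units of per-component noise sigma


@dataclass
class UnmixConfig:
    """End-to-end pipeline settings."""

    seed: int = 0
    force_p: int | None = None
    normalize_pixels: bool = False
    sisal: SisalConfig | None = None
    em: EmConfig | None = None


@dataclass
class DirichletMixture:
    weights: np.ndarray  # (kappa,), on the simplex
    theta: np.ndarray  # (kappa, p), entries > 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.theta = np.asarray(self.theta, float)
        if np.any(self.theta <= 0):
            raise ValueError("Dirichlet parameters must be positive")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mode weights must lie on the simplex")


@dataclass
class UnmixResult:
    endmembers: EndmemberMatrix
    abundances: AbundanceMatrix
    W: np.ndarray
    mixture: DirichletMixture
    loglik_trace: np.ndarray
    subspace: SubspaceModel
    n_projected: int = 0  # abundance columns repaired by simplex projection
    seed: int | None = None


# ---------------------------------------------------------------------------
# geometry helpers


def simplex_project(S: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    S = np.asarray(S, float)
    p, n = S.shape
    u = np.sort(S, axis=0)[::-1]
    css = np.cumsum(u, axis=0) - 1.0
    ind = np.arange(1, p + 1)[:, None]
    cond = u - css / ind > 0
    rho = p - np.argmax(cond[::-1], axis=0) - 1  # last True index per column
    lam = -css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(S + lam, 0.0)


def vca(Y: np.ndarray, p: int, seed: int = 0) -> np.ndarray:
    """Vertex component analysis: endmembers by repeated orthogonal projection.

    Returns p columns of ``Y``.  Data containing pure pixels are recovered
    exactly (up to permutation); ``p = 1`` returns the maximum-norm pixel.
    """
    Y = np.asarray(Y, float)
    d, n = Y.shape
    if p < 1 or p > min(d, n):
        raise ValueError(f"p={p} out of range for data of shape {Y.shape}")
    if p == 1:
        return Y[:, [int(np.argmax(np.linalg.norm(Y, axis=0)))]]
    rng = np.random.default_rng(seed)
    # projective normalization: map the data's affine hull to a linear
    # subspace so simplex vertices become extreme in every direction
    u = Y.mean(axis=1)
    u /= np.linalg.norm(u)
    denom = u @ Y
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    Z = Y / denom
    A = np.zeros((d, p))
    A[0, 0] = 1.0
    indices: list[int] = []
    for i in range(p):
        w = rng.standard_normal(d)
        proj = A[:, : max(i, 1)]
        f = w - proj @ np.linalg.lstsq(proj, w, rcond=None)[0]
        nf = np.linalg.norm(f)
        if nf < 1e-12:  # degenerate draw; fall back to the raw direction
            f = w
            nf = np.linalg.norm(f)
        f /= nf
        k = int(np.argmax(np.abs(f @ Z)))
        indices.append(k)
        A[:, i] = Z[:, k]
    return Y[:, indices]


def _affine_normal(Y: np.ndarray) -> np.ndarray:
    """The vector c with c^T y ~= 1 on the data's affine hull."""
    c, *_ = np.linalg.lstsq(Y.T, np.ones(Y.shape[1]), rcond=None)
    return c


# ---------------------------------------------------------------------------
# SISAL


def sisal(
    y_sub: np.ndarray,
    p: int,
    config: SisalConfig | None = None,
    sigma_rel: float | None = None,
) -> np.ndarray:
    """Minimum-volume simplex via split augmented Lagrangian.

    ``y_sub`` must be the (p, N) subspace representation whose columns
    affinely span p-1 dimensions.  ``sigma_rel`` (noise-to-signal
    amplitude ratio) activates the noise-adaptive hinge weight.  Returns
    the (p, p) vertex estimate ``A0`` (columns are simplex vertices in
    subspace coordinates).
    """
    config = config or SisalConfig()
    Y = np.asarray(y_sub, float)
    if Y.ndim != 2 or Y.shape[0] != p:
        raise ValueError(f"y_sub must be ({p}, N), got {Y.shape}")
    if p < 2:
        raise ValueError("SISAL needs p >= 2 (a 1-vertex simplex is a point)")
    n = Y.shape[1]
    centered = Y - Y.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(Y).max())) < p - 1:
        raise ValueError(
            "data do not affinely span p-1 dimensions; "
            "reduce p or check the subspace projection"
        )
    # normalize the working scale so the AL penalty schedule (and hence the
    # iteration-budget regularization) behaves identically for any units
    scale = float(np.sqrt(np.mean(Y**2)))
    if scale <= 0:
        raise ValueError("y_sub has zero amplitude")
    Y = Y / scale
    c = _affine_normal(Y)

    tau = config.tau
    if config.adapt_tau and sigma_rel is not None and sigma_rel > 0:
        tau = min(tau, config.tau_scale / sigma_rel)

    A0 = vca(Y, p, seed=config.seed)
    Q = np.linalg.inv(A0)
    # VCA vertices are data columns, so 1^T Q = c^T holds up to noise;
    # enforce it exactly
    Q += np.outer(np.ones(p), c - Q.sum(axis=0)) / p

    mu = config.mu0
    Lam = np.zeros((p, n))
    obj_prev = np.inf

    def hinge_obj(Q):
        s = Q @ Y
        sign, logdet = np.linalg.slogdet(Q)
        if sign == 0:
            return np.inf
        return -logdet + tau * np.maximum(0.0, -s).sum()

    for it in range(config.max_iter):
        # Z-update: prox of the hinge
        V = Q @ Y - Lam
        Z = np.where(V >= 0.0, V, np.minimum(V + tau / mu, 0.0))
        # Q-update: smooth subproblem -log|det Q| + mu/2 ||QY - (Z + Lam)||^2
        C = Z + Lam
        Q = _solve_q(Q, Y, C, c, mu)
        Lam = Lam - (Q @ Y - Z)
        if (it + 1) % 10 == 0:
            mu = min(mu * 2.0, config.mu_max)
        obj = hinge_obj(Q)
        gap = np.abs(Q @ Y - Z).max()
        if gap < config.tol and abs(obj - obj_prev) <= config.tol * (1.0 + abs(obj)):
            break
        obj_prev = obj
    return np.linalg.inv(Q) * scale


def _solve_q(Q0: np.ndarray, Y: np.ndarray, C: np.ndarray, c: np.ndarray, mu: float) -> np.ndarray:
    """min_Q -log|det Q| + mu/2 ||QY - C||_F^2  s.t.  1^T Q = c^T."""
    p = Q0.shape[0]

    def unpack(x):
        Qf = x.reshape(p - 1, p)
        return np.vstack([Qf, c - Qf.sum(axis=0)])

    def fun(x):
        Q = unpack(x)
        sign, logdet = np.linalg.slogdet(Q)
        if sign == 0 or not np.isfinite(logdet):
            return 1e30, np.zeros_like(x)
        R = Q @ Y - C
        f = -logdet + 0.5 * mu * (R * R).sum()
        G = -np.linalg.inv(Q).T + mu * (R @ Y.T)
        Gf = G[: p - 1] - G[p - 1]  # chain rule through the dependent last row
        return f, Gf.ravel()

    res = minimize(
        fun,
        Q0[: p - 1].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 60, "ftol": 1e-14, "gtol": 1e-12},
    )
    return unpack(res.x)


# ---------------------------------------------------------------------------
# Dirichlet-mixture GEM


def _floored_log(S: np.ndarray, delta: float) -> np.ndarray:
    """log(s) floored at log(delta).

    Abundances below ``delta`` (including noise-displaced negative ones)
    contribute a flat floor term rather than a theta-scaled barrier, so
    the simplex is not forced to expand around noisy outliers; their
    negativity is charged to the separate quadratic hinge instead.
    """
    return np.log(np.maximum(S, delta))


def _floored_log_grad(S: np.ndarray, delta: float) -> np.ndarray:
    return np.where(S >= delta, 1.0 / np.maximum(S, delta), 0.0)


def _mode_loglik(G: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-pixel Dirichlet log-density for each mode; G = floored log(S)."""
    norm = gammaln(theta.sum(axis=1)) - gammaln(theta).sum(axis=1)
    return norm[:, None] + (theta - 1.0) @ G


def _inv_digamma(y: np.ndarray) -> np.ndarray:
    """Inverse of the digamma function (Minka's Newton iteration)."""
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - psi(1.0)))
    for _ in range(6):
        x = x - (psi(x) - y) / polygamma(1, x)
        x = np.maximum(x, 1e-8)
    return x


def _fit_dirichlet(
    mbar: np.ndarray,
    theta0: np.ndarray,
    floor: float,
    alpha0_cap: float,
) -> np.ndarray:
    """Weighted Dirichlet ML fixed point for sufficient stats E[log s_j].

    The total concentration is capped: an uncapped mixture mode can
    concentrate without bound on a shrinking set of pixels (the standard
    degeneracy of mixture likelihoods).
    """
    theta = theta0.copy()
    for _ in range(25):
        theta_new = _inv_digamma(psi(theta.sum()) + mbar)
        theta_new = np.maximum(theta_new, floor)
        if theta_new.sum() > alpha0_cap:
            theta_new = np.maximum(theta_new * (alpha0_cap / theta_new.sum()), floor)
        if np.max(np.abs(theta_new - theta)) < 1e-9 * (1.0 + theta.max()):
            theta = theta_new
            break
        theta = theta_new
    return theta


def _em_objective(W, Y, weights, theta, delta, inv2):
    """Penalized observed-data objective of the GEM.

    N*log|det W| + mixture log-likelihood - quadratic noise hinge on
    negative abundances (their Gaussian negative log-likelihood).
    """
    S = W @ Y
    G = _floored_log(S, delta)
    ll = _mode_loglik(G, theta)
    m = ll.max(axis=0)
    sign, logdet = np.linalg.slogdet(W)
    if sign == 0:
        return -np.inf
    mix = m + np.log((weights[:, None] * np.exp(ll - m)).sum(axis=0))
    pen = 0.5 * (np.minimum(S, 0.0) ** 2 * inv2).sum()
    return Y.shape[1] * logdet + mix.sum() - pen


def rodeca_em(
    y_sub: np.ndarray,
    A0: np.ndarray,
    config: EmConfig | None = None,
    noise_cov: np.ndarray | None = None,
) -> tuple[np.ndarray, DirichletMixture, np.ndarray]:
    """Dirichlet-mixture GEM refinement of the simplex.

    ``noise_cov`` is the (p, p) noise covariance in subspace coordinates
    (from the subspace model); omitted, the data are treated as noiseless,
    which makes the negativity hinge stiff and the W trust region tight.
    Returns ``(W, mixture, objective_trace)`` with ``W = A^-1`` in
    subspace coordinates; the trace is non-decreasing within numerical
    slack on every run.
    """
    config = config or EmConfig()
    Y = np.asarray(y_sub, float)
    p, n = Y.shape
    A0 = np.asarray(A0, float)
    if A0.shape != (p, p) or np.linalg.slogdet(A0)[0] == 0:
        raise ValueError("A0 must be a full-rank (p, p) matrix")
    # work at unit data RMS so optimizer tolerances are unit-independent;
    # abundances s = W y are unaffected
    scale = float(np.sqrt(np.mean(Y**2)))
    if scale <= 0:
        raise ValueError("y_sub has zero amplitude")
    Y = Y / scale
    A0 = A0 / scale
    if noise_cov is not None:
        noise_cov = np.asarray(noise_cov, float) / scale**2
    rng = np.random.default_rng(config.seed)
    c = _affine_normal(Y)
    W = np.linalg.inv(A0)
    W += np.outer(np.ones(p), c - W.sum(axis=0)) / p
    W_anchor = W.copy()

    # per-component abundance noise scale at the initial geometry
    if noise_cov is not None:
        sig2_s = np.maximum(np.diag(W @ noise_cov @ W.T), 0.0)
    else:
        sig2_s = np.zeros(p)
    inv2 = (1.0 / np.maximum(sig2_s, 1e-12))[:, None]
    radius = np.maximum(config.trust * np.sqrt(sig2_s), 1e-9)

    kappa = max(1, config.kappa_max)
    delta = config.delta
    # seed the modes from the initial abundance geometry: one cluster per
    # dominant component (a flat symmetric start cannot break the mode
    # symmetry and lets the volume term collapse the mixture)
    S0 = W @ Y
    G0 = _floored_log(S0, delta)
    labels = np.argmax(S0, axis=0)
    theta = np.ones((kappa, p))
    weights = np.full(kappa, 1.0 / kappa)
    for q in range(kappa):
        members = labels == (q % p)
        if members.sum() >= p + 1:
            theta[q] = _fit_dirichlet(
                G0[:, members].mean(axis=1),
                np.ones(p),
                config.theta_floor,
                config.alpha0_cap,
            )
            weights[q] = members.mean()
        else:
            theta[q] = np.maximum(
                1.0 + rng.uniform(-0.5, 0.5, size=p), config.theta_floor
            )
    weights /= weights.sum()

    trace = [_em_objective(W, Y, weights, theta, delta, inv2)]
    J = trace[0]

    for _ in range(config.max_iter):
        # E-step
        S = W @ Y
        G = _floored_log(S, delta)
        ll = _mode_loglik(G, theta)
        m = ll.max(axis=0)
        post = weights[:, None] * np.exp(ll - m)
        tot = post.sum(axis=0)
        post /= np.where(tot > 0, tot, 1.0)

        # mixture weights, with guarded pruning of starved modes
        w_new = post.sum(axis=1) / n
        if kappa > 1:
            keep = w_new >= 1.0 / (10.0 * n)
            if not np.all(keep) and keep.sum() >= 1:
                J_try = _em_objective(
                    W, Y, w_new[keep] / w_new[keep].sum(), theta[keep], delta, inv2
                )
                if J_try >= J - 1e-9 * (1.0 + abs(J)):
                    post, theta = post[keep], theta[keep]
                    w_new = w_new[keep]
                    kappa = int(keep.sum())
        weights = np.maximum(w_new, 1e-300)
        weights /= weights.sum()

        # Dirichlet parameters per mode (weighted Minka fixed point)
        theta_new = theta.copy()
        for q in range(kappa):
            wq = post[q]
            totq = wq.sum()
            if totq > 0:
                theta_new[q] = _fit_dirichlet(
                    (G * wq).sum(axis=1) / totq,
                    theta[q],
                    config.theta_floor,
                    config.alpha0_cap,
                )
        J_try = _em_objective(W, Y, weights, theta_new, delta, inv2)
        if J_try >= J - 1e-9 * (1.0 + abs(J)):
            theta = theta_new
            J = J_try

        # W update: trust-region quasi-Newton ascent, accepted on improvement
        W_new = _update_w(W, Y, weights, theta, c, delta, inv2, W_anchor, radius)
        J_new = _em_objective(W_new, Y, weights, theta, delta, inv2)
        if J_new > J:
            W = W_new
            J = J_new

        trace.append(J)
        if abs(trace[-1] - trace[-2]) <= config.tol * (1.0 + abs(trace[-2])):
            break

    return W / scale, DirichletMixture(weights=weights, theta=theta), np.asarray(trace)


def _update_w(W0, Y, weights, theta, c, delta, inv2, W_anchor, radius):
    """Ascend the penalized objective over W with 1^T W = c^T fixed and the
    free rows box-bounded inside the trust region around the anchor."""
    p, n = W0.shape[0], Y.shape[1]
    lb = (W_anchor[: p - 1] - radius[: p - 1, None]).ravel()
    ub = (W_anchor[: p - 1] + radius[: p - 1, None]).ravel()

    def unpack(x):
        Wf = x.reshape(p - 1, p)
        return np.vstack([Wf, c - Wf.sum(axis=0)])

    def fun(x):
        W = unpack(x)
        sign, logdet = np.linalg.slogdet(W)
        if sign == 0 or not np.isfinite(logdet):
            return 1e30, np.zeros_like(x)
        S = W @ Y
        G = _floored_log(S, delta)
        ll = _mode_loglik(G, theta)
        m = ll.max(axis=0)
        E = weights[:, None] * np.exp(ll - m)
        tot = E.sum(axis=0)
        J = (
            n * logdet
            + (m + np.log(tot)).sum()
            - 0.5 * (np.minimum(S, 0.0) ** 2 * inv2).sum()
        )
        beta = E / tot
        # dJ/dS: mixture term + quadratic hinge
        coeff = np.einsum("qi,qj->ji", beta, theta - 1.0)
        D = coeff * _floored_log_grad(S, delta) - np.minimum(S, 0.0) * inv2
        Grad = n * np.linalg.inv(W).T + D @ Y.T
        Gf = Grad[: p - 1] - Grad[p - 1]
        return -J, -Gf.ravel()

    res = minimize(
        fun,
        np.clip(W0[: p - 1].ravel(), lb, ub),
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": 25, "ftol": 1e-13, "gtol": 1e-10},
    )
    return unpack(res.x)


# ---------------------------------------------------------------------------
# reconstruction


def recover_endmembers(
    W: np.ndarray,
    model: SubspaceModel,
    names: list[str] | None = None,
) -> EndmemberMatrix:
    """Lift A = W^-1 back to channel space; clip negatives, normalize max to 1."""
    A = np.linalg.inv(np.asarray(W, float))
    M = back_project(A, model)
    return EndmemberMatrix(M, names=names).normalized()


def compute_abundance(
    W: np.ndarray,
    y_sub: np.ndarray,
    pixel_map: np.ndarray | None = None,
    canvas_shape: tuple[int, int] | None = None,
    names: list[str] | None = None,
) -> tuple[AbundanceMatrix, int]:
    """Abundances s = W y, repaired by Euclidean projection onto the simplex.

    Returns the abundance matrix and the number of columns the projection
    actually changed (a diagnostic: how many pixels left the simplex).
    """
    S = np.asarray(W, float) @ np.asarray(y_sub, float)
    S_proj = simplex_project(S)
    n_projected = int(np.sum(np.abs(S_proj - S).max(axis=0) > 1e-12))
    ab = AbundanceMatrix(
        fractions=S_proj, pixel_map=pixel_map, names=names, canvas_shape=canvas_shape
    )
    return ab, n_projected


# ---------------------------------------------------------------------------
# full pipeline


def unmix(cube: HyperspectralCube, config: UnmixConfig | None = None) -> UnmixResult:
    """Noise estimation -> HySime -> projection -> SISAL -> GEM -> reconstruction."""
    config = config or UnmixConfig()
    ss = np.random.SeedSequence(config.seed)
    s_sisal, s_em = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    Y = cube.values
    if config.normalize_pixels:
        norms = np.abs(Y).sum(axis=0)
        Y = Y / np.where(norms > 0, norms, 1.0)
    # internal amplitude normalization: makes the pipeline scale-equivariant
    # and keeps optimizer tolerances meaningful for any input units
    y_scale = float(np.sqrt(np.mean(Y**2)))
    if y_scale <= 0:
        raise ValueError("cube has zero signal")
    work = HyperspectralCube(
        values=Y / y_scale,
        pixel_map=cube.pixel_map,
        channel_set=cube.channel_set,
        canvas_shape=cube.canvas_shape,
    )

    noise = estimate_noise(work)
    if config.force_p is not None:
        model = _force_p_model(work, noise, config.force_p)
    else:
        model = hysime(work, noise)
    y_sub = project(work, model)

    # noise-to-signal amplitude ratio (channel space) and subspace noise
    # covariance, both from the regression-based noise estimate
    sigma_rel = float(np.sqrt(np.mean(np.diag(noise[1]))) / np.sqrt(np.mean(work.values**2)))
    noise_cov_sub = model.basis.T @ np.diag(np.diag(noise[1])) @ model.basis

    sisal_cfg = replace(config.sisal or SisalConfig(), seed=s_sisal)
    em_cfg = replace(config.em or EmConfig(), seed=s_em)

    if model.p >= 2:
        A0 = sisal(y_sub, model.p, sisal_cfg, sigma_rel=sigma_rel)
        W, mixture, trace = rodeca_em(y_sub, A0, em_cfg, noise_cov=noise_cov_sub)
    else:
        # single-endmember cube: the simplex is a point
        W = np.atleast_2d(_affine_normal(y_sub))
        mixture = DirichletMixture(weights=np.ones(1), theta=np.ones((1, 1)))
        trace = np.zeros(1)

    endmembers = recover_endmembers(W, model)  # scale-free (normalized)
    abundances, n_proj = compute_abundance(
        W, y_sub, pixel_map=cube.pixel_map, canvas_shape=cube.canvas_shape
    )
    return UnmixResult(
        endmembers=endmembers,
        abundances=abundances,
        W=W,
        mixture=mixture,
        loglik_trace=trace,
        subspace=model,
        n_projected=n_proj,
        seed=config.seed,
    )


def _force_p_model(cube, noise, p_forced: int) -> SubspaceModel:
    """Rebuild a subspace model with a user-fixed dimension."""
    resid, Rn = noise
    Y = cube.values
    L, N = Y.shape
    if not (1 <= p_forced <= L - 1):
        raise ValueError(f"force_p must be in [1, {L - 1}]")
    X = Y - resid
    Rx = X @ X.T / N
    Rx = (Rx + Rx.T) / 2.0
    evals, evecs = np.linalg.eigh(Rx)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    base = hysime(cube, noise)
    return SubspaceModel(
        p=p_forced,
        basis=evecs[:, :p_forced],
        noise_variance=base.noise_variance,
        mse_curve=base.mse_curve,
        eigenvalues=evals[order],
    )
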