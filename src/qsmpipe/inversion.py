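"""Dipole inversion: forward model and regularised field-to-susceptibility solvers.

The magnetic field perturbation (in ppm of B0) produced by a susceptibility
distribution chi (ppm) is the convolution of chi with the unit dipole kernel,
which is diagonal in k-space:

    D(k) = 1/3 - (k . b)^2 / |k|^2,      D(0) = 0,

with b the unit B0 direction.  D vanishes on the magic-angle cone, which makes
the inverse problem ill-posed; the three solvers here regularise it in the
three ways commonly used for clinical gradient-echo data:

* ``invert_tikhonov`` -- iterative Tikhonov (L2 penalty on chi), solved by
  conjugate gradient on the normal equations.
* ``invert_nltv`` -- nonlinear total-variation inversion: a complex-exponential
  data-fidelity term (appropriate for complex Gaussian MRI noise) with an
  anisotropic TV penalty, solved by ADMM with per-voxel Newton updates on the
  phase split.
* ``invert_whqsm`` -- weak-harmonic QSM: the nonlinear-TV problem augmented
  with a jointly estimated residual field phi_h whose in-mask Laplacian is
  penalised, so that smooth (harmonic) background remnants are absorbed by
  phi_h instead of leaking into chi.

All solvers work in ppm, so the explicit B0 factor of the physical forward
model is absorbed into the units.  Solutions are mean-referenced over the FFT
volume (D(0) = 0 convention); no CSF referencing is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DipoleKernel",
    "InversionParams",
    "SusceptibilityMap",
    "HarmonicField",
    "ITERTIK_PRESET",
    "NLTV_PRESET",
    "WHQSM_PRESET",
    "dipole_kernel",
    "forward_field",
    "invert_tikhonov",
    "invert_nltv",
    "invert_whqsm",
    "lcurve_select",
]


# ---------------------------------------------------------------------------
# Types


@dataclass
class DipoleKernel:
    """k-space unit dipole kernel on a given (working, possibly padded) grid."""

    values: np.ndarray
    voxel_size: tuple
    b0_direction: np.ndarray

    @property
    def shape(self):
        return self.values.shape


@dataclass
class InversionParams:
    """Parameters shared by the three inverters.

    alpha : regularisation strength (L2 weight for Tikhonov, TV weight for
        nlTV / WH-QSM).
    beta : weak-harmonic penalty weight (WH-QSM only).
    tol : convergence tolerance.  For the ADMM solvers this is a *percent*
        relative update (stop when 100 * ||dchi|| / ||chi|| < tol); for
        Tikhonov CG it is the relative residual norm.
    max_iter : iteration cap.
    mu_grad, mu_fidelity : ADMM penalty weights for the gradient and phase
        splits.  ``mu_grad`` defaults to 100 * alpha when left as None.
    pad_factor : zero-padding factor for the convolution grid (1 = periodic).
    newton_iters : inner Newton steps for the nonlinear phase update.
    """

    alpha: float = 1e-3
    beta: float = 150.0
    tol: float = 0.1
    max_iter: int = 100
    mu_grad: float | None = None
    mu_fidelity: float = 1.0
    pad_factor: int = 2
    newton_iters: int = 2

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")

    @property
    def mu1(self) -> float:
        return 100.0 * self.alpha if self.mu_grad is None else self.mu_grad


#: Regularisation presets as used on the clinical cohort: Tikhonov alpha from
#: an averaged L-curve over 10 subjects; TV / weak-harmonic alpha likewise;
#: beta at the weak-harmonic solver default.
ITERTIK_PRESET = InversionParams(alpha=0.0652)
NLTV_PRESET = InversionParams(alpha=1.956e-5)
WHQSM_PRESET = InversionParams(alpha=1.956e-5, beta=150.0)


@dataclass
class SusceptibilityMap:
    """Susceptibility distribution in ppm, zero outside the mask."""

    values: np.ndarray
    method: str
    mask: np.ndarray
    params: InversionParams
    converged: bool = True
    n_iter: int = 0


@dataclass
class HarmonicField:
    """Residual (nearly harmonic) field estimated jointly by WH-QSM, in ppm."""

    values: np.ndarray


# ---------------------------------------------------------------------------
# Forward model


def dipole_kernel(shape, voxel_size, b0_direction) -> DipoleKernel:
    """Unit dipole kernel D(k) = 1/3 - (k.b)^2/|k|^2 on the discrete grid.

    D(0) is set to 0 (mean-referenced convention).  Values lie in
    [-2/3, 1/3]; the kernel is even, D(k) = D(-k).
    """
    b = np.asarray(b0_direction, dtype=float)
    b = b / np.linalg.norm(b)
    freqs = [np.fft.fftfreq(n, d=dx) for n, dx in zip(shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[k2 == 0] = 0.0
    return DipoleKernel(values=d, voxel_size=tuple(voxel_size), b0_direction=b)


def _pad_shape(shape, pad_factor):
    return tuple(int(n * pad_factor) for n in shape)


def _embed(vol, big_shape):
    out = np.zeros(big_shape, dtype=vol.dtype)
    out[tuple(slice(0, n) for n in vol.shape)] = vol
    return out


def _crop(vol, small_shape):
    return vol[tuple(slice(0, n) for n in small_shape)]


def forward_field(chi, kernel: DipoleKernel | None = None, *, voxel_size=(1, 1, 1),
                  b0_direction=(0, 0, 1), pad_factor=2) -> np.ndarray:
    """Field (ppm) induced by a susceptibility map (ppm) via dipole convolution.

    The convolution runs on a zero-padded grid (``pad_factor`` times the input
    along each axis, default 2) to suppress periodic wrap-around, then crops
    back.  Pass a precomputed ``kernel`` on the padded grid to amortise the
    kernel construction; its shape must be ``pad_factor`` times ``chi.shape``.
    """
    chi = np.asarray(chi)
    if isinstance(chi, np.ndarray) is False:  # pragma: no cover
        raise TypeError("chi must be array-like")
    if kernel is None:
        big = _pad_shape(chi.shape, pad_factor)
        kernel = dipole_kernel(big, voxel_size, b0_direction)
    big = kernel.shape
    if any(b < s for b, s in zip(big, chi.shape)):
        raise ValueError(f"kernel grid {big} smaller than chi grid {chi.shape}")
    work = _embed(chi.astype(float), big)
    out = np.fft.ifftn(kernel.values * np.fft.fftn(work)).real
    return _crop(out, chi.shape)


# ---------------------------------------------------------------------------
# Solver internals


def _grad(x):
    """Forward differences with periodic boundary, unit spacing."""
    return np.stack([np.roll(x, -1, axis=a) - x for a in range(3)])


def _div(g):
    """Negative adjoint of ``_grad``: divergence with backward differences."""
    return sum(g[a] - np.roll(g[a], 1, axis=a) for a in range(3))


def _grad_symbol(shape):
    """|E|^2 summed over axes: spectral symbol of -div(grad) (periodic)."""
    k2 = np.zeros(shape)
    for a, n in enumerate(shape):
        f = np.fft.fftfreq(n)
        sl = [None] * 3
        sl[a] = slice(None)
        k2 = k2 + (2.0 - 2.0 * np.cos(2 * np.pi * f))[tuple(sl)]
    return k2


def _prepare(local_field, mask, weight, params, voxel_size, b0_direction):
    """Embed inputs on the padded working grid; build kernel and weights."""
    shape = local_field.shape
    big = _pad_shape(shape, params.pad_factor)
    kernel = dipole_kernel(big, voxel_size, b0_direction)
    f = _embed(np.nan_to_num(local_field.astype(float)), big)
    m = _embed(mask.astype(bool), big)
    if weight is None:
        w = m.astype(float)
    else:
        w = _embed(np.asarray(weight, dtype=float), big) * m
    return shape, big, kernel, f * m, m, w


def invert_tikhonov(local_field, mask, weight=None, params: InversionParams | None = None,
                    *, voxel_size=(1, 1, 1), b0_direction=(0, 0, 1)) -> SusceptibilityMap:
    """Iterative Tikhonov inversion.

    Minimises ``||W M (dB - chi * d)||_2^2 + alpha ||chi||_2^2`` by conjugate
    gradient on the normal equations, with the dipole convolution evaluated on
    the padded working grid.  With W = M = 1 and ``pad_factor=1`` the solution
    coincides with the closed-form k-space Tikhonov filter
    ``F^-1[D F(dB) / (D^2 + alpha)]``.
    """
    params = params or ITERTIK_PRESET
    shape, big, kernel, f, m, w = _prepare(
        local_field, mask, weight, params, voxel_size, b0_direction)
    d = kernel.values
    w2 = w * w

    def conv(x):
        return np.fft.ifftn(d * np.fft.fftn(x)).real

    def normal_op(x):
        return conv(w2 * conv(x)) + params.alpha * x

    b = conv(w2 * f)
    x = np.zeros(big)
    r = b - normal_op(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    b_norm = np.sqrt(np.vdot(b, b).real) or 1.0
    tol = min(params.tol, 1e-6) if params.tol >= 1e-2 else params.tol
    converged = rs == 0.0
    it = 0
    for it in range(1, max(params.max_iter, 300) + 1):
        if converged:
            break
        ap = normal_op(p)
        alpha_cg = rs / np.vdot(p, ap).real
        x += alpha_cg * p
        r -= alpha_cg * ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) / b_norm < tol:
            converged = True
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    if not converged:
        warnings.warn(
            f"Tikhonov CG did not reach tolerance {tol:g} in {it} iterations "
            f"(relative residual {np.sqrt(rs) / b_norm:.2e}); returning best iterate",
            RuntimeWarning,
        )
    chi = _crop(x, shape) * mask
    return SusceptibilityMap(chi, "iterTik", mask.astype(bool), params, converged, it)


def _admm_nltv(f, m, w, d, params, with_harmonic, beta, project_support=True):
    """Shared ADMM core for nlTV and WH-QSM on the padded grid.

    Splitting: z1 = grad(chi) (anisotropic L1 shrinkage), z2 = chi*d (+ phi_h)
    with a per-voxel Newton update on the complex-exponential fidelity; for
    WH-QSM an extra split z3 = lap(phi_h) confines the harmonic penalty to
    the mask.  phi_h is updated before chi each iteration so that smooth
    near-harmonic components are absorbed by the residual field rather than
    by susceptibility sources.  With ``project_support`` (default) chi is
    restricted to the mask after each update, enforcing the in-mask support
    contract and removing the degeneracy between external chi sources and
    phi_h.
    """
    big = f.shape
    alpha, mu1, mu2 = params.alpha, params.mu1, params.mu_fidelity
    w2 = w * w
    k2 = _grad_symbol(big)
    denom_x = mu1 * k2 + mu2 * d * d
    denom_x[denom_x == 0] = np.inf  # DC and exact nulls -> zero response

    # spectral multiplier of the periodic forward difference along each axis
    ek = []
    for a, n in enumerate(big):
        e = np.exp(2j * np.pi * np.fft.fftfreq(n)) - 1.0
        sl = [None] * 3
        sl[a] = slice(None)
        ek.append(e[tuple(sl)])

    x = np.zeros(big)
    z2 = f.copy()
    s2 = np.zeros(big)
    z1 = np.zeros((3,) + big)
    s1 = np.zeros((3,) + big)
    phi_h = np.zeros(big)
    if with_harmonic:
        # extra split z3 = lap(phi_h) so the beta penalty applies only inside
        # the mask: outside, phi_h is free to continue smoothly, which lets a
        # harmonic contaminant be absorbed at zero cost
        mu3 = params.mu_fidelity
        z3 = np.zeros(big)
        s3 = np.zeros(big)
        denom_z3 = beta * m.astype(float) + mu3
        denom_h = mu2 + mu3 * k2 * k2

        def lap(v):
            return np.fft.ifftn(-k2 * np.fft.fftn(v)).real

    dx = np.zeros(big)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # z2: Newton steps on  W^2 |e^{i z2} - e^{i f}|^2 + mu2 (z2 - dx - phi_h - s2)^2
        target = dx + phi_h + s2
        for _ in range(params.newton_iters):
            g = w2 * np.sin(z2 - f) + mu2 * (z2 - target)
            h = w2 * np.cos(z2 - f) + mu2
            z2 = z2 - g / np.maximum(h, 1e-12)
        if with_harmonic:
            lphi = lap(phi_h)
            z3 = mu3 * (lphi + s3) / denom_z3
            rhs = (mu2 * np.fft.fftn(z2 - s2 - dx)
                   - k2 * mu3 * np.fft.fftn(z3 - s3))
            phi_h = np.fft.ifftn(rhs / denom_h).real
            s3 = s3 + lap(phi_h) - z3
        # z1: anisotropic shrinkage
        gx = _grad(x)
        t = gx + s1
        z1 = np.sign(t) * np.maximum(np.abs(t) - alpha / mu1, 0.0)
        # chi: quadratic solve in k-space
        rhs_k = mu2 * d * np.fft.fftn(z2 - s2 - phi_h)
        diff = z1 - s1
        for a in range(3):
            rhs_k += mu1 * np.conj(ek[a]) * np.fft.fftn(diff[a])
        x_new = np.fft.ifftn(rhs_k / denom_x).real
        if project_support:
            x_new *= m
        upd = np.linalg.norm(x_new - x) / (np.linalg.norm(x_new) or 1.0)
        x = x_new
        gx = _grad(x)
        dx = np.fft.ifftn(d * np.fft.fftn(x)).real
        # duals
        s1 = s1 + gx - z1
        s2 = s2 + dx + phi_h - z2
        if 100.0 * upd < params.tol:
            converged = True
            break
    return x, phi_h, converged, it


def invert_nltv(local_field, mask, weight=None, params: InversionParams | None = None,
                *, voxel_size=(1, 1, 1), b0_direction=(0, 0, 1),
                **_admm_kw) -> SusceptibilityMap:
    """Nonlinear total-variation inversion (ADMM).

    Fidelity compares complex exponentials of the predicted and measured
    fields, which is the correct likelihood under complex Gaussian MRI noise;
    the anisotropic TV penalty promotes piecewise-constant solutions.  Stops
    when the percent relative chi update falls below ``params.tol``.
    """
    params = params or NLTV_PRESET
    shape, big, kernel, f, m, w = _prepare(
        local_field, mask, weight, params, voxel_size, b0_direction)
    x, _, converged, it = _admm_nltv(f, m, w, kernel.values, params,
                                     with_harmonic=False, beta=params.beta,
                                     **_admm_kw)
    if not converged:
        warnings.warn(
            f"nlTV ADMM hit max_iter={params.max_iter} before the {params.tol}% "
            "update tolerance; returning best iterate", RuntimeWarning)
    chi = _crop(x, shape) * mask
    return SusceptibilityMap(chi, "nlTV", mask.astype(bool), params, converged, it)


def invert_whqsm(local_field, mask, weight=None, params: InversionParams | None = None,
                 *, voxel_size=(1, 1, 1), b0_direction=(0, 0, 1),
                 **_admm_kw):
    """Weak-harmonic QSM: joint (chi, phi_h) estimation.

    The residual field phi_h enters the fidelity additively and is penalised
    by ``(beta/2) ||grad^2 phi_h||^2``, so smooth near-harmonic background
    remnants left after background-field removal are captured by phi_h at
    negligible cost while anatomy (which is not harmonic) stays in chi.
    Returns ``(SusceptibilityMap, HarmonicField)``.
    """
    params = params or WHQSM_PRESET
    shape, big, kernel, f, m, w = _prepare(
        local_field, mask, weight, params, voxel_size, b0_direction)
    x, phi_h, converged, it = _admm_nltv(f, m, w, kernel.values, params,
                                         with_harmonic=True, beta=params.beta,
                                         **_admm_kw)
    if not converged:
        warnings.warn(
            f"WH-QSM ADMM hit max_iter={params.max_iter} before the {params.tol}% "
            "update tolerance; returning best iterate", RuntimeWarning)
    chi = _crop(x, shape) * mask
    harm = _crop(phi_h, shape) * mask
    return (SusceptibilityMap(chi, "WH-QSM", mask.astype(bool), params, converged, it),
            HarmonicField(harm))


# ---------------------------------------------------------------------------
# L-curve regularisation selection


def _lcurve_corner(log_res, log_sol, alphas):
    """Maximum-curvature corner of the (log residual, log solution) curve.

    Curvature of the parametric curve (x(t), y(t)) with t = log alpha, via
    central finite differences.  Returns (alpha_star, had_corner).
    """
    t = np.log(alphas)
    x, y = np.asarray(log_res), np.asarray(log_sol)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / denom
    kappa = np.nan_to_num(kappa, nan=-np.inf)
    interior = kappa[1:-1]
    if not np.any(interior > 0):
        return float(np.sqrt(alphas[0] * alphas[-1])), False
    idx = int(np.argmax(interior)) + 1
    return float(alphas[idx]), True


def lcurve_select(fields, masks, weights, alpha_grid, method="tikhonov",
                  *, voxel_size=(1, 1, 1), b0_direction=(0, 0, 1),
                  params: InversionParams | None = None):
    """Average L-curve corner over subjects.

    For each subject, solves the inversion across ``alpha_grid`` (log-spaced,
    at least 8 points), locates the maximum-curvature corner of the
    log-residual vs log-solution-norm curve, and returns the mean of the
    per-subject corner alphas.  A subject whose curve has no positive-curvature
    corner contributes the grid (geometric) midpoint, with a warning.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size < 8:
        raise ValueError("alpha_grid must have at least 8 points")
    if np.any(np.diff(alpha_grid) <= 0):
        raise ValueError("alpha_grid must be strictly increasing")
    solver = {"tikhonov": invert_tikhonov, "nltv": invert_nltv}[method]
    base = params or (ITERTIK_PRESET if method == "tikhonov" else NLTV_PRESET)
    corners = []
    for fld, msk, wgt in zip(fields, masks, weights):
        log_res, log_sol = [], []
        for a in alpha_grid:
            p = replace(base, alpha=float(a))
            chi = solver(fld, msk, wgt, p, voxel_size=voxel_size,
                         b0_direction=b0_direction)
            pred = forward_field(chi.values, voxel_size=voxel_size,
                                 b0_direction=b0_direction,
                                 pad_factor=p.pad_factor)
            w = msk.astype(float) if wgt is None else wgt * msk
            res = np.linalg.norm(w * (fld - pred))
            sol = np.linalg.norm(chi.values)
            log_res.append(np.log(max(res, 1e-300)))
            log_sol.append(np.log(max(sol, 1e-300)))
        corner, ok = _lcurve_corner(log_res, log_sol, alpha_grid)
        if not ok:
            warnings.warn("L-curve has no positive-curvature corner; "
                          "using grid midpoint", RuntimeWarning)
        corners.append(corner)
    return float(np.mean(corners))
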