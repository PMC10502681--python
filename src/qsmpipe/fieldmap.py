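"""Total-field, noise-map and R2* estimation from multi-echo gradient-echo data.

The complex signal at echo time TE in a voxel is modelled as

    S(TE) = A exp(-R2* TE) exp(i (phi0 + 2 pi f TE)),

where f (Hz) is the off-resonance frequency induced by the susceptibility
distribution.  ``fit_field_nonlinear`` estimates f per voxel by a
Gauss-Newton fit of the constant-magnitude complex model over all echoes and
propagates the residual variance into a per-voxel frequency standard
deviation (noise map).  ``fit_r2star`` estimates R2* by a log-linear
least-squares fit of the magnitudes.  ``laplacian_unwrap`` removes residual
phase wraps spectrally; the unwrapped phase equals the true phase up to an
additive harmonic component, which the downstream background-removal stage
absorbs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Reduced gyromagnetic ratio of the proton, MHz/T.  Multiplying by B0 (T)
#: gives Hz per ppm of field offset.
GAMMA_BAR_MHZ_PER_T = 42.577

__all__ = [
    "GAMMA_BAR_MHZ_PER_T",
    "EchoSeries",
    "FieldMap",
    "NoiseMap",
    "R2StarMap",
    "fit_field_nonlinear",
    "laplacian_unwrap",
    "fit_r2star",
    "to_ppm",
    "to_hz",
    "inverse_noise_weight",
]


# ---------------------------------------------------------------------------
# Types


@dataclass
class EchoSeries:
    """Complex multi-echo volume with acquisition metadata.

    ``data`` is (x, y, z, echo) complex; ``te_list`` in seconds, strictly
    increasing; ``b0_strength`` in Tesla; ``b0_direction`` a unit vector in
    image coordinates.
    """

    data: np.ndarray
    te_list: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    b0_strength: float = 3.0
    b0_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.te_list = np.asarray(self.te_list, dtype=float)
        self.b0_direction = np.asarray(self.b0_direction, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, echo)")
        if self.data.shape[-1] != self.te_list.size:
            raise ValueError("number of echoes does not match te_list")
        if self.te_list.size < 2:
            raise ValueError("need at least 2 echoes")
        if np.any(np.diff(self.te_list) <= 0) or np.any(self.te_list <= 0):
            raise ValueError("te_list must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return self.te_list.size

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


@dataclass
class FieldMap:
    """Scalar field on the image grid with an explicit units tag.

    ``units`` is one of ``"Hz"``, ``"ppm"``, ``"rad"``; every consumer checks
    the tag rather than assuming a convention.
    """

    values: np.ndarray
    units: str
    voxel_size: tuple = (1.0, 1.0, 1.0)
    b0_strength: float = 3.0
    b0_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    affine: np.ndarray | None = None

    _UNITS = {"Hz", "ppm", "rad"}

    def __post_init__(self):
        if self.units not in self._UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {self._UNITS}")

    def with_values(self, values, units=None) -> "FieldMap":
        return FieldMap(values, units or self.units, self.voxel_size,
                        self.b0_strength, self.b0_direction, self.affine)


@dataclass
class NoiseMap:
    """Per-voxel standard deviation of the field estimate (same units)."""

    values: np.ndarray
    units: str = "Hz"


@dataclass
class R2StarMap:
    """Effective transverse relaxation rate, 1/s; negative fits floored at 0."""

    values: np.ndarray
    n_floored: int = 0
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Nonlinear complex field fit


def fit_field_nonlinear(series: EchoSeries, n_iter: int = 12):
    """Per-voxel Gauss-Newton fit of S_j = A exp(i(phi0 + 2 pi f TE_j)).

    Initialised from the phase difference of the first two echoes (|f| capped
    at the aliasing limit 1/(2 dTE)); the residual variance feeds the inverse
    Fisher information of f to produce the noise map.  Zero-magnitude voxels
    get f = 0 with the noise set to the map maximum so downstream weighting
    suppresses them.

    Returns ``(FieldMap[Hz], NoiseMap[Hz])``.
    """
    if series.n_echoes < 3:
        raise ValueError("need >= 3 echoes to estimate the noise map")
    S = series.data
    te = series.te_list
    n = te.size
    dte = te[1] - te[0]

    mag0 = np.abs(S[..., 0])
    dead = mag0 <= 0
    # init: f from first-echo-difference phase, A and phi0 from echo 1
    f = np.angle(S[..., 1] * np.conj(S[..., 0])) / (2 * np.pi * dte)
    np.clip(f, -1.0 / (2 * dte), 1.0 / (2 * dte), out=f)
    A = mag0.copy()
    phi0 = np.angle(S[..., 0]) - 2 * np.pi * f * te[0]

    te_b = te.reshape((1,) * 3 + (n,))
    for _ in range(n_iter):
        theta = phi0[..., None] + 2 * np.pi * f[..., None] * te_b
        e = np.exp(1j * theta)
        r = A[..., None] * e - S
        ce_r = np.conj(e) * r
        g_a = ce_r.real.sum(axis=-1)
        im = ce_r.imag
        g_p = A * im.sum(axis=-1)
        g_f = A * (2 * np.pi * te_b * im).sum(axis=-1)
        # Normal matrix: A decouples; (phi0, f) block is A^2 [[n, s1],[s1, s2]]
        s1 = 2 * np.pi * te.sum()
        s2 = (2 * np.pi * te) @ (2 * np.pi * te)
        det = (n * s2 - s1 * s1)
        A2 = np.maximum(A * A, 1e-300)
        d_phi = -(s2 * g_p - s1 * g_f) / (A2 * det)
        d_f = -(n * g_f - s1 * g_p) / (A2 * det)
        A = A - g_a / n
        phi0 = phi0 + d_phi
        f = f + d_f

    theta = phi0[..., None] + 2 * np.pi * f[..., None] * te_b
    resid = A[..., None] * np.exp(1j * theta) - S
    # residual variance per real channel; 2n real observations, 3 parameters
    sigma2 = (np.abs(resid) ** 2).sum(axis=-1) / (2 * n - 3)
    sst = np.sum((te - te.mean()) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_sd = np.sqrt(sigma2) / (np.abs(A) * 2 * np.pi * np.sqrt(sst))
    f_sd[~np.isfinite(f_sd)] = 0.0

    f = np.where(dead, 0.0, f)
    finite_max = f_sd[~dead].max() if np.any(~dead) else 1.0
    f_sd = np.where(dead, max(finite_max, 1e-12), f_sd)
    fmap = FieldMap(f, "Hz", series.voxel_size, series.b0_strength,
                    series.b0_direction, series.affine)
    return fmap, NoiseMap(f_sd, "Hz")


# ---------------------------------------------------------------------------
# Laplacian unwrapping


def _spectral_k2(shape, voxel_size):
    """Continuous spectral symbol |2 pi k|^2 on the FFT grid."""
    k2 = np.zeros(shape)
    for a, (npts, dx) in enumerate(zip(shape, voxel_size)):
        f = np.fft.fftfreq(npts, d=dx)
        sl = [None] * len(shape)
        sl[a] = slice(None)
        k2 = k2 + ((2 * np.pi * f) ** 2)[tuple(sl)]
    return k2


def laplacian_unwrap(phase: FieldMap, pad: int = 8) -> FieldMap:
    """Spectral Laplacian phase unwrapping.

    Computes ``phi_u = L^-1[cos(phi) L(sin phi) - sin(phi) L(cos phi)]`` with
    an FFT Laplacian on a symmetrically padded grid (``pad`` voxels per side,
    mirror boundary) and the DC component of the inverse zeroed.  The output
    is wrap-free but only equals the true phase up to an additive harmonic
    component, which background-field removal later absorbs.
    """
    if phase.units != "rad":
        raise ValueError(f"laplacian_unwrap expects rad input, got {phase.units!r}")
    phi = np.asarray(phase.values, dtype=float)
    padded = np.pad(phi, pad, mode="symmetric") if pad else phi
    k2 = _spectral_k2(padded.shape, phase.voxel_size)
    inv_k2 = np.zeros_like(k2)
    nz = k2 > 0
    inv_k2[nz] = 1.0 / k2[nz]  # DC stays zero

    def lap(x):
        return np.fft.ifftn(-k2 * np.fft.fftn(x)).real

    s, c = np.sin(padded), np.cos(padded)
    rhs = c * lap(s) - s * lap(c)
    out = np.fft.ifftn(-inv_k2 * np.fft.fftn(rhs)).real
    if pad:
        out = out[(slice(pad, -pad),) * phi.ndim]
    return phase.with_values(out, "rad")


# ---------------------------------------------------------------------------
# R2* relaxometry


def fit_r2star(magnitudes: np.ndarray, te_list) -> R2StarMap:
    """Log-linear least-squares R2* fit: slope of ln|S| vs TE is -R2*.

    Voxels with any nonpositive magnitude are excluded (R2* = 0, counted in
    ``n_excluded``); negative rate estimates are floored at 0 and counted in
    ``n_floored``.  Invariant to global magnitude scaling.
    """
    te = np.asarray(te_list, dtype=float)
    mag = np.asarray(magnitudes, dtype=float)
    if mag.shape[-1] != te.size:
        raise ValueError("last axis of magnitudes must match te_list")
    ok = np.all(mag > 0, axis=-1)
    logm = np.zeros_like(mag)
    np.log(mag, out=logm, where=mag > 0)
    te_c = te - te.mean()
    sst = te_c @ te_c
    slope = (logm * te_c).sum(axis=-1) / sst
    r2s = -slope
    r2s[~ok] = 0.0
    n_floored = int(np.sum((r2s < 0) & ok))
    np.clip(r2s, 0.0, None, out=r2s)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.info("fit_r2star: %d voxels with nonpositive magnitude excluded",
                    n_excluded)
    return R2StarMap(r2s, n_floored=n_floored, n_excluded=n_excluded)


def inverse_noise_weight(noise_values, mask) -> np.ndarray:
    """Fidelity weight W = 1/noise, stabilised and mean-normalised in-mask.

    The noise map is floored at its 1st in-mask percentile before taking the
    reciprocal (so near-zero noise estimates cannot dominate), and W is then
    scaled to mean 1 inside the mask and zeroed outside.
    """
    noise = np.asarray(noise_values, dtype=float)
    m = np.asarray(getattr(mask, "values", mask), dtype=bool)
    inside = noise[m]
    if inside.size == 0:
        raise ValueError("empty mask")
    floor = np.percentile(inside, 1)
    if floor <= 0:
        floor = max(inside[inside > 0].min(initial=1e-12), 1e-12)
    w = 1.0 / np.maximum(noise, floor)
    w *= m
    w /= w[m].mean()
    return w


# ---------------------------------------------------------------------------
# Unit conversion


def to_ppm(fmap: FieldMap, b0_strength: float | None = None,
           te_spacing: float | None = None) -> FieldMap:
    """Convert a field map to ppm of B0.

    Hz input: ppm = Hz / (gamma_bar * B0).  rad input needs the echo spacing
    that produced the phase (rad per dTE): Hz = rad / (2 pi dTE) first.
    """
    b0 = b0_strength if b0_strength is not None else fmap.b0_strength
    hz_per_ppm = GAMMA_BAR_MHZ_PER_T * b0  # MHz/T * T * 1e6 * 1e-6
    if fmap.units == "ppm":
        return fmap
    if fmap.units == "Hz":
        return fmap.with_values(fmap.values / hz_per_ppm, "ppm")
    if fmap.units == "rad":
        if te_spacing is None:
            raise ValueError("rad -> ppm conversion needs te_spacing (s)")
        hz = fmap.values / (2 * np.pi * te_spacing)
        return fmap.with_values(hz / hz_per_ppm, "ppm")
    raise ValueError(f"unknown units tag {fmap.units!r}")


def to_hz(fmap: FieldMap, b0_strength: float | None = None) -> FieldMap:
    """Convert a ppm field map back to Hz (inverse of :func:`to_ppm`)."""
    b0 = b0_strength if b0_strength is not None else fmap.b0_strength
    if fmap.units == "Hz":
        return fmap
    if fmap.units == "ppm":
        return fmap.with_values(fmap.values * GAMMA_BAR_MHZ_PER_T * b0, "Hz")
    raise ValueError(f"cannot convert units {fmap.units!r} to Hz")
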