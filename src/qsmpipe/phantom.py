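"""Digital susceptibility phantoms and simulated cohorts.

Patient multi-echo MRI for this kind of study is rarely shareable, so every
downstream stage is exercised on synthetic data with the structure the
analysis assumes:

* ``make_phantom`` builds a 3D piecewise-constant susceptibility "brain": an
  ellipsoidal brain volume containing six bilateral subcortical ROIs
  (amygdala, caudate, globus pallidus, putamen, thalamus, hippocampus), each
  an ellipsoid with its own susceptibility (ppm), R2* (1/s) and proton
  density, plus optional high-susceptibility external bodies (air-like
  sinuses) that generate background fields, and an optional smooth harmonic
  contamination field inside the brain for testing weak-harmonic QSM.  The
  ground-truth field is computed with the same forward dipole operator the
  inversion stage uses.
* ``simulate_echoes`` turns the ground truth into a complex multi-echo
  gradient-echo series: mono-exponential R2* magnitude decay, field-induced
  phase evolution (wraps arise naturally), and circular complex Gaussian
  noise.
* ``simulate_cohort`` generates a table-level cohort (healthy controls and
  left/right temporal lobe epilepsy patients) with per-ROI means built from
  baseline + linear age trend + additive group effects + within-group noise,
  and clinical covariates (age of epilepsy onset, focal-to-bilateral
  tonic-clonic seizure status and log-normal frequency, cognitive scores
  linearly coupled to ROI values with group and interaction terms,
  hippocampal volume).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .fieldmap import GAMMA_BAR_MHZ_PER_T, EchoSeries
from .inversion import forward_field
from .masking import BinaryMask, ROILabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "ROI_NAMES",
    "RoiGeometry",
    "BackgroundSource",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "simulate_echoes",
    "harmonic_polynomial",
    "CovariateModel",
    "CohortSpec",
    "SubjectRecord",
    "simulate_cohort",
]

ROI_NAMES = ("amygdala", "caudate", "globus pallidus", "putamen",
             "thalamus", "hippocampus")

#: Echo times of the multi-echo gradient-echo protocol the pipeline targets:
#: TE1 = 12.9 ms, spacing 5.0 ms, five echoes (last at 32.8 ms).
DEFAULT_TE_LIST = tuple(0.0129 + 0.005 * i for i in range(5))


# ---------------------------------------------------------------------------
# Image-level phantom


@dataclass
class RoiGeometry:
    """Ellipsoidal ROI in fractional grid coordinates (resolution-agnostic)."""

    name: str
    hemisphere: str  # "left" | "right"
    label: int
    center: tuple  # fractions of grid extent per axis
    semi_axes: tuple  # fractions of grid extent per axis


@dataclass
class BackgroundSource:
    """External susceptibility body (e.g. air cavity) outside the brain."""

    center: tuple  # fractional grid coordinates
    semi_axes: tuple
    chi_ppm: float = 9.0


def _default_rois():
    # Mirror-symmetric layout: x is the left-right axis (left = low x).
    layout = {
        "amygdala": ((0.33, 0.80, 0.38), (0.045, 0.05, 0.055)),
        "caudate": ((0.40, 0.38, 0.60), (0.045, 0.06, 0.075)),
        "globus pallidus": ((0.43, 0.52, 0.48), (0.040, 0.05, 0.055)),
        "putamen": ((0.31, 0.50, 0.52), (0.050, 0.07, 0.075)),
        "thalamus": ((0.41, 0.66, 0.56), (0.055, 0.07, 0.070)),
        "hippocampus": ((0.32, 0.66, 0.34), (0.050, 0.08, 0.055)),
    }
    rois = []
    label = 1
    for name in ROI_NAMES:
        (cx, cy, cz), ax = layout[name]
        for hemi, x in (("left", cx), ("right", 1.0 - cx)):
            rois.append(RoiGeometry(name, hemi, label, (x, cy, cz), ax))
            label += 1
    return tuple(rois)


#: Plausible deep-grey susceptibilities (ppm): iron-rich nuclei positive
#: (globus pallidus highest), amygdala slightly diamagnetic, hippocampi
#: asymmetric in the pattern seen in operated left-TLE (left -0.050 /
#: right -0.035 ppm).  Configuration, not ground truth.
DEFAULT_CHI = {
    ("amygdala", "left"): -0.01, ("amygdala", "right"): -0.01,
    ("caudate", "left"): 0.05, ("caudate", "right"): 0.05,
    ("globus pallidus", "left"): 0.13, ("globus pallidus", "right"): 0.13,
    ("putamen", "left"): 0.043, ("putamen", "right"): 0.043,
    ("thalamus", "left"): 0.01, ("thalamus", "right"): 0.01,
    ("hippocampus", "left"): -0.050, ("hippocampus", "right"): -0.035,
}

#: Plausible deep-grey R2* (1/s) at 3 T, ordered like iron content.
DEFAULT_R2STAR = {
    ("amygdala", "left"): 18.0, ("amygdala", "right"): 18.0,
    ("caudate", "left"): 26.0, ("caudate", "right"): 26.0,
    ("globus pallidus", "left"): 45.0, ("globus pallidus", "right"): 45.0,
    ("putamen", "left"): 32.0, ("putamen", "right"): 32.0,
    ("thalamus", "left"): 21.0, ("thalamus", "right"): 21.0,
    ("hippocampus", "left"): 18.0, ("hippocampus", "right"): 18.0,
}


def _default_background_sources():
    return (
        BackgroundSource(center=(0.50, 0.86, 0.12), semi_axes=(0.10, 0.08, 0.07)),
        BackgroundSource(center=(0.26, 0.08, 0.82), semi_axes=(0.08, 0.06, 0.08)),
    )


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom acquisition.

    Defaults: 64 x 64 x 48 grid at 1 mm isotropic, 3 T with B0 along the
    scanner z axis, the five-echo protocol above, and the ROI/χ/R2* tables
    above.  ``oblique_rotation`` (Euler xyz, degrees) tilts the *image grid*
    relative to the scanner; the effective B0 direction in image coordinates
    is the inverse rotation applied to ``b0_direction``.
    ``harmonic_contamination_ppm`` generates a random low-order harmonic
    polynomial of that in-brain RMS amplitude (``contamination_true``),
    modelling a residual background field that survives background-field
    removal; it is carried separately from ``field_true`` (which always
    equals the forward convolution of ``chi_true``) and is added to the
    local field downstream.
    """

    grid_shape: tuple = (64, 64, 48)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    b0_strength: float = 3.0
    b0_direction: tuple = (0.0, 0.0, 1.0)
    te_list: tuple = DEFAULT_TE_LIST
    roi_geometry: tuple = field(default_factory=_default_rois)
    chi_per_roi: dict = field(default_factory=lambda: dict(DEFAULT_CHI))
    r2star_per_roi: dict = field(default_factory=lambda: dict(DEFAULT_R2STAR))
    m0_per_roi: dict = field(default_factory=dict)  # default: brain value
    background_sources: tuple = field(default_factory=_default_background_sources)
    noise_sd: float = 2.0
    oblique_rotation: tuple = (0.0, 0.0, 0.0)
    harmonic_contamination_ppm: float = 0.0
    brain_semi_axes: tuple = (0.42, 0.45, 0.40)
    chi_brain: float = 0.0
    r2star_brain: float = 15.0
    m0_brain: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        te = np.asarray(self.te_list)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be positive and strictly increasing")
        b = np.asarray(self.b0_direction, float)
        if not np.isclose(np.linalg.norm(b), 1.0, atol=1e-6):
            raise ValueError("b0_direction must be a unit vector")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = [r.label for r in self.roi_geometry]
        if len(labels) != len(set(labels)):
            raise ValueError("ROI labels must be unique")

    @property
    def effective_b0_direction(self) -> np.ndarray:
        """B0 direction in image coordinates, accounting for obliquity."""
        r = Rotation.from_euler("xyz", self.oblique_rotation, degrees=True)
        return r.inv().apply(np.asarray(self.b0_direction, float))


@dataclass
class GroundTruth:
    """True maps underlying one phantom acquisition (all on the spec grid)."""

    chi_true: np.ndarray  # ppm, brain tissue + external sources
    r2star_true: np.ndarray  # 1/s
    m0_true: np.ndarray
    labels: ROILabelMap
    mask_true: BinaryMask
    field_true: np.ndarray  # ppm, forward dipole convolution of chi_true
    contamination_true: np.ndarray | None = None  # ppm, harmonic, in-mask


def _ellipsoid_mask(shape, center_frac, semi_frac):
    idx = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for a in range(3):
        c = center_frac[a] * (shape[a] - 1)
        r = max(semi_frac[a] * shape[a], 1e-9)
        acc += ((idx[a] - c) / r) ** 2
    return acc <= 1.0


def harmonic_polynomial(shape, coeffs) -> np.ndarray:
    """Low-order harmonic polynomial on the grid.

    Basis (harmonic in the continuum): 1, x, y, z, xy, xz, yz,
    x^2 - y^2, y^2 - z^2, with coordinates scaled to [-1, 1].
    ``coeffs`` supplies up to 9 weights in that order.
    """
    ax = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    basis = [np.ones(shape), x, y, z, x * y, x * z, y * z,
             x**2 - y**2, y**2 - z**2]
    coeffs = np.asarray(coeffs, dtype=float)
    out = np.zeros(shape)
    for c, b in zip(coeffs, basis):
        out += c * b
    return out


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the ground-truth maps for one phantom acquisition.

    Overlapping ROI definitions raise a ``ValueError`` naming the pair.  The
    true field is the forward dipole convolution of the full susceptibility
    distribution (tissue + external sources) using the image-frame B0
    direction, plus the optional harmonic contamination inside the brain.
    """
    shape = tuple(spec.grid_shape)
    brain = _ellipsoid_mask(shape, (0.5, 0.5, 0.5), spec.brain_semi_axes)

    chi = np.where(brain, spec.chi_brain, 0.0)
    r2s = np.where(brain, spec.r2star_brain, 0.0)
    m0 = np.where(brain, spec.m0_brain, 0.0)
    labels = np.zeros(shape, dtype=np.int32)
    table = {}
    claimed: dict[int, RoiGeometry] = {}
    for roi in spec.roi_geometry:
        m = _ellipsoid_mask(shape, roi.center, roi.semi_axes)
        clash = m & (labels > 0)
        if clash.any():
            other = claimed[int(labels[clash][0])]
            raise ValueError(
                f"overlapping ROI definitions: {roi.name} ({roi.hemisphere}) "
                f"and {other.name} ({other.hemisphere})")
        if not (m & brain).all() and not m.any():
            logger.warning("ROI %s (%s) voxelises to nothing", roi.name,
                           roi.hemisphere)
        labels[m] = roi.label
        claimed[roi.label] = roi
        table[roi.label] = (roi.name, roi.hemisphere)
        key = (roi.name, roi.hemisphere)
        chi[m] = spec.chi_per_roi.get(key, spec.chi_brain)
        r2s[m] = spec.r2star_per_roi.get(key, spec.r2star_brain)
        m0[m] = spec.m0_per_roi.get(key, spec.m0_brain)

    for src in spec.background_sources:
        m = _ellipsoid_mask(shape, src.center, src.semi_axes)
        if (m & brain).any():
            raise ValueError("background source overlaps the brain volume")
        chi[m] = src.chi_ppm

    b_eff = spec.effective_b0_direction
    field = forward_field(chi, voxel_size=spec.voxel_size,
                          b0_direction=b_eff, pad_factor=2)

    contamination = None
    if spec.harmonic_contamination_ppm > 0:
        rng = np.random.default_rng(spec.seed + 104729)
        coeffs = np.concatenate([[0.0], rng.standard_normal(8)])
        poly = harmonic_polynomial(shape, coeffs)
        in_brain = poly[brain]
        poly = poly - in_brain.mean()
        rms = np.sqrt(np.mean(poly[brain] ** 2)) or 1.0
        contamination = poly * (spec.harmonic_contamination_ppm / rms)

    return GroundTruth(chi, r2s, m0, ROILabelMap(labels, table),
                       BinaryMask(brain, spec.voxel_size), field,
                       contamination)


def simulate_echoes(truth: GroundTruth, spec: PhantomSpec) -> EchoSeries:
    """Simulate the complex multi-echo series from the ground truth.

    Per voxel: ``S(TE) = m0 exp(-R2* TE) exp(i 2 pi f TE) + noise`` with
    ``f [Hz] = gamma_bar * B0 * field[ppm]`` and circular complex Gaussian
    noise of standard deviation ``noise_sd`` per channel.  Phase wraps arise
    naturally from the complex representation.
    """
    if truth.chi_true.shape != tuple(spec.grid_shape):
        raise ValueError("ground-truth grid does not match spec")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    te = np.asarray(spec.te_list, dtype=float)
    f_hz = GAMMA_BAR_MHZ_PER_T * spec.b0_strength * truth.field_true
    te_b = te.reshape((1,) * 3 + (-1,))
    signal = (truth.m0_true[..., None]
              * np.exp(-truth.r2star_true[..., None] * te_b)
              * np.exp(2j * np.pi * f_hz[..., None] * te_b))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(scale=spec.noise_sd, size=signal.shape + (2,))
        signal = signal + noise[..., 0] + 1j * noise[..., 1]
    return EchoSeries(signal, te, spec.voxel_size, spec.b0_strength,
                      spec.effective_b0_direction)


# ---------------------------------------------------------------------------
# Table-level cohort simulation

GROUPS = ("HC", "LTLE", "RTLE")


@dataclass
class CovariateModel:
    """Parameters of the clinical covariate generator.

    Ages are Uniform(age_range); onset = age - Uniform(*onset_lag_years)
    clipped at >= 1 y.  FBTCS status is drawn from ``fbtcs_probs`` (none /
    historic / recent, "recent" = within the last 12 months); monthly
    frequency for the recent stratum is log-normal.  Each cognitive test is
    ``a * roi_value + b * group01 + c * group01 * roi_value + noise`` with
    group01 coding LTLE = 0, RTLE = 1 (patients only).  Hippocampal volume is
    Gaussian with an optional linear coupling to ipsilateral hippocampal R2*.
    """

    onset_lag_years: tuple = (5.0, 40.0)
    fbtcs_probs: tuple = (0.3, 0.3, 0.4)  # none, historic, recent
    fbtcs_log_mean: float = 0.5  # log of events/month
    fbtcs_log_sd: float = 0.9
    cognitive_tests: dict = field(default_factory=lambda: {
        # name: (roi, hemisphere, measure, a, b, c, noise_sd)
        "arithmetic": ("caudate", "left", "chi_ppm", 120.0, 2.0, -40.0, 1.5),
        "letter_fluency": ("hippocampus", "left", "r2star_per_s", 1.2, -4.0, 0.8, 2.0),
    })
    volume_mean_mm3: float = 3000.0
    volume_sd_mm3: float = 300.0
    volume_r2star_coef: float = 0.0  # mm^3 per (1/s), ipsilateral hippocampus


@dataclass
class CohortSpec:
    """Structure of a simulated cohort.

    Default group sizes follow the clinical cohort the pipeline targets:
    27 healthy controls, 19 left-TLE, 17 right-TLE.  ``group_effects`` maps
    ``(group, roi, hemisphere, measure)`` to an additive offset; the default
    carries the headline left-hippocampus susceptibility deficit in LTLE
    (Cohen's d 0.837 at the hippocampal within-group SD).  ``age_slopes`` and
    ``within_group_sd`` map ``(roi, measure)`` to a slope per year and a
    within-group SD.
    """

    n_per_group: dict = field(default_factory=lambda: {"HC": 27, "LTLE": 19, "RTLE": 17})
    age_range: tuple = (20.0, 60.0)
    group_effects: dict = field(default_factory=lambda: {
        ("LTLE", "hippocampus", "left", "chi_ppm"): -0.837 * 0.027,
    })
    age_slopes: dict = field(default_factory=dict)
    within_group_sd: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"need >= 2 subjects per group (got {n} for {g})")
        for k, v in self.within_group_sd.items():
            if v <= 0:
                raise ValueError(f"within_group_sd must be > 0 ({k})")

    def sd(self, roi, measure):
        if (roi, measure) in self.within_group_sd:
            return self.within_group_sd[(roi, measure)]
        return 0.027 if measure == "chi_ppm" else 2.5

    def slope(self, roi, measure):
        if (roi, measure) in self.age_slopes:
            return self.age_slopes[(roi, measure)]
        # plausible ageing trends: slow iron accumulation
        return 5e-4 if measure == "chi_ppm" else 0.08

    def base(self, roi, hemisphere, measure):
        if (roi, hemisphere, measure) in self.baseline:
            return self.baseline[(roi, hemisphere, measure)]
        table = DEFAULT_CHI if measure == "chi_ppm" else DEFAULT_R2STAR
        return table[(roi, hemisphere)]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    age_of_onset: float | None = None
    fbtcs_status: str = "none"
    fbtcs_frequency: float | None = None
    cognitive_scores: dict = field(default_factory=dict)
    hippocampal_volume: float = 0.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.age_of_onset is not None and self.age_of_onset > self.age:
            raise ValueError("age_of_onset must be <= age")
        if (self.fbtcs_frequency is not None) != (self.fbtcs_status == "recent"):
            raise ValueError("fbtcs_frequency set iff status is 'recent'")


def simulate_cohort(cspec: CohortSpec):
    """Generate subject records and a per-subject ROI table.

    ROI means: baseline + slope * (age - 40) + group effect + Normal(0, sd).
    Centring the age trend at 40 y keeps the baselines interpretable as the
    mid-cohort values.  Returns ``(records, table)`` where ``table`` is a tidy
    DataFrame with one row per (subject, roi, hemisphere, measure).
    """
    rng = np.random.default_rng(cspec.seed)
    cm = cspec.covariate_model
    zero_sd = [k for k, v in cspec.within_group_sd.items() if v == 0]
    if zero_sd:  # pragma: no cover - guarded in __post_init__
        logger.warning("zero within-group variance requested: %s", zero_sd)

    records = []
    rows = []
    measures = ("chi_ppm", "r2star_per_s")
    for group in GROUPS:
        n = cspec.n_per_group.get(group, 0)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            age = rng.uniform(*cspec.age_range)
            sex = "F" if rng.random() < 0.5 else "M"
            onset = None
            status, freq = "none", None
            if group != "HC":
                onset = max(1.0, age - rng.uniform(*cm.onset_lag_years))
                status = rng.choice(["none", "historic", "recent"], p=cm.fbtcs_probs)
                if status == "recent":
                    freq = float(np.exp(rng.normal(cm.fbtcs_log_mean, cm.fbtcs_log_sd)))

            values = {}
            for roi in ROI_NAMES:
                for hemi in ("left", "right"):
                    for meas in measures:
                        v = (cspec.base(roi, hemi, meas)
                             + cspec.slope(roi, meas) * (age - 40.0)
                             + cspec.group_effects.get((group, roi, hemi, meas), 0.0)
                             + rng.normal(0.0, cspec.sd(roi, meas)))
                        values[(roi, hemi, meas)] = v
                        rows.append({"subject_id": sid, "roi": roi,
                                     "hemisphere": hemi, "measure": meas,
                                     "mean": v, "std": 0.0, "voxel_count": 150,
                                     "method": "simulated"})

            ipsi = {"LTLE": "left", "RTLE": "right"}.get(group, "left")
            volume = rng.normal(cm.volume_mean_mm3, cm.volume_sd_mm3)
            volume += cm.volume_r2star_coef * values[("hippocampus", ipsi, "r2star_per_s")]
            scores = {}
            if group != "HC":
                g01 = 0.0 if group == "LTLE" else 1.0
                for name, (roi, hemi, meas, a, b, c, nsd) in cm.cognitive_tests.items():
                    rv = values[(roi, hemi, meas)]
                    scores[name] = a * rv + b * g01 + c * g01 * rv + rng.normal(0, nsd)
            records.append(SubjectRecord(sid, group, age, sex, onset, status,
                                         freq, scores, float(volume)))
    table = pd.DataFrame(rows)
    return records, table


def records_to_frame(records) -> pd.DataFrame:
    """Flatten subject records into a tidy covariate DataFrame."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "age": r.age,
               "sex": r.sex, "age_of_onset": r.age_of_onset,
               "fbtcs_status": r.fbtcs_status,
               "fbtcs_frequency": r.fbtcs_frequency,
               "hippocampal_volume": r.hippocampal_volume}
        for name, val in r.cognitive_scores.items():
            row[f"score_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
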