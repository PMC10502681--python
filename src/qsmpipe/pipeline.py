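"""End-to-end pipeline orchestration.

``run_pipeline`` executes the reconstruction chain for one (simulated)
acquisition in the canonical order -- nonlinear field fit, Laplacian
unwrapping, Otsu masking, noise-based erosion sparing ROIs, optional
rotation to scanner axes, 3-voxel erosion, PDF background removal, and the
three dipole inversions -- and writes every artefact with a JSON manifest.
``run_method_comparison`` reconstructs a small simulated cohort with all
three methods and runs the ROI-standard-deviation quality comparison.
``run_cohort_stats`` generates a table-level cohort and runs the full group
and clinical statistics battery.

ROI statistics are read on the noise-eroded (pre-BFR-erosion) mask
intersected with the labels; the 3-voxel-eroded mask is used for PDF and
inversion only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import RotationSpec, pdf_remove, rotate_to_scanner
from .fieldmap import (fit_field_nonlinear, fit_r2star, inverse_noise_weight,
                       laplacian_unwrap, to_ppm)
from .inversion import (InversionParams, invert_nltv, invert_tikhonov,
                        invert_whqsm)
from .masking import BinaryMask, erode, noise_erode, otsu_mask
from .phantom import CohortSpec, PhantomSpec, make_phantom, records_to_frame, simulate_cohort, simulate_echoes
from .roistats import (age_correct, ancova_slopes, cognition_regress,
                       demographics_compare, fbtcs_analyses, fit_age_model,
                       group_anova, normality_check, onset_corr,
                       paired_lr_test, quality_compare, roi_summary,
                       tukey_kramer, volume_corr)
from . import io as qio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_method_comparison",
           "run_cohort_stats", "reconstruct_subject"]

METHODS = ("itertik", "nltv", "whqsm")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable).

    Unknown keys in the YAML are rejected before any stage runs.  Inversion
    parameter blocks map method name to :class:`InversionParams` keyword
    arguments; defaults here are sized for desk-scale phantoms rather than
    full-resolution clinical volumes.
    """

    seed: int = 0
    outdir: str = "qsm_out"
    phantom: dict = field(default_factory=dict)
    methods: tuple = METHODS
    erode_voxels: int = 3
    pdf_tol: float = 1e-4
    pdf_max_iter: int = 200
    inversion: dict = field(default_factory=lambda: {
        "itertik": {"alpha": 0.05},
        "nltv": {"alpha": 3e-4, "tol": 0.1, "max_iter": 100},
        "whqsm": {"alpha": 3e-4, "beta": 150.0, "tol": 0.1, "max_iter": 100},
    })
    n_subjects: int = 10
    stats_alpha: float = 0.05
    normality_alpha: float = 0.01
    fdr_q: float = 0.05
    cohort: dict = field(default_factory=dict)

    def __post_init__(self):
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
        if self.erode_voxels < 0:
            raise ValueError("erode_voxels must be >= 0")
        if self.pdf_tol <= 0 or self.pdf_max_iter < 1:
            raise ValueError("invalid PDF solver settings")
        if not (0 < self.stats_alpha < 1 and 0 < self.normality_alpha < 1
                and 0 < self.fdr_q < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        # materialise and validate all inversion parameter blocks up front
        self._params = {m: InversionParams(**self.inversion.get(m, {}))
                        for m in self.methods}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = qio.load_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def params_for(self, method: str) -> InversionParams:
        return self._params[method]

    def config_hash(self) -> str:
        public = {k: v for k, v in dataclasses.asdict(self).items()}
        blob = yaml.safe_dump(public, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _phantom_spec(config: PipelineConfig, seed_offset: int = 0) -> PhantomSpec:
    kw = dict(config.phantom)
    kw.setdefault("seed", config.seed)
    kw["seed"] = kw["seed"] + seed_offset
    return PhantomSpec(**kw)


def reconstruct_subject(spec: PhantomSpec, config: PipelineConfig):
    """Run the reconstruction chain for one phantom acquisition.

    Returns a dict with the ground truth, intermediate maps, masks, and one
    SusceptibilityMap per configured method (plus the weak-harmonic residual
    field under ``"phi_h"``).
    """
    truth = make_phantom(spec)
    series = simulate_echoes(truth, spec)

    fmap_hz, noise = fit_field_nonlinear(series)
    r2star = fit_r2star(series.magnitude, series.te_list)

    # residual wrap removal on the phase accumulated over one echo spacing
    dte = series.te_list[1] - series.te_list[0]
    phase = fmap_hz.with_values(
        np.angle(np.exp(2j * np.pi * fmap_hz.values * dte)), "rad")
    unwrapped = laplacian_unwrap(phase)
    total_ppm = to_ppm(unwrapped, series.b0_strength, te_spacing=dte)

    mask0 = otsu_mask(series.magnitude[..., -1])
    # fill interior signal-dropout holes (high-R2* nuclei can fall below the
    # last-echo Otsu threshold) so the brain volume stays simply connected
    from scipy import ndimage as _ndi

    mask0 = BinaryMask(_ndi.binary_fill_holes(mask0.values), spec.voxel_size)
    mask_roi = noise_erode(mask0, noise.values, truth.labels)
    labels = truth.labels

    oblique = np.any(np.asarray(spec.oblique_rotation) != 0)
    if oblique:
        rot = RotationSpec.from_euler(spec.oblique_rotation)
        total_ppm, valid = rotate_to_scanner(total_ppm, rot)
        from .background import rotate_labels

        mask_roi = BinaryMask(
            rotate_labels(mask_roi.values.astype(np.int8), rot).astype(bool)
            & valid.values, spec.voxel_size)
        labels = type(labels)(rotate_labels(labels.values, rot), dict(labels.table))
        noise_vals = np.where(mask_roi.values, 1.0, noise.values.max())
    else:
        noise_vals = noise.values

    mask_inv = erode(mask_roi, config.erode_voxels)
    weight = inverse_noise_weight(noise_vals, mask_inv)

    local, background = pdf_remove(total_ppm, mask_inv, weight,
                                   tol=config.pdf_tol,
                                   max_iter=config.pdf_max_iter)
    if truth.contamination_true is not None and not oblique:
        # emulated residual background field that survived BFR
        local = local.with_values(
            local.values + truth.contamination_true * mask_inv.values)

    out = {"truth": truth, "series": series, "field_hz": fmap_hz,
           "noise": noise, "r2star": r2star, "total_ppm": total_ppm,
           "mask_roi": mask_roi, "mask_inv": mask_inv, "labels": labels,
           "weight": weight, "local": local, "background": background,
           "chi": {}}
    b_dir = total_ppm.b0_direction
    for method in config.methods:
        params = config.params_for(method)
        if method == "itertik":
            chi = invert_tikhonov(local.values, mask_inv.values, weight, params,
                                  voxel_size=spec.voxel_size, b0_direction=b_dir)
        elif method == "nltv":
            chi = invert_nltv(local.values, mask_inv.values, weight, params,
                              voxel_size=spec.voxel_size, b0_direction=b_dir)
        else:
            chi, phi_h = invert_whqsm(local.values, mask_inv.values, weight,
                                      params, voxel_size=spec.voxel_size,
                                      b0_direction=b_dir)
            out["phi_h"] = phi_h
        out["chi"][method] = chi
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate one acquisition, reconstruct it, and write all artefacts.

    Returns the manifest (also written to ``manifest.json``): every artefact
    path with the parameters that produced it and the package version.
    Deterministic given the same seed and configuration.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = _phantom_spec(config)
    t0 = time.time()
    res = reconstruct_subject(spec, config)
    artefacts = {}

    vs = spec.voxel_size
    artefacts["field_hz"] = str(qio.save_map(
        outdir / "field_total.nii.gz", res["field_hz"].values, units="Hz",
        voxel_size=vs))
    artefacts["noise_hz"] = str(qio.save_map(
        outdir / "noise.nii.gz", res["noise"].values, units="Hz", voxel_size=vs))
    artefacts["r2star"] = str(qio.save_map(
        outdir / "r2star.nii.gz", res["r2star"].values, units="1/s",
        voxel_size=vs,
        sidecar={"n_floored": res["r2star"].n_floored,
                 "n_excluded": res["r2star"].n_excluded}))
    artefacts["local_ppm"] = str(qio.save_map(
        outdir / "field_local.nii.gz", res["local"].values, units="ppm",
        voxel_size=vs))
    artefacts["background_ppm"] = str(qio.save_map(
        outdir / "field_background.nii.gz", res["background"].values,
        units="ppm", voxel_size=vs))
    artefacts["mask"] = str(qio.save_map(
        outdir / "mask.nii.gz", res["mask_inv"].values.astype(np.float64),
        voxel_size=vs))
    artefacts["labels"] = str(qio.save_labels(outdir / "labels.nii.gz",
                                              res["labels"], vs))
    mask_counts = {"otsu+noise_erode": int(res["mask_roi"].n_voxels),
                   "eroded": int(res["mask_inv"].n_voxels)}
    tables = []
    for method, chi in res["chi"].items():
        artefacts[f"chi_{method}"] = str(qio.save_map(
            outdir / f"chi_{method}.nii.gz", chi.values, units="ppm",
            voxel_size=vs,
            sidecar={"method": chi.method, "converged": chi.converged,
                     "n_iter": chi.n_iter,
                     "params": dataclasses.asdict(chi.params)}))
        t = roi_summary(chi.values, res["labels"], res["mask_roi"],
                        subject_id="subject000", measure="chi_ppm",
                        method=method)
        tables.append(t)
    if "phi_h" in res:
        artefacts["phi_h"] = str(qio.save_map(
            outdir / "phi_h.nii.gz", res["phi_h"].values, units="ppm",
            voxel_size=vs))
    roi_table = pd.concat(tables, ignore_index=True)
    roi_path = outdir / "roi_table.csv"
    roi_table.to_csv(roi_path, index=False)
    artefacts["roi_table"] = str(roi_path)

    manifest = {"version": __version__, "config_hash": config.config_hash(),
                "seed": config.seed, "elapsed_s": round(time.time() - t0, 2),
                "mask_voxel_counts": mask_counts, "artefacts": artefacts}
    qio.save_json(outdir / "manifest.json", manifest)
    return manifest


def run_method_comparison(config: PipelineConfig):
    """Reconstruct ``config.n_subjects`` phantoms with all methods and
    compare per-ROI standard deviations across methods.

    Returns ``(report, roi_table)``; also writes ``method_comparison.csv``
    (per subject x ROI x method std values, the per-ROI figure data) and
    ``quality_report.csv`` under ``config.outdir``.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects for the method comparison")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_method: dict[str, list] = {m: [] for m in config.methods}
    for i in range(config.n_subjects):
        spec = _phantom_spec(config, seed_offset=1000 + i)
        res = reconstruct_subject(spec, config)
        for method, chi in res["chi"].items():
            per_method[method].append(roi_summary(
                chi.values, res["labels"], res["mask_roi"],
                subject_id=f"subject{i:03d}", measure="chi_ppm", method=method))
        logger.info("method comparison: subject %d/%d done", i + 1,
                    config.n_subjects)
    tables = {m: pd.concat(ts, ignore_index=True) for m, ts in per_method.items()}
    report = quality_compare(tables)
    all_rows = pd.concat(tables.values(), ignore_index=True)
    all_rows.to_csv(outdir / "method_comparison.csv", index=False)
    report.to_csv(outdir / "quality_report.csv", index=False)
    return report, all_rows


def run_cohort_stats(config: PipelineConfig):
    """Simulate a table-level cohort and run the full statistics battery.

    Age correction is fitted on controls and applied to all groups before the
    group comparisons.  Returns ``(report, roi_table, covariates)`` and
    writes them as CSV under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ckw = dict(config.cohort)
    ckw.setdefault("seed", config.seed)
    cspec = CohortSpec(**ckw)
    records, table = simulate_cohort(cspec)
    cov = records_to_frame(records)
    ages = dict(zip(cov["subject_id"], cov["age"]))
    groups = dict(zip(cov["subject_id"], cov["group"]))

    hc_ids = [s for s, g in groups.items() if g == "HC"]
    model = fit_age_model(table[table["subject_id"].isin(hc_ids)], ages)
    corrected = age_correct(table, model, ages)

    reports = [demographics_compare(records)]
    # normality of each (roi, hemi, measure, group) cell
    norm_rows = []
    for (roi, hemi, meas), sub in corrected.groupby(["roi", "hemisphere", "measure"]):
        g = sub["subject_id"].map(groups)
        for grp_name in ("HC", "LTLE", "RTLE"):
            vals = sub.loc[g == grp_name, "mean"]
            if len(vals) >= 4:
                r = normality_check(vals, label=f"{roi}/{hemi}/{meas}/{grp_name}")
                r[["roi", "hemisphere", "measure"]] = roi, hemi, meas
                norm_rows.append(r)
    reports.append(pd.concat(norm_rows, ignore_index=True))
    reports.append(group_anova(corrected, groups))
    reports.append(tukey_kramer(corrected, groups))
    reports.append(paired_lr_test(corrected, groups))
    reports.append(ancova_slopes(table, ages, groups))
    reports.append(onset_corr(corrected, records))
    reports.append(fbtcs_analyses(corrected, records))
    reports.append(cognition_regress(corrected, records, q=config.fdr_q))
    reports.append(volume_corr(corrected, records))
    report = pd.concat(reports, ignore_index=True)

    table.to_csv(outdir / "cohort_roi_table.csv", index=False)
    cov.to_csv(outdir / "cohort_covariates.csv", index=False)
    report.to_csv(outdir / "stat_report.csv", index=False)
    return report, table, cov
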