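# Methods

This note documents the models, algorithms and numerical choices behind
`qsmpipe`, and what the synthetic data can and cannot establish.

## Physical model

Tissue magnetic susceptibility χ (ppm) perturbs the main field B0. In the
Lorentz-sphere convention the measured field offset, expressed in ppm of B0,
is the convolution of χ with the unit dipole kernel, diagonal in k-space:

    ΔB(k) = D(k) χ(k),    D(k) = 1/3 − (k·b̂)² / |k|²,   D(0) = 0

with b̂ the unit B0 direction. D vanishes on the magic-angle cone
(54.7°), so recovering χ from ΔB is ill-posed and must be regularised.
Working in ppm absorbs the explicit B0 factor; `fieldmap.to_ppm` converts
Hz ↔ ppm with γ̄ = 42.577 MHz/T. The convolution is evaluated by FFT on a
zero-padded grid (factor 2 per axis by default) to suppress periodic
wrap-around; `D(0) = 0` makes every reconstruction mean-referenced over the
FFT volume. No CSF or regional referencing is applied, so absolute χ values
are comparable only within a pipeline, which is how the group statistics
use them.

The complex gradient-echo signal in a voxel is modelled as

    S(TE) = m0 · exp(−R2* TE) · exp(i(φ0 + 2π f TE)) + ε,

with circular complex Gaussian noise ε and f (Hz) the field-induced
off-resonance. The default echo train is TE1 = 12.9 ms, ΔTE = 5.0 ms, five
echoes (last echo 32.8 ms) at 3 T.

## Estimation chain

1. **Field and noise maps** (`fit_field_nonlinear`). Per-voxel Gauss–Newton
   fit of the constant-magnitude complex model A·exp(i(φ0 + 2π f TE_j))
   over all echoes, initialised from the first-echo-pair phase difference
   with |f| capped at the aliasing limit 1/(2ΔTE) = 100 Hz. Because TE1 is
   not an integer multiple of ΔTE, f and f + k/ΔTE are exactly equivalent
   up to a φ0 shift, so the fit returns the wrapped frequency; residual
   wraps are removed downstream. The noise map is the CRLB of f:
   σ_f = σ_ch / (A · 2π · √Σ(TE−T̄E)²), with the per-channel residual
   variance estimated on 2n−3 degrees of freedom. The constant-magnitude
   model ignores R2* decay; this biases the *noise* map upward in
   fast-decaying tissue (by design — such voxels deserve down-weighting)
   but not the frequency estimate itself, since the residual is minimised
   when model and data phases align echo-by-echo.
2. **R2\*** (`fit_r2star`). Ordinary least squares of ln|S| on TE; the
   negative slope is R2*. Voxels with nonpositive magnitudes are excluded
   and counted; negative rates are floored at zero and counted. At
   first-echo SNR 50 with the default echo train the Monte-Carlo bias is
   below 1%.
3. **Phase unwrapping** (`laplacian_unwrap`). The fitted field is reduced
   to its wrapped per-ΔTE phase and unwrapped spectrally via
   φ_u = L⁻¹[cos φ · L sin φ − sin φ · L cos φ], with the FFT Laplacian on
   a grid mirror-padded by 8 voxels and the DC term of the inverse zeroed.
   The output equals the true phase up to an additive harmonic component,
   which background-field removal absorbs.
4. **Masking** (`masking`). Otsu threshold (256 bins) on the *last*-echo
   magnitude — a conservative choice that drops dropout regions — keeping
   the largest 6-connected component; the pipeline then fills interior
   holes (high-R2* nuclei can fall below the last-echo threshold).
   Noise-based erosion removes voxels whose inverse noise falls below the
   in-mask mean, sparing ROI-labelled voxels; the noise map is
   Gaussian-smoothed (2 voxels) first because the per-voxel residual
   variance from five echoes has ~40% sampling CV, and thresholding the
   raw map would punch random holes in homogeneous tissue rather than
   remove coherently bad regions. Finally a 3-voxel 6-connected erosion
   produces the background-removal/inversion mask; ROI statistics are read
   on the pre-erosion (noise-eroded) mask intersected with the labels.
5. **Oblique correction** (`rotate_to_scanner`). For oblique acquisitions
   the total field is resampled onto scanner axes by trilinear
   interpolation (labels and masks nearest-neighbour), before background
   removal, so the dipole kernel can assume B0 along the grid z axis.
   Out-of-domain voxels are flagged and removed from the mask.
6. **Background-field removal** (`pdf_remove`). Projection onto dipole
   fields: weighted least-squares fit of external susceptibility sources,
   supported on the complement of the mask dilated by a 2-voxel guard
   band within the padded FOV, solved by conjugate gradient on the normal
   equations (relative residual 1e-4 or 200 iterations). The guard band
   keeps near-boundary source modes from absorbing genuine tissue field;
   two voxels gave materially better internal-field preservation than one
   on phantoms with no loss of background removal.

## The three inversions

All solvers share the fidelity weight W = reciprocal noise map, floored at
its 1st in-mask percentile and normalised to mean 1 in-mask, and all return
χ that is identically zero outside the mask.

* **Iterative Tikhonov**: min ‖W M (ΔB − χ∗d)‖₂² + α‖χ‖₂², solved by CG on
  the normal equations. With W = M = 1 and no padding this equals the
  closed-form k-space filter D/(D²+α), which the tests verify to 1e-5.
* **Nonlinear TV**: min ‖W(e^{i χ∗d} − e^{i ΔB})‖₂² + α‖∇χ‖₁ — the complex
  exponential fidelity is the correct likelihood under complex Gaussian
  noise, and anisotropic TV promotes piecewise-constant maps. Solved by
  ADMM with splits z1 = ∇χ (soft-thresholding) and z2 = χ∗d (two per-voxel
  Newton steps per outer iteration). The χ subproblem is diagonal in
  k-space. Convergence: stop when the percent relative χ update falls
  below `tol` (default 0.1, i.e. 0.1%).
* **Weak-harmonic QSM**: the nonlinear-TV objective plus a jointly
  estimated residual field φ_h inside the fidelity, penalised by
  (β/2)‖M∇²φ_h‖₂². A third split z3 = ∇²φ_h confines the penalty to the
  mask exactly as written: outside the mask φ_h is free to continue
  smoothly, so an in-mask harmonic contaminant is absorbed at zero cost.
  φ_h is updated *before* χ each iteration, and χ is projected onto the
  mask support after each update; both choices resolve the degeneracy
  between external χ sources and φ_h (without them roughly 4% of an
  injected ramp leaked into χ; with them the recovered φ_h correlates
  > 0.99 with the injected field and ROI means shift < 0.005 ppm).

ADMM penalty weights default to 100·α for the gradient split and 1.0 for
the fidelity and Laplacian splits, exposed in `InversionParams`. The
regularisation presets used on clinical data ship as named constants
(Tikhonov α = 0.0652; TV and weak-harmonic α = 1.956e-5, β = 150);
phantom-scale runs in the test-suite use α values appropriate to the
phantom's field magnitudes. `lcurve_select` picks α as the mean over
subjects of the maximum-curvature corner of the log-residual vs
log-solution-norm curve (central finite differences in log α); a curve
with no positive-curvature interior point contributes the grid's geometric
midpoint with a warning.

## Synthetic data

**Image level.** The phantom is an ellipsoidal "brain" (χ = 0, R2* = 15/s,
m0 = 100) containing six bilateral ellipsoidal ROIs — amygdala, caudate,
globus pallidus, putamen, thalamus, hippocampus — on a 64×64×48 grid at
1 mm isotropic by default; all operators are resolution-agnostic and the
geometry is specified in grid fractions. Default susceptibilities follow
the iron-ordering of deep grey matter (globus pallidus 0.13, putamen
0.043, caudate 0.05, thalamus 0.01, amygdala −0.01 ppm) with asymmetric
hippocampi (left −0.050, right −0.035 ppm, the operated-left-TLE pattern);
R2* likewise (globus pallidus 45/s down to 18/s). These are configuration,
not ground truth: no test asserts them except through self-consistency.
Two air-like ellipsoids (χ = 9 ppm) outside the brain generate background
fields; complex noise is white circular Gaussian (default sd 2, i.e.
first-echo SNR 50); oblique acquisition tilts the image grid by Euler
angles. The true field is always the forward dipole convolution of the
full χ map. Optional harmonic contamination — a random low-order harmonic
polynomial (basis 1, x, y, z, xy, xz, yz, x²−y², y²−z²) of specified
in-brain RMS — is carried separately and added to the *local* field after
background removal: it models residual background fields that survive BFR,
which is precisely what the weak-harmonic term targets (an in-mask
harmonic added to the acquired field would simply be removed by PDF).
For the method-quality comparison the default residual level is 0.01 ppm
RMS: visible against deep-grey contrasts (~0.01–0.13 ppm) without
dominating them.

**Table level.** `simulate_cohort` draws 27 healthy controls, 19 left-TLE
and 17 right-TLE subjects. Per (ROI, hemisphere, measure):
baseline + θ·(age − 40) + group effect + N(0, σ_within), with ages
Uniform(20, 60), default slopes 5e-4 ppm/yr (χ) and 0.08 s⁻¹/yr (R2*), and
default within-group SDs 0.027 ppm and 2.5 s⁻¹. The default group-effect
table carries one effect: a left-hippocampus χ deficit in left-TLE of
0.837 pooled-SD units (Cohen's d). Covariates: onset = age −
Uniform(5, 40) clipped at ≥ 1 y; FBTCS status none/historic/recent with
probabilities 0.3/0.3/0.4 ("recent" = within 12 months) and log-normal
monthly frequency for the recent stratum; cognitive scores
a·(ROI value) + b·group + c·group×(ROI value) + noise with group coded
LTLE = 0, RTLE = 1; hippocampal volume Gaussian (3000 ± 300 mm³) with an
optional linear coupling to ipsilateral hippocampal R2*.

**What passing tests do and do not show.** The phantom establishes that
the operators implement their mathematics correctly and that the
weak-harmonic mechanism removes residual fields it was designed for. It
does not contain cortical folding, flow, motion, coil-combination
artefacts, or realistic noise correlations, so the tests say nothing about
robustness to those. The cohort generator has exactly the statistical
structure the analysis assumes (linear age trends, Gaussian within-group
variation); it validates the statistics stage's operating characteristics
under its own model, not the model's adequacy for real patients.

## Statistics

Age correction fits Y = λ + θ·A by least squares on controls per ROI,
hemispheres pooled, and corrects every subject by Y + θ(μ − A) with μ the
control mean age; after correction the refitted control slope is
statistically zero in ≥ 95% of simulated cohorts. Group comparisons:
one-way ANOVA per (ROI, hemisphere, measure) with η² = SS_between/SS_total
("two-tailed ANOVA" is implemented as the standard upper-tail F test);
Tukey–Kramer post hocs via the studentized-range distribution with the
unequal-n Kramer standard error and pairwise-pooled Cohen's d; paired t
tests on intra-subject left−right differences; ANCOVA of value-vs-age
slopes via the group×age interaction extra-sum-of-squares F test.
Clinical correlations: Spearman (midranks) against onset age; FBTCS
stratification ANOVA and Pearson correlation against log monthly
frequency with ROIs relabelled ipsi/contralateral to seizure side and
patient groups pooled; cognitive-score regressions
value ~ score + group + score×group per (ROI, side, measure, test) with
Benjamini–Hochberg FDR over the family of coefficient p-values per side
and measure; Pearson correlations of hippocampal volume with hippocampal
χ and R2* per group and hemisphere. Demographics use tie-corrected
Kruskal–Wallis (η² = (H−k+1)/(n−k)) and Pearson chi-square without
continuity correction. Composite normality uses the Lilliefors statistic
with Monte-Carlo null tables (10⁴ standard-normal samples per sample
size, cached, fixed seed) at p < .01; other tests at p < .05. Missing
clinical values are handled by per-analysis complete-case deletion with n
reported. Age correction is applied to all groups (controls included)
before group comparisons; both this and the Pearson choice for volume
correlations are switchable.

## Numerical notes and limitations

* Deterministic throughout: one `numpy` generator per simulated object,
  seeded from the spec; reruns are bit-identical.
* Problem sizes in the test-suite and acceptance script are chosen for
  desk-scale runtimes: phantoms 32³–64×64×48 rather than the clinical
  384×384×114, with solver iteration caps (60–300) sized to those grids.
* CG on the PDF normal equations is ill-conditioned and may stall around
  relative residual 1e-3; the returned best iterate is reported with the
  residual. Superposition consequently holds to a few percent, not to
  machine precision.
* The 7-point discrete Laplacian applied to spectrally computed dipole
  fields has a discretisation floor around 1e-2 relative RMS, so
  "numerically harmonic" background fields are verified as being orders of
  magnitude more harmonic than local fields, not as absolutely zero.
* Tie-breaks: noise-based erosion keeps voxels exactly at the threshold;
  BH rejection uses the standard step-up; Tukey–Kramer p-values are
  clipped to [0, 1] by the studentized-range survival function.
* The frequency-spectrum component of TV α selection is not implemented;
  the L-curve alone selects α, and the clinical presets ship as constants.
* ROI means are read from the noise-eroded mask; whether to use the
  3-voxel-eroded mask instead is a flag, since either convention is
  defensible.
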