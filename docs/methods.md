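# Methods

This note documents the models behind `dtialps`, the defaults and why,
the numerical choices, and what the synthetic data does and does not
emulate.

## Study conditions emulated

The generator reproduces the design of a three-group glycemic cohort of
community-dwelling older adults: 30 normal-glucose (NGM), 22 prediabetes
(Pre-DM) and 18 type-2-diabetes (T2DM) subjects, imaged with a
single-shell diffusion protocol (one b = 0 volume, 64 gradient directions
at b = 1000 s/mm², 1.8 mm isotropic voxels).  Default population
parameters per group (the published cohort profile):

| parameter | NGM | Pre-DM | T2DM |
|---|---|---|---|
| n | 30 | 22 | 18 |
| true ALPS (mean ± SD) | 1.58 ± 0.20 | 1.43 ± 0.08 | 1.36 ± 0.14 |
| age, years | 70.3 ± 4.8 | 72.1 ± 4.0 | 72.6 ± 6.0 |
| female proportion | 16/30 | 12/22 | 5/18 |
| education, years | 14.3 ± 2.2 | 14.1 ± 1.9 | 13.8 ± 2.2 |
| hypertension / hyperlipidemia prevalence | 0.50 / 0.47 | 0.68 / 0.82 | 0.67 / 0.72 |
| total Fazekas (rounded, clipped 0–6) | 2.1 ± 0.61 | 2.5 ± 0.8 | 2.78 ± 1.0 |
| HOMA-IR | 0.8 ± 0.5 | 1.2 ± 0.4 | 1.7 ± 1.3 |
| FPG, mg/dL | 92.4 ± 5.7 | 99.0 ± 7.8 | 121.0 ± 20.3 |
| 2-h OGTT, mg/dL | 105.0 ± 21.4 | 154.0 ± 21.0 | 254.4 ± 64.5 |
| HbA1c, % | 5.5 ± 0.3 | 5.9 ± 0.2 | 6.6 ± 0.9 |

Intracranial volume is not part of the published profile; the default
(1.45 × 10⁶ ± 1.5 × 10⁵ mm³) is a typical FreeSurfer-scale value for an
elderly cohort and acts purely as a covariate.

Continuous covariates are normal draws, binaries Bernoulli at the printed
prevalence, Fazekas a rounded normal clipped to 0–6.  Glycemic markers
are drawn from the group's normal distributions and rejection-sampled
against the diagnostic classifier, so every subject's markers re-classify
to the intended group by construction.  The classifier applies, in order:
T2DM if (FPG ≥ 126 or OGTT ≥ 200) and HbA1c ≥ 6.1; NGM if FPG < 110 and
OGTT < 140 and HbA1c < 5.4 simultaneously; otherwise Pre-DM.  The printed
criteria leave HbA1c ∈ [5.4, 5.6) with normal glucose in no class; the
classifier assigns such values to Pre-DM and logs a warning, and the
generator never emits them for NGM subjects (rejection takes care of it).

## Ground-truth ALPS and the phantom

Each subject's true ALPS index is drawn from its group's normal
distribution (truncated at 0) and realized as a one-parameter tensor
family: the perpendicular diffusivities are fixed at
Dyy_proj = Dzz_assoc = 1.0 × 10⁻³ mm²/s and the perivascular-axis values
at Dxx_proj = Dxx_assoc = ALPS × 10⁻³, which makes the index exactly
invertible from the stored diffusivities.

The phantom replaces real periventricular anatomy with labeled slabs
mirrored about a ventricle midline on a RAS grid (default 64³ voxels,
1.8 mm isotropic, identity-scaled affine): projection slabs (fibers along
z) lie medially at 6–12 voxels from the midline, association slabs
(fibers along y) laterally at 16–22 voxels, both spanning ±8 voxels in
y and z.  Projection voxels carry diag(Dxx_proj, Dyy_proj, λ∥),
association voxels diag(Dxx_assoc, λ∥, Dzz_assoc) with the fiber-axis
eigenvalue fixed at λ∥ = 2.4 × 10⁻³ mm²/s — above any ALPS-bearing cross
diffusivity the default distributions produce, so the stated fiber
orientation always holds.  Background is isotropic at 0.8 × 10⁻³.
ROI centers sit on voxel centers inside each slab; the default 5.4 mm
sphere therefore voxelizes to a fixed 19-voxel quasi-sphere.  Tests and
examples use a trimmed 48 × 20 × 20 grid with the identical slab layout
and ROI placement; grid size only changes how much background is
simulated.

DWI follows the monoexponential tensor model S = S0 exp(−b gᵀDg)
(S0 = 1000, arbitrary units) with Rician noise
sqrt((S + ε₁)² + ε₂²), ε ~ N(0, σ·S0); the default σ = 0.01 (1% of b0).
Gradient directions are a spherical Fibonacci lattice — deterministic,
well-conditioned (design rank 7 for any n ≥ 6 directions).  Per-subject
noise seeds are master_seed + subject index, so single subjects are
reproducible independently of cohort composition.

## HOMA-IR coupling

HOMA-IR is generated from a linear latent model on the true ALPS index:
with z the true ALPS standardized by the pooled mixture moments of the
configured cohort and u_g the standardized group mean,

    H = μ_H(group) + β (z − u_g) + σ_ε ε,   ε ~ N(0, 1).

β is solved in closed form so the *population* correlation of (z, H) —
which equals the partial correlation given the clinical covariates, since
those are generated independently — is exactly the configured target
(default −0.35).  Per-group HOMA-IR means and the pooled HOMA-IR variance
are preserved exactly; the residual is homoscedastic, so per-group SDs
deviate slightly from their nominal values (this widens the feasible
coupling range compared to preserving per-group SDs strictly).  The
covariate loadings of the latent model are zero by default, which is what
keeps the calibration closed-form and exact.  Infeasible requests — a
coupling requiring more variance than the pooled within-group HOMA-IR
variance provides, or any nonzero target when all ALPS SDs are zero with
equal means — raise an error naming `alps_homair_partial_r`.  When ALPS
SDs are all zero but group means differ, the correlation is dictated by
the group structure; the generator then ignores the target with a logged
warning rather than failing, so degenerate configurations remain usable.

Two consequences worth knowing: (a) because the published T2DM HOMA-IR
distribution is wide (1.7 ± 1.3), normal draws occasionally go
non-positive (~9% of T2DM subjects); they are left as drawn, because any
truncation would bias the calibrated correlation.  (b) the estimator
itself has the usual O(1/n) shrinkage toward zero, ~+0.01 at n = 40 for
a target of −0.35 — visible in, and accepted by, the recovery tests.

## Tensor fit and scalar maps

The fit is plain OLS on log-signals — no weighted least squares, no
positive-definiteness projection — matching the estimator the analysis
emulates.  Design row: [−b gx², −2b gx gy, −2b gx gz, −b gy², −2b gy gz,
−b gz², 1]; element order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) is fixed and
recorded in the output sidecar.  Non-positive noisy signals are clamped
to 10⁻⁶ × the voxel's mean b0 signal before the log (count logged);
all-zero voxels are dropped from the mask (count logged).  Gradient
directions are interpreted in the image frame, consistent with the
phantom writer — there is no scanner-frame reorientation.

FA uses the normalized eigenvalue-dispersion formula with negative
eigenvalues clamped to zero first (keeps FA ∈ [0, 1] even for indefinite
noisy fits); color-FA encodes |e₁|·FA.  Diagonal clamping happens only in
map derivation, never in the stored tensor elements.

## ALPS computation

Sphere voxelization is by voxel-center inclusion (distance ≤ radius, no
partial volumes) — the simplest rule whose voxel set is symmetric about
an on-grid center, making ROI means of linear fields exact at the center.
ROI means are unweighted voxel averages over mask-valid voxels; a fully
masked-out ROI is an error, as is any non-positive extracted diffusivity.
The bilateral index is the arithmetic mean of the two hemisphere indices,
not the index of pooled diffusivities; the pooled alternative exists only
as a test oracle.  The ROI diameter defaults to 5.4 mm (the protocol's
main stated value; 5 mm also circulates) and is a config field, as are
per-ROI center shifts for manual placement adjustments.

## Statistics

* Group contrasts: one GLM over all subjects, ALPS on group dummies
  (NGM reference) + 7 covariates, t test on the pairwise contrast,
  two-sided, α = 0.05.  Family-wise-error correction is Bonferroni over
  the three pairs — the method is deliberately the simplest one
  consistent with a corrected p of exactly 1.00 being attainable.
* Cohen's d uses the n-pooled denominator (no −2 correction), computed
  from raw group summaries, not covariate-adjusted means.  Bands:
  |d| ≤ 0.2 negligible, ≤ 0.5 small, ≤ 0.8 medium, else large.
* Partial correlation residualizes both variables on the covariates with
  intercept; p from t = r·sqrt(df/(1−r²)) with df = n − k − 2, which is
  algebraically identical to the GLM coefficient's t statistic (oracle-
  tested).  The df convention is documented rather than asserted as the
  emulated study's.
* VIF regresses each covariate on the others with intercept; ≥ 5 flags
  multicollinearity; perfect collinearity reports inf.
* Kruskal–Wallis (tie-corrected, χ² p) serves both as the omnibus test
  and in two-group pairwise mode for demographic-table entries; Fisher's
  exact test enumerates all margin-fixed 2×2 or 2×3 tables with exact
  integer arithmetic, two-sided by probability mass.

Cohort tables degrade gracefully: statistics that need more subjects than
they have degrees of freedom (GLM contrasts, VIF, partial correlation)
are skipped on minimal cohorts instead of failing the pipeline.

## Problem sizes used by the test suite and acceptance script

Tests use the trimmed 48 × 20 × 20 phantom: the noiseless round trip runs
100 subjects, group-mean recovery the full 70-subject cohort at 1% noise,
coupling calibration 3 × 500 tabular cohorts, and type-I calibration 2000
null cohorts.  The acceptance script uses the default 64³ phantom for the
isotropic null and the NGM (n = 30) / T2DM (n = 18) recovery runs, and
500 tabular cohorts of n = 40 for the coupling target.

## What passing tests do and do not show

The phantom demonstrates estimator correctness — that the pipeline
recovers known diffusivities, indices, group differences and couplings
under the stated noise model.  It deliberately omits: real brain anatomy
and registration (ROIs live at known template coordinates), partial
volumes and crossing fibers, susceptibility/eddy/motion artifacts and the
preprocessing that removes them (the emulated protocol handles those with
external tools; synthetic data is generated artifact-free, so that stage
is a documented no-op), Rician noise-floor bias at low SNR (at 1% noise
and b·D ≲ 2.4 the bias is negligible; the simulator will happily produce
high-noise data where it is not), and any physiological model linking
glycemia to perivascular flow — the ALPS–HOMA-IR coupling is a
statistical construction, not a mechanism.  Passing tests therefore
validate the software and its statistics, not the biological claim.
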