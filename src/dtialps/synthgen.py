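"""Synthetic diffusion-MRI cohorts with known glymphatic structure.

This module emulates the study conditions of a three-group glycemic
cohort (normal glucose metabolism, prediabetes, type 2 diabetes) imaged
with a single-shell DTI protocol:

* a cohort table of clinical covariates whose glycemic markers are
  consistent with the diagnostic classifier by construction;
* per-subject ground-truth ALPS indices realized as a one-parameter
  family of ROI diffusivities, so the index is exactly invertible;
* a digital phantom whose projection-region fibers run along z and
  association-region fibers along y, with the x axis orthogonal to the
  fibers in both — the geometry the ALPS method assumes;
* a monoexponential tensor forward model with Rician magnitude noise.

Insulin resistance (HOMA-IR) is coupled to the true ALPS index through a
linear latent model calibrated in closed form so that the population
partial correlation of ALPS with HOMA-IR given the (independent) clinical
covariates equals a configurable target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scheme import AcquisitionScheme

__all__ = [
    "GroupParams",
    "CohortConfig",
    "PhantomGeometry",
    "classify_glycemic_status",
    "generate_cohort",
    "build_tensor_field",
    "simulate_dwi",
    "DEFAULT_GROUPS",
    "REGION_LABELS",
    "GROUP_ORDER",
]

log = logging.getLogger(__name__)

GROUP_ORDER = ("NGM", "Pre-DM", "T2DM")

#: integer codes of the phantom region map
REGION_LABELS = {
    "background": 0,
    "projection-left": 1,
    "projection-right": 2,
    "association-left": 3,
    "association-right": 4,
}


# --------------------------------------------------------------------------
# glycemic classification
# --------------------------------------------------------------------------

def _classify_arrays(fpg, ogtt2h, hba1c):
    fpg = np.asarray(fpg, dtype=float)
    ogtt2h = np.asarray(ogtt2h, dtype=float)
    hba1c = np.asarray(hba1c, dtype=float)
    if np.any(~np.isfinite(fpg)) or np.any(~np.isfinite(ogtt2h)) \
            or np.any(~np.isfinite(hba1c)):
        raise ValueError("glycemic markers must be finite")
    if np.any(fpg < 0) or np.any(ogtt2h < 0) or np.any(hba1c < 0):
        raise ValueError("glycemic markers must be non-negative")
    t2dm = ((fpg >= 126.0) | (ogtt2h >= 200.0)) & (hba1c >= 6.1)
    ngm = (fpg < 110.0) & (ogtt2h < 140.0) & (hba1c < 5.4)
    out = np.where(t2dm, "T2DM", np.where(ngm, "NGM", "Pre-DM"))
    return out, t2dm, ngm


def classify_glycemic_status(fpg: float, ogtt2h: float, hba1c: float) -> str:
    """Assign T2DM / Pre-DM / NGM from the three glycemic markers (mg/dL, %).

    Diabetes requires an elevated glucose criterion (FPG >= 126 or 2-h
    OGTT >= 200) together with HbA1c >= 6.1; the normal class requires all
    three markers simultaneously below their cut-offs (FPG < 110,
    OGTT < 140, HbA1c < 5.4); everything else is prediabetes.  The printed
    criteria leave HbA1c in [5.4, 5.6) unassigned when glucose is normal;
    such gap values fall to Pre-DM with a logged warning.
    """
    labels, t2dm, ngm = _classify_arrays(fpg, ogtt2h, hba1c)
    label = str(labels.item()) if labels.ndim == 0 else labels
    if labels.ndim == 0 and label == "Pre-DM":
        in_gap = (
            fpg < 110.0 and ogtt2h < 140.0 and 5.4 <= hba1c < 5.6
        )
        if in_gap:
            log.warning(
                "HbA1c %.2f%% with normal glucose falls in the unclassified "
                "5.4-5.6 gap; assigning Pre-DM", hba1c
            )
    return label


# --------------------------------------------------------------------------
# cohort configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Population parameters for one glycemic group.

    Means/SDs follow the published cohort profile; ALPS parameters are the
    group's population mean and SD of the true (ground-truth) ALPS index.
    """

    name: str
    n: int
    alps_mean: float
    alps_sd: float
    age_mean: float
    age_sd: float
    female_prop: float
    education_mean: float
    education_sd: float
    icv_mean: float
    icv_sd: float
    hypertension_prev: float
    hyperlipidemia_prev: float
    fazekas_mean: float
    fazekas_sd: float
    homa_mean: float
    homa_sd: float
    fpg_mean: float
    fpg_sd: float
    ogtt_mean: float
    ogtt_sd: float
    hba1c_mean: float
    hba1c_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.name}: size must be >= 0")
        for f in ("alps_sd", "age_sd", "education_sd", "icv_sd",
                  "fazekas_sd", "homa_sd", "fpg_sd", "ogtt_sd", "hba1c_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"group {self.name}: {f} must be >= 0")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ValueError(f"group {self.name}: female_prop must be in [0,1]")


# Defaults reproduce the published cohort profile: group sizes 30/22/18,
# ALPS 1.58±0.20 / 1.43±0.08 / 1.36±0.14, and the printed covariate
# means/SDs and prevalences.  ICV is not printed and uses a typical
# elderly-cohort value.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "NGM": GroupParams(
        name="NGM", n=30, alps_mean=1.58, alps_sd=0.20,
        age_mean=70.3, age_sd=4.8, female_prop=16 / 30,
        education_mean=14.3, education_sd=2.2,
        icv_mean=1.45e6, icv_sd=1.5e5,
        hypertension_prev=15 / 30, hyperlipidemia_prev=14 / 30,
        fazekas_mean=2.1, fazekas_sd=0.61,
        homa_mean=0.8, homa_sd=0.5,
        fpg_mean=92.4, fpg_sd=5.7, ogtt_mean=105.0, ogtt_sd=21.4,
        hba1c_mean=5.5, hba1c_sd=0.3,
    ),
    "Pre-DM": GroupParams(
        name="Pre-DM", n=22, alps_mean=1.43, alps_sd=0.08,
        age_mean=72.1, age_sd=4.0, female_prop=12 / 22,
        education_mean=14.1, education_sd=1.9,
        icv_mean=1.45e6, icv_sd=1.5e5,
        hypertension_prev=15 / 22, hyperlipidemia_prev=18 / 22,
        fazekas_mean=2.5, fazekas_sd=0.8,
        homa_mean=1.2, homa_sd=0.4,
        fpg_mean=99.0, fpg_sd=7.8, ogtt_mean=154.0, ogtt_sd=21.0,
        hba1c_mean=5.9, hba1c_sd=0.2,
    ),
    "T2DM": GroupParams(
        name="T2DM", n=18, alps_mean=1.36, alps_sd=0.14,
        age_mean=72.6, age_sd=6.0, female_prop=5 / 18,
        education_mean=13.8, education_sd=2.2,
        icv_mean=1.45e6, icv_sd=1.5e5,
        hypertension_prev=12 / 18, hyperlipidemia_prev=13 / 18,
        fazekas_mean=2.78, fazekas_sd=1.0,
        homa_mean=1.7, homa_sd=1.3,
        fpg_mean=121.0, fpg_sd=20.3, ogtt_mean=254.4, ogtt_sd=64.5,
        hba1c_mean=6.6, hba1c_sd=0.9,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    ``alps_homair_partial_r`` is the target population partial correlation
    between true ALPS and HOMA-IR given the seven clinical covariates;
    ``noise_sigma`` is the Rician noise SD relative to the b0 signal.
    """

    groups: tuple[GroupParams, ...] = field(
        default_factory=lambda: tuple(DEFAULT_GROUPS[g] for g in GROUP_ORDER)
    )
    alps_homair_partial_r: float = -0.35
    noise_sigma: float = 0.01
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.alps_homair_partial_r < 1.0:
            raise ValueError("alps_homair_partial_r must lie in (-1, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in config")

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups)

    def with_groups(self, **sizes: int) -> "CohortConfig":
        """Return a copy with some group sizes replaced (0 drops a group)."""
        groups = tuple(
            replace(g, n=sizes.get(g.name, g.n)) for g in self.groups
        )
        return replace(self, groups=groups)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _draw_markers(rng: np.random.Generator, gp: GroupParams) -> np.ndarray:
    """Rejection-sample (FPG, OGTT, HbA1c) until the classifier agrees.

    Draws from the group's normal marker distributions and keeps only
    triples the diagnostic classifier maps back to the group, so labels
    are consistent by construction.
    """
    out = np.empty((gp.n, 3))
    need = np.arange(gp.n)
    for _ in range(10000):
        if need.size == 0:
            return out
        m = np.column_stack([
            rng.normal(gp.fpg_mean, gp.fpg_sd, need.size),
            rng.normal(gp.ogtt_mean, gp.ogtt_sd, need.size),
            rng.normal(gp.hba1c_mean, gp.hba1c_sd, need.size),
        ])
        valid = np.all(m >= 0, axis=1)
        labels, _, _ = _classify_arrays(
            np.where(valid, m[:, 0], 0.0), np.where(valid, m[:, 1], 0.0),
            np.where(valid, m[:, 2], 0.0))
        ok = valid & (labels == gp.name)
        out[need[ok]] = m[ok]
        need = need[~ok]
    raise RuntimeError(
        f"could not sample {gp.name} glycemic markers consistent with the "
        "classifier; marker distribution barely overlaps the class region"
    )


def _truncated_normal_positive(rng, mean, sd, n):
    """Normal draws resampled to be strictly positive (degenerate sd=0 ok)."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate distribution at a non-positive mean")
        return np.full(n, float(mean))
    x = rng.normal(mean, sd, n)
    for _ in range(1000):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("positive-truncated sampling failed to converge")


def _pooled_alps_moments(groups):
    n = np.array([g.n for g in groups], dtype=float)
    w = n / n.sum()
    mu = np.array([g.alps_mean for g in groups])
    sd = np.array([g.alps_sd for g in groups])
    m = float(w @ mu)
    v = float(w @ (sd**2 + mu**2) - m**2)
    return m, v, w, mu, sd


def _homa_coupling(groups, rho):
    """Closed-form coupling slope for the ALPS -> HOMA-IR latent model.

    The model is ``H = mu_H(group) + beta * (z - u_group) + sigma_eps * eps``
    with ``z`` the true ALPS standardized by its pooled mixture moments and
    ``u_group`` the standardized group mean.  Per-group HOMA means and the
    pooled HOMA variance are preserved exactly (the residual is
    homoscedastic, so per-group SDs adjust slightly around their targets),
    and the population correlation of (z, H) — which equals the partial
    correlation given the independent covariates — is exactly ``rho``.
    Returns (beta, eps SD, pooled ALPS mean, pooled ALPS variance).
    """
    m_a, v_a, w, mu_a, sd_a = _pooled_alps_moments(groups)
    mu_h = np.array([g.homa_mean for g in groups])
    sd_h = np.array([g.homa_sd for g in groups])
    m_h = float(w @ mu_h)
    v_h = float(w @ (sd_h**2 + mu_h**2) - m_h**2)
    if v_a <= 0:
        if rho != 0:
            raise ValueError(
                "alps_homair_partial_r != 0 is infeasible: pooled ALPS "
                "variance is zero (all alps_sd zero and equal group means)"
            )
        return 0.0, float(np.sqrt(w @ sd_h**2)), m_a, v_a
    s_a = np.sqrt(v_a)
    u = (mu_a - m_a) / s_a                      # standardized group means
    v_within = float(w @ (sd_a / s_a) ** 2)      # within-group share of var(z)
    cov_between = float(w @ (u * (mu_h - m_h)))
    if v_within <= 0:
        # all alps_sd zero: the ALPS-HOMA correlation is fully determined
        # by the group structure and cannot be steered
        implied = cov_between / np.sqrt(v_h) if v_h > 0 else 0.0
        log.warning(
            "all alps_sd are zero; ignoring alps_homair_partial_r=%s "
            "(group structure implies a population correlation of %.3f)",
            rho, implied)
        return 0.0, float(np.sqrt(w @ sd_h**2)), m_a, v_a
    beta = (rho * np.sqrt(v_h) - cov_between) / v_within
    resid_var = float(w @ sd_h**2) - beta**2 * v_within
    if resid_var < 0:
        raise ValueError(
            f"alps_homair_partial_r={rho} is infeasible: the required "
            "ALPS->HOMA-IR coupling exceeds the pooled within-group "
            "HOMA-IR variance; reduce |alps_homair_partial_r| or raise "
            "the groups' homa_sd"
        )
    return float(beta), float(np.sqrt(resid_var)), m_a, v_a


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and its ground truth, reproducibly.

    Returns ``(cohort, truth)``.  ``cohort`` has one row per subject with
    group label, clinical covariates and glycemic markers guaranteed to
    re-classify to the label.  ``truth`` stores the subject's true ROI
    diffusivities (mm²/s), true ALPS index and per-subject noise seed
    (``master_seed`` + subject index).
    """
    rng = np.random.default_rng(config.master_seed)
    groups = [g for g in config.groups if g.n > 0]
    beta, eps_sd, m_a, v_a = _homa_coupling(
        groups, config.alps_homair_partial_r)

    frames = []
    for gp in groups:
        markers = _draw_markers(rng, gp)
        alps = _truncated_normal_positive(rng, gp.alps_mean, gp.alps_sd, gp.n)
        if v_a > 0:
            z_within = (alps - gp.alps_mean) / np.sqrt(v_a)
        else:
            z_within = np.zeros(gp.n)
        homa = (gp.homa_mean + beta * z_within
                + eps_sd * rng.standard_normal(gp.n))
        fazekas = np.clip(
            np.rint(rng.normal(gp.fazekas_mean, gp.fazekas_sd, gp.n)),
            0, 6).astype(int)
        frames.append(pd.DataFrame({
            "group": gp.name,
            "age": rng.normal(gp.age_mean, gp.age_sd, gp.n),
            "sex_female": (rng.random(gp.n) < gp.female_prop).astype(int),
            "education_years": rng.normal(
                gp.education_mean, gp.education_sd, gp.n),
            "icv_mm3": rng.normal(gp.icv_mean, gp.icv_sd, gp.n),
            "hypertension": (rng.random(gp.n) < gp.hypertension_prev)
            .astype(int),
            "hyperlipidemia": (rng.random(gp.n) < gp.hyperlipidemia_prev)
            .astype(int),
            "fazekas_total": fazekas,
            "homa_ir": homa,
            "fpg_mgdl": markers[:, 0],
            "ogtt2h_mgdl": markers[:, 1],
            "hba1c_pct": markers[:, 2],
            "alps_true": alps,
        }))
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "subject_id",
                  [f"sub-{i:03d}" for i in range(len(cohort))])

    relabeled, _, _ = _classify_arrays(
        cohort["fpg_mgdl"], cohort["ogtt2h_mgdl"], cohort["hba1c_pct"])
    assert (relabeled == cohort["group"].to_numpy()).all()

    alps = cohort.pop("alps_true").to_numpy()
    truth = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "dxx_proj": alps * 1e-3,
        "dxx_assoc": alps * 1e-3,
        "dyy_proj": 1.0e-3,
        "dzz_assoc": 1.0e-3,
        "alps_true": alps,
        "seed": config.master_seed + np.arange(len(cohort)),
    })
    return cohort, truth


# --------------------------------------------------------------------------
# phantom geometry and forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomGeometry:
    """Labeled phantom grid in a common template space.

    The real periventricular anatomy is replaced by labeled slabs flanking
    a simulated ventricle midline: projection slabs (fibers along z) lie
    medially and association slabs (fibers along y) laterally, mirrored
    across the x midline.  Voxel centers sit at ``index * voxel_size`` mm.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    labels: np.ndarray
    roi_centers_mm: dict[str, np.ndarray]

    @classmethod
    def default(cls, shape: tuple[int, int, int] = (64, 64, 64),
                voxel_size: float = 1.8) -> "PhantomGeometry":
        nx, ny, nz = shape
        cx, cy, cz = nx // 2, ny // 2, nz // 2
        if cx - 22 < 0 or cx + 22 >= nx or cy - 8 < 0 or cy + 8 >= ny \
                or cz - 8 < 0 or cz + 8 >= nz:
            raise ValueError(f"grid {shape} too small for the slab layout")
        labels = np.zeros(shape, dtype=np.int8)
        ys = slice(cy - 8, cy + 9)
        zs = slice(cz - 8, cz + 9)
        labels[cx - 12:cx - 5, ys, zs] = REGION_LABELS["projection-left"]
        labels[cx + 6:cx + 13, ys, zs] = REGION_LABELS["projection-right"]
        labels[cx - 22:cx - 15, ys, zs] = REGION_LABELS["association-left"]
        labels[cx + 16:cx + 23, ys, zs] = REGION_LABELS["association-right"]
        vs = float(voxel_size)
        centers = {
            "projection-left": np.array([cx - 9, cy, cz]) * vs,
            "projection-right": np.array([cx + 9, cy, cz]) * vs,
            "association-left": np.array([cx - 19, cy, cz]) * vs,
            "association-right": np.array([cx + 19, cy, cz]) * vs,
        }
        return cls(shape=tuple(shape), voxel_size=vs, labels=labels,
                   roi_centers_mm=centers)

    def region_mask(self, *names: str) -> np.ndarray:
        codes = [REGION_LABELS[n] for n in names]
        return np.isin(self.labels, codes)

    @property
    def tissue_mask(self) -> np.ndarray:
        """All labeled (non-background) voxels."""
        return self.labels > 0


def build_tensor_field(
    geometry: PhantomGeometry,
    truth,
    principal_diffusivity: float = 2.4e-3,
    background_diffusivity: float = 0.8e-3,
) -> np.ndarray:
    """Construct the per-voxel 3x3 diffusion tensor field for one subject.

    ``truth`` is a mapping (e.g. a ground-truth table row) providing
    ``dxx_proj``, ``dxx_assoc``, ``dyy_proj``, ``dzz_assoc`` in mm²/s.
    Projection voxels carry ``diag(dxx_proj, dyy_proj, principal)`` (fibers
    along z); association voxels ``diag(dxx_assoc, principal, dzz_assoc)``
    (fibers along y); background is isotropic.
    """
    vals = {k: float(truth[k])
            for k in ("dxx_proj", "dxx_assoc", "dyy_proj", "dzz_assoc")}
    if any(v <= 0 for v in vals.values()) or principal_diffusivity <= 0 \
            or background_diffusivity <= 0:
        raise ValueError(
            "all diffusivities must be positive to build a positive-definite "
            f"tensor field (got {vals})"
        )
    D = np.zeros(geometry.shape + (3, 3))
    for ax in range(3):
        D[..., ax, ax] = background_diffusivity
    proj = geometry.region_mask("projection-left", "projection-right")
    assoc = geometry.region_mask("association-left", "association-right")
    D[proj] = np.diag([vals["dxx_proj"], vals["dyy_proj"],
                       principal_diffusivity])
    D[assoc] = np.diag([vals["dxx_assoc"], principal_diffusivity,
                        vals["dzz_assoc"]])
    return D


def simulate_dwi(
    tensor_field: np.ndarray,
    scheme: AcquisitionScheme,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    s0: float = 1000.0,
) -> np.ndarray:
    """Simulate a DWI series from a tensor field.

    Per voxel and volume the noiseless signal is ``S0 exp(-b g' D g)``.
    Rician noise is applied as ``sqrt((S + e1)^2 + e2^2)`` with independent
    ``e ~ Normal(0, noise_sigma * S0)``, the magnitude-MRI noise model.
    Reproducible from ``seed``.
    """
    D = np.asarray(tensor_field, dtype=float)
    if D.shape[-2:] != (3, 3):
        raise ValueError("tensor_field must have trailing (3, 3) dimensions")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    g = scheme.bvecs
    quad = np.einsum("...ij,ni,nj->...n", D, g, g, optimize=True)
    S = s0 * np.exp(-scheme.bvals * quad)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sigma * s0
        e1 = rng.normal(0.0, sd, S.shape)
        e2 = rng.normal(0.0, sd, S.shape)
        S = np.sqrt((S + e1) ** 2 + e2**2)
    return S
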