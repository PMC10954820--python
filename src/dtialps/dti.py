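"""Per-voxel diffusion-tensor fitting by ordinary least squares.

The forward model is the monoexponential Stejskal–Tanner equation
``S = S0 * exp(-b g' D g)``; taking logs makes the six unique tensor
elements plus log-S0 linear in the measurements, and a single OLS solve
shared across voxels recovers them.  Derived maps are the diagonal
diffusivities Dxx/Dyy/Dzz, fractional anisotropy (FA) and a
direction-encoded (color) FA map.

Tensor elements are stored in the fixed order
``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)`` — see :data:`TENSOR_ELEMENT_ORDER`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "TENSOR_ELEMENT_ORDER",
    "TensorField",
    "ScalarMaps",
    "build_design_matrix",
    "fit_tensor_ols",
    "compute_scalar_maps",
]

log = logging.getLogger(__name__)

TENSOR_ELEMENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# index of each diagonal element within the 6-vector
_IDX_DXX, _IDX_DYY, _IDX_DZZ = 0, 3, 5


@dataclass
class TensorField:
    """Fitted tensor elements, log-S0 and the fit mask.

    ``elements`` has shape ``grid + (6,)`` in :data:`TENSOR_ELEMENT_ORDER`
    (units mm²/s); values outside ``mask`` are zero.  ``n_clamped`` counts
    non-positive signal samples floored before the log (QC counter).
    """

    elements: np.ndarray
    log_s0: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0
    n_dropped: int = 0

    def as_matrices(self) -> np.ndarray:
        """Expand the 6-element storage to full symmetric 3x3 matrices."""
        e = self.elements
        D = np.zeros(e.shape[:-1] + (3, 3))
        D[..., 0, 0] = e[..., 0]
        D[..., 0, 1] = D[..., 1, 0] = e[..., 1]
        D[..., 0, 2] = D[..., 2, 0] = e[..., 2]
        D[..., 1, 1] = e[..., 3]
        D[..., 1, 2] = D[..., 2, 1] = e[..., 4]
        D[..., 2, 2] = e[..., 5]
        return D

    @classmethod
    def from_matrices(cls, D: np.ndarray, log_s0: np.ndarray | None = None,
                      mask: np.ndarray | None = None) -> "TensorField":
        D = np.asarray(D, dtype=float)
        if D.shape[-2:] != (3, 3):
            raise ValueError("expected trailing (3, 3) tensor dimensions")
        grid = D.shape[:-2]
        e = np.stack(
            [D[..., 0, 0], D[..., 0, 1], D[..., 0, 2],
             D[..., 1, 1], D[..., 1, 2], D[..., 2, 2]], axis=-1
        )
        if log_s0 is None:
            log_s0 = np.zeros(grid)
        if mask is None:
            mask = np.ones(grid, dtype=bool)
        return cls(e, np.asarray(log_s0, float), np.asarray(mask, bool))


@dataclass
class ScalarMaps:
    """FA and diagonal-diffusivity maps derived from a tensor field."""

    fa: np.ndarray
    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    mask: np.ndarray
    color_fa: np.ndarray | None = field(default=None)


def build_design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Log-linear tensor design matrix, one row per volume.

    Row layout ``[-b gx², -2b gx gy, -2b gx gz, -b gy², -2b gy gz, -b gz², 1]``,
    matching :data:`TENSOR_ELEMENT_ORDER` plus a final log-S0 column.
    """
    b = scheme.bvals
    gx, gy, gz = scheme.bvecs[:, 0], scheme.bvecs[:, 1], scheme.bvecs[:, 2]
    X = np.column_stack([
        -b * gx * gx,
        -2.0 * b * gx * gy,
        -2.0 * b * gx * gz,
        -b * gy * gy,
        -2.0 * b * gy * gz,
        -b * gz * gz,
        np.ones_like(b),
    ])
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "gradient scheme is rank-deficient: cannot identify all six "
            "tensor elements plus log-S0"
        )
    return X


def fit_tensor_ols(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    signal_floor_rel: float = 1e-6,
) -> TensorField:
    """Fit the diffusion tensor per voxel by OLS on log-signals.

    Parameters
    ----------
    dwi:
        Array of shape ``grid + (n_volumes,)``.
    scheme:
        Acquisition scheme; its length must equal the last dwi axis.
    mask:
        Boolean array over ``grid``; voxels outside are skipped.  Voxels
        whose signal is identically zero are dropped from the mask (the
        count is logged).
    signal_floor_rel:
        Non-positive signal samples are clamped to ``signal_floor_rel``
        times the voxel's mean b0 signal before the log, keeping OLS
        defined under noise.  Clamped-sample counts are logged.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != len(scheme):
        raise ValueError(
            f"dwi has {dwi.shape[-1]} volumes but scheme has {len(scheme)}"
        )
    grid = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match dwi grid")

    X = build_design_matrix(scheme)
    S = dwi[mask]  # (n_voxels, n_volumes)

    alive = np.any(S != 0.0, axis=1)
    n_dropped = int(np.count_nonzero(~alive))
    if n_dropped:
        log.warning("dropping %d all-zero voxels from fit mask", n_dropped)
        fit_mask = mask.copy()
        fit_mask[mask] = alive
        S = S[alive]
    else:
        fit_mask = mask

    b0 = scheme.bvals == 0
    s0_ref = S[:, b0].mean(axis=1)
    s0_ref = np.where(s0_ref > 0, s0_ref, 1.0)
    floor = signal_floor_rel * s0_ref[:, None]
    bad = S <= 0.0
    n_clamped = int(np.count_nonzero(bad))
    if n_clamped:
        log.info("clamped %d non-positive signal samples to the log floor",
                 n_clamped)
        S = np.where(bad, floor, S)

    # one shared solve: X (n_vol, 7), log S.T (n_vol, n_voxels)
    coef, *_ = np.linalg.lstsq(X, np.log(S).T, rcond=None)

    elements = np.zeros(grid + (6,))
    log_s0 = np.zeros(grid)
    elements[fit_mask] = coef[:6].T
    log_s0[fit_mask] = coef[6]
    return TensorField(elements, log_s0, fit_mask,
                       n_clamped=n_clamped, n_dropped=n_dropped)


def compute_scalar_maps(tensors: TensorField, with_color: bool = True) -> ScalarMaps:
    """Derive Dxx/Dyy/Dzz, FA and optionally color-FA from a tensor field.

    FA uses the standard normalized eigenvalue-dispersion formula; negative
    eigenvalues (possible after a noisy OLS fit) are clamped to zero first,
    which keeps FA in [0, 1].  Color-FA encodes the principal eigenvector
    as RGB = |e1| * FA.
    """
    e = tensors.elements
    mask = tensors.mask
    grid = mask.shape

    dxx = np.where(mask, e[..., _IDX_DXX], 0.0)
    dyy = np.where(mask, e[..., _IDX_DYY], 0.0)
    dzz = np.where(mask, e[..., _IDX_DZZ], 0.0)

    fa = np.zeros(grid)
    color = np.zeros(grid + (3,)) if with_color else None

    D = tensors.as_matrices()[mask]
    if D.size:
        evals, evecs = np.linalg.eigh(D)
        evals = np.clip(evals, 0.0, None)
        mean_ev = evals.mean(axis=1, keepdims=True)
        num = np.sum((evals - mean_ev) ** 2, axis=1)
        den = np.sum(evals**2, axis=1)
        fa_v = np.sqrt(1.5 * np.divide(num, den, out=np.zeros_like(num),
                                       where=den > 0))
        fa_v = np.clip(fa_v, 0.0, 1.0)
        fa[mask] = fa_v
        if with_color:
            e1 = evecs[..., -1]  # eigh sorts ascending; last is principal
            color[mask] = np.abs(e1) * fa_v[:, None]
    return ScalarMaps(fa=fa, dxx=dxx, dyy=dyy, dzz=dzz, mask=mask,
                      color_fa=color)
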