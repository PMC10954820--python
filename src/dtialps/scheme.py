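"""Diffusion acquisition schemes (b-values + gradient directions).

The default scheme mirrors a single-shell clinical protocol: one
non-diffusion-weighted (b = 0) volume followed by 64 unit gradient
directions at b = 1000 s/mm², the standard setting for DTI-ALPS work.
Directions are read/written in the FSL dialect: a one-line whitespace
separated ``.bval`` file and a three-row ``.bvec`` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionScheme", "fibonacci_directions"]

_UNIT_TOL = 1e-6


def fibonacci_directions(n: int) -> np.ndarray:
    """Return ``n`` approximately uniform unit vectors on the sphere.

    Uses the spherical Fibonacci lattice, which is deterministic and has
    excellent angular coverage for tensor estimation (the resulting design
    matrix is always full rank for n >= 6).
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    # offset by 0.5 keeps points away from the poles
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm²) and unit gradient directions, one row per volume.

    Zero vectors are allowed (and expected) for b = 0 volumes.  At least
    seven volumes including one b = 0 are required: the tensor model has
    six unknowns plus log-S0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs length mismatch")
        if bvals.shape[0] < 7:
            raise ValueError(
                "scheme needs >= 7 volumes (6 tensor unknowns + log-S0)"
            )
        if not np.any(bvals == 0):
            raise ValueError("scheme needs at least one b = 0 volume")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("non-b0 gradient directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(self.bvals > 0))

    @classmethod
    def default(cls, n_directions: int = 64, b: float = 1000.0) -> "AcquisitionScheme":
        """One b = 0 volume plus ``n_directions`` directions at ``b`` s/mm²."""
        g = fibonacci_directions(n_directions)
        bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
        bvecs = np.vstack([np.zeros(3), g])
        return cls(bvals, bvecs)

    # ---- FSL-dialect I/O -------------------------------------------------

    def to_files(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        Path(bval_path).write_text(
            " ".join(f"{b:g}" for b in self.bvals) + "\n"
        )
        rows = [
            " ".join(f"{v:.8f}" for v in self.bvecs[:, ax]) for ax in range(3)
        ]
        Path(bvec_path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_files(cls, bval_path: str | Path, bvec_path: str | Path) -> "AcquisitionScheme":
        bvals = np.loadtxt(bval_path, dtype=float).ravel()
        bvecs = np.loadtxt(bvec_path, dtype=float)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            # ambiguous 3x3: FSL convention stores one column per volume
            bvecs = bvecs.T
        return cls(bvals, bvecs)
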