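"""ALPS index: spherical ROI placement, diffusivity extraction, Eq. of the
"diffusivity along the perivascular space" method.

The index contrasts x-axis diffusivity (parallel to the deep medullary
perivascular spaces) in the projection and association regions with the
diffusivities perpendicular to the dominant fibers of those regions::

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

A value near 1.0 indicates minimal diffusion along the perivascular
space; larger values indicate freer perivascular flow.  Four spherical
ROIs (projection/association x left/right, default diameter 5.4 mm) are
placed at fixed template coordinates; per-hemisphere indices are averaged
arithmetically into the bilateral index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dti import ScalarMaps
from .synthgen import PhantomGeometry

__all__ = [
    "ROISpec",
    "ROISet",
    "ALPSResult",
    "voxelize_roi",
    "extract_roi_diffusivities",
    "alps_index",
    "bilateral_alps",
    "compute_alps",
]

DEFAULT_ROI_DIAMETER_MM = 5.4

_HEMIS = ("left", "right")
_REGIONS = ("projection", "association")


@dataclass(frozen=True)
class ROISpec:
    """One spherical ROI in template space (mm coordinates)."""

    region: str
    hemisphere: str
    center_mm: tuple[float, float, float]
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.region not in _REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.hemisphere not in _HEMIS:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")


class ROISet(dict):
    """The four ALPS ROIs keyed by ``(region, hemisphere)``."""

    @classmethod
    def from_geometry(cls, geometry: PhantomGeometry,
                      diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
                      center_shifts_mm: dict | None = None) -> "ROISet":
        """Place the four ROIs at the geometry's template coordinates.

        ``center_shifts_mm`` optionally maps ``(region, hemisphere)`` to an
        xyz shift, mirroring a manual per-subject placement adjustment.
        """
        rois = cls()
        for region in _REGIONS:
            for hemi in _HEMIS:
                center = np.asarray(
                    geometry.roi_centers_mm[f"{region}-{hemi}"], dtype=float)
                shift = (center_shifts_mm or {}).get((region, hemi))
                if shift is not None:
                    center = center + np.asarray(shift, dtype=float)
                rois[(region, hemi)] = ROISpec(
                    region=region, hemisphere=hemi,
                    center_mm=tuple(center), diameter_mm=diameter_mm)
        return rois

    @classmethod
    def from_records(cls, records) -> "ROISet":
        rois = cls()
        for rec in records:
            spec = ROISpec(region=rec["region"], hemisphere=rec["hemisphere"],
                           center_mm=tuple(rec["center_mm"]),
                           diameter_mm=rec.get("diameter_mm",
                                               DEFAULT_ROI_DIAMETER_MM))
            rois[(spec.region, spec.hemisphere)] = spec
        return rois

    def to_records(self) -> list[dict]:
        return [
            {"region": s.region, "hemisphere": s.hemisphere,
             "center_mm": list(s.center_mm), "diameter_mm": s.diameter_mm}
            for s in self.values()
        ]


@dataclass
class ALPSResult:
    """Per-hemisphere ROI diffusivities (mm²/s), indices and voxel counts."""

    diffusivities: dict  # (hemisphere -> {dxx_proj, dxx_assoc, dyy_proj, dzz_assoc})
    index_left: float
    index_right: float
    index_bilateral: float
    voxel_counts: dict  # (region, hemisphere) -> int


def voxelize_roi(spec: ROISpec, shape: tuple[int, int, int],
                 voxel_size: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the ROI sphere.

    Voxel-center inclusion (no partial volumes): a voxel belongs to the
    ROI iff its center is within ``diameter/2`` mm (Euclidean) of the ROI
    center.  Voxel centers sit at ``index * voxel_size`` mm.
    """
    center = np.asarray(spec.center_mm, dtype=float)
    upper = (np.asarray(shape) - 1) * voxel_size
    if np.any(center < 0) or np.any(center > upper):
        raise ValueError(
            f"ROI {spec.region}-{spec.hemisphere} center {tuple(center)} mm "
            f"lies outside the grid (extent 0..{tuple(upper)} mm)"
        )
    radius = spec.diameter_mm / 2.0
    # only scan the bounding box around the sphere
    lo = np.maximum(np.floor((center - radius) / voxel_size).astype(int), 0)
    hi = np.minimum(np.ceil((center + radius) / voxel_size).astype(int),
                    np.asarray(shape) - 1)
    mask = np.zeros(shape, dtype=bool)
    ix, iy, iz = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    d2 = ((gx * voxel_size - center[0]) ** 2
          + (gy * voxel_size - center[1]) ** 2
          + (gz * voxel_size - center[2]) ** 2)
    inside = d2 <= radius**2
    mask[gx[inside], gy[inside], gz[inside]] = True
    if not mask.any():
        raise ValueError(
            f"ROI {spec.region}-{spec.hemisphere} voxelizes to an empty mask"
        )
    return mask


def extract_roi_diffusivities(
    maps: ScalarMaps, rois: ROISet, voxel_size: float
) -> tuple[dict, dict]:
    """Unweighted ROI means of the axis diffusivities, per hemisphere.

    Returns ``(diffusivities, voxel_counts)`` where diffusivities maps each
    hemisphere to the four means entering the ALPS index: Dxx over the
    projection and association ROIs, Dyy over the projection ROI and Dzz
    over the association ROI.  ROI voxels outside the fit mask are
    excluded; a fully excluded ROI is an error.
    """
    shape = maps.mask.shape
    out: dict[str, dict[str, float]] = {}
    counts: dict[tuple[str, str], int] = {}
    for hemi in _HEMIS:
        vals: dict[str, float] = {}
        for region in _REGIONS:
            spec = rois[(region, hemi)]
            roi = voxelize_roi(spec, shape, voxel_size)
            usable = roi & maps.mask
            n = int(usable.sum())
            if n == 0:
                raise ValueError(
                    f"ROI {region}-{hemi}: every voxel is outside the fit mask"
                )
            counts[(region, hemi)] = n
            vals[f"dxx_{'proj' if region == 'projection' else 'assoc'}"] = \
                float(maps.dxx[usable].mean())
            if region == "projection":
                vals["dyy_proj"] = float(maps.dyy[usable].mean())
            else:
                vals["dzz_assoc"] = float(maps.dzz[usable].mean())
        out[hemi] = vals
    return out, counts


def alps_index(dxx_proj: float, dxx_assoc: float,
               dyy_proj: float, dzz_assoc: float) -> float:
    """The ALPS index: mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

    All inputs must be strictly positive; a non-positive extracted
    diffusivity signals an upstream fit failure rather than a valid index.
    """
    vals = (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc)
    if any(not np.isfinite(v) or v <= 0 for v in vals):
        raise ValueError(
            f"ALPS inputs must be positive and finite, got {vals}"
        )
    return ((dxx_proj + dxx_assoc) / 2.0) / ((dyy_proj + dzz_assoc) / 2.0)


def bilateral_alps(index_left: float | None, index_right: float | None) -> float:
    """Arithmetic mean of the two hemisphere indices.

    Both hemispheres are required — there is no silent single-hemisphere
    fallback (a missing hemisphere indicates a failed extraction).
    """
    if index_left is None or index_right is None:
        raise ValueError("both hemisphere indices are required")
    return (float(index_left) + float(index_right)) / 2.0


def compute_alps(maps: ScalarMaps, rois: ROISet,
                 voxel_size: float) -> ALPSResult:
    """Extract ROI diffusivities and compute hemisphere + bilateral indices."""
    diffs, counts = extract_roi_diffusivities(maps, rois, voxel_size)
    idx = {h: alps_index(**diffs[h]) for h in _HEMIS}
    return ALPSResult(
        diffusivities=diffs,
        index_left=idx["left"],
        index_right=idx["right"],
        index_bilateral=bilateral_alps(idx["left"], idx["right"]),
        voxel_counts=counts,
    )
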