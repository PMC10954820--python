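"""Orchestration: simulate → fit-dti → alps → stats, on disk or in memory.

Every stage reads and writes standard formats (NIfTI-1 DWI with FSL
bval/bvec, TSV tables, JSON results, YAML config), so runs are resumable
from any intermediate.  A manifest with SHA-256 hashes, the seed and a
config echo makes runs auditable; QC counters (clamped signal samples,
dropped voxels, ROI exclusions) are logged rather than silently absorbed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .alps import ROISet, compute_alps
from .dti import (TENSOR_ELEMENT_ORDER, ScalarMaps, compute_scalar_maps,
                  fit_tensor_ols)
from .scheme import AcquisitionScheme
from .synthgen import (
    CohortConfig,
    DEFAULT_GROUPS,
    GROUP_ORDER,
    GroupParams,
    PhantomGeometry,
    build_tensor_field,
    generate_cohort,
    simulate_dwi,
)

__all__ = ["RunConfig", "measure_subject", "measure_cohort",
           "run_simulate", "run_fit", "run_alps", "run_stats", "run_full"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (serializable to YAML)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.8
    b_value: float = 1000.0
    n_directions: int = 64
    roi_diameter_mm: float = 5.4
    s0: float = 1000.0
    alpha: float = 0.05

    def geometry(self) -> PhantomGeometry:
        return PhantomGeometry.default(self.grid_shape, self.voxel_size_mm)

    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme.default(self.n_directions, self.b_value)

    # ---- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["groups"] = [dataclasses.asdict(g)
                                 for g in self.cohort.groups]
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "groups" in c:
                c["groups"] = tuple(GroupParams(**g) for g in c["groups"])
            d["cohort"] = CohortConfig(**c)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# in-memory measurement (the core loop, shared with the on-disk stages)
# --------------------------------------------------------------------------

def measure_subject(truth_row, geometry, scheme, noise_sigma, seed,
                    rois: ROISet | None = None, s0: float = 1000.0):
    """Run one subject through simulate → OLS fit → ROI → ALPS, in memory.

    The tensor fit is restricted to the labeled (tissue) voxels; the ALPS
    ROIs lie entirely inside them.  Returns an :class:`~dtialps.alps.ALPSResult`.
    """
    if rois is None:
        rois = ROISet.from_geometry(geometry)
    D = build_tensor_field(geometry, truth_row)
    dwi = simulate_dwi(D, scheme, noise_sigma=noise_sigma, seed=seed, s0=s0)
    tf = fit_tensor_ols(dwi, scheme, mask=geometry.tissue_mask)
    maps = compute_scalar_maps(tf, with_color=False)
    return compute_alps(maps, rois, geometry.voxel_size)


def measure_cohort(truth: pd.DataFrame, geometry, scheme, noise_sigma,
                   rois: ROISet | None = None, s0: float = 1000.0
                   ) -> pd.DataFrame:
    """Measured ALPS for every subject of a ground-truth table."""
    if rois is None:
        rois = ROISet.from_geometry(geometry)
    rows = []
    for _, tr in truth.iterrows():
        res = measure_subject(tr, geometry, scheme, noise_sigma,
                              seed=int(tr["seed"]), rois=rois, s0=s0)
        row = {"subject_id": tr["subject_id"],
               "alps_left": res.index_left,
               "alps_right": res.index_right,
               "alps_bilateral": res.index_bilateral}
        for hemi, vals in res.diffusivities.items():
            for k, v in vals.items():
                row[f"{k}_{hemi}"] = v
        for (region, hemi), n in res.voxel_counts.items():
            row[f"nvox_{region}_{hemi}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# on-disk stages
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, files) -> Path:
    manifest = {
        "seed": config.cohort.master_seed,
        "config": config.to_dict(),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def _save_nifti(data, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size))
    # fixed gzip mtime keeps re-runs byte-identical
    nib.save(img, str(path))


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Write the cohort TSV, ground-truth JSON, DWI NIfTIs and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry()
    scheme = config.scheme()
    cohort, truth = generate_cohort(config.cohort)

    files = []
    cohort_path = outdir / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)
    files.append(cohort_path)

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(
        {"tensor_element_order": list(TENSOR_ELEMENT_ORDER),
         "subjects": truth.to_dict(orient="records")},
        indent=2))
    files.append(truth_path)

    bval, bvec = outdir / "dwi.bval", outdir / "dwi.bvec"
    scheme.to_files(bval, bvec)
    files += [bval, bvec]

    for _, tr in truth.iterrows():
        D = build_tensor_field(geometry, tr)
        dwi = simulate_dwi(D, scheme, noise_sigma=config.cohort.noise_sigma,
                           seed=int(tr["seed"]), s0=config.s0)
        p = outdir / f"{tr['subject_id']}_dwi.nii.gz"
        _save_nifti(dwi, config.voxel_size_mm, p)
        files.append(p)

    mask_path = outdir / "tissue_mask.nii.gz"
    _save_nifti(geometry.tissue_mask.astype(np.float32),
                config.voxel_size_mm, mask_path)
    files.append(mask_path)

    roi_path = outdir / "rois.json"
    roi_path.write_text(json.dumps(ROISet.from_geometry(
        geometry, config.roi_diameter_mm).to_records(), indent=2))
    files.append(roi_path)

    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    files.append(cfg_path)
    return _write_manifest(outdir, config, files)


def run_fit(config: RunConfig, workdir: str | Path) -> list[Path]:
    """Fit tensors for every simulated subject; write scalar-map NIfTIs."""
    workdir = Path(workdir)
    scheme = AcquisitionScheme.from_files(workdir / "dwi.bval",
                                          workdir / "dwi.bvec")
    mask = nib.load(str(workdir / "tissue_mask.nii.gz")).get_fdata() > 0.5
    truth = json.loads((workdir / "ground_truth.json").read_text())
    written = []
    total_clamped = 0
    for rec in truth["subjects"]:
        sid = rec["subject_id"]
        dwi = nib.load(str(workdir / f"{sid}_dwi.nii.gz")).get_fdata()
        tf = fit_tensor_ols(dwi, scheme, mask=mask)
        total_clamped += tf.n_clamped
        maps = compute_scalar_maps(tf, with_color=True)
        stack = np.stack([maps.fa, maps.dxx, maps.dyy, maps.dzz], axis=-1)
        p = workdir / f"{sid}_maps.nii.gz"
        _save_nifti(stack, config.voxel_size_mm, p)
        written.append(p)
    sidecar = {
        "volumes": ["FA", "Dxx", "Dyy", "Dzz"],
        "tensor_element_order": list(TENSOR_ELEMENT_ORDER),
        "fit": {"estimator": "OLS", "signal_floor_rel": 1e-6},
    }
    (workdir / "maps.json").write_text(json.dumps(sidecar, indent=2))
    log.info("tensor fits complete; %d clamped signal samples in total",
             total_clamped)
    return written


def run_alps(config: RunConfig, workdir: str | Path) -> Path:
    """Extract ROI diffusivities and ALPS indices; write alps.tsv."""
    workdir = Path(workdir)
    rois = ROISet.from_records(
        json.loads((workdir / "rois.json").read_text()))
    truth = json.loads((workdir / "ground_truth.json").read_text())
    mask = nib.load(str(workdir / "tissue_mask.nii.gz")).get_fdata() > 0.5
    rows = []
    for rec in truth["subjects"]:
        sid = rec["subject_id"]
        stack = nib.load(str(workdir / f"{sid}_maps.nii.gz")).get_fdata()
        maps = ScalarMaps(fa=stack[..., 0], dxx=stack[..., 1],
                          dyy=stack[..., 2], dzz=stack[..., 3], mask=mask)
        res = compute_alps(maps, rois, config.voxel_size_mm)
        row = {"subject_id": sid, "alps_left": res.index_left,
               "alps_right": res.index_right,
               "alps_bilateral": res.index_bilateral}
        for hemi, vals in res.diffusivities.items():
            for k, v in vals.items():
                row[f"{k}_{hemi}"] = v
        for (region, hemi), n in res.voxel_counts.items():
            row[f"nvox_{region}_{hemi}"] = n
        rows.append(row)
    path = workdir / "alps.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_stats(config: RunConfig, workdir: str | Path) -> Path:
    """Group comparisons, partial correlation, VIF; write results + report."""
    workdir = Path(workdir)
    cohort = pd.read_csv(workdir / "cohort.tsv", sep="\t")
    alps_tab = pd.read_csv(workdir / "alps.tsv", sep="\t")
    merged = cohort.merge(alps_tab, on="subject_id", validate="1:1")
    results = analyze_cohort(merged, alpha=config.alpha)
    path = workdir / "results.json"
    path.write_text(json.dumps(results, indent=2))
    (workdir / "report.md").write_text(format_report(merged, results))
    return path


def analyze_cohort(merged: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Statistics battery on a merged cohort+ALPS table (plain-dict output)."""
    alps = merged["alps_bilateral"].to_numpy()
    out: dict = {"alpha": alpha, "n": int(len(merged))}

    covars = merged.loc[:, list(st.COVARIATE_COLUMNS)]
    # VIF screening needs more subjects than covariates (and variation)
    if len(merged) > len(st.COVARIATE_COLUMNS) + 1 \
            and (covars.nunique() > 1).all():
        vif = st.compute_vif(covars)
        out["vif"] = {k: float(v) for k, v in vif.items()}

    levels = [g for g in GROUP_ORDER if (merged["group"] == g).sum() >= 2]
    out["group_summaries"] = {
        g: {"n": int((merged["group"] == g).sum()),
            "mean": float(alps[merged["group"] == g].mean()),
            "sd": float(alps[merged["group"] == g].std(ddof=1))}
        for g in levels
    }
    n_model_cols = len(levels) + len(st.COVARIATE_COLUMNS)  # dummies + const
    if len(levels) >= 2 and len(merged) > n_model_cols:
        out["group_comparisons"] = [
            dataclasses.asdict(c)
            for c in st.all_group_contrasts(alps, merged)
        ]
        for c in out["group_comparisons"]:
            c["pair"] = list(c["pair"])

    dm = merged[merged["group"].isin(["Pre-DM", "T2DM"])]
    if len(dm) > len(st.COVARIATE_COLUMNS) + 2:
        pc = st.partial_correlation(
            dm["alps_bilateral"].to_numpy(), dm["homa_ir"].to_numpy(),
            dm.loc[:, list(st.COVARIATE_COLUMNS)].to_numpy(dtype=float))
        out["alps_homair_partial"] = dataclasses.asdict(pc)
    return out


def format_report(merged: pd.DataFrame, results: dict) -> str:
    """Markdown report mirroring the cohort-profile and group-comparison tables."""
    lines = ["# ALPS analysis report", "",
             f"Subjects: {results['n']}", ""]
    levels = list(results["group_summaries"])
    if len(levels) >= 2:
        lines += ["## Cohort profile", ""]
        cont = [("age", "Age, years"),
                ("education_years", "Education, years"),
                ("homa_ir", "HOMA-IR"), ("fpg_mgdl", "FPG, mg/dL"),
                ("ogtt2h_mgdl", "2-h OGTT, mg/dL"), ("hba1c_pct", "HbA1c, %"),
                ("fazekas_total", "Total Fazekas")]
        lines.append("| Variable | " + " | ".join(levels) + " | p (KW) |")
        lines.append("|---|" + "---|" * (len(levels) + 1))
        for col, label in cont:
            cells, samples = [], []
            for g in levels:
                v = merged.loc[merged["group"] == g, col]
                samples.append(v.to_numpy(dtype=float))
                cells.append(f"{v.mean():.1f} ± {v.std(ddof=1):.1f}")
            _, p = st.kruskal_wallis(*samples)
            lines.append(f"| {label} | " + " | ".join(cells)
                         + f" | {p:.3f} |")
        for col, label in [("sex_female", "Sex (F/M)"),
                           ("hypertension", "Hypertension (y/n)"),
                           ("hyperlipidemia", "Hyperlipidemia (y/n)")]:
            counts = []
            for g in levels[:3]:
                v = merged.loc[merged["group"] == g, col]
                counts.append([int(v.sum()), int((1 - v).sum())])
            table = np.array(counts).T  # 2 x n_groups
            try:
                p = st.fisher_exact(table)
                ptxt = f"{p:.3f}"
            except ValueError:
                ptxt = "n/a"
            cells = [f"{a}/{b}" for a, b in counts]
            lines.append(f"| {label} | " + " | ".join(cells) + f" | {ptxt} |")

    if results.get("group_comparisons"):
        lines += ["", "## ALPS index group comparison", ""]
        lines.append(
            "| Pair | adj. diff | t | p | p (FWE) | Cohen's d | effect |")
        lines.append("|---|---|---|---|---|---|---|")
        for c in results["group_comparisons"]:
            lines.append(
                f"| {c['pair'][0]} vs. {c['pair'][1]} | "
                f"{c['adjusted_difference']:+.3f} | {c['t']:.2f} | "
                f"{c['p_raw']:.4f} | {c['p_fwe']:.4f} | "
                f"{c['cohens_d']:.2f} | {c['effect_category']} |")
    gs = results["group_summaries"]
    if gs:
        lines += ["", "Group means ± SD: " + ", ".join(
            f"{g}: {s['mean']:.2f} ± {s['sd']:.2f} (n={s['n']})"
            for g, s in gs.items())]

    if "alps_homair_partial" in results:
        pc = results["alps_homair_partial"]
        lines += ["", "## ALPS–HOMA-IR partial correlation (Pre-DM + T2DM)",
                  "",
                  f"r = {pc['r']:.3f}, p = {pc['p']:.4f}, df = {pc['df']}"]
    if "vif" in results:
        lines += ["", "## Covariate VIF", ""]
        lines += [f"- {k}: {v:.2f}" for k, v in results["vif"].items()]
    return "\n".join(lines) + "\n"


def run_full(config: RunConfig, workdir: str | Path) -> dict:
    """simulate → fit-dti → alps → stats; returns the results dict."""
    workdir = Path(workdir)
    for stage, fn in [("simulate", run_simulate), ("fit-dti", run_fit),
                      ("alps", run_alps), ("stats", run_stats)]:
        try:
            fn(config, workdir)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return json.loads((workdir / "results.json").read_text())
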