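"""File formats, run configuration, and the end-to-end pipeline.

Volumes and masks travel as NIfTI with voxel spacing in the header plus a
JSON sidecar for acquisition metadata and a CSV for the per-slice tube
current; projections as 16-bit PNG with a JSON sidecar carrying the view,
the row -> z affine and the normalization record (the sidecar is what makes
range conversion possible after the fact); ranges and dose reports as
CSV/JSON.  A pipeline run writes a manifest listing every artifact with its
SHA-256, so re-runs can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CTVolume, LungMask3D, Mask2D, Projection2D, ScanRange, TCMProfile, stage_rng
from .phantom import (
    HumanRangeSimConfig,
    PhantomConfig,
    generate_phantom,
    range_from_mask3d,
    sample_config,
    simulate_human_range,
)

log = logging.getLogger("scoutrange")

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "read_ct",
    "write_volume",
    "write_mask",
    "write_projection",
    "read_projection",
    "run_pipeline",
    "evaluate_cohort",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# volumes


def write_volume(volume: CTVolume, path) -> list[Path]:
    """Write a CT volume as NIfTI plus metadata sidecar and TCM CSV.

    The NIfTI data array keeps the package's (slice, row, col) axis order;
    the header zooms carry the matching (slice_mm, row_mm, col_mm) spacing.
    Returns the written paths.
    """
    import nibabel as nib

    path = Path(path)
    affine = np.diag([volume.slice_spacing, volume.spacing[0], volume.spacing[1], 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    nib.save(img, path)
    written = [path]

    meta = {
        "ctdi_vol": volume.ctdi_vol,
        "kvp": volume.kvp,
        "z0": volume.z0,
        "spacing_row_col_slice_mm": list(volume.spacing),
        "patient_meta": volume.patient_meta,
    }
    meta_path = path.with_name(path.name.split(".")[0] + "_meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(meta_path)

    if volume.tcm is not None:
        tcm_path = path.with_name(path.name.split(".")[0] + "_tcm.csv")
        pd.DataFrame(
            {
                "slice_index": np.arange(len(volume.tcm)),
                "ma": volume.tcm.ma_per_slice,
            }
        ).to_csv(tcm_path, index=False)
        written.append(tcm_path)
    return written


def write_mask(mask: LungMask3D, path) -> Path:
    import nibabel as nib

    path = Path(path)
    affine = np.diag([mask.slice_spacing, mask.spacing[0], mask.spacing[1], 1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), path)
    return path


def _read_nifti_ct(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[1]), float(zooms[2]), float(zooms[0]))
    if any(s <= 0 for s in spacing):
        raise ConfigError(f"{path}: missing or invalid voxel spacing")

    meta_path = path.with_name(path.name.split(".")[0] + "_meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if "spacing_row_col_slice_mm" in meta:
        spacing = tuple(meta["spacing_row_col_slice_mm"])

    tcm = None
    tcm_path = path.with_name(path.name.split(".")[0] + "_tcm.csv")
    if tcm_path.exists():
        tcm = TCMProfile(pd.read_csv(tcm_path)["ma"].to_numpy())

    volume = CTVolume(
        data,
        spacing,
        ctdi_vol=float(meta.get("ctdi_vol", 0.0)),
        kvp=float(meta.get("kvp", 120.0)),
        z0=float(meta.get("z0", 0.0)),
        patient_meta=meta.get("patient_meta", {}),
    )
    if tcm is not None and len(tcm) == volume.n_slices:
        volume.tcm = tcm
    return volume


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ConfigError(f"{path}: no readable DICOM slices")

    uids = sorted({str(ds.SeriesInstanceUID) for ds in slices})
    if len(uids) > 1:
        raise ConfigError(
            f"{path}: directory mixes {len(uids)} series: {', '.join(uids)}"
        )

    # DICOM patient z increases toward the head: superior slice first.
    slices.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise ConfigError(f"{path}: missing PixelSpacing")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(
            float(slices[0].ImagePositionPatient[2])
            - float(slices[1].ImagePositionPatient[2])
        )
    else:
        dz = float(getattr(first, "SliceThickness", 0.0))
    if dz <= 0:
        raise ConfigError(f"{path}: cannot determine slice spacing")

    vol = []
    mas = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol.append(ds.pixel_array.astype(np.float32) * slope + intercept)
        ma = getattr(ds, "XRayTubeCurrent", None)
        mas.append(float(ma) if ma is not None else np.nan)

    ma_arr = np.array(mas)
    if np.isnan(ma_arr).any():
        fallback = float(np.nanmean(ma_arr)) if np.isfinite(ma_arr).any() else 100.0
        warnings.warn(
            "per-slice tube current missing; using a constant profile",
            stacklevel=2,
        )
        ma_arr = np.full(len(slices), fallback)

    voxels = np.clip(np.stack(vol), -1024.0, 3071.0)
    ctdi = float(getattr(first, "CTDIvol", 0.0) or 0.0)
    return CTVolume(
        voxels,
        (row_mm, col_mm, dz),
        ctdi_vol=ctdi,
        kvp=float(getattr(first, "KVP", 120.0) or 120.0),
        tcm=TCMProfile(ma_arr),
        z0=0.0,
        patient_meta={"sex": str(getattr(first, "PatientSex", "unknown") or "unknown")},
    )


def read_ct(path) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Slices are returned most-superior-first; per-slice tube current is
    populated from the DICOM headers (or the TCM CSV sidecar for NIfTI),
    falling back to a constant profile with a warning.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return _read_nifti_ct(path)
    raise ConfigError(f"{path}: expected a NIfTI file or DICOM directory")


# ---------------------------------------------------------------------------
# projections


def write_projection(
    projection: Projection2D, path, mask: Mask2D | None = None
) -> list[Path]:
    """16-bit PNG plus JSON sidecar (view, row -> z affine, normalization)."""
    import imageio.v3 as iio

    path = Path(path)
    pix = projection.pixels.astype(np.float64)
    hi = pix.max() if pix.max() > 0 else 1.0
    iio.imwrite(path, np.round(pix / hi * 65535).astype(np.uint16))
    sidecar = {
        "view": projection.view,
        "z0": projection.z0,
        "dz": projection.dz,
        "png_scale": hi,
        "normalization": projection.normalization,
        "provenance": projection.provenance,
    }
    side_path = path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written = [path, side_path]
    if mask is not None:
        mask_path = path.with_name(path.stem + "_mask.png")
        iio.imwrite(mask_path, (mask.pixels.astype(np.uint16)) * 65535)
        written.append(mask_path)
    return written


def read_projection(path) -> Projection2D:
    import imageio.v3 as iio

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pix = iio.imread(path).astype(np.float64) / 65535.0 * sidecar["png_scale"]
    return Projection2D(
        pix.astype(np.float32),
        view=sidecar["view"],
        z0=sidecar["z0"],
        dz=sidecar["dz"],
        normalization=sidecar["normalization"],
        provenance=sidecar.get("provenance", "summed"),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    outdir: str = "scoutrange_run"
    seed: int = 0
    n_patients: int = 5
    input_volume: str | None = None  # None -> simulate phantoms
    segmenter: str = "classical"  # classical | model
    model_path: str | None = None
    size: int = 256
    min_pixels: int = 50
    margin_voxels: int = 1
    combine_rule: str = "average"
    noise_sd: float | None = None
    pathology_fraction: float | None = None
    scatter_length_mm: float = 30.0
    human: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.segmenter not in ("classical", "model"):
            raise ConfigError(f"unknown segmenter {self.segmenter!r}")
        if self.segmenter == "model" and not self.model_path:
            raise ConfigError("segmenter 'model' requires model_path")
        for key in ("input_volume", "model_path"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{key} does not exist: {val}")
        if self.combine_rule not in ("average", "union", "intersection"):
            raise ConfigError(f"unknown combine rule {self.combine_rule!r}")
        HumanRangeSimConfig(**self.human).validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/ingest -> project -> segment -> range -> dose -> evaluate.

    Writes every intermediate artifact under ``config.outdir`` together
    with a manifest (inputs, parameters, seed, package version, SHA-256 of
    each output).  Deterministic: re-running with the same config and seed
    reproduces the range and dose CSVs byte for byte.
    """
    from .dosimetry import (
        compare_scenarios,
        effective_diameter,
        load_organ_table,
        measure_body_diameters,
        scenario_report,
    )
    from .projection import normalize_resize, project_mask, project_volume
    from .ranges import combine_ranges, mask_to_range, overscan_error, postprocess_mask
    from .segmentation import classical_segment, load_model, predict_mask

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    organs = load_organ_table()
    model = load_model(config.model_path) if config.segmenter == "model" else None

    range_rows: list[dict] = []
    error_rows: list[dict] = []
    dose_rows: list[dict] = []

    def _stage(name):
        stages.append(name)
        log.info("stage: %s", name)

    rng = stage_rng(config.seed, "cohort")
    _stage("simulate" if config.input_volume is None else "ingest")
    patients = []
    for i in range(config.n_patients if config.input_volume is None else 1):
        if config.input_volume is None:
            cfg = sample_config(rng, small=False)
            if config.noise_sd is not None:
                cfg = dataclasses.replace(cfg, noise_sd=config.noise_sd)
            if config.pathology_fraction is not None:
                cfg = dataclasses.replace(
                    cfg, pathology_fraction=config.pathology_fraction
                )
            vol, mask3 = generate_phantom(cfg, seed=int(rng.integers(2**31)))
        else:
            vol = read_ct(config.input_volume)
            mask3 = None
        patients.append((f"P{i:03d}", vol, mask3))

    try:
        for pid, vol, mask3 in patients:
            _run_one(
                pid, vol, mask3, config, model, organs, rng,
                range_rows, error_rows, dose_rows, stages, _stage,
            )
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapper
        raise StageError(f"stage {stages[-1]!r} failed: {exc}") from exc

    _stage("evaluate")
    written = []
    ranges_csv = outdir / "ranges.csv"
    pd.DataFrame(range_rows).to_csv(ranges_csv, index=False, float_format="%.6f")
    written.append(ranges_csv)
    errors_csv = outdir / "errors.csv"
    pd.DataFrame(error_rows).to_csv(errors_csv, index=False, float_format="%.6f")
    written.append(errors_csv)
    if dose_rows:
        doses_csv = outdir / "doses.csv"
        pd.DataFrame(dose_rows).to_csv(doses_csv, index=False, float_format="%.6f")
        written.append(doses_csv)
    if error_rows:
        summary = _summary_frame(pd.DataFrame(error_rows))
        summary_csv = outdir / "summary.csv"
        summary.to_csv(summary_csv, float_format="%.6f")
        written.append(summary_csv)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": _dedupe(stages),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


_PIPELINE_STAGES = ("simulate", "project", "segment", "range", "dose", "evaluate")


def _dedupe(stages):
    seen = []
    for s in stages:
        if s not in seen:
            seen.append(s)
    return seen


def _run_one(pid, vol, mask3, config, model, organs, rng,
             range_rows, error_rows, dose_rows, stages, _stage):
    from .dosimetry import (
        compare_scenarios,
        effective_diameter,
        measure_body_diameters,
        scenario_report,
    )
    from .projection import normalize_resize, project_mask, project_volume
    from .ranges import combine_ranges, mask_to_range, overscan_error, postprocess_mask
    from .segmentation import classical_segment, predict_mask

    _stage("project")
    views = {}
    for view in ("AP", "LAT"):
        proj = project_volume(vol, view)
        proj_n, _ = normalize_resize(proj, None, size=config.size)
        views[view] = proj_n

    _stage("segment")
    pred = {}
    for view, proj_n in views.items():
        if model is not None:
            mask2 = predict_mask(model, proj_n)
        else:
            mask2 = classical_segment(proj_n)
        pred[view] = postprocess_mask(mask2, min_pixels=config.min_pixels)

    _stage("range")
    truth = range_from_mask3d(mask3) if mask3 is not None else None
    selections: dict[str, ScanRange] = {}
    for view, mask2 in pred.items():
        selections[view] = mask_to_range(mask2, margin_voxels=config.margin_voxels)
    both = combine_ranges(selections["AP"], selections["LAT"], rule=config.combine_rule)
    selections["Both"] = both
    if truth is not None:
        human_cfg = HumanRangeSimConfig(**config.human)
        human = simulate_human_range(truth, human_cfg, seed=int(rng.integers(2**31)))
        selections["human"] = human
        selections["exact"] = truth

    for name, sel in selections.items():
        range_rows.append(
            {
                "patient_id": pid,
                "provenance": sel.provenance,
                "selection": name,
                "superior_z": sel.superior_z,
                "inferior_z": sel.inferior_z,
            }
        )
    if truth is not None:
        for name in ("AP", "LAT", "Both", "human"):
            err = overscan_error(selections[name], truth)
            error_rows.append(
                {
                    "patient_id": pid,
                    "provenance": selections[name].provenance,
                    "superior_error_mm": err.superior_error_mm,
                    "inferior_error_mm": err.inferior_error_mm,
                }
            )

    if truth is not None and vol.tcm is not None and vol.ctdi_vol > 0:
        _stage("dose")
        d_ap, d_lat = measure_body_diameters(vol)
        d_eff = effective_diameter(d_ap, d_lat)
        reports = {}
        for name, scen in (("exact", truth), ("human", selections["human"]),
                           ("DL", selections["Both"])):
            reports[name] = scenario_report(
                name, truth, _clip_to_volume(scen, vol), vol, d_eff, organs,
                scatter_length_mm=config.scatter_length_mm,
            )
        comparison = compare_scenarios(reports["exact"], reports["human"], reports["DL"])
        for name, rep in reports.items():
            dose_rows.append(
                {
                    "patient_id": pid,
                    "scenario": name,
                    "scan_length_cm": rep.scan_length_cm,
                    "ssde_mgy": rep.ssde,
                    "dlp_mgy_cm": rep.dlp,
                    "ed_msv": rep.ed,
                    "ed_reduction_percent": (
                        comparison.ed_reduction_percent if name == "DL" else 0.0
                    ),
                }
            )


def _clip_to_volume(scan_range: ScanRange, vol: CTVolume) -> ScanRange:
    z_min = vol.z0
    z_max = vol.z0 + (vol.n_slices - 1) * vol.slice_spacing
    return ScanRange(
        max(scan_range.superior_z, z_min),
        min(scan_range.inferior_z, z_max),
        provenance=scan_range.provenance,
    )


def _summary_frame(errors: pd.DataFrame) -> pd.DataFrame:
    from .core import OverscanReport
    from .ranges import summarize_cohort

    frames = []
    for prov, group in errors.groupby("provenance"):
        reports = [
            OverscanReport(r.superior_error_mm, r.inferior_error_mm)
            for r in group.itertuples()
        ]
        summary = summarize_cohort(reports)
        summary.insert(0, "provenance", prov)
        frames.append(summary.reset_index())
    return pd.concat(frames, ignore_index=True).set_index(["provenance", "direction"])


def evaluate_cohort(ranges_csv, truth_csv, outdir, make_plots: bool = True) -> pd.DataFrame:
    """Per-provenance error summaries (and box plots) for a cohort.

    ``ranges_csv`` holds one selected range per (patient, provenance);
    ``truth_csv`` one exact range per patient.  Patient ids must match.
    """
    from .core import OverscanReport
    from .ranges import summarize_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ranges = pd.read_csv(ranges_csv)
    truth = pd.read_csv(truth_csv)
    missing = set(ranges.patient_id) ^ set(truth.patient_id)
    if missing:
        raise ConfigError(f"patient ids do not match: {sorted(missing)[:5]} ...")

    truth_map = {
        r.patient_id: (r.superior_z, r.inferior_z) for r in truth.itertuples()
    }
    rows = []
    for r in ranges.itertuples():
        t_sup, t_inf = truth_map[r.patient_id]
        rows.append(
            {
                "patient_id": r.patient_id,
                "provenance": r.provenance,
                "superior_error_mm": t_sup - r.superior_z,
                "inferior_error_mm": r.inferior_z - t_inf,
            }
        )
    errors = pd.DataFrame(rows)
    summary = _summary_frame(errors)
    summary.to_csv(outdir / "cohort_summary.csv", float_format="%.6f")

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, direction in zip(axes, ("superior_error_mm", "inferior_error_mm")):
            data = [g[direction].to_numpy() for _, g in errors.groupby("provenance")]
            labels = [p for p, _ in errors.groupby("provenance")]
            ax.boxplot(data, tick_labels=labels)
            ax.axhline(0.0, color="k", lw=0.8)
            ax.set_title(direction.replace("_", " "))
            ax.set_ylabel("error (mm)")
        fig.tight_layout()
        fig.savefig(outdir / "cohort_errors.png", dpi=120)
        plt.close(fig)
    return summary
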