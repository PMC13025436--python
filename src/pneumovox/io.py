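"""Reading and writing cases, observation tables and fit reports.

Volumes travel as NIfTI (one file per field: CT, dose, lungs, PTV,
infiltrate); observation tables as CSV with a JSON metadata sidecar holding
the binning scheme, per-patient volumes and QC counts.  An optional DICOM
RT Dose reader applies the DoseGridScaling factor.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import ImageGrid, PatientCase
from .phantom import GroundTruth
from .volumetry import BinningScheme, ObservationTable

__all__ = [
    "save_case",
    "load_case",
    "read_dicom_rtdose",
    "write_observations",
    "read_observations",
    "fit_report_dict",
]

_FIELDS = ("ct", "dose", "lungs", "ptv", "inf")


def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_case(case: PatientCase, out_dir: str | Path, truth: GroundTruth | None = None) -> Path:
    """Write one case as ``<id>_{ct,dose,lungs,ptv,inf}.nii.gz`` + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = case.patient_id
    vols = {
        "ct": case.ct.values.astype(np.float32),
        "dose": case.dose.values.astype(np.float32),
        "lungs": case.lungs_mask.astype(np.uint8),
        "ptv": case.ptv_mask.astype(np.uint8),
        "inf": case.infiltrate_mask.astype(np.uint8),
    }
    aff = _affine(case.ct)
    for name, arr in vols.items():
        nib.save(nib.Nifti1Image(arr, aff), out / f"{pid}_{name}.nii.gz")
    meta = {"patient_id": pid, "grade": case.grade, "meta": case.meta}
    if truth is not None:
        meta["ground_truth"] = _jsonable(dataclasses.asdict(truth))
    (out / f"{pid}_meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_case(case_dir: str | Path, patient_id: str) -> PatientCase:
    d = Path(case_dir)
    imgs = {}
    for name in _FIELDS:
        img = nib.load(d / f"{patient_id}_{name}.nii.gz")
        imgs[name] = img
    spacing = tuple(float(s) for s in imgs["ct"].header.get_zooms()[:3])
    origin = tuple(float(o) for o in imgs["ct"].affine[:3, 3])
    meta_path = d / f"{patient_id}_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    get = lambda n: np.asarray(imgs[n].dataobj)  # noqa: E731
    return PatientCase(
        patient_id=patient_id,
        grade=int(meta.get("grade", 0)),
        ct=ImageGrid(get("ct").astype(float), spacing, origin),
        dose=ImageGrid(get("dose").astype(float), spacing, origin),
        lungs_mask=get("lungs") > 0,
        ptv_mask=get("ptv") > 0,
        infiltrate_mask=get("inf") > 0,
        meta=meta.get("meta", {}),
    )


def read_dicom_rtdose(path: str | Path) -> ImageGrid:
    """Read a DICOM RT Dose file into Gy, applying DoseGridScaling."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pixel_array is (frames, rows, cols); reorder to (x, y, z)
    arr = ds.pixel_array.astype(float) * scaling
    arr = np.transpose(arr, (2, 1, 0))
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = getattr(ds, "GridFrameOffsetVector", None)
    dz = float(offsets[1] - offsets[0]) if offsets is not None and len(offsets) > 1 else 1.0
    origin = tuple(float(v) for v in getattr(ds, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    return ImageGrid(arr, (dx, dy, dz), origin)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_observations(table: ObservationTable, csv_path: str | Path) -> None:
    """CSV (patient_id, dose_step, dose_bin, hu_bin, pv, weight) + sidecar JSON."""
    csv_path = Path(csv_path)
    table.data.to_csv(csv_path, index=False)
    sidecar = {
        "scheme": dataclasses.asdict(table.scheme),
        "lung_volume_ml": table.lung_volume_ml,
        "step_lung_volume_ml": {k: v.tolist() for k, v in table.step_lung_volume_ml.items()},
        "grades": table.grades,
        "qc": table.qc,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(_jsonable(sidecar)))


def read_observations(csv_path: str | Path) -> ObservationTable:
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    scheme_kwargs = side["scheme"]
    for key in ("dose_range", "hu_range"):
        scheme_kwargs[key] = tuple(scheme_kwargs[key])
    return ObservationTable(
        data=data,
        scheme=BinningScheme(**scheme_kwargs),
        lung_volume_ml={k: float(v) for k, v in side["lung_volume_ml"].items()},
        step_lung_volume_ml={k: np.asarray(v) for k, v in side["step_lung_volume_ml"].items()},
        grades={k: int(v) for k, v in side["grades"].items()},
        qc=side.get("qc", {}),
    )


def fit_report_dict(fit) -> dict:
    """JSON-ready summary of a MixedFit (effects, variances, tests, AIC)."""
    return _jsonable(
        {
            "dose_form": fit.spec.dose_form,
            "intercept": fit.intercept,
            "alpha": fit.alpha,
            "alpha_se": fit.alpha_se,
            "alpha_ci": fit.alpha_ci,
            "beta": fit.beta,
            "beta_se": fit.beta_se,
            "beta_ci": fit.beta_ci,
            "sigma2_u": fit.sigma2_u,
            "sigma2_e": fit.sigma2_e,
            "aic": fit.aic,
            "aic_reml": fit.aic_reml,
            "loglik_reml": fit.engine.loglik,
            "loglik_ml": fit.engine.loglik_ml,
            "tests": fit.tests,
            "monotone_alpha": fit.monotone_alpha,
            "ddf_method": fit.engine.ddf_method,
            "n_obs_used": fit.engine.n_obs,
            "n_random_groups": fit.engine.n_groups,
            "slope": fit.slope,
            "slope_se": fit.slope_se,
            "slope_p": fit.slope_p,
        }
    )
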