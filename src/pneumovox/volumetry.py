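"""From aligned CT / dose / structures to the dose-density observation table.

The analysis endpoint is the *partial infiltrate volume* pv(s, h): the volume
of infiltrated lung (outside the PTV) whose CT density falls in the 50 HU bin
h and whose dose falls in the 0.1 Gy step s, divided by the total
lung-outside-PTV volume receiving dose in step s.  Each cell also carries a
weight: the lung-outside-PTV volume in that (step, HU bin) cell normalized by
the patient's total lung-outside-PTV volume, so weights partition the lung
volume over the dose x density grid.

Structure algebra follows the clinical naming: INF_PTV is infiltrate minus
PTV, Lungs_PTV is lung minus PTV and Lungs_PTV_INF is lung minus PTV minus
infiltrate; the latter two-part split partitions Lungs_PTV exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ImageGrid, PatientCase

__all__ = [
    "BinningScheme",
    "ObservationTable",
    "DoseBinFeatures",
    "DoseMetrics",
    "derive_structures",
    "downsample_case",
    "quantize_dose",
    "compute_observations",
    "concat_observations",
    "dose_bin_features",
    "dose_metrics",
]

# guard against float representation error in floor(x / step): a value that is
# exactly on a bin edge in real arithmetic must land in the upper bin
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class BinningScheme:
    """Joint dose / density binning.

    Defaults give 550 dose steps of 0.1 Gy on [0, 55) Gy, 11 dose bins of
    5 Gy, and 22 density bins of 50 HU on [-1000, 100) HU.  All intervals are
    half-open.  Voxels with dose >= the top of the dose range are excluded
    from the model grid and counted as spill-over unless ``top_bin_clamp``.
    """

    dose_step: float = 0.1
    dose_bin_width: float = 5.0
    dose_range: tuple[float, float] = (0.0, 55.0)
    hu_bin_width: float = 50.0
    hu_range: tuple[float, float] = (-1000.0, 100.0)
    top_bin_clamp: bool = False

    def __post_init__(self) -> None:
        for width, lo, hi, name in (
            (self.dose_step, *self.dose_range, "dose_range/dose_step"),
            (self.dose_bin_width, *self.dose_range, "dose_range/dose_bin_width"),
            (self.hu_bin_width, *self.hu_range, "hu_range/hu_bin_width"),
        ):
            if width <= 0:
                raise ValueError(f"bin width must be positive in {name}")
            n = (hi - lo) / width
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name}: width {width} does not divide range [{lo}, {hi})")
        n = self.dose_bin_width / self.dose_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dose_bin_width must be a multiple of dose_step")

    @property
    def n_dose_steps(self) -> int:
        return round((self.dose_range[1] - self.dose_range[0]) / self.dose_step)

    @property
    def n_dose_bins(self) -> int:
        return round((self.dose_range[1] - self.dose_range[0]) / self.dose_bin_width)

    @property
    def n_hu_bins(self) -> int:
        return round((self.hu_range[1] - self.hu_range[0]) / self.hu_bin_width)

    @property
    def steps_per_bin(self) -> int:
        return round(self.dose_bin_width / self.dose_step)

    def dose_step_midpoints(self) -> np.ndarray:
        """Physical dose (Gy) at the midpoint of every 0.1 Gy step."""
        lo = self.dose_range[0]
        return lo + (np.arange(self.n_dose_steps) + 0.5) * self.dose_step

    def hu_bin_edges(self) -> np.ndarray:
        lo, hi = self.hu_range
        return np.linspace(lo, hi, self.n_hu_bins + 1)

    def hu_bin_midpoints(self) -> np.ndarray:
        e = self.hu_bin_edges()
        return 0.5 * (e[:-1] + e[1:])

    def dose_bin_edges(self) -> np.ndarray:
        lo, hi = self.dose_range
        return np.linspace(lo, hi, self.n_dose_bins + 1)

    def hu_bin_index(self, hu: np.ndarray) -> np.ndarray:
        """Half-open 50 HU bin index; -1 where outside the density range."""
        hu = np.asarray(hu, dtype=float)
        idx = np.floor((hu - self.hu_range[0]) / self.hu_bin_width + _EDGE_EPS).astype(int)
        idx[(idx < 0) | (idx >= self.n_hu_bins)] = -1
        return idx


@dataclass
class ObservationTable:
    """Full-grid observation table: one row per (patient, dose step, HU bin).

    ``data`` columns: patient_id, dose_step, dose_bin, hu_bin, pv, weight.
    Zero-lung cells are retained with pv = 0 and weight = 0 so the row count
    is exactly n_patients x n_dose_steps x n_hu_bins.  Auxiliary per-patient
    arrays carry the total lung-outside-PTV volume (mL) and the per-dose-step
    lung volume (mL, all densities) needed to reconstruct absolute volumes.
    """

    data: pd.DataFrame
    scheme: BinningScheme
    lung_volume_ml: dict[str, float]
    step_lung_volume_ml: dict[str, np.ndarray]
    grades: dict[str, int]
    qc: dict[str, dict] = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(self.lung_volume_ml.keys())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DoseBinFeatures:
    """Per-patient infiltrate load per 5 Gy dose bin (length-11 vectors).

    ``values`` is a patients x n_dose_bins frame; bins without any lung
    volume are NaN and flagged in ``missing``.
    """

    values: pd.DataFrame
    grades: dict[str, int]
    missing: pd.DataFrame

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class DoseMetrics:
    """Standard dosimetric summary over lung-outside-PTV."""

    mean_lung_dose: float
    v5: float
    v20: float
    mean_infiltrate_hu: float


def derive_structures(case: PatientCase) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clinical structure algebra.

    Returns ``(inf_ptv, lungs_ptv, lungs_ptv_inf)`` where inf_ptv is
    infiltrate within lung minus PTV, lungs_ptv is lung minus PTV and
    lungs_ptv_inf is lung minus PTV minus infiltrate.  inf_ptv and
    lungs_ptv_inf partition lungs_ptv voxel-by-voxel.
    """
    if not case.lungs_mask.any():
        raise ValueError("empty lungs mask")
    lungs_ptv = case.lungs_mask & ~case.ptv_mask
    inf_ptv = case.infiltrate_mask & lungs_ptv
    lungs_ptv_inf = lungs_ptv & ~case.infiltrate_mask
    return inf_ptv, lungs_ptv, lungs_ptv_inf


def _overlap_matrix(n_fine: int, n_coarse: int) -> np.ndarray:
    """Fractional-overlap operator along one axis.

    ``M[j, i]`` is the length (in fine-voxel units) of the overlap between
    coarse voxel j (spanning ``[j*r, (j+1)*r)`` with ``r = n_fine/n_coarse``)
    and fine voxel i.  Row sums equal r; no cropping occurs even when r is
    not an integer.
    """
    r = n_fine / n_coarse
    j = np.arange(n_coarse)[:, None]
    i = np.arange(n_fine)[None, :]
    lo = np.maximum(j * r, i)
    hi = np.minimum((j + 1) * r, i + 1)
    return np.clip(hi - lo, 0.0, None)


def _block_average(values: np.ndarray, target_dims: tuple[int, int, int]) -> np.ndarray:
    out = np.asarray(values, dtype=float)
    for axis in range(3):
        m = _overlap_matrix(out.shape[axis], target_dims[axis])
        out = np.moveaxis(np.tensordot(m, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    scale = np.prod([values.shape[a] / target_dims[a] for a in range(3)])
    return out / scale


def _nearest_neighbor(values: np.ndarray, target_dims: tuple[int, int, int]) -> np.ndarray:
    idx = [
        np.minimum(
            (((np.arange(target_dims[a]) + 0.5) * values.shape[a] / target_dims[a])).astype(int),
            values.shape[a] - 1,
        )
        for a in range(3)
    ]
    return values[np.ix_(*idx)]


def downsample_case(
    case: PatientCase,
    target_dims: tuple[int, int, int],
    method: str = "fractional",
    mask_threshold: float = 0.5,
) -> PatientCase:
    """Down-sample a case onto a coarser grid, preserving physical extent.

    HU and dose are block-averaged with exact fractional-overlap weighting;
    a coarse mask voxel is set when the fine mask covers more than
    ``mask_threshold`` of its volume (the >50% coverage rule).  With
    ``method='nearest'`` both scalars and masks use nearest-neighbor
    sampling instead (dialect for pipelines that interpolate binary masks).
    """
    src = case.ct.dims
    if any(t > s for t, s in zip(target_dims, src)):
        raise ValueError(f"target dims {target_dims} exceed source dims {src}")
    ratios = [s / t for s, t in zip(src, target_dims)]
    spacing = tuple(sp * r for sp, r in zip(case.ct.spacing, ratios))
    origin = tuple(o + (r - 1) / 2 * sp for o, r, sp in zip(case.ct.origin, ratios, case.ct.spacing))

    if method == "fractional":
        scalar = lambda v: _block_average(v, target_dims)  # noqa: E731
        binary = lambda m: _block_average(m.astype(float), target_dims) > mask_threshold  # noqa: E731
    elif method == "nearest":
        scalar = lambda v: _nearest_neighbor(np.asarray(v, dtype=float), target_dims)  # noqa: E731
        binary = lambda m: _nearest_neighbor(m, target_dims)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")

    ct = ImageGrid(scalar(case.ct.values), spacing, origin)
    dose = ImageGrid(scalar(case.dose.values), spacing, origin)
    return PatientCase(
        patient_id=case.patient_id,
        grade=case.grade,
        ct=ct,
        dose=dose,
        lungs_mask=binary(case.lungs_mask),
        ptv_mask=binary(case.ptv_mask),
        infiltrate_mask=binary(case.infiltrate_mask),
        meta=dict(case.meta),
    )


def quantize_dose(dose: ImageGrid | np.ndarray, dose_step: float = 0.1) -> np.ndarray:
    """Integer dose-step indices: ``floor(dose / dose_step)`` per voxel.

    Intervals are half-open [k*step, (k+1)*step).  Negative dose is an error.
    """
    values = dose.values if isinstance(dose, ImageGrid) else np.asarray(dose)
    if np.any(values < 0):
        raise ValueError("negative dose values")
    return np.floor(values / dose_step + _EDGE_EPS).astype(np.int64)


def compute_observations(case: PatientCase, scheme: BinningScheme | None = None) -> ObservationTable:
    """Build the full (dose step x HU bin) observation grid for one patient.

    For every cell: ``pv`` = infiltrate volume with HU in the bin and dose in
    the step, divided by the lung-outside-PTV volume in that dose step (all
    densities); ``weight`` = lung-outside-PTV volume in the cell divided by
    the patient's total lung-outside-PTV volume.  Voxels with HU outside the
    density range (dense vessels, air artifacts) are excluded from both the
    infiltrate numerator and the weight partition; voxels with dose at or
    above the top of the dose range are excluded as spill-over (or clamped
    into the top bin when the scheme says so).  QC counts record both.
    """
    scheme = scheme or BinningScheme()
    inf_ptv, lungs_ptv, _ = derive_structures(case)
    if not lungs_ptv.any():
        raise ValueError("no lung voxels outside the PTV")

    vox_ml = case.ct.voxel_volume_ml
    dose = case.dose.values[lungs_ptv]
    hu = case.ct.values[lungs_ptv]
    inf = case.infiltrate_mask[lungs_ptv]

    n_steps, n_hu = scheme.n_dose_steps, scheme.n_hu_bins
    step = quantize_dose(dose - scheme.dose_range[0], scheme.dose_step)
    spill = step >= n_steps
    if scheme.top_bin_clamp:
        step = np.minimum(step, n_steps - 1)
        in_dose = np.ones_like(spill)
    else:
        in_dose = ~spill
    hu_bin = scheme.hu_bin_index(hu)
    in_hu = hu_bin >= 0

    v_p = lungs_ptv.sum() * vox_ml
    # per-step lung volume over all densities (the pv denominator)
    step_lung = np.bincount(step[in_dose], minlength=n_steps).astype(float) * vox_ml

    cell = step * n_hu + hu_bin
    keep = in_dose & in_hu
    lung_cell = np.bincount(cell[keep], minlength=n_steps * n_hu).astype(float) * vox_ml
    inf_cell = np.bincount(cell[keep & inf], minlength=n_steps * n_hu).astype(float) * vox_ml

    denom = np.repeat(step_lung, n_hu)
    with np.errstate(divide="ignore", invalid="ignore"):
        pv = np.where(denom > 0, inf_cell / denom, 0.0)
    weight = lung_cell / v_p

    steps_idx = np.repeat(np.arange(n_steps), n_hu)
    data = pd.DataFrame(
        {
            "patient_id": case.patient_id,
            "dose_step": steps_idx,
            "dose_bin": steps_idx // scheme.steps_per_bin,
            "hu_bin": np.tile(np.arange(n_hu), n_steps),
            "pv": pv,
            "weight": weight,
        }
    )
    qc = {
        "spill_dose_voxels": int(spill.sum()),
        "excluded_hu_voxels": int((~in_hu & in_dose).sum()),
        "hu_below_range_voxels": int((hu < scheme.hu_range[0])[in_dose].sum()),
        "lung_voxels": int(lungs_ptv.sum()),
        "infiltrate_voxels": int(inf.sum()),
    }
    return ObservationTable(
        data=data,
        scheme=scheme,
        lung_volume_ml={case.patient_id: float(v_p)},
        step_lung_volume_ml={case.patient_id: step_lung},
        grades={case.patient_id: case.grade},
        qc={case.patient_id: qc},
    )


def concat_observations(tables: list[ObservationTable]) -> ObservationTable:
    """Stack per-patient tables into one cohort table (schemes must match)."""
    if not tables:
        raise ValueError("no tables to concatenate")
    scheme = tables[0].scheme
    if any(t.scheme != scheme for t in tables):
        raise ValueError("all tables must share one binning scheme")
    out = ObservationTable(
        data=pd.concat([t.data for t in tables], ignore_index=True),
        scheme=scheme,
        lung_volume_ml={},
        step_lung_volume_ml={},
        grades={},
        qc={},
    )
    for t in tables:
        out.lung_volume_ml.update(t.lung_volume_ml)
        out.step_lung_volume_ml.update(t.step_lung_volume_ml)
        out.grades.update(t.grades)
        out.qc.update(t.qc)
    return out


def dose_bin_features(table: ObservationTable) -> DoseBinFeatures:
    """Accumulate infiltrate load per 5 Gy dose bin over all density strata.

    feature(d) = sum over the bin's dose steps and HU bins of infiltrate
    volume, divided by the lung-outside-PTV volume over the same steps.
    Dose bins with no lung volume yield NaN and are flagged.
    """
    scheme = table.scheme
    n_bins, spb, n_hu = scheme.n_dose_bins, scheme.steps_per_bin, scheme.n_hu_bins
    rows, missing = {}, {}
    for pid in table.patients:
        sub = table.data[table.data["patient_id"] == pid]
        step_lung = table.step_lung_volume_ml[pid]
        # pv * per-step lung volume reconstructs the infiltrate volume exactly
        inf_vol = (sub["pv"].to_numpy() * step_lung[sub["dose_step"].to_numpy()]).reshape(-1, n_hu).sum(axis=1)
        inf_per_bin = inf_vol.reshape(n_bins, spb).sum(axis=1)
        lung_per_bin = step_lung.reshape(n_bins, spb).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            feat = np.where(lung_per_bin > 0, inf_per_bin / np.where(lung_per_bin > 0, lung_per_bin, 1.0), np.nan)
        rows[pid] = feat
        missing[pid] = lung_per_bin <= 0
    values = pd.DataFrame.from_dict(rows, orient="index", columns=range(n_bins))
    miss = pd.DataFrame.from_dict(missing, orient="index", columns=range(n_bins))
    return DoseBinFeatures(values=values, grades=dict(table.grades), missing=miss)


def dose_metrics(case: PatientCase) -> DoseMetrics:
    """Mean lung dose, V5, V20 over lung-outside-PTV and mean infiltrate HU."""
    inf_ptv, lungs_ptv, _ = derive_structures(case)
    if not lungs_ptv.any():
        raise ValueError("no lung voxels outside the PTV")
    dose = case.dose.values[lungs_ptv]
    mld = float(dose.mean())
    v5 = float((dose >= 5.0).mean() * 100.0)
    v20 = float((dose >= 20.0).mean() * 100.0)
    mean_hu = float(case.ct.values[inf_ptv].mean()) if inf_ptv.any() else float("nan")
    return DoseMetrics(mean_lung_dose=mld, v5=v5, v20=v20, mean_infiltrate_hu=mean_hu)
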