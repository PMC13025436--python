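"""Axis-aligned image grids and the per-patient case container.

All volumes in one case live on a single grid (voxel-center convention,
0-based indices). CT values are Hounsfield units, dose is physical dose in
Gy, structures are boolean masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageGrid", "PatientCase"]


@dataclass
class ImageGrid:
    """A 3-D scalar field on a regular axis-aligned grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field (HU or Gy).
    spacing : tuple of float
        Voxel spacing in mm per axis; must be positive.
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D field, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0

    def like(self, values: np.ndarray) -> "ImageGrid":
        """A new field with the same geometry."""
        return ImageGrid(values, self.spacing, self.origin)


@dataclass
class PatientCase:
    """One patient's co-registered CT, dose and structure set.

    The infiltrate mask is clipped to the lungs on construction so that
    ``infiltrate_mask <= lungs_mask`` always holds.
    """

    patient_id: str
    grade: int
    ct: ImageGrid
    dose: ImageGrid
    lungs_mask: np.ndarray
    ptv_mask: np.ndarray
    infiltrate_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = self.ct.dims
        for name in ("lungs_mask", "ptv_mask", "infiltrate_mask"):
            m = np.asarray(getattr(self, name))
            if m.shape != dims:
                raise ValueError(f"{name} shape {m.shape} != CT dims {dims}")
            setattr(self, name, m.astype(bool))
        if self.dose.dims != dims:
            raise ValueError(f"dose dims {self.dose.dims} != CT dims {dims}")
        self.infiltrate_mask = self.infiltrate_mask & self.lungs_mask

    def with_grids(self, **kwargs) -> "PatientCase":
        return replace(self, **kwargs)
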