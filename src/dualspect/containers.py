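"""In-memory containers shared by every stage of the pipeline.

Conventions
-----------
Volumes are float32 arrays of shape ``(nx, ny, nz)`` with isotropic voxels:
axis 0 runs right-to-left, axis 1 posterior-to-anterior, axis 2
inferior-to-superior (axial slices are ``vol[:, :, k]``).  Projection stacks
are ``(n_views, nu, nz)`` where ``nu`` is the transaxial detector bin and
``nz`` the axial bin.  All lengths are millimetres, all attenuation
coefficients 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ActivityVolume",
    "AttenuationMap",
    "ProjectionSet",
]


@dataclass
class ActivityVolume:
    """Non-negative emission density of one isotope on a regular grid."""

    values: np.ndarray          # (nx, ny, nz) float32, >= 0
    voxel_mm: float
    isotope: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(
                f"activity volume must be 3-D, got {self.values.ndim} axes"
            )
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def total(self) -> float:
        return float(self.values.sum(dtype=np.float64))

    def copy_with(self, values: np.ndarray) -> "ActivityVolume":
        return replace(self, values=np.asarray(values, dtype=np.float32))


@dataclass
class AttenuationMap:
    """Linear attenuation coefficients plus the material labels behind them.

    ``mu`` holds the coefficients at ``reference_kev``; ``labels`` carries a
    small-integer material id per voxel so the map can be rescaled to any
    photon energy through the material table.
    """

    mu: np.ndarray              # (nx, ny, nz) float32, 1/cm
    voxel_mm: float
    reference_kev: float
    labels: np.ndarray | None = None   # same shape, small ints
    materials: tuple[str, ...] = ()    # material name per label id

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float32)
        if self.mu.ndim != 3:
            raise ValueError(f"attenuation map must be 3-D, got {self.mu.ndim} axes")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.mu.shape:
                raise ValueError("label grid shape must match mu grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu.shape


@dataclass
class ProjectionSet:
    """Stack of 2-D detector views plus the geometry they were acquired in."""

    data: np.ndarray            # (n_views, nu, nz) float32
    angles_deg: np.ndarray      # (n_views,)
    orbit_radius_mm: float
    pixel_mm: float
    window_center_kev: float | None = None
    window_width_frac: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"projection stack must be 3-D, got {self.data.ndim} axes")
        if self.data.shape[0] != self.angles_deg.shape[0]:
            raise ValueError(
                f"view count mismatch: {self.data.shape[0]} views in stack, "
                f"{self.angles_deg.shape[0]} angles"
            )

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    def total(self) -> float:
        return float(self.data.sum(dtype=np.float64))

    def copy_with(self, data: np.ndarray) -> "ProjectionSet":
        return replace(self, data=np.asarray(data, dtype=np.float32))
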