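"""Synthetic prosthesis phantom: titanium nail in a bone analog in water.

The phantom emulates an intramedullary-nail fixation test object: a
titanium-alloy rod (the nail) inside a tubular foam-cortical-shell bone
analog with a water-filled medullary canal, immersed in a water cylinder
(the phantom case). An optional transverse fracture gap interrupts the bone
shell while the nail bridges it. The cylinder axis lies along x, parallel
to the detector rows and perpendicular to the source sweep, so metal
streaks spread along the sweep (v) direction of the projections.

Voxels store per-material volume fractions (titanium alloy, water, foam
cortical shell); boundary voxels carry partial fractions computed by
in-plane supersampling, so analytic volumes are matched to sub-voxel
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomConfig", "VoxelPhantom", "build_phantom", "MATERIAL_ORDER"]

# Canonical material-channel order used by every downstream stage.
MATERIAL_ORDER = ("titanium_alloy", "water", "foam_cortical_shell")


@dataclass(frozen=True)
class PhantomConfig:
    """Desk-scale prosthesis phantom parameters (mm).

    The defaults shrink the clinical phi-200 mm water case onto a 64^3 grid
    at 3.5 mm voxels while keeping the nested structure: implant radius <
    bone inner radius < bone outer radius < case radius.
    """

    grid_shape: tuple = (64, 64, 64)  # (nz, ny, nx)
    voxel_size_mm: float = 3.5
    case_radius_mm: float = 100.0
    bone_outer_radius_mm: float = 22.0
    bone_inner_radius_mm: float = 14.0
    implant_radius_mm: float = 10.0
    bone_length_mm: float = 160.0
    fracture_gap_mm: float = 7.0  # 0 disables the gap
    fracture_center_mm: float = 25.0  # along x, offset from phantom center
    supersample: int = 4

    def __post_init__(self):
        r = (
            self.implant_radius_mm,
            self.bone_inner_radius_mm,
            self.bone_outer_radius_mm,
            self.case_radius_mm,
        )
        if any(x < 0 for x in r) or self.fracture_gap_mm < 0:
            raise ValueError("radii and gap must be non-negative")
        if not (r[0] <= r[1] <= r[2] <= r[3]):
            raise ValueError(
                "radii must be nested: implant <= bone inner <= bone outer <= case"
            )
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class VoxelPhantom:
    """Per-voxel volume fractions of the three basis materials.

    ``fractions`` has shape (3, nz, ny, nx) ordered as MATERIAL_ORDER; each
    fraction lies in [0, 1] and the per-voxel sum is <= 1 (remainder air).
    The grid is centered on the isocenter with voxel centers at
    half-integer offsets from the grid center.
    """

    fractions: np.ndarray
    voxel_size_mm: float

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.fractions.ndim != 4 or self.fractions.shape[0] != 3:
            raise ValueError("fractions must have shape (3, nz, ny, nx)")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValueError("volume fractions must lie in [0, 1]")
        if np.any(self.fractions.sum(axis=0) > 1 + 1e-9):
            raise ValueError("per-voxel fraction sum exceeds 1")

    @property
    def grid_shape(self) -> tuple:
        return self.fractions.shape[1:]

    def material_volume_mm3(self, channel: int) -> float:
        """Total volume of one material channel (mm^3)."""
        return float(self.fractions[channel].sum() * self.voxel_size_mm**3)

    def axis_coords_mm(self):
        """World coordinates (z, y, x) of voxel centers."""
        out = []
        for n in self.grid_shape:
            out.append((np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm)
        return tuple(out)


def _disc_coverage(yy: np.ndarray, zz: np.ndarray, radius: float, step: float, ss: int) -> np.ndarray:
    """Fractional in-plane coverage of a disc y^2+z^2<=r^2 per voxel (supersampled)."""
    if radius <= 0:
        return np.zeros_like(yy)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    cov = np.zeros_like(yy)
    for oy in offs:
        for oz in offs:
            cov += (yy + oy * step) ** 2 + (zz[:, None] + oz * step) ** 2 <= radius**2
    return cov / ss**2


def build_phantom(config: PhantomConfig = PhantomConfig()) -> VoxelPhantom:
    """Voxelize the prosthesis phantom from a geometric configuration.

    Deterministic for a given configuration. With all radii zero the
    phantom is empty; with only the case radius set it is a pure water
    cylinder.
    """
    nz, ny, nx = config.grid_shape
    step = config.voxel_size_mm
    z = (np.arange(nz) - (nz - 1) / 2.0) * step
    y = (np.arange(ny) - (ny - 1) / 2.0) * step
    x = (np.arange(nx) - (nx - 1) / 2.0) * step

    yy = np.broadcast_to(y[None, :], (nz, ny)).copy()
    zz = z

    ss = config.supersample
    c_imp = _disc_coverage(yy, zz, config.implant_radius_mm, step, ss)
    c_binn = _disc_coverage(yy, zz, config.bone_inner_radius_mm, step, ss)
    c_bout = _disc_coverage(yy, zz, config.bone_outer_radius_mm, step, ss)
    c_case = _disc_coverage(yy, zz, config.case_radius_mm, step, ss)

    # Nested discs => coverages are ordered, differences are valid fractions.
    shell_2d = c_bout - c_binn
    water_2d = (c_case - c_bout) + (c_binn - c_imp)

    fractions = np.zeros((3, nz, ny, nx))

    half_len = config.bone_length_mm / 2.0
    in_rod = np.abs(x) <= half_len
    in_bone = in_rod.copy()
    if config.fracture_gap_mm > 0:
        gap_lo = config.fracture_center_mm - config.fracture_gap_mm / 2.0
        gap_hi = config.fracture_center_mm + config.fracture_gap_mm / 2.0
        in_bone &= ~((x >= gap_lo) & (x <= gap_hi))

    # titanium nail: continuous over the rod extent (bridges the fracture)
    fractions[0] = c_imp[:, :, None] * in_rod[None, None, :]
    # bone shell: interrupted by the fracture gap
    fractions[2] = shell_2d[:, :, None] * in_bone[None, None, :]
    # water: case fill, medullary canal, gap fill, and rod-absent sections
    case_3d = np.broadcast_to(c_case[:, :, None], (nz, ny, nx))
    fractions[1] = case_3d - fractions[0] - fractions[2]

    return VoxelPhantom(fractions=np.clip(fractions, 0.0, 1.0), voxel_size_mm=step)
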