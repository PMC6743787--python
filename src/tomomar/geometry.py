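"""Limited-angle linear-sweep tomosynthesis acquisition geometry.

The X-ray source translates along the sweep axis (y) at constant height
above the isocenter while the detector stays stationary below it; view
angles are defined at the isocenter. Coordinates: x is the detector row
direction (phantom cylinder axis), y the sweep/column direction, z the
depth axis from detector (negative) through the isocenter (0) toward the
source (positive). Detector arrays are indexed [view, v, u] with v along
the sweep (y) and u along x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TomoGeometry"]


@dataclass(frozen=True)
class TomoGeometry:
    """Geometry of a dual-energy digital tomosynthesis sweep.

    Defaults mirror a clinical linear-sweep system: source-to-isocenter
    distance 924 mm, source-to-detector distance 1100 mm, a 40 degree total
    swing (+/- 20 degrees) covered by 37 equally spaced views, and 50
    reconstruction slices at 1 mm spacing. The desk-scale detector default
    is 128 x 128 pixels at 2.232 mm pitch, i.e. the clinical 1024-pixel,
    0.279 mm/pixel field of view rebinned 8x; the full-resolution matrix is
    reachable through configuration.
    """

    sad_mm: float = 924.0
    sdd_mm: float = 1100.0
    swing_deg: float = 40.0
    n_views: int = 37
    detector_shape: tuple = (128, 128)  # (nv, nu)
    pixel_pitch_mm: float = 2.232
    slice_interval_mm: float = 1.0
    n_slices: int = 50

    def __post_init__(self):
        if self.sad_mm <= 0 or self.sdd_mm <= 0:
            raise ValueError("distances must be positive")
        if self.sad_mm >= self.sdd_mm:
            raise ValueError("source-to-isocenter must be smaller than source-to-detector")
        if self.n_views < 3 or self.n_views % 2 == 0:
            raise ValueError("n_views must be odd and >= 3 (symmetric sweep including 0 deg)")
        if self.pixel_pitch_mm <= 0 or self.slice_interval_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.swing_deg <= 0 or self.swing_deg >= 180:
            raise ValueError("swing angle must lie in (0, 180) degrees")

    @property
    def view_angles_deg(self) -> np.ndarray:
        """Equally spaced view angles from -swing/2 to +swing/2, including 0."""
        half = self.swing_deg / 2.0
        return np.linspace(-half, half, self.n_views)

    @property
    def detector_z_mm(self) -> float:
        """z of the detector plane (below the isocenter)."""
        return -(self.sdd_mm - self.sad_mm)

    def source_position(self, angle_deg: float) -> np.ndarray:
        """Source (x, y, z) for a view angle; linear translation along y."""
        y = self.sad_mm * np.tan(np.deg2rad(angle_deg))
        return np.array([0.0, y, self.sad_mm])

    def detector_coords(self):
        """World (u=x, v=y) coordinates of detector pixel centers (mm)."""
        nv, nu = self.detector_shape
        u = (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_pitch_mm
        v = (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_pitch_mm
        return u, v

    def slice_z_mm(self) -> np.ndarray:
        """World z of reconstruction slice centers, centered on the isocenter."""
        k = np.arange(self.n_slices) - (self.n_slices - 1) / 2.0
        return k * self.slice_interval_mm

    @property
    def magnification(self) -> float:
        return self.sdd_mm / self.sad_mm

    def to_dict(self) -> dict:
        return {
            "sad_mm": self.sad_mm,
            "sdd_mm": self.sdd_mm,
            "swing_deg": self.swing_deg,
            "n_views": self.n_views,
            "detector_shape": list(self.detector_shape),
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "slice_interval_mm": self.slice_interval_mm,
            "n_slices": self.n_slices,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TomoGeometry":
        d = dict(d)
        if "detector_shape" in d:
            d["detector_shape"] = tuple(d["detector_shape"])
        return cls(**d)
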