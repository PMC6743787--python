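"""Projection-space three-material decomposition and VM synthesis.

Per detector pixel, the dual-energy intensity pair is modeled as a linear
combination of the simulated pure-material attenuation responses at a
reference area density, closed with a sum-to-one constraint on the material
fractions:

    [P_L_t  P_L_w  P_L_f] [F_t]   [I_L]
    [P_H_t  P_H_w  P_H_f] [F_w] = [I_H]
    [ 1      1      1   ] [F_f]   [ 1 ]

Both the measured stacks and the sensitivity entries are normalized to
unattenuated intensity 1, which makes the unity row dimensionally coherent.
Raw per-pixel solutions are clamped to [0, 1] and renormalized to sum 1.
The virtual-monochromatic projection is the fraction-weighted sum of the
basis materials' mass attenuation coefficients at the chosen energy
(140 keV by default), which is free of beam-hardening nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import AttenuationTable
from .phantom import MATERIAL_ORDER
from .projector import ProjectionStack
from .spectra import EnergySpectrum

__all__ = [
    "DecompositionError",
    "SensitivityMatrix",
    "build_sensitivity_matrix",
    "decompose_projections",
    "vm_projection",
]

_COND_LIMIT = 1e12


class DecompositionError(RuntimeError):
    """Raised when the material system is singular or infeasible."""


@dataclass
class SensitivityMatrix:
    """3x3 simulated-response matrix, its inverse, and conditioning.

    Rows: low-energy response, high-energy response, unity constraint.
    Columns follow MATERIAL_ORDER (titanium alloy, water, foam shell).
    """

    matrix: np.ndarray
    reference_densities: dict  # material -> g/cm^2 used for the responses
    materials: tuple = MATERIAL_ORDER

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise ValueError("sensitivity matrix must be 3x3")
        if not np.allclose(self.matrix[2], 1.0):
            raise ValueError("third row must be the unity constraint")
        self.condition_number = float(np.linalg.cond(self.matrix))
        if not np.isfinite(self.condition_number) or self.condition_number > _COND_LIMIT:
            raise DecompositionError(
                f"sensitivity matrix is singular (condition number {self.condition_number:.3g})"
            )
        self.inverse = np.linalg.inv(self.matrix)

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "inverse": self.inverse.tolist(),
            "condition_number": self.condition_number,
            "materials": list(self.materials),
            "reference_densities": dict(self.reference_densities),
        }


def _pure_material_response(
    spectrum: EnergySpectrum, attn: AttenuationTable, material: str, area_density: float
) -> float:
    """Normalized transmitted intensity through one pure material."""
    w = spectrum.weights
    mu = attn.mu_rho(material, spectrum.energies)
    return float(np.dot(w, np.exp(-mu * area_density)) / w.sum())


def build_sensitivity_matrix(
    spec_low: EnergySpectrum,
    spec_high: EnergySpectrum,
    attn: AttenuationTable,
    reference_densities: dict,
) -> SensitivityMatrix:
    """Simulate the six pure-material responses and assemble the system.

    ``reference_densities`` maps each basis material to the area density
    (g/cm^2) at which its response is simulated; sensible values are the
    central-ray area densities through the phantom, which keep the matrix
    well scaled.
    """
    for name in MATERIAL_ORDER:
        if reference_densities.get(name, 0.0) <= 0:
            raise ValueError(f"reference density for {name!r} must be positive")
    rows = []
    for spec in (spec_low, spec_high):
        rows.append(
            [
                _pure_material_response(spec, attn, name, reference_densities[name])
                for name in MATERIAL_ORDER
            ]
        )
    rows.append([1.0, 1.0, 1.0])
    return SensitivityMatrix(
        matrix=np.array(rows), reference_densities=dict(reference_densities)
    )


def decompose_projections(
    stack_low: ProjectionStack,
    stack_high: ProjectionStack,
    sens: SensitivityMatrix,
    clamp: bool = True,
) -> np.ndarray:
    """Solve per-pixel material fractions from the dual-energy pair.

    Returns fractions of shape (3, n_views, nv, nu) in MATERIAL_ORDER.
    With ``clamp`` (default) raw solutions are clipped to [0, 1] and
    renormalized to sum exactly 1; already-feasible solutions pass through
    unchanged, so clamping is idempotent.
    """
    if not stack_low.congruent_with(stack_high):
        raise ValueError("dual-energy stacks are not congruent")
    shape = stack_low.data.shape
    rhs = np.stack(
        [
            stack_low.data.reshape(-1),
            stack_high.data.reshape(-1),
            np.ones(stack_low.data.size),
        ]
    )  # (3, npix)
    F = sens.inverse @ rhs  # (3, npix)
    if clamp:
        F = np.clip(F, 0.0, 1.0)
        s = F.sum(axis=0)
        # pixels where everything clipped to zero: fall back to pure water
        dead = s <= 1e-12
        if dead.any():
            F[:, dead] = np.array([[0.0], [1.0], [0.0]])
            s = F.sum(axis=0)
        F = F / s
    return F.reshape((3,) + shape)


def vm_projection(
    fractions: np.ndarray,
    geometry,
    energy_kev: float = 140.0,
    attn: AttenuationTable | None = None,
) -> ProjectionStack:
    """Synthesize the virtual-monochromatic projection from fraction maps.

    VM(i, j) = sum_m F_m(i, j) * (mu/rho)_m(E); linear in the fractions.
    """
    if attn is None:
        attn = AttenuationTable.for_materials()
    if not (attn.energies[0] <= energy_kev <= attn.energies[-1]):
        raise ValueError(f"VM energy {energy_kev} keV outside attenuation grid")
    fractions = np.asarray(fractions)
    if fractions.ndim != 4 or fractions.shape[0] != 3:
        raise ValueError("fractions must be (3, n_views, nv, nu)")
    coeffs = np.array([float(attn.mu_rho(name, energy_kev)) for name in MATERIAL_ORDER])
    data = np.einsum("m,mvij->vij", coeffs, fractions)
    return ProjectionStack(
        data=data,
        geometry=geometry,
        tag=f"VM-{energy_kev:g}",
        convention="mu_rho",
    )
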