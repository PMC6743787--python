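"""Parametric polychromatic tube spectra for the dual-energy pair.

The spectrum model is a Kramers bremsstrahlung continuum from a tungsten
anode with an anode self-attenuation hardening term, tungsten K
characteristic lines for tube potentials above the K edge (69.525 keV), and
Beer-Lambert filtration through the stated aluminum + copper filter stack.
The two free shape parameters (hardening exponent, K-line fluence fraction)
are fixed once so that the default filtered 70 kV and 140 kV spectra have
fluence-weighted mean energies of 49 and 80 keV, the values quoted for the
measured clinical tube; only the means of the real spectra are published, so
they define the calibration surface.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .materials import ALUMINUM, COPPER, MaterialSpec, mixture_mu_rho

__all__ = [
    "EnergySpectrum",
    "simulate_spectrum",
    "spectrum_mean_energy",
    "delta_spectrum",
    "DEFAULT_FILTRATION",
]

# Total default filtration: 2.0 mm Al (1.1 inherent + 0.9 additional) + 0.1 mm Cu.
DEFAULT_FILTRATION = (("Al", 2.0), ("Cu", 0.1))

_FILTER_MATERIALS: dict[str, MaterialSpec] = {
    "Al": ALUMINUM,
    "aluminum": ALUMINUM,
    "Cu": COPPER,
    "copper": COPPER,
}

# Tungsten K-shell data: edge energy and K alpha/beta line energies (keV)
# with relative emission intensities.
_W_K_EDGE_KEV = 69.525
_W_K_LINES = (
    (57.982, 0.576),  # K-alpha2
    (59.318, 1.000),  # K-alpha1
    (66.951, 0.116),  # K-beta3
    (67.244, 0.223),  # K-beta1
    (69.067, 0.077),  # K-beta2
)

# Calibrated shape parameters (see module docstring): the continuum is
# E^a * (kVp/E - 1)^b; b < 1 flattens the raw Kramers rise toward low
# energies (anode self-absorption), a > 0 hardens the transmitted beam.
_HARDENING_EXPONENT = 1.25
_KRAMERS_EXPONENT = 0.6
_K_LINE_FRACTION_140 = 0.18


@dataclass
class EnergySpectrum:
    """Discretized X-ray fluence: photons per 1 keV bin, normalized to sum 1.

    ``energies`` are bin centers in keV; ``weights`` are relative photon
    fluences (>= 0, zero above the tube potential, at least one nonzero bin).
    """

    energies: np.ndarray
    weights: np.ndarray
    tube_potential: float
    filtration: tuple = field(default=())

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.energies.shape != self.weights.shape:
            raise ValueError("energies and weights must have the same shape")
        if np.any(self.weights < 0):
            raise ValueError("fluence weights must be non-negative")
        if np.any(self.weights[self.energies > self.tube_potential] > 0):
            raise ValueError("fluence above the tube potential must be zero")
        if not np.any(self.weights > 0):
            raise ValueError("spectrum has no nonzero bin")
        total = self.weights.sum()
        self.weights = self.weights / total

    @property
    def mean_energy(self) -> float:
        return spectrum_mean_energy(self)

    def to_csv(self, path) -> None:
        """Two-column CSV export: energy_keV, weight."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["energy_keV", "weight"])
            for e, w in zip(self.energies, self.weights):
                writer.writerow([f"{e:g}", f"{w:.10g}"])


def delta_spectrum(energy_kev: float) -> EnergySpectrum:
    """Monochromatic limit: all fluence in the single bin at ``energy_kev``."""
    return EnergySpectrum(
        energies=np.array([float(energy_kev)]),
        weights=np.array([1.0]),
        tube_potential=float(energy_kev),
    )


def _filtration_transmission(energies: np.ndarray, filtration) -> np.ndarray:
    trans = np.ones_like(energies)
    for name, thickness_mm in filtration:
        if thickness_mm <= 0:
            raise ValueError(f"filtration thickness must be positive, got {thickness_mm}")
        mat = _FILTER_MATERIALS.get(name)
        if mat is None:
            raise KeyError(f"unknown filtration material {name!r}")
        mu = mixture_mu_rho(mat, energies) * mat.density  # 1/cm
        trans *= np.exp(-mu * thickness_mm / 10.0)
    return trans


def simulate_spectrum(tube_potential: float, filtration=DEFAULT_FILTRATION) -> EnergySpectrum:
    """Simulate a filtered tungsten-anode spectrum on a 1 keV grid.

    Parameters
    ----------
    tube_potential : float
        Tube potential in kV; 40-150 accepted, the system defaults are 70
        (low energy) and 140 (high energy).
    filtration : sequence of (material name, thickness mm)
        Beer-Lambert filter stack; defaults to 2.0 mm Al + 0.1 mm Cu.
    """
    kvp = float(tube_potential)
    if not (40.0 <= kvp <= 150.0):
        raise ValueError(f"tube potential {kvp} kV outside supported range 40-150")
    filtration = tuple((str(n), float(t)) for n, t in filtration)

    energies = np.arange(10.0, 151.0)  # 1 keV bins
    weights = np.zeros_like(energies)
    cont = energies < kvp
    # Kramers continuum with anode self-attenuation hardening.
    weights[cont] = (kvp / energies[cont] - 1.0) ** _KRAMERS_EXPONENT * energies[
        cont
    ] ** _HARDENING_EXPONENT
    weights *= _filtration_transmission(energies, filtration)

    if kvp > _W_K_EDGE_KEV:
        # K characteristic lines; excitation grows as (U/U_K - 1)^1.65,
        # fluence fraction anchored at the 140 kV operating point.
        excitation = (kvp / _W_K_EDGE_KEV - 1.0) ** 1.65
        excitation_140 = (140.0 / _W_K_EDGE_KEV - 1.0) ** 1.65
        frac = _K_LINE_FRACTION_140 * excitation / excitation_140
        line_e = np.array([e for e, _ in _W_K_LINES])
        line_w = np.array([w for _, w in _W_K_LINES])
        line_w = line_w * _filtration_transmission(line_e, filtration)
        line_w *= frac * weights.sum() / (1.0 - frac) / line_w.sum()
        idx = np.searchsorted(energies, np.round(line_e))
        np.add.at(weights, idx, line_w)

    return EnergySpectrum(
        energies=energies, weights=weights, tube_potential=kvp, filtration=filtration
    )


def spectrum_mean_energy(spectrum: EnergySpectrum) -> float:
    """Fluence-weighted mean photon energy, sum(E I(E)) / sum(I(E)), in keV."""
    total = spectrum.weights.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all weights are zero")
    return float(np.dot(spectrum.energies, spectrum.weights) / total)
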