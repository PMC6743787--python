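"""Basis materials and photon mass attenuation coefficients.

The toolkit models every object in the beam as a mixture of chemical
elements. Mass attenuation coefficients (mu/rho, cm^2/g) for the elements
that occur in the phantom and in the tube filtration are embedded as static
tables on the standard 10-150 keV grid of the published photon cross-section
compilations; values in between are obtained by log-log interpolation, which
reproduces the tabulated nodes exactly and tracks the smooth power-law decay
of the photoelectric and Compton cross sections.

Three basis materials drive the dual-energy decomposition: the titanium
alloy of the implant, water (soft-tissue analog), and the foam cortical
shell of the artificial bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialSpec",
    "AttenuationTable",
    "mixture_mu_rho",
    "element_mu_rho",
    "TITANIUM_ALLOY",
    "WATER",
    "FOAM_CORTICAL_SHELL",
    "ALUMINUM",
    "COPPER",
    "BASIS_MATERIALS",
    "ELEMENT_ENERGIES_KEV",
]

# Photon energies (keV) of the standard attenuation-table grid.
ELEMENT_ENERGIES_KEV = np.array(
    [10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0]
)

# Total mass attenuation coefficients with coherent scattering, cm^2/g,
# on ELEMENT_ENERGIES_KEV. Transcribed from the standard published
# photon-attenuation reference tables.
ELEMENT_MU_RHO: dict[str, np.ndarray] = {
    "H": np.array(
        [0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091, 0.2944, 0.2651]
    ),
    "C": np.array(
        [2.373, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610, 0.1514, 0.1347]
    ),
    "N": np.array(
        [3.879, 1.236, 0.6178, 0.3066, 0.2288, 0.1980, 0.1817, 0.1639, 0.1529, 0.1353]
    ),
    "O": np.array(
        [5.952, 1.836, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678, 0.1551, 0.1361]
    ),
    "Al": np.array(
        [26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378]
    ),
    "Ti": np.array(
        [110.7, 35.87, 15.85, 4.972, 2.214, 1.213, 0.7661, 0.4052, 0.2721, 0.1649]
    ),
    "V": np.array(
        [125.3, 40.88, 18.06, 5.681, 2.530, 1.385, 0.8726, 0.4573, 0.3037, 0.1779]
    ),
    "Fe": np.array(
        [170.6, 57.08, 25.68, 8.176, 3.629, 1.958, 1.205, 0.5952, 0.3717, 0.1964]
    ),
    "Cu": np.array(
        [215.9, 74.05, 33.79, 10.92, 4.862, 2.613, 1.593, 0.7630, 0.4584, 0.2217]
    ),
}

# Elemental densities (g/cm^3) used for filtration thicknesses.
ELEMENT_DENSITY: dict[str, float] = {"Al": 2.699, "Cu": 8.96}


def _loglog_interp(energy: np.ndarray, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Log-log interpolation of attenuation values; exact at the nodes."""
    energy = np.asarray(energy, dtype=float)
    lo, hi = grid[0], grid[-1]
    if np.any(energy < lo) or np.any(energy > hi):
        raise ValueError(
            f"energy outside attenuation table range [{lo}, {hi}] keV"
        )
    out = np.exp(np.interp(np.log(energy), np.log(grid), np.log(values)))
    return out


def element_mu_rho(symbol: str, energy) -> np.ndarray:
    """Elemental mass attenuation coefficient (cm^2/g) at ``energy`` keV."""
    if symbol not in ELEMENT_MU_RHO:
        raise KeyError(f"no attenuation data for element {symbol!r}")
    return _loglog_interp(np.asarray(energy, dtype=float), ELEMENT_ENERGIES_KEV, ELEMENT_MU_RHO[symbol])


@dataclass(frozen=True)
class MaterialSpec:
    """A material as a mass-fraction mixture of elements.

    Parameters
    ----------
    name : str
    elements : list of (element symbol, mass fraction)
        Fractions must lie in [0, 1] and sum to 1 within 1e-6.
    density : float
        Local density in g/cm^3, must be positive.
    """

    name: str
    elements: tuple = field(default=())
    density: float = 1.0

    def __post_init__(self):
        fracs = np.array([w for _, w in self.elements], dtype=float)
        if fracs.size == 0:
            raise ValueError("material needs at least one element")
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ValueError(f"{self.name}: mass fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.name}: mass fractions sum to {fracs.sum():.8f}, not 1"
            )
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")

    def mu_rho(self, energy) -> np.ndarray:
        """Mixture mass attenuation coefficient at ``energy`` keV."""
        return mixture_mu_rho(self, energy)


def mixture_mu_rho(material: MaterialSpec, energy, element_table: dict | None = None):
    """Mass attenuation coefficient of a mixture (cm^2/g).

    The mixture rule is the mass-fraction-weighted sum of the elemental
    coefficients, mu/rho = sum_e w_e (mu/rho)_e(E); it is exactly linear in
    the mass fractions.
    """
    table = ELEMENT_MU_RHO if element_table is None else element_table
    energy = np.asarray(energy, dtype=float)
    out = np.zeros_like(energy)
    for symbol, frac in material.elements:
        if symbol not in table:
            raise KeyError(f"no attenuation data for element {symbol!r}")
        out = out + frac * _loglog_interp(energy, ELEMENT_ENERGIES_KEV, table[symbol])
    return out


# Phantom basis materials: implant alloy, soft-tissue analog and bone analog.
TITANIUM_ALLOY = MaterialSpec(
    name="titanium_alloy",
    elements=(
        ("Ti", 0.90255),
        ("Al", 0.055),
        ("V", 0.035),
        ("Fe", 0.0040),
        ("O", 0.0020),
        ("C", 0.0008),
        ("N", 0.0005),
        ("H", 0.00015),
    ),
    density=4.43,
)

WATER = MaterialSpec(
    name="water",
    elements=(("H", 0.1119), ("O", 0.8881)),
    density=1.0,
)

FOAM_CORTICAL_SHELL = MaterialSpec(
    name="foam_cortical_shell",
    elements=(
        ("H", 0.079192),
        ("C", 0.404437),
        ("N", 0.157213),
        ("O", 0.359157 + 1e-6),  # printed fractions sum to 0.999999
    ),
    density=0.48,
)

ALUMINUM = MaterialSpec(name="aluminum", elements=(("Al", 1.0),), density=2.699)
COPPER = MaterialSpec(name="copper", elements=(("Cu", 1.0),), density=8.96)

# Canonical ordering used throughout: (titanium alloy, water, foam shell).
BASIS_MATERIALS = (TITANIUM_ALLOY, WATER, FOAM_CORTICAL_SHELL)


@dataclass
class AttenuationTable:
    """Per-material mass attenuation coefficients on a shared energy grid.

    ``energies`` is strictly increasing and must cover at least
    [10, 150] keV; lookups between nodes use log-log interpolation.
    """

    energies: np.ndarray
    tables: dict  # material name -> mu/rho values on the grid (cm^2/g)
    densities: dict  # material name -> g/cm^3

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if self.energies[0] > 10.0 or self.energies[-1] < 150.0:
            raise ValueError("energy grid must cover [10, 150] keV")
        for name, vals in self.tables.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.energies.shape:
                raise ValueError(f"{name}: values do not match grid")
            if np.any(vals <= 0):
                raise ValueError(f"{name}: attenuation values must be positive")
            self.tables[name] = vals

    @classmethod
    def for_materials(cls, materials=BASIS_MATERIALS, energies=None) -> "AttenuationTable":
        if energies is None:
            energies = np.arange(10.0, 151.0)
        energies = np.asarray(energies, dtype=float)
        tables = {m.name: mixture_mu_rho(m, energies) for m in materials}
        densities = {m.name: m.density for m in materials}
        return cls(energies=energies, tables=tables, densities=densities)

    def mu_rho(self, name: str, energy) -> np.ndarray:
        if name not in self.tables:
            raise KeyError(f"material {name!r} not in table")
        return _loglog_interp(np.asarray(energy, dtype=float), self.energies, self.tables[name])

    @property
    def material_names(self):
        return list(self.tables)
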