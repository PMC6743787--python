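"""Three-material decomposition and 140 keV virtual-monochromatic synthesis.

Decomposes the dual-energy projection pair into titanium-alloy / water /
foam-bone fraction maps by the constrained per-pixel 3x3 solve and builds
the 140 keV VM reference projection. Prints the sensitivity-matrix
condition number (how well the two spectra separate the materials) and the
recovered fraction of each material along two representative rays.
"""

import numpy as np

from tomomar import (
    AttenuationTable,
    PhantomConfig,
    TomoGeometry,
    build_phantom,
    build_sensitivity_matrix,
    decompose_projections,
    material_pathlengths,
    polychromatic_project,
    simulate_spectrum,
    vm_projection,
)

geo = TomoGeometry(detector_shape=(64, 64), pixel_pitch_mm=4.464, n_views=37,
                   n_slices=21, slice_interval_mm=5.0)
phantom = build_phantom(PhantomConfig())
attn = AttenuationTable.for_materials()
spec_l, spec_h = simulate_spectrum(70), simulate_spectrum(140)

paths = material_pathlengths(phantom, geo)
low = polychromatic_project(paths, spec_l, attn, tag="70kV")
high = polychromatic_project(paths, spec_h, attn, tag="140kV")

ref = {m: max(paths.maps[m][18, 32, 32], paths.maps[m].max() * 0.5) for m in paths.maps}
sens = build_sensitivity_matrix(spec_l, spec_h, attn, ref)
print(f"sensitivity matrix condition number: {sens.condition_number:.1f} "
      "(finite and modest -> the three materials are separable)")

F = decompose_projections(low, high, sens)
print("fractions on a ray through the implant (t, w, f):",
      np.round(F[:, 18, 32, 32], 3))
print("fractions on a water-only ray          (t, w, f):",
      np.round(F[:, 18, 50, 32], 3))

vm = vm_projection(F, geo, 140.0, attn)
print(f"VM-140 projection range: {vm.data.min():.4f} .. {vm.data.max():.4f} cm^2/g "
      "(mass-attenuation scale; free of beam-hardening nonlinearity)")
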