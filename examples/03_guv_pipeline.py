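"""End-to-end pipeline on a GUV phantom.

A giant unilamellar vesicle labeled with a membrane-crossing dye has dipoles
everywhere normal to its spherical shell.  We simulate the tilted
six-measurement acquisition with shot noise, reconstruct the ODF field by
per-frequency Tikhonov inversion, and score how many per-voxel peak axes
land within a 42-degree half-angle cone of the true radial direction
(qualifying voxels = total counts > 5,000 across measurements).
"""

import numpy as np

from polspim import (
    ReconConfig,
    add_noise,
    forward_project,
    guv_phantom,
    make_scheme,
    reconstruct_field,
)
from polspim.sphharm import peak_field

field, truth, shell = guv_phantom(shape=(48, 48, 48), spacing_nm=130.0,
                                  radius_nm=2200.0, shell_width_nm=390.0,
                                  kappa=5.0)
scheme = make_scheme("six_with_tilt")
stack = forward_project(field, scheme, pad=16)
median_signal = np.median(stack.total_counts()[shell])
noisy = add_noise(stack, "poisson",
                  photons_per_unit=10000.0 / median_signal, seed=123)
rec = reconstruct_field(noisy, ReconConfig())

axes, values, degen = peak_field(rec.coeffs[shell])
ang = np.degrees(np.arccos(np.clip(
    np.abs(np.sum(axes * truth[shell], axis=-1)), 0, 1)))
qual = noisy.total_counts()[shell] > 5000
print(f"shell voxels: {shell.sum()}, qualifying: {qual.sum()}")
print(f"median peak error: {np.median(ang[qual]):.1f} deg")
print(f"within 42 deg cone: {100 * np.mean(ang[qual] < 42):.1f}%")
# The cone fraction is the instrument's angular performance figure; the
# median error shows typical accuracy is far better than the cone bound.
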