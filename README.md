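# fibredisp

Cross-modality analysis of **fibre orientation dispersion** in white
matter: estimate within-voxel dispersion from diffusion MRI with a
two-compartment Bingham model, derive reference dispersion from polarized
light imaging (PLI) and from structure-tensor analysis of stained
histological sections, and compare the three by region, left–right
profile and voxel. A synthetic-data module generates every input with
known ground truth, so the whole pipeline is testable end to end without
any archived specimen data.

The package is a library: import it from Python, or start from the
narrative scripts in `examples/`.

## The model

The fibre orientation distribution (fODF) of a dispersed population is an
antipodally symmetric **Bingham distribution** on the sphere,

```
p(n) ∝ exp(−k₁ (μ₁·n)² − k₂ (μ₂·n)²),   k₁ ≥ k₂ ≥ 0,
```

with principal axis μ₀ and concentrations k₁, k₂ along the two dispersion
axes (k₁ = k₂ = κ is the Watson distribution; low k means high
dispersion). The diffusion-weighted signal is modelled as

```
S(g, b) = S₀ [ f_iso e^(−b·d_iso) + (1 − f_iso) ∫ B(n) e^(−b·d_par (g·n)²) dn ],
```

a stick response dispersed by the Bingham fODF plus an isotropic
compartment. Because microscopy measures orientations in a 2D section,
dispersion is compared in-plane: restricting the Bingham to the section
plane gives a one-parameter axial law with concentration k₂D, and the
scalar **orientation dispersion index**

```
ODI = (2/π) · arctan(1 / k₂D) ∈ [0, 1]
```

(0 = perfectly parallel, 1 = uniform on the circle). PLI recovers
per-pixel fibre orientation from the phase of the intensity sinusoid
`I(ρ) = (I₀/2)(1 + |sin δ| sin(2ρ − 2φ))` over analyser angles ρ;
histology recovers it from the structure tensor of the stain image. Both
are histogrammed into per-patch FODs, fitted with the same Bingham
machinery, and mapped to the same ODI. Myelin and astrocyte FODs combine
as `FOD_MA = f_M·FOD_M + f_A·FOD_A`, with volume fractions obtained from
measured area fractions through a simulated cylinder-packing
area→volume mapping and rescaled so f_M + f_A = 1.

## Worked example

```python
import numpy as np
from fibredisp import Bingham2, fit_bingham2, AxialFOD2D
from fibredisp.synthetic import PhantomSpec, gen_dwi
from fibredisp.dmri import DWIProtocol, fit_dispersion

spec = PhantomSpec(seed=0)                 # CC band with a midline dispersion bump
protocol = DWIProtocol.single_shell()      # 120 dirs at b = 5000 s/mm² + 4 b0
signals, _ = gen_dwi(spec, protocol, snr=15.0, seed=5)

fit = fit_dispersion(signals[2, 7], protocol, seed=1)   # a midline voxel
print(round(fit.odi_in_plane(), 3), round(spec.odi_map[2, 7], 3))
```

prints

```
0.291 0.293
```

— the in-plane ODI refitted from noisy signals (0.291) against the
planted ground truth (0.293) for a strongly dispersed midline voxel.
`examples/06_cross_modality_phantom.py` runs the same comparison for all
three modalities and prints the corpus-callosum profiles, which peak at
the midline in every modality and correlate across modalities with
r > 0.9.

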