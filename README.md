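# fiberalign

Quantifying the direction and extent of structural-protein alignment in
engineered tissue constructs, three ways at once:

1. **Polarized Raman spectroscopy (PRS).** Spectra acquired at polarization
   angles φ ∈ {0°, 30°, …, 150°} are baseline-subtracted (iterative 11th-order
   polynomial), Savitzky–Golay smoothed (3rd order, 11-point frame),
   SNV-normalized, cropped to 1400–1800 cm⁻¹, and projected onto a *master
   loading function* — the first principal-component loading of a highly
   aligned reference muscle spectrum library, dominated by the amide-I C=O
   band. The resulting PC1 score oscillates with polarization angle as

       PC1(φ) = PC1₀ + A · sin(π (φ − φc) / 90°),

   where the amplitude *A* measures the extent of alignment and
   β_PRS = (φc + 45°) mod 180° is the dominant fiber direction.

2. **Immunofluorescence fiber tables** (CT-FIRE-style CSV). The discrete
   alignment index S = 2⟨cos²θ⟩ − 1 = ⟨cos 2θ⟩, with θ measured from the mean
   fiber axis (the major axis of the orientation tensor ⟨u uᵀ⟩), plus axial
   circular SD and polar histograms.

3. **A contraction finite-element model** that bridges the two. The cell-laden
   4 × 10 mm gauge strip of the dog-bone construct (E = 700 Pa, ν = 0.4,
   plane-stress compressible neo-Hookean,
   ψ = E/(4(1+ν)) (Ī₁ − 3) + E/(6(1−2ν)) (J_el − 1)²) contracts under a
   stress-free shrinkage strain εs fitted to the measured ~60 % area
   shrinkage. A material circle at each point deforms into an ellipse with
   axis ratio α = b/a and major-axis angle β_model; embedding N = 150 uniform
   fibers and pushing them through the local deformation gradient yields an
   equivalent S (→ (α−1)/(α+1) for pure stretch), directly comparable with
   the imaging metric.

Across modalities, regions are compared through the alignment aspect ratio
γ = metric / metric_max (A/A_max for PRS, α/α_max for the model).

Because real acquisitions of this kind are rarely deposited, the
`synthetic` module generates inputs with the same statistical structure
(polarization-modulated band spectra, wrapped-normal fiber populations), so
every stage is testable end to end.

## Worked example

Run the contraction model at 100 µm elements, fit the shrinkage strain to
60 % area loss, and read out the regional alignment:

```python
import numpy as np
from fiberalign import fem, kinematics

mesh = fem.build_mesh(fem.Geometry())          # 4 x 10 mm strip, 100 um mesh
fit = fem.fit_shrinkage_strain(0.60, mesh, fem.Material(),
                               sweep=np.round(np.arange(0, 0.7001, 0.05), 10))
print("best-fit eps_s =", fit.eps_best)
amap = kinematics.alignment_map(mesh, fit.field_best)
for loc, r in amap.regions.items():
    print(f"{loc}: alpha = {r.alpha:.2f}, beta = {r.beta_model_deg:.1f} deg, "
          f"S = {r.S:.3f}")
```

prints

```
best-fit eps_s = 0.6
CE: alpha = 7.76, beta = 145.5 deg, S = 0.772
ME: alpha = 3.50, beta = 90.0 deg, S = 0.556
MC: alpha = 3.51, beta = 90.0 deg, S = 0.556
```

i.e. a shrinkage strain of 0.6 reproduces the measured area loss; the corner
edge (CE) is strongly aligned at ≈145°, while the middle edge and middle
center (ME, MC) align along the inter-anchor axis (90°) with α ≈ 3.5. The
full pipeline — synthetic PRS + fiber tables + model, ending in the
cross-modality comparison tables — runs from a YAML config:

```bash
fiberalign run --config run.yaml          # writes comparison_{gamma,angles,S}.csv
```

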