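# lungmech

Tools for quantifying acinar-scale lung biomechanics from 4D (3D + time)
micro-CT of the breathing lung: retrospective cardiorespiratory gating,
airspace/vessel segmentation with proximal–intermediate–terminal
classification, B-spline non-rigid registration composed into Lagrangian
displacement fields, voxel-wise volumetric strain and internal-surface
change through divergence-theorem operators, skeleton-based detection of
recruited airspaces, and the S = kV^n conformation analysis of how acini
change shape as they inflate.

It is written for researchers processing gated synchrotron or micro-CT
volume series of small-animal lungs (or any periodically deforming
segmented structure) who need reproducible strain maps and surface–volume
scaling exponents rather than renderings. Every stage is exercisable
end-to-end on a bundled synthetic phantom — a bronchial trunk feeding an
acinar duct and clusters of spherical terminal airspaces, deformed by
analytic fields — whose volumes, surfaces, labels and displacement fields
are known exactly, so the whole chain can be validated without external
data.

## The model in brief

A breath is sampled as volumes V(0), V(Δt), …, one per phase bin of width
Δt, sorted retrospectively from continuously acquired projections using the
ECG-triggered ventilation scheme (an R-wave starts a breath; detection is
disabled for the trigger-signal duration T, so each cycle spans a whole
number of heartbeats). Pairwise displacement fields u*(x; (n−1)Δt, nΔt)
between consecutive phases (cubic B-spline parametrization, SSD similarity
with Laplacian regularization) are composed into Lagrangian fields by

    u(x; 0, nΔt) = u(x; 0, (n−1)Δt) + u*(x + u(x; 0, (n−1)Δt); (n−1)Δt, nΔt).

Local strain is the divergence of the Lagrangian field, δV/V_t0, estimated
over the segmented voxels Ω with a moving-least-squares corrected kernel
convolution that is exact for affine fields even at the boundary:

    ⟨∇·u⟩(x_i) = Σ_{j∈Ω} (u_j − u_i)·(L(x_i)·∇W(x_j − x_i)),
    L(x_i) = [Σ_{j∈Ω} (x_j − x_i) ⊗ ∇W(x_j − x_i)]⁻¹.

Volume change is Δv = Σ_Ω ⟨∇·u⟩·v_voxel and internal-surface change is
Δs = Σ_Ω ⟨∇·(h u)⟩ with h the total curvature κ₁+κ₂ of ∂Ω (2/R on a sphere
of radius R), both instances of the divergence theorem. Fitting S = kV^n
through the per-phase (V, S) pairs by log–log least squares classifies the
conformational regime: n = 2/3 isotropic balloon-like inflation, n < 2/3
ductal-dominant expansion, 2/3 < n < 1 predominant alveolar expansion,
n ≈ 1 recruitment-like behavior. Recruited (newly inflated) airspaces are
found by comparing each phase's airspace skeleton against the
field-advected baseline skeleton: voxels farther from any advected skeleton
than from their own wall (d_s > d_Ω) seed recruited components.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Run the full pipeline on the bundled alveolar-dominant phantom (terminal
units inflating about their own centres while the ducts stay fixed, 64³
voxels, 8 phase bins):

```python
from lungmech.phantom import demo_spec
from lungmech.pipeline import PipelineConfig, run_pipeline

spec = demo_spec("alveolar_dominant", n_steps=8, seed=1)
cfg = PipelineConfig(out_dir="out/alveolar", phantom=spec.to_dict())
bundle = run_pipeline(cfg)
print(f"fitted exponent n = {bundle['fit']['n']:.3f}")
print(f"conformation regime: {bundle['fit']['regime']}")
print(f"peak mean strain dV/V_t0 = {bundle['peak_strain']:.3f}")
print(f"recruited components per phase: "
      f"{[r['n_components'] for r in bundle['recruitment']]}")
```

prints

```
fitted exponent n = 0.822
conformation regime: alveolar_dominant
peak mean strain dV/V_t0 = 0.172
recruited components per phase: [0, 0, 0, 0, 0, 0, 0]
```

The exponent n = 0.82 says the peripheral airspace gained surface area
faster than isotropic scaling would allow (n = 2/3): the alveoli expanded
while the ductal volume stayed put — exactly how the phantom was built.
The peak mean strain 0.172 is the fractional volume change of the
peripheral airspace at mid-breath recovered purely from image
registration, and no recruitment is (correctly) detected. The same
pipeline on the isotropic phantom (`demo_spec("isotropic", n_steps=10)`)
returns n = 0.623, at the low edge of the isotropic band, and on the
recruitment phantom reports each appearing unit from its appearance step
onward.

The same chain is scriptable from the shell:

```bash
lungmech phantom generate --mode recruitment --out out/ph
lungmech run --config config.json --seed 1
lungmech gating assign --ecg ecg.csv --proj projections.csv --out table.csv
```

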