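# Methods

`lungmech` implements the processing chain used to quantify acinar-scale lung
biomechanics from retrospectively gated 4D micro-CT: phase sorting of
projections, airspace/vessel segmentation and classification, pairwise
non-rigid registration composed into Lagrangian displacement fields,
divergence-theorem estimators of volumetric strain and internal-surface
change, skeleton-based recruitment detection, and the S = kV^n conformation
fit. This note records the models, the numerical choices and their
rationale, and what the synthetic phantom does and does not establish.

## Retrospective gating model

The acquisition is modelled as: an R-wave detector triggers an assisted
breath through a square signal of duration `T`; detection is disabled while
the signal is high, so each respiratory cycle spans a whole number `n_ECG`
of heartbeats. Projections acquired continuously at rotation speed ω are
characterized by an angle α = ω(t − t₀) and a phase time t* = t − t_j (time
since the start of cycle j), and are sorted into bins of width `Δt`.
Defaults (`T = 0.75 s`, heartbeat period 0.39 s, `Δt = 10 ms`,
`ω = 0.34°/s`) give 2 beats per cycle, a 0.78 s nominal cycle, 78 phase
bins, an 8.8 min half-rotation and ≈ 700 breaths per scan.

Conventions: the boundary t = t_j belongs to cycle j, bin 0 (half-open
bins, no projection lost); projections before the first trigger or beyond
the last trigger plus the longest observed cycle are flagged unassigned
rather than dropped. The bin count is `ceil(max cycle / Δt)`; because ECG
jitter makes cycles unequal, the report also carries the nominal-mean
variant (`n_bins_nominal`), and per-bin counts are exposed as a sampling
quality metric instead of resampling.

## Segmentation and structure classification

Air/non-air partition is Otsu's threshold (air is dark). Connected air is
classified by the stepwise-erosion procedure with the 6-connected cross as
structuring element, so a voxel's erosion survival depth equals its
city-block distance to background (property-tested).

* **Proximal bronchi** are recovered as a morphological opening: the deep
  erosion core at radius `depth_max − prox_margin` (default margin 2)
  dilated back by the same radius, both realized through Euclidean distance
  transforms. A ball opening is used rather than the iterated cross because
  the city-block ball is a diamond that recovers only ~64 % of a circular
  cross-section.
* **Quasi-cylinder acceptance** combines the linear-regression statistic on
  the erosion profile (relative RMSE of a linear fit over the first
  ⌈depth/2⌉ steps, default tolerance 0.10) with an *elongation* gate:
  component volume / ((4/3)π(d+0.5)³) ≥ 1.25, where d is the max EDT depth.
  At the depths reachable in a 64³ volume the RMSE statistic alone cannot
  separate digital spheres from short cylinders (measured: sphere r = 20
  gives 4.3 %, trunk r = 10, L = 18 gives 5.6 %); the elongation ratio is
  ≈ 1 for any sphere and ≥ ~1.5·L/2r for tubes, which restores the intended
  discrimination. Both thresholds are config keys
  (`ClassifierConfig`) — the original procedure states neither.
* **Intermediate structures** are the remaining connected components that
  pass the quasi-cylinder test with EDT depth in `[theta_term,
  proximal depth)`; default `theta_term = 4` voxels. Everything else is
  terminal. If nothing passes the quasi-cylinder test the whole mask is
  terminal and a warning is emitted.
* **Vessels** reuse the same machinery on the blood/tissue contrast; the
  blood threshold is an explicit config (default midway between the nominal
  blood and tissue grey levels) because the blood class is far too small a
  histogram fraction for a second Otsu split, and a 2-voxel halo around air
  is excluded because smoothing drags the air/tissue boundary below the
  blood threshold.
* **Manual edits** are marker watersheds on the inverted EDT, constrained
  to the mask.

Known limitation: an exact ball opening cannot reach the rim wedges at flat
bronchus end caps, so a thin annulus at each cut end of a capped tube is
classified terminal; on the bundled phantom this bounds class-wise Dice at
about 0.88–0.94 rather than 1.

## Registration and Lagrangian composition

Pairwise displacement between consecutive phases is parametrized by a cubic
B-spline control grid (default spacing 8 voxels) and estimated by
minimizing SSD plus a Laplacian penalty `λ·Σ‖Δu‖²` on the dense field
(default λ = 0.02, intensity-normalized), coarse-to-fine over a 3-level
image pyramid, with gradient descent and Armijo backtracking (monotone
objective). The convention is pull-back: u maps a material point at x in
frame n−1 to x + u(x) in frame n, so fields compose forward in time by the
recursion u(x;0,n) = u(x;0,n−1) + u*(x + u(x;0,n−1)), with trilinear
interpolation of u* at the advected point; advected points leaving the grid
are clamped and masked, and masked voxels are excluded from downstream
sums. Warping uses trilinear interpolation for grey values and
nearest-neighbour for labels.

Registration quality is summarized by ε_u = (composed − direct)/max|direct|
where "direct" is one extra pairwise solve between the reference frame and
a late frame. The pipeline anchors the direct solve at the *peak-inflation*
phase: at end-exhalation the true field returns to ~zero and the
normalization is ill-conditioned. ε_u is reported as a per-voxel vector
magnitude (the component-wise alternative is noted but not used).

The optimizer is native to the package and is the reference implementation
the tests run against; the registration entry point is a seam behind which
an external engine could be substituted.

## Strain and surface change

Strain is the divergence of the Lagrangian field (δV/V at breath start, not
a log strain), estimated with a moving-least-squares corrected kernel
convolution over segmented voxels only:

    ⟨∇·u⟩(x_i) = Σ_{j∈Ω} (u_j − u_i) · (L(x_i)·∇W(x_j − x_i)),
    L(x_i) = [Σ_{j∈Ω} (x_j − x_i) ⊗ ∇W(x_j − x_i)]⁻¹

with W a cubic B-spline radial profile of support 2.5 voxels. The
difference form (u_j − u_i) is used because it is algebraically identical
to the plain convolution wherever the stencil is symmetric and extends
exact linear consistency (affine fields recovered to machine precision) to
boundary voxels with truncated supports. L is a per-voxel 3×3 solve with a
condition-number guard (default 10⁶); ill-conditioned voxels — isolated or
needle-thin structures — are masked invalid rather than extrapolated, and
the volume sums assign them the mean strain of the valid voxels.

Volume change is Δv(t) = Σ_Ω ⟨∇·u⟩·v_voxel over Ω at breath start; both the
dimensionless voxel-count form and the physical form are available. An
independent discrete-flux cross-check (Σ_{∂Ω} u·n̂ with face-centred
sampling) agrees with the volume sum within 5 % on phantoms.

Surface change uses the divergence theorem on the curvature-weighted field:
Δs(t) = Σ_Ω ⟨∇·(h u)⟩, whose flux form ∮ h (u·n̂) dS is the first-order
change of the internal surface area when h is the total curvature κ₁+κ₂ on
∂Ω (2/R on a sphere). h is estimated as the divergence of the outward unit
gradient of the Gaussian-smoothed signed distance function (σ = 1 voxel),
propagated from voxel centres to the zero level set by κ₀ = κ/(1 + |φ|κ/2)
(exact for spheres, which anchor the convention), and clipped at 0.6/voxel
to contain medial-axis and rim singularities. The estimator carries a
frozen sphere-calibrated factor 0.949, fixed once so that a digital ball of
radius 12 voxels under a uniform radial displacement of 0.5 voxel
reproduces ΔS = 8πRδR; the convention and factor are recorded here and in
the output metadata. "Total curvature κ₁+κ₂" is a deliberate resolution of
the ambiguous naming of h — the sphere oracle cannot distinguish
conventions differing by a constant, which is exactly why it is used as the
calibration.

The baseline S(0) of the conformation series is anchored by the divergence
identity S = Σ_Ω ∇·n̂ (the flux of the unit normal through ∂Ω) rather than
by marching cubes: the identity shares its discretization with the Δs
estimator, so the ratio S(t)/S(0) is unbiased, whereas mixing a
marching-cubes anchor with the divergence increments inflates relative
surface change by the ~10 % scale mismatch between the two discretizations
on multi-scale geometry. A marching-cubes area (on a lightly smoothed mask,
σ = 0.6) is still provided and validated against analytic spheres.

## Recruitment detection

Airspace segmentations are thinned to one-voxel skeletons
(topology-preserving 3D thinning; a guard restores the EDT-deepest voxel of
any connected component the thinning deletes outright, which happens for
small digital balls). The baseline skeleton is advected by the Lagrangian
field, rounded to voxels, clamped and masked at the grid edge. For each
phase-skeleton voxel, d_Ω (EDT to the segmentation boundary) and d_s (EDT
to the deformed baseline skeleton) are compared; voxels with d_s > d_Ω seed
recruited structures, grown to full structures by a marker watershed of the
inverted EDT inside Ω competing against the deformed baseline skeleton.
Distances are Euclidean in voxel units (isotropic voxels). The optional
minimum seed-component size is off by default: a compact recruited
alveolus thins to a single skeleton voxel, and the d_s > d_Ω margin — a
false seed needs skeleton error exceeding the local structure radius —
already suppresses jitter (verified: zero false positives across registered
no-recruitment phantom series, and under ±0.5-voxel field perturbation).

## Conformation fit

S = kV^n is fitted by ordinary least squares of log S on log V (natural
logs; k = exp(intercept)), pooling the inflation and deflation limbs;
`split_limbs` allows limb-separate fits for hysteresis exploration.
Reference regimes: n < 0.67 ductal-dominant, n ≈ 0.67 isotropic,
0.67 < n < 1 alveolar-dominant, n ≈ 1 recruitment-like, with a ±0.03 band
around the reference exponents. The pipeline fits the *peripheral*
airspace — intermediate ducts plus terminal units, the proximal bronchus
excluded — because the regime separation depends on including the
non-participating ductal volume alongside the deforming alveoli.

## The phantom and what passing tests show

The generator renders a proximal trunk (r = 10 vx) feeding an intermediate
acinar duct (r = 6.5 vx), three clusters of five spherical terminal units,
and one vessel, on a 64³ grid at 6 µm voxels, deformed over a raised-cosine
breath (inhale half / exhale half, nominal duration 0.76 s). Greyscale:
tissue 1.0, air 0.0, blood 0.8, additive Gaussian noise (default σ = 0.05),
2× supersampled anti-aliased rendering (labels are center-inclusion
against the exact implicit surfaces). Unit spheres are pairwise disjoint
and clear of the ducts, so the analytic V and S of the airspace union are
plain sums of primitive formulas (cylinder areas include both end caps;
the junction overlap of trunk and duct is the one deliberate approximation
and is excluded from the peripheral sums anyway). Default amplitudes:
ε = 0.05 for the isotropic breath, 0.15 for the ductal/alveolar regimes
(where only part of the scene deforms); the alveolar-size distribution at
this resolution is not constrained by any source, so unit radii are free
parameters with defaults of 4–5 voxels.

Deformation regimes and their analytic exponents as built: isotropic
n = 2/3 exactly; ductal-dominant (duct radius scales) n ≈ 0.39;
alveolar-dominant (units scale about their own centres, ducts fixed)
n ≈ 0.89; recruitment (units appear at prescribed steps, no deformation)
n = 1 exactly. The `custom_analytic` mode supports user displacement
callables through `analytic_displacement` but is not renderable — a
consistent image series for an arbitrary warp of the implicit geometry is
out of scope.

What the phantom does **not** emulate: phase-contrast edge enhancement,
reconstruction artefacts (cupping, streaks), cardiac-frequency motion
superimposed on the breath, intra-breath derecruitment, irregular alveolar
shapes and shared septal walls, and anisotropic voxels. Passing the
end-to-end tests therefore demonstrates that the operators are correct and
that the pipeline recovers imposed kinematics on attenuation-like contrast
with realistic noise; it does not by itself validate performance on real
phase-contrast reconstructions.

## Problem sizes and determinism

The bundled study conditions are 64³ grids with 4–10 phase bins per breath:
large enough that every structure class is several voxels deep and the
registration pyramid has three useful levels, while a full three-regime
pipeline sweep (≈ 26 pairwise registrations) completes in a few minutes on
one core. All randomness (phantom noise, synthetic ECG jitter, projection
times) flows from explicit integer seeds; identical configuration plus seed
reproduces bit-identical volumes and identical pipeline bundles, and every
pipeline stage writes a resumable intermediate keyed by the configuration
hash.
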