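# Methods

## Model overview

`piezoecho` solves the ultrasound forward problem in two complementary
pieces, both linear in the excitation:

1. a **full-domain scattering operator** — the time-harmonic volume
   integral equation for the total pressure in an inhomogeneous lossy
   medium, solved iteratively — giving the spatial distribution of the
   incident, total and scattered fields; and
2. a **ray-tracing operator** — straight-segment rays with Snell
   refraction, interface amplitude splitting and per-segment
   attenuation/phase delay — giving the time-resolved echo train at a
   detection aperture.

The split assumes the time-invariant interference phenomena (scattering,
absorption) can be computed independently of the time-of-flight effects
(refraction, delays). Shear waves, mode conversion, anisotropy and
nonlinear propagation are out of scope.

## Materials and attenuation

Tissue rows carry a power-law attenuation model α(f) = a·fʸ with `a` in
dB·MHz⁻ʸ·cm⁻¹ and f in MHz; internally everything is SI (Np/m, conversion
1 Np = 8.6859 dB, 1 cm⁻¹ = 100 m⁻¹). The phase constant is
β = ω/v + tan(πy/2)·a·fʸ (same unit convention), the standard power-law
dispersion correction. That correction is singular at y = 1 (the muscle and
fat rows); the usual remedy replaces it with a logarithmic form, and since
the printed model covers only the tan form we set the correction to zero at
y = 1. The attenuation term α is unaffected. Piezo rows (no attenuation
law) are treated as lossless (a = 0) when they enter per-cell maps.

The water density is 1000 kg/m³; PDMS is assigned fat-like acoustic
properties (its impedance is close to fat), both as overridable table rows.
The background medium of a scene defaults to water, the majority medium of
every built-in scene; it is configurable per scene.

## Mesh and discrete operators

The domain is tiled by cubic cells at up to three resolution levels
(h, h/2, h/4; defaults 10/5/2.5 mm at full scale, 5/2.5/1.25 mm in the
desk-scale scenes), refined by octant splits with 2:1 face grading.
Refinement propagates across faces only, not edges or corners. Neighbor
relations are kept in six sparse matrices (per axis and direction): a
same-level neighbor contributes a single 1; a coarse cell facing four finer
cells reads them with equal interpolation weights 1/4 (the simplest scheme
whose weights sum to one); a fine cell reads its single coarser neighbor
with weight 1; boundary rows are zero.

The raw topological operators are `div = 3D − N_xx+ − N_yy+ − N_zz+` and
`grad_c = D − N_cc−`. Note the raw `div` is the *negative* of a
forward-difference divergence; the scaled physical variants divide by the
face-pair distance (mean of the two cells' edge lengths) and flip the
divergence sign, so that scaled div∘grad reproduces the standard 7-point
Laplacian (−6/h² centre, +1/h² neighbours) on uniform interiors. Boundary
rows of the scaled operators are zeroed (no one-sided stencil is invented
there). Cell indexing is 0-based, lexicographic with x fastest; cells are
half-open boxes; values live at barycentres.

## Scattering solver

### Kernel discretisation

The continuous kernel is G(r) = exp(−γ₀|r|)/(4π|r|). A midpoint
discretisation K_jl = G(r_jl)·V_l is accurate only when cells are small
against the wavelength. The study conditions are the opposite regime
(h = 1.25–5 mm against λ ≈ 0.3 mm at 5 MHz), where midpoint sampling loses
the sub-cell phase cancellation of the oscillatory kernel and inflates the
operator by orders of magnitude. We therefore integrate the kernel
analytically over each source cell's volume-equivalent sphere
(r_eq = h·(3/4π)^{1/3}):

* off-diagonal: K_jl = G(r_jl)·V_l·F(γ₀ r_eq), with the form factor
  F(x) = 3(x cosh x − sinh x)/x³ → 1 as x → 0, so the midpoint product is
  recovered exactly on wavelength-resolved grids;
* diagonal (self term): the exact integral of G over the sphere,
  (1 − e^{−x}(1+x))/(γ₀²V), which reduces to the mean of 1/(4π|r|) over
  the sphere (R²_eq/2 per cell volume) in the lossless limit.

This is the standard method-of-moments regularisation for volume integral
equations; it keeps the discrete operator a small perturbation of the
identity in the weak-contrast (Born) regime, which is what makes iterative
solution at coarse resolution meaningful at all.

The operator is stored as a dense complex matrix up to 6000 cells and
applied matrix-free in row blocks above that; both modes share the block
constructor, so tests of one exercise the other.

### Conjugate gradient

The system O[p_tot] = p_inc is solved from p₀ = 0 by conjugate gradient on
the normal equations, with the update direction built from the Hermitian
adjoint O*. Two step-size rules are implemented:

* `variant="cgnr"` (default): textbook squared-norm ratios
  (θ = ‖O*r‖²/‖Oξ‖², momentum ‖O*rₙ‖²/‖O*rₙ₋₁‖²). This is a descent
  method; its error history is monotone and it converges to the direct
  dense solution (verified to 1e−6 against `numpy.linalg.solve`).
* `variant="printed"`: the same recursion with plain (unsquared) norm
  ratios. This variant is **not** a descent scheme — on any appreciably
  contrasted scene it diverges within a few iterations — and is retained
  only for comparison. It cannot produce a monotone sub-10 % error
  history, so the convergent CGNR rule is the package default.

Stopping: relative residual ‖r‖₂/‖p_inc‖₂ ≤ 10 % (configurable) or 100
iterations. The incident field is computed once per scenario and never
updated during iteration. On the reference breast scene (3556 cells,
5 MHz) CGNR passes the 10 % stopping level in 16 iterations and reaches
≈0.02 % at the 100-iteration budget.

## Ray tracer

* Refraction index: n = v_background/v_medium, so Snell's law reduces to
  sinθ₁/v₁ = sinθ₂/v₂.
* Amplitude split: Υᴿ = R·Υ and Υᵀ = (1−R)·Υ with the normal-incidence
  impedance coefficient R = (Z₂−Z₁)/(Z₂+Z₁), conserving the nominal
  amplitude exactly (Υ = Υᵀ + Υᴿ) at every event, including total internal
  reflection (the transmitted branch folds into the reflected one). The
  physically standard pressure-continuity split T = 1 + R is available via
  `pressure_continuity=True`. R is reused at oblique incidence (no oblique
  formula is modelled).
* Interface hits are accepted inside a tolerance sphere of radius
  0.5·(4500 m/s)/f, 4500 m/s being the average velocity over the tissues
  and piezo materials used; marching steps at half that radius. After an
  interface event a child ray ignores hits for two tolerance radii so it
  can leave the parent's hit neighbourhood.
* Emission: ray origins uniform over the source disk, directions uniform
  in solid angle within a forward cone (default half-angle 30°); amplitude
  per ray = source amplitude / n_rays. All sampling is seeded.
* Termination: 1000 wavelengths travelled, amplitude below the
  10 µV-equivalent threshold, or domain exit. Echo records are dropped
  below that threshold and capped at the 1200 largest.
* Media are sampled per marching step from the per-cell property maps, so
  delay Σ Δ/v and attenuation exp(−Σ αΔ) are exact in piecewise-constant
  regions.

## Signals

Waveforms live on a 20 MS/s grid over 100 µs (the acquisition settings of
the detection electronics). The impulsive excitation is
v(t) = 10 sin(ωt)·exp{−[0.2ω(t − 8π²/ω)]²/20}; echo synthesis superposes
that template at each arrival (nearest-sample delay quantisation,
pressure-to-voltage factor 1, i.e. perfect electromechanical coupling).
Echo energy is E = Σ|x(t)|² over the window; the spectrum is the one-sided
unnormalised DFT magnitude, with Parseval's identity
Σ|x|² = (1/N)Σ|X_k|² (interior one-sided bins doubled) used as a
consistency check.

## Synthetic scenes

The generator replaces external anatomical imagery with three reproducible
scenes:

* **water_tank** — homogeneous water box, default 0.30 × 0.25 × 0.25 m
  (the experimental tank footprint), source plane centred on one wall;
* **layered_breast** — hemispherical breast analog (default shells: skin
  2 mm, fat 10 mm, breast interior 18 mm; dome radius 30 mm) resting on a
  10 mm chest-wall (muscle) slab, immersed in water, with the source
  transducer in contact with the skin at the dome apex aimed down the dome
  axis (as in the breast-phantom experiments). Skin is assigned
  breast-tissue acoustic values in the default table (no dedicated skin
  row exists); desk-scale defaults keep the grid below 5000 cells after
  implant refinement;
* **homogeneous** — single-material box for controlled tests.

The **reference implant scenario** embeds a lens implant
(PZT-5A inner 1 mm / LiNbO₃ outer 2 mm, 1 × 1 × 0.5 cm bounding box,
0.5 mm PDMS shell) 1 cm above the dome centre facing the source; embedding
refines the mesh to the finest level in a padded box around the implant and
along the source–implant corridor.

What the generator emulates: realistic property contrasts, curved nested
tissue interfaces, a strong scatterer at depth, water coupling. What it
does not: anatomical irregularity, speckle-scale heterogeneity,
out-of-plane asymmetry, real skin properties. Passing tests on these
scenes therefore validates the numerics and the implementation contracts,
not clinical-scale predictive accuracy.

## Implant geometry

Lens = paraboloid cap (height = bounding thickness) on a circular base;
disk = right cylinder; cone = right cone with apex along the axis. Layer
interfaces are inset copies of the bounding shape: lateral and front
surfaces move inward by the cumulative layer thickness while the base
plane is shared, mirroring a coated transducer stack. (A symmetric inset
on all sides would make the default configuration — 1 mm/2 mm layers in a
1 × 1 × 0.5 cm solid — geometrically degenerate.) Strict layer nesting
holds for every surface point off the shared base plane; the base ring is
the documented exception, as is the cone base edge for the
outward-normal/centroid convexity property. Surfaces are sampled at
≤ λ/4 at 10 MHz in tissue (37.5 µm) with analytic outward normals; inward
normals are their exact negatives.

## Known limitations

* The grids are far coarser than the wavelength at MHz frequencies; the
  cell-averaged kernel makes the discrete operator well behaved, but
  sub-wavelength field structure is not resolved. This matches the method
  being reproduced, not diffraction-accurate simulation.
* On the layered-breast scene the fat/water contrast directly under the
  source keeps the peak scattered magnitude comparable to the peak
  incident magnitude at desk scale; the order-of-magnitude separation
  between scattered and incident fields is asserted on the water-tank
  implant scene (implant 4 cm on-axis, within the experimental stand-off
  range), where the implant is the only scatterer.
* The amplitude-conserving split T = 1 − R under-weights transmission
  relative to pressure continuity (T = 1 + R); choose the variant
  explicitly when absolute echo amplitudes matter.
* Segmentation clusters on grey level only (k-means, deterministic seed,
  clusters ordered by intensity); it is intended for high-contrast
  phantom imagery, not clinical-grade tissue classification.
* Boundary extraction assumes star-convex tissues; for others the first
  radial transition is used and a warning is emitted.
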