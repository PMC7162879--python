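# piezoecho

3D ultrasound forward-problem simulation for deeply implanted piezoelectric
devices.

Acoustically powered implants — small solids carrying a double piezoelectric
layer (e.g. PZT-5A under LiNbO₃) inside a bio-compatible PDMS shell — can be
interrogated from outside the body with an ultrasound transducer. Designing
such a device requires predicting (i) the pressure field an external source
sets up inside inhomogeneous tissue containing the implant, and (ii) the echo
train the implant returns to the probe. `piezoecho` computes both, for users
prototyping implant geometry (lens / disk / cone), layer materials and
thicknesses, excitation frequency and detection aperture.

## The two forward operators

**Scattering operator.** In a lossy medium with background density ρ₀ and
complex propagation coefficient γ₀ = α₀ + iβ₀ (power-law tissue attenuation
α = a·fʸ), the total pressure obeys the volume integral equation

```
p_tot(r) = p_inc(r) + ∫ G(r−r′) Δγ(r′) p_tot(r′) dV
                    + ∫ G(r−r′) ∇·[Δρ(r′) ∇p_tot(r′)] dV
```

with the lossy free-space kernel G(r) = exp(−γ₀|r|)/(4π|r|), density
contrast Δρ = (ρ₀−ρ)/ρ and propagation contrast Δγ = γ₀² − (ρ₀/ρ)γ². The
incident field of the discretized circular piston source is
p_inc(r) = iωρ₀ Σ G(r−r*) s(r*) ΔS. Discretized on a graded octree mesh
(three resolution levels; the finest cells cover the source–implant
corridor), the equation becomes a linear system p_inc = O[p_tot] that is
solved by conjugate gradient on the normal equations, using the Hermitian
adjoint of the assembled operator; the run stops at a relative residual
‖r‖₂/‖p_inc‖₂ of 10 % or after 100 iterations.

**Ray-tracing operator.** Rays leave the source over a forward cone, travel
in straight segments, and at every tissue or implant interface split into a
reflected and a transmitted branch. The refracted direction follows the 3D
vector form of Snell's law with the interface normal (refraction index
n = v_background/v); amplitudes split with the impedance reflection
coefficient R = (Z₂−Z₁)/(Z₂+Z₁) so that Υ = Υᵀ + Υᴿ. Rays accumulate delay
Σ Δ/v and attenuation exp(−Σ αΔ) and die after 1000 wavelengths or below the
10 µV-equivalent threshold. Arrivals crossing the detection aperture
(diameter swept over 0.01–0.07 m) are superposed into the received waveform
using the excitation template (10 V Gaussian pulse or harmonic), capped at
1200 records.

Scenes come from a built-in synthetic generator (water tank, layered breast
analog with skin/fat/breast shells over a chest wall, homogeneous box) or
from grey-level slice stacks segmented by Gaussian smoothing + k-means, with
tissue boundaries and normals extracted by radial marching.

## Worked example

```python
import numpy as np
from piezoecho import materials as mat
from piezoecho import scattering as sca, raytrace as rt, signals as sig
from piezoecho.runner import reference_breast_scenario

z_li = mat.acoustic_impedance(mat.get_material("LiNbO3"))
z_pz = mat.acoustic_impedance(mat.get_material("PZT-5A"))
print(f"Z(LiNbO3)  = {z_li:.2f} MRayls")
print(f"R(tissue->LiNbO3)  = {mat.reflection_coefficient(1.5, z_li):.3f}")

scene, source = reference_breast_scenario(seed=1, frequency=5e6)
total, scattered, state = sca.cg_solve(scene, source, max_iter=100, tol=0.10)
print(f"scene: {scene.grid.n_cells} cells, "
      f"CG error {state.errors[-1]*100:.2f}% after {state.iterations} iterations")

rays, _ = rt.trace_rays(scene, source, 5e6, n_rays=256, seed=1)
records = rt.collect_echo(rays, source.center, 0.03, 5e6,
                          detector_normal=source.normal)
echo = sig.synthesize_echo(records, sig.gaussian_pulse(5e6))
energy, peak, n_inter, _ = sig.echo_metrics(echo, records=records)
print(f"echo: {n_inter} meaningful interactions, peak {peak*1e3:.2f} mV")
```

prints

```
Z(LiNbO3)  = 34.15 MRayls
R(tissue->LiNbO3)  = 0.916
scene: 3556 cells, CG error 9.10% after 16 iterations
echo: 21 meaningful interactions, peak 200.22 mV
```

The impedance mismatch between soft tissue (≈1.5 MRayls) and the outer
LiNbO₃ layer reflects ≈92 % of the incident pressure amplitude — the effect
that makes the implant visible from outside — while the LiNbO₃/PZT-5A
interface is nearly matched. The conjugate-gradient solver reaches the 10 %
stopping residual in 16 iterations on the 3556-cell breast scene; the echo
line reports the arrivals the 3 cm aperture collects from the lens implant.

A `piezoecho` CLI wraps the same stages
(`build-scene`, `run-scattering`, `run-raytrace`, `sweep`, `report`)
around a YAML scenario file.

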