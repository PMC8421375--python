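# Methods

## Model

`phasemc` is a Monte Carlo radiation transfer (MCRT) engine in which each
photon power packet carries, in addition to position and direction, its
accumulated optical path length OPL = Σ nᵢ·lᵢ over the segments it has
travelled. A packet's complex field is

    E = E₀ · exp(i·2π·OPL/λ),      E₀ = √(P/A) / N,

where P is the beam power, A the illuminated area used for normalization,
N the number of packets and λ the vacuum wavelength. Interference is
evaluated per area or volume element only: each packet adds its field to
exactly one detector bin (or voxel-plane bin), and the intensity of a bin
is the squared modulus of its field sum,

    I(ξ) = |Σ_ξ E₀·cos(2π·OPL/λ) + i·Σ_ξ E₀·sin(2π·OPL/λ)|².

Packets never interfere at points — ballistic packets essentially never
meet — so the bin size is a resolution/coherence trade-off; 1 μm bins are
the default for the detector scenes here.

### Huygens–Fresnel launching

Sources are wavefront-shaping elements (slit pair, square aperture,
plano-convex lens, axicon). Packets are placed on the element's emitting
surface and receive a direction by uniformly sampling a point on the
downstream target plane; only forward-going wavelets are generated. The
optical path up to the emitting surface is obtained by exact vector-Snell
ray tracing through the glass (plane-wave or collimated-Gaussian
illumination defines a zero-phase reference plane at the element's first
surface).

Two details of the sampling measure matter for quantitative agreement
with wave optics and are design choices of this package:

1. **Launch density is field amplitude.** The expected accumulated field
   in a bin is ∝ ∫ p(ρ)·e^{ikL(ρ)} dρ over the emitting surface, so the
   position density p plays the role of the aperture field amplitude in
   the Huygens integral. Uniformly illuminated apertures therefore use
   uniform sampling, and a Gaussian beam with 1/e² intensity radius w
   samples positions from the *amplitude* profile e^(−ρ²/w²) (a normal
   with σ = w/√2 per axis) while E₀ stays constant across packets.
   Sampling from the intensity profile instead would narrow the effective
   aperture by √2 and inflate the focal waist by the same factor.

2. **Bundle compression.** When an element compresses the ray bundle
   between its entry and exit surfaces (a convex-first lens converges
   rays inside the glass), the launch density at the exit surface
   acquires the full area-compression Jacobian, whereas energy
   conservation requires the *field* amplitude to grow only with its
   square root. Each packet's field is therefore scaled by
   m = h_exit/h_entry (paraxially m = 1 − t(n−1)/(nR) for a convex-first
   plano-convex lens; m = 1 for thin elements, flat-first lenses and
   axicons). Without this factor a focusing lens over-weights its beam's
   intensity by 1/m² (≈ 1.39 for the modelled singlet), which matters
   whenever two different beams are compared on a common intensity scale.

No obliquity (cosine) factor and no 1/L spherical-wave decay are applied,
following the algorithm being modelled; over the small detector fields
and near-paraxial angles of every scene here both are negligible within a
single scene, and the comparisons that span scenes are made at a common
detector plane.

### Elements

* **Slit pair / square aperture** — thin screens at z = 0; positions
  uniform over the open area (each slit chosen with probability ½),
  OPL = 0 at the screen (plane-wave illumination).
* **Plano-convex lens** — exact Snell refraction at the spherical surface;
  `convex_first` (default) places the curved side toward the collimated
  source, the standard focusing orientation whose back focal distance
  f − t/n matches the modelled singlet's quoted working distance;
  `flat_first` is also supported. Rays missing the usable aperture (the
  mechanical semi-diameter clamped to the spherical cap's extent) or
  totally internally reflected are discarded and counted.
* **Axicon** — flat entry face, conical exit surface z = t − r·tan α with
  the tip downstream; exact Snell at the cone deflects rays toward the
  axis by β = arcsin(n·sin α) − α ≈ (n−1)α. A ray exactly on the axis is
  left undeviated (probability-zero event, fixed for determinism). A
  helical order m adds OPL = m·φ·λ/2π at azimuth φ, producing an m-th
  order (vortex) Bessel beam with an on-axis null.

### Transport in scattering media

Media are homogeneous axis-aligned slabs/cuvettes. Free paths are
exponential against μt = μs + μa (s = −ln U/μt); deflection cosines follow
the Henyey–Greenstein phase function with asymmetry g (the de facto
tissue-optics standard; the scalar g is the only shape parameter the
modelled experiments state); azimuths are uniform. Absorption is sampled
with probability μa/μt at each interaction and terminates the packet —
partial packet weights have no phase semantics in a coherent sum, so all
surviving packets keep constant amplitude. A sampled step that would
leave the slab is clipped exactly to the face intersection; packets
crossing the far (detector-facing) face are detected with their exact
exit point and total OPL, all other exits are discarded. Boundaries are
index-matched: no Fresnel reflection or refraction, the medium index
enters only through OPL accumulation.

One consequence of index-matched boundaries is that a beam converging at
angle β in air keeps that geometric angle inside the medium while its
phase advances n× faster, so the transverse fringe frequency at a depth
reached through l_air of air and l_med of medium is

    k_r,eff = k·sin β · (l_air + n·l_med)/(l_air + l_med),

not the n·k·sin β of a refracting interface. The in-medium consistency
checks use this effective wavevector.

With a medium present, Huygens directions still aim at a window on the
detector plane (by default the detector extent) and the random walk
starts where the ray crosses the entry face. This keeps the free-space
importance sampling for the ballistic component; scattered packets evolve
physically from their launch ray. Light that would enter the cuvette far
off-axis and scatter back toward the detector is consequently
under-represented, so diffuse backgrounds are lower than a full-face
launch would give — the in-medium tests therefore assert pattern
consistency and relative degradation, not absolute diffuse levels.

### Detection

2D detector planes and interior recording planes are complex
accumulators; straight segments (free space or between scattering events)
deposit the packet field at each plane crossing with the OPL at the
crossing. Voxel indexing is 0-based half-open, a point on an internal
boundary belongs to the higher-index bin. Images can be max-pixel
normalized (the convention used when comparing simulated and experimental
exit-face images); an all-zero field is returned raw with a warning flag.

## Gaussian vs Bessel beam comparison

The Bessel core is matched to the Gaussian waist through the 1/e² metric:
κ = 1.75 solves J₀²(κ) = e⁻², the core radius is r₀ = κ/(k·sin β), and
setting r₀ equal to the focal waist w₀ = 2λf/(πD) gives the axicon angle

    α = arcsin(1.75·D/(4f)) / (n − 1).

The comparison fixtures use the singlet of the Gaussian-beam scene
(ROC 4.6 mm, t = 2.2 mm, fused silica n = 1.4631 at 488 nm,
f = R/(n−1) = 9.93 mm) and the D = 0.5 mm beam used with that lens; the
matched axicon then has α ≈ 2.73° and shares the lens's centre thickness
so both elements span the same axial extent. With the configured
geometry the core-width mismatch is 0.02%, far inside the 2% refusal
threshold.

`matched_peak` calibration runs both beams in free space at equal power
with the detector at the Gaussian focal plane (paraxial ray-trace focus,
z = t + f − t/n) and takes the ratio of the on-axis 1 μm-bin intensities;
since intensity is linear in power (E₀ ∝ √P), that single ratio is the
power scaling that equalizes the maxima. At 10⁷ packets per beam the
ratio is ≈ 15 with a seed-to-seed spread of roughly ±1.5 (central-bin
speckle); the acceptance script uses 3×10⁷ per beam, narrowing the spread
to about ±0.6.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| wavelength | 488 nm | the laser line of every modelled scene |
| lens n | 1.4631 | fused silica at 488 nm |
| lens orientation | convex_first | standard focusing orientation; matches the quoted 8.5 mm working distance |
| axicon thickness | 2.2 mm | same axial extent as the lens blank, so comparison planes are a common distance from both exit surfaces |
| detector bins | 1 μm | the bin resolution of the modelled exit-face images |
| g (Intralipid) | 0.82 | published Intralipid anisotropy near 488 nm; user-overridable |
| Intralipid μs anchor | 557.14 m⁻¹ at 2 μL/500 μL | anchor row of the dilution series; "table" scaling reproduces the printed series exactly (linear in stock volume), "volume_fraction" scaling is the physically-correct alternative |
| n (water/Intralipid) | 1.33 | water at visible wavelengths |
| packet blocks | 10⁶ | reproducibility contract: fixed blocks with spawned substreams make results independent of chunking |
| max events | 10⁵ | safety valve against pathological walks; never reached in practice |

## Problem sizes

All validation scenes run at 10⁷ packets (the cuvette degradation scan
uses 3×10⁶ per dilution), roughly 1% of the original studies; the
agreement thresholds (correlation ≥ 0.98–0.99, waist within 5%, power
ratio 12–18) are stated at this statistics level. Vectorized numpy makes
a 10⁷-packet free-space scene run in seconds on one core.

## What the fixtures emulate — and what they do not

The fixture configurations generate every input the simulator needs; no
external data are read. They emulate idealized bench scenes:
monochromatic, perfectly collimated, spatially coherent illumination;
lossless, aberration-free-mounted elements; homogeneous media with a
single (μs, μa, g, n); index-matched cuvette walls with no reflections;
an ideal detector that records every far-face crossing regardless of
angle (no objective/NA model, no camera noise or background). Passing
tests therefore demonstrate the engine's wave-optical and transport
correctness against analytic theory — not agreement with any physical
camera image, which would additionally involve collection optics,
Fresnel losses, beam imperfections and detector response.

## Numerical choices

* Exact vector Snell everywhere in glass; small-angle formulas live only
  in `theory` as oracles.
* Half-open bin/voxel intervals; boundary points go to the higher index.
* On-axis axicon rays are undeviated by convention.
* Free-path sampling uses U ∈ (0, 1], so U = 1 gives a zero step and
  −ln U never overflows.
* Degenerate comparisons (constant images) are flagged rather than
  returning a spurious correlation; all-zero images cannot be
  max-normalized and are flagged.
* κ values are obtained by Brent root finding on J₀ and J₀²−e⁻², not from
  printed constants.
* The waist fit adds a constant offset to absorb the finite-N speckle
  pedestal, and the caustic fit leaves the focus location free, as a beam
  profiler would.

## Known limitations

* No polarization, fluorescence, or heterogeneous (voxel-wise) optical
  properties; one homogeneous slab per scene.
* No Fresnel reflection/refraction at medium boundaries (see the
  effective-wavevector consequence above).
* The missing 1/L and obliquity factors of the full
  Huygens–Fresnel–Kirchhoff kernel are inherited from the modelled
  algorithm; they bias only comparisons across widely different
  propagation distances.
* Diffuse background under-representation with the windowed in-medium
  launch, as described above.
* Absolute intensities are meaningful relative to P/A per scene; no
  radiometric calibration is attempted.
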