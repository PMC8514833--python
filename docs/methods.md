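# Methods

This document describes the models, numerical choices and known
limitations behind `ratsar`: a desk-scale reconstruction of the dosimetry
of two freely moving rats in a shared cage under 1.8 GHz far-field
exposure. The pipeline estimates how much a neighbouring animal changes
one animal's whole-body average specific absorption rate (WB-avgSAR),
time-weighted by how the pair actually postures itself over a recording.

## 1. Problem model

Two adult rats share a 0.46 m × 0.30 m cage under a plane wave at
1.8 GHz (free-space wavelength λ ≈ 166.7 mm) with incident power density
S = 1 W/m², propagating downward (+Z → −Z). Two linear polarisations are
considered, named by the field-vector/propagation ordering relative to
the reference animal:

* **EHK** — E parallel to the rat's long (spine) axis;
* **HEK** — E parallel to the rat's short axis.

The relative posture of the pair in a frame is reduced to a triple

* `d` — centre-to-centre distance (mm),
* `α` — angle of the connecting line measured from the axis
  perpendicular to rat 1's long axis,
* `β` — angle between the two long axes,

folded into the first quadrant (head/tail and animal-exchange
indistinguishability) and binned on a 5 × 5 × 5 grid: `d` in λ/2 steps
(0, 0.5λ, λ, 1.5λ, 2λ+), angles in 22.5° steps. Bins are enumerated as
`case_id = 25·d_idx + 5·α_idx + β_idx + 1`, i.e. 125 cases. The
occupancy probability `W_i` of case `i` is its frame fraction over the
recording.

Per case, the neighbour's influence on rat 1 is the variation rate

```
η_i = (S_1i − S_1) / S_1 × 100 %
```

with `S_1i` rat 1's WB-avgSAR in case `i` and `S_1` the single-animal
reference, and the recording-level effect is the time-weighted average

```
η_avg = Σ_i W_i · η_i .
```

All 25 `d = 0` cases describe a closely huddled pair whose angles are
not meaningful; they are merged into one super-case represented by a
flank-to-flank contact configuration, and its SAR value is broadcast to
cases 1–25.

## 2. Synthetic recordings

No video of the original experiment is available, so the package
generates one: two warm elliptical bodies (244.8 mm × 46.8 mm) move
through a cooler cage under a seeded correlated random walk, with a
`contact_affinity` parameter biasing steps toward the other animal to
produce huddling episodes. Frames are rendered as false-colour RGB
(body heat in the red channel, background in the blue channel), with a
soft 10 % rim on each silhouette emulating a slightly defocused thermal
camera and Gaussian sensor noise on all channels. Every frame carries
exact ground-truth poses, which is what makes the downstream stages
testable without any external data.

## 3. Tracking

Segmentation follows the classic thermal-video chain:

1. grayscale = red − blue channel difference (body-vs-background
   contrast regardless of the colour map);
2. Otsu threshold on the bimodal histogram;
3. connected components; specks below 10 % of one expected body area are
   dropped as noise. A single merged component is split by a
   marker-controlled watershed on the negated Euclidean distance
   transform, with markers taken as the connected cores above 70 % of
   the distance maximum. A tight huddle yields one core, stays one
   label, and is flagged as a contact frame (binned into the `d = 0`
   super-case).
4. Each labelled region is summarised by its second-moment ellipse:
   centroid, orientation (principal eigenvector of the pixel covariance,
   folded to [0, 180)), and semi-axes (2σ along each eigenvector). When
   the eigenvalue ratio is too close to 1 the orientation is
   meaningless; it is flagged unreliable and the previous frame's
   orientation for that identity is carried forward.
5. Frame-to-frame identity is kept by minimum total centroid
   displacement (identity vs. swap).

On the reference synthetic benchmark (200 frames, separated resting
animals, 2 mm/pixel, noise sd 5) the chain recovers centroids with a
median error well below 1 mm and orientations well below 1°
(`scripts/acceptance.py` recomputes this from scratch).

## 4. Field solver

WB-avgSAR is computed by a purpose-built 3-D FDTD solver on a uniform
Yee grid.

**Phantoms.** Each rat is a homogeneous prolate ellipsoid with circular
cross-section, semi-axes 23.4 × 122.4 × 23.4 mm (from the
244.8 × 46.8 mm animal), filled with two-thirds-muscle tissue
(ε_r = 53.5, σ = 1.34 S/m, ρ = 1040 kg/m³). Mass follows from volume
times density (~0.29 kg) rather than being forced to a nominal animal
weight — a documented simplification. The internal wavelength is
λ/√ε_r ≈ 22.8 mm, so a 2 mm grid resolves it with ~11 cells and a 4 mm
grid with ~6.

**Boundaries and source.** Seven-layer CPML (polynomial grading of
order 3, σ_max = 0.8(m+1)/(Z₀Δ), κ = 1, α_max = 0.05) lines every face.
The plane wave enters through a total-field/scattered-field (TF/SF) box
with a dispersion-matched analytic incident field: the incident-wave
phase uses the numerical wavenumber k_num = (2/Δ)·asin((Δ/(cΔt))·
sin(ωΔt/2)) of the discrete axial dispersion relation, which keeps the
empty-scene interior field equal to the nominal amplitude to machine
precision. The drive is a CW sinusoid ramped over five periods at a
Courant factor of 0.5; a per-period single-frequency projection over the
phantom region declares steady state when consecutive periods agree to
1 %, after which one further period is projected onto the drive
frequency over the full grid to obtain complex field amplitudes.

**Material interfaces.** Staircased homogeneous phantoms converge only
first-order in Δ and overestimate absorption badly at coarse grids. The
solver therefore applies anisotropic diagonal subpixel smoothing at
every E-edge: cell fill fractions are computed by 6³ supersampling, the
interface normal comes from the analytic ellipsoid gradient, and the
complex permittivity at an edge mixes harmonically along the normal and
arithmetically transverse to it,

```
ε_ii = 1 / ( n_i²·⟨1/ε⟩ + (1 − n_i²) / ⟨ε⟩ ),   ε = ε' + jσ/(ωε₀),
```

yielding an effective (ε, σ) per edge.

**Power accounting.** With fractional edge conductivities, absorbed
power is accumulated on edges, `P = Σ_e ½ σ_e |E_e|² Δ³`, which by the
discrete Poynting theorem equals the net power influx — the whole-body
SAR then needs no ambiguous boundary-voxel masses. Each edge's power is
attributed to the phantom owning it and distributed onto the four
adjacent cells for the per-voxel SAR map; phantom mass is the fill-sum
mass Σf·ρ·Δ³, which matches the analytic ellipsoid mass to well under
1 %.

**Verification ladder** (all reproduced in the test suite):

1. empty scene: interior amplitude equals E₀ = √(2SZ₀) ≈ 27.45 V/m to
   numerical precision;
2. PEC standing wave: reflection off a perfect-conductor sheet gives
   nulls spaced λ/2 within 1.5 cells (a finite TF/SF aperture diffracts,
   so the check uses a domain several λ wide);
3. lossy small sphere vs. the quasi-static Rayleigh solution
   E_in = 3E₀/|ε* + 2|: a 5 mm sphere (ε_r = 4, σ = 0.05 S/m) agrees
   within 15 % at 1 mm and 0.5 mm grids, with the error decreasing
   under refinement (first-order interface convergence; a full Mie
   evaluation puts the continuum answer ~4 % above quasi-static, well
   inside the budget).

**Problem sizes.** Production two-phantom runs use a 4 mm grid (tight
per-axis bounding boxes, ~0.2–0.5 M cells, tens of seconds per case on
one CPU); the verification sphere runs use 1 mm and 0.5 mm grids. These
sizes are this package's own choices balancing accuracy against the
one-CPU test budget; they are far coarser than the 0.4 mm commercial
solver runs behind the original study.

**Representative case geometry.** Cases with `d > 0` are simulated at
their bin's lower-edge (d, α, β), with `d` snapped to whole grid cells
so mirror-symmetric pairs voxelise identically. Rigid full-size
ellipsoids cannot realise every nominal pose (e.g. a perpendicular
neighbour at d = 122.4 mm would sweep through rat 1); infeasible poses
are pushed outward in whole grid cells to the closest feasible
separation and flagged `adjusted` in the output.

## 5. Aggregation

`dosimetry.build_report` combines the occupancy distribution, the
per-case SAR table (broadcasting the contact value over cases 1–25) and
the single-animal reference into per-case η_i and η_avg. Any case with
W_i > 0 but no SAR entry raises an error naming the offending cases —
silent zero-filling would bias η_avg toward 0.

## 6. Observed physics

At 4 mm resolution the solver reproduces the qualitative findings of
the underlying study: the neighbour modulates WB-avgSAR λ-periodically
with distance, with an oscillation amplitude that decays as the pair
separates; the modulation is far stronger under EHK (≈ ±40 % near the
first constructive distance) than under HEK (≈ ±5 %); the two identical
phantoms absorb identically (to solver precision for grid-snapped
mirror-symmetric placements); and the EHK reference SAR exceeds the HEK
reference, as expected for E polarised along the long axis of a thin
lossy body.

One systematic difference is documented rather than hidden: for these
homogeneous rigid ellipsoids the distance-sweep extrema sit ~0.25λ
beyond the positions reported for anatomical rat models (maxima near
0.75λ and 1.75λ rather than 0.5λ and 1.5λ). The interference geometry
of the scattered near field depends on body shape and internal
structure, so only "extrema at λ-periodic positions within one sample
spacing" is asserted, not their absolute phase.

## 7. Limitations

* Homogeneous rigid ellipsoids: no anatomy, no posture deformation; the
  original study's absolute numbers (S₁ = 0.043/0.0245 W/kg, η_avg ≈ −10.3 %,
  P(d=0) = 57.74 %) are model-dependent and are not reproduction
  targets.
* The synthetic recording is a stand-in for the undeposited 48 h video;
  occupancy statistics depend on its random-walk parameters.
* The TF/SF correction assumes scatterers stay inside the box;
  full-domain slabs or sheets crossing the box walls are
  diagnostics-only configurations.
* First-order interface convergence: coarse-grid SAR retains a positive
  bias of order 10 % (quantified against the Rayleigh/Mie oracle).
* Single frequency, far field, fixed incidence direction; no
  uncertainty propagation beyond the documented verification margins.
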