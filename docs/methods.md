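# Methods

This note documents the physical model, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Transport model

The engine is a condensed-history Monte Carlo for protons and electrons in
rectilinear voxel grids. Each history is stepped with

```
step = min(f_vox · min(spacing),  f_range · residual_CSDA_range,  distance to voxel boundary)
```

with defaults `f_vox = 0.5`, `f_range = 0.02`, and a floor `min_step = 50 µm`
that tames the logarithmic blow-up of range-proportional steps near the end
of the track. Steps are always capped at the current voxel's boundary, so
every step deposits into exactly one voxel and path-length splitting is
exact by construction.

**Energy loss.** The mean loss over a step is obtained by inverting the CSDA
range table: `ΔE = E − E(R(E) − ρ·step)`. Because the same tables serve as
the public `csda_range` oracle, stopping depths reproduce the oracle to
interpolation accuracy by construction; the tables themselves are built by
cumulative trapezoid integration of 1/S on an 800-knot log-energy grid
(interpolated log-log; equivalent to an adaptive scheme with relative
tolerance well below 1e-4 over the supported bands). Stopping powers:

* protons — Bethe formula without shell or density corrections,
  I(water) = 75 eV, validity floor 1 MeV. Agrees with published water values
  to ~1–2% over 20–80 MeV.
* electrons — Berger–Seltzer collision formula (Møller), no density
  correction (a few-% overestimate at 6–12 MeV, which cancels in the
  normalized profiles this package reports). Radiative losses use the
  rule-of-thumb ratio S_rad/S_col ≈ T·Z_eff/700 and are **removed without
  being deposited**: photon transport is out of scope, so the build-up
  region carries a small (percent-level) deficit that is uniform across the
  comparisons made here.

**Straggling.** Per-step Gaussian (Bohr) straggling,
σ² = 0.1569·(Z/A)·ρ·t MeV². The sampled perturbation is *zero-mean*,
truncated symmetrically at ±min(3σ, ΔE_mean, E−ΔE_mean). A one-sided clamp
at zero would bias the mean loss by several percent per step whenever
σ ≈ ΔE_mean (thin steps at high proton energy) and systematically shorten
ranges; the symmetric truncation keeps the sampled deposit non-negative,
bounded by the remaining energy, and unbiased, which is what lets measured
peak depths track the CSDA oracle to <2%. Landau/Vavilov shapes are not
modeled; Bragg-peak widths are therefore slightly too Gaussian.

**Multiple scattering.** Highland's formula
σ_θ = (13.6 MeV/βpc)·√(t/X₀)·(1+0.038·ln(t/X₀)), applied as two independent
transverse Gaussian angles with the direction renormalized; the logarithmic
correction is floored at 0.25 so σ_θ → 0 as t → 0. Radiation lengths come
from Tsai's per-element formula combined by mass fraction.

**Low-density fast path.** Voxels with ρ < 0.01 g/cm³ (air) are traversed in
whole-voxel hops without random sampling; the accumulated air thickness is
converted into a single aggregated Highland deflection when the particle
re-enters dense material, applied with the lateral displacement of a kick at
the air-path midpoint (a Fermi–Eyges-style lumping that slightly
underestimates in-gap lateral diffusion, ~15% on the displacement width).
The aggregate kick is drawn from a dedicated per-history auxiliary stream
(xorshift/Box–Muller), so the main stream's draw sequence is identical for
geometries that differ only in their air regions. This makes paired
comparisons (the air-gap study) common-random-number experiments: the same
primaries, the same wall scatter, the same in-phantom sampling.

**Cutoffs and termination.** Electrons 0.2 MeV, protons 1 MeV; the residual
energy is deposited locally at termination, so with straggling and
scattering disabled the energy ledger closes exactly. Outside the grid
particles fly in vacuum (the upstream air column of the long-SSD electron
geometry is *not* transported; all air that matters — gaps, enclosure
padding — is voxelized). Optional proton "nuclear attenuation" removes the
history with survival probability exp(−κ·ρ·t) and deposits nothing (default
κ = 0); this mimics fluence loss to nuclear interactions but not the local
dose those interactions deposit.

**Batches and reproducibility.** Each batch has its own seed
(base_seed + batch index); within a batch, every history derives its own
counter-based stream, so results are independent of history ordering and
bitwise reproducible for a given (seed, config, beam, grid). Batch
combination reports the per-voxel mean and sem = population-std/√n (the
two-batch convention {D, 3D} → sem D/√2).

## Beam models

The large-field electron source is a 2 cm-radius planar disc 1 m upstream of
the machine isocenter; each primary aims at a point drawn uniformly on the
34 cm × 34 cm collimator aperture in the isocenter plane, with a Gaussian
energy spread interpreted as σ = 10% of the nominal energy (the
`spread_is_sigma` knob switches to FWHM). The phantom face sits at SSD 5 m.
For small scoring regions the sampler can restrict primaries to the exact
subset of the full-field phase space whose straight-ray surface crossing
lands within a window of the axis — an unbiased importance restriction
(the acceptance probability is independent of the source point, so no
reweighting is needed). The SPE proton beam is a broad parallel beam with
energies drawn from a discrete spectrum; its default field covers the
entrance face plus a 2 cm margin. Beam angles are the four cardinal angles
about the crown–rump axis, implemented by rotating the source assembly —
the grid is never resampled.

## Spectrum unfolding

Basis columns are depth-dose curves of monoenergetic parallel beams in a
water cube, extracted by the 5 mm-radius central-axis integration and kept
un-normalized (dose per history), so NNLS weights are relative particle
fluences; the normalized view is what the two-column spectrum file carries.
The measured profile is linearly resampled onto the basis depth grid;
extrapolation is forbidden (depths outside the measured support or beyond
the deepest basis peak are trimmed). No smoothing or regularization beyond
non-negativity is applied, so entrance-region mismatches (low-energy
scattered protons a pristine-peak basis cannot represent) remain visible
rather than hidden. Basis generation uses a 4 cm-halfwidth field by
default: proton lateral spread over these ranges is millimetric, so a field
extending ≥1.5 cm beyond the scoring cylinder already provides lateral
scatter equilibrium, at a fraction of the full-face cost.

## Geometry and HU conversion

CT voxels inside the BODY contour are mapped through a contiguous HU-bin
table (default 4 bins: air < −950 < lung < −200 < soft tissue < +120 <
bone, piecewise-affine densities anchored so HU 0 → 1.00 g/cm³); finer
stoichiometric tables load from a plain-text file. A voxel takes the
material of its single HU value (no partial-volume mixing), boundary HU
values fall to the lower bin, and a voxel belongs to a contour if its
center is inside under the even–odd rule — the package's explicit
convention for edge voxels. Voxels outside BODY become air and the grid is
cropped to BODY's bounding box. The PMMA enclosure (C₅H₈O₂, 1.19 g/cm³,
standard values) is a closed rectilinear shell in the padded axes around
the air gap + payload box.

## Synthetic fixtures

The digital animal is an idealized stand-in for real CT datasets, which are
not distributable: a prolate ellipsoidal soft-tissue body (transverse
diameter 0.55 × crown–rump length), a skin shell, two lung ellipsoids at
0.3 g/cm³, a dorsal bone column plus four limb rods (the BFO mask), and two
eye spheres (1.5 cm diameter at the 54 cm reference length). Every
proportion is a fixed multiple of the crown–rump length — including the
skin thickness (2 mm at 54 cm), since a fixed-thickness shell would break
the similarity scaling that makes the 54 vs 63 cm comparison a pure size
effect. Organ volumes therefore scale exactly as length³ up to
voxelization. What a green test on these fixtures establishes is the
*dosimetric machinery* — transport, scoring, angle weighting, DVH
construction, size scaling; it does not validate anatomical realism, organ
topology beyond the masks listed, or tissue heterogeneity within organs.

The air-gap study uses a 20 cm solid-water block (Gammex composition,
vendor density 1.04 g/cm³) voxelized at 1 mm along the beam so that
millimetre gaps are exact, with profiles rebinned to the 2 mm analysis
resolution and smoothed by a 9-point quadratic Savitzky–Golay filter
(window ≈ 1.8 cm, short against the breadth of the 6 MeV peak) before
d_max normalization. The deviation statistic evaluates every normalized
profile at a common reference depth (the mean of the refined d_max depths);
with per-profile normalization, evaluating each profile at its *own*
maximum would be identically 1 and carry no information.

## Known limitations

* No secondary particles (δ-rays, neutrons, bremsstrahlung photons); no
  nuclear reaction products beyond optional fluence attenuation.
* Electron depth of maximum dose lands a few millimetres shallow of
  measured 6 MeV data — expected for a collision-only condensed-history
  model without δ-ray transport; normalized comparisons between runs of the
  same model are unaffected.
* Bohr straggling underestimates the skewness of thin-step loss
  distributions; Highland scattering is a small-angle Gaussian without
  single-scattering tails.
* DICOM paths (CT read, RT-Dose write) require the optional `pydicom` and
  are exercised only when it is installed; the HDF5 container is the
  canonical interchange format and round-trips bit-exactly.
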