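# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `ctdose`. It states nothing that the test
suite or `scripts/acceptance.py` does not itself compute.

## Semi-empirical engine

The engine is a measured-correction superposition: each fan beam
contributes `TMR(d_eff) · P_x · P_z · (SID/r)²` at every voxel center, an
axial rotation is an equal-weight sum over `n_beams` source angles, and a
scan is a sum over couch positions. The model rests on three assumptions:

1. **Broad-beam commissioning data carry the scatter.** TMR and crossbeam
   profiles are measured (here: synthesized) under broad-beam conditions,
   so no explicit scatter kernel is applied. There is consequently no
   lateral scatter transport: dose shadows behind heterogeneities are as
   sharp as the ray trace makes them.
2. **Heterogeneity correction is radiological depth only.** The TMR is
   looked up at the electron-density-scaled depth along the source ray.
   At kilovoltage energies this under-corrects bone, whose photoelectric
   cross-section grows ~Z³ while electron-density scaling is Z-blind;
   the Monte Carlo arm shows the residual (interior doses behind bone rings
   a few percent lower than the engine predicts).
3. **Kerma-like local deposition.** Doses are water-equivalent; no
   dose-to-medium conversion is applied. The MC arm, which scores energy
   deposited per unit electron density in the actual medium, reads ~2.5×
   higher in bone — the expected photoelectric enhancement, visible in any
   engine-vs-MC comparison table on a phantom with ribs.

Numerical choices: ray tracing is exact incremental voxel traversal
(Amanatides–Woo stepping with double precision); TMR is piecewise linear
with an exponential tail continuing the log-slope of the last table
segment (kV depth dose is near-exponential); profiles are piecewise linear
with endpoint clamping; voxels whose projected profile product falls below
`profile_cutoff` (default 1e-5) are skipped — an intentional truncation of
the profile tails that bounds the per-voxel error at ~1e-5 of the local
maximum. The inverse-square factor can be disabled and the dose can be
super-sampled on a 2×2×2 sub-voxel lattice for convergence studies.
Normalization divides by the maximum dose over *body* voxels (relative
electron density > 0.2); the formula extrapolates into surrounding air
where inverse square exceeds unity near the grid corners, and that
unphysical air maximum must not set the scale. Ties at the maximum resolve
to the lowest linear voxel index.

Calibration: the average isocenter depth is found by casting 360 in-plane
rays from the isocenter and locating, per ray, the outermost sample above
the surface threshold (density 0.2, sampling step one quarter of the
in-plane voxel size, crossing taken midway between samples). The CTDI100
reference table is indexed by depth = cylinder radius and interpolated
linearly; outside its range the nearest entry is used with a warning. With
the scan at 100 mAs the isocenter dose then equals the interpolated
CTDI100 value exactly, and dose is exactly linear in mAs.

## Synthetic commissioning data

The generator emulates a 120 kVp scanner with head/body bowtie filters and
5/10/15/20 mm beam widths:

* **TMR**: `exp(-μ_eff d)` with μ_eff = 0.0185 mm⁻¹ (broad-beam water
  HVL ≈ 37 mm at 120 kVp, a standard beam-data value). A `tmr_override`
  accepts any measured or computed curve; `kv_mc.parallel_beam_depth_dose`
  supplies one from the package's own MC physics when the two arms must
  share depth physics (this is how the engine-vs-MC concordance test is
  commissioned — a broad 120×120 mm field, whose full-scatter conditions
  approximate the many-beam rotational scatter environment better than the
  narrow collimated field does).
* **Transaxial profile**: the transmission of a parametric bowtie —
  equivalent-aluminium thickness growing quadratically from 0 at the
  central ray to 10 mm (head) / 14 mm (body) at the fan edge (fan
  half-widths 125/250 mm at the isocenter, i.e. the 25/50 cm fields of
  view), evaluated at 0.0775 mm⁻¹ (aluminium near the ~58 keV mean
  spectral energy), with an error-function collimator roll-off. The MC
  source applies the *same* thickness law energy-by-energy as a
  statistical weight, so the two arms share the bowtie.
* **Longitudinal profile**: near-rectangle of the nominal beam width with
  ~1.5 mm penumbra; the anode heel enters as asymmetric shoulder widths
  (default tilt 0.25), which keeps the profile maximum at the FWHM center
  so the stored values stay in (0, 1].
* **CTDI100 anchors** at 100/160/240/320 mm diameters: 32/25/16.5/10.5
  (head) and 28/21/13.5/8.5 (body) mGy/100 mAs — plausible magnitudes for
  a 120 kVp scanner, decreasing with diameter. All generator defaults are
  documented choices, not measurements.

Profiles are normalized at their FWHM center and clipped at unity (the
plateau may exceed the center value by <1e-6 for asymmetric shoulders);
`noise_sd` adds optional seeded measurement jitter, after which
monotonicity is re-imposed.

## Phantoms

Synthetic phantoms are generated on a cell-centered grid (default
1×1×4 mm³, the working resolution of CT-derived virtual phantoms) with
odd in-plane voxel counts so the rotation axis passes through a voxel
center. Voxelization is binary center-in/out — simple and exactly
testable, at the price of a staircase surface that real CT-derived
phantoms do not have (their partial-volume voxels smooth the surface).
The chest presets (newborn: 110×90 mm section; child: 230×170 mm) contain
two low-density lungs (−700 HU), a thin high-density rib shell and a
sternum block (+700 HU) in water-like tissue, with five-voxel TLD-like
marker clusters at lung/rib/sternum/breast sites; optional thin
transverse air layers emulate the inter-slab gaps of physical sectional
phantoms. The head preset is an elliptic skull shell with eye/jaw sites.
What the generators do *not* emulate: real anatomy, partial-volume
surfaces, tissue composition variety — so passing tests demonstrate
correctness of the machinery on controlled geometry, not anatomical
realism.

HU → relative electron density is piecewise linear through (−1000, 0),
(0, 1), (1000, 1.55), (3000, 2.5); values below the curve are clamped.

## Monte Carlo arm

Photons are sampled from a packaged parametric 120 kVp spectrum (filtered
Kramers bremsstrahlung plus tungsten K lines, 2 keV bins). Cross-sections
are packaged parametric tables on a 10–150 keV log grid: incoherent
scattering is the Klein–Nishina cross-section times electrons per gram
(computed, hence exactly consistent with the angular sampling);
photoelectric and coherent are power-law fits anchored at 30 keV to
standard values for air, tissue, bone and aluminium. Binding corrections
and fluorescence are neglected; below 10 keV the lookup clamps to the
10 keV value (such photons have sub-millimetre mean free paths and die
immediately). Materials are assigned from electron-density bands
(air < 0.05 < lung < 0.60 < soft tissue < 1.10 < bone), a deliberate
simplification of HU→composition mapping.

Transport is boundary-to-boundary voxel traversal with optical-depth
sampling; interactions branch photoelectric (local deposition), Compton
(Klein–Nishina composition-rejection sampling; energy transferred is
deposited locally — the kerma approximation, valid because secondary
electron ranges at ≤120 keV are below the millimetre voxel scale) and
Rayleigh (Thomson-like direction change). Photons below 1 keV are
absorbed on the spot. The fan source rotates over the same discrete beam
angles and couch positions as the engine; fan and cone angles are sampled
uniformly and the bowtie enters as an attenuation weight.

Per-voxel uncertainty uses the history-by-history method with
flush-on-new-history accumulators; the reported sigma is the relative
standard deviation of the per-history mean. The sigma estimator needs a
reasonably populated voxel: at very low history counts it is biased low,
which is why the 1/√n scaling check runs on a coarse (8×8×20 mm) grid.
Relative dose is energy per unit electron density, normalized by the
in-body maximum (voxels below density 0.01 report zero dose — their mass
is negligible and their dose estimate pure noise). The random stream is
xorshift128+ seeded via splitmix64; a fixed (seed, n_histories) pair is
bit-reproducible. Absolute calibration reuses the engine's CTDI anchor —
the chain from energy-per-particle to mGy is not specified independently,
so both arms share the same anchor by construction.

## Beam-count convergence (16 vs 32 beams)

On the synthetic newborn chest at 2×2×4 mm with a full-length axial scan,
the maximum in-body relative difference between 16- and 32-beam scans is
**≈1.8%** (about 3% for the child preset); on a homogeneous elliptical
section of the same size it is 0.78%, and the 32-vs-64 difference is
0.94%. The excess over the homogeneous case concentrates behind thin
bone: without lateral kernel smoothing, heterogeneity shadows put high
harmonics into each voxel's dose-versus-angle function, which 16-angle
sampling resolves imperfectly. Kernel-based superposition engines blur
exactly these shadows and converge faster; users of this package who need
sub-percent angular convergence on heterogeneous phantoms should run 32
beams. `scripts/acceptance.py` reports the 16-vs-32 figure unmodified.

## Problem sizes

Default study sizes were chosen so every computation is a desk-scale run:
acceptance convergence at 2×2×4 mm (≈88k body voxels, seconds per scan);
engine-vs-MC concordance on a 16 cm cylinder at 4×4×8 mm with 3×10⁶
histories (σ ≈ 10% per voxel, a few seconds); demo pipeline at 2×2×4 mm
with 10⁵ histories (noise-dominated MC, intended as a smoke run — use
≥2×10⁶ histories for quantitative comparisons). Marker-cluster
uncertainties are quoted conservatively without a √n reduction because
deposits within a cluster share histories and are correlated.

## Known limitations

* No helical acquisition, tube-current modulation, or electron transport.
* Water-equivalent dose only in the engine; dose-to-medium only in the MC.
* Electron-density depth scaling under-corrects bone photoelectric
  absorption in the engine.
* The transaxial free-in-air profile is used directly as an in-phantom
  off-axis multiplier.
* Binary voxelization; organ segmentation and dose-volume histograms are
  out of scope.
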