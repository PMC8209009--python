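# Methods

This note documents the models behind each analysis, the defaults that
matter, what the synthetic data do and do not emulate, and the choices
made where the design was genuinely open.

## Homo-FRET anisotropy imaging

### Measurement model

Plane-polarized excitation photoselects fluorophores; emission is split
into parallel (I_pa) and perpendicular (I_pe) channels.  Steady-state
anisotropy and total intensity per pixel are

    r = (I_pa − g I_pe) / (I_pa + 2 g I_pe),
    I_tot = I_pa + 2 g I_pe,

bounded in [−0.5, 1] for nonnegative inputs.  The G-factor g corrects
unequal channel detection efficiency and is estimated as the **median**
of the per-pixel background-subtracted I_pa/I_pe ratio over an
isotropic dye reference (median rather than mean: robust to hot
pixels).  A usable reference leaves |median r| < 0.01 after applying
the estimate; larger residuals are logged as warnings.  Constant
per-channel background offsets are subtracted and the result clipped at
zero; pixels with I_tot ≤ 0 are masked invalid rather than erroring,
since noisy background pixels are expected.

### Binned curves and the clustering signature

Valid ROI pixels (pooled across images/cells) are sorted by I_tot and
split into equal-count bins (default 20).  Equal-count rather than
equal-width binning stabilizes the per-bin SD where intensities are
sparse.  The signature test fits anisotropy against log10(I_tot) by
weighted least squares (weights 1/SD² per bin; intensity spans decades,
so the log axis linearizes the trend) and labels the curve:

* `active_clustered`: |slope| < 0.01 anisotropy units per decade AND
  pixel-weighted mean anisotropy < 0.8 × monomer reference;
* `random_proximity`: slope < −0.01 per decade;
* `indeterminate`: otherwise, or fewer than 3 usable bins.

The 0.01/decade flatness band and the 0.8 low fraction are package
defaults validated against the forward simulator (they separate the
two regimes by several standard errors at the standard protocol below);
both are configurable and recorded in every result.

The default foreground ROI is "valid pixels above 10% of the peak
total intensity".  Dimmer pixels are shot-noise dominated, where
ratio-of-counts estimators acquire a small intensity-sorting bias (the
lowest-intensity bin preferentially collects pixels whose perpendicular
channel fluctuated low, biasing its mean anisotropy upward); above the
10% threshold this effect stays below ~0.01 anisotropy units at the
photon budgets used here.

### Forward model

Each simulated emitter i keeps a self-emission weight

    w_i = 1 / (1 + Σ_{j≠i} (R0 / d_ij)^6),

a one-step transfer approximation summed over neighbors within 4·R0,
and emits with anisotropy r_i = w_i·r_base + (1 − w_i)·r_et.
Coincident emitters transfer fully (w → 0).  Defaults: R0 = 5 nm,
r_mono = 0.35, r_et = 0 (transfer fully depolarizes), and
r_mono_bound = 0.45 for toxin-bound emitters, whose rotational
diffusion the bound pentamer restricts.  These are conventional values
for a green dye, not measurements of a particular conjugate.  Photon budgets are Poisson per
emitter; channel amplitudes B(1+2r)/3 and B(1−r)/(3g) are deposited at
the emitter pixel, blurred by a Gaussian PSF (σ = 150 nm, 100 nm
pixels), then pixelwise Poisson shot noise, Gaussian read noise
(σ = 2 counts) and a 100-count camera offset are applied.  Analysing
the output with the true g recovers r_i in the sparse limit.

Three emitter-field generators cover the observed regimes: CSR
monomers (bystander FRET grows with density), fixed-size Gaussian
clusters (flat-low curves), and pentamer rings — up to 5 bound
emitters on a 3 nm-radius ring, the toxin's five-site footprint.

**Standard clustered-signature protocol**: three cluster densities
spanning 16-fold (0.5/2/8 clusters µm⁻²), a 12.8 µm field, 2×10⁴
photons per emitter, 20 bins.  This mirrors pooling ROIs across ~20
cells and gives the WLS slope a standard deviation of ~0.004 per decade
— enough power for the flatness test to classify reliably.  Smaller
fields leave the slope noise-limited.

**Toxin-binding contrast**: the bound condition is compared against the
*same* emitter geometry with the restriction removed (states set back
to free clusters).  With independent geometries, differences in
intra-cluster FRET weight between Gaussian clusters and pentamer rings
would confound the rotational-restriction effect that the experiment
isolates; the matched contrast tests exactly the quantity of interest
at matched intensity.

## SMLM spatial statistics

Coordinates are in nm with the origin at the window's lower-left
corner; windows are half-open `[origin, origin + extent)`.

* **Neighbor density**: per localization, the count of others within a
  radius (default 100 nm), self excluded.
* **Ripley's K**: K̂(r) = (A/n(n−1)) Σ_{i≠j} w_ij 1(d_ij ≤ r).  The
  default edge correction is Ripley's isotropic correction, computed
  analytically for rectangles by the two-side/corner case analysis
  (valid for r ≤ min(W,H)/2, which the precondition enforces);
  translation correction and no correction are available by flag.
  L = √(K/π) and H = L − r.
* **r_max**: the location of the maximum of H(r) on the grid (default
  0–500 nm in 5 nm steps, covering the 90–225 nm range typical of
  GSL cluster data), refined by a parabola through the three points
  around the discrete argmax; ties break toward smaller r, and maxima
  at the grid ends set a boundary flag instead of refining.
* **Cross-correlation**: observed A–B pair counts per annulus (default
  10 nm bins) divided by the closed-form expectation for independent
  uniform points in the same rectangle, using the isotropized set
  covariance γ̄(s) = WH − (2s/π)(W+H) + s²/π integrated per annulus
  (exact for s ≤ min(W,H)).  Bins with zero expectation are reported
  missing (NaN), not zero.
* **Tiling**: complete tile×tile sub-windows only (floor rule),
  half-open point assignment, low-occupancy tiles dropped with a log
  record — matching the practice of analysing stochastically chosen
  3×3 µm² regions.
* **Blinking**: analysis is as-recorded by default.  An optional
  frame-linking merge collapses localizations within a radius across
  consecutive frames (molecules blink over short random onsets in the
  simulated movies, 1000 frames by default) and restores CSR
  calibration that duplicate localizations would otherwise inflate.

The Thomas process simulator (Poisson parents κ, Poisson(µ) offspring,
Gaussian spread σ) wraps parents *and* offspring toroidally into the
window so the restriction stays stationary and the closed form
K(r) = πr² + (1/κ)(1 − e^{−r²/4σ²}) applies; the wrap slightly
misplaces the cluster excess of boundary-straddling clusters under the
window's Euclidean metric, a sub-percent effect at the sizes used.
Two-channel generation either shares one parent set (co-clustered) or
draws independent realizations (C = 1).

## Bilayer coordinate metrics

These are post-hoc analyses of coordinate ensembles; no dynamics are
run here.  Conventions: nm, bilayer normal +z, periodic boxes with
minimum-image distances.

* **σθ**: per lipid and headgroup vector (three ordered atom pairs,
  named in a species schema since the defining atoms are a modelling
  choice), the sample SD over frames of the angle to +z; group means
  for toxin-bound vs unbound lipids and their ratio.  Bound/unbound
  membership is an input list — deriving it from protein contacts is
  out of scope.
* **Interdigitation**: fraction of a chain's carbons past the bilayer
  midplane, averaged over lipids and frames.  The midplane is the
  per-frame z-COM of all terminal chain carbons (robust to leaflet
  asymmetry); a fixed numeric midplane can be supplied.  Interdigitation
  is reported in the literature without a single standard formula; the
  fraction-past-midplane definition used here is chosen because it is
  bounded in [0,1] and monotone in penetration depth.
* **Trans-bilayer coupling**: heavy-atom chain–chain contacts between
  an upper-leaflet and a lower-leaflet species within a 0.4 nm cutoff
  (a conventional contact criterion), normalized per lipid of the
  upper species per frame.
* **Area per lipid**: 2-D Voronoi tessellation of anchor (x,y)
  positions with 9-replica periodic ghosts; per-lipid cell areas must
  sum to the box area to 1e-6 relative (checked every call).
  Coincident anchors are perturbed by 1e-6 nm with a warning.
* **S_CD**: per interior chain carbon, ⟨(3cos²θ_CH − 1)/2⟩ with C–H
  unit vectors reconstructed by ideal tetrahedral geometry from three
  consecutive carbons (the two hydrogens sit in the plane of the
  C–C–C bisector and normal, at half the ideal H–C–H angle).  −0.5 for
  chains aligned with the normal, 0 for isotropic orientations;
  collinear carbon triples contribute NaN.

### Synthetic bilayer ensembles

The generator stands in for all-atom trajectories: anchor positions on
a jittered lattice (upper/lower lattices laterally offset by half a
spacing), headgroup vectors drawn per frame with per-group angular SD
about a stated mean (default 40°; bound 4°, unbound 12° — the 3×
restriction regime), z-directed zigzag chains whose per-frame
midplane-crossing counts are fixed or binomial at a stated fraction,
and optional planted inter-leaflet contact pairs at 0.2 nm separation.
The construction is mirror-symmetric, so with fixed crossing counts the
terminal-carbon midplane sits exactly at z = 0 and planted fractions
are recovered exactly.  Planted-contact ensembles use a 2.0 nm lattice
spacing so only the planted pairs fall within the 0.4 nm cutoff.

What these ensembles do **not** emulate: real chain conformational
disorder, lipid diffusion, correlated headgroup/chain motion, protein
structure, and force-field physics.  Passing the recovery tests shows
the *estimators* are correct and calibrated, not that any published
all-atom simulation values are reproduced — those require microsecond
trajectories, which are out of scope here.

## Numerical choices and degenerate inputs

* Equal-count bins may merge only in the degenerate case of massively
  tied intensities; bin mean intensities are strictly increasing for
  continuous data.
* WLS falls back to equal weights when any bin SD is zero (constant
  synthetic fields).
* `estimate_rmax` requires ≥ 5 grid points; a non-concave local fit
  falls back to the grid argmax.
* KD-trees back all neighbor searches; pair statistics for n ≤ 2000
  are verified bit-for-bit (integer counts) or to 1e-10 relative
  (weighted sums, summation order) against brute-force enumeration in
  the test suite.
* Simulation seeds: one `numpy` Generator per simulation call; every
  truth record stores its seed.  The acceptance script derives
  independent sub-seeds per experiment from the command-line seed via
  `SeedSequence`.

## Problem sizes

The test and acceptance runs use: 50-seed calibrations at n = 5000
(CSR) and κ=50 µm⁻², µ=20 (Thomas, ~9000 points) in 3×3 µm windows;
12-seed averages per cluster scale for r_max; 20-seed nulls at n = 3000
per channel; 40 classification replicates at the standard protocol;
10⁴-frame ensembles for σθ and 10⁵ samples for the isotropic S_CD
null.  These sizes put Monte-Carlo error comfortably inside each
stated tolerance while keeping a full run in the minutes range on one
CPU.

## Known limitations

* The homo-FRET model is one-step (no multi-step transfer chains) and
  scalar (no dipole orientation factor beyond the bound/unbound
  anisotropy levels); it reproduces directions and regimes, not
  absolute transfer efficiencies.
* No image registration between polarization channels is performed;
  inputs are assumed registered (dual-camera setups).
* Spatial statistics are 2-D only and assume rectangular windows.
* The cross-correlation's closed-form normalization assumes uniform
  intensity within the window; strong intensity gradients (e.g. a cell
  edge inside the window) would need the mask-autocorrelation variant
  on a segmented mask, which is not implemented.
* r_max values computed by other localization-microscopy software on
  cellular data depend on that software's internal edge correction and
  grid and will not be matched digit-for-digit by these defaults.
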