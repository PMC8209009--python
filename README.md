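# nanodomain

Quantitative machinery for studying how glycosphingolipids (GSLs) such
as GM1 assemble into plasma-membrane nanodomains, and how a pentameric
lectin (cholera toxin B-subunit, CTxB) reorganizes them.  The package
is aimed at membrane biophysicists who have one or more of:

* **polarization-resolved fluorescence images** (parallel/perpendicular
  emission) of headgroup-labelled lipids — homo-FRET anisotropy
  imaging distinguishes *actively clustered* lipids from lipids brought
  together by *random proximity*;
* **single-molecule localization tables** (STORM/PALM) — neighbor
  density, Ripley's K/L/H with the clustering length r_max, and the
  two-color pair cross-correlation C(r) for co-clustering;
* **bilayer coordinate snapshots** (PDB/GRO) — headgroup angle
  fluctuation σθ, chain interdigitation, trans-bilayer contacts, Voronoi
  area per lipid, and the C–H order parameter S_CD.

Because such datasets are rarely public, the package ships forward
simulators that generate every input with embedded ground truth, so the
whole pipeline is testable end to end.

## The statistics at the core

**Anisotropy.** With G-factor g calibrated on an isotropic dye,

    I_tot = I_pa + 2 g I_pe,      r = (I_pa − g I_pe) / (I_pa + 2 g I_pe).

Pixels pooled over ROIs are sorted by I_tot and split into equal-count
bins.  A *flat, low* r-vs-I_tot curve (|slope| < 0.01 per decade and
mean r below 0.8 × the monomer anisotropy) is the signature of
fixed-size nanoclusters; a *falling* curve is bystander (random
proximity) FRET.  The forward model gives each simulated emitter a
self-emission weight w_i = 1/(1 + Σ_j (R0/d_ij)^6) and anisotropy
r_i = w_i·r_base + (1 − w_i)·r_et.

**Point patterns.** K̂(r) = (A/n(n−1)) Σ_{i≠j} w_ij 1(d_ij ≤ r) with
analytic rectangle edge corrections; L = √(K/π), H = L − r, and
r_max = argmax H(r) (parabolically refined).  Under CSR, K(r) = πr²;
for a Thomas cluster process, K(r) = πr² + (1/κ)(1 − e^{−r²/4σ²}).
C(r) divides observed two-channel pair counts per annulus by the
closed-form expectation for independent uniform points in the window.

**Bilayer metrics.** σθ is the per-lipid SD over frames of the angle
between each headgroup vector (V1–V3) and the bilayer normal;
interdigitation is the time-averaged fraction of chain carbons past the
bilayer midplane; trans-bilayer coupling counts inter-leaflet chain
contacts within 0.4 nm (minimum image); area per lipid is a periodic
Voronoi tessellation of anchor positions; S_CD(k) = ⟨(3cos²θ_CH − 1)/2⟩
with hydrogens rebuilt by ideal tetrahedral geometry.

## Worked example

Simulate fixed-size nanoclusters at three surface densities, run the
anisotropy pipeline, and classify the signature:

```sh
cat > cfg.yaml <<'YAML'
stages: [simulate_images, anisotropy, classify]
simulate_images:
  mode: clustered
  densities_per_um2: [0.5, 2.0, 8.0]
classify:
  monomer_reference: 0.35
YAML
nanodomain run --config cfg.yaml --seed 17 --out demo_out
```

which prints (abridged):

```json
{"classify": {"label": "active_clustered",
              "slope": -0.00188,
              "mean_anisotropy": 0.0631}}
```

The binned anisotropy sits near 0.06 in every bin (first bins 0.065,
0.059, 0.062, 0.063, 0.059, ...) even though mean intensity spans
1 700–17 000 counts: depolarization that does not grow with
concentration, i.e. clusters of fixed small size.  The slope
(−0.002 per decade of intensity, within the ±0.01 flatness band) and
the mean anisotropy far below the 0.35 monomer reference yield the
`active_clustered` label.  Rerunning with `mode: ramp` over increasing
monomer densities instead gives a falling curve (slope ≈ −0.12 per
decade) and the `random_proximity` label.

Other entry points: `nanodomain ripley|density|crosscorr` for
localization CSVs, `nanodomain bilayer sigma-theta|interdigitation|contacts|apl|scd`
for coordinate frames, and `nanodomain simulate pattern|images|bilayer`
for synthetic data with truth records.  Everything is also available as
a library (`import nanodomain`).

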