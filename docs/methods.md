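# Methods

## Dielectric model of liquid water

The inelastic response of liquid water is a semiempirical energy-loss
function (ELF) written as a sum of Drude oscillator channels,

    Im[-1/eps(0, E)] = Σ_k  f_k Ep² γ_k E / ((E_k² − E²)² + (γ_k E)²),

with `Ep = 21.47 eV` the plasma energy of water at 1 g/cm³.  The channel
set (five discrete excitations A1B1, B1A1, two Rydberg groups and the
diffuse bands; five ionization shells 1b1, 3a1, 1b2, 2a1 and the oxygen
K-shell) lives in the versioned fixture `data/drude_channels.tsv`.  No
channel table for the liquid phase is tabulated in one agreed place in the
literature; this set was constructed once under four constraints and then
frozen:

* lowest excitation threshold exactly 8.23 eV,
* optical ELF peak at ≈21 eV (this set: 21.3 eV, height 1.30),
* f-sum rule ∫E·ELF dE = (π/2)Ep² within 5% (ratio 1.038),
* mean excitation energy from the model's own f-sum log-moment close to the
  Bragg-additivity value for water (63.2 eV vs 68.9 eV).

With those constraints the derived electron stopping power at 10 keV comes
out at 2.49 eV/nm (within 1.5% of the Bethe closed form with the model's
own I) and the inelastic mean free path bottoms out at 0.65 nm near
100 eV, both in the expected range for liquid water.  **Not included**:
collective (plasmon-like) excitations, autoionization, exchange and
low-energy Born corrections, and phase variants (ice/vapour).  These are
model limitations, not adjustable options.

Finite momentum transfer uses impulse (quadratic) dispersion
`E_k(q) = E_k + α_k q²·Ry` (q in atomic units, α_k = 1 by default), which
drives the surface's crest to the free-electron locus `E = q² Ry` at large
q; at moderate q the crest still carries the `E_k` offset, so the
free-electron limit is only reached to ~10% for q ≳ 5 a.u.

For cross sections each channel is truncated below its threshold (the
transition energy for excitations, the binding energy for ionization
shells); the untruncated lineshape is used for the optical ELF itself.
This makes the inelastic inverse mean free path exactly zero at and below
8.23 eV.

### Kinematics and integration

Electron kinematics are nonrelativistic, valid to the 10 keV ceiling of the
event-by-event model (<1% error there).  Energy transfer `E` and momentum
transfer `q` are sampled from

    d2Λ/(dq dE) = ELF(q, E) / (π a0 q T),   q−(T,E) ≤ q ≤ q+(T,E).

Integrals use log-spaced grids (≈96–128 points per decade, trapezoid rule)
with one essential refinement: the inner q-integral packs 64 extra linear
nodes around the Bethe-ridge crossing `q_r(E)`, whose width `γ/(4 Ry q_r)`
is far below any affordable global grid spacing at large E.  Without the
refinement the tail of dΛ/dE is wrong by factors; with it, 10⁵-sample
chi-square tests against adaptive quadrature pass comfortably.

Energy transfers are drawn by inverse-CDF interpolation of the exact-T
marginal; conditional momentum transfers from the tabulated cumulative
`∫ ELF/q dq` restricted to the kinematic band (the conditional table is
coarser than the marginal near the ridge; it affects only angular detail).

## Electron transport

Event-by-event: exponential free flight against the total (inelastic +
elastic) inverse mean free path, channel choice ∝ Λ_k, excitation (loss
E_k, no deflection), ionization (loss E, binding B_k deposited locally,
secondary of energy E − B_k ejected along the transferred momentum with
uniform azimuth, primary deflected by the momentum triangle), elastic
deflection from a screened-Rutherford angular law with Moliere-form
screening.  The elastic inverse mean free path is a fixture table
(`data/elastic_imfp.tsv`) in the same drop-in format a partial-wave table
would use.  Secondaries are transported LIFO from an explicit stack.

Numerical/termination choices, each with its rationale:

* **Tracking cutoff** 8.23 eV by default (configurable down to a few eV);
  sub-cutoff energy deposits at the current position.
* **Sub-ionization floor.**  Below the lowest ionization binding energy
  (10.79 eV) an electron can excite but never ionize.  The truncated Drude
  channels give such electrons unphysically long inelastic mean free paths
  (tens of µm), which would teleport ~10 eV deposits far from the track;
  real sub-ionization electrons thermalize within nanometres through
  vibrational channels this model lacks.  They are therefore terminated on
  the spot.  Set `subionization_floor_ev = 0` to walk them explicitly.
* **Grouped elastic diffusion.**  Where the elastic IMFP exceeds 20× the
  inelastic IMFP the walk between inelastic events is strongly diffusive;
  the individual elastic vertices are condensed into one isotropised
  displacement of random-walk length sqrt(s·mfp_el).  Energy-loss statistics
  are untouched.
* **Condensed-history hybrid.**  Electrons above 10 keV are first slowed to
  10 keV along a straight line using the relativistic Bethe stopping power
  (5% energy steps), then handed to the discrete loop — the standard
  "condensed above / track structure below" split.  Ionizations inside a
  condensed segment are not individually scored.
* **Point cascades.**  When the scoring raster is much coarser than a
  secondary's range (e.g. ≤2 keV deltas vs 0.25 µm phantom voxels) the
  secondary's collision sequence is run in energy space only and its
  ionization count and energy deposited at the creation vertex.

Energy closure is exact bookkeeping: initial energy = deposits + energy
carried out of the world box, to ~1e-15 relative per track.

## Ion transport (protons, alphas)

Ionization by ions uses a binary-encounter singly differential cross
section per molecule, `dσ/dW ∝ z_eff² Σ_k N_k/(W + B_k)²` up to the
kinematic limit `W_max = 2 m_e c² β² γ²`, with the ionization-shell binding
energies of the dielectric model.  It reproduces the 1/W² delta-ray tail
and integrates analytically (total cross section, mean loss per vertex and
the inverse CDF are closed forms).  Alphas scale the proton cross section
at equal velocity by the Barkas effective charge
`z_eff = z(1 − exp(−125 β z^(−2/3)))`; explicit charge-state transport is
not modelled.  Every vertex is sampled discretely and spawns a delta
electron; electronic excitation is carried as the continuous remainder
`S_exc = S_Bethe − S_ionization` between vertices, so slab energy loss
matches the Bethe stopping power (1 MeV protons through 1 µm agree with
S·Δx to better than 1%).  Ions terminate with a local deposit below 200 keV
(range ≲1 µm, below every scoring resolution used here).

Multiple Coulomb scattering uses the Highland formula: Gaussian angular
kicks batched every 5 µm of path, plus a correlated lateral offset on
bulk-transit segments.  For 200 MeV protons this produces the ≈0.1 µm
lateral spread at 0.25 mm depth that the cluster maps resolve; a strictly
straight zero-width beam would funnel every primary vertex into a single
2 × 2 nm column and distort the cluster-size statistics.

## Photon transport

Valid 1 keV–1 MeV: photoelectric (log-log interpolated fixture
coefficients, photoelectron of `E − B_K` with the oxygen K edge at
543.1 eV), Compton on free electrons (exact Klein–Nishina total cross
section and Kahn rejection sampling; electron direction from momentum
conservation), Rayleigh (Thomson-like angular shape, no energy transfer;
the atomic form factor is neglected).  Pair production is below threshold
for every photon used here and is a hard error.  Scattered photons below
2 keV are absorbed on the spot.

## Matched-dose cluster experiment

Geometry: 40 mm water cube, pencil beams along +x.  Pilot runs with all
secondaries absorbed locally estimate the mean deposit per primary
(18.7 MeV per 200 MeV proton crossing; 10.3 keV per 100 keV photon); the
photon history count is then chosen for equal total deposit — about 1.8
thousand photons per proton.  Problem sizes: 10³ protons and the matched
~1.8 × 10⁶ photons.

Scoring-slab strategy: the bulk is transported exactly in energy, but
secondaries are generated and tracked event-by-event only when the parent
vertex lies within 50 µm of a scoring slab — only those can reach the
nanometric voxels (the most energetic relevant electrons have ranges well
below the buffer).

Raster: 2 × 2 nm transverse voxels over 1 µm × 1 µm centred on the axis.
The slab integration depth is 1 µm.  A few-nanometre depth would leave the
raster with O(1) counts at these history counts; the per-voxel counts the
cluster maps are meant to exhibit (tens per voxel) likewise require a
micrometre-scale integration depth.  The transverse cluster metric — the
per-voxel count histogram and its mean over occupied voxels — remains
nanometric and is compared between beams at identical raster settings.

Reported similarity metrics: ratio of near-axis mean cluster sizes,
total-variation distance between the cluster-size distributions, and two
normalisations of the 0.25 mm near-axis density contrast.  At matched total
dose both beams necessarily deposit the same energy per unit depth, so the
per-dose core ratio measures lateral concentration only (≈0.3 here); the
per-primary ratio expresses how rarely a single photon interacts at that
shallow depth compared with a proton (≲10⁻³) and is the quantity asserted
in the acceptance suite.

## Cell microbeam experiment

The phantom is **synthetic**: an ellipsoidal cell (semi-axes
12.5 × 12.5 × 5.5 µm) with an ellipsoidal nucleus (5 × 5 × 2.5 µm) and 20
non-overlapping spherical organelles (r = 0.5 µm) placed by rejection
sampling in the cytoplasm; 0.25 µm voxels.  Materials: cytoplasm
(O 58 / C 20 / H 9 / N 8.5 / P 4.5 % by mass, 1 g/cm³), nuclear material
(O 74.5 / H 11 / C 9 / N 3 / P 2.5 %, 1 g/cm³), organelles with the nuclear
composition at 10 g/cm³, vacuum outside the cell.  A real segmented-cell
raster would replace the geometry; all headline numbers from this phantom
are order-of-magnitude anchors, not exact targets.

Non-water media reuse the water cross sections with per-voxel scale
factors: electron-density ratio with a Bragg-additivity mean-excitation
logarithmic correction for inelastic interactions, Z²-weighted atom density
ratio for elastic scattering.  Elemental I values follow the standard
tabulation (H 19.2, C 78, N 82, O 95, P 173 eV).

Beam: uniform 5 µm disc of parallel 3 MeV alphas, offset 8 µm in y so the
footprint clears the nucleus projection by construction.  Alphas enter the
cell with ≈3 MeV (range ≈17 µm) and almost always stop inside, so the mean
specific energy per event over the whole cell (mass 3.7 × 10⁻¹² kg) is
z̄ ≈ 0.12 J/kg.  The scored volume for z̄ is configurable (whole cell or
cytoplasm only); whole cell is the default.  Problem size: 10³ alphas
(a tenth of the nominal experiment, which changes z̄ and the histogram
shape only through counting noise).

Delta rays from 3 MeV alphas carry ≤1.7 keV (range ≲0.1 µm, far below the
voxel size) and are collapsed to point cascades; electron elastic
deflection is disabled inside the phantom for the same reason.

The organelle density factor uses a dedicated probe configuration: a 1 µm
beam aimed through a single organelle placed just inside the cell entry,
where the alphas still carry nearly full energy, against the identical
region of an organelle-free phantom under the identical (paired-seed)
beam.  Linear density scaling predicts a factor near the density ratio of
10; the slight excess of stopping power as the alpha slows inside the dense
sphere keeps the measured factor around 11–12.  Placing the probe deeper
would push the factor above the linear band as the alpha approaches its
Bragg peak — the configuration is a thin-probe measurement by design.

## Randomness and reproducibility

All randomness flows from one master seed through named
`numpy.random.SeedSequence` substreams (one per stage / beam / history);
per-history streams make paired-phantom comparisons see identical beams.
Track files, cluster maps and phantom files are plain text with `repr`
floats and embedded sha256 checksums: equal seeds give byte-identical
payloads, and every run writes a manifest (config echo, fixture versions,
runtimes, output checksums).

## Known limitations

* The Drude fixture is a constrained reconstruction, not a fit to measured
  optical data; quantities that weight the ELF tail (mean excitation
  energy, K-shell physics) carry its uncertainty.
* No collective excitations, autoionization, exchange, radiolysis or
  radical chemistry; ionization counts are a proxy for free-radical yield,
  not a chemistry simulation.
* Sub-ionization (<10.79 eV) electron spatial diffusion is truncated (see
  above); energy deposits are exact, their final ~nm-scale positions are
  not.
* Photon coherent scattering ignores form factors; photoelectric angular
  distributions are dipole-like.
* The microbeam phantom is synthetic; comparisons with measurements of a
  specific cell line require replacing the geometry, not the physics.
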