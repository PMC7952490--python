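# Methods

This note documents the models, data, numerical choices and known
limitations of `ludose`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Decay data and beta sampling

The Lu-177 emission table (`ludose/data/lu177_decay.json`) keeps three
beta branches (endpoints 498.3 / 385.3 / 177.0 keV at 79.4 / 9.1 / 11.5 %),
every gamma and K-x-ray line with yield ≥ 0.1 %, and lumped
conversion/Auger electron lines whose yields follow from
conversion-coefficient arithmetic of the 112.95 and 208.37 keV
transitions. The table carries published reference totals
(147.9 keV electron, 34.8 keV photon per decay) as a curation
cross-check; the tabulated emissions reproduce the total within 1 %.

Beta spectra use the allowed Fermi shape with the relativistic
point-Coulomb Fermi function
`F = 2(1+γ)(2pR)^(2γ−2) e^{πη} |Γ(γ+iη)|² / Γ(2γ+1)²`,
γ = √(1−(αZ)²), η = αZE/p, nuclear radius R = 1.2 A^{1/3} fm. Each branch
is integrated on a 1 keV grid and sampled by inverse-CDF lookup on a
1024-point uniform-u table — exact to the grid resolution and fast. The
simpler non-relativistic Fermi factor overestimates the dominant-branch
mean energy by ≈ 4 % and was rejected.

Yields above 1 are interpreted as expected multiplicities (integer part
always emitted, fractional part Bernoulli).

## Interaction data

No pre-installed package provides photon cross sections, so
`scripts/build_physics_tables.py` generates the elemental table
(H…Ca, 10–700 keV):

* **incoherent** — exact total Klein–Nishina cross section per electron
  times Z (free-electron approximation);
* **photoelectric** — `μ_pe/ρ = C · Z^4.4 / (A · E^m)`, with C and m
  fitted so that water reproduces the published NIST-style total
  attenuation curve over 15–200 keV. Because the free-electron
  approximation overstates incoherent scattering at low energy, the
  binding-correction residual is deliberately folded into this effective
  photoelectric term;
* **coherent** — `μ_coh/ρ = C' · Z^1.9 / (A · E²)`, a small
  direction-change-only term.

The resulting water total matches the published curve to 0.1 % at
100 keV and < 1 % over 30–500 keV (−5 % at 15 keV, below the relevant
Lu-177 photon energies). Compounds use the mass-fraction mixture rule
with log-log energy interpolation. Electron CSDA ranges are the published
water values in g/cm², used for all tissues: mass range is nearly
material-independent for low-Z media, and the maximal Lu-177 beta range
(≈ 0.18 g/cm², < 2 mm) is far below the 4.7952 mm voxel.

Tissue compositions are ICRP adult soft tissue (nominal density fixed at
1.00 g/cm³) and ICRP cortical bone (1.85 g/cm³). The soft-tissue nominal
density is the reference density ρ_ICRP of the voxel-wise weighting; both
values live in `tissues.json` and are configurable.

The HU→density conversion is a monotone piecewise-linear
stoichiometric-style calibration anchored at air (−1000 HU,
1.2·10⁻³ g/cm³), water (0 HU, 1.000) and a bone ramp to (1600 HU, 1.964);
values are clamped at the table ends. Monotonicity makes the curve
invertible, which the phantom generator uses to paint lesion densities
into the synthetic CT exactly.

## Monte Carlo engine

Decays are sampled from the normalized TIA image (voxel by inverse CDF,
position uniform within the voxel). Transport, in numba-compiled kernels:

* **electrons** travel on straight continuous-slowing-down tracks,
  depositing energy uniformly per unit mass path (`E₀/R₀` per g/cm²),
  with the local density setting the physical step length; a track whose
  residual range falls below the 0.1 mm range cut deposits its remaining
  energy locally. No multiple scattering and no bremsstrahlung: with
  ranges ≤ 2 mm against 4.8 mm voxels, track shape barely moves energy
  between voxels.
* **photons** are ray-traced voxel face to voxel face, accumulating
  optical depth from the per-voxel material (soft/bone μ/ρ) times
  density. Interactions: photoelectric → local deposit; incoherent →
  Klein–Nishina energy/angle by rejection sampling, recoil energy
  deposited at the interaction point; coherent → Thomson-shaped
  direction change without energy loss. Photons below the 10 keV cutoff
  deposit locally; photons leaving the grid close the ledger as escaped.

Every emission is booked as emitted and ends as deposited or escaped, so
the energy ledger closes to floating-point precision; the acceptance
suite enforces < 0.1 %.

Histories are split into 20 independently seeded sub-simulation batches
(matching the study design this reimplements); the per-voxel relative
uncertainty is the batch-scatter estimate
`√(n/(n−1) · (Σd_b² − (Σd_b)²/n)) / Σd_b`, an aggregate approximation of
the history-by-history estimator. It is bounded by 1 and NaN where no
energy was scored. The result for a fixed (seed, n_batches) pair is
independent of execution order.

Desk-scale defaults are 10⁶ histories (kernels and phantom runs); the
full-scale 10⁸/10⁹ counts pass through the same `n_primaries` field. At
10⁶ histories a 48³ phantom runs in a few seconds on one CPU.

**Known engine limitations.** One μ/ρ table per material class (soft
tissue everywhere, cortical bone where HU ≥ 200) with per-voxel density
scaling — intermediate bone compositions are approximated by density
alone. Secondary electrons deposit at their creation point. Coherent
angular shape is Thomson rather than form-factor weighted.

## Voxel-S-value kernels and dose methods

Kernels are 51³ grids of Gy/decay around a central source voxel in a
homogeneous medium, generated by the same engine (odd size enforced; the
central voxel is maximal since electrons deposit ≈ 93 % of their energy
in the source voxel). Convolution with the TIA image is spectral with
zero padding (true linear convolution cropped to the input geometry); a
brute-force superposition oracle guards it in the tests at 1e-10.

The sphere-model tumor S value uses the printed power-law fit
`S(m) = 2.19·10⁻⁵ · m^(−0.99)` Gy/(MBq·s) with the lesion mass in grams
taken equal to its volume in ml (unit-density assumption). The package
also re-derives this law: unit-density soft-tissue spheres of 1–1000 g
are simulated with uniform activity (voxel size scaled to radius/6 so
small spheres stay resolved), the self-dose per decay is scored inside
the voxelized sphere, and a log-log fit returns (c, b). The fit units are
Gy/(MBq·s) with m in g — consistent with the Lu-177 mean emitted energy
of ≈ 2.4·10⁻⁵ Gy·g per MBq·s scaled by the absorbed fraction.

Density weighting is exact arithmetic: `D · 1/ρ̄_lesion` per lesion
(mass scaling of the sphere model) and `D · ρ_kernel/ρ_voxel` per voxel.
For the soft+bone composite, both kernels convolve the full TIA and the
bone map selects per target voxel; its weighted variant uses the
region-dependent kernel density (1.00 or 1.85 g/cm³) as reference.
Weighting is restricted to the body mask — outside the body the density
approaches that of air and the ratio is meaningless.

## Synthetic phantoms

A phantom is a body ellipsoid (soft tissue, 1.00 g/cm³) containing an
ellipsoidal skeleton shell (per-voxel HU uniform in 250–800), two kidney
ellipsoids, and spherical lesions centered in the shell. Lesion volumes
are log-normal (σ_log = 1.1, location set so the mean of the
range-truncated distribution is 19.1 ml within [1.1, 453.2] ml); lesion
mean densities are normal (1.25, 0.11) truncated to [0.80, 1.66] g/cm³;
within a lesion, voxel densities scatter by a Gaussian σ of 0.08 g/cm³.
Densities are converted to HU through the inverse calibration so the
synthetic CT and the truth density are consistent voxel by voxel.

Activity washout is mono-exponential per VOI with effective half-lives of
40 h (lesions), 30 h (kidneys) and 50 h (remainder) — chosen once within
the clinically reported range for this therapy, all below the 159.5 h
physical half-life, and configurable. Timepoint images at 24/48/72 h get
optional Gaussian PSF blur (off by default; partial-volume effects are
out of scope) and Poisson noise on a configurable counts-per-Bq scale.
The truth TIA image is the closed form `A₂₄ · e^{λ·24h} / λ`.

What the phantoms do **not** emulate: SPECT projection/reconstruction,
spill-over and partial-volume effects, co-registration error, and
anatomically realistic skeletons. Passing cohort tests therefore
demonstrate the *method-ranking* mechanics (density-driven biases and
their correction), not clinical accuracy on reconstructed patient data.

## Segmentation and TIA

Bone map: HU ≥ 200 (inclusive). Body: HU ≥ −150 (midpoint of the
−200…−100 convention), largest 26-connected component, morphological
hole fill. Lesions: k-means (k = 4, k-means++ seeded, single init) on
voxel intensities inside the bone map; the highest-mean cluster is
foreground by default, split into 26-connected components with a 1 ml
minimum volume. The labeling is deterministic for a fixed seed and
invariant under positive rescaling of the activity image.

TIA fitting is unweighted least squares on log activity — exact on
noiseless data; non-positive samples are excluded and a fitted
non-decaying rate falls back to the physical decay constant with a flag.
The hybrid image preserves the voxel pattern of the 24 h image within
each VOI; only the scale comes from the fit. With three-point curves at
≈ 5 % Poisson noise the recovered half-life carries a small positive
bias (≈ +1 % measured over 2·10⁴ replicates; a 200-replicate estimate
has ± 0.8 % standard error).

The cohort pipeline fits the skeleton shell together with the body
remainder (one washout), kidneys and each lesion separately. By default
the dosimetry comparison uses the truth lesion VOIs while segmentation
results are reported alongside: lesions whose sampled density falls below
≈ 1.14 g/cm³ sit under the 200 HU bone-map threshold and would silently
drop out of a segmented comparison, truncating exactly the low-density
tail the comparison is about. `voi_source="segmented"` switches to the
segmented labels.

## Comparison metrics

`PD^av` and `PD^vox` are percentage differences against the MC reference;
`PD^vox` is averaged per lesion first, and cohort statistics average the
per-lesion values (never pooled voxels). Voxels whose MC relative
uncertainty exceeds 20 % are excluded from `PD^vox` — Eq.-level division
by a noisy reference otherwise dominates; the floor is configurable.
D25/D50/D75 are the minimum dose within the hottest 25/50/75 % of the
lesion volume using the `⌈f·n⌉`-th sorted voxel without interpolation
(reproducible on small VOIs). Bland–Altman uses the pair mean as the
denominator of the relative difference and 1.96 sample SDs for the
limits of agreement.

## Problem sizes

Default experiment sizes were chosen for single-CPU reproducibility:
10⁶–2·10⁶ Monte Carlo histories per phantom and kernel (against 10⁹/10⁸
at full scale), 48³ phantom grids, 30-lesion cohorts in batches of 5
lesions per phantom, and 1.5–2·10⁵ decays per sphere in the power-law
refit. At these sizes per-voxel MC uncertainty in lesions is a few
percent, well below the method differences under study; all counts
accept larger values through configuration.
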