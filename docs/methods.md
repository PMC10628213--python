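# Methods

## Optical model

The interface is parameterized as a stack of homogeneous slabs between two
semi-infinite media (fronting = the medium the beam travels through, air or
aqueous buffer; backing = the silicon substrate). Each slab carries a
thickness d (Å), an electron density ρ (e⁻·Å⁻³) and a Gaussian roughness σ
(Å) assigned to the interface on its fronting side; the last-slab/substrate
interface roughness is a property of the stack (`backing_roughness`).

Electron density converts to X-ray scattering-length density through the
classical electron radius, sld = ρ·r_e with r_e = 2.818×10⁻⁵ Å. The normal
wavevector in layer j is k_j = √(k₀² − 4π(sld_j − sld_fronting)) with
k₀ = q/2, complex below the layer's critical edge. Reflectivity is computed
two independent ways:

* **Abeles transfer matrices** — the production kernel, including a batch
  variant that evaluates a whole optimizer population in one vectorized
  pass;
* **Parratt recursion** — an algebraically distinct route used as an
  internal oracle; the two agree to better than 10⁻⁸ relative on random
  stacks (tested), and both reduce to the closed-form Fresnel reflectivity
  for a bare interface.

Roughness uses the Névot–Croce factor exp(−2·k_j·k_{j+1}·σ²) on each
interfacial Fresnel coefficient (the MOTOFIT convention of attaching σ to
the layer below the interface). Absorption is neglected: at 22 keV the
imaginary part of the scattering factor of these materials is ~10⁻³ of the
real part, far below the other error sources here. Constant-dq/q Gaussian
resolution smearing is implemented but off by default; high-energy
solid/liquid reflectometers are rarely resolution-limited in this q range.

One subtlety worth recording: "roughness only ever damps reflectivity" is
exactly true point-wise only for a single interface. In a multilayer the
damping of individual interface amplitudes shifts the interference
balance, and near destructive-interference minima R can locally *increase*
with σ — occasionally even when integrated over a broad q band. The
property tests therefore assert per-q monotonicity for bare interfaces
(where it is exact) and, for multilayers, that the Névot–Croce factor
damps every individual interface amplitude.

Units are fixed throughout: Å, e⁻·Å⁻³, Å⁻¹; degrees appear only in the
angle-to-q conversion q_z = 4π·sin(α)/λ (default λ = 0.56 Å, i.e. 22 keV).

## Fixed densities and stack conventions

Following standard practice for silicon-supported films, the densities of
silicon (0.692), native oxide (0.660) and buffer (0.335 e⁻·Å⁻³) are held
fixed during refinement; the native-oxide thickness is bounded to the
physically known 12–25 Å range (presets use the 18 Å midpoint). Dry
monolayer scenarios are measured through air (fronting ρ = 0); scenarios
after proteoliposome injection through buffer (0.335). Interfaces not
listed in the published tables (oxide boundaries) default to a 3 Å
polished-substrate roughness.

## Fitting

Reflectivity spans ~6 decades, so the default objective is the unweighted
mean squared residual of log₁₀R, with the model curve scaled (default
scale fixed at 1 — curves are normalized to the incident beam) and offset
by a constant background (free in [0, 10⁻⁸] by default). A χ²-weighted
linear-space cost is available when per-point uncertainties are trusted.
Non-positive data points are masked with a warning under the log cost.

The global search is differential evolution: population 15× the number of
free parameters, strategy best/1/bin with mutation dithered in (0.3, 0.9),
crossover 0.9, up to 600 generations, tolerance 10⁻⁸, followed by an
L-BFGS-B polish. Dithered best/1/bin was chosen after convergence trials
on the 16-parameter four-slab scenario: rand/1/bin with fixed F = 0.7
needed well over 1000 generations to reach the noise floor, while the
dithered best/1 variant gets there in ~250. All stochastic pieces are
seeded; identical seed and configuration give bit-identical results.
`FitConfig.n_starts` runs several independently seeded searches and keeps
the best — on ~20% of noise draws of the three-slab scenario a single
population trapped in a boundary local minimum at ~8× the noise floor, and
a second start removed every observed trap.

Parameter uncertainties come from a residual bootstrap: log-space
residuals of the best fit are resampled with replacement, added back to
the best-fit model, and each synthetic curve is re-fit locally (L-BFGS-B
in bounds-normalized units, so thicknesses and densities see comparable
finite-difference steps). The spread of the refits is the reported 1σ.
This choice is pragmatic — the bootstrap measures the noise-driven
dispersion of the estimator; it does not capture model-choice uncertainty.

Slab-count selection is parsimony-based: a model with an extra slab is
retained only if it improves the cost by more than a configurable
threshold (default 10% relative). Ties go to the smaller model; an extra
slab that does not improve the fit is physically uninformative.

## Composition layer

Fitted slab densities are interpreted with two-component volume mixing:

* head-group hydration φ_w = (ρ_H − ρ_meas)/(ρ_H − ρ_water), with ρ_H the
  dry head-group density taken from the corresponding dry-monolayer fit;
* protein volume fraction φ = (ρ_meas − ρ_water)/(ρ_protein − ρ_water).

Measured densities outside the component/water interval are clipped with a
warning. A hydration drop Δφ_w converts to displaced waters per lipid via
Δφ_w·(A·t)/V_w with defaults A = 70 Å² per lipid, t = 11.5 Å head-group
thickness (midrange of the 11–12 Å typical of phosphatidylcholine) and
V_w = 29 Å³; both the exact value and the nearest integer are reported.

Protein volume is the sum of mean residue volumes over the sequence, using
the bundled Zamyatnin (1972) table; electron density divides the total
in-chain residue electrons (residue formulas already account for the water
lost per peptide bond; terminal H/OH electrons are neglected, a < 0.05%
effect at protein length) by that volume. Globular size estimates:
equivalent-sphere diameter d = (6V/π)^⅓ and minimal anhydrous radius
R_min = 0.066·M^⅓ nm (M in Da), the standard relation implied by a partial
specific volume of ~0.73 cm³/g.

The bundled protein sequence fixture is **synthetic**: a 641-residue
Hsp70-like sequence whose amino-acid composition was chosen to emulate
human Hsp70 (~70 kDa, residue volume ≈ 84,300 Å³, anhydrous density
≈ 0.445 e⁻·Å⁻³). The real HSPA1A sequence is a drop-in replacement; all
sequence-derived operations are sequence-agnostic and carry exact
single-residue and additivity tests.

## Synthetic data and what the tests show

Scenario presets carry the published fitted slab parameters of DOPC and
DOPC/DOPS films before and after Hsp70 adsorption, so simulated curves
have realistic layer contrasts, thicknesses and roughnesses. The default
measurement emulation is 200 log-spaced q points in [0.01, 0.7] Å⁻¹ with
2% multiplicative Gaussian noise (the effective error model once curves
are normalized and background-subtracted); Poisson counting noise with a
configurable incident intensity is available. Simulated curves carry no
residual background — they stand in for background-subtracted data — so
the recovery study pins the fitted background at zero. (Leaving the
background nuisance free on background-free data blurs the high-q fringes
and inflates thin-layer thickness scatter several-fold past the
Cramér–Rao bound; with it pinned, the observed per-parameter recovery
matches the bound.)

The parameter-recovery study (20 replicates per scenario, fresh noise each,
fit bounds centred on the true values: ±30% thickness, ±12% density,
roughness in [0, 1.5σ_true], oxide thickness in [12, 25] Å) recovers every
thickness and density with median absolute error ≤ ~3% and the
protein-layer thickness within a fraction of an Å of its true 22.6 Å.
Passing this shows the chain is consistent and statistically efficient on
data generated by its own forward model; it does not validate the slab
parameterization against real membranes, footprint/resolution effects, or
systematic backgrounds, none of which the generator emulates.

## Degenerate and edge cases

Zero-thickness and zero-contrast slabs are exact no-ops of the optical
model (for sharp interfaces; with Névot–Croce damping a zero-thickness
layer of distinct density is not exactly invisible, which is physically
sensible — the factor depends on the local wavevector). A stack roughness
exceeding twice the thinnest adjacent slab triggers a warning, not an
error: genuinely diffuse layers (e.g. a disrupted film fit by one slab)
are legitimate. Curves must have strictly increasing positive q;
non-positive reflectivities are dropped on read with a logged count.

## Known limitations

* Real-valued optical profile: no absorption, no anomalous terms.
* Specular-only: no off-specular/diffuse scattering, no footprint
  correction; data are assumed corrected and background-subtracted.
* The residue-volume table and the synthetic sequence fixture introduce a
  ~1–2% systematic envelope on sequence-derived volumes and densities.
* Residual-bootstrap uncertainties assume exchangeable residuals in log
  space; strongly q-dependent noise would call for the weighted cost and
  a wild bootstrap instead.
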