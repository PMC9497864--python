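# Methods

## Scope and model

The package analyses thin-layer convective drying of sliced plant tissue in
the falling-rate period, where internal moisture diffusion limits the rate
and the moisture ratio decays roughly exponentially. A drying run is a
time–weight series with condition metadata (air temperature, slice
thickness, air velocity, load). All internal quantities are SI except time
(minutes — the natural unit of the weighing schedule and of the reported
rate constants k) and moisture content, which is stored as a fraction
(kg water / kg dry matter); percent dry basis appears only at I/O
boundaries, avoiding silent 100× errors. Drying rate is reported per hour,
the unit in which losses are usually quoted.

## Curve primitives

Moisture content: `M_t = (W_t − W_dry)/W_dry`. Moisture ratio:
`MR = (M_t − M_e)/(M_0 − M_e)`; the default equilibrium moisture is zero,
the standard simplification when the drying range (≈ 6 → 0.12 kg/kg) dwarfs
equilibrium moisture, with the full form available through the
`equilibrium_moisture_db` field. Runs are normalised so MR(0) = 1.
Drying rate uses plain forward differences located at interval midpoints;
by construction the rate telescopes: Σ DR·Δt equals the total moisture
lost exactly.

## The seven model forms

See the table in `drykin.models`. Two decisions were genuinely open:

- **Page vs Modified Page.** Much of the applied literature prints both
  with the same formula. We implement the standard distinct lineages —
  Page `exp(−k tⁿ)`, Modified Page `exp(−(k t)ⁿ)` — rather than duplicate a
  registry entry. With n free both families span the same curves, so the
  choice affects the reported k, not the fit quality.
- **Defaults and bounds.** Initial guesses (a = 0.9, k = 0.03 min⁻¹,
  b = 0.3, n = 1, c = 0.05, g = 0.01 min⁻¹) sit at the centre of the
  parameter ranges reported for fruit-slice drying at 50–80 °C; bounds
  (k, g, b ∈ (10⁻⁶, 10); a ∈ (0, 2); n ∈ (0.1, 5); c ∈ (−1, 1)) are wide
  enough to contain every published triple by two orders of magnitude in
  the rates. The a, b bounds also exclude the mirror solution of the
  diffusion-approach form (a ↔ 1−a, k ↔ kb, b ↔ 1/b) whenever b < 0.1,
  which keeps the recovered parameterisation unique.

## Fitting and ranking

Fitting is bounded trust-region least squares (`scipy.optimize.least_squares`,
tolerances 10⁻¹⁴) with a five-start strategy: the default guess, a
degenerate-submodel start (e.g. diffusion approach at b = 1, which equals
the Newton model), and jittered starts — rates perturbed log-uniformly by
±50%, shape parameters by ±0.15 — drawn from a fixed seed (1405). The best
objective wins, so fits are reproducible bit-for-bit; if nothing converges
the result is flagged, never silently returned.

Fit statistics are the standard drying-literature definitions:
R² = 1 − SS_res/SS_tot, RMSE = √(SS_res/N), reduced χ² = SS_res/(N − z)
with z the number of fitted parameters. (The source study prints R² without
the "1 −" and normalises χ² by the mean; those printed forms cannot produce
the R² ≈ 0.99 / χ² ≈ 10⁻⁵ magnitudes it reports, so the standard forms are
used and the discrepancy noted here.) A zero-variance observation vector
makes R² undefined; it is flagged rather than raised so rankings survive
degenerate inputs.

Ranking sorts by descending R², then ascending reduced χ², then RMSE. Two
subtleties:

- Criteria are compared with a relative quantisation of 10⁻⁶: the Verma
  form (a, k, g) and the diffusion-approach form (a, k, b; g = k·b) span
  the same function family, so their converged objectives differ only by
  optimizer round-off and raw float comparison would order them by noise.
- Residual ties resolve by fewer parameters (parsimony), then model name.
  Non-converged and zero-variance fits rank last and are flagged; a model
  whose fit raises is recorded as a failure without aborting the ranking.

## Transport chain

**Diffusivity.** Single-term Fick slab solution,
`MR = (8/π²)·exp(−π² D_eff t/(4 L²))`, L = **half** thickness. D_eff comes
from OLS of ln MR on t over points with 0.02 < MR ≤ 0.95 — the ceiling
drops the pre-falling-rate start, the floor the noise-dominated tail; all
points are weighted equally. The window is a package choice (the study does
not state one); both bounds are exposed as parameters. The full multi-term
series (terms summed until below 10⁻¹²) is available as a forward simulator
for round-trip testing.

**Activation energy.** OLS of ln D_eff on 1/(T + 273.15);
E_a = −slope·R with R = 8.314×10⁻³ kJ/(mol·K); D_0 = exp(intercept).

**Dincer chain.** Di = v/(k·L) with k in min⁻¹, v in m/s and L the **full**
thickness — dimensionally inconsistent, but it is the empirical convention
of the published correlation and the only one that reproduces the reference
study's Biot numbers (verified row by row: all fifteen conditions whose k
is reported to four decimals reproduce the published Bi after rounding to
two decimals and h_m to three significant figures). A `strict_si` flag
converts k to s⁻¹ for users who want the dimensionless variant. Then
Bi = 24.848·Di^(−0.375) — the exponent is negative; the positive sign some
sources print fails the row-by-row check by orders of magnitude — and
h_m = Bi·D_eff/L, valid for Bi > 0.1 (a warning is emitted below that).

Note the deliberate asymmetry: the slope method uses the half thickness
(slab drying from both faces), the Dincer chain the full thickness. Both
lengths are stored explicitly on the result object.

## Energy

`E_T = A·v·ρ_a·C_a·ΔT·t` with ρ_a = 101.325/(0.287·T_abs) (ideal gas,
kPa/(kJ kg⁻¹ K⁻¹ · K)) and the quartic dry-air specific-heat correlation
Ca(T) = 1.04841 − 3.83719×10⁻⁴ T + 9.45378×10⁻⁷ T² − 5.49031×10⁻¹⁰ T³ +
7.92981×10⁻¹⁴ T⁴ (kJ/(kg·K), guarded to 250–450 K). Air properties are
evaluated at the drying-air temperature, not a film temperature. The
ambient reference for ΔT defaults to 25 °C and is configurable; tray area
has no default — it is rig-specific and must be supplied. E_T is linear in
time, lift and area by construction; it is *not* monotone in drying
temperature (ΔT rises while ρ_a falls), and the tests assert only the
component monotonicities. Absolute specific-energy values for the reference
study are not reproducible (its tray area and drying times are unreported),
so the module is validated on identities, not on those figures.

## Correlation module

Features are standardized per column to zero mean and unit *population*
variance (ddof = 0, so two samples map to ±1). PCA loadings come from a
full SVD with a deterministic sign convention (largest-magnitude loading
positive per component). Clustering is agglomerative Ward linkage on
Euclidean distance, cut at a fixed count (default 4) with labels renumbered
by first appearance. The reference study's printed four-group partition is
treated as a qualitative benchmark only: its feature set and linkage are
unreported, and Ward on the standardized
(temperature, thickness, D_eff, Bi, h_m, hardness) features recovers a
partition whose adjusted Rand index against the printed grouping is
reported by the test suite rather than asserted.

## Synthetic data generator

The generator defines the study conditions: initial moisture 5.9812 kg/kg
d.b. (598.12% d.b.), load 0.88 kg, air velocity 1.5 m/s, the
10/20/30-min-then-hourly weighing schedule, and per-condition
diffusion-approach triples as the forward model (the best-fitting family
for these data). A run stops at MR ≤ 0.0205, the ratio implied by the
reported final (~12% d.b.) and initial moisture contents, rather than at a
fixed duration — mirroring "dry until constant weight". Dry mass is derived
as load/(1 + M₀), since per-tray dry mass is not reported. Weights carry
additive Gaussian noise, default sd 10⁻⁴ kg — a free default standing in
for balance accuracy plus sample-handling variation, since replicate
variance is unreported; in MR units it is ≈ 1.3×10⁻⁴.

What the generator does **not** emulate: within-tray spatial gradients,
shrinkage, hardness/texture, replicate-to-replicate biological variance,
and — importantly — the short-time curvature of real Fick-series curves.
Because the diffusion-approach tail decays at rate k·b (slow), the slope
method applied to *synthetic* runs yields a much smaller D_eff than the
study's experimental values; the transport chain is therefore verified
against the published k and D_eff directly, and the slope estimator is
verified by round-trip against the Fick-series forward simulator. Passing
tests demonstrate internal consistency of the pipeline under these stated
conditions, not agreement with new laboratory data.

Identifiability: with the default noise, a and k of the diffusion-approach
form recover within 5% virtually always; b is weakly identified when
k·b·t_max < 0.2 (the second exponential barely decays over the run), which
is documented rather than asserted.

## Problem sizes and determinism

The test suite fits ≈ 700 curves (16 conditions × 7 models plus 20-seed
recovery sweeps) and runs in well under a minute; the acceptance script is
a handful of desk-scale computations plus one 15-point refit. Every source
of randomness flows through an explicit seed (`numpy.random.default_rng` /
`SeedSequence.spawn` for per-run substreams), so studies, fits, rankings
and CLI outputs are byte-reproducible under a fixed seed.

## Known limitations

- The per-thickness activation energies recomputed from 3-significant-
  figure diffusivities undershoot the reference study's 4/6/8 mm values by
  ~7–10% (the study evidently used unrounded internal D_eff); only the 2 mm
  value is reproducible within a few percent, and the test suite asserts
  exactly that.
- The Dincer chain inherits the correlation's mixed units; `strict_si`
  changes the numbers and is off by default for fidelity to the published
  chain.
- No shrinkage correction, no temperature-dependent D_eff within a run, no
  heat-transfer coefficients, no exergy efficiency.
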