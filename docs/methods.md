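# Methods

This note records the models gelkit implements, the conventions and
tunable parameters that matter, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Units and conventions

Scattering vectors q are in Å⁻¹ throughout (the measured range of
interest is roughly 0.004–0.4 Å⁻¹); real-space lengths are reported in
nm, with the single conversion factor centralized in `gelkit.io`.
Residue numbering is 1-based inclusive, so a 227-residue protein with a
linker at residues 91–195 has terminal regions 1–90 and 196–227. All
containers validate their invariants (monotone grids, positive
uncertainties, simplex weights) at construction.

## Charge patterning (κ)

κ compares the sequence's local charge asymmetry to that of a maximally
segregated rearrangement of the same composition. Charges are D/E = −1,
K/R = +1, histidine 0 (neutral pH), termini ignored. For blob sizes 5
and 6 (averaged), the local asymmetry σ = (f₊−f₋)²/(f₊+f₋) is computed
over sliding windows; δ is the mean squared deviation of window σ from
the global σ, and κ = δ/δ_max.

δ_max is found by a deterministic scan rather than a single arrangement
or a stochastic permutation search: candidates place the negative
block, then s neutral residues, then the positive block, with the
remaining neutrals appended, for every split s. Putting neutrals
between the charge blocks is what actually maximizes segregation when
the composition is charge-poor; the naive "all charges first"
arrangement can be beaten by the real sequence, which would push κ
above 1 (an 8-mer enumeration in the test suite demonstrates this).
Even the scan can be marginally exceeded by exhaustive permutation in
rare dilute-charge corner cases, so κ is clipped at 1.0; the clip never
engages for realistically charged sequences. Determinism was chosen
over marginal exactness so that κ is reproducible run to run.

The helical-wheel hydrophobic moment uses 100°/residue (α-helix) and
the Fauchère–Pliška octanol/water scale by default; both are
configurable because published wheel tools fix their own scales, and
absolute moment values are only comparable within one scale.

## Reference polymer ensembles

One bead per residue, bond length b = 0.55 nm by default. The Gaussian
chain draws i.i.d. bond vectors with ⟨r_ij²⟩ = b²|i−j| and is the
ideal-chain reference for distance-map normalization. The self-avoiding
random coil (SARC) is sampled by the pivot algorithm: a random internal
bead, a uniform random rotation of the downstream tail, rejection if
any non-bonded pair comes within two bead radii (default radius
0.2 nm). One pivot attempt per bead per sweep, 10 burn-in sweeps,
thinning every 5 sweeps; acceptance statistics are logged and a
patience window of 2000 consecutive rejections raises a convergence
error. The end-to-end scaling exponent of the sampler is checked in the
suite against the Flory value ν ≈ 0.588 over n = 24–96 at modest frame
counts — sizes chosen so the whole suite stays interactive; the
estimate is accepted in 0.53–0.66.

The dumbbell ensemble scales bond vectors inside the terminal spans by
a compaction factor c ∈ (0, 1], emulating a disordered protein with two
collapsed termini and an expanded linker; within a terminus the
distance ratio to the ideal chain is c by construction, which the
normalized-distance-map tests verify by simulation.

Contact order is the weighted fraction of frames in which a residue has
any bead within a cutoff, excluding |i−j| ≤ 2 neighbours. At one bead
per residue the atomic 5 Å heavy-atom contact criterion is not
representable, so the coarse default is 0.8 nm bead–bead; this is a
deliberate coarse-graining, and the cutoff is a parameter.

Debye scattering treats beads as unit point scatterers:
I(q) = Σ_f w_f Σ_{ij} sinc(q·r_ij), so I(0) = n² exactly. No form
factors or hydration layer — it exists to close the loop between
real-space ensembles and q-space observables, not to reproduce atomic
scattering.

## BME reweighting

Frame weights minimize ½χ²(w) − θ·S_rel(w) on the simplex, with S_rel
the entropy relative to uniform weights and χ² the unreduced misfit of
the weighted-mean curve (after a scalar intensity scale fit by weighted
least squares). Optimization is in the dual — one multiplier per data
point — which is smooth and convex. Two numerical choices matter:

* the multipliers are scaled by σ so the dual gradient is in
  standardized-residual units, making the L-BFGS tolerance (1e-10)
  scale-free;
* the intensity scale and the dual solve alternate until the scale
  stabilizes (relative change ≤ 1e-9, at most 100 rounds). A fixed
  small number of alternations is not enough: the scale converges
  geometrically, and truncating it early leaves a biased scale that
  inflates χ² and distorts recovered observables.

Reduced χ² is reported with the number of q points as denominator (no
parameter correction). Φ = exp(S_rel) equals 1 iff the weights are
uniform. θ-scans tabulate (θ, χ², Φ) on a descending grid and suggest
the smallest θ past which χ² has plateaued (relative improvement < 5%
per step) — a heuristic, reported together with the full table.

Weight-vector recovery is only meaningful when the per-frame curves are
informative; the closed-loop test uses more data points than frames so
the generating Dirichlet weights are identifiable (correlation > 0.8 at
1% noise), and a separate test checks that the reweighted ensemble
average Rg lands within 2% of the generating value, which is the
quantity that matters even when individual weights are not identifiable.

## SAXS

Guinier: weighted linear fit of ln I vs q², growing the window from the
five lowest-q points while q_max·Rg ≤ 1.3; a positive slope on a small
noisy window is treated as inconclusive rather than fatal, and the
error is raised only if no window in the data shows a decaying Guinier
region. Rg = √(−3·slope).

The gel model superposes a Lorentzian-like mesh term A₁/(1+(qζ)^d), a
power law A₂q^(−p), and a fixed-width Lorentzian peak
A₃/(1+((q−q₀)/B)²). The two exponents are independent parameters (they
describe different physics: mesh density vs interface character). The
peak width B is fixed by default so A₃ stays well determined across a
concentration series. Because intensities span ~4 decades, residuals
are σ-weighted when uncertainties exist and relative otherwise; the
(ζ, d) surface is multimodal, so the fit multi-starts from
ζ ∈ {1, 2, 3, 4.5} nm and keeps the best χ². Repeat spacing is reported
as 2π/q₀ (Bragg-like conversion, stated explicitly since peak-position
→ distance conventions differ). At the default synthetic conditions
(200 points, 1% relative noise) the ζ estimator is unbiased with
per-seed SD ≈ 0.027 nm.

Histogram statistics use the probability-weighted mean and population
SD, renormalizing probabilities only within 1e-6 of unity.

## CD and FTIR

MRE = θ·100/(c·l·b) with θ in mdeg, c in mM, l in cm, b the number of
amide bonds. Helix fraction from MRE at 222 nm uses the coil baseline
MRE_coil = 640 − 45·T and the length-corrected helix limit
−42500·(1−3/n); note the bond count entering the helix formula
conventionally includes the C-terminal amide while the MRE conversion
excludes it — both counts are explicit arguments, never silently
unified.

Basis deconvolution is non-negative least squares on a shared
wavelength grid (basis spectra resampled by linear interpolation), with
an optional simplex (sum-to-one) mode. The packaged helix/sheet/coil
basis spectra are *synthetic* Gaussian-band idealisations of the
canonical far-UV shapes — not measured reference sets — suitable for
validation and demos; real samples should use measured basis spectra.

Thermal melts fit a two-state sigmoid with linear folded/unfolded
baselines; T_M is the inflection point, and hysteresis is the absolute
heating/cooling T_M difference. A fitted transition amplitude below 3×
the residual SD flags "no transition" instead of reporting a spurious
T_M.

Amide-I′ decomposition seeds three Gaussian centres from the
Savitzky–Golay-smoothed second-derivative minima and fourth-derivative
maxima, constrained to the assignment windows 1619–1628 (β, low),
1644–1648 (unordered/helix) and 1676–1688 cm⁻¹ (β, high), then
least-squares-fits the three Gaussians plus an optional linear
baseline (Levenberg–Marquardt; same objective as a grid search, far
fewer evaluations). Fractional band areas are the secondary-structure
readout. H/D-exchange traces integrate the amide-II′ band (≈1450 cm⁻¹)
above a straight baseline drawn between the minima flanking the band,
normalized to the amide-I′ area so the trace is invariant to global
intensity rescaling.

## Distributed-rate kinetics

The survival law N(t) = (1 + σ²t/⟨k⟩)^(−⟨k⟩²/σ²) is the Laplace
transform of a gamma rate density with shape α = ⟨k⟩²/σ² and rate
β = ⟨k⟩/σ²; σ → 0 recovers a single exponential. Fitting is in
(log α, log β) for stability with α bounded in [0.05, 10⁴];
initialization takes ⟨k⟩ from the early-time log-slope and σ from the
upward curvature of ln N. Hitting the upper α bound means the data are
indistinguishable from a single exponential, and the fit reports a
flagged single-exponential fallback rate instead of a meaningless σ.
Residuals are unweighted by default (inverse-variance optional). The
closed form is verified against numerical gamma quadrature to 1e-8 over
50 random parameter pairs in the suite.

## Assembly geometry and assay statistics

The necklace model counts coiled-coil dimers in a fiber bundle
cross-section as round((bundle_d/dimer_d)²) — the plain area ratio,
which is the arithmetic behind "a ~9.4 nm bundle of ~2 nm dimers holds
22 dimers" (9.4²/2² = 22.09). A hexagonal-packing alternative
(×π/(2√3)) is provided but non-default. Welch's unequal-variance t with
Satterthwaite degrees of freedom is the default two-sample comparison;
a paired t is exposed for matched designs and the caller must choose.
"Average deviation" error bars (mean absolute deviation from the mean)
are reported alongside SD because they are distinct statistics.
CTCF = integrated density − area × mean background. Survival fractions
are per-replicate stressed/unstressed ratios; metabolic rate per live
cell divides the metabolic signal ratio by the survival fraction, with
optional further normalization to a control line (chaining equals the
combined ratio).

## Synthetic data: what it does and does not show

Each generator is fully determined by (kind, parameters, noise model,
seed); seeds are split per-kind through `SeedSequence(seed, kind_id)`
with append-only kind ids, so adding a generator never changes existing
outputs. Truth manifests (JSON) record every generating parameter.
Noise models report the exact per-point SD used, so a correct analysis
achieves reduced χ² ≈ 1 — the generators are calibrated for closed-loop
validation.

Default parameters encode the study conditions the package targets:
gel mesh ζ between 2.6 and 2.0 nm across concentration, 9.5 nm fiber
repeat, monomer Guinier Rg 4.66 nm and an Rg histogram at
4.84 ± 0.92 nm, melt midpoints between 20 °C (linker alone) and
36.5 °C (full-length), amide-I′ components at 1624/1646/1680 cm⁻¹,
recombination parameters (8.8, 3.6) s⁻¹ in solution and (35.5, 23.8)
s⁻¹ in the dry glass, fiber widths near 12.3 ± 2.3 nm, and 1% relative
noise where a level is not otherwise stated.

What passing closed-loop tests demonstrate: the estimators are
implemented correctly, are unbiased at the stated noise levels, and the
analysis pipeline round-trips its own forward models. What they do not
demonstrate: agreement with real instruments. The generators omit
beamline smearing and buffer-subtraction artifacts, CD instrument
response, FTIR band asymmetry and overlapping water bands, and the
atomic detail of real conformational ensembles; published experimental
fit values (initial χ² of a real ensemble against beamline data, etc.)
require the original data and are out of scope. The dumbbell generator
reproduces the *topology* of a compact-termini/expanded-linker ensemble,
not its sequence-specific dimensions.

## Known limitations

* κ follows one (documented) δ_max convention; tools differing in their
  δ_max search can report slightly different absolute κ for the same
  sequence, so cross-tool comparisons should re-anchor on shared
  sequences.
* The SARC sampler is validated for chain lengths up to a few hundred
  beads; much longer chains need longer decorrelation times than the
  default thinning provides.
* BME assumes Gaussian, independent per-point errors; correlated
  detector errors would need a covariance-aware χ².
* The gel model's peak term is a symmetric Lorentzian; strongly
  asymmetric diffraction peaks (paracrystalline disorder) are not
  modelled.
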