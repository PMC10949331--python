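# gelkit

Quantitative analyses for proteins that form labile, protective gels —
the tardigrade CAHS family being the motivating case. A CAHS protein is
a highly charged intrinsically disordered protein whose central linker
folds into amphipathic helices while its termini carry β-structure;
above a critical concentration it assembles into ~9.5 nm fibers that
network into a reversible gel, and on drying the gel vitrifies and
immobilizes everything inside it. Characterizing that process touches
half a dozen quantitative techniques, and `gelkit` implements the
analysis layer for each of them:

* **Sequence** — Das–Pappu charge-patterning κ, FCR/NCPR, per-region
  arithmetic (expected helix fraction), helical-wheel hydrophobic
  moments, composition profiles.
* **Ensembles** — coarse (one bead per residue) reference ensembles:
  Gaussian chain, self-avoiding random coil (pivot Monte Carlo),
  compact-termini "dumbbell" chains; Rg statistics, normalized distance
  maps, contact-order profiles, Debye scattering.
* **Ensemble reweighting** — Bayesian/Maximum-Entropy (BME) reweighting
  of per-frame scattering against an experimental curve, with θ-scans
  and the effective-frame fraction Φ.
* **SAXS** — Guinier fits, Kratky transforms, and a three-component
  gel-network model (Lorentzian mesh term with correlation length ζ,
  low-q power law, fixed-width Lorentzian diffraction peak with repeat
  spacing 2π/q₀); Rg-histogram summary statistics.
* **Spectroscopy** — CD unit conversion (MRE), helix fraction from
  MRE₂₂₂, basis-spectrum deconvolution, two-state thermal melts; FTIR
  amide-I′ three-Gaussian decomposition and H/D-exchange kinetics from
  the amide-II′ band.
* **Kinetics** — the distributed-rate-constant survival law
  N(t) = (1 + σ²t/⟨k⟩)^(−⟨k⟩²/σ²) for charge recombination in vitrified
  matrices (gamma-distributed rates), with fitting of ⟨k⟩ and σ.
* **Assembly & assays** — necklace-model dimer counts for fiber
  bundles, fiber-width statistics, Welch's t, CTCF, survival and
  metabolic normalizations, Pearson R².
* **Synthetic data** — seeded generators with truth manifests for every
  input above, so each analysis can be validated closed-loop.

## Worked example

Fit the distributed-rate survival law to a synthetic recombination
trace generated at the solution-state condition (⟨k⟩ = 8.8 s⁻¹,
σ = 3.6 s⁻¹, 1% noise):

```python
from gelkit.synth import GeneratorSpec, generate
from gelkit.kinetics import SurvivalDecayModel

out = generate(GeneratorSpec("kinetics", seed=11))
result = SurvivalDecayModel(out["data"]["trace"]).fit()
print(result.summary())
```

```
Distributed-rate survival fit
  <k>   : 8.84 +/- 0.0169 1/s
  sigma : 3.661 +/- 0.0283 1/s
  red-chi2: 5.459e-06   converged: True
```

The fitted mean rate constant and distribution width recover the
generating values within their uncertainties; a stiffer matrix shows up
as growth in both numbers (the dry-glass condition is ⟨k⟩ = 35.5 s⁻¹,
σ = 23.8 s⁻¹).

Gel-network scattering works the same way:

```python
from gelkit.saxs import GelScatteringModel

out = generate(GeneratorSpec("saxs_gel", seed=5))
fit = GelScatteringModel(out["data"]["curve"]).fit()
print(f"mesh size {fit.zeta_nm:.2f} nm, repeat spacing {fit.spacing_nm:.2f} nm")
```

```
mesh size 2.58 nm, repeat spacing 9.50 nm
```

A thin CLI mirrors the common analyses:

```bash
gelkit necklace --bundle-d 9.4 --dimer-d 2    # -> 22
gelkit synth --kind saxs_gel --seed 7 --out demo/
gelkit gelfit --dat demo/saxs_gel.dat
```

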