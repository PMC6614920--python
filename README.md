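# tectofit

Quantitative analysis of **tectoRNA self-assembly** driven by the
tetrahydrofolate (THF) riboswitch loop–receptor interaction.

TectoRNAs are rationally designed RNA monomers in which a terminal loop and
a complementary receptor, joined by a helical stem, drive programmed
dimerization. Gel-shift titrations and lead(II)-cleavage footprinting report
on how strongly a given loop–receptor variant assembles, and how the folate
ligand (folinic acid, FA) shifts that equilibrium. `tectofit` turns those
assays into numbers:

- **Homodimer isotherm fitting.** For 2M ⇌ D with an active fraction β,

  f_D(M₀) = [(4βM₀ + K_d) − √(8M₀βK_d + K_d²)] / 4M₀

  fitted to fraction-dimerized observations from monomer/dimer band
  intensities to estimate K_d and β (with replicate averaging and
  detection-limit / no-assembly flags).
- **Free-energy calculus.** ΔG = RT ln K_d (K_d in mol/L,
  R = 1.987 cal K⁻¹ mol⁻¹), ΔΔG against a reference construct,
  ΔΔG_FA = RT ln(K_d(+FA)/K_d(−FA)) for ligand responsiveness, and K_d
  fold-changes.
- **Lead-probing two-state quantification.** Per-position cleavage
  intensities across a concentration ladder are normalized between the
  full-monomer and full-dimer extremes and fitted with
  f_M(M₀) = 1 − f_D(M₀; K_d, β=1) to yield apparent K_d values, plus
  protection/enhancement calls per phosphate position.
- **Heterodimer model.** A + B ⇌ AB at equimolar input, for mixed
  loop–receptor architectures.
- **Sequence signatures.** The 23-position loop–receptor alphabet with
  insertion ("6.1") and deletion labels, Watson–Crick/wobble/mismatch
  classification of the long-range pairs 8:22…12:18, point-mutation
  distances, sequence families, and ≥75%-conservation IUPAC consensus.
- **Synthetic assays.** Seeded generators for titrations, cleavage profiles
  and heterodimer series with realistic noise, so the whole pipeline is
  testable end to end without wet-lab data.

The fitting operations are scikit-learn-style estimators
(`HomodimerIsothermRegressor`, `TwoStateCleavageRegressor`,
`HeterodimerIsothermRegressor`) and compose with sklearn tooling; the
module-level functions wrap them.

## Worked example

```python
import numpy as np
from tectofit import (
    GelShiftSimSpec, simulate_gelshift, fit_homodimer, aggregate_replicates,
    delta_g, ddg_fa, fold_change,
)

# three replicate gel-shift titrations of a strong natural variant
spec = GelShiftSimSpec(true_Kd_nM=26.0, true_beta=0.85, noise_sd_fD=0.02,
                       n_replicates=3, seed=1, construct_id="980")
series, truth = simulate_gelshift(spec)
fit = aggregate_replicates([fit_homodimer(s) for s in series])
print(f"980: Kd = {fit.Kd_nM:.1f} +/- {fit.Kd_sd_nM:.1f} nM, "
      f"beta = {fit.beta:.2f}, dG(280 K) = {delta_g(fit.Kd_nM, 280.0):.2f} kcal/mol")

# ligand responsiveness from measured Kd pairs (7 degC gel shifts)
print(f"ddG_FA(4LVV_9) = {ddg_fa(74, 3694, 280.0):.2f} kcal/mol "
      f"({fold_change(3694, 74):.0f}-fold)")
print(f"ddG_FA(4LVV)   = {ddg_fa(86, 1072, 280.0):.2f} kcal/mol "
      f"({fold_change(1072, 86):.0f}-fold)")
```

prints

```
980: Kd = 24.9 +/- 0.4 nM, beta = 0.85, dG(280 K) = -9.74 kcal/mol
ddG_FA(4LVV_9) = -2.18 kcal/mol (50-fold)
ddG_FA(4LVV)   = -1.40 kcal/mol (12-fold)
```

The fitted K_d (24.9 ± 0.4 nM) recovers the generating value of 26 nM within
replicate scatter; ΔG ≈ −9.7 kcal/mol is the association free energy of that
dimer at 7 °C. The two ΔΔG_FA values quantify how much folinic acid
stabilizes assembly: the 9-bp-stem construct gains 2.2 kcal/mol (a 50-fold
K_d drop), its 11-bp counterpart 1.4 kcal/mol (12-fold) — the shorter stem
is the more ligand-responsive architecture.

The same workflow is available from the shell:

```bash
tectofit simulate gelshift --kd 26 --seed 1 --outdir sim/
tectofit fit-gelshift --input sim/titration.csv --output kd.csv
tectofit thermo --input kd.csv --output thermo.csv --reference 4LVV
tectofit run --config run.toml        # full report bundle
```

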