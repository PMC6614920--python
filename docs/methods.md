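# Methods

## Equilibrium models

**Homodimer with an active fraction.** Self-assembly is modeled as
2M ⇌ D with dissociation constant K_d = [M]²/[D] and an *active fraction*
β ∈ (0, 1]: only βM₀ of the total monomer concentration M₀ is competent to
dimerize (misfolded or damaged molecules occupy the rest). Mass balance
gives the closed form

    f_D(M₀) = [(4βM₀ + K_d) − √(8M₀βK_d + K_d²)] / 4M₀,

where f_D is the fraction of *all* molecules in dimers, so f_D → β as
M₀ → ∞ and, for β = 1, f_D = 1/2 exactly at M₀ = K_d. The subtraction in
this form cancels catastrophically when 4βM₀ ≪ K_d; `homodimer_fraction`
therefore evaluates the algebraically identical conjugate form

    f_D = 4β²M₀ / (4βM₀ + K_d + √(8M₀βK_d + K_d²)),

which is exact for all arguments and stable at extreme dilution (it tends
to 2β²M₀/K_d). Unit tests pin it against an independent Brent root-finder
on the mass-action system to 10⁻⁹ over a K_d × M₀ × β grid spanning eight
decades of concentration.

**Heterodimer.** For A + B ⇌ AB with equimolar inputs C, the free monomer
of each species solves m²/K_d + m − C = 0, so the dimerized fraction is
1 − m/C with m = (−K_d + √(K_d² + 4K_dC))/2. At C = K_d the fraction is
(3 − √5)/2, a closed-form anchor used in the tests.

**Free energies.** ΔG = RT ln(K_d in mol/L) with
R = 1.987 × 10⁻³ kcal K⁻¹ mol⁻¹ — the association free energy, negative
for sub-molar K_d. Note the sign: the convention sometimes quoted as
ΔG = −RT ln K_d yields positive values for nanomolar binders and the wrong
sign for every derived ΔΔG; the form used here reproduces all reference
ligand-shift values (e.g. RT·ln(74/3694) at 280 K = −2.18 kcal/mol).
Differences are ΔΔG = RT ln(K_d,n/K_d,o) against a reference construct and
ΔΔG_FA = RT ln(K_d(+FA)/K_d(−FA)); both are antisymmetric and recomputable
from the ΔG column, which a report-consistency test enforces. K_d is
carried in nM everywhere and converted only inside `delta_g`. Temperatures
default to 280 K (7 °C, native gels) and 293 K (20 °C, lead probing).

## Gel-shift fitting

Lanes are quantified as f_D = I_D/(I_M + I_D). With trace-labeled RNA the
probability that a labeled molecule sits in a dimer equals the bulk
fraction of molecules dimerized, so no stoichiometric factor is applied;
per-lane loading factors cancel in the ratio. Lanes with both bands at
zero are skipped with a logged warning.

`HomodimerIsothermRegressor` minimizes unweighted squared residuals on f_D
with `scipy.optimize.least_squares` (trust-region reflective) over
log₁₀K_d ∈ [−2, 8] and β ∈ (0, 1], multi-started from five log-spaced K_d
values across the observed concentration range with β₀ = max observed f_D
(clipped into (0.05, 1]); the best residual sum of squares wins, ties going
to the smaller K_d. The multi-start grid is deterministic, so fits are
reproducible without a seed. Termination tolerance is 10⁻¹⁰ with a
500-evaluation budget. Flags:

- `below_detection_` — K̂_d under the assay detection limit (default 1 nM,
  configurable): the estimate is an upper bound;
- `no_assembly_` — every observed f_D below 0.05: K_d is reported as a
  lower bound at the highest tested concentration;
- `converged_` — optimizer status.

Each replicate gel is fitted independently and estimates are averaged
(mean, sample SD with n−1); flags OR-combine, and aggregating fewer than
three replicates logs a warning. Pooled fitting across replicates is
available by concatenating series, but per-replicate fitting is the
default because it matches how replicate scatter is reported.

A design note on precision: with σ_fD = 0.02 on the 5–20 000 nM two-fold
ladder and β free, the Cramér–Rao bound for a *single* series at
K_d ≈ 3700 nM is sd(ln K_d) ≈ 0.18 — the ladder tops out at ~5 × K_d, so
K_d and β are partially confounded. Parameter-recovery tests therefore
evaluate the three-replicate average, the protocol's actual unit of
analysis, where the bound tightens to ~10% and the fitted medians pass
with margin.

## Lead-probing two-state analysis

Cleavage intensities at informative positions are mapped to a relative
monomer fraction f_M by the two-state convention: for positions whose
cleavage *decreases* on dimerization, f_M = (I − I_min)/(I_max − I_min)
over the concentration ladder of that construct/condition series; for
*increasing* positions (induced flexibility, e.g. after the bulged
nucleotide) the mirrored form. Values are clipped to [0, 1]. The min/max
anchors are per-series, never shared across gels.

`TwoStateCleavageRegressor` fits f_M(M₀) = 1 − f_D(M₀; K_d, β = 1). β is
fixed at 1 because the normalization defines the extremes as full monomer
and full dimer. Crucially, the curve is fitted with free endpoint levels,

    f_M ≈ f_dim + (f_mono − f_dim)·(1 − f_D(M₀; K_d)),

because the observed extremes of a finite ladder are *not* the asymptotic
states: at K_d = 1573 nM a 5 nM–20 µM ladder reaches only ~82% dimer, and
anchoring that lane to f_M = 0 while fitting the bare one-parameter curve
biases K̂_d by up to −46% (measured on noiseless data). With free
endpoints the generating K_d is recovered exactly on noiseless input under
any affine normalization, and to within a few percent at 3% multiplicative
intensity noise. `fit_endpoints=False` restores the bare curve for
saturated ladders. A residual RMSE above 0.10 sets a `noisy_` flag; a
series with < 0.05 total range is flagged `no_assembly_`.

Protection calls compare a monomer-state and a dimer-state intensity map
per position via r = I_mono/I_dimer with a pseudo-count of 1% of the
series median (division safety): r ≥ 1.5 → protected in the dimer,
r ≤ 1/1.5 → enhanced, otherwise unchanged; the same machinery applied to
the two dimer states ± ligand yields FA-specific calls. The 1.5-fold
default is deliberately conservative and configurable; magnitudes are
max(r, 1/r). Calls are antisymmetric under swapping the two states, a
property test. Optional raw-lane mode: `integrate_band` sums a window of a
1-D densitometry trace minus a local-median baseline from flanking
segments, floored at zero; the primary input remains the quantified
position × lane table.

## Sequence signatures

Variants live on a 23-position label scheme; insertions carry fractional
labels ("6.1" sorts between "6" and "7") and deletions are absent labels,
so no renumbering ever occurs. The stem connector is metadata
(9/10/11 bp), not sequence. The five long-range pairs are fixed
(8:22, 9:21, 10:20, 11:19, 12:18) and classified Watson–Crick
({A:U, U:A, G:C, C:G}), wobble ({G:U, U:G}), mismatch (all other base
combinations) or unpaired (deleted partner); the G:C count within the
pairing is reported because it governs mismatch tolerance.

Point-mutation distance counts differing columns over the label union,
with residue-vs-absence counting 1 — making deletion and insertion
contexts one mutation from their parents. It is a metric (verified by a
property test over random signatures). Families are single-linkage
connected components at distance ≤ 2, ordered largest-first with
lexicographic tie-breaks; the output partitions the input and is invariant
to input order.

Consensus emits the majority symbol when its frequency among non-gap
entries is ≥ 0.75 (inclusive); otherwise the smallest IUPAC code among
R/Y/W covering all bases at ≥ 10% frequency, else N; gap-majority columns
emit "-". Degenerate symbols are legal input, making consensus idempotent.

The shipped variant set is a **synthetic reconstruction**: the published
construct sequences exist only as figure panels, so the curated FASTA is
built to satisfy every stated relationship (pairwise distances to the 980
anchor, the C6/U14/C17 vs U6/C14/del17 context split, pair-class and G:C
constraints, the conserved G7). It exercises the machinery faithfully but
is not the experimental sequence set, and no test asserts a claim that
depends on residues the constraints leave free.

## Synthetic-data generators

The generators emulate the assays' statistical structure, not their
physics (no gel migration, band smearing or label decay):

- **Gel shift** — f_D from the isotherm; additive Gaussian noise on f_D
  (default σ = 0.02, chosen so replicate scatter matches the ±SD scale of
  reported K_d values), clipped to [0, 1]; band intensities back-computed
  with a lognormal lane-loading factor (σ_log = 0.05) that cancels in the
  f_D ratio, as real loading variation does. Default ladder: two-fold
  steps, 5 → 20 000 nM; three replicates.
- **Lead profiles** — per lane f_M = 1 − f_D(M₀; K_d, β=1); each position
  mixes its full-monomer/full-dimer intensities linearly in f_M with
  multiplicative Gaussian noise (default σ = 0.03), floored at 0. The ±FA
  pair is a discrete K_d pair (a single ligand concentration is modeled,
  not a binding polynomial). Default positions include decreasing and
  increasing flavors.
- **Heterodimer** — fractions from the quadratic model with additive
  Gaussian noise (σ = 0.02) on a 2–2 000 nM per-partner ladder.

All generators take a single integer seed (numpy `default_rng`); identical
specs and seeds give byte-identical outputs. Truth records carry the
generating parameters for recovery tests. Replicate variance is a single
compound noise term; real gel-vs-pipetting variance components are not
separable from published information and are not modeled. Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed error model, not robustness to structured artifacts (lane bleed,
baseline drift, partial degradation) that real gels can show.

## Reporting

The pipeline runner reads a TOML config, fits every declared input,
and writes `kd_table.csv`, `ddg_ledger.csv` (sorted ΔΔG ascending —
strongest binder first; unmeasurable constructs carry bound markers
instead of numbers), `fa_response.csv` (matched ±FA pairs with fold-change
and ΔΔG_FA), the signature report, and a JSON manifest with config hash,
seed, versions and output checksums. Per-construct failures are isolated:
the run continues and returns a nonzero summary status. CSV dialect:
UTF-8, comma, "." decimal, header row, empty string for missing. Threshold
queries (`query_report`) use inclusive semantics for ≤/≥.

## Problem sizes

Recovery statistics in tests and the acceptance script use 25-seed
ensembles (50 for the median-error properties), 13-point ladders and three
replicates per estimate — ensembles large enough that the mean fitted K_d
is dominated by estimator properties rather than seed luck, while the full
suite runs in well under a minute.
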