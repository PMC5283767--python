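# Methods

## The recursion

The state of the simulator is the vector of relative frequencies of the
ten two-locus diploid genotypes in each sex. Three genotypes per locus
(SS, RS, RR) give nine combinations; the double heterozygote is tracked
as two types — coupling (both R alleles on one chromosome) and repulsion
(R alleles on opposite chromosomes) — because they produce different
gamete distributions under linkage. Coupling and repulsion carry equal
fitness; they differ only in meiosis.

A generation is non-overlapping and consists of:

1. **Selection.** Marginal fitness of genotype g in sex x is
   W(x, g) = Σ_n α(x, n) · W_niche(g, n), the exposure-weighted average
   over the nine niches. W_niche is the product of the two single-locus
   fitnesses (from the effectiveness/dominance/selection table), scaled
   by Λ in dual-insecticide niches. Fitnesses are frequency-independent,
   so the table is computed once per deployment phase.
2. **Gamete production.** Per sex, haplotype frequencies are the
   fitness-weighted genotype frequencies pushed through the Mendelian
   segregation table and normalised; the normaliser (total
   fitness-weighted mass) is retained, and a zero normaliser raises an
   explicit extinction error. The coupling double heterozygote emits
   parental SS/RR haplotypes at (1−r)/2 and recombinant SR/RS at r/2;
   repulsion the reverse.
3. **Random union.** Offspring genotype frequencies are the outer
   product of female and male gamete frequencies mapped through the
   union table; (SS, RR) gamete pairs yield coupling double
   heterozygotes, (SR, RS) pairs repulsion. Both loci are autosomal, so
   female and male offspring frequencies are identical.

Summaries: per-locus R-allele frequencies (threshold tests use the
sex-averaged value, which equals either sex's under equal exposure);
gametic linkage disequilibrium D = f(RR) − f(R₁)f(R₂) averaged over the
sexes (both contribute equal numbers of gametes); and mean female
population fitness Σ F_i W_i, a proxy for the relative egg lay of the
controlled population.

## Parameters

| parameter | meaning | default |
|---|---|---|
| φ (effectiveness) | proportion of SS killed on contact, per concentration level | calibration-specific, ∈ [0, 1] |
| h (dominance) | position of RS between SS and RR under exposure | ∈ [0, 1] |
| s (selection) | RR fitness gain under exposure; s = restoration × φ guarantees w(RR) ≤ 1 | via restoration ∈ [0, 1] |
| z, h_z | fitness cost of resistance and its dominance, insecticide-free niches | 0 |
| r (recombination) | rate between the loci; 0.5 = unlinked | 0.5 |
| α (exposure) | per-sex niche proportions; built from exposure, male_exposure_prop, correct_mix_deploy | — |
| Λ | dual-niche interaction (synergy < 1 < antagonism) | 1 |
| threshold | R-frequency defining operational failure | 0.5 |

Defaults follow the headline analyses: unlinked loci (linkage is a user
option), no costs, multiplicative mixture action. Low-concentration
niches are fully represented in the data model but default to the
high-concentration parameters; no analysis here exercises distinct
low-concentration calibrations. Fitness-table violations (any w outside
[0, 1]) raise errors rather than clamping, so mis-calibrations are loud.
Frequencies are renormalised every generation; pre-normalisation drift
beyond 1e-9 is treated as a bug. There is no mutation: allele
frequencies change only through selection and recombination.

## Deployment strategies and time counting

An insecticide (or mixture) is deemed of no further value when its
resistance-allele frequency strictly exceeds the threshold. Because the
model advances in one-generation steps, a threshold crossing is acted on
one generation later; the exhausted deployment inevitably "overshoots"
by one generation. This fixes the bookkeeping:

- **single**: time = selective generations until the allele crosses
  (starts of 10⁻²/10⁻³/10⁻⁴ under the idealised calibration give 3/4/5).
- **sequential**: first insecticide until crossing (t₁), one further
  lag generation, then the second until crossing (t₂); total
  t₁ + 1 + t₂. This is the unique convention reproducing every
  published sequential total on the idealised starting-frequency grid.
- **mixture**: both insecticides together; the reported lifespan is the
  final crossing plus the detection generation (raw crossing times are
  also reported). With this convention the idealised (1%, 0.1%) example
  gives mixture = sequential = 8 generations, the published equality.
  The published grid of mixture times mixes the raw and lagged
  conventions across rows (an internal off-by-one acknowledged in the
  source analysis); we reproduce the solo column exactly and expose both
  conventions rather than force agreement row by row.
- **adaptive mixture**: the mixture runs until the first allele's
  crossing is detected (t_first + 1 generations), then the surviving
  insecticide continues alone, restarted from an HWE/LE population at
  the surviving allele's frequency at the replacement generation. The
  restart deliberately ignores the Hardy-Weinberg and linkage
  disequilibrium accrued under the mixture; these decay within a few
  generations once selection at the exhausted locus is withdrawn, and
  the approximation lets the adaptive time be derived from the mixture
  and solo runs without a third simulation.

The idealised fixture uses exposure 0.9 for both sexes. That value is
fixed by calibration: it exactly reproduces the published one-generation
update 0.1% → 0.98% under solo deployment (and 0.1% → 0.118% for the
rarer allele in a mixture) and the 3/4/5 solo crossing times, and
matches the classic escape-probability-0.1 convention.

In sequential single-insecticide phases the unused insecticide's niches
receive zero exposure; generic runs deploy insecticide 1 first (in the
sensitivity analysis parameters are sampled exchangeably, so the choice
cannot bias aggregate shares). A generations-to-years constant
(12 generations/year) is provided for axis labelling only and never
enters a computation.

## Sensitivity analysis

Each of 10,000 runs samples independently: starting R frequencies
(log-uniform 10⁻⁴–10⁻¹ per locus), exposure (uniform 0.1–0.9),
male exposure as a proportion of female (0–1), per-insecticide
effectiveness (0.3–1), dominance (0–1), restoration (0.2–1) and
correct mixture deployment (0.5–1, the incorrectly-deployed remainder
split equally between the single-insecticide niches). Costs are zero.
Runs use the two-niche structure (unexposed plus the deployed
insecticide(s)), HWE/LE starts, threshold 0.5, and a 500-generation cap;
runs not reaching the threshold are flagged censored and excluded from
comparisons. Sampling is plain independent Monte Carlo (not Latin
hypercube), reproducible from a seed.

The batch engine is a vectorised re-implementation of the same
per-generation kernel across all parameter sets at once (unlinked loci);
a test pins it run-for-run against the single-population engine.
Sequential times are assembled as t₁ + 1 + t₂ from the two solo runs,
which is exact here because with zero costs the idle locus is neutral
and stays at its starting frequency.

Analyses:

- **PRCC** — each input's ranks are regressed on all other inputs'
  ranks, the outcome's ranks on the same, and the residuals correlated;
  implemented directly (rank transform + least squares) and validated
  against an independent correlation-matrix-inversion oracle.
  Significance is not computed, only coefficients.
- **Strategy comparison** — the mixture-type strategy is superior when
  its time is strictly more than (1 + margin) times the sequential time
  (margins 0 and 0.2); ties favour sequential. The headline
  superiority comparisons (shares, decision line, classification rates)
  use the adaptive mixture against sequential deployment; the plain
  mixture is available through the same interfaces.
- **Decision line** — OLS of summed effectiveness on exposure through
  the equal-time runs (exact integer equality at margin 0; a 19–21%
  band at margin 0.2); classification rates report TPR/TNR of the
  line's predictions against the simulated labels.
- **Classification trees** — binary recursive partitioning (scikit-learn
  split search) on the sampled inputs plus the two starting-frequency
  ratios; tree depth is restricted to the minimum level at which the
  resubstitution relative error plus its cross-validated standard error
  falls below the cross-validation error (errors relative to the
  root/majority-class error, as in standard recursive-partitioning
  software); the unpruned tree is retained for inspection.

## What the synthetic conditions do and do not show

All inputs are either printed calibrations (the idealised scenario) or
parameter sets drawn from the stated ranges; there are no field data.
Passing tests therefore demonstrate the internal correctness of the
recursion (against brute-force enumeration oracles), the exact
reproduction of the desk-checkable published anchors, and the stability
of the aggregate sensitivity statistics across seeds — not the fidelity
of any particular field calibration. The deterministic model ignores
drift (infinite population), mutation, age structure, insecticide decay
within a deployment span, spatial structure and epidemiology, so
absolute times to resistance should be read comparatively, not as
calendar predictions.

Two aggregate statistics land close to, but outside, the published
values under these conditions: the fraction of runs censored in both
strategies (≈21% here vs 24%) and the sequential-favoured share among
completed runs (≈52% vs 56%). Every desk-checkable anchor is exact and
the decision line and classification rates agree within their
tolerances, so the residual gap most plausibly reflects minor
implementation conventions of the original analysis that are not
derivable from its description; it is left as-is rather than calibrated
away.

## Numerical choices

Tolerances: genotype/exposure tables accepted when per-sex sums are
within 1e-8 of 1, then renormalised exactly; the engine's own
per-generation drift check is 1e-9. Threshold comparisons are strict
(exactly 50% does not trigger). Tie-breaks: simultaneous crossings make
the adaptive time equal the mixture time; equal mixture/sequential times
label a run sequential-favoured. Degenerate inputs: a population whose
fitness-weighted mass vanishes raises an extinction error; a start
already above threshold contributes zero selective generations but still
incurs the switch lag.

## Known limitations

Sex-linked loci are not implemented (the data model is autosomal-only).
Coupling/repulsion fitness differences and sex-specific per-niche
fitness tables are intentionally not supported. The shipped
DDT/HCH-style fixture is a synthetic, incomplete stand-in (only the
DDT-like locus's survival figures are calibrated) and is marked as such.
Table-level reproduction of the field-calibrated sequential/mixture
grid is out of scope because the full calibration is not printed in the
source's main text.
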