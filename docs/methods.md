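# Methods

## Two-state model of mtDNA loss

The model describes a well-mixed, nutrient-replete population in which
respiration-competent ρ⁺ cells divide with exponential growth constant
`g_wt` (per hour, natural log), irreversibly lose their mtDNA at a constant
per-cell rate `r`, and thereby become ρ⁰ cells dividing at `g_mut`:

    dP_wt/dt  = (g_wt − r) P_wt
    dP_mut/dt = g_mut P_mut + r P_wt

Assumptions: rates are constant (exponential-phase culture, constant
stress), loss is binary and irreversible (no partial-deletion ρ⁻ states,
no reversion), and conversion conserves the cell — which is what makes the
instantaneous per-capita growth rate of the whole population equal to the
mutant-fraction-weighted average `(1−f)g_wt + f·g_mut` at every time, not
only asymptotically.

Closed form, with `a = g_wt − r`, `b = g_mut`:

    P_wt(t)  = P_wt(0) e^{a t}
    P_mut(t) = P_mut(0) e^{b t} + r P_wt(0) (e^{a t} − e^{b t})/(a − b)

and `P_mut(0) e^{b t} + r P_wt(0) t e^{b t}` when `a = b`. The conversion
kernel is evaluated through an `expm1`-based series wherever `|a−b|·t <
1e-6` to avoid catastrophic cancellation; both branches are validated
against adaptive Runge–Kutta integration (relative error ≤ 1e-8 on a
100-point random parameter grid, degenerate branch included). Mutant
fractions are computed with all exponentials rescaled by `e^{-max(a,b)t}`,
so `f(t)` is overflow-safe at arbitrarily large times.

Regimes: if `g_wt − r > g_mut` (strictly) the mutant fraction converges to
`f* = r/(g_wt − g_mut) < 1` (coexistence); otherwise the mutant fixes,
`f* = 1`. The boundary `g_wt − r = g_mut` has no finite equilibrium and is
classified with the fixation branch; the inequality is deliberately strict.

Units: all rates are per hour in base e. Conversion to doublings/hour is a
reporting-layer convenience (`GrowthFit.doublings_per_hour`); nothing
internal uses base 2. `r` is treated as per hour (not per generation).

## Stochastic counterpart

`simulate_population_stochastic` is an exact event-driven (Gillespie)
simulation of the linear branching process with events ρ⁺ division
(propensity `g_wt·P_wt`), conversion (`r·P_wt`), and ρ⁰ division
(`g_mut·P_mut`). The first moments of this process obey the deterministic
ODEs exactly; the ensemble-mean mutant *fraction* differs from the
deterministic `f(t)` only by O(1/N) Jensen terms, which is why agreement
tests start from N = 1000 founder cells. A configurable population cap
(default 1e6) truncates runaway trajectories with a warning.

## Loss-rate estimation from petite time series

The measured petite fraction at each plating is identified with the
population's ρ⁰ fraction at that instant (a petite colony ⇔ its founding
cell was non-respiring when plated). No correction is applied for colonies
founded by cells that lose mtDNA *after* plating; the estimator reports
this assumption in its workflow output rather than hiding it.

Estimator: minimize colony-count-weighted least squares between observed
fractions `k_i/n_i` and the model `f(t_i; r, f0)`, with `r ∈ [0, g_wt]`
and the baseline fraction `f0` fitted by default (aerobically conditioned
cultures retain a nonzero petite baseline; `fit_f0=False` pins it to 0).
Weighted LS with binomial-count weights was chosen over maximum likelihood
for robustness to between-replicate overdispersion; a binomial ML option
(`method="ml"`) is provided and the two agree within the CI width on
synthetic data. Solutions within 1e-6 of either bound are flagged
`at_boundary`. Confidence intervals are percentile bootstrap over whole
replicates (cases, not residuals), default `n_boot=1000`, default level
0.90. With 8 replicates the percentile interval is expected to undercover
slightly (small-cluster bootstrap); measured coverage of the 90% interval
is ~80–85% under the reference design (8 replicates, timepoints 0/3/6/9 h,
~150 colonies per plate, true r = 0.15/h).

## Petite calling and threshold calibration

Petite iff colony area < threshold, strict, default 1.5 mm². Calibration
scans candidate cutoffs at midpoints between sorted distinct areas and
keeps those where, for every strain, the respiring fraction among colonies
below the cutoff is < 50% (false-positive constraint); among those it
returns the candidate minimizing non-respiring colonies above the cutoff,
ties resolved toward the smaller threshold. "Few false negatives" is not
quantified by the source protocol; minimization is this package's
operationalization. Infeasible calibrations raise an error carrying the
best infeasible candidate and its diagnostics.

Summary statistics follow the plate-assay convention: the group mean is
population-weighted (`Σk/Σn`, pooling colonies), the error bar is the
*unweighted* SEM of per-replicate fractions; with one replicate the SEM is
flagged undefined rather than fabricated.

## Growth-constant fitting

Curves are blank-subtracted (default blank 0, i.e. raw OD — whether the
source data were blanked is unknown, so the blank is explicit config), log
transformed, and fit by OLS over the longest contiguous window whose OD
lies in `[od_min, od_max]` = [0.02, 0.5] and whose fit reaches `R² ≥ 0.99`
with ≥ 9 points (ties between equally long windows go to the higher R²).
This window rule is an operationalization of "truncate to the linear
range"; all four knobs are exposed in `FitConfig`. Group comparison uses
Welch's unequal-variance t-test by default (`equal_var=True` switches to
pooled); the one-tailed direction is group_a > group_b.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (arguments, seed) and emulate the
reference designs: 8 replicate cultures plated at 3-h intervals for 9 h at
~150 colonies per plate (Poisson plate totals, binomial petite counts);
20-minute OD600 sampling; bimodal log-normal colony areas (~0.5 mm² petite
component, ~4 mm² respiring component) with optional label flips; amplicon
reads carrying a 6-nt in-line sample index and 20-nt gene barcode at fixed
offsets (configurable layout — the real primer geometry lives in an
unpublished supplement, so the defaults are declared, not inferred) with
uniform per-base substitution errors and a per-read truth table; and
multi-condition count matrices with log-normal gene abundances, spiked
log2 effects, and gamma-Poisson (negative-binomial) overdispersion.

Growth curves are lag + exponential + saturation: exponential growth from
`initial_od` after `lag_h`, blended into `capacity_od` by a sharp
soft-minimum (p-norm, p = 8), so the sub-saturation phase is *genuinely*
exponential at the nominal rate. A Verhulst logistic was rejected because
its log-slope is `rate·(1 − OD/K)` from the outset — no finite window of
it has the nominal rate, making "recover the true rate" ill-posed. Real
cultures bend earlier and asymmetrically; the generator's saturation shape
is a convenience, not a growth law. Defaults are chosen as study
conditions: `initial_od=0.015` (a 1:200 dilution of a saturated overnight
culture — conveniently below `od_min`, so the lag phase is excluded from
the fitted window), `noise_sd=0.002` OD, 24-h duration (slow growers near
0.1/h need most of it to traverse the window), `lag_h=0.5`.

What passing tests therefore show: the estimators are correct and
well-calibrated *under these generative assumptions* (binomial plating,
uniform substitution errors, NB counts, exact exponential phase). They do
not show robustness to PCR bias, quality-dependent or indel errors,
density-dependent growth, diauxic shifts, or colony-segmentation error —
none of which the generators produce.

## Screen statistics

Demultiplexing is exact-match on both fields: a read counts toward
(sample, gene) iff its index and barcode substrings equal mapped sequences
exactly; everything else is discarded with a reason (bad index / bad
barcode / both / too short), and `counted + discarded = total` is asserted
behavior, not accident.

The enrichment test is a conditional binomial exact test on pooled counts:
replicate samples are rescaled to the common median library size, rounded,
summed per condition; given `n = a + b`, under the null `a ~ Binomial(n,
s_a/(s_a+s_b))`. Two-sided p-values use the minimum-likelihood rule (sum
of all outcome probabilities ≤ the observed one) rather than tail
doubling; the two differ on skewed nulls and the choice is stated for
that reason. `n = 0` gives `p = 1` by convention and a low-evidence flag.
This is deliberately the dispersion-0 member of the NB exact-test family:
replicate pooling plus a fixed-dispersion NB variant
(`exact_count_test_nb`) stand in for tagwise-dispersion estimation, which
is out of scope; with biological overdispersion the binomial p-values are
anti-conservative, which is why the type-I calibration is stated under
Poisson sampling. The log2 fold-change uses half-count pseudocounts
(`(a+0.5)/s_a` vs `(b+0.5)/s_b`), which only matters at zero counts.

Rank metric: `sign(log2fc) · (−log10 p)`, zero when `p = 1` or `log2fc =
0`; p-values are floored at 1e-300 before the logarithm (and the exact
test floors its own underflows at the same constant, keeping p ∈ (0, 1]).
BH adjustment is the standard step-up procedure (statsmodels), returned in
input order. Hit selection orders by rank metric descending with
lexicographic gene-id tie-breaks, so hit lists are deterministic.

## Numerical choices and degenerate inputs

- Closed-form kernel switches to its series form at `|a−b|t < 1e-6`;
  fraction computations rescale by the dominant exponent.
- `least_squares` bounds: `r ∈ [0, g_wt]`, `f0 ∈ [0, 1−1e-6]`; `xtol =
  ftol = 1e-12`; initial guesses from the empirical early slope.
- Bootstrap resamples that collapse below 3 distinct timepoints are
  skipped; a warning fires if fewer than half succeed.
- Zero-variance t-test groups: equal means → (t=0, p=1); separated
  constants → ±inf with p ∈ {0, 1} by direction.
- The exact test returns p = 1 exactly whenever the observed outcome is
  modal (the full support is included), avoiding float-summation residue.
- Times are serialized in hours (assay tables) and minutes (plate-reader
  CSV, instrument convention) and converted to hours internally.

## Problem sizes used in checks

Model/oracle grid: 100 parameter draws. Stochastic ensemble: 200 runs from
1000 founder cells, checkpoints at 2/4/6 h. Loss-rate recovery: reference
design above; CI coverage over 50 generated experiments with 200-resample
bootstraps (1000 for single estimates). Growth recovery: 50 curves, rates
0.1–0.6/h. Exact-test enumeration: all count pairs with n ≤ 50 at two size
ratios; type-I control: 1000 null genes × 100 matrices. Screen recovery:
1000 genes, 10 spikes at |log2FC| = 2, 3 replicates per condition.

## Known limitations

- Copy-number dynamics, ρ⁻ intermediates, and reversion are out of scope;
  mtDNA state is binary.
- No density dependence: rates assume cultures held in exponential phase.
- The screen test does not estimate per-gene dispersions; with strongly
  overdispersed replicates its p-values are optimistic.
- Median-library rescaling is the only normalization offered (no TMM).
- The petite assay cannot distinguish loss from loss-of-function mutation;
  that distinction requires staining, outside this package's scope.
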