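# Methods

## The phenology model

`headcast` predicts bread-wheat heading date with a daily-time-step model
in the thermal-time tradition: development is an accumulation of daily
increments, and cool-requiring (vernalization) and day-length
(photoperiod) responses act as multiplicative brakes on that
accumulation.

Each day the mean temperature `TM = (Tmin + Tmax)/2` is mapped to a
temperature factor `FT` — a bilinear response that is 0 at or below the
base temperature (1 °C), 1 at the optimum (26 °C), 0 at or above the
ceiling (37 °C) — giving the daily thermal time `Tt = FT × T_opt` in
degree-days. A vernalizing-day efficiency `Veff` (trapezoid: 0 outside
−4..17 °C, 1 on the 3..10 °C plateau) accumulates into `VDD`, the running
count of vernalizing days, and the vernalization factor is
`FV = clip(VDD / V_sat, 0, 1)`. The photoperiod factor is
`FP = clip((Ph − P_base)/(P_opt − P_base), 0, 1)` with `P_opt = 20 h`;
`Ph` is the astronomical day length counted while the sun is above 6°
below the horizon. From emergence to heading the daily increment is the
*modified* thermal time `PVTt = Tt × FV × FP`.

Two phases are simulated: sowing → emergence needs 148 degree-days of
plain `Tt` (the vernalization and photoperiod brakes act only after
emergence), and emergence → heading needs `TT_emhe` modified degree-days
(default 500). A stage is assigned to the first day its accumulator
reaches or exceeds the threshold; the accumulator then resets, surplus
discarded (at 26 °C this costs at most one day). Accumulation starts the
day after the reference event, and `VDD` starts counting the day after
sowing (germination, the biological start of cold perception, is not
modelled; sowing is its closest observable proxy). `FV` keeps modifying
the increment until heading — there is no early release other than the
factor saturating at 1. A genotype with `V_sat = 0` is fully spring:
the 0/0 in `FV` is defined as 1.

The three genotype-specific parameters and their units:

| parameter | meaning | units | grid |
|---|---|---|---|
| `V_sat` | vernalizing days needed for `FV = 1` | days | 0..130 step 1 |
| `P_base` | day length below which development stops | hours | 0..10 step 0.1 |
| `TT_emhe` | emergence→heading duration (earliness *per se*) | modified °C·d | 400..800 step 10 |

### Day length

No installed package provides day length at an arbitrary twilight depth,
so it is computed from standard solar geometry: Spencer's Fourier series
for the solar declination and the closed-form hour angle at which the
solar altitude equals −6°. Tests check it against a brute-force
numerical integration of the solar position (0.2-minute sampling) to
within 0.1 h. Polar day/night clamp to 24/0 h. No longitude or time-zone
correction is applied — only the duration matters.

### Scoring horizon

An `Experiment` may carry a `horizon_days` bound on the simulated window
(default: the full weather record). Field trials are scored until
harvest; with an unbounded warm record the model eventually heads every
genotype, so the horizon is what lets an obligate-winter genotype be
recorded "did not head" (NH) after a spring sowing, in the simulation
exactly as in the field.

## Grid calibration

For each genotype the model is run for every vector of the parameter grid
(13 231 vectors in the two-parameter strategy with `TT_emhe` pinned at
500; 542 471 in the three-parameter one) in every experiment where the
genotype headed, and the root-mean-square error of prediction (RMSEP, in
days, by calendar-date arithmetic) across experiments is minimized by
exhaustive search. Predictions depend only on environment and parameters,
never on the genotype, so the per-experiment daily series and the whole
grid's predicted dates are computed once and shared by all genotypes; a
full two-parameter panel calibration takes under a second per hundred
genotypes. A vector whose heading is never reached is scored at the day
after the record ends — any finite monotone penalty preserves the argmin
on realistic grids.

Ties are exact on the day-resolved objective (vectors within 1e-9 days of
the minimum). The representative of a tied set is the member closest, in
grid-step-scaled Euclidean distance, to the component-wise median, with a
deterministic tie-break (lowest `V_sat`, then `P_base`, then `TT_emhe`).

Winter genotypes — observed in at least one spring sowing and headed in
none — are calibrated on autumn sowings only, where `V_sat` is barely
identifiable. The spring information is then used as a filter: a tied
vector is discarded if, in any spring-sown experiment, it predicts
heading strictly before the last recorded heading there plus a 10-day
margin (vectors predicting no heading always pass). If the whole tied set
fails the filter (observation noise can pull it entirely below the
cutoff), the fit re-minimizes the RMSEP over the filter-passing subset of
the full grid instead of giving up.

Robustness is assessed by re-optimizing on random subsets that drop one
spring and one autumn experiment (`n−1` of each, 10 repeats by default)
and reporting the spread of the selected `V_sat` and `P_base`.

### Identifiability

Heading dates are whole days, so the objective is piecewise constant:
several adjacent grid vectors typically predict identical dates in every
experiment. A 0.1 h `P_base` step moves a simulated heading date by only
~0.3 day, and any `V_sat` smaller than the `VDD` already banked by
emergence has no effect at all. Consequently, with a handful of
experiments the noiseless tie set always *contains* the true vector
(mathematically guaranteed for forward-simulated data, and asserted in
tests) but is rarely a singleton, and the median representative can sit a
step or two away from the truth. Users should read calibrated parameters
with the tie-set width (`n_vectors`) in mind, not as point-identified
values.

## Sensitivity analysis

Per experiment, heading date is simulated for a full or thinned
three-parameter grid and regressed (OLS with intercept) on `V_sat`,
`P_base`, `TT_emhe`. The share of output variance from parameter *i* is
the standardized regression coefficient
`SRC_i = β_i² V(X_i) / Σ_j β_j² V(X_j)`, which sums to one by
construction whenever the output varies. Vectors that never head are
excluded from the fit (a penalty date would fabricate linear signal); the
excluded fraction is reported. SRC is a ratio, stable under grid
thinning; tests use an 11 × 15 × 5 grid. The seasonal contrast is the
model's signature behaviour: autumn sowings vernalize fully (SRC of
`V_sat` ≈ 0, `TT_emhe` dominant), spring sowings are dominated by
`V_sat`.

## Marker pipeline

Genotype matrices hold opaque multi-allelic class labels (SNP genotypes,
SSR fragment lengths, insertion/deletion states). Preprocessing follows
the association-panel conventions: allele classes rarer than 5% of a
marker's non-missing calls become missing; missing calls are imputed by
an iterative random-forest scheme (mode-seeded, fewest-missing-first,
refit until the fraction of changed cells stops decreasing, keeping the
previous iteration's fill, 100 trees and at most 10 iterations by
default) whose out-of-bag error is the per-marker PFC (proportion of
falsely classified); markers with PFC strictly above 0.2 are discarded.

Association scans fit, per marker, trait ~ marker class (categorical) +
population-structure covariates. The four ancestral-group contributions
sum to one, so three of them enter beside the intercept — an equivalent
fit that avoids a singular design. The marker's partial F-test gives the
raw p-value and its incremental sum of squares over the structure-only
model the `r2`. Adjusted p-values come from permuting the trait across
genotypes (covariates fixed; scheme `trait_shuffle`), with one shared,
seeded set of B = 1000 permutations, computed by projecting the permuted
trait matrix through each marker's residual-maker — bit-reproducible
under a fixed seed, and `adjusted_p = (1 + #{F_perm ≥ F_obs})/(B + 1)`.

Significant markers are thinned for collinearity: `r_LD` between two
multi-allelic markers is the maximum absolute correlation over their
allele-indicator pairs (a choice recorded in output; no standard
definition exists for multi-allelic loci), blocks are connected
components of the `r_LD ≥ 0.8` graph, and each block is represented by
its member with the fewest missing calls *before* imputation. Multiple
regression with backward elimination (drop the marker term with the
largest partial-F p > 0.05, refit, repeat) yields an additive
allele-effect model: an intercept plus per-allele deviations from each
marker's reference allele (its most frequent class). Prediction for a new
genotype is the intercept plus the effects of its non-reference alleles;
a missing or unknown call at a model marker is an explicit error, never a
silent zero. A major-genes-only variant restricts the candidate set to
supplied markers.

Two fitted reference models ship with the package
(`load_bundled_model("v_sat"|"p_base")`): 11 markers for `V_sat`
(intercept 53.9 d; leading terms at the *Vrn-A1* and *Vrn-B1*
vernalization genes, e.g. Vrn.A1ex7 allele 12 → −24.7 d) and 12 markers
for `P_base` (intercept 4.85 h; leading term the *Ppd-D1* photoperiod
gene, allele 2 → −1.5 h). They are stored as JSON data files with exactly
the published coefficients, including the multi-allelic SSR terms.

## Synthetic data

The generator emulates a temperate trial network at desk scale — its
defaults are the package's study conditions: 60 genotypes, 300 markers, 3
autumn + 2 spring sowings at two mid-latitude sites (45.8° and 48.7° N),
1.5-day observation noise (matching the best calibration errors one can
expect on real heading dates), winter fraction 0.25.

Weather is a sinusoidal annual mean-temperature cycle (level and
amplitude set from latitude; coldest mid-January, with winters sitting in
the 3–10 °C vernalizing plateau) plus AR(1) daily noise (φ = 0.7,
σ = 2.5 °C) and a positive diurnal range, so `tmin ≤ tmax` by
construction. True parameters are an intercept plus planted additive
marker effects plus a small polygenic deviation (SD 1 d / 0.15 h),
snapped to the calibration grid; one major allele at frequency
`winter_fraction` adds 100 d of `V_sat`, making carriers obligate-winter.
Effect markers are disjoint between traits. Missingness is injected on
~10% of the non-planted markers only — mirroring real panels, where a
few assays are unreliable while major-gene diagnostics are complete; this
matters because without linkage disequilibrium an unlinked marker's
imputation error approaches its minority-allele frequency, and the PFC
filter would otherwise discard most of the panel. Phenotypes are
forward-simulated and rounded-normal noise added; headings past the
scoring horizon (280 d after autumn sowings, 130 d after spring ones)
become NH.

What the generator does **not** emulate: linkage disequilibrium between
markers, pedigree or kinship structure, genotype × environment
interaction beyond the model's own, scoring error correlated within
trials, and trait-correlated population structure. Passing tests
therefore demonstrate the machinery's correctness and calibration, not
performance on real panels, where structure confounding and LD make both
association and imputation harder.

## Numerical choices

- Stage thresholds use ≥ (first day the accumulator meets the threshold);
  a strict > could never trigger on exact hits.
- RMSEP ties: exact comparison at 1e-9 days; all vectors share the same
  arithmetic path, so ties are genuine.
- The vectorized grid engine mirrors the scalar simulator
  operation-for-operation (same multiplication order, sequential
  cumulative sums) and is tested bit-identical to per-vector
  re-simulation.
- R² in evaluation reports is the squared Pearson correlation of observed
  and predicted dates (recorded in report metadata), and dates are
  compared as calendar dates — day-of-year is display-only, avoiding
  year-wrap artifacts for autumn sowings heading the following year.
- Degenerate SRC inputs (constant axis, constant output) yield NaN shares
  flagged rather than zeros.
- Problem sizes in tests: recovery panels use 50 genotypes over 3
  experiments; the association null uses 200 markers × 120 genotypes ×
  1000 permutations; the round trip uses 90 genotypes × 120 markers × 7
  experiments with B = 100. These sizes make the full suite run in well
  under a minute of simulation time while keeping every statistical check
  at a meaningful n.

## Known limitations

- Day-quantization makes the calibration objective piecewise constant;
  parameters are set-identified (see Identifiability above).
- The winter filter depends on the panel's latest spring heading; with
  very few spring genotypes it weakens accordingly.
- Permutation p-values use a single trait-shuffle scheme; under strong
  dependence between trait and structure a residual-permutation scheme
  would be more exact.
- The imputation PFC is an out-of-bag estimate; for markers with very few
  observed calls it is noisy.
- The double-ridge stage, frost/heat stress, and sub-daily temperature
  integration are out of scope.
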