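# Methods

## Experimental design being modeled

A master cell lysate is split into four arms — vehicle, cosubstrate, enzyme,
enzyme + cosubstrate ("both") — with (by default) two replicates per arm.
Each replicate is aliquoted across a 10-point temperature gradient
(37, 41, 44, 47, 50, 53, 56, 59, 63, 67 °C), heated, ultracentrifuged, and
the soluble fraction quantified per protein (one multiplexed reporter channel
per temperature). The package consumes the resulting wide protein × channel
table; all upstream processing (search, quantification) is out of scope.

Class logic: a cosubstrate binder shifts in the cosubstrate and combination
arms; an enzyme interactor shifts in the enzyme and combination arms; a
substrate shifts **only** in the combination arm, because the shift requires
the catalyzed modification rather than binding of either reagent alone.

## Curve construction and normalization

Relative solubility is abundance(T) / abundance(37 °C) per protein/sample;
proteins with a missing or non-positive reference abundance in a sample are
excluded from that sample with an explicit reason (nothing is silently
dropped, and exclusion flags are monotone).

Samples are then normalized to the bulk-proteome melting behavior. The
normalization set contains proteins quantified at every temperature in every
sample whose raw curves are monotone-decreasing (Spearman correlation with
temperature ≤ −0.8) and melt out (fraction < 0.3 at 67 °C) in every sample;
at least 20 such proteins are required (configurable; an error advises
skipping normalization for small panels). Each sample's median curve over
that set is corrected multiplicatively onto the across-sample median of
those medians, at every temperature **above** the reference (the 37 °C point
is untouched, factor 1 by construction). The raw across-sample median — not
its sigmoid fit — is the target, so that samples already in agreement are a
fixed point of the operation; a sigmoid fit of the target is still computed
and reported as a sanity check on the normalization set. The set criteria
follow the established bulk-curve normalization practice for this assay;
the exact published filter set is not restated anywhere authoritative, so
ours is a documented approximation, exposed in the configuration.

## Sigmoid model and fitting

    I(T) = (1 − Pl) / (1 + exp((T − Tm) / (b·T))) + Pl

* `Tm` (°C): melting temperature; I(Tm) = (1 + Pl)/2 exactly.
* `b` (dimensionless): slope parameter; the exponent is read as
  (T − Tm)/(b·T), i.e. b multiplies T — the re-centered form of the
  classical a/T-parameterized melting sigmoid. Typical values 0.02–0.08.
  The alternative reading (T − Tm)/b (b in °C) is selectable via
  `slope_times_t=False`.
* `Pl` ∈ [0, 1): high-temperature plateau. Bounded below 1; a fitted
  plateau ≥ 0.5 (configurable `plateau_max`) marks a **non-melter** whose Tm
  is not measurable (e.g. a protein still >60% soluble at 67 °C); such fits
  contribute no Tm and proteins with no usable fit anywhere carry the
  `no_melting` flag.

Fitting is bounded trust-region nonlinear least squares with an analytic
Jacobian; Tm is bounded to the grid range ± 15 °C. The start schedule is
deterministic: a data-driven Tm start at the interpolated half-melt
crossing, then the grid minimum, median and maximum; the schedule stops as
soon as a start reaches R² ≥ 0.95 (a clearly successful fit), and the best
start by SSE wins, ties broken by lower Tm. Optimizer failure yields
`converged = False`, never an exception; curves with fewer than 5 observed
points are skipped with a reason. R² = 1 − SSE/SST against the observed
fractions (undefined for constant curves, which then fail the gate).

## Screening statistics

**Contrasts.** Binders: cosubstrate − vehicle. Interactors: enzyme −
vehicle. Substrates: both − enzyme *and* both − cosubstrate (vehicle anchors
the single-arm classes; the substrate definition is the specific response
relative to both single treatments). A protein enters a contrast only with a
complete set of Tm values in the four samples involved (≥ 2 per group).

**Test.** Two-sided t-test on the replicate Tm values; pooled (Student) or
Welch variance chosen per protein by a two-sided F-test at α = 0.05 — with
n = 2 per group this gate is low-powered, which is accepted as part of the
procedure. No multiple-testing adjustment is applied; the permutation FDR
below is the global error estimate (a per-test correction would require an
error model the compound selection criteria do not admit).

**Selection gates** (defaults, all configurable): R² > 0.7 in every sample
of the relevant treatments; per-treatment replicate SD(Tm) < 2.5 °C;
p < 0.05 (substrates: minimum of the two contrast p-values < 0.05 and
maximum < 0.1); |ΔTm| > 1 °C (substrates: in both contrasts, with concordant
signs — a Tm sitting between the two single arms is not a specific
combination response). The 1 °C cutoff sits well above the typical
between-replicate Tm variation (median ≈ 0.4–0.6 °C, reported by
`replicate_variation_summary`); every candidate record carries per-criterion
booleans so a rejection is attributable.

**Permutation FDR.** Each round reassigns every protein's observed (Tm, R²)
pairs uniformly at random across its sample labels — preserving the
per-protein Tm distribution and missingness pattern while destroying the
treatment structure — and re-runs the complete selection, including the QC
gates that depend on the shuffled values (re-application is the default and
can be disabled; a whole-column shuffle mode is provided as an alternative
granularity). FDR = mean permuted hits / observed hits; undefined (NaN, with
a warning) when nothing was observed. Fully reproducible for a fixed seed.

## OPLS-DA and VIP

The Tm matrix (samples × proteins, complete cases, mean-centered and
unit-variance scaled per protein; centering-only is available) is modeled
against the binary class vector (+1 combination arm, −1 single arms) with a
NIPALS-style OPLS: `n_ortho` components of X-variation orthogonal to the
class response are removed (default 1), then one predictive component is
extracted. The single-response algorithm is iteration-free and exactly
deterministic; predictive and orthogonal scores are orthogonal by
construction, and removing the orthogonal components before a plain PLS fit
reproduces the predictive component (both tested numerically).

VIP defaults to the predictive-only variant, VIP_j = √K·|w_j| with unit
predictive weights (so ΣVIP² = K, the number of proteins); a total variant
additionally credits orthogonal components weighted by their explained
X-variance share. 95% confidence bounds come from leave-one-sample-out
jackknife refits — with 2–6 observations these are approximate by
construction and flagged as such. Class "reference points" (the stars of a
biplot) are the loading-space coordinates of the autoscaled class-indicator
dummy variables: t·d̃/(t·t) per component axis. R²X, R²Y and leave-one-out
Q² are reported but not gated on at these sample sizes. Candidates are
ranked both by |ΔTm| and by VIP (primary key configurable; ties broken by
the other key, then accession); candidates missing from the model input
keep the |ΔTm| rank and are flagged.

## Synthetic data generator

`SimulationConfig` defaults are the reference study conditions: 1000
proteins, 2 replicates × 4 arms on the default grid; baseline Tm ~ N(52, 4²)
°C, slope ~ N(0.035, 0.008²) clipped positive, plateau ~ U(0, 0.15); planted
classes 5% binders / 3% substrates / 2% interactors with signed |ΔTm| ~
N(2.5, 0.5²) °C (matching typical confirmed-substrate shift magnitudes;
`destabilization_prob` skews the sign for e.g. reductase systems); replicate
Tm jitter σ = 0.5 °C (the typical between-replicate variation of the assay);
multiplicative log-normal reporter noise (σ = 0.05) per cell; shared
per-sample per-temperature distortions (σ = 0.05) that normalization must
undo; 1% whole-protein-per-sample missingness; small contaminant and
single-peptide fractions to exercise the input filters. Planted effects act
on Tm only (slope and plateau held); an optional plateau-shift mode mimics
non-melters. Identical seeds give byte-identical tables, and the generator
writes the same TSV dialect the reader consumes.

What the simulator does **not** emulate: peptide/PSM-level structure,
reporter-ion interference and ratio compression, co-isolation, temperature-
dependent missingness, correlated melting of complexes, or heteroscedastic
abundance-dependent noise. Passing tests therefore demonstrate the
statistical machinery under honest noise of the right scale, not performance
on any measured dataset.

## Statistical power and expected recovery

With two replicates per arm, every contrast is a t-test on 2 + 2 values
(df = 2). At |ΔTm| = 3 °C and σ(Tm) = 0.5 °C the compound substrate gates
have a Monte-Carlo power ceiling of ≈ 87% even on error-free Tm values;
curve-fitting noise and missingness put realistic end-to-end recovery at
≈ 60–75%, with empirical FDR in the 10–20% range and the permutation
estimate tracking it within about a factor of two. Sensitivity claims
beyond that ceiling are not achievable at this replication level — adding
replicates, not loosening gates, is the remedy.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 1000
proteins (the generator default) with 50 permutation rounds, and smaller
panels (60–300 proteins) for focused checks — sizes chosen so any stage's
behavior is measurable while a complete run stays around half a minute on
one CPU. Optimizer tolerances: xtol 1e-9 / ftol 1e-12, max 2000 evaluations
per start. p-values are floored at 1e-300 (the contract is p ∈ (0, 1]);
degenerate zero-variance contrasts give p = 1 when the means agree and the
floor when they differ. All randomness flows through a single seeded
generator handed to each stage; thread count never affects results.

## Known limitations

* Two replicates per arm give df = 2 tests; the F-test variance gate is
  essentially powerless there and the Welch branch rarely fires.
* The permutation null preserves each protein's Tm multiset but not any
  between-protein correlation; FDR estimates for correlated families
  (complexes) may be optimistic.
* The jackknife VIP intervals are approximate at n ≤ 6 observations.
* The normalization reference-set criteria are a documented approximation
  to common practice, not a restatement of any specific published filter.
* Non-melters are excluded by a fitted-plateau threshold (0.5 by default);
  genuinely two-transition curves are out of scope.
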