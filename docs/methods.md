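# Methods

`ptew` assesses potentially toxic elements (PTEs — here Pb, Hg, Mn, Fe) in
drinking water along three axes: water-quality contamination indices,
deterministic ingestion health risk for children and adults, and Monte Carlo
uncertainty/sensitivity analysis of the risk outputs, plus the seasonal
statistics used to compare winter and summer campaigns. All concentrations
are µg/L; doses are mg/kg/day.

## Contamination indices

For metal *i* with measured mean concentration `M_i` and agency standard
`S_i`:

- contamination factor `Cf_i = M_i/S_i − 1`; negative below standard;
- degree of contamination `C_d = Σ Cf_i`, classified significantly low
  (`C_d < 1`), moderate (`1 < C_d < 3`) or high (`C_d > 3`);
- unit weight `W_i = k/S_i` with `k = 1`;
- sub-index `Q_i = |M_i − I_i| / |S_i − I_i| × 100`, where `I_i` is the ideal
  concentration. Absolute differences are used in both numerator and
  denominator, so a metal whose ideal value exceeds its standard (Mn:
  `I = 100 > S = 50` µg/L for EPA) stays well-defined and positive;
- `HPI = Σ W_i Q_i / Σ W_i`, classified excellent (<50), good (50–99.99),
  poor (100–199.99), very poor (200–299.99), unsuitable (≥300).

Band boundaries are unassigned by the usual strict-inequality definitions;
we assign `C_d = 1` to significantly_low and `C_d = 3` to moderate, and an
HPI boundary opens its band (HPI = 50 → good). Custom bands can be passed to
the classifiers.

### Rounding modes

`hpi(..., rounding="full")` (default) keeps full precision.
`rounding="table2"` reproduces the arithmetic of a typical tabulated report:
weights truncated at 4 decimals, `Q_i` and `W_iQ_i` rounded at 2 decimals,
the numerator sum rounded and the denominator sum truncated at 2 decimals
before the division. With the EPA standards the exact `ΣW_i` is 177/300 =
0.59, while the truncated-weight sum is 0.5899 → 0.58; the two modes
therefore differ visibly (full 20.47 vs tabulated 20.83 for the winter EPA
inputs). New analyses should use `"full"`; `"table2"` exists to reconcile
against legacy reports.

Known inconsistencies of the reference survey tables, reproduced here for
transparency and **not** emulated:

- the Fe summer contamination factor is tabulated as −0.96 although
  10.36/300 − 1 = −0.9655 rounds to −0.97, and the Mn summer WHO factor is
  tabulated as −0.99 although 0.55/400 − 1 = −0.9986 rounds to −1.00; the
  tabulated WHO `C_d` values (−3.87) sum those cells, whereas the exact sums
  are −3.876 (winter) and −3.881 (summer), both −3.88 at 2 decimals. This
  package reports the exact sums.
- the Mn summer WHO product `W_iQ_i` is tabulated as 0.07 although
  0.0025 × 33.15 = 0.083; we report 0.08, which makes the summer WHO HPI
  4.22 rather than the tabulated 4.18.

## Deterministic health risk

Chronic daily intake through drinking-water ingestion:

    CDI = C · IR · EF · ED / (f · BW · AT)        [mg/kg/day]

with intake rate IR (children 1.25, adults 1.95 L/day), exposure frequency
EF (triangular 180/345/365 days/year), exposure duration ED (6/50 years),
conversion f = 1000 (µg→mg), body weight BW (10.64/61.68 kg), and averaging
time AT = ED·365 days for the noncarcinogenic endpoint (ED cancels) or
70·365 days for the carcinogenic endpoint. Point estimates evaluate EF at
its mode (345 days/year): that is the value under which the reported mean
CDIs (e.g. Mn, children, winter: 0.00025 mg/kg/day) are reproduced, whereas
EF = 365 is not; EF remains an explicit argument.

`HQ = CDI / RfD` (RfD: Mn 0.14, Hg 0.0003, Fe 0.7 mg/kg/day) or `CDI / TDI`
for Pb (0.0035 mg/kg/day); `HI = Σ HQ`; acceptable when ≤ 1. Carcinogenic
risk `CR = CDI · SF` with the Pb slope factor 0.0085 (mg/kg/day)⁻¹;
negligible below 1e−6, threshold between 1e−6 and 1e−4 (inclusive), potent
above. CR is computed for every metal with a configured slope factor — only
Pb by default.

The children's winter+summer HI sum computes to 0.22503 here; reports that
state 0.22 are consistent with truncation or with summing display-rounded
seasonal values (0.13 + 0.09). We do not round intermediate values.

## Monte Carlo engine

Input distributions follow the standard exposure-modelling assignment:
concentrations lognormal, IR normal, EF triangular, BW lognormal, and ED,
AT, RfD, SF fixed (fixed per receptor group; ED and AT differ between groups
but do not vary within a simulation). Lognormals are parameterised by
**moment matching** so the arithmetic mean and sd equal the configured
values: `σ² = ln(1 + (s/m)²)`, `µ = ln m − σ²/2`. Triangular sampling uses
the inverse CDF; the truncated normal for IR resamples rejected (negative)
draws.

The survey states only the distribution *families* for IR and BW, not their
spreads. Defaults here: IR normal with CV 20% truncated at 0, BW lognormal
with CV 20%; both are explicit configuration (`mcs.ir_cv`, `mcs.bw_cv`) and
are flagged in every pipeline manifest. Published sensitivity percentages
depend on those unstated spreads, so only their signs and ranking are
meaningful comparisons, not the printed numbers.

Concentrations may be simulated per season or pooled; pooling draws the
season uniformly (50/50 mixture) and then the seasonal lognormal, matching
the single per-group histograms that surveys usually report. Inputs are
mutually independent — the source analysis states no correlation structure.

Reproducibility: one root seed; every input draws from its own child stream
keyed on (seed, input name) via `SeedSequence`, so adding an input never
perturbs the other inputs' draws, and identical seeds give bit-identical
results. With 10,000 iterations a run takes well under a second.

Numerical conventions: when every input is fixed the output vector is
constant and the mean/percentiles are returned as that constant exactly
(pairwise summation of a constant vector is not bit-exact for arbitrary n,
so the collapse is handled explicitly); a constant output yields an empty
sensitivity map rather than a 0/0.

Sensitivity is rank-correlation contribution-to-variance: Spearman ρ_j
between each input's draws and the output, reported as
`sign(ρ_j)·ρ_j²/Σ ρ_k² × 100`; fixed inputs contribute exactly 0, and the
absolute contributions sum to 100%. Variance-based (Sobol) indices are out
of scope.

With the default assumptions the children's pooled HI mean lands near 0.10
(5th–95th: ≈0.03–0.21), body weight carries a negative contribution for both
groups and both endpoints, and the Pb concentration dominates CR sensitivity
— matching the qualitative published findings.

## Seasonal statistics

Per metal: one-sample Kolmogorov–Smirnov normality per season at the fitted
mean/sd (the convention of classic SPSS output; `normality="lilliefors"`
switches to the estimated-parameter correction via statsmodels). If both
seasons pass at α = 0.05 the winter/summer comparison is Welch's t-test
(unequal variances — the equal-variance form is a strictly stronger
assumption with no benefit here), otherwise the two-sided Mann–Whitney rank
test. Two identical constant samples short-circuit to a flagged degenerate
result (p = 1).

Pairwise Spearman correlations come with two-sided p-values and strength
bands on |ρ|: weak (<0.5), moderate (0.5–0.7), strong (>0.7); boundaries
join the higher band. A constant metal column gives an undefined ρ, reported
as NaN with a warning. No multiple-testing correction is applied across
pairs, matching common practice in these surveys. Published correlation
values serve only as classification examples — they derive from raw samples
that are not deposited.

## Synthetic generator

Emulates the study design: 45 winter + 45 summer samples, each metal×season
drawn from a lognormal moment-matched to the configured mean/sd (lognormal
because that is the family the uncertainty analysis itself assigns to
concentrations). Per-metal-per-season child streams make the generator
bit-reproducible and insensitive to adding metals. Optional rejection
truncation to the observed ranges is off by default — truncation biases the
moments the generator is asked to recover. Site ids and box-jittered
coordinates are cosmetic; there is no spatial model.

`inject_correlation` retargets the Spearman correlation of one metal pair
inside one season by a Gaussian-copula rank coupling (latent Pearson
correlation `2·sin(πρ/6)`), permuting one metal's values only — marginal
multisets are exactly preserved; ρ = ±1 uses the exact co-/antimonotone
rearrangement. It needs ≥5 samples to be meaningful.

What passing tests on generated data do **not** show: real tap-water
campaigns have spatial structure, detection limits, seasonal site pairing
and inter-metal correlations that the independent-lognormal generator does
not emulate; conclusions about method behaviour under those features require
real data.

## Problem sizes

Monte Carlo runs use the conventional 10,000 repetitions; distribution-level
checks in the test suite use 10⁶ draws; the type-I-error and
parameter-recovery simulations use 200 generator seeds at the study's
n = 45 per season. The full test suite runs in well under a minute.

## Known limitations

- Ingestion is the only exposure route (no dermal/inhalation terms).
- Only Cf/C_d/HPI among water-quality indices; no WQI/Nemerow/I_geo.
- Sensitivity contributions assume monotone input–output relations (rank
  correlation); strongly non-monotone models would need variance-based
  indices.
- The KS normality default (estimated parameters, uncorrected) is
  conservative; prefer `lilliefors` when the decision between t-test and
  rank test matters.
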