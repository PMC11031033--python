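# Methods

## Decision problem and model

The package implements a decision-tree cost-effectiveness comparison of
tooth-whitening strategies from the consumer/patient perspective. Each
strategy is reduced to two parameters per market: an annual cost in USD and an
effectiveness in CIELAB ΔE\*ab units (the Euclidean distance between before
and after L\*a\*b\* coordinates). There is no state transition or time
dependence beyond the costing horizon: outcomes accrue once over a 12-month
horizon, the period the underlying randomized trials evaluate. Effectiveness
is interpreted against two clinical thresholds: a color change above 1.2
ΔE\*ab units is perceptible, above 2.7 clinically acceptable.

## Costing

Macro-costing values each strategy from aggregate unit prices. Dentifrice
strategies use the arithmetic mean of retailer tube prices, one tube per month
over the horizon; professional at-home bleaching is a one-off procedure fee at
month 0. Local-currency totals are converted to USD by dividing by the
market's conversion rate (5.42 BRL per USD for the Brazilian fixture).

The engine supports monthly discounting of recurring outlays at the monthly
equivalent `(1 + r)^(1/12) − 1` of the configured annual rate (default 5%/yr),
as an explicit `discount=True` flag; the default is undiscounted. This is a
deliberate choice: the packaged strategy costs (e.g. 10.3 USD = 12 undiscounted
tubes at the average tube price) are consistent with undiscounted sums, and
over a single year discounting changes a recurring cost by under 3%, less than
price variation between retailers. One-off fees at month 0 are never
discounted. `income_share` expresses a cost against any income figure
(monthly wage, weekly earnings) as a percentage; the income period is the
caller's choice and is reported with the result.

## Effectiveness pooling

Strategy-level effectiveness is pooled from trial arms by the sample-size
weighted mean Σnᵢxᵢ/Σnᵢ. This is the minimal defensible synthesis when arm
SDs are unreported (as in the packaged trial table): inverse-variance
weighting is impossible without dispersions, and n-weighting reproduces the
hydrogen-peroxide-dentifrice pooled value (≈3.9) used in the case studies.
When all arm SDs are present the pooled SD combines within- and between-arm
variance, `s² = [Σ(nᵢ−1)sᵢ² + Σnᵢ(xᵢ−x̄)²]/(Σnᵢ−1)`, i.e. the sample variance
of the concatenated subject-level data implied by the summaries; if any arm SD
is missing the pooled SD is reported as missing rather than guessed.

The packaged market fixtures carry the effectiveness point values of the
published model inputs directly rather than re-pooling them from the trial
table: the mapping from trial arms to model inputs in the source material is
not reproducible (the positive control's model value exceeds every
corresponding trial arm), so model effectiveness is treated as configuration
input and the trial table is shipped alongside for pooling analyses.

## Incremental analysis

Strategies are sorted by ascending cost. Strict dominance flags any strategy
for which an alternative costs no more and is strictly more effective, or
costs strictly less and is no less effective. Extended dominance is then
applied to the surviving candidates with the standard ICER-ladder rule:
repeatedly remove a middle candidate whose ICER against the previous frontier
member is not smaller than the next member's ICER against it, until ICERs
strictly increase along the frontier. Both labels are distinguishable in
output (`dominated` vs `extended_dominated`). In the US case study this marks
HPD extended-dominated (its 52.7 USD/unit ICER against CD exceeds CP10's
36.9); published tables often collapse both labels to "dominated".

In the Brazilian case study the engine reports HPD on the frontier
(ladder ICERs 8.1 < 13.1 are increasing), which matches the published CP10
row being computed against HPD, even though the source table's label column
calls HPD dominated; the engine follows the dominance definitions.

Row-wise incremental quantities (Δcost, Δeffect, ICER) are computed against
the previous less-costly frontier member — the convention of published CEA
tables — and an `icer_mode="reference"` option compares every row against the
reference strategy instead. An ICER with zero effectiveness difference is
undefined and is exported as the symbolic marker `dominated-or-equal`, never
as an infinity. NMB is `effect × WTP − cost`; the %NMB gain against the
reference uses `|NMB_ref|` in the denominator so the sign remains
interpretable when the reference NMB is negative (for a positive reference it
reduces to the plain relative difference). Ties in the NMB argmax go to the
lower-cost strategy, then lexicographic name, making all outputs
deterministic. The WTP switch points are the frontier ICERs: the upper NMB
envelope is convex piecewise-linear and its breakpoints coincide with them.

Published tables were evidently computed from unrounded inputs and then
rounded per cell, so cell-for-cell agreement at printed precision is not
attainable from printed inputs (e.g. an NMB printed 84.2 where rounded inputs
give 84.7). The package keeps full precision internally and rounds only for
display; tests assert the cells that are reproducible from printed inputs.

## Probabilistic sensitivity analysis

Parameter uncertainty is second-order: each Monte Carlo iteration draws a
(cost, effectiveness) pair per strategy, costs from a gamma distribution
(shape = mean²/SD², scale = SD²/mean; non-negative support, the PSA
convention for costs) and effectiveness from a normal distribution (color
change can regress below zero). A zero SD yields a point mass, so the
all-deterministic limit reproduces the deterministic analysis exactly — this
oracle equivalence is tested. The default cohort is 1,000 iterations; the
default WTP grid is 0–100 USD in steps of 1. All sampling flows through
one `numpy` generator seeded by the caller, so the full pipeline
(sample → CEAC → summary) is bitwise reproducible; the fixtures' default seed
is 20240205.

The acceptability curve assigns each iteration to the strategy with maximal
sampled NMB (ties to lower sampled cost) and reports per-strategy winning
fractions per grid point; they partition the iterations and sum to 1.

Because the source tables print no SDs, configurations missing an SD impute
`sd = 0.2 × mean` (an explicit, overridable coefficient of variation; a
moderate dispersion typical of PSA practice, emitted with a warning).
Consequently the probabilistic results for the case studies are qualitative:
the tests assert curve shape and threshold behaviour (the positive control
becomes and stays the probably-optimal choice above its deterministic switch
point), not exact probabilities.

## Synthetic data

`dentcea.synthetic` generates the two raw input kinds with known ground
truth: trial arms whose per-subject ΔE\*ab is normal with configurable true
mean/SD (each arm records the sample mean, SD and n of its subjects), and
retailer price lists that are lognormal around a true median price (prices
stay positive; the spread parameter is the log-scale sigma). Default sizes
mirror the packaged evidence base (about four arms of 15–25 subjects, three
retailers). The generator does not simulate color trajectories over time,
rebound, adherence, or arm-level covariates; passing recovery tests therefore
show that pooling, costing and frontier construction are statistically
consistent under the stated sampling models, not that real trial heterogeneity
is captured.

## Numerical choices and edge cases

- Monetary and effect values are floats at full precision; 2-decimal money is
  display-only.
- Duplicate (cost, effect) points both survive strict dominance (neither
  dominates); the ladder and switch-point logic collapse them to one
  representative so ICERs between consecutive frontier members are defined.
- Validation is eager and names the offending field; NaN/infinite inputs are
  rejected at construction.
- The sub-second runtimes of the test suite and acceptance script come from
  desk-scale problems: 4-strategy markets, 1,000-iteration cohorts, and
  500-config randomized cross-checks, which are the sizes the analysis is
  designed for.

## Known limitations

- Only the CIELAB ΔE\*ab metric is implemented; CIEDE2000 is out of scope.
- Effectiveness stays in ΔE\*ab units; no QALY/utility conversion.
- No EVPI/EVPPI; uncertainty is summarised by acceptability curves and PSA
  means only.
- The per-strategy cost and effectiveness draws are sampled independently;
  correlated parameter uncertainty is not modelled.
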