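# Methods

## Scope and structure

`herdsim` models a 1,000-cow commercial cow-calf operation that turns
bulls out on the same date every year and sells every weaned calf. Two
bull-management strategies are compared: an annual veterinary breeding
soundness evaluation of every bull with culling of failures ("tested"),
versus no evaluation ("untested"). The model is a hybrid: herd
reproduction and calf revenue are deterministic expected-value
recursions, while culling and mortality are random draws; the Monte
Carlo layer propagates that randomness into the distribution of the NPV
difference between strategies.

## Reproduction recursion

Conceptions per cycle follow
`IC_k = (CH − Σ_{j<k} IC_j) · e_k · f`, applied sequentially within the
year. Fertility `f` is the per-cycle conception probability of an
eligible cow and is treated as the bull-side rate limit; cow fertility
is not modelled separately. Eligibility `e_k` is 1 everywhere in year 1.
Afterwards a 2.5-cycle postpartum anestrus applies: for cycle `k`, cows
bred in previous-year cycles ≤ `k+1` are fully eligible, cycle `k+2`
cows half eligible, later cows ineligible, giving

    e_k = (CH − Σ_{j=k+2..K} IC_j,prev)/CH + IC_{k+2,prev}/(2·CH)

capped at 1. Counts are fractional expectations on purpose: integer
draws could not reproduce the herd-average grids, and the stochastic
machinery lives downstream in culling.

**Known discrepancy.** The published 65-cell herd-average grids this
model is calibrated against cannot be reproduced exactly from the
recursion above. The 2-cycle row matches cell for cell (with round-up
display), but elsewhere residuals of ±1–4 cows appear with no
systematic pattern: we scored 432 combinations of eligibility readings
(fraction-of-pool vs. count subtraction, lag offsets 1/2/3, half-return
0 or 0.5, 50- or 51-year horizons, round/ceil/floor display) against
all 195 published cells and the best reading matches 83. The published
grid's own rounding is internally inconsistent (884.4 prints as 885 but
998.02 prints as 998), which suggests the original spreadsheet included
additional unstated dynamics or manual transcription. The spot
quantities reported by `scripts/acceptance.py` all agree within 0.31%,
seven of nine exactly. The package keeps the recursion exactly as the
equations state it.

## Calf crop and pricing

Calves are weaned and sold 225 d after the calving season opens. The
cycle-1 cohort averages 214.5 d (born mid-cycle), each later cohort 21 d
less; weight is `birth weight (80 lb) + ADG (2 lb/d) × age`, spanning
509 lb down to 299 lb for a 6-cycle season. Pricing uses half-open 50-lb
classes keyed to the slide's row weights — weight `w ∈ (lo, lo+50]`
sells at the `lo` row, so 509 lb prices at the 500 row ($2.15) and an
exact 500 lb at the 450 row ($2.23); out-of-range weights clamp to the
end rows (never triggered by defaults). Weaned count applies the
survival product αδ; α and δ are not separately identifiable from the
published revenue grid, which pins only αδ = 0.9801, split evenly as 1%
abortion and 1% calf death loss by default (both configurable). Calf
revenue is booked in the conception year: a constant one-year gestation
shift would rescale both strategies' NPVs identically and is omitted.

## Culling and mortality

Bull culling is a sequential cascade — injury/temperament, exam failure
(tested only), age — with each event a binomial draw over the survivors
of the previous event, so no bull is culled twice. Defaults: injury 0.10
tested / 0.05 untested (handling for the exam is itself a risk event),
exam failure 0.20, age 0.25 (= 1/4-yr working life). Because the cascade
thins the battery bull by bull, the annual total is exactly
`Binomial(BH, P)` with `P = p_I + (1−p_I)p_T + (1−p_I)(1−p_T)p_A`;
`expected_bull_culls` returns that exact mean and variance (stage-wise
variance addition over expected survivor counts would overstate the
spread, 14.76 vs the true 9.94 for the tested 40-bull battery).

Cows not pregnant at diagnosis are culled deterministically
(fractional, inherited from the recursion); pregnant cows face a
binomial nonreproductive cull at 0.10 (= 1/10-yr working life).
Mortality (default 1%/yr for cows and bulls, configurable assumptions —
the source material prints no rates) is drawn over the full maintained
herd: animals are replaced within the period, so the at-risk pool stays
at capacity. Dead animals produce replacement costs but no salvage
revenue. Mortality is drawn independently of culling rather than from
the post-cull remainder; at 1% rates the distinction is far below the
Monte Carlo noise floor.

## Economics

Annual net cashflow = calf revenue + cull-cow salvage (1,000 lb ×
$0.86) + cull-bull salvage (2,000 lb × $0.85) − heifer replacements
($1,116 × all cow culls and deaths) − bull replacements ($7,250 × all
bull culls and deaths) − bull maintenance ($542.30/bull, plus the
$100/bull exam fee when testing). Cow maintenance is equal between
strategies and excluded by construction. All prices are time-invariant
over the horizon. Discounting uses a 20% total cost of capital with the
first production year at exponent 1; the alternative year-0 convention
rescales both strategies identically and cannot change the sign of any
ΔNPV. The exam fee may be set to 0 to express a cost-symmetric null
comparison.

## Monte Carlo design

Each scenario pair fixes (season length K, fertility difference d,
ratio pairing). The tested strategy holds fertility at the 66%
biological ceiling; the untested strategy runs at 66% − d,
d ∈ {0, 0.01, …, 0.12}. Ratio pairings are 25:25 and 33:25 (1,000 cows
→ 40 or 30 bulls, nearest-integer). Deterministic layers are computed
once per strategy; 500 iterations (the default, matching the original
analysis's stability choice) draw the culling/mortality panels
vectorized over (iterations × years). Each (scenario, strategy) draws
from its own named substream of the master seed (CRC-keyed
`SeedSequence` spawn), so strategies are independent by default and any
subset of the grid reproduces exactly; a common-random-numbers switch
shares the substream between paired strategies for variance reduction.
Ties (ΔNPV exactly 0) count as not-positive. Indifference points are
linear interpolations of the first 0.5 crossing of each p-vs-d curve,
with explicit "below grid"/"above grid" sentinels.

The full sweep (130 pairs × 500 iterations × 50 years) runs in a few
seconds on one CPU, so no subsampling is needed anywhere in the test
suite; distributional checks use 10^5 draws.

## What the generator does and does not emulate

The stochastic draws are the synthetic data: there is no field dataset.
The model captures the interaction the decision turns on — season
length, fertility, stocking rate, and the cost asymmetry of testing —
under i.i.d. binomial culling with time-invariant prices. It does not
capture price cycles or stochastic prices, bull age structure (age
culls are memoryless), within-herd fertility heterogeneity, disease
events, or correlated year effects (drought, market shocks). Passing
tests therefore demonstrate internal consistency of the capital
budget and the orderings it implies, not forecasts for any particular
operation.

## Numerical conventions

- Display rounding for the published-style grids: cows bred round *up*
  (matches the published 2-cycle row exactly), weights to the nearest
  pound, revenue to the nearest thousand dollars.
- `bulls_required` rounds to the nearest whole bull (1000/33 → 30).
- Fractional (expected) cull counts flow through revenue and
  replacement formulas unchanged; only genuinely random counts are
  integers.
- The recursion, pricing and NPV are pure float64 arithmetic; the only
  tolerance anywhere is the 1e-9 guard when testing eligibility caps
  and ceilings against accumulated rounding.

## Known limitations

- The published herd-average grids are only approximately recoverable
  (see "Known discrepancy" above).
- The original analysis reports realized bull-cull averages (12.6 and
  9.5 per year) that are inconsistent with its own stated cascade
  probabilities (closed-form 18.4 and 11.5); this package follows the
  probabilities. Conclusions that depend on the smaller printed cull
  numbers — notably that a 33:25 stocking advantage alone makes testing
  better than even odds at zero fertility difference — do not hold
  under the stated probabilities (p ≈ 0.11 at d = 0).
- A 15-yr horizon / 5% discount sensitivity is not re-run here, though
  both parameters are configurable.
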