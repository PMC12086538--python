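# herdsim

A capital-budgeting simulator for a question every cow-calf producer
faces: **is it worth paying a veterinarian to perform breeding soundness
evaluations (BSE) on the bull battery every year?** Screening culls
subfertile bulls, which protects the herd's per-cycle conception rate —
but it also costs an exam fee per bull and, because failures are culled,
raises bull replacement costs. `herdsim` compares the two strategies
(test vs. don't test) by net present value over a 50-year planning
horizon for a 1,000-cow southeastern-US herd, across breeding-season
lengths, fertility differences, and cow:bull ratios.

## The model

**Reproduction (deterministic).** With herd size CH, per-cycle conception
probability *f* (bull fertility is rate-limiting), and a breeding season
of *K* 21-day estrus cycles, the expected conceptions in cycle *k* of a
year follow

    IC_k = (CH − Σ_{j<k} IC_j) · e_k · f

where the eligibility fraction *e_k* encodes a 2.5-cycle postpartum
anestrus: cows bred in cycles ≥ *k*+2 of the previous year are removed
(half of cycle *k*+2 added back), so late-bred cows cannot rebreed early
the next year. Open cows are culled and replaced with bred heifers
calving in the first two cycles.

**Calf crop.** Calves sell 225 d after the calving season opens; the
cycle-*k* cohort averages 214.5 − 21(*k*−1) days of age and weighs
`birth weight + ADG × age`. Each cohort's weight is priced on a 50-lb
price slide (heavier calves, lower $/lb): weight *w* falls in the
half-open class (lo, lo+50] and sells at the lo-row price. Weaned count
is `IC_k · α · δ` with α, δ the abortion and death-loss survivals
(αδ = 0.9801 by default).

**Culling (stochastic).** Bulls pass through sequential binomial culling
events each year — injury/temperament, exam failure (tested strategy
only), age — so no bull is culled twice; the annual total is exactly
Binomial(BH, P) with P the compounded per-bull probability
(means 18.4 of 40 tested, 11.5 untested). Pregnant cows face a binomial
nonreproductive cull; mortality is drawn separately and triggers
replacement without salvage revenue.

**Economics.** Annual net cashflow = calf revenue + cull-cow and
cull-bull salvage − heifer and bull replacements − bull maintenance
(plus the $100/bull exam fee when testing). NPV discounts at a 20% cost
of capital. The decision statistic is ΔNPV = NPV(test) − NPV(no test),
and a Monte Carlo sweep (500 iterations per scenario) estimates
P(ΔNPV > 0) across the factorial grid of K ∈ {2..6}, fertility
differences d ∈ {0, 0.01, …, 0.12} and ratio pairings 25:25 and 33:25.

## A worked example

```bash
python examples/sweep_curves.py
```

prints, among the full probability grid, the indifference points — the
fertility difference at which testing reaches even odds of paying off:

```
         K=2, 25:1 vs 25:1: 0.044
         K=3, 25:1 vs 25:1: 0.066
         K=4, 25:1 vs 25:1: 0.092
         K=5, 25:1 vs 25:1: 0.114
         K=6, 25:1 vs 25:1: above grid
         K=2, 33:1 vs 25:1: 0.010
         K=6, 33:1 vs 25:1: 0.041
```

Read: with a tight 2-cycle season and equal 25:1 stocking, a 4.4-point
fertility protection already justifies testing; with a 6-cycle season
even 12 points does not give better-than-even odds ("above grid") —
long breeding seasons let extra cycles recover pregnancies a subfertile
bull missed. If testing lets the producer run 33 cows per bull instead
of 25, the threshold collapses to 1–4 points: fewer bulls to maintain
and replace pays for the exams almost by itself.

The deterministic layer is tabulated by `examples/deterministic_grid.py`
(e.g. a 2-cycle season at 66% fertility breeds 885 of 1,000 cows, weans
498-lb calves and grosses $937k/yr; at 54% fertility revenue falls to
$833k), and `examples/bull_culling.py` and `examples/npv_comparison.py`
walk the stochastic layers.

The same computations are available from a shell:

```bash
herdsim deterministic --out out/
herdsim montecarlo --out out/ --iterations 500 --seed 1 [--plot] [--audit]
```

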