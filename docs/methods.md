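# Methods

## Model structure

The whitefly life cycle is represented by four stages (egg, pooled nymph,
pupa, adult) on a daily time step. Each immature stage is a
stay/advance/die chain with daily probabilities (s, r, d), s = 1 − r − d;
adults survive with probability 1 − d_A and lay F eggs per day. The daily
projection matrix is

```
        egg      nymph    pupa     adult
egg   [ s₁       0        0        F   ]
nymph [ r₁       s₂       0        0   ]
pupa  [ 0        r₂       s₃       0   ]
adult [ 0        0        r₃       1−d_A]
```

Each day the state vector is multiplied by the matrix interpolated at
that day's mean temperature, after which γ·A² is subtracted from the
adult class (clamped at zero). The multiply-then-subtract order matters:
the scalar equilibrium satisfies A* = B − γB² with
B = (1 + F·E − d_A)·A*, not the naive flux balance γA*² = (F·E − d_A)A*.
The geometric stage durations implied by the chain act as distributed
delays, which keeps the calibrated equilibrium stable (the dominant
transient eigenvalue on the default fixture is ≈ 0.94).

Assumptions worth keeping in mind: abundances are continuous and
deterministic (no demographic stochasticity); density dependence acts
only on adults; vital rates respond to temperature only through the
anchor matrices; there is no evolution of resistance.

## Parameterization

* r = 1/m from median stage durations; d = 1 − stage survival.
* The four nymphal instars are pooled: r₂ = (T₁+T₂+T₃+T₄)⁻¹ and
  d₂ = (T₁N₁+T₂N₂+T₃N₃+T₄N₄)/(T₁+T₂+T₃+T₄) — the duration-weighted mean
  instar mortality.
* **Field mortality q.** Laboratory survival overstates field survival.
  A single additive daily mortality q is applied uniformly to egg, nymph
  and pupa and solved by bisection (tolerance 1e−12 on q) so the
  analytic egg-to-adult emergence E = Π r/(r+d+q) equals the observed
  ~10% field emergence. A single uniform additive q is the simplest
  one-parameter mechanism consistent with "reduced immature survival";
  it is isolated in `with_field_adjustment` and trivially swappable for
  a stage-specific or multiplicative variant.
* **Emergence probability.** "Adult emergence rate" is interpreted as
  the probability an egg ever reaches adulthood, which for the daily
  chain is exactly Π r/(r+d). A vectorized Monte-Carlo cohort simulator
  (`simulate_cohort`) provides an independent stochastic check.
* **Density dependence γ.** Solved by bisection on log₁₀γ so that the
  mean adult density over the last 60 days of a 730-day run at the 28 °C
  reference equals K = 500 adults/leaf. The steady state is monotone
  decreasing in γ, so the bracket (10⁻⁹, 10) always contains a single
  root when the population grows at all; a non-growing population
  (dominant eigenvalue ≤ 1) raises an error instead.
* **Generation length g.** The expected egg-to-adult time Σ 1/r at the
  reference temperature, rounded to whole days (20 on the default
  fixture). Used to convert per-generation kill fractions P into the
  daily increment 1 − (1−P)^(1/g), added to adult (P_A) and nymph (P_L)
  daily mortality. Increments are capped so stay probabilities remain
  non-negative; eggs and pupae are untouched because the bioassays
  measured only adult survival and nymph development.

Defaults: reference temperature 28 °C (an anchor); initial state one
adult per leaf; horizon 730 days; steady state = mean of the last 60
days; take-off day = first day adults ≥ 5% of K. The last two are
reporting conventions, configurable in `scenarios`.

## Two-patch landscape

The state doubles to (wild-type patch, transgenic patch) × 4 stages with
an 8×8 block matrix; the WT patch uses untreated matrices, the
transgenic patch treated ones, and γ acts within each patch. Adult
migration runs WT → transgenic only. The daily migration fraction is
m = m_max·(1 − coverage): immigration pressure on a transgenic plot is
proportional to the surrounding WT area, vanishing at full coverage.
(The alternative scalings — by transgenic share, or symmetric — are one
line away in `effective_migration`; the proportional-to-WT-area rule is
the one that makes the coverage experiments meaningful.) The coupling
entry is m × (WT adult daily survival), i.e. movement composes with the
mover's survival; summed over patches, migration itself neither creates
nor destroys adults. With m = 0 the 8×8 system reduces to two
independent 4×4 systems bit-for-bit, which the tests assert.

## Scenario grids

* Treatment grid: intensities {30…80}% × modes {both, nymph-only,
  adult-only}, one shared WT baseline; metrics are steady-state adults,
  percent reduction vs WT, take-off day and take-off delay in
  generations ((takeoff_treated − takeoff_WT)/g).
* Coverage grid: coverages {0.2, 0.4, 0.6, 0.8} × m_max {1%, 10%}/day
  with a fixed 60%/60% treatment; metrics are computed on the transgenic
  patch.

## Synthetic data

The generator emulates the study's three inputs so nothing external is
required.

**Life tables.** Stage-level whitefly demography in the 16–32 °C band is
smooth and unimodal; the generator uses quadratic temperature responses
centred at 28 °C. Base values at 28 °C: durations 4 d (egg), 3+3+3+3 d
(instars), 4 d (pupa) — summing to a ~20-day generation, so two
generations ≈ 40 days; stage survivals 0.70 (egg), 0.995 per instar,
0.70 (pupa); adult daily survival 0.95; fecundity 8 eggs/adult/day
(within the published range for *B. tabaci* on good hosts). Durations
scale by 1 + 0.005(T−28)², survivals lose 0.0005(T−28)², fecundity
follows 8(1 − ((T−28)/20)²). Laboratory mortality is deliberately
concentrated in the egg and pupal stages (moulting failure) with very
low per-instar nymph mortality: most immature field mortality then
enters through the calibrated q, and the pooled nymph turnover r₂+d₂
stays small relative to the recruitment margin F·E. That is the regime
in which nymph-stage suppression structurally outweighs adult-stage
suppression — the qualitative configuration the simulation experiments
probe. A seeded 1% log-normal jitter on durations/fecundity and ±0.003
on survivals distinguishes replicate tables without disturbing this
structure.

**Temperature series.** Daily means = 23 °C + 4 °C·sin(2πt/365) +
N(0, 1 °C), clamped to [16, 32] — tropical and near-constant, like
Kampala. The series seed is offset from the life-table seed so the two
streams are independent.

**Sequence panels.** Uniform-random A/C/G/T dsRNAs and references, with
optional planted 21-mers (forward or reverse-complemented) at stated
positions, for exercising the screen.

What the fixture does *not* emulate: real instar-resolved vital rates
(the study's are from a separate laboratory dataset), diurnal/seasonal
temperature structure beyond a sinusoid, and any correlation between
vital-rate errors across temperatures. Passing tests therefore
demonstrate the correctness of the machinery and the *qualitative*
structure of the findings (orderings, monotonicities, migration
effects), not the study's printed effect sizes, which depend on the
deposited demographic rates.

## Off-target screen

Each dsRNA is decomposed into all overlapping 21-mers (1-nt sliding
window). References are scanned with a sliding window and tested against
a hash of the dsRNA k-mers (forward) and of their reverse complements
(reverse strand), so the scan is linear in the reference length.
Matching is exact (0 mismatches) and case-insensitive; windows
containing N never match; overlapping occurrences are each counted; a
k-mer occurring at several offsets of one dsRNA is counted once per
reference occurrence. Reverse-strand hits are reported at the
forward-strand coordinate of the matched window; positions are 0-based
half-open internally and 1-based inclusive in reports. Genome-scale
panels stream through the same code path; all tests use small generated
fixtures, cross-checked against a naive quadratic string-search oracle.

## Numerical choices and problem sizes

All bisection tolerances (1e−12) are far below the reporting precision.
Interpolation is exact at anchors by construction (weight 0/1 arithmetic)
and clamps outside the anchor range. Simulations run 730 days; the
Monte-Carlo cohort uses 100,000 eggs (3 s.e. ≈ 0.3 percentage points on
a 10% emergence); the screen's randomized equivalence trials use 40-nt
dsRNAs against 10-kb references, 50 fixtures. The whole suite and the
acceptance script each run in seconds on one CPU.

## Known limitations

* q uniform across immature stages is an identifiability choice: any
  stage allocation reproducing the same E is observationally equivalent
  in this model.
* Per-generation kill fractions are converted assuming constant daily
  hazard over the generation; time-varying RNAi exposure is not
  modelled.
* The two-patch model has no spatial structure beyond the two
  compartments, and migrants adopt the destination patch's demography
  instantly.
* Sub-21-nt or >21-nt partial matches are outside the screen's contract
  (exact 21-mers only), as is mismatch-tolerant search.
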