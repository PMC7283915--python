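# Methods

## Scope and data model

`droughtmix` analyses designed pot experiments that compare two legume
cover-crop species — alsike clover (*Trifolium hybridum*, `AC`) and black
medic (*Medicago lupulina*, `BM`) — grown as monocultures and as a 1:1
mixture, under two drought regimes:

* **Resistance** (constant cumulative drought): three diversity treatments
  × six irrigation levels (100/85/70/55/40/25% of soil water-holding
  capacity, WHC), four complete blocks, one destructive harvest at 50 days
  after sowing (DAS).
* **Resilience** (transient drought event): three diversity treatments ×
  two arms (non-stressed vs stressed) × five destructive harvests
  (23/37/44/58/72 DAS), five complete blocks. The stressed arm receives
  33% of the control water for 14 days starting at 23 DAS and is rewatered
  identically from 37 DAS.

All analyses consume one tidy long-format table with columns
`experiment, block, diversity, component, arm, harvest, das, biomass_g,
cum_water_l`. Monoculture pots carry a single `total` row; mixture pots
carry per-species component rows plus a `total` row equal to their sum.
Because harvests are destructive, every pot appears at exactly one
harvest, while block identifiers are shared across harvests so that
within-block pairing across treatments and harvests is possible.

## Index calculus

For biomass `b` (g DM pot⁻¹) and cumulative applied water `w` (L pot⁻¹):

* **WUE** = `b / w` (g DM L⁻¹).
* **CGR** = `(b_i − b_{i−1}) / [A (t_i − t_{i−1})]` (g m⁻² d⁻¹), with `A`
  the pot ground area. Negative rates (net loss) are legal.
* **PLER/LER**: `PLER_s = b_s,mix / b_s,mono`, `LER = PLER_AC + PLER_BM`.
  `LER > 1` indicates a mixture land-use advantage.
* **AME** = `y_mix − (y_AC + y_BM)/2`, the absolute mixture effect for any
  variable `y`.
* **Relative change** = `100 · (y_stressed / y_non-stressed − 1)` (%).
* **Resilience** `r = 2|D0| / (|D0| + |Dx|) − 1`, where `D0` is the
  non-stressed − stressed difference at the end of the drought event and
  `Dx` the same difference at a later recovery harvest. The index lives in
  `[−1, 1]` with complete recovery at `+1`; the absolute values mean that
  overcompensation (stressed overtaking control) is scored by the size of
  the residual gap, not its sign. Signed `D0`/`Dx` are retained alongside
  for diagnostics.

Degenerate denominators never become silent numbers: scalar functions
raise, table functions emit `NaN` plus a reason flag
(`nonpositive_monoculture`, `d0_zero`, `nonpositive_baseline`), and the
test layer turns zero-variance inputs into flagged results.

### Aggregation

Indices are reported at two levels. Point estimates use treatment means
per design cell; inferential statistics use **block-paired replicates**
(e.g., a per-block LER formed from the block's own mixture and
monoculture pots), which is what gives the tests against 1 (LER) and 0
(AME, resilience) their replicate-level variance. `D0` is taken at the
end-of-event harvest (H2), `Dx` at each of H3–H5. CGR point estimates use
consecutive-harvest treatment means; for ANOVA/Tukey letters and
mixture-effect tests, a per-block CGR is formed by pairing each block's
pots across the two harvests of the interval — this exploits the shared
block labels and is the only way to attach replicate variance to a rate
that spans two destructive harvests.

The first harvest has no CGR (no preceding interval); starting the rate at
sowing with zero biomass is deliberately not done by default, since the
establishment phase is not comparable to between-harvest growth.

## Comparison layer

* Per design cell, a one-way ANOVA across the three diversity treatments,
  followed by Tukey's HSD (studentized-range distribution, via
  `scipy.stats.tukey_hsd`) at α = 0.05 and a compact letter display. The
  letter display enumerates maximal cliques of the non-significance graph
  (exact for the small level counts of designed experiments); clique order
  and therefore lettering is deterministic, ties broken by level label.
* Indices against a constant (LER vs 1, AME and resilience vs 0) use a
  two-sided one-sample t test on the block-paired replicates; testing
  against a constant is the degenerate case of the two-sample unequal-
  variance framing, since the constant contributes no variance.
* Pearson correlation (t-based p, n−2 df) relates per-level mean LER and
  AME to drought intensity, encoded as the numeric WHC fraction
  (1.00 … 0.25), giving df = 4 for six levels.
* p values are not adjusted across cells or harvests; each cell's test is
  reported on its own, matching how such trials are conventionally
  summarized figure by figure.

## Synthetic experiment generator

The generator exists so that every stage of the pipeline can be exercised,
calibrated and property-tested without the original raw data. It emulates
the two designs above; it is not a soil-physics model.

### Irrigation schedules

Only cumulative constraints of the original trials are published, so daily
series are smooth constructions satisfying them exactly:

* Resistance: all levels share the sowing water (0.478 L at day 0) and a
  uniform evaporation replacement (default 0.055 L d⁻¹) for the first
  week; from 7 DAS level `f` receives `f × (E(t) + T(t))`, where
  transpiration compensation `T` starts at 21 DAS and ramps to a 0.08 L
  d⁻¹ cap (canopy closure).
* Resilience: both arms receive identical water summing to exactly 0.98 L
  pot⁻¹ by 22 DAS (0.525 L at sowing, the remainder spread evenly); during
  the event (23–36 DAS) the stressed arm gets 33% of the control's daily
  amount (default 0.09 L d⁻¹); afterwards both arms are identical.
  `event_fraction = 1` is the no-drought configuration: the arms are then
  identical and no event window is recorded, which downstream produces
  `D0 = 0` and flagged-undefined resilience — never a spurious `+1`.

### Growth model

Each pot runs a discrete-day two-species Lotka–Volterra update

    B_s(t+1) = B_s(t) + r_s · m_s(t) · B_s(t) · (1 − [B_s + α_s B_s′]/K_s) · g_s(w_t)

with saturating water limitation `g_s(w) = w/(w + h_s)` driven by the
day's applied water, and a stress multiplier `m_s(t)`: 1 before the event,
`s_event` during it, then a linear ramp to the compensatory boost
`c_comp` over `tau_recovery` days after rewatering and a linear decay back
to 1 over the same span. `s_event = 1` disables the whole mechanism (no
stress, hence no compensatory response). The daily Euler step tracks the
continuous logistic to within 1% over 50 days at small growth rates,
which is the regime the tests pin down.

Observed biomass is the trajectory value at the pot's harvest day times
`exp(block effect) × exp(pot noise)`, with a shared per-block normal
effect (sd 0.10 on the log scale) and per-pot noise (sd 0.07). Both
multiplicative terms reflect that biomass is positive and replicate CVs
of pot trials are roughly proportional; one pot-level draw scales both
mixture components so the emitted total equals the component sum exactly.
All randomness flows from one mandatory seed; identical inputs give
byte-identical tables.

### Default species parameters

Defaults are model constants, not fits — no raw data are available to fit.
They were calibrated once so that noise-free runs reproduce the
qualitative contrasts the experiments established, then frozen:

| parameter | AC | BM | meaning |
|---|---|---|---|
| `r_max` (d⁻¹) | 0.30 | 0.14 | intrinsic relative growth rate |
| `K` (g pot⁻¹) | 14 | 10 | per-pot biomass ceiling |
| `alpha_inter` | 0.70 | 0.70 | interspecific competition (<1 ⇒ complementarity) |
| `h_water` (L d⁻¹) | 0.12 | 0.06 | water-response half-saturation |
| `s_event` | 0.35 | 0.60 | growth multiplier during the event |
| `tau_recovery` (d) | 10 | 4 | recovery ramp length |
| `c_comp` | 2.4 | 1.10 | compensatory boost after rewatering |
| `b0` (g plant⁻¹) | 0.006 | 0.030 | seedling biomass at emergence |

The contrast encodes the two species' strategies: AC is
drought-sensitive (high `h_water`, low `s_event`) with a high ceiling and
a slow but strong compensatory recovery; BM is drought-adapted with quick
but shallow recovery. BM's early vigour is expressed through its large
seedling mass rather than a higher intrinsic rate: with a fast late-season
rate BM's stressed arm saturates at its ceiling by the final harvest,
which erases the stressed/control gap and with it the species contrast in
the resilience index. With these defaults, noise-free runs show: AC
out-yielding BM at full irrigation but losing a far larger biomass
fraction at 25% WHC; stressed-arm regrowth (CGR) of BM exceeding AC in
the first recovery week; the resilience index increasing over harvests
for every treatment, negative at H3 for AC and the mixture; and a fuller
final recovery in AC than BM (r ≈ 0.78 vs 0.29 at H5). The default
complementarity (`alpha_inter = 0.70`) yields a mixture biomass effect of
about 2.1 g pot⁻¹ at the final harvest, which the replicate-level test
against zero detects with roughly 90% power at five blocks.

## What the generator does and does not emulate

It reproduces the design geometry (blocks, arms, destructive harvests),
multiplicative replicate noise, water-driven growth limitation, and the
asynchronous two-species recovery. It does **not** model germination or
emergence stochasticity, soil physics or evapotranspiration feedback,
root allocation, nutrient dynamics, or mortality. Passing tests therefore
demonstrate that the index and inference machinery behaves correctly on
data with the declared structure — not that the growth model is an
adequate description of any particular field or greenhouse dataset.

## Numerical and design choices

* Time is integer DAS with 0 = sowing; the event window is the inclusive
  interval [23, 36], release at 37 DAS.
* Pot areas come from the stated geometry: square 12 × 12 cm ⇒ 0.0144 m²;
  round Ø12 cm ⇒ π·0.06² ≈ 0.011310 m².
* Simulation problem sizes in the test-suite: statistical calibration uses
  10⁴ null replicates for the one-sample and ANOVA type-I error and 3·10³
  for the Tukey family-wise rate (the studentized-range quadrature
  dominates the cost); the mixture-null LER calibration uses 10³ simulated
  experiments; effect recovery uses 200.
* Report serialization rounds percentages to 1 decimal and index values
  to 3; internal computation is full precision. CSV output is
  deterministic, so re-running an analysis reproduces files byte for byte.

## Known limitations

* The exact daily watering pattern of the original trials is
  unrecoverable; only the published cumulative constraints are enforced,
  so absolute WUE levels from synthetic runs are schedule-dependent.
* The compact letter display is exact but enumerative; it is guarded to at
  most 12 levels (designed experiments rarely exceed a handful).
* One-sample tests on five blocks have modest power; resilience contrasts
  near zero will often be non-significant, as in the motivating trials.
* The three-factor omnibus ANOVA (diversity × drought × harvest) and
  GLM-based modelling are out of scope; the package reports the per-cell
  one-way layer that figures conventionally summarize.
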