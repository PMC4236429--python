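# Methods

## Model

The package implements a deliberately minimal, static model of
innate-adaptive immune communication. Its single mechanistic premise is
that the innate system never names its target: danger signals activate
antigen-presenting cells (APCs), which display a sample of *all* ambient
antigens, and the adaptive system must pick its target from that sample.
Every result follows from the sampling probabilities.

State is an abundance vector: antigen `i` occupies any given MHC slot with
probability `a_i`, its normalized effective abundance. Three processes are
modelled on top of it:

1. **Negative selection.** Each of the `m` naive clones reactive to a
   self antigen independently experiences `t0` presentations; a single
   encounter with the cognate antigen deletes the clone. The per-clone
   cognate count is binomial(`t0`, `a_i`); the analytic layer uses the
   Poisson zero-count approximation, giving the tolerance probability
   `f_i = (1 - e^{-a_i t0})^m`.
2. **Efficient presentation.** Lymphocyte activation requires at least
   `n*` cognate MHC-peptide-TCR complexes on one APC with `N` slots.
   The slot count is binomial(`N`, `a_i`); the analytic form is the
   Poisson survival function at rate `a_i N`, which switches from 0 to 1
   around `a* = n*/N` and is replaced by a Heaviside step in the default
   `"step"` mode.
3. **Response.** Conditional on innate activation, the targeting
   probability of an antigen is its exposure times its untolerated
   fraction, `a_i (1 - f_i)` (generalized to
   `1 - (1 - a_i(1-f_i))^m`), gated by the presentation threshold.

Perturbations: a pathogen of total abundance `p` rescales self abundances
by `(1 - p)` (the pathogen itself is never tolerated); a `k`-fold
over-expression multiplies one antigen's abundance. Tolerance is *always*
evaluated at basal abundance — the abundances at the time of maturation —
which is what makes raised self antigens (infections, tumors) dangerous:
they are exposed at their new abundance but were tolerated at their old
one.

## Parameters

| symbol | meaning | default / typical | notes |
|---|---|---|---|
| `t0` | presentations during maturation | 10^3-10^4 | `t0 = K N s` |
| `N`  | MHC slots per APC | 10^3 | dimensionless count |
| `n*` | complexes needed for activation | 5-10 | experimental estimates |
| `K`  | APCs scanned during maturation | 200-several thousand | |
| `s`  | fraction of APC surface scanned | 0.05 (conservative) | (0, 1] |
| `m`  | naive clones per self antigen | 1 | m>1 forms approximate |
| `p`  | pathogen effective abundance | scenario knob | must be >= `a*` to be visible |
| `k`  | over-expression fold factor | scenario knob | detection needs `k a_i >= a*` |

Derived: `a* = n*/N` (threshold), `a_max = 1/(t0 m)` (riskiest self
abundance), `MDI = a* t0 = K s n*`, `Δ = tanh((MDI-1)/2)` for `m = 1`.

## Numerical choices

- All survival/CDF quantities go through `scipy.stats` primitives
  (`poisson.sf`, `binom.pmf`), never naive summation.
- Ratios are computed in log space (`log_correct_targeting_ratio`,
  `log_lower_bound_ratio`): R reaches `e^{50}`-`e^{500}` and the
  denominator bracket `1 - (1 - a*(1-f*))^m` underflows `1 - x` at
  `x ~ 1e-17` if formed directly; it is built from `expm1`/`log1p`
  instead. Linear accessors exponentiate and may return `inf`, which is
  meaningful.
- `Δ` saturates to float 1.0 above MDI ≈ 37. `discrimination_complement`
  returns `1 - Δ = 2e^{-(MDI-1)}/(1 + e^{-(MDI-1)})` without
  cancellation (at MDI = 50 it is ~1.05e-21).
- `a_i t0` beyond the exp range returns the exact limit (`f = 1`,
  targeting 0) rather than raising.
- The exact correct-targeting quotient is the default; the truncated
  `p e^{a* t0}/((1-p) a* m^2)` form is exposed separately
  (`approx_correct_targeting_ratio`) for comparison only. For `m = 1` the
  two agree to the `(1-p)`-order terms; the validity range of the `m^2`
  truncation for `m > 1` is not characterized, and we found numerically
  that the companion claim `a_max = 1/(t0 m)` is itself only an
  order-of-magnitude guide for `m > 1` (the true risk maximum for `m = 2`
  sits at `1.21/t0`, not `1/(2 t0)`).
- Over-expression supports both conventions: un-renormalized (the
  analytic closed forms' convention) and renormalized (required before
  sampling). The two differ by `O(k a_i)`.
- Region boundaries on the Δ-MDI trade-off default to (3, 20): they are
  an explicitly arbitrary convention chosen so that "almost full
  discrimination just above 10-fold" lands in the optimal region 2 and
  the physiological MDI ~ 100 in region 3. Half-open intervals, lower
  edge inclusive.
- Half-integer rounding in reported integer ratios uses Python's
  round-half-even.

## Simulator

`montecarlo` samples the exact finite-count model — binomial maturation
encounters and multinomial APC slots — precisely so that the analytic
layer's Poisson approximations are *validated* rather than assumed.

The response rule is: draw one APC (multinomial slots), inspect **one
uniformly chosen slot**, and target that slot's antigen iff its total
slot count reaches `n*` and a surviving reactive clone exists; otherwise
no response. The uniform slot pick lands on antigen `i` with probability
`E[c_i]/N = a_i` exactly, so for `m = 1` the simulated marginal equals
the closed form `a_i(1 - f_i)` (times the threshold gate) with no bias.
The alternative rule of renormalizing over currently eligible antigens
couples the marginals across antigens and inflates the pathogen/self hit
ratio by ~`f*/(1-f*)` (a ~7% bias at the validation parameters, outside
3 SE at 10^6 replicates), so it was rejected. For `m > 1` the simulator
still makes a single slot inspection per decision; its marginal is then
`a_i(1 - f_i)` rather than the closed forms'
`1 - (1 - a_i(1-f_i))^m ≈ m a_i(1-f_i)`, so oracle comparisons are done
at `m = 1` (the default) and the `m`-fold forms are checked analytically.

One APC encounter per response decision; `K` and `s` enter only through
`t0 = K N s`. A master seed drives `numpy.random.default_rng`; results
are bit-reproducible for a fixed seed and batch size (batches bound
memory; different batch sizes consume the RNG stream differently and are
only statistically equivalent).

## Synthetic environments

`generate_environment` draws raw abundances log-uniformly (default) or
log-normally over a decade range (default 1e-6..1e-2) and normalizes.
This emulates the only feature of real antigenic microenvironments the
model consumes — abundances spanning several orders of magnitude — and
nothing else: no correlation structure, no tissue compartments, no MHC
allele diversity, no temporal fluctuation. A green simulation test
therefore establishes agreement between simulator and closed forms under
the model's own assumptions, not fidelity to measured peptidomes.

## Validation regimes

The step-function closed forms idealize the sharp but finite multinomial
threshold. Oracle-equivalence tests therefore run in regimes where the
gate factor is immaterial: reference antigens are kept well above the
threshold (`n* = 1` with large `a N`, or fold changes overshooting the
MDI), because an antigen sitting *exactly* at its threshold is presented
efficiently only ~half the time (Poisson median), which the step form
rounds up to 1. This is a property of the approximation, not a simulator
artifact, and is itself tested (convergence of exact to step as N grows).

## Limitations

- Static and probabilistic: no lymphocyte population dynamics, expansion,
  memory or affinity maturation; no time-resolved infection course.
- Peripheral tolerance is a passive threshold ("peripheral ignorance"),
  not an active regulatory process; specific peripheral tolerance,
  regulatory cells and tolerogenic presentation are out of scope.
- Commensal (non-pathogenic foreign) antigens are not modelled.
- `m > 1` closed forms are heuristic compositions (see above); treat
  their quantitative output as order-of-magnitude.
- The multi-antigen response rule beyond the single-slot inspection is
  underdetermined by the model; quantities that depend on competition
  between simultaneously eligible antigens should not be over-read.
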