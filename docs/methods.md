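# Methods

## The model

The package implements a discrete-generation life-cycle model for a haploid
population of fixed adult number `A` carrying two self-incompatible mating
types, X and Y, inspired by the reproductive biology of green and brown algae
(*Chlamydomonas*, *Ectocarpus*) in which sex is facultative.  Each adult of
class *i* has a fixed mass budget `M` and a heritable gamete size `m_i`, and
differentiates completely into `N_i = A_i M / m_i` gametes — the
quality–quantity tradeoff.  Gametes of opposite mating type fuse by mass
action at a size-independent rate over a fertilisation window; the joint
effect of rate and window length is the single dimensionless parameter `phi`.
In the gamete-competition limit `phi → ∞` every macrogamete is fertilised and
only surplus microgametes remain unfused.

Survival of both routes to adulthood follows a Vance function, a decaying
exponential in inverse propagule size:

* a zygote formed from gametes of sizes `m_i`, `m_j` survives with
  `exp(-beta_z / (m_i + m_j))` — zygotes pool the mass of both gametes;
* an unfused gamete developing as a parthenosporophyte survives with
  `exp(-beta_p / m_i)`.

`beta_p > beta_z` is the parthenogenetic-disadvantage scenario,
`beta_p < beta_z` the advantage scenario; `beta_p = ∞` recovers obligate sex.
Each surviving zygote undergoes meiosis and contributes exactly one adult to
each parental class — the expected value of Mendelian mating-type
inheritance, and the convention under which the closed-form adult sex ratio
below is the exact fixed point of the map (any other meiotic yield changes
the zygote/parthenogen weighting).  Density regulation then rescales all
counts by a common factor so the total is `A`, after which any class below
the extinction threshold (default 1 adult — the model's only trace of
demographic finiteness) is culled and the remainder re-normalised.  Dynamics
are deterministic expected-value recursions; there is no demographic
sampling noise.

## The analytic layer (`phi → ∞`)

Writing the microgametic (smaller-gamete) type's trait as `m_micro` and the
macrogametic one's as `m_macro`, the equilibrium adult sex ratio — the
proportion of microgamete producers — is

    R = m_micro (E_p − E_z) / (2 m_micro E_p − (m_macro + m_micro) E_z),

with `E_p = exp(beta_p/m_micro)` and `E_z = exp(beta_z/(m_macro+m_micro))`,
valid while

    beta_p > beta_z m_micro/(m_macro+m_micro) − m_micro log(m_micro/m_macro);

below that threshold surplus-microgamete parthenogenesis overwhelms the
zygotic route and `R = 1` (macrogametes extinct, de facto asexuality).  The
implementation evaluates the ratio through the single exponent
`E_z/E_p = exp(beta_z/s − beta_p/m_micro)`, which is bounded above by
`m_micro/m_macro` in the valid regime, so no overflow is possible; the
threshold is checked first.

Selection gradients are derivatives of the log growth factor of a rare
mutant at the resident demographic equilibrium, weighted by the resident
frequency of the mutating type (mutations arise at a fixed rate per adult);
the global mutation-rate constant is absorbed into the rescaled time `tau`:

* obligate sex: `dm/dtau = (beta_z m − s²)/(m s²)` for each type, with
  `s = mx + my`; saddle at isogamy `(beta_z/4, beta_z/4)`, attractors at the
  extreme anisogamous states `(beta_z, 0)` and `(0, beta_z)`;
* single asexual/partnerless lineage: `dm/dtau = (beta_p − m)/m²`, attractor
  at the optimal independent progeny size `m* = beta_p`;
* mixed regime: the macro component is the obligate-sex kernel weighted by
  `1 − R` (macrogametes are always fully fertilised, so only the mutation
  supply changes); the micro component is `R · d/dm̂ [ln λ̂(m̂)]` with
  `λ̂(m̂) = (1/m̂)(F e^{−beta_z/(m_macro+m̂)} + (1−F) e^{−beta_p/m̂})` and
  `F = (1−R) m_micro/(R m_macro)` the rare-mutant fertilised fraction.

The micro component is implemented as the exact closed-form derivative of
`ln λ̂` (not a transcription of any printed formula) and is cross-checked in
the test suite against central-difference numerical differentiation of
`ln λ̂` over random interior parameter draws (relative tolerance 1e-5 at
step `1e-6·m`), and the macro weight against the identity
`(m_micro E_p − m_macro E_z)/(2 m_micro E_p − s E_z) = 1 − R`.  As
`beta_p → ∞` the mixed field converges to the obligate-sex field times the
even type frequency 1/2; the two fields share zeros and signs, differing
only in the time rescaling.

Obligately asexual mutants invade iff their parthenogenetic growth factor
`(M/m) e^{−beta_p/m}` exceeds the residents' common equilibrium growth
factor `(M/m_macro) e^{−beta_z/s}`, giving

* microgametic background: invasion iff the sex-ratio threshold above
  exceeds `beta_p` — exactly the macrogamete-extinction condition, which is
  why genotypic microgametic asexuality and de facto asexuality occupy the
  same region of state space;
* macrogametic background: invasion iff
  `beta_z m_macro/s > beta_p` while macrogametes still exist (`R < 1`).

At isogamy both conditions reduce to `beta_z/2 > beta_p` plus its converse,
hence neither can hold: isogamous sex doubles zygote size relative to a lone
parthenogen, which protects it even when parthenogens hold an intrinsic
survival advantage.

## Invasion dynamics and the trait-substitution walk

A mutation arises in one resident adult: the ancestor class loses one adult
and a mutant class of count 1 appears, keeping the total at `A`.  (Stacking
the mutant on top of `A` adults would impose a spurious first-generation
dilution of order `2/A` that blocks every invasion with selective advantage
below it; with replacement the deterministic dichotomy is governed by the
sign of the growth-rate difference, deleterious mutants are culled in one
generation, and exactly neutral mutants remain unresolved.)  The map is then
iterated until the mutant or its same-type competitors fall below the
extinction threshold, the opposite mating type is lost (reported as de facto
asexuality), or the generation cap (default 1e5) is reached.

The stochastic walk draws the mutating class proportionally to adult counts,
moves its trait by exactly ±`delta_m` with equal probability (proposals
below the minimum gamete size `m_min = delta_m` are discarded and redrawn;
trait values are snapped to the mutational lattice to prevent floating-point
drift), resolves the invasion, re-equilibrates on fixation, and stops after
`stop_k = 50` consecutive failed invasions — a pragmatic surrogate for "a
state the population cannot leave".  Optionally each proposal is instead a
switch to obligate asexuality with probability `asex_rate_ratio` (default
0.05; such mutations are biologically rarer than size mutations, and the
precise ratio only sets how long one waits for an asexual attempt, not
whether it can succeed); after an asexual takeover the walk keeps evolving
progeny size until the lineage reaches `m* = beta_p`.

### Where discrete walks end

Because the microgamete trait is pinned at `m_min > 0`, the macro trait's
invasion-fitness maximum sits at the root of
`beta_z·m = (m + m_min)²`, i.e. `beta_z − 2 m_min + O(m_min²)` — for the
stock scenarios (`beta_z = 1`, `m_min = 0.02`) at 0.9596, so walks terminate
at the lattice point 0.96 rather than at the idealised `m_min → 0` fixed
point `beta_z = 1`.  The discrepancy is intrinsic to any finite minimum
gamete size, not a numerical artifact.

The per-generation inner loop is plain-float Python with all survival
factors precomputed per invasion (class sizes are fixed while only counts
change); near-neutral fixations take ~1e5 generations and a full walk a few
hundred thousand, which runs in about a second.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| `beta_z` | zygote survival scale | scenario | mass |
| `beta_p` | parthenosporophyte survival scale; `inf` = obligate sex | scenario | mass |
| `phi` | fertilisation effort (rate × window); `inf` = gamete competition | `inf` | — |
| `M` | adult mass budget | 1 | mass |
| `A` | adult population size | 1000 | count |
| `delta_m` | mutational step | 0.02 | mass |
| `m_min` | minimum viable gamete size | `delta_m` | mass |
| `extinction_threshold` | culling threshold | 1 adult | count |
| `max_generations` | cap per invasion/equilibration | 1e5 | — |

The stock scenarios fix `beta_z = 1`, `delta_m = 0.02`, `phi = 100` and
`beta_p = 1.3` (parthenogenetic disadvantage) or `beta_p = 0.7` (advantage),
with initial conditions (2,2), (1,1) and (1.5,0.2).  `A = 1000` and `M = 1`
are this package's choices: the `phi → ∞` analytics are independent of both,
and `A` only enters through the extinction threshold (larger `A` delays
culling logarithmically without moving any boundary).  Scripted analyses use
`phi = ∞` where the analytic layer applies; at the stock scenarios' gamete
sizes `phi = 100` already fertilises every macrogamete, so the two settings
coincide there.

## Finite-`phi` normalisation

For finite windows the kinetics integrate `dn_x/dt = dn_y/dt = −n_x n_y`
over dimensionless time `phi` in closed form (evaluated from the exhausted
minority side for numerical stability).  Densities are gametes per unit
total population mass (`frequency/m`), which makes finite-`phi` outcomes
independent of `A` and `M`.  This normalisation is the package's declared
convention: any other choice rescales `phi` and therefore shifts
quantitative finite-`phi` results (e.g. where a mixed-regime isogamous
attractor sits), while every `phi = ∞` result is unaffected.  For this
reason the finite-`phi` layer is treated as qualitative and no analytic
layer is built for the gamete-limitation (short-window) regime.

## What the simulations do and do not show

The generator of study conditions is the model itself — there is no external
data.  Passing tests demonstrate internal consistency (simulated map ≡
closed forms to 1e-8 over randomised sweeps; invasion verdicts ≡ analytic
conditions and gradient signs away from their zeros) and reproduction of the
model's qualitative biology: disruptive selection on gamete size, de facto
asexuality through sex-ratio skew, mating-type-dependent fates of asexual
mutations, and isogamy stabilised by facultative parthenogenesis.  They say
nothing about real algal populations beyond the model's idealisations: no
gamete mortality during the window, no size-dependent encounter rates, no
within-class trait variance, no demographic stochasticity, exactly two
mating types, and parthenogenesis propensity independent of strain identity.

## Numerical choices

* Survival functions evaluate the exponent first; exponents below about
  −745 underflow silently to exactly 0 (survivals of order 1e-29 are a
  genuine model regime, not an error).
* Equilibration stops when class-frequency changes fall below 1e-12
  (1e-13/1e-14 where an oracle comparison needs it); period-2 oscillations
  are detected and reported as non-convergent rather than iterated out.
* Regulation rescales before culling; culling re-normalises the survivors.
  The ordering is a documented choice — the alternative order differs only
  within one threshold-width of the culling boundary.
* Fixed points: multi-start `scipy.optimize.root` on a lattice plus an
  explicit scan of the isogamous diagonal (symmetric roots sit exactly on
  it) and of the trait floor (boundary attractors, tagged `BOUNDARY`);
  stability from eigenvalues of a central-difference Jacobian (`h = 1e-6`),
  with |Re| < 1e-8 reported as marginal.  Across the diagonal the mixed
  field's normal derivative has a symmetry kink; the central difference
  yields the symmetrised Jacobian, which classifies the isogamous point
  consistently with the flow on either side.
* Gradient-flow streamlines use `solve_ivp` with terminal events at the
  trait floor and at the macrogamete-extinction boundary, switching to the
  single-type flow toward `m* = beta_p` after extinction; trial steps are
  evaluated on a clamped, continuously extended field so overshoot past an
  event cannot raise.

## Known limitations

* Exact analytic-boundary cases (neutral coexistence) are classified
  `UNRESOLVED`, never forced; sweep tests exclude a ±1–2% band around each
  boundary, where deterministic sorting times diverge.
* The sign-agreement between small-step invasions and the gradient field is
  asserted only where the gradient magnitude exceeds 0.2: closer to a zero
  the fixation time exceeds the generation cap (it scales as the inverse
  selective advantage).
* Basins of attraction of the mixed regime are explored only by integration
  and simulation; no analytic basin boundaries are attempted.
* Back-mutation from asexuality, novel mating types, per-gamete mutation
  rates and gamete mortality in the pool are out of scope.
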