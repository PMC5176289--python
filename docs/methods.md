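# Methods

## Decision model

Two states, two behaviors; behavior `b` is optimal in state `b`. A learner
in state `z` receives a private signal `s`, observes `i` of `N`
demonstrators exhibiting behavior 1 (demonstrator state `y`, per-
demonstrator accuracy `q`), and a similarity signal `a` that reports whether
`z = y`, correctly with probability `φ`. Discordance (`z ≠ y`) has
probability `γ`.

**Private-signal family.** `s | z ~ Normal(2z − 1, σ²)`. This makes
individual-learning reliability `α = P(sign(s) matches state) = Φ(1/σ)` and
turns the optimal decision rule into a threshold on `s`. The Gaussian
two-mean family is a reconstruction: the signal distribution is not pinned
down by the published account of the model, and any single-crossing family
would serve; the Gaussian is the canonical choice.

**Inference.** The learner evaluates the posterior `P(y, z | a, i, s)` with
her heritable representations `(q̂, γ̂, φ̂, σ̂)` in place of `(q, γ, φ, σ)`,
a flat prior on her own state (states are exchangeable ex ante, independent
of the realized demonstrator frequency), and a flat prior on `y`. The social
evidence enters through `social_log_odds`, computed on the log scale
(`logaddexp`) so unanimous counts at extreme `q̂` stay finite; probabilities
are clipped to `[1e−12, 1 − 1e−12]` before logs. The choice rule is
`choose 1 ⟺ 2s/σ̂² + L(a, i) > 0`, exact ties broken by a fair coin from the
injected generator.

**Identifiability (fitness ridge).** Behavior depends on the private weight
`2/σ̂²` and the social evidence scale set by `q̂` only through their ratio,
so one degree of freedom is redundant. The package pins `σ̂ = σ` (the
learner represents her own signal noise accurately) and lets `q̂` carry the
evolvable social-weight trait. Only the combination is identified; evolved
`q̂` values should be read as social weights, not beliefs about demonstrator
accuracy in isolation.

**Learning functions.** `learning_function(world, rep, a)` reports
`P(choose own optimum)` against the count of demonstrators exhibiting that
optimum, averaging the two state labelings; by the antisymmetry
`L(a, N−i) = −L(a, i)` the two labelings agree exactly, so the curve is
symmetric under relabeling by construction. `choice_probability` is closed
form (a Normal survival function); no simulation.

**Asymmetry index.** Facultative adjustments are quantified in posterior-
belief space, the space in which the asymmetry argument lives. With
`b_a = P(z = y | a)` under `(γ̂, φ̂)`,

```
asymmetry = (b_same + b_diff − 1) · (b_same − b_diff).
```

The first factor is the excess of the concordant signal's upward belief
shift over the discordant signal's downward shift; the second scales by the
size of the facultative response so that a learner who ignores the signal
(`φ̂ = 0.5`) scores exactly zero. The index vanishes at `γ̂ = 0.5` (no
covariance in optima), at `φ̂ = 0.5`, and as `φ̂ → 1`, and is strictly
positive for a concordance-biased prior with an informative but imperfect
signal. A curve-space definition (differences of mirrored learning
functions) was considered and rejected: with the private channel included
such differences pick up a pure individual-learning residual, and for purely
social strategies they vanish identically regardless of asymmetry, because
own-optimum curves then satisfy `f(k) + f(N−k) = 1`.

## Coevolutionary simulation

Each generation: (1) the cohort state flips from the demonstrators' state
with probability `γ` — a single cohort-level event, because discordance is
defined between whole cohorts and per-learner flips would break the shared
demonstrator pool; (2) each learner independently samples `N = 5`
demonstrators uniformly with replacement from the previous cohort's realized
choices (equivalently a Binomial draw at the pool frequency), receives her
similarity signal (correct w.p. `φ`, independently per learner) and private
signal, and chooses; (3) payoff is `base + bonus · 1[choice optimal]` with
`base = bonus = 1`; (4) the next generation's genotypes are Wright–Fisher
payoff-proportional resamples, each trait mutating with probability 0.01 by
`Normal(0, 0.1)` noise on the unconstrained scale; (5) the cohort's choices
become the next demonstrator pool.

Genotypes live on an unconstrained scale: `q̂ = 0.5 + 0.5·expit(x_q)`,
`γ̂ = expit(x_γ)`, `φ̂ = expit(x_φ)`; founders are `Normal(0, 2)` on that
scale. Defaults are `pop_size = 1000`, `generations = 5000`,
`burn_in = 2000`. These magnitudes are the package's own choices — standard
for individual-based Wright–Fisher simulations of this kind, large enough
that the reference regimes stabilize well before the burn-in ends — and all
are configurable. The run summary reports the learning functions of the
*time-averaged population-mean genotype* (averaged on the unconstrained
scale), evaluated at the mean demonstrator accuracy actually observed after
burn-in; per-individual curves can be recomputed from any genotype via
`Genotype.to_rep` and `learning_function`.

Reference regimes with unreliable individual learning (`σ = 3`,
`α ≈ 0.63`):

- `γ = 0.01, φ = 0.5`: the signal is noise; the evolved strategy ignores it
  (conditional curves coincide) and shows conformist positive influence —
  the majority side of the curve lies above the diagonal.
- `γ = 0.1, φ = 0.9`: majority-following after a concordant signal and a
  positive asymmetry index evolve reliably. These parameters sit exactly on
  the boundary `γ = 1 − φ` where `γφ = (1−γ)(1−φ)`: a discordant signal
  then neutralizes the prior exactly, demonstrator counts carry zero
  information about the learner's state, and ignoring them is weakly
  optimal. Minority-following after a discordant signal is therefore
  selectively *neutral* here — it appears in roughly half of replicate runs
  as drift, not reliably. Strictly inside the regime (`γ > 1 − φ`, e.g.
  `γ = 0.2, φ = 0.9`) strong facultative switching — majority under `same`,
  minority under `different` — evolves in essentially every replicate.

Neutrality (`bonus = 0`) leaves trait means performing an unbiased random
walk; with mutation off a clonal population's traits are exactly constant.
Runs are bit-reproducible under a fixed seed, and learner updates within a
generation are order-free (fully vectorized).

## Synthetic experiment generator

Emulates the two-urn sessions: per group, 5 demonstrators × 20 blocks × 5
trials and 4–11 social learners with one choice per block. The optimal urn
is re-randomized each block; the optimal urn pays with probability 0.75
(one urn holds 3 of 4 winning balls, the other 1 of 4), 100 points per
winning draw, 5 payoff draws per social choice. Within-subjects designs
alternate discordant/concordant with the starting condition counterbalanced
across a session's two groups; between-subjects sessions hold one
all-discordant and one all-concordant group; opaque designs alternate but
hide the block type (with or without a stated 50/50 prior).

Demonstrators are greedy count learners: the two urns' compositions make
each observed draw multiply the posterior odds of the chosen urn being
optimal by 3 or 1/3, so with a uniform prior the Beta-binomial posterior
comparison reduces to a win/loss evidence count; ties are random, and an
exploration rate ε (default 0) is available. This is a stand-in for
pipeline testing — the real participants' decision processes are not
modelled — but it lands in the empirically observed range: a demonstrator
majority finds its optimum in ~94% of blocks at these settings (humans:
90.7%/95.5%), albeit with modal outcome 5/5 where humans had 4/5.
Screen-side and color counterbalancing are randomized per subject/trial as
in the laboratory design but are not surfaced: the analysis operates on urn
identity.

Social learners follow static strategies (majority, minority,
unconditional, random, logistic in the centered demonstrator proportion, or
block-type-facultative logistic) — static because participants received no
within-session feedback. Payoff equivalence under the opaque design (any
strategy nets 250 points per block in expectation) is checked by vectorized
Monte Carlo; a transparent concordant design breaks the equivalence as a
sanity contrast.

What passing tests show — and do not: the generator reproduces the *design*
(counterbalancing, record structure, payoff mechanics) and known strategy
mixes, so pipeline recovery on it validates the statistics, not any claim
about human behavior. Real data add learner heterogeneity, non-static
strategies and demonstrator biases the generator deliberately lacks.

## Statistical pipeline

All regressions are ML logistic fits with a clustered sandwich covariance
(cluster = social learner). The sandwich is assembled from the score and
Hessian with pseudo-inverses, so perfect separation yields flagged, reported
coefficients (with a warning and unstable SEs) rather than a crash or silent
regularization. The small-sample factor `M/(M−1)` (`M` clusters) is applied
by default and switchable, since published tables rarely state their
correction; coefficient estimates are invariant to it. Wald tests of linear
combinations are reported as `F = (w'β̂)²/(w'V̂w)` with `(1, M−1)` degrees
of freedom; the χ² convention is available. The block index is coded 1–20
(affects the intercept only).

Per-learner classification follows the exact-rule-first procedure:
always-minority → Min, always-majority → Maj (over all blocks with a strict
demonstrator majority; with 5 demonstrators ties cannot occur), always-left
or always-right → U, otherwise a no-intercept slope-only logistic MLE
`P(left) = expit(β x)` with a 5% Wald flag. A learner whose choices all
follow (or all oppose) the majority perfectly separates this fit; the
estimate is then capped at ±50 with an infinite SE and a separation flag
(within the classifier such learners are caught by the exact rules first).
Fewer than two distinct demonstrator distributions leave the slope
undefined, reported as such.

Learning curves resample learners (clusters) with replacement, n_boot =
2000 by default; 95% intervals are percentile intervals of the resampled
rates, hence always inside [0, 1]; never-observed demonstrator counts are
omitted.

Raw tables are read through a declarative dialect (delimiter, column map,
value recodes) and strictly validated against the design (5 rows per
demonstrator-block, 1 per learner-block, all blocks present per learner in
within-style sessions, urn/similarity consistency); violations raise errors
naming the row and column. The deposited raw data file itself is not
distributed with the package; its exact column layout must be described as
a dialect when it is available.

## Problem sizes and numerical choices

The test suite runs the coevolutionary reference regimes at full size
(pop 1000 × 5000 generations; a run takes ~2 s vectorized) with 5 fixed
replicate seeds, regime properties asserted in ≥4 of 5. Pipeline-recovery
tests use 4 synthetic sessions (~60 learners, ~1100 choices) — enough for
slope CIs of width ~1 at β = 8. The payoff-equivalence check uses 10⁵
replicate blocks (SE ≈ 0.5 points). Monte-Carlo agreement tests use 3
binomial standard errors; exact identities use 1e−12.

## Known limitations

- Exactly two behaviors and two states; no continuous behavior spaces.
- The evolutionary parameterization (population size, mutation kernel,
  selection scheme, run length) is a reconstruction; conclusions are
  asserted at regime level, not as exact curves.
- The asymmetry index is a belief-space summary; it deliberately does not
  disentangle `γ̂` from `φ̂` beyond the two posterior beliefs, which are the
  behaviorally identified quantities.
- The demonstrator model is a clean count learner; it does not reproduce
  human demonstrators' error structure (e.g. their modal 4-of-5 optimality).
- At the regime boundary `γ = 1 − φ` the discordant-signal response is
  selectively neutral, so "minority-following under a discordant signal"
  should not be expected to evolve reliably there (see the simulation
  section).
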