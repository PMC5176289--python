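"""Gene-culture coevolutionary simulator.

Each generation a cohort of learners inherits cognitive representations
(``q_hat, gamma_hat, phi_hat``), observes the previous cohort's realized
behaviors as demonstrators, and chooses via the similarity-conditioned
Bayesian decision rule in :mod:`similearn.bayes_core`. Payoffs reward
choosing the behavior matching the cohort's current state; the next cohort's
genotypes come from Wright-Fisher payoff-proportional resampling with
per-trait Gaussian mutation on an unconstrained (log-odds) scale. The
distribution of behaviors evolves culturally while the distribution of
representations evolves genetically, and the two are coupled through the
demonstrator pool.

Environment process: the cohort state flips from the demonstrators' state
with probability ``gamma`` as a single cohort-level event, so all learners in
a generation share one true concordance indicator (per-learner flips would
break the shared demonstrator pool). Similarity signals are per-learner,
correct with probability ``phi``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .bayes_core import (
    DIFFERENT,
    SAME,
    CognitiveRep,
    LearningFunction,
    WorldParams,
    asymmetry_index,
    learning_function,
)

__all__ = [
    "Genotype",
    "EvoConfig",
    "EvoState",
    "EvoSummary",
    "init_population",
    "generation_step",
    "run_evolution",
]


def _to_qhat(x: np.ndarray) -> np.ndarray:
    """Map unconstrained trait to q_hat in (0.5, 1)."""
    return 0.5 + 0.5 * expit(x)


def _to_prob(x: np.ndarray) -> np.ndarray:
    """Map unconstrained trait to (0, 1)."""
    return expit(x)


@dataclass(frozen=True)
class Genotype:
    """One learner's heritable traits on the unconstrained (logit) scale.

    ``x_q`` maps to ``q_hat`` in (0.5, 1) via ``0.5 + 0.5*expit``; ``x_gamma``
    and ``x_phi`` map to ``gamma_hat``, ``phi_hat`` in (0, 1) via ``expit``.
    ``sigma_hat`` is pinned to the world's ``sigma`` (normalization: only the
    ratio of private to social weight is identified).
    """

    x_q: float
    x_gamma: float
    x_phi: float

    def to_rep(self, sigma_hat: float) -> CognitiveRep:
        # extreme trait values saturate in float; keep probabilities strictly
        # inside their open intervals
        eps = 1e-12
        return CognitiveRep(
            q_hat=float(np.clip(_to_qhat(np.asarray(self.x_q)), 0.5 + eps, 1 - eps)),
            gamma_hat=float(np.clip(_to_prob(np.asarray(self.x_gamma)), eps, 1 - eps)),
            phi_hat=float(np.clip(_to_prob(np.asarray(self.x_phi)), eps, 1 - eps)),
            sigma_hat=sigma_hat,
        )


@dataclass(frozen=True)
class EvoConfig:
    """Simulation settings.

    Population size, run length and the mutation kernel are reconstructions
    (exposed here rather than fixed) chosen at standard magnitudes for
    individual-based Wright-Fisher simulations.
    """

    world: WorldParams
    pop_size: int = 1000
    generations: int = 5000
    burn_in: int = 2000
    mutation_prob: float = 0.01
    mutation_sd: float = 0.1
    payoff_base: float = 1.0
    payoff_bonus: float = 1.0
    init_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.generations:
            raise ValueError("burn_in must be smaller than generations")
        if self.pop_size < self.world.n_demo:
            raise ValueError("pop_size must be at least n_demo")
        if self.mutation_sd <= 0:
            raise ValueError("mutation_sd must be positive")
        if self.payoff_base <= 0:
            raise ValueError("payoff_base must be positive (all-zero payoffs)")


@dataclass
class EvoState:
    """Mutable per-generation state of the coevolutionary system."""

    generation: int
    z: int                       # cohort (learner) state this generation
    y: int                       # demonstrators' state (= previous cohort's z)
    demo_behaviors: np.ndarray   # previous cohort's realized choices, shape (pop,)
    traits: np.ndarray           # unconstrained genotypes, shape (pop, 3)
    behavior_freq: float = 0.5   # frequency of behavior 1 in demo pool
    demo_accuracy: float = 0.5   # fraction of demo pool matching its own state y

    def mean_genotype(self) -> Genotype:
        m = self.traits.mean(axis=0)
        return Genotype(x_q=float(m[0]), x_gamma=float(m[1]), x_phi=float(m[2]))


@dataclass(frozen=True)
class EvoSummary:
    """Post-burn-in summary of a run."""

    mean_genotype: Genotype
    mean_rep: CognitiveRep
    mean_demo_accuracy: float
    lf_same: LearningFunction
    lf_diff: LearningFunction
    asymmetry: float
    config: EvoConfig
    trajectory: "np.ndarray | None" = None  # per-generation summary rows


def init_population(config: EvoConfig, rng: np.random.Generator | None = None) -> EvoState:
    """Draw founder genotypes from wide Normal(0, init_sd) distributions on the
    transformed scale, random initial behaviors and a random initial state."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    traits = rng.normal(0.0, config.init_sd, size=(config.pop_size, 3))
    behaviors = rng.integers(2, size=config.pop_size)
    y = int(rng.integers(2))
    state = EvoState(
        generation=0,
        z=y,
        y=y,
        demo_behaviors=behaviors,
        traits=traits,
        behavior_freq=float(behaviors.mean()),
        demo_accuracy=float((behaviors == y).mean()),
    )
    return state


def _social_log_odds_vec(
    a_same: np.ndarray, i: np.ndarray, n: int, traits: np.ndarray
) -> np.ndarray:
    """Vectorized social log odds for heterogeneous genotypes.

    Same computation as :func:`similearn.bayes_core.social_log_odds`, applied
    row-wise: ``a_same`` boolean per learner, ``i`` counts per learner,
    ``traits`` (pop, 3) on the unconstrained scale.
    """
    q = _to_qhat(traits[:, 0])
    g = _to_prob(traits[:, 1])
    f = _to_prob(traits[:, 2])
    p_signal = np.where(a_same, f, 1.0 - f)
    w_same = np.clip((1.0 - g) * p_signal, 1e-12, None)
    w_diff = np.clip(g * (1.0 - p_signal), 1e-12, None)
    log_ratio = (2 * i - n) * (np.log(q) - np.log1p(-q))
    num = np.logaddexp(np.log(w_same) + log_ratio, np.log(w_diff))
    den = np.logaddexp(np.log(w_diff) + log_ratio, np.log(w_same))
    return num - den


def generation_step(
    state: EvoState, config: EvoConfig, rng: np.random.Generator
) -> EvoState:
    """Advance the coevolutionary system by one generation.

    Order of events: environment flip -> each learner samples demonstrators,
    receives similarity and private signals, chooses -> payoffs -> Wright-
    Fisher resampling with mutation -> this cohort's choices become the next
    demonstrator pool.
    """
    world = config.world
    pop = config.pop_size
    n = world.n_demo

    # (1) cohort state: single cohort-level flip with probability gamma
    z = state.y if rng.random() >= world.gamma else 1 - state.y
    concordant = z == state.y

    # (2) observations; sampling n demonstrators uniformly with replacement
    # from the previous cohort is a Binomial draw at the pool frequency
    freq1 = float(state.demo_behaviors.mean())
    i = rng.binomial(n, freq1, size=pop)
    signal_correct = rng.random(pop) < world.phi
    a_same = np.where(signal_correct, concordant, not concordant)
    s = rng.normal(2 * z - 1, world.sigma, size=pop)

    L = _social_log_odds_vec(a_same, i, n, state.traits)
    total = 2.0 * s / world.sigma**2 + L  # sigma_hat pinned to sigma
    choices = (total > 0).astype(np.int64)
    ties = total == 0
    if ties.any():
        choices[ties] = rng.integers(2, size=int(ties.sum()))

    # (3) payoffs and (4) Wright-Fisher resampling with mutation
    payoffs = config.payoff_base + config.payoff_bonus * (choices == z)
    probs = payoffs / payoffs.sum()
    parents = rng.choice(pop, size=pop, p=probs)
    traits = state.traits[parents].copy()
    mutate = rng.random(size=traits.shape) < config.mutation_prob
    traits[mutate] += rng.normal(0.0, config.mutation_sd, size=int(mutate.sum()))

    # (5) this cohort's choices become the next demonstrator pool
    return EvoState(
        generation=state.generation + 1,
        z=z,
        y=z,  # next generation's demonstrators faced state z
        demo_behaviors=choices,
        traits=traits,
        behavior_freq=float(choices.mean()),
        demo_accuracy=float((choices == z).mean()),
    )


TRAJECTORY_COLUMNS = (
    "generation",
    "mean_q_hat",
    "mean_gamma_hat",
    "mean_phi_hat",
    "behavior_freq",
    "demo_accuracy",
)


def run_evolution(
    config: EvoConfig, keep_trajectory: bool = True
) -> EvoSummary:
    """Run the coevolutionary simulation and summarize the post-burn-in era.

    The reported strategy is the learning function of the time-averaged
    population-mean genotype (averaged on the unconstrained scale), evaluated
    at the mean demonstrator accuracy observed after burn-in. Per-individual
    learning functions can be recovered from the trajectory/config by the
    caller; the mean-genotype summary is the headline object.
    """
    rng = np.random.default_rng(config.seed)
    state = init_population(config, rng)

    rows = np.empty((config.generations, len(TRAJECTORY_COLUMNS)))
    trait_sum = np.zeros(3)
    acc_sum = 0.0
    n_kept = 0
    for t in range(config.generations):
        state = generation_step(state, config, rng)
        m = state.traits.mean(axis=0)
        rows[t] = (
            state.generation,
            float(_to_qhat(m[0])),
            float(_to_prob(m[1])),
            float(_to_prob(m[2])),
            state.behavior_freq,
            state.demo_accuracy,
        )
        if state.generation > config.burn_in:
            trait_sum += m
            acc_sum += state.demo_accuracy
            n_kept += 1

    mean_traits = trait_sum / n_kept
    mean_genotype = Genotype(*map(float, mean_traits))
    mean_rep = mean_genotype.to_rep(sigma_hat=config.world.sigma)
    mean_acc = acc_sum / n_kept
    # observed demonstrator accuracy replaces the nominal q when evaluating
    # the evolved strategy against the world it actually faced
    eval_world = dataclasses.replace(config.world, q=min(max(mean_acc, 0.5), 1.0))
    return EvoSummary(
        mean_genotype=mean_genotype,
        mean_rep=mean_rep,
        mean_demo_accuracy=mean_acc,
        lf_same=learning_function(eval_world, mean_rep, SAME),
        lf_diff=learning_function(eval_world, mean_rep, DIFFERENT),
        asymmetry=asymmetry_index(eval_world, mean_rep),
        config=config,
        trajectory=rows if keep_trajectory else None,
    )
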