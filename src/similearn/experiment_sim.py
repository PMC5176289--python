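"""Synthetic generator for the two-urn social-learning experiments.

Emulates the laboratory design: sessions contain groups of 5 demonstrators
and a handful of social learners. Each of 20 blocks re-randomizes which urn
is optimal; demonstrators learn individually over 5 trials per block by
drawing (with replacement) from their chosen urn, where the optimal urn pays
with probability 0.75 and the other with 0.25, at 100 points per winning
draw. After the demonstrators' fifth trial, each social learner sees the
distribution of fifth-trial urn choices and makes a single choice, paid by 5
independent draws. Social learners get no feedback within the session, so
their strategies are static.

Treatments cross discordant/concordant (social learners rewarded on the
opposite or the same urn as demonstrators) with how the distinction is
administered: within subjects (10+10 alternating blocks, starting condition
counterbalanced across the two groups of a session), between subjects (one
all-discordant and one all-concordant group per session), or opaque (within
subjects but the block type is hidden; with or without a stated 50/50
prior). Social learners follow configurable :class:`StrategySpec` rules —
the generator tests the analysis pipeline, it does not model human
demonstrator biases beyond a count-based individual learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "URNS",
    "TRIAL_COLUMNS",
    "ExperimentConfig",
    "StrategySpec",
    "simulate_demonstrator_block",
    "simulate_session",
    "simulate_experiment",
    "payoff_equivalence_check",
]

URNS = ("L", "R")

#: Canonical tidy schema for one choice record. Demonstrators contribute 5
#: rows per block (one per trial); social learners 1 row per block (trial 5).
TRIAL_COLUMNS = (
    "session",
    "group",
    "similarity",   # discordant | concordant (ground truth, even if opaque)
    "design",       # within | between | opaque_prior | opaque_noprior
    "role",         # demonstrator | social_learner
    "subject",
    "block",
    "trial",
    "urn_chosen",
    "demo_optimal_urn",
    "social_optimal_urn",
    "wins",         # winning draws out of draws made for this record
    "points",
)

WIN_POINTS = 100


@dataclass(frozen=True)
class StrategySpec:
    """A social learner's (static) decision rule.

    kind:
      - ``majority`` / ``minority``: follow the (counter-)majority of the
        demonstrators' fifth-trial choices; 50/50 on a tie.
      - ``unconditional_L`` / ``unconditional_R``: always the same urn.
      - ``random``: fair coin each block.
      - ``logistic``: P(choose L) = expit(beta * x) with x the centered
        proportion of demonstrators choosing L.
      - ``facultative``: logistic with ``beta_same`` in concordant blocks and
        ``beta_diff`` in discordant blocks (meaningful only when the block
        type is shown to the learner, i.e. transparent designs).
    """

    kind: str
    beta: float = 0.0
    beta_same: float = 0.0
    beta_diff: float = 0.0

    KINDS = (
        "majority",
        "minority",
        "unconditional_L",
        "unconditional_R",
        "random",
        "logistic",
        "facultative",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")

    def prob_left(self, n_left: int, n_demo: int, concordant: bool) -> float:
        """Probability of choosing the left urn given the demonstrators'
        fifth-trial distribution and (for facultative rules) the block type."""
        x = n_left / n_demo - 0.5
        if self.kind == "majority":
            return 0.5 if n_left * 2 == n_demo else float(n_left * 2 > n_demo)
        if self.kind == "minority":
            return 0.5 if n_left * 2 == n_demo else float(n_left * 2 < n_demo)
        if self.kind == "unconditional_L":
            return 1.0
        if self.kind == "unconditional_R":
            return 0.0
        if self.kind == "random":
            return 0.5
        if self.kind == "logistic":
            return float(expit(self.beta * x))
        beta = self.beta_same if concordant else self.beta_diff
        return float(expit(beta * x))


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters; defaults mirror the laboratory sessions."""

    design: str = "within"  # within | between | opaque_prior | opaque_noprior
    n_groups: int = 2
    demonstrators_per_group: int = 5
    social_learners_per_group: tuple[int, int] = (4, 11)
    n_blocks: int = 20
    trials_per_block: int = 5
    win_prob_optimal: float = 0.75
    draws_per_social_choice: int = 5
    demonstrator_epsilon: float = 0.0  # exploration rate of the count learner
    social_strategies: Sequence[StrategySpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("within", "between", "opaque_prior", "opaque_noprior"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0.5 < self.win_prob_optimal <= 1.0:
            raise ValueError("win_prob_optimal must be in (0.5, 1]")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")


def _demonstrator_choices_one_block(
    n_demo: int,
    n_trials: int,
    optimal_urn: str,
    win_prob: float,
    epsilon: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one block of individual learning for ``n_demo`` demonstrators.

    Each demonstrator is a greedy count learner: the two urns hold 3-of-4 and
    1-of-4 winning balls, so each observed draw multiplies the posterior odds
    that the chosen urn is optimal by 3 (win) or 1/3 (loss); with a uniform
    prior the log-odds that L is optimal is log(3) * (winsL - lossesL -
    winsR + lossesR). The demonstrator picks the urn with the higher
    posterior probability of being optimal, ties at random, and explores
    uniformly with probability ``epsilon``.

    Returns (choices, wins), each of shape (n_demo, n_trials); choices are 0
    for L, 1 for R.
    """
    choices = np.empty((n_demo, n_trials), dtype=np.int64)
    wins = np.empty((n_demo, n_trials), dtype=np.int64)
    opt = URNS.index(optimal_urn)
    # evidence count: (wins - losses) on L minus (wins - losses) on R
    evidence = np.zeros(n_demo, dtype=np.int64)
    for t in range(n_trials):
        pick = np.where(
            evidence > 0, 0, np.where(evidence < 0, 1, rng.integers(2, size=n_demo))
        )
        if epsilon > 0:
            explore = rng.random(n_demo) < epsilon
            pick = np.where(explore, rng.integers(2, size=n_demo), pick)
        p_win = np.where(pick == opt, win_prob, 1.0 - win_prob)
        won = rng.random(n_demo) < p_win
        evidence += np.where(pick == 0, 1, -1) * np.where(won, 1, -1)
        choices[:, t] = pick
        wins[:, t] = won
    return choices, wins


def simulate_demonstrator_block(
    config: ExperimentConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One group-block of demonstrator records (5 demonstrators x 5 trials),
    with the optimal urn randomized; mainly a testing hook around the count
    learner used inside :func:`simulate_session`."""
    optimal = URNS[rng.integers(2)]
    choices, wins = _demonstrator_choices_one_block(
        config.demonstrators_per_group,
        config.trials_per_block,
        optimal,
        config.win_prob_optimal,
        config.demonstrator_epsilon,
        rng,
    )
    rows = []
    for d in range(config.demonstrators_per_group):
        for t in range(config.trials_per_block):
            rows.append(
                {
                    "session": 1,
                    "group": 1,
                    "similarity": "concordant",
                    "design": config.design,
                    "role": "demonstrator",
                    "subject": f"d{d + 1}",
                    "block": 1,
                    "trial": t + 1,
                    "urn_chosen": URNS[choices[d, t]],
                    "demo_optimal_urn": optimal,
                    "social_optimal_urn": optimal,
                    "wins": int(wins[d, t]),
                    "points": int(wins[d, t]) * WIN_POINTS,
                }
            )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def _block_types(design: str, group_index: int, n_blocks: int, rng: np.random.Generator) -> list[str]:
    """Sequence of block similarity labels for one group.

    Within-subjects (and opaque) designs alternate discordant/concordant with
    the starting condition counterbalanced across the session's two groups;
    between-subjects designs give each group a constant type (group 1
    discordant, group 2 concordant).
    """
    if design == "between":
        label = "discordant" if group_index % 2 == 0 else "concordant"
        return [label] * n_blocks
    start = group_index % 2  # counterbalanced starting condition
    labels = ("discordant", "concordant")
    return [labels[(start + b) % 2] for b in range(n_blocks)]


def simulate_session(
    config: ExperimentConfig,
    rng: np.random.Generator,
    session: int = 1,
) -> pd.DataFrame:
    """Simulate one full session (all groups) into the tidy record table."""
    n_demo = config.demonstrators_per_group
    strategies = config.social_strategies
    rows: list[dict] = []
    for g in range(config.n_groups):
        lo, hi = config.social_learners_per_group
        n_social = int(rng.integers(lo, hi + 1))
        if strategies is None:
            group_strats = [StrategySpec("random")] * n_social
        else:
            group_strats = [strategies[j % len(strategies)] for j in range(n_social)]
        types = _block_types(config.design, g, config.n_blocks, rng)
        for b in range(config.n_blocks):
            demo_opt = URNS[rng.integers(2)]
            concordant = types[b] == "concordant"
            social_opt = demo_opt if concordant else URNS[1 - URNS.index(demo_opt)]
            choices, wins = _demonstrator_choices_one_block(
                n_demo,
                config.trials_per_block,
                demo_opt,
                config.win_prob_optimal,
                config.demonstrator_epsilon,
                rng,
            )
            common = {
                "session": session,
                "group": g + 1,
                "similarity": types[b],
                "design": config.design,
                "block": b + 1,
                "demo_optimal_urn": demo_opt,
                "social_optimal_urn": social_opt,
            }
            for d in range(n_demo):
                for t in range(config.trials_per_block):
                    rows.append(
                        dict(
                            common,
                            role="demonstrator",
                            subject=f"s{session}g{g + 1}d{d + 1}",
                            trial=t + 1,
                            urn_chosen=URNS[choices[d, t]],
                            wins=int(wins[d, t]),
                            points=int(wins[d, t]) * WIN_POINTS,
                        )
                    )
            n_left = int((choices[:, -1] == 0).sum())
            for j, strat in enumerate(group_strats):
                p_left = strat.prob_left(n_left, n_demo, concordant)
                urn = "L" if rng.random() < p_left else "R"
                p_win = (
                    config.win_prob_optimal
                    if urn == social_opt
                    else 1.0 - config.win_prob_optimal
                )
                n_wins = int(rng.binomial(config.draws_per_social_choice, p_win))
                rows.append(
                    dict(
                        common,
                        role="social_learner",
                        subject=f"s{session}g{g + 1}l{j + 1}",
                        trial=config.trials_per_block,
                        urn_chosen=urn,
                        wins=n_wins,
                        points=n_wins * WIN_POINTS,
                    )
                )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def simulate_experiment(
    config: ExperimentConfig, n_sessions: int = 1, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate ``n_sessions`` sessions and concatenate the record tables."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tables = [simulate_session(config, rng, session=s + 1) for s in range(n_sessions)]
    return pd.concat(tables, ignore_index=True)


def payoff_equivalence_check(
    config: ExperimentConfig,
    n_reps: int,
    rng: np.random.Generator,
    strategies: Sequence[StrategySpec] | None = None,
    force_concordant: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo mean social-learner payoff per block for each strategy.

    Under the opaque design with a 50/50 discordant/concordant prior and
    uniform urn assignment, every social learning strategy has the same
    expected payoff (5 draws x 100 points x 1/2 = 250 per block): whatever
    urn a strategy picks, the social optimum is equally likely to be either
    urn. ``force_concordant=True`` breaks the symmetry (as in a transparent
    concordant design), where majority-following beats minority-following.

    Returns a DataFrame with one row per strategy: mean points per block and
    the Monte-Carlo standard error of that mean.
    """
    if strategies is None:
        strategies = [
            StrategySpec("majority"),
            StrategySpec("minority"),
            StrategySpec("random"),
            StrategySpec("unconditional_L"),
            StrategySpec("unconditional_R"),
        ]
    n_demo = config.demonstrators_per_group
    # all replicate blocks simulated at once: rows are (rep, demonstrator)
    demo_opt_left = rng.integers(2, size=n_reps)  # 1 if L is demo-optimal
    concordant = (
        np.ones(n_reps, dtype=bool)
        if force_concordant
        else rng.integers(2, size=n_reps).astype(bool)
    )
    flat_choices, _ = _demonstrator_choices_one_block(
        n_reps * n_demo,
        config.trials_per_block,
        "L",
        config.win_prob_optimal,
        config.demonstrator_epsilon,
        rng,
    )
    final = flat_choices[:, -1].reshape(n_reps, n_demo)  # 0 = optimal urn
    # demonstrators were simulated with L optimal; flip labels where R is
    chose_left = np.where(demo_opt_left[:, None] == 1, final == 0, final == 1)
    n_left = chose_left.sum(axis=1)
    social_opt_left = np.where(concordant, demo_opt_left, 1 - demo_opt_left)

    u = rng.random(n_reps)  # common random numbers across strategies
    draws = rng.random((n_reps, config.draws_per_social_choice))
    payoffs = np.zeros((len(strategies), n_reps))
    for k, strat in enumerate(strategies):
        lookup = np.array(
            [
                [strat.prob_left(i, n_demo, bool(c)) for c in (0, 1)]
                for i in range(n_demo + 1)
            ]
        )
        p_left = lookup[n_left, concordant.astype(int)]
        left = u < p_left
        optimal = left == (social_opt_left == 1)
        p_win = np.where(optimal, config.win_prob_optimal, 1.0 - config.win_prob_optimal)
        payoffs[k] = (draws < p_win[:, None]).sum(axis=1) * WIN_POINTS
    mean = payoffs.mean(axis=1)
    se = payoffs.std(axis=1, ddof=1) / np.sqrt(n_reps)
    return pd.DataFrame(
        {
            "strategy": [s.kind for s in strategies],
            "mean_points_per_block": mean,
            "se": se,
        }
    )
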