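"""Similarity-conditioned Bayesian social learning: posteriors, decision rule,
learning functions.

A learner must choose between two behaviors, 0 and 1; behavior ``b`` is optimal
in state ``b``. Before choosing she observes

* a private signal ``s`` about her own state ``z`` (modelled here as
  ``s | z ~ Normal(2z - 1, sigma^2)``, so reliability ``alpha = Phi(1/sigma)``),
* the count ``i`` of behavior-1 choices in a sample of ``n_demo`` demonstrators
  whose state was ``y`` (each demonstrator exhibits its own optimum with
  probability ``q``), and
* a binary similarity signal ``a`` indicating whether ``z == y``; the signal is
  correct with probability ``phi``.

Learner and demonstrator states differ (``z != y``) with probability ``gamma``.
The learner does not know the true task parameters; her decision rule plugs in
heritable *cognitive representations* ``q_hat, gamma_hat, phi_hat`` (and
``sigma_hat`` for the private channel) into the Bayesian posterior
``P(y, z | a, i, s)`` and chooses the behavior with the higher posterior
probability of being optimal.

Only the combination of the private-signal weight ``2/sigma_hat^2`` and the
social log-likelihood scale set by ``q_hat`` is payoff-relevant (a fitness
ridge); by convention ``sigma_hat`` is pinned to the true ``sigma`` and
``q_hat`` carries the evolvable social-weight degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SAME",
    "DIFFERENT",
    "WorldParams",
    "CognitiveRep",
    "Observation",
    "LearningFunction",
    "demo_count_likelihood",
    "similarity_posterior",
    "social_log_odds",
    "choose",
    "choice_probability",
    "learning_function",
    "asymmetry_index",
]

# Similarity-signal values. SAME = "the signal says learner and demonstrators
# share an optimum" (concordant); DIFFERENT = discordant.
SAME: Literal["same"] = "same"
DIFFERENT: Literal["different"] = "different"

#: Probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before logs so that
#: boundary representations produce large finite log odds instead of inf/nan.
PROB_CLIP = 1e-12


def _clip(p: float | np.ndarray) -> float | np.ndarray:
    return np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)


@dataclass(frozen=True)
class WorldParams:
    """True task structure (not visible to the learner).

    Parameters
    ----------
    gamma : float
        Probability that learner and demonstrator states differ, in [0, 1].
    phi : float
        Probability that the similarity signal is correct, in [0.5, 1].
    n_demo : int
        Number of demonstrators each learner samples.
    sigma : float
        Standard deviation of the private signal around its mean ``2z - 1``.
    q : float
        Per-demonstrator probability of exhibiting the demonstrator-optimal
        behavior, in [0.5, 1].
    """

    gamma: float
    phi: float
    n_demo: int = 5
    sigma: float = 1.0
    q: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.5 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0.5, 1], got {self.phi}")
        if self.n_demo < 1:
            raise ValueError(f"n_demo must be positive, got {self.n_demo}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.5 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0.5, 1], got {self.q}")

    @property
    def alpha(self) -> float:
        """Reliability of individual learning: P(sign(s) matches state)."""
        return float(stats.norm.cdf(1.0 / self.sigma))


@dataclass(frozen=True)
class CognitiveRep:
    """Heritable cognitive representations used by the decision rule.

    ``q_hat`` in (0.5, 1), ``gamma_hat`` and ``phi_hat`` in (0, 1),
    ``sigma_hat`` > 0. These are the learner's possibly inaccurate stand-ins
    for the true ``q``, ``gamma``, ``phi`` and ``sigma``.
    """

    q_hat: float
    gamma_hat: float
    phi_hat: float
    sigma_hat: float = 1.0

    def __post_init__(self) -> None:
        if not 0.5 < self.q_hat < 1.0:
            raise ValueError(f"q_hat must be in (0.5, 1), got {self.q_hat}")
        if not 0.0 < self.gamma_hat < 1.0:
            raise ValueError(f"gamma_hat must be in (0, 1), got {self.gamma_hat}")
        if not 0.0 < self.phi_hat < 1.0:
            raise ValueError(f"phi_hat must be in (0, 1), got {self.phi_hat}")
        if self.sigma_hat <= 0:
            raise ValueError(f"sigma_hat must be positive, got {self.sigma_hat}")


@dataclass(frozen=True)
class Observation:
    """One learner's inputs: private signal ``s``, behavior-1 demonstrator
    count ``i`` out of ``n_demo``, and similarity signal ``a``."""

    s: float
    i: int
    n_demo: int
    a: str

    def __post_init__(self) -> None:
        if not 0 <= self.i <= self.n_demo:
            raise ValueError(f"i must be in [0, {self.n_demo}], got {self.i}")
        if self.a not in (SAME, DIFFERENT):
            raise ValueError(f"a must be 'same' or 'different', got {self.a!r}")


@dataclass(frozen=True)
class LearningFunction:
    """P(learner chooses her own optimum) indexed by the demonstrator count of
    that same behavior, for one similarity-signal condition."""

    condition: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        counts = [k for k, _ in self.points]
        if counts != list(range(len(counts))):
            raise ValueError("points must cover counts 0..n_demo in order")
        for _, p in self.points:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def probs(self) -> np.ndarray:
        return np.array([p for _, p in self.points])

    def __getitem__(self, k: int) -> float:
        return self.points[k][1]


def demo_count_likelihood(i: int, n_demo: int, q: float, y: int) -> float:
    """Binomial probability of observing ``i`` demonstrators exhibiting
    behavior 1 when the demonstrator state is ``y``.

    Each demonstrator independently exhibits behavior 1 with probability ``q``
    if ``y == 1`` and ``1 - q`` if ``y == 0``.
    """
    if not 0 <= i <= n_demo:
        raise ValueError(f"i must be in [0, {n_demo}], got {i}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if y not in (0, 1):
        raise ValueError(f"y must be 0 or 1, got {y}")
    p = q if y == 1 else 1.0 - q
    return float(stats.binom.pmf(i, n_demo, p))


def similarity_posterior(gamma: float, phi: float, a: str) -> float:
    """Posterior probability that learner and demonstrator states coincide
    (``z == y``) after observing the similarity signal ``a``.

    With prior P(same) = 1 - gamma and signal reliability phi:

    * ``a = same``:      (1-g) phi     / ((1-g) phi     + g (1-phi))
    * ``a = different``: (1-g) (1-phi) / ((1-g) (1-phi) + g phi)

    A biased prior (gamma < 0.5) makes the two posteriors asymmetric: a
    concordant signal reinforces the prior while a discordant signal must
    first offset it.
    """
    if a not in (SAME, DIFFERENT):
        raise ValueError(f"a must be 'same' or 'different', got {a!r}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    p_signal = phi if a == SAME else 1.0 - phi
    num = (1.0 - gamma) * p_signal
    den = num + gamma * (1.0 - p_signal)
    if den == 0.0:
        raise ValueError(
            f"degenerate posterior: gamma={gamma}, phi={phi}, a={a!r} "
            "gives a zero-probability signal"
        )
    return num / den


def social_log_odds(a: str, i: int, n_demo: int, rep: CognitiveRep) -> float:
    """Log posterior odds log[P(z=1 | a, i) / P(z=0 | a, i)] carried by the
    social information, under the learner's representations and a flat prior
    on her own state.

    Marginalizes the demonstrator state ``y`` using the similarity-signal
    weights: with ``B1 = q_hat^i (1-q_hat)^(n-i)`` and ``B0`` its mirror,

    ``a = same``:      log[((1-g)f B1 + g(1-f) B0) / (g(1-f) B1 + (1-g)f B0)]

    with ``g = gamma_hat``, ``f = phi_hat``; ``a = different`` swaps
    ``f <-> 1-f``. Antisymmetric in ``i``: L(a, n-i) = -L(a, i).
    """
    if not 0 <= i <= n_demo:
        raise ValueError(f"i must be in [0, {n_demo}], got {i}")
    g, f, q = rep.gamma_hat, rep.phi_hat, rep.q_hat
    p_signal = f if a == SAME else (1.0 - f) if a == DIFFERENT else None
    if p_signal is None:
        raise ValueError(f"a must be 'same' or 'different', got {a!r}")
    # weight on (z == y) vs (z != y) after the similarity signal, unnormalized
    w_same = _clip((1.0 - g) * p_signal)
    w_diff = _clip(g * (1.0 - p_signal))
    # work with the binomial likelihood ratio to keep the computation stable:
    # B1/B0 = (q/(1-q))^(2i - n)
    log_ratio = (2 * i - n_demo) * (np.log(q) - np.log1p(-q))
    # L = log[(w_same * B1/B0 + w_diff) / (w_diff * B1/B0 + w_same)]
    num = np.logaddexp(np.log(w_same) + log_ratio, np.log(w_diff))
    den = np.logaddexp(np.log(w_diff) + log_ratio, np.log(w_same))
    return float(num - den)


def choose(obs: Observation, rep: CognitiveRep, rng: np.random.Generator) -> int:
    """Choose a behavior by thresholding the combined posterior log odds.

    Returns 1 iff ``2 s / sigma_hat^2 + social_log_odds(a, i) > 0``; an exact
    tie is broken by a fair coin from ``rng``.
    """
    total = 2.0 * obs.s / rep.sigma_hat**2 + social_log_odds(
        obs.a, obs.i, obs.n_demo, rep
    )
    if total > 0:
        return 1
    if total < 0:
        return 0
    return int(rng.integers(2))


def choice_probability(
    z: int, a: str, i: int, world: WorldParams, rep: CognitiveRep
) -> float:
    """Probability the learner chooses behavior 1 given her true state ``z``,
    the similarity signal and the demonstrator count, in closed form.

    The decision rule chooses 1 when ``s > -(sigma_hat^2 / 2) L`` with
    ``L = social_log_odds(a, i)``; under ``s ~ Normal(2z - 1, sigma^2)`` this
    is one minus a Normal CDF (the tie has probability zero).
    """
    if z not in (0, 1):
        raise ValueError(f"z must be 0 or 1, got {z}")
    L = social_log_odds(a, i, world.n_demo, rep)
    threshold = -(rep.sigma_hat**2 / 2.0) * L
    return float(stats.norm.sf(threshold, loc=2 * z - 1, scale=world.sigma))


def learning_function(
    world: WorldParams, rep: CognitiveRep, a: str
) -> LearningFunction:
    """Probability the learner chooses her own optimum as a function of how
    many of the ``n_demo`` demonstrators exhibit that same behavior.

    Averages the two state labelings, making the curve exactly symmetric
    under relabeling of the behaviors: at count ``k``,

    * if her optimum is behavior 1 (z = 1), ``i = k`` demonstrators exhibit it;
    * if her optimum is behavior 0 (z = 0), ``i = n - k`` exhibit behavior 1.
    """
    n = world.n_demo
    pts = []
    for k in range(n + 1):
        p1 = choice_probability(1, a, k, world, rep)
        p0 = 1.0 - choice_probability(0, a, n - k, world, rep)
        pts.append((k, 0.5 * (p1 + p0)))
    return LearningFunction(condition=a, points=tuple(pts))


def asymmetry_index(world: WorldParams | None, rep: CognitiveRep) -> float:
    """Asymmetry of the facultative adjustments implied by ``rep``.

    Let ``b_same`` and ``b_diff`` be the learner's posterior beliefs that she
    shares an optimum with demonstrators after a concordant and a discordant
    similarity signal respectively (``similarity_posterior`` with her
    ``gamma_hat, phi_hat``). The concordant signal moves her belief above 1/2
    by ``b_same - 1/2``; the discordant signal moves it below 1/2 by
    ``1/2 - b_diff``. The index is the excess of the first shift over the
    second, scaled by the size of the facultative response:

        (b_same + b_diff - 1) * (b_same - b_diff)

    It is zero when the signal is ignored (``phi_hat = 0.5``, non-facultative,
    second factor), when optima do not covary (``gamma_hat = 0.5``, first
    factor), and in the perfectly-reliable-signal limit ``phi_hat -> 1``; it
    is strictly positive for a biased prior ``gamma_hat < 0.5`` with an
    informative but imperfect signal, where the concordant signal reinforces
    the prior while the discordant signal must first offset it.

    ``world`` is accepted for interface symmetry with ``learning_function``
    but the index depends only on ``rep``.
    """
    b_same = similarity_posterior(rep.gamma_hat, rep.phi_hat, SAME)
    b_diff = similarity_posterior(rep.gamma_hat, rep.phi_hat, DIFFERENT)
    return float((b_same + b_diff - 1.0) * (b_same - b_diff))
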