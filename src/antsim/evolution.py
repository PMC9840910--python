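"""Lifecycle and genetics: hunger, death, parthenogenesis, mutation.

The energy budget is a single scalar, satiety.  It starts at 8, is capped
at 15, drops by one unit every hunger period, and rises by one unit per
food particle eaten.  An organism dies when satiety reaches zero.  When
satiety reaches the birth threshold (0.7 of the maximum, i.e. 10.5 under
defaults) the organism reproduces by parthenogenesis: half of its satiety
stays with it and half passes to the descendant, which inherits a mutated
copy of the parent's genome.

Mutation perturbs every weight-matrix and bias-vector element
independently: a mutation probability epsilon is drawn once per
reproduction uniformly in [a, b]; each element then changes by +delta or
-delta with probability epsilon, where delta is drawn uniformly in [c, d]
per mutated element and the sign is a fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .brain import Genome

__all__ = [
    "MutationParams",
    "BirthEvent",
    "mutate",
    "metabolism_tick",
    "split_satiety",
]


@dataclass(frozen=True)
class MutationParams:
    """Bounds of the mutation distributions: epsilon ~ U[a, b], delta ~ U[c, d]."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not 0 <= self.a <= self.b <= 1:
            raise ValueError(f"mutation probability bounds need 0 <= a <= b <= 1, "
                             f"got a={self.a}, b={self.b}")
        if self.c > self.d:
            raise ValueError(f"mutation magnitude bounds need c <= d, "
                             f"got c={self.c}, d={self.d}")

    @classmethod
    def from_config(cls, config) -> "MutationParams":
        return cls(config.mutation_a, config.mutation_b,
                   config.mutation_c, config.mutation_d)


@dataclass(frozen=True)
class BirthEvent:
    """Record of one parthenogenetic birth."""

    parent_id: int
    child_id: int
    tick: int
    parent_satiety_after: float
    child_satiety: float


def mutate(genome: Genome, params: MutationParams,
           rng: np.random.Generator) -> Genome:
    """Return a mutated copy of ``genome``; the parent is left untouched.

    Draw order is fixed (epsilon, then per layer: weight mask, signs,
    magnitudes, then the same for the bias) so results are reproducible
    from the generator state.
    """
    eps = rng.uniform(params.a, params.b)
    new_weights, new_biases = [], []
    for w, b in zip(genome.weights, genome.biases):
        new_weights.append(_perturb(w, eps, params, rng))
        new_biases.append(_perturb(b, eps, params, rng))
    return Genome(genome.layer_sizes, new_weights, new_biases)


def _perturb(arr: np.ndarray, eps: float, params: MutationParams,
             rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(arr.shape) < eps
    signs = rng.integers(0, 2, size=arr.shape) * 2 - 1
    delta = rng.uniform(params.c, params.d, size=arr.shape)
    return arr + mask * signs * delta


def split_satiety(satiety: float) -> tuple[float, float]:
    """Halve the parent's resources at birth: (parent_after, child)."""
    half = satiety / 2.0
    return half, satiety - half   # exact conservation


def metabolism_tick(organism, config, elapsed: float) -> bool:
    """Advance hunger by ``elapsed`` seconds; return True if the organism died.

    Satiety drops by one unit each time a full hunger period has
    accumulated since the last decrement; death occurs the moment satiety
    reaches zero.  The accumulator tolerates 1 ns of float drift so that a
    period spanning an integer number of ticks fires on the expected tick
    (ten additions of dt = 0.1 fall a few ulp short of 1.0).
    """
    organism.hunger_elapsed += elapsed
    while organism.hunger_elapsed >= config.hunger_period - 1e-9:
        organism.hunger_elapsed = max(
            organism.hunger_elapsed - config.hunger_period, 0.0)
        organism.satiety -= 1.0
        if organism.satiety <= 0.0:
            organism.satiety = max(organism.satiety, 0.0)
            return True
    return False
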