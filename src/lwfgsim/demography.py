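"""Single-year update rule and trajectory simulation for a staging-ground
goose population.

The model tracks the number of Lesser White-fronted Geese observed at a
migratory staging area once per year.  A year consists of four processes:

1. **Survival and return** — each of the ``N_t`` individuals present in year
   ``t`` independently survives the rest of the flyway and returns with
   probability ``phi`` (the *return rate*), so the number of returning
   adults is ``Binomial(N_t, phi)``.
2. **Recruitment** — half of the returning adults are assumed female, a
   proportion ``p`` of those females (drawn each year from a normal
   distribution) returns accompanied by offspring, and each successful
   female contributes a ``Poisson`` number of juveniles with mean equal to
   the brood size ``r``.  The number of breeding females is floored to an
   integer.
3. **Offtake** — a fixed number of birds is removed from the combined
   post-return pool (adults plus juveniles, no age bias), clamped at zero.
4. **Density dependence** — whenever the pool exceeds the carrying
   capacity ``K``, every individual dies independently with probability
   ``psi = min(1, (pool - K) / K)``; below ``K`` nobody dies.

Extinction (a count of zero) is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "DemographicParams",
    "YearState",
    "Trajectory",
    "draw_breeding_proportion",
    "survive_and_return",
    "recruit",
    "apply_offtake",
    "density_mortality",
    "step_year",
    "simulate_trajectory",
]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, list, tuple, None]


def as_generator(seed: SeedLike) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, entropy list or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DemographicParams:
    """Parameters of the annual population model.

    Attributes
    ----------
    phi:
        Mean individual return rate: probability that an individual present
        at the staging ground in year t survives the rest of the flyway and
        returns in year t+1.  Plausible range for this population: 0.6-0.84.
    p_mean, p_sd:
        Mean and standard deviation of the yearly breeding proportion p
        (fraction of returning females accompanied by offspring).  p is drawn
        from Normal(p_mean, p_sd) and clamped to [0, 1].
    r:
        Mean brood size (juveniles per successfully breeding female).
    K:
        Carrying capacity (individuals); density mortality engages linearly
        above it.
    N0:
        Initial population size (individuals).
    T:
        Management horizon in years.
    """

    phi: float = 0.84
    p_mean: float = 0.5
    p_sd: float = 0.05
    r: float = 1.26
    K: int = 250_000
    N0: int = 32_000
    T: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if self.p_sd < 0:
            raise ValueError(f"p_sd must be non-negative, got {self.p_sd}")
        if self.r < 0:
            raise ValueError(f"r must be non-negative, got {self.r}")
        if self.K < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        if self.N0 < 0:
            raise ValueError(f"N0 must be non-negative, got {self.N0}")
        if self.T < 0:
            raise ValueError(f"T must be non-negative, got {self.T}")


@dataclass(frozen=True)
class YearState:
    """Intermediate quantities of one simulated year."""

    n_adults: int
    n_juveniles: int
    p_draw: float
    psi: float
    n_end: int


@dataclass(frozen=True)
class Trajectory:
    """Yearly population sizes ``N_0 .. N_T`` for one replicate."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=np.int64))
        if self.sizes.ndim != 1 or self.sizes.size < 1:
            raise ValueError("sizes must be a non-empty 1-d array")
        if (self.sizes < 0).any():
            raise ValueError("population sizes must be non-negative")

    @property
    def extinct(self) -> bool:
        return bool((self.sizes == 0).any())


def draw_breeding_proportion(
    p_mean: float, p_sd: float, rng: SeedLike = None, size=None
):
    """Draw the yearly breeding proportion from Normal(p_mean, p_sd), clamped to [0, 1].

    At the default (0.5, 0.05) a draw outside [0, 1] is a ~1e-23 event, so
    clamping cannot influence results; it only guarantees a valid probability.
    """
    if p_sd < 0:
        raise ValueError(f"p_sd must be non-negative, got {p_sd}")
    rng = as_generator(rng)
    return np.clip(rng.normal(p_mean, p_sd, size=size), 0.0, 1.0)


def survive_and_return(n, phi: float, rng: SeedLike = None):
    """Number of individuals returning next year: Binomial(n, phi).

    Mortality along the flyway is assumed independent across individuals.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    if np.any(np.asarray(n) < 0):
        raise ValueError("n must be non-negative")
    rng = as_generator(rng)
    return rng.binomial(n, phi)


def recruit(n_adults, p, r: float, rng: SeedLike = None):
    """Juveniles recruited by the returning adults: Poisson(r * F).

    F = floor(0.5 * p * n_adults) is the integer number of breeding females
    (50% of returning adults assumed female, a proportion p of them breeding).
    """
    if r < 0:
        raise ValueError(f"r must be non-negative, got {r}")
    if np.any(np.asarray(n_adults) < 0):
        raise ValueError("n_adults must be non-negative")
    rng = as_generator(rng)
    females_breeding = np.floor(0.5 * np.asarray(p) * np.asarray(n_adults))
    return rng.poisson(r * females_breeding)


def apply_offtake(pool, offtake: int):
    """Remove ``offtake`` birds from the pool, never going below zero.

    Harvest happens once all individuals (adults and accompanying juveniles)
    have returned to the staging area; removal is uniform across ages.
    """
    if offtake < 0:
        raise ValueError(f"offtake must be non-negative, got {offtake}")
    return np.maximum(np.asarray(pool) - offtake, 0)


def density_mortality(n_adults, n_juveniles, K: int):
    """Per-individual mortality probability from crowding.

    psi = clamp((n_adults + n_juveniles - K) / K, 0, 1): zero below carrying
    capacity, rising linearly above it, capped at complete mortality.
    """
    if K < 1:
        raise ValueError(f"K must be a positive integer, got {K}")
    total = np.asarray(n_adults) + np.asarray(n_juveniles)
    return np.clip((total - K) / K, 0.0, 1.0)


def step_year(
    n: int,
    params: DemographicParams,
    offtake: int = 0,
    rng: SeedLike = None,
    *,
    p_draw: float | None = None,
    psi_before_offtake: bool = False,
) -> YearState:
    """Advance the population one year and return the intermediate state.

    Order of events: adults return (binomial survival); juveniles are
    recruited from the *pre-harvest* adult count; offtake is removed from
    the combined pool; density thinning Binomial(pool, 1 - psi) follows.
    By default psi is computed on the post-offtake pool (the thinned pool is
    what density acts on); set ``psi_before_offtake=True`` to evaluate it on
    the pre-offtake pool instead — at realistic parameters the two are
    indistinguishable because psi > 0 only near K.

    ``p_draw`` lets the caller pin the breeding proportion (e.g. one draw
    per replicate rather than per year).
    """
    if n < 0:
        raise ValueError("population size must be non-negative")
    rng = as_generator(rng)
    if n == 0:  # extinction is absorbing
        return YearState(0, 0, float(params.p_mean), 0.0, 0)
    n_adults = int(survive_and_return(n, params.phi, rng))
    if p_draw is None:
        p_draw = float(draw_breeding_proportion(params.p_mean, params.p_sd, rng))
    n_juveniles = int(recruit(n_adults, p_draw, params.r, rng))
    pool = int(apply_offtake(n_adults + n_juveniles, offtake))
    psi_pool = n_adults + n_juveniles if psi_before_offtake else pool
    psi = float(density_mortality(psi_pool, 0, params.K))
    n_end = int(rng.binomial(pool, 1.0 - psi))
    return YearState(n_adults, n_juveniles, p_draw, psi, n_end)


def simulate_trajectory(
    params: DemographicParams,
    offtake: int = 0,
    rng: SeedLike = None,
    *,
    p_redraw: str = "per_year",
    psi_before_offtake: bool = False,
) -> Trajectory:
    """Simulate one replicate of the T-year management period.

    ``p_redraw`` controls how often the breeding proportion is sampled:
    ``"per_year"`` (default, interannual breeding variation) or
    ``"per_replicate"`` (a single draw held fixed for the whole trajectory).
    Deterministic given the same seed and parameters.
    """
    if p_redraw not in ("per_year", "per_replicate"):
        raise ValueError(f"p_redraw must be 'per_year' or 'per_replicate', got {p_redraw!r}")
    rng = as_generator(rng)
    sizes = np.empty(params.T + 1, dtype=np.int64)
    sizes[0] = params.N0
    p_fixed = None
    if p_redraw == "per_replicate":
        p_fixed = float(draw_breeding_proportion(params.p_mean, params.p_sd, rng))
    for t in range(params.T):
        state = step_year(
            int(sizes[t]), params, offtake, rng,
            p_draw=p_fixed, psi_before_offtake=psi_before_offtake,
        )
        sizes[t + 1] = state.n_end
    return Trajectory(sizes)
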