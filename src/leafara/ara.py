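"""Artificial Rabbits Algorithm (ARA) for bound-constrained minimization.

ARA is a swarm metaheuristic modelled on rabbit foraging behaviour.  Each
candidate solution ("rabbit") alternates between two moves:

* **detour foraging** (exploration): a rabbit steps toward the position of a
  randomly chosen peer, perturbed along a random subset of dimensions --
  rabbits feed far from their own nest;
* **random hiding** (exploitation): a rabbit steps toward a "burrow", a copy
  of its own position perturbed in one randomly selected dimension.

A time-decaying stochastic *energy factor* ``E`` switches each rabbit between
the two moves: high energy early in the run favours exploration, low energy
later favours exploitation.  Selection is greedy -- a move is kept only if it
does not worsen the objective -- so the best objective value is non-increasing
over iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ARAConfig",
    "StepRandoms",
    "OptimizationTrace",
    "running_length",
    "dimension_selector",
    "detour_foraging_step",
    "energy_factor",
    "random_burrow",
    "random_hiding_step",
    "ara_optimize",
]


@dataclass(frozen=True)
class ARAConfig:
    """Configuration of an ARA run.

    Parameters
    ----------
    population_size : int
        Number of rabbits N (at least 2, so every rabbit has a peer).
    max_iterations : int
        Number of iterations T.
    dimensions : int
        Dimensionality D of the search box.
    lower_bounds, upper_bounds : array-like of shape (D,)
        Box constraints; candidates are clipped to this box.
    seed : int
        Seed for all random draws of the run.
    round_mode : {"printed", "aro_compat"}
        How the ``round(0.5*R1)`` perturbation offset of the detour-foraging
        move is computed.  ``"printed"`` evaluates the formula literally
        (the offset is almost surely 0); ``"aro_compat"`` uses
        ``round(0.5*(0.05 + R1))`` so the offset fires whenever R1 >= 0.95.
    energy_threshold : float
        Energy cutoff: a rabbit explores when its energy factor E exceeds
        this value and exploits otherwise.
    """

    population_size: int
    max_iterations: int
    dimensions: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    seed: int = 0
    round_mode: str = "printed"
    energy_threshold: float = 1.0

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        if lo.shape != (self.dimensions,) or hi.shape != (self.dimensions,):
            raise ValueError(
                f"bounds must have shape ({self.dimensions},); "
                f"got {lo.shape} and {hi.shape}"
            )
        if not np.all(lo < hi):
            raise ValueError("lower_bounds must be < upper_bounds elementwise")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.dimensions < 1:
            raise ValueError("dimensions must be >= 1")
        if self.round_mode not in ("printed", "aro_compat"):
            raise ValueError(f"unknown round_mode {self.round_mode!r}")
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)


@dataclass(frozen=True)
class StepRandoms:
    """Random draws consumed by one rabbit's move in one iteration.

    R1, R2, R4, R5, R6 are uniform on [0, 1]; n1 is a per-dimension standard
    normal vector, n2 a scalar standard normal; g is a random permutation of
    the dimension indices (0-based).
    """

    R1: float
    R2: float
    R4: float
    R5: float
    R6: float
    n1: np.ndarray
    n2: float
    g: np.ndarray

    @classmethod
    def draw(cls, rng: np.random.Generator, dimensions: int) -> "StepRandoms":
        r = rng.uniform(0.0, 1.0, size=5)
        return cls(
            R1=float(r[0]),
            R2=float(r[1]),
            R4=float(r[2]),
            R5=float(r[3]),
            R6=float(r[4]),
            n1=rng.standard_normal(dimensions),
            n2=float(rng.standard_normal()),
            g=rng.permutation(dimensions),
        )


@dataclass
class OptimizationTrace:
    """Per-iteration record of an ARA run."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    n_explore: list[int] = field(default_factory=list)
    n_exploit: list[int] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "iteration": t + 1,
                "best_fitness": self.best_fitness[t],
                "mean_fitness": self.mean_fitness[t],
                "n_explore": self.n_explore[t],
                "n_exploit": self.n_exploit[t],
            }
            for t in range(len(self.best_fitness))
        ]


def running_length(t: int, T: int, R2: float) -> float:
    """Running length L = (e - e^(((t-1)/T)^2)) * sin(2*pi*R2).

    Scales the detour-foraging step; its envelope shrinks from e - 1 at the
    first iteration toward zero as t approaches T, and the sine factor gives
    it a random sign and magnitude.
    """
    if not 1 <= t <= T:
        raise ValueError(f"iteration t={t} outside [1, {T}]")
    return (math.e - math.exp(((t - 1) / T) ** 2)) * math.sin(2.0 * math.pi * R2)


def dimension_selector(D: int, R: float, g: np.ndarray) -> np.ndarray:
    """Binary selector c marking the dimensions a move is applied to.

    The first ``max(1, ceil(R*D))`` entries of the random permutation ``g``
    are switched on, so at least one dimension always moves.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    g = np.asarray(g)
    if sorted(g.tolist()) != list(range(D)):
        raise ValueError("g must be a permutation of 0..D-1")
    k = max(1, math.ceil(R * D))
    c = np.zeros(D, dtype=float)
    c[g[:k]] = 1.0
    return c


def _round_offset(R1: float, round_mode: str) -> float:
    # round-half-away-from-zero, as in the printed formula's convention
    x = 0.5 * R1 if round_mode == "printed" else 0.5 * (0.05 + R1)
    return math.floor(x + 0.5)


def detour_foraging_step(
    X_i: np.ndarray,
    X_j: np.ndarray,
    A: np.ndarray,
    R1: float,
    n1: np.ndarray,
    round_mode: str = "printed",
) -> np.ndarray:
    """Exploration move: candidate = X_j + A*(X_i - X_j + round(0.5*R1))*n1.

    Elementwise; the movement vector ``A = L*c`` zeroes the perturbation on
    unselected dimensions, leaving the candidate at the peer position X_j
    there.  Returned before bounds clipping.
    """
    X_i, X_j, A = np.asarray(X_i, float), np.asarray(X_j, float), np.asarray(A, float)
    n1 = np.broadcast_to(np.asarray(n1, float), X_i.shape)
    if not (X_i.shape == X_j.shape == A.shape):
        raise ValueError("X_i, X_j and A must have matching lengths")
    offset = _round_offset(R1, round_mode)
    return X_j + A * (X_i - X_j + offset) * n1


def energy_factor(t: int, T: int, R4: float) -> float:
    """Energy E = 4*(1 - t/T)*ln(1/R4); decays linearly in t in expectation."""
    if not 1 <= t <= T:
        raise ValueError(f"iteration t={t} outside [1, {T}]")
    if not 0.0 < R4 <= 1.0:
        raise ValueError("R4 must lie in (0, 1]")
    return 4.0 * (1.0 - t / T) * math.log(1.0 / R4)


def random_burrow(
    X_i: np.ndarray, t: int, T: int, n2: float, R6: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Generate a rabbit's burrow: its own position nudged in one dimension.

    H = ((T - t + 1)/T) * n2 is the hiding parameter; the one-hot selector
    g_r picks dimension ceil(R6*D) (clamped to [1, D]); the burrow is
    b = X_i + H * g_r * X_i, i.e. b_k = X_k * (1 + H) at the selected k.
    """
    if not 1 <= t <= T:
        raise ValueError(f"iteration t={t} outside [1, {T}]")
    X_i = np.asarray(X_i, float)
    D = X_i.shape[0]
    H = ((T - t + 1) / T) * n2
    k = min(max(math.ceil(R6 * D), 1), D) - 1  # 0-based
    g_r = np.zeros(D, dtype=float)
    g_r[k] = 1.0
    b = X_i + H * g_r * X_i
    return b, g_r, H


def random_hiding_step(
    X_i: np.ndarray, A: np.ndarray, R5: float, b: np.ndarray
) -> np.ndarray:
    """Exploitation move: candidate = X_i + A*(R5*b - X_i), before clipping."""
    X_i, A, b = np.asarray(X_i, float), np.asarray(A, float), np.asarray(b, float)
    if not (X_i.shape == A.shape == b.shape):
        raise ValueError("X_i, A and b must have matching lengths")
    return X_i + A * (R5 * b - X_i)


def _evaluate(objective, x: np.ndarray) -> float:
    f = float(objective(x))
    if not math.isfinite(f):
        raise ValueError(f"objective returned non-finite value {f} at position {x}")
    return f


def ara_optimize(objective, config: ARAConfig):
    """Run the ARA loop and return ``(best_position, best_fitness, trace)``.

    Per rabbit per iteration: draw the step randoms, compute the energy
    factor E; if E exceeds ``config.energy_threshold`` take a detour-foraging
    step against a uniformly chosen peer j != i, otherwise a random-hiding
    step toward a fresh burrow.  Candidates are clipped to the box and kept
    only if their fitness does not exceed the incumbent's (greedy selection,
    minimization).  Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    N, T, D = config.population_size, config.max_iterations, config.dimensions
    lo, hi = config.lower_bounds, config.upper_bounds

    positions = rng.uniform(lo, hi, size=(N, D))
    fitnesses = np.array([_evaluate(objective, x) for x in positions])
    best_idx = int(np.argmin(fitnesses))
    best_position = positions[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])

    trace = OptimizationTrace()
    for t in range(1, T + 1):
        n_explore = n_exploit = 0
        for i in range(N):
            sr = StepRandoms.draw(rng, D)
            E = energy_factor(t, T, max(sr.R4, np.finfo(float).tiny))
            L = running_length(t, T, sr.R2)
            c = dimension_selector(D, sr.R1, sr.g)
            A = L * c
            if E > config.energy_threshold:
                j = int(rng.integers(N - 1))
                if j >= i:
                    j += 1
                candidate = detour_foraging_step(
                    positions[i], positions[j], A, sr.R1, sr.n1, config.round_mode
                )
                n_explore += 1
            else:
                b, _, _ = random_burrow(positions[i], t, T, sr.n2, sr.R6)
                candidate = random_hiding_step(positions[i], A, sr.R5, b)
                n_exploit += 1
            candidate = np.clip(candidate, lo, hi)
            f_cand = _evaluate(objective, candidate)
            if f_cand <= fitnesses[i]:
                positions[i] = candidate
                fitnesses[i] = f_cand
                if f_cand < best_fitness:
                    best_fitness = f_cand
                    best_position = candidate.copy()
        trace.best_fitness.append(best_fitness)
        trace.mean_fitness.append(float(fitnesses.mean()))
        trace.n_explore.append(n_explore)
        trace.n_exploit.append(n_exploit)

    return best_position, best_fitness, trace
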