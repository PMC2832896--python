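"""Real-coded genetic algorithm with optional local polish.

Minimises a vectorised objective ``f(P) -> (pop,)`` over a box.  Operators:
tournament selection, BLX-alpha blend crossover, per-coordinate Gaussian
mutation scaled to the box width, single-individual elitism, clamp-to-bounds
repair.  Deterministic given a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares, minimize

from .errors import InvalidConfigError

__all__ = ["GASettings", "GAResult", "minimize_ga"]


@dataclass
class GASettings:
    population_size: int = 100
    generations: int = 200
    tournament_size: int = 3
    crossover_prob: float = 0.9
    blend_alpha: float = 0.5
    mutation_rate: float = 0.1
    mutation_sigma_frac: float = 0.05
    elitism: int = 1
    polish: bool = True

    def validate(self) -> "GASettings":
        if self.population_size < 2:
            raise InvalidConfigError("population_size must be >= 2")
        if self.generations < 1:
            raise InvalidConfigError("generations must be >= 1")
        if self.tournament_size < 1:
            raise InvalidConfigError("tournament_size must be >= 1")
        for name in ("crossover_prob", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.mutation_sigma_frac < 0 or self.blend_alpha < 0:
            raise InvalidConfigError("blend_alpha and mutation_sigma_frac must be >= 0")
        if self.elitism < 0:
            raise InvalidConfigError("elitism must be >= 0")
        return self


@dataclass
class GAResult:
    x: np.ndarray
    fun: float
    history: np.ndarray = field(repr=False)  # best-so-far per generation
    n_evaluations: int = 0


def _tournament(fitness: np.ndarray, n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    cand = rng.integers(0, fitness.size, size=(n, size))
    return cand[np.arange(n), np.argmin(fitness[cand], axis=1)]


def minimize_ga(
    objective: Callable[[np.ndarray], np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    settings: GASettings | None = None,
    rng: np.random.Generator | int | None = None,
    residuals: Callable[[np.ndarray], np.ndarray] | None = None,
) -> GAResult:
    """Minimise ``objective`` over the box ``[lower, upper]``.

    ``objective`` must accept a population matrix ``(pop, dim)`` and return a
    fitness vector.  When ``settings.polish`` is set the best individual is
    refined locally before return: with bounded trust-region least squares if
    ``residuals`` provides the residual vector whose sum of squares equals the
    objective (much better conditioned in the sloppy valleys typical of
    kinetic fits), otherwise with bounded L-BFGS-B.
    """
    s = (settings or GASettings()).validate()
    rng = np.random.default_rng(rng)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(upper <= lower):
        raise InvalidConfigError("bounds must satisfy lower < upper elementwise")
    dim = lower.size
    width = upper - lower
    P = s.population_size

    pop = rng.uniform(lower, upper, size=(P, dim))
    fit = np.asarray(objective(pop), dtype=float)
    n_eval = P
    best_i = int(np.argmin(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    history = [best_f]

    sigma = s.mutation_sigma_frac * width
    for _ in range(s.generations):
        parents = pop[_tournament(fit, P, s.tournament_size, rng)]
        children = parents.copy()
        # BLX-alpha on consecutive pairs
        for i in range(0, P - 1, 2):
            if rng.random() < s.crossover_prob:
                a, b = parents[i], parents[i + 1]
                lo = np.minimum(a, b) - s.blend_alpha * np.abs(a - b)
                hi = np.maximum(a, b) + s.blend_alpha * np.abs(a - b)
                children[i] = rng.uniform(lo, hi)
                children[i + 1] = rng.uniform(lo, hi)
        mask = rng.random(size=(P, dim)) < s.mutation_rate
        children = children + mask * rng.normal(0.0, 1.0, size=(P, dim)) * sigma
        np.clip(children, lower, upper, out=children)
        for e in range(min(s.elitism, P)):
            children[e] = best_x
        fit = np.asarray(objective(children), dtype=float)
        n_eval += P
        pop = children
        gi = int(np.argmin(fit))
        if fit[gi] < best_f:
            best_f, best_x = float(fit[gi]), pop[gi].copy()
        history.append(best_f)

    if s.polish:
        if residuals is not None:
            res = least_squares(residuals, best_x, bounds=(lower, upper), method="trf")
            fun = float(2.0 * res.cost)
        else:
            res = minimize(
                lambda v: float(objective(v[None, :])[0]),
                best_x,
                method="L-BFGS-B",
                bounds=list(zip(lower, upper)),
            )
            fun = float(res.fun)
        n_eval += res.nfev * (dim + 1)
        if fun < best_f:
            best_f, best_x = fun, np.clip(res.x, lower, upper)
        history.append(best_f)

    return GAResult(x=best_x, fun=best_f, history=np.asarray(history), n_evaluations=n_eval)
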