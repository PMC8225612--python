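"""Constrained random-walk dispersal with landscape resistance.

Long-range dispersal is a neighbour-to-neighbour walk on the hexagon lattice.
Every cell entered adds ``10 − score`` to the walker's cumulative resistance
(land cells cost 10, open water 0); the walk stops at the first of

* cumulative resistance reaching ``resistance_threshold`` (default 500, i.e.
  50 land cells ≈ 3 km of overland travel at 60 m cells), or
* ``step_cap`` steps (default 1000 cells ≈ 60 km, the literature ceiling for
  yearly muskrat emigration through water).

Step selection prefers wet cells — neighbours scoring in the attraction range
[2, 10] carry ``attraction_multiplier`` (default 5) times the weight of
neighbours in the repulsion range [0, 1]; scores between 1 and 2 interpolate
linearly.  With probability ``autocorrelation`` (default 0.5) a step instead
follows the mean heading of the last ``trend_period`` (default 3) steps,
giving directional persistence.

Flood transport reuses the same walk on a constant score-10 surface (zero
resistance) with the step count drawn from a log-normal kernel whose mode and
median are configured in hexagon units (defaults 10 and 100, i.e. 600 m and
6 km at 60 m cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hexgrid import DIRECTION_VECTORS, HexGrid

MAX_SCORE = 10.0


@dataclass(frozen=True)
class WalkParams:
    resistance_threshold: float = 500.0
    step_cap: int = 1000
    attraction_multiplier: float = 5.0
    attract_low: float = 2.0      # scores in [attract_low, 10] attract
    repel_high: float = 1.0       # scores in [0, repel_high] repel
    autocorrelation: float = 0.5
    trend_period: int = 3

    def __post_init__(self) -> None:
        if self.resistance_threshold <= 0:
            raise ValueError("resistance threshold must be positive")
        if self.step_cap < 1:
            raise ValueError("step cap must be >= 1")
        if not 0.0 <= self.autocorrelation <= 1.0:
            raise ValueError("autocorrelation must be a probability")


@dataclass
class WalkOutcome:
    path: np.ndarray              # flat cell indices, start first
    cumulative_resistance: float
    stopped_by: str               # "threshold" | "step_cap"

    @property
    def terminal(self) -> int:
        return int(self.path[-1])

    @property
    def n_steps(self) -> int:
        return len(self.path) - 1


@dataclass(frozen=True)
class FloodKernel:
    """Log-normal flood-transport distance kernel, in hexagon units."""

    mode: float = 10.0
    median: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.mode < self.median:
            raise ValueError("kernel requires 0 < mode < median")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log(self.median / self.mode))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.lognormal(self.mu, self.sigma, size=size)


def sample_flood_distance(kernel: FloodKernel, rng: np.random.Generator) -> int:
    """One flood-walk length draw, rounded to a whole number of cells (>= 1)."""
    return max(1, int(round(float(kernel.sample(rng)))))


def step_weight(score: float, params: WalkParams) -> float:
    """Relative choice weight of a neighbour with the given cell score."""
    if score <= params.repel_high:
        return 1.0
    if score >= params.attract_low:
        return params.attraction_multiplier
    # linear ramp across the unspecified (repel_high, attract_low) gap
    t = (score - params.repel_high) / (params.attract_low - params.repel_high)
    return 1.0 + t * (params.attraction_multiplier - 1.0)


class DispersalContext:
    """Walk machinery bound to one (grid, surface, params) triple.

    Precomputes per-cell neighbour lists, choice weights and resistances as
    plain Python lists so the inner walk loop avoids array overhead.
    """

    def __init__(self, grid: HexGrid, surface: np.ndarray, params: WalkParams):
        surface = np.asarray(surface, dtype=float)
        if surface.shape != (grid.n_cells,):
            raise ValueError("surface must be a flat per-cell score array")
        self.grid = grid
        self.params = params
        self.surface = surface
        nbrs = grid.neighbors_array()
        weights = np.array([step_weight(s, params) for s in surface])
        resistance = MAX_SCORE - surface
        self._nbrs: list[tuple[int, ...]] = []
        self._slots: list[tuple[int, ...]] = []
        self._wts: list[tuple[float, ...]] = []
        for i in range(grid.n_cells):
            row = nbrs[i]
            ok = row >= 0
            idx = row[ok]
            self._nbrs.append(tuple(int(j) for j in idx))
            self._slots.append(tuple(int(k) for k in np.flatnonzero(ok)))
            self._wts.append(tuple(float(w) for w in weights[idx]))
        self._res = resistance.tolist()
        self._dirs = [tuple(v) for v in DIRECTION_VECTORS]

    # -- single step -----------------------------------------------------

    def step_choice(
        self,
        current: int,
        heading_history: list[tuple[float, float]],
        rng: np.random.Generator,
    ) -> tuple[int, tuple[float, float]] | None:
        """Sample the next cell; returns (cell, step direction) or None if stuck."""
        nbrs = self._nbrs[current]
        if not nbrs:
            return None
        p = self.params
        if heading_history and rng.random() < p.autocorrelation:
            hist = heading_history[-p.trend_period:]
            mx = sum(v[0] for v in hist)
            my = sum(v[1] for v in hist)
            best, best_dot = [], -math.inf
            for j, slot in zip(nbrs, self._slots[current]):
                d = self._dirs[slot]
                dot = d[0] * mx + d[1] * my
                if dot > best_dot + 1e-12:
                    best, best_dot = [(j, d)], dot
                elif dot > best_dot - 1e-12:
                    best.append((j, d))
            pick = best[0] if len(best) == 1 else best[int(rng.integers(len(best)))]
            return pick
        wts = self._wts[current]
        total = sum(wts)
        u = rng.random() * total
        acc = 0.0
        for j, wt, slot in zip(nbrs, wts, self._slots[current]):
            acc += wt
            if u <= acc:
                return j, self._dirs[slot]
        slot = self._slots[current][-1]
        return nbrs[-1], self._dirs[slot]

    # -- whole walk ------------------------------------------------------

    def walk(self, start: int, rng: np.random.Generator,
             step_cap: int | None = None) -> WalkOutcome:
        p = self.params
        cap = p.step_cap if step_cap is None else step_cap
        path = [start]
        cum = 0.0
        headings: list[tuple[float, float]] = []
        stopped = "step_cap"
        for _ in range(cap):
            nxt = self.step_choice(path[-1], headings, rng)
            if nxt is None:
                stopped = "step_cap"
                break
            cell, direction = nxt
            path.append(cell)
            headings.append(direction)
            if len(headings) > p.trend_period:
                headings.pop(0)
            cum += self._res[cell]
            if cum >= p.resistance_threshold:
                stopped = "threshold"
                break
        return WalkOutcome(np.asarray(path, dtype=np.int64), cum, stopped)


def step_choice(grid: HexGrid, current: int, heading_history, surface,
                params: WalkParams, rng: np.random.Generator):
    """One-shot convenience wrapper around :meth:`DispersalContext.step_choice`."""
    return DispersalContext(grid, surface, params).step_choice(current, heading_history, rng)


def constrained_walk(grid: HexGrid, start: int, surface, params: WalkParams,
                     rng: np.random.Generator) -> WalkOutcome:
    """One-shot long-range dispersal walk (builds a fresh context)."""
    return DispersalContext(grid, surface, params).walk(start, rng)


def flood_walk(context: DispersalContext, start: int, kernel: FloodKernel,
               rng: np.random.Generator) -> WalkOutcome:
    """Flood-transport walk: kernel-drawn step count on a zero-resistance surface.

    ``context`` must be built on the constant score-10 flood surface, on which
    the resistance threshold can never trigger.
    """
    length = sample_flood_distance(kernel, rng)
    return context.walk(start, rng, step_cap=length)
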