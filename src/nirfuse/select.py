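"""Wavelength-subset selection: CARS and a binary shuffled frog leaping search.

CARS (competitive adaptive reweighted sampling) runs a fixed number of
Monte-Carlo rounds.  Each round fits a PLSR on a random calibration subset
using the currently retained wavelengths, shrinks the retained set to the
count dictated by an exponentially decreasing schedule (keeping the largest
|coefficient| wavelengths), then resamples that count with replacement with
probability proportional to |coefficient| — duplicates collapse, so the set
may shrink further.  The round's retained set is scored by cross-validated
RMSE and the best-scoring round wins.

SFLA (shuffled frog leaping) is a memetic population search over binary
inclusion masks: frogs are ranked by fitness (CV RMSE plus an optional
per-band penalty), dealt round-robin into memeplexes, and within each
memeplex the worst frog repeatedly leaps toward the memeplex best (each
differing bit copied with probability ½), falling back to the global best and
finally to re-randomisation when a leap does not improve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import cv_rmse, fit_plsr


class SelectError(ValueError):
    """Raised on selector configuration/contract violations."""


@dataclass
class SelectionResult:
    selected: list[int]             # ordered wavelength (column) indices
    fitness_trace: list[float]      # per-iteration CV RMSE
    best_fitness: float
    config_echo: dict
    seed: int

    def wavelengths_nm(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid, float)[self.selected]


@dataclass
class CarsConfig:
    n_runs: int = 50
    cal_fraction: float = 0.8
    cv_folds: int = 5
    final_keep: int = 2
    n_components: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cal_fraction < 1.0:
            raise SelectError("cal_fraction must be in (0, 1)")
        if self.final_keep < 1:
            raise SelectError("final_keep must be >= 1")
        if self.n_runs < 2:
            raise SelectError("n_runs must be >= 2")


@dataclass
class SflaConfig:
    n_frogs: int = 24
    n_memeplexes: int = 4
    n_shuffles: int = 10
    local_steps: int = 5
    cv_folds: int = 5
    n_components: int = 5
    penalty_per_band: float = 0.0
    init_include_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frogs % self.n_memeplexes != 0:
            raise SelectError("n_frogs must be divisible by n_memeplexes")


def edf_ratio(run_index: int, config: CarsConfig, p: int) -> float:
    """Exponentially decreasing retention ratio r_i = a·e^(−k·i).

    The two constants are fixed by the boundary conditions r_1 = 1 (all p
    wavelengths kept at the first run) and r_{n_runs} = final_keep/p.
    """
    if p < config.final_keep:
        raise SelectError(f"p={p} smaller than final_keep={config.final_keep}")
    if not 1 <= run_index <= config.n_runs:
        raise SelectError("run_index out of range")
    N = config.n_runs
    k = math.log(p / config.final_keep) / (N - 1)
    a = math.exp(k)                       # so that a·e^(−k·1) = 1
    return a * math.exp(-k * run_index)


def _max_components(n_train: int, p: int, requested: int) -> int:
    return max(1, min(requested, n_train - 1, p))


def cars(X: np.ndarray, y: np.ndarray, config: CarsConfig | None = None
         ) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the columns of X."""
    config = CarsConfig() if config is None else config
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise SelectError("y is constant")
    if p == 1:
        return SelectionResult([0], [cv_rmse(X, y, 1, min(config.cv_folds, n))],
                               cv_rmse(X, y, 1, min(config.cv_folds, n)),
                               asdict(config), config.seed)
    rng = np.random.default_rng(config.seed)
    n_cal = max(2, int(round(config.cal_fraction * n)))
    retained = np.arange(p)
    trace: list[float] = []
    best_set, best_rmse = retained.copy(), np.inf
    for i in range(1, config.n_runs + 1):
        if retained.size < 1:
            break
        cal = rng.choice(n, size=n_cal, replace=False)
        a = _max_components(n_cal, retained.size, config.n_components)
        m = fit_plsr(X[np.ix_(cal, retained)], y[cal], a)
        w = np.abs(m.coefficients)
        # enforced shrink by the exponential schedule
        keep = max(config.final_keep, int(round(p * edf_ratio(i, config, p))))
        keep = min(keep, retained.size)
        order = np.argsort(-w, kind="stable")
        retained_shrunk = retained[order[:keep]]
        w_shrunk = w[order[:keep]]
        # adaptive reweighted sampling: weighted draw with replacement,
        # duplicates collapse
        if w_shrunk.sum() <= 0:
            picked = retained_shrunk
        else:
            draw = rng.choice(retained_shrunk, size=keep, replace=True,
                              p=w_shrunk / w_shrunk.sum())
            picked = np.unique(draw)
        retained = np.sort(picked)
        a_cv = _max_components(n - math.ceil(n / config.cv_folds),
                               retained.size, config.n_components)
        r = cv_rmse(X[:, retained], y, a_cv, config.cv_folds)
        trace.append(r)
        if r < best_rmse:
            best_rmse, best_set = r, retained.copy()
    return SelectionResult(sorted(int(j) for j in best_set), trace,
                           float(min(trace)), asdict(config), config.seed)


def _mask_fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray,
                  config: SflaConfig) -> float:
    idx = np.nonzero(mask)[0]
    n = X.shape[0]
    a = _max_components(n - math.ceil(n / config.cv_folds), idx.size,
                        config.n_components)
    return (cv_rmse(X[:, idx], y, a, config.cv_folds)
            + config.penalty_per_band * idx.size)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def sfla(X: np.ndarray, y: np.ndarray, config: SflaConfig | None = None,
         initial_masks: np.ndarray | None = None) -> SelectionResult:
    """Binary shuffled-frog-leaping wavelength search.

    ``initial_masks`` optionally seeds the population (rows are inclusion
    masks); remaining frogs are Bernoulli(init_include_prob) random.  The
    trace records the global-best fitness after initialisation and after each
    shuffle round, so it is non-increasing by construction.
    """
    config = SflaConfig() if config is None else config
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise SelectError("y is constant")
    rng = np.random.default_rng(config.seed)

    masks = np.zeros((config.n_frogs, p), dtype=bool)
    k0 = 0
    if initial_masks is not None:
        seeded = np.atleast_2d(np.asarray(initial_masks, bool))
        k0 = min(seeded.shape[0], config.n_frogs)
        masks[:k0] = seeded[:k0]
    masks[k0:] = rng.random((config.n_frogs - k0, p)) < config.init_include_prob
    for f in range(config.n_frogs):
        masks[f] = _repair(masks[f], rng)
    fitness = np.array([_mask_fitness(m, X, y, config) for m in masks])

    b0 = int(np.argmin(fitness))
    best_ever_mask, best_ever_fit = masks[b0].copy(), float(fitness[b0])
    trace = [best_ever_fit]
    per_plex = config.n_frogs // config.n_memeplexes
    for _ in range(config.n_shuffles):
        rank = np.argsort(fitness, kind="stable")
        gbest_mask = masks[rank[0]].copy()
        # round-robin deal by rank into memeplexes
        plexes = [rank[m::config.n_memeplexes][:per_plex]
                  for m in range(config.n_memeplexes)]
        for plex in plexes:
            for _ in range(config.local_steps):
                order = plex[np.argsort(fitness[plex], kind="stable")]
                worst, best = order[-1], order[0]

                def leap(target: np.ndarray) -> tuple[np.ndarray, float]:
                    cand = masks[worst].copy()
                    diff = cand != target
                    flip = diff & (rng.random(p) < 0.5)
                    cand[flip] = target[flip]
                    cand = _repair(cand, rng)
                    return cand, _mask_fitness(cand, X, y, config)

                cand, fit = leap(masks[best])
                if fit >= fitness[worst]:
                    cand, fit = leap(gbest_mask)
                if fit >= fitness[worst]:
                    # censorship: a stuck frog is replaced by a random one
                    cand = _repair(rng.random(p) < config.init_include_prob, rng)
                    fit = _mask_fitness(cand, X, y, config)
                masks[worst], fitness[worst] = cand, fit
                if fit < best_ever_fit:
                    best_ever_mask, best_ever_fit = cand.copy(), fit
        trace.append(best_ever_fit)

    return SelectionResult([int(j) for j in np.nonzero(best_ever_mask)[0]],
                           trace, best_ever_fit, asdict(config), config.seed)
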