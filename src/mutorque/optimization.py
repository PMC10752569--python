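"""Genetic-algorithm optimization of the MUDrive pool parameter bounds.

The cost of a candidate bounds vector is the *training* RMSE of the MUDrive
fit (the regression is refit for every candidate so the cost is
well-defined).  The search runs only over the masked-on parameters; the rest
stay at caller-supplied fixed values.  The midpoint of the constraint box is
always injected into generation 0, so the result can never be worse than the
no-optimization baseline, and the best candidate *ever evaluated* is
returned.  Everything is driven by one numpy Generator, so a fixed seed gives
identical results.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .decoders import CONSTRAINT_BOX, PARAM_NAMES, MudriveFitter, PoolParameterBounds

logger = logging.getLogger("mutorque")


@dataclass
class GAConfig:
    """GA hyperparameters: tournament selection, blend crossover, Gaussian
    mutation (sd = ``mutation_sd_frac`` of each parameter's box range),
    elitism of one, and early stop on a stagnant best cost."""

    population: int = 30
    generations: int = 40
    tournament: int = 3
    crossover_prob: float = 0.7
    blend_alpha: float = 0.5
    mutation_prob: float = 0.25
    mutation_sd_frac: float = 0.10
    elitism: int = 1
    stagnation_generations: int = 10
    stagnation_tol: float = 1e-6


@dataclass
class OptimizationResult:
    best_bounds: PoolParameterBounds
    best_cost: float
    n_generations: int
    elapsed: float
    optimized_mask: dict[str, bool]
    seed: int


def _normalize_mask(mask) -> dict[str, bool]:
    if isinstance(mask, dict):
        unknown = set(mask) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s) in mask: {sorted(unknown)}")
        return {name: bool(mask.get(name, False)) for name in PARAM_NAMES}
    on = set(mask)
    unknown = on - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter(s) in mask: {sorted(unknown)}")
    return {name: name in on for name in PARAM_NAMES}


def ga_optimize(
    fitter: MudriveFitter,
    mask,
    fixed_values: PoolParameterBounds,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    extra_candidates: list[PoolParameterBounds] | None = None,
) -> OptimizationResult:
    """Minimize training RMSE over the masked-on parameters inside the box.

    ``mask`` is a dict (or iterable of names) selecting the searched
    parameters; the rest are pinned at ``fixed_values``.  An all-off mask
    evaluates ``fixed_values`` directly with no search.  Infeasible
    combinations (min >= max after merging) get infinite cost.
    ``extra_candidates`` are injected into generation 0 (projected onto the
    searched parameters), e.g. to warm-start from a previous optimum.
    """
    cfg = ga_config or GAConfig()
    mask = _normalize_mask(mask)
    free = [name for name in PARAM_NAMES if mask[name]]
    t_start = time.perf_counter()

    def make_bounds(vec: np.ndarray) -> PoolParameterBounds:
        kwargs = fixed_values.as_dict()
        for name, value in zip(free, vec):
            kwargs[name] = float(value)
        return PoolParameterBounds(**kwargs)

    def cost(vec: np.ndarray) -> float:
        b = make_bounds(vec)
        if not b.feasible():
            return np.inf
        try:
            return fitter.fit(b)[1]
        except ValueError as exc:
            raise ValueError(f"degenerate training data: {exc}") from exc

    if not free:
        c = cost(np.empty(0))
        return OptimizationResult(
            make_bounds(np.empty(0)), c, 0, time.perf_counter() - t_start, mask, seed
        )

    rng = np.random.default_rng(seed)
    lo = np.array([CONSTRAINT_BOX[name][0] for name in free])
    hi = np.array([CONSTRAINT_BOX[name][1] for name in free])
    span = hi - lo
    pop = lo + rng.uniform(size=(cfg.population, len(free))) * span
    pop[0] = 0.5 * (lo + hi)  # midpoint baseline always evaluated
    for j, cand in enumerate(extra_candidates or []):
        if 1 + j < cfg.population:
            pop[1 + j] = np.clip([getattr(cand, name) for name in free], lo, hi)
    costs = np.array([cost(v) for v in pop])
    if not np.isfinite(costs).any():
        raise ValueError("degenerate training data: no feasible candidate in initial population")
    best_idx = int(np.argmin(costs))
    best_vec, best_cost = pop[best_idx].copy(), float(costs[best_idx])
    stagnant = 0
    gens_run = 0
    mut_sd = cfg.mutation_sd_frac * span

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, cfg.population, size=cfg.tournament)
        return pop[contenders[np.argmin(costs[contenders])]]

    for gen in range(cfg.generations):
        new = [best_vec.copy()] * cfg.elitism
        while len(new) < cfg.population:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_prob:
                u = rng.uniform(-cfg.blend_alpha, 1.0 + cfg.blend_alpha, size=len(free))
                child = p1 + u * (p2 - p1)
            else:
                child = p1.copy()
            mut = rng.random(len(free)) < cfg.mutation_prob
            if mut.any():
                child = child + mut * rng.normal(0.0, 1.0, size=len(free)) * mut_sd
            new.append(np.clip(child, lo, hi))
        pop = np.asarray(new)
        costs = np.array([cost(v) for v in pop])
        gens_run = gen + 1
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost - cfg.stagnation_tol:
            best_vec, best_cost = pop[gen_best].copy(), float(costs[gen_best])
            stagnant = 0
        else:
            if costs[gen_best] < best_cost:
                best_vec, best_cost = pop[gen_best].copy(), float(costs[gen_best])
            stagnant += 1
            if stagnant >= cfg.stagnation_generations:
                break

    return OptimizationResult(
        make_bounds(best_vec), best_cost, gens_run,
        time.perf_counter() - t_start, mask, seed,
    )


def refine_and_time(
    fitter: MudriveFitter,
    sensitivity_rank: list[str],
    k: int,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    warm_start: PoolParameterBounds | None = None,
) -> OptimizationResult:
    """Optimize only the ``k`` most sensitive parameters.

    The remaining 5-k parameters are fixed at the midpoints of their
    constraint-box ranges; k = 0 is the pure midpoint baseline (cost
    evaluation only) and k = 5 is the full search.
    """
    if not 0 <= k <= 5:
        raise ValueError("k must be in 0..5")
    if len(sensitivity_rank) != len(PARAM_NAMES) or set(sensitivity_rank) != set(PARAM_NAMES):
        raise ValueError("sensitivity_rank must order all five parameters")
    mask = {name: name in sensitivity_rank[:k] for name in PARAM_NAMES}
    extra = [warm_start] if warm_start is not None else None
    return ga_optimize(fitter, mask, PoolParameterBounds.midpoint(), ga_config, seed,
                       extra_candidates=extra)


def refinement_sweep(
    fitter: MudriveFitter,
    sensitivity_rank: list[str],
    ga_config: GAConfig | None = None,
    seed: int = 0,
) -> list[OptimizationResult]:
    """Run the refinement for k = 0..5, warm-starting each search with the
    previous optimum.

    The k-1 optimum lies inside the k search space (its unoptimized
    parameters sit at the box midpoints), so injecting it into generation 0
    guarantees the best cost is nonincreasing in k.
    """
    results = []
    best: PoolParameterBounds | None = None
    for k in range(6):
        res = refine_and_time(
            fitter, sensitivity_rank, k, ga_config,
            seed=int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % 2**31),
            warm_start=best,
        )
        results.append(res)
        best = res.best_bounds
    return results
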