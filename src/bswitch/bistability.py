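"""Bistability sensitivity sweeps and genetic-algorithm parameter discovery.

One-at-a-time sensitivity: a kinetic parameter is scanned over a log grid
(default 33 points spanning x1/64 .. x64 around its nominal value) and the
*bistability predicate* -- at least two admissible stable equilibria at the
reference inputs -- is evaluated at each point.  The boundaries of the
contiguous bistable block containing the nominal value are then refined by
bisection in log space and reported both as raw values and as log2 fold
changes versus nominal.  Parameters whose scan never yields bistability are
classified ``unimodal`` (a single homeostatic expression level at every
scanned value); boundaries that run off the scan edge are flagged censored.

Parameter discovery re-implements a bifurcation-discovery search: a seeded
genetic algorithm (tournament selection, blend crossover and log-normal
mutation in log-parameter space) maximizes a graded distance-to-bistability
score built from the number of admissible stable equilibria at probe input
levels, and every reported hit is re-verified with a full continuation
diagram and switch classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelInputError, ParameterError, ParameterSet, get_model
from .dynamics import find_equilibria
from .continuation import build_diagram

__all__ = [
    "BistabilityInterval",
    "SearchResult",
    "is_bistable",
    "bistability_interval",
    "sensitivity_table",
    "search_bistable_parameters",
]


def is_bistable(model, params: ParameterSet, inputs=(0.0, 0.0), n_starts: int = 120,
                seed: int = 0) -> bool:
    """Predicate: >= 2 admissible stable equilibria at the reference inputs."""
    eqs = find_equilibria(model, params, inputs, n_starts=n_starts, seed=seed)
    return sum(1 for e in eqs if e.is_stable and e.admissible) >= 2


@dataclass(frozen=True)
class BistabilityInterval:
    """Admissible range of one parameter preserving bistability.

    ``log2_min``/``log2_max`` are log2(min/nominal) and log2(max/nominal);
    they are NaN when the nominal value is zero (the log ratio is undefined)
    and carry the scan-edge value when the corresponding bound is censored.
    """

    param: str
    nominal: float
    p_min: float
    p_max: float
    log2_min: float
    log2_max: float
    classification: str  # bistable_interval | unimodal | failed
    censored_lo: bool = False
    censored_hi: bool = False
    note: str = ""


def _log2_ratio(value: float, nominal: float) -> float:
    if nominal <= 0 or value <= 0:
        return float("nan")
    return math.log2(value / nominal)


def bistability_interval(
    model,
    params: ParameterSet,
    inputs=(0.0, 0.0),
    param: str = "b4",
    scan_decades: float = 6.0,
    n_grid: int = 33,
    rel_tol: float = 1e-3,
    n_starts: int = 120,
    seed: int = 0,
) -> BistabilityInterval:
    """Scan-and-bisect the bistable range of one kinetic parameter.

    ``scan_decades`` is in log2 units per side (default 6: x1/64..x64).
    Boundary refinement bisects the bistable/non-bistable predicate in log
    space down to relative tolerance ``rel_tol``.
    """
    spec = get_model(model)
    if param not in spec.required_parameters:
        raise ModelInputError(
            f"parameter '{param}' does not enter model '{spec.model_id}'"
        )
    nominal = params[param]

    def predicate(value: float) -> bool:
        return is_bistable(
            spec, params.replace(**{param: value}), inputs,
            n_starts=n_starts, seed=seed,
        )

    if nominal == 0:
        # log scan undefined; linear scan upward from zero
        grid = np.linspace(0.0, 1.0, n_grid)
        flags = [predicate(v) for v in grid]
        if not any(flags):
            return BistabilityInterval(param, nominal, math.nan, math.nan,
                                       math.nan, math.nan, "unimodal",
                                       note="zero nominal; linear scan")
        lo = grid[flags.index(True)]
        hi = grid[len(flags) - 1 - flags[::-1].index(True)]
        return BistabilityInterval(param, nominal, float(lo), float(hi),
                                   math.nan, math.nan, "bistable_interval",
                                   censored_hi=bool(flags[-1]),
                                   note="zero nominal; linear bounds only")

    grid = nominal * np.logspace(-scan_decades, scan_decades, n_grid, base=2.0)
    flags = np.array([predicate(v) for v in grid])
    if not flags.any():
        return BistabilityInterval(param, nominal, math.nan, math.nan,
                                   math.nan, math.nan, "unimodal")

    center = int(np.argmin(np.abs(np.log2(grid / nominal))))
    if not flags[center]:
        # nominal configuration not bistable: report the nearest bistable
        # block found by the scan
        center = int(np.nonzero(flags)[0][np.argmin(
            np.abs(np.nonzero(flags)[0] - center))])
    i = j = center
    while i - 1 >= 0 and flags[i - 1]:
        i -= 1
    while j + 1 < len(grid) and flags[j + 1]:
        j += 1

    def bisect(lo_val, hi_val, want_hi: bool) -> float:
        """Bisect in log space; lo_val bistable-side, hi_val non-bistable."""
        a, b = math.log(lo_val), math.log(hi_val)
        while abs(b - a) > rel_tol:
            m = 0.5 * (a + b)
            if predicate(math.exp(m)) :
                a = m
            else:
                b = m
        return math.exp(a)

    censored_lo = i == 0
    censored_hi = j == len(grid) - 1
    p_min = grid[0] if censored_lo else bisect(grid[i], grid[i - 1], False)
    p_max = grid[-1] if censored_hi else bisect(grid[j], grid[j + 1], True)
    return BistabilityInterval(
        param=param,
        nominal=float(nominal),
        p_min=float(p_min),
        p_max=float(p_max),
        log2_min=_log2_ratio(p_min, nominal),
        log2_max=_log2_ratio(p_max, nominal),
        classification="bistable_interval",
        censored_lo=censored_lo,
        censored_hi=censored_hi,
    )


def sensitivity_table(
    model,
    params: ParameterSet,
    inputs=(0.0, 0.0),
    parameter_list=None,
    **kwargs,
) -> pd.DataFrame:
    """One :func:`bistability_interval` row per parameter.

    A row that raises is marked ``failed`` instead of aborting the sweep.
    Returns a DataFrame indexed by parameter name with the interval fields.
    """
    spec = get_model(model)
    if parameter_list is None:
        parameter_list = [
            p for p in spec.required_parameters if not p.startswith("mu")
        ]
    rows = []
    for name in parameter_list:
        try:
            iv = bistability_interval(spec, params, inputs, name, **kwargs)
        except Exception as ex:  # noqa: BLE001 - per-row fault isolation
            iv = BistabilityInterval(name, params.get(name, math.nan),
                                     math.nan, math.nan, math.nan, math.nan,
                                     "failed", note=str(ex))
        rows.append(
            dict(param=iv.param, nominal=iv.nominal, p_min=iv.p_min,
                 p_max=iv.p_max, log2_min=iv.log2_min, log2_max=iv.log2_max,
                 classification=iv.classification,
                 censored_lo=iv.censored_lo, censored_hi=iv.censored_hi,
                 note=iv.note)
        )
    return pd.DataFrame(rows).set_index("param")


# --------------------------------------------------------------------------
# genetic-algorithm bistable-parameter discovery
# --------------------------------------------------------------------------

@dataclass
class SearchResult:
    """Outcome of a GA search: verified hits and the fitness history."""

    parameter_sets: list[ParameterSet]
    classifications: list[str]
    fitness_trace: np.ndarray
    seed: int
    best_fitness: float

    @property
    def found(self) -> bool:
        return len(self.parameter_sets) > 0


def _ga_fitness(spec, base: ParameterSet, names, values, inputs, probes,
                n_starts, seed, objective) -> float:
    try:
        ps = base.replace(**dict(zip(names, values)))
    except ParameterError:
        return -1.0
    t_e, t_z = float(inputs[0]), float(inputs[1])
    score = 0.0
    for probe in probes:
        try:
            eqs = find_equilibria(spec, ps, (t_e + probe, t_z),
                                  n_starts=n_starts, seed=seed)
        except Exception:  # noqa: BLE001
            return -1.0
        stable = [e for e in eqs if e.is_stable and e.admissible]
        n = len(stable)
        score += min(n, 2) / 2.0
        if n >= 2:
            sep = max(
                float(np.max(np.abs(a.state - b.state)))
                for i, a in enumerate(stable)
                for b in stable[i + 1:]
            )
            score += 0.1 * min(sep, 1.0)
        if objective == "fold_exists" and n >= 1:
            # a nearly-singular Jacobian anywhere is a fold-margin signal
            sv = min(
                float(np.linalg.svd(
                    spec.jac(e.state, spec.param_array(ps), t_e + probe, t_z),
                    compute_uv=False)[-1])
                for e in eqs
            )
            score += 0.2 / (1.0 + 10.0 * sv)
    return score / len(probes)


def search_bistable_parameters(
    model,
    ranges: dict[str, tuple[float, float]],
    objective: str = "bistable",
    population: int = 32,
    generations: int = 25,
    seed: int = 0,
    base: ParameterSet | None = None,
    inputs=(0.0, 0.0),
    probes=(0.0,),
    n_starts: int = 40,
    fitness_threshold: float = 0.99,
    verify_range: tuple[float, float] = (-1.5, 3.0),
    max_hits: int = 3,
) -> SearchResult:
    """Seeded GA over ``ranges`` seeking bistable (or fold-bearing) sets.

    ``objective`` is one of ``bistable``, ``irreversible_bistable`` or
    ``fold_exists``.  Candidate genomes live in log-parameter space;
    selection is 3-way tournament, crossover is BLX-0.5 blending, mutation
    multiplies by a log-normal factor.  Every candidate whose graded fitness
    clears ``fitness_threshold`` is re-verified by :func:`build_diagram` +
    switch classification before being reported.  Identical seeds and
    settings give identical results.
    """
    if objective not in ("bistable", "irreversible_bistable", "fold_exists"):
        raise ModelInputError(f"unknown objective '{objective}'")
    if not ranges:
        raise ModelInputError("empty parameter ranges")
    for name, (lo, hi) in ranges.items():
        if not (0 <= lo <= hi):
            raise ModelInputError(f"invalid range for {name}: ({lo}, {hi})")
    spec = get_model(model)
    if base is None:
        from .model_core import nominal_parameters

        base = nominal_parameters()
    names = list(ranges)
    lo = np.array([max(ranges[n][0], 1e-12) for n in names])
    hi = np.array([max(ranges[n][1], 1e-12) for n in names])
    llo, lhi = np.log(lo), np.log(hi)

    rng = np.random.default_rng(seed)
    pop = rng.uniform(llo, lhi, size=(population, len(names)))

    def fit(genome):
        return _ga_fitness(spec, base, names, np.exp(genome), inputs, probes,
                           n_starts, seed, objective)

    fitness = np.array([fit(g) for g in pop])
    trace = [float(fitness.max())]
    for _ in range(generations):
        if fitness.max() >= fitness_threshold:
            break
        new = [pop[int(np.argmax(fitness))].copy()]  # elitism
        while len(new) < population:
            idx = rng.integers(0, population, size=(2, 3))
            pa = pop[idx[0][np.argmax(fitness[idx[0]])]]
            pb = pop[idx[1][np.argmax(fitness[idx[1]])]]
            w = rng.uniform(-0.5, 1.5, size=len(names))
            child = w * pa + (1 - w) * pb
            mut = rng.random(len(names)) < 0.25
            child = np.where(mut, child + rng.normal(0, 0.35, len(names)),
                             child)
            new.append(np.clip(child, llo, lhi))
        pop = np.array(new)
        fitness = np.array([fit(g) for g in pop])
        trace.append(float(fitness.max()))

    # verify the best distinct candidates with a full diagram
    order = np.argsort(fitness)[::-1]
    hits: list[ParameterSet] = []
    classes: list[str] = []
    want = {"bistable": ("reversible_bistable", "irreversible_bistable"),
            "irreversible_bistable": ("irreversible_bistable",),
            "fold_exists": ("reversible_bistable", "irreversible_bistable",
                            "monostable")}[objective]
    for k in order[: 2 * max_hits]:
        if fitness[k] < fitness_threshold or len(hits) >= max_hits:
            break
        ps = base.replace(**dict(zip(names, np.exp(pop[k]))))
        diagram = build_diagram(spec, ps, inputs, "T_EBF1", verify_range,
                                seed=seed, n_starts=60)
        cls = diagram.switch_class
        if objective == "fold_exists":
            if not diagram.folds:
                continue
        elif cls not in want:
            continue
        if any(
            max(abs(ps[n] - h[n]) / max(h[n], 1e-12) for n in names) < 1e-3
            for h in hits
        ):
            continue
        hits.append(ps)
        classes.append(cls)
    return SearchResult(
        parameter_sets=hits,
        classifications=classes,
        fitness_trace=np.array(trace),
        seed=seed,
        best_fitness=float(fitness.max()),
    )
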