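"""Synthetic data generators for exercising the analysis pipeline.

The expression fixture emulates the two-condition microarray pattern used
to assess the model: a CD34+/lin- multipotent sample (LMPP) and a pro-B
sample, with FLT3 and ZNF521 high in the multipotent condition, EBF1, PAX5
and CD19 high in the committed one, and the remaining factors at similar
intermediate levels in both.  Noise is multiplicative log-normal (microarray
intensities are positive and right-skewed); the sd is on the log scale.
These fixtures reproduce the *direction structure* of real profiling data,
not its probe-level artifacts (background, cross-hybridization) or
between-replicate correlation -- agreement with a fixture therefore
exercises the comparison pipeline, not array preprocessing.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelInputError, PARAM_NAMES, ParameterSet

__all__ = [
    "FixtureSpec",
    "DEFAULT_PROGRAM",
    "default_fixture_spec",
    "make_expression_fixture",
    "make_de_table",
    "sample_parameter_sets",
]

#: (LMPP mean, proB mean) per factor, arbitrary units: the two-condition
#: expression program (markers separated ~4-6x, the rest flat)
DEFAULT_PROGRAM: dict[str, tuple[float, float]] = {
    "FLT3": (8.0, 2.0),
    "ZNF521": (9.0, 1.5),
    "EBF1": (1.5, 9.0),
    "PAX5": (1.0, 8.0),
    "CD19": (0.8, 10.0),
    "IKAROS": (5.0, 5.0),
    "GFI1": (4.0, 4.0),
    "PU1": (5.0, 5.0),
    "E2A": (6.0, 6.0),
    "IL7R": (6.0, 6.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative spec of a two-condition expression fixture."""

    program: tuple[tuple[str, float, float], ...]
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name, lmpp, prob in self.program:
            if lmpp < 0 or prob < 0:
                raise ModelInputError(f"negative mean for factor {name}")
        if self.noise_sd < 0:
            raise ModelInputError("noise_sd must be >= 0")


def default_fixture_spec(noise_sd: float = 0.05, seed: int = 0) -> FixtureSpec:
    return FixtureSpec(
        program=tuple((n, a, b) for n, (a, b) in DEFAULT_PROGRAM.items()),
        noise_sd=noise_sd,
        seed=seed,
    )


def make_expression_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Seeded factor x (LMPP, proB) table with log-normal noise."""
    rng = np.random.default_rng(spec.seed)
    names = [p[0] for p in spec.program]
    means = np.array([[p[1], p[2]] for p in spec.program], dtype=float)
    noise = np.exp(rng.normal(0.0, spec.noise_sd, size=means.shape))
    values = means * noise if spec.noise_sd > 0 else means
    return pd.DataFrame(values, index=names, columns=["LMPP", "proB"])


def make_de_table(
    n_rows: int,
    n_planted: int,
    seed: int = 0,
    planted_fold_range: tuple[float, float] = (2.5, 8.0),
    planted_p_range: tuple[float, float] = (1e-6, 0.01),
    null_fold_range: tuple[float, float] = (1.0, 1.5),
    null_p_range: tuple[float, float] = (0.2, 1.0),
) -> pd.DataFrame:
    """Toy differential-expression table with known planted positives.

    Planted rows pass the |fold| >= 2, p < 0.05 filter by construction;
    null rows fail on both the fold and the p-value margin.  The ``planted``
    column retains ground truth for testing.
    """
    if n_planted > n_rows:
        raise ModelInputError("n_planted cannot exceed n_rows")
    rng = np.random.default_rng(seed)
    planted = np.zeros(n_rows, dtype=bool)
    planted[rng.choice(n_rows, size=n_planted, replace=False)] = True

    fold = np.empty(n_rows)
    pval = np.empty(n_rows)
    signs = rng.choice([-1.0, 1.0], size=n_rows)
    n_null = n_rows - n_planted
    fold[planted] = signs[planted] * rng.uniform(*planted_fold_range, n_planted)
    lo, hi = np.log10(planted_p_range[0]), np.log10(planted_p_range[1])
    pval[planted] = 10 ** rng.uniform(lo, hi, n_planted)
    fold[~planted] = signs[~planted] * rng.uniform(*null_fold_range, n_null)
    pval[~planted] = rng.uniform(*null_p_range, n_null)

    return pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n_rows)],
            "fold_change_linear": fold,
            "p_value": pval,
            "planted": planted,
        }
    ).set_index("gene")


def sample_parameter_sets(
    ranges: dict[str, tuple[float, float]],
    n: int,
    distribution: str = "log-uniform",
    seed: int = 0,
    base: ParameterSet | None = None,
) -> list[ParameterSet]:
    """Seeded random parameter sets: ``base`` with ``ranges`` resampled.

    ``distribution`` is ``log-uniform`` (default; requires positive bounds)
    or ``uniform``.  Degenerate ranges (lo == hi) pin the value.
    """
    if distribution not in ("log-uniform", "uniform"):
        raise ModelInputError(f"unknown distribution '{distribution}'")
    for name, (lo, hi) in ranges.items():
        if name not in PARAM_NAMES:
            raise ModelInputError(f"unknown parameter symbol(s): {name}")
        if lo > hi:
            raise ModelInputError(f"inverted range for {name}: ({lo}, {hi})")
        if distribution == "log-uniform" and lo <= 0:
            raise ModelInputError(
                f"log-uniform sampling needs positive bounds ({name})"
            )
    if base is None:
        from .model_core import nominal_parameters

        base = nominal_parameters()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draw = {}
        for name, (lo, hi) in ranges.items():
            if distribution == "log-uniform":
                draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                draw[name] = float(rng.uniform(lo, hi))
        out.append(base.replace(**draw))
    return out
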