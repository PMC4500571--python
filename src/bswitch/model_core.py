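"""ODE models of the B-lymphoid lineage-commitment gene regulatory network.

The network couples two cytokine receptors (FLT3, IL-7R) and seven
transcription factors (PU.1, IKAROS, GFI1, E2A, EBF1, PAX5, ZNF521) that
together decide whether a lymphoid-primed multipotent progenitor (LMPP)
commits to the B-lymphoid lineage (pro-B, marked by surface CD19).  Every
model here shares the same kinetic vocabulary: each species is produced at a
saturating rational rate (basal term plus heterodimeric pairwise activation
terms in the numerator, the same terms plus repression products in the
denominator, which is always ``1 + nonnegative``) and degraded linearly.
Two dimensionless environmental inputs, ``T_EBF1`` and ``T_ZNF521``, promote
the transcription of EBF1 and ZNF521 and serve as bifurcation parameters.

Eleven model variants are exposed behind one uniform right-hand-side /
Jacobian contract:

* ``full_A`` -- the complete 10-species network, including the putative
  direct repression of ZNF521 by PAX5 (strength ``b4``);
* ``full_no_pax5_znf521`` -- the same network with ``b4`` forced to zero
  (ablation of the PAX5 -| ZNF521 edge);
* ``full_B`` / ``full_C`` -- alternative hypotheses in which the PAX5
  repression of ZNF521 is replaced by repression through E2A (B) or through
  IKAROS (C).  The repression term of B and C is a reconstruction built on
  the same structural pattern as the PAX5 term (an ``EBF1 x partner``
  product in the ZNF521 denominator); the original studies do not print it.
* seven sub-modules (``ebf1_znf521`` ... ``ebf1_pax5_znf521``) isolating the
  core feedback loops.

Two printed idiosyncrasies are deliberately preserved: the full model
represses EBF1 through ``a4*x_ZNF521`` (linear) and ZNF521 through
``b3*x_ZNF521*x_EBF1``, while the sub-modules use ``a4*x_EBF1*x_ZNF521`` and
``b3*x_EBF1``.  Each variant is implemented exactly in its published form,
except for two documented corrections: the two-node module's ZNF521 equation
degrades its own state (``-mu7*x_ZNF521``), and the five-/four-node modules
with a leading ``(numerator) x (1 + ...)`` production use division by the
saturating factor, consistent with every other equation.
"""

from __future__ import annotations

import functools
import io
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES_FULL",
    "MODEL_IDS",
    "ParameterError",
    "ModelInputError",
    "ParameterSet",
    "EnvironmentalInputs",
    "ModelSpec",
    "rhs",
    "jacobian",
    "rhs_input_derivative",
    "production_bounds",
    "state_box",
    "list_models",
    "get_model",
    "custom_model",
    "load_parameters",
    "save_parameters",
    "nominal_parameters",
]


# --------------------------------------------------------------------------
# parameter bookkeeping
# --------------------------------------------------------------------------

def _expand(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


#: Every kinetic symbol of the full network, in canonical order.  Basal
#: production rates are a0, b0, ..., j0; mu1..mu10 are degradation rates of
#: the ten species in equation order.
PARAM_NAMES: tuple[str, ...] = tuple(
    _expand("a", 13)
    + _expand("b", 5)
    + _expand("c", 4)
    + ["d0", "d1"]
    + _expand("e", 7)
    + _expand("f", 4)
    + _expand("g", 3)
    + ["h0", "h1"]
    + ["i0"]
    + ["j0", "j1"]
    + [f"mu{i}" for i in range(1, 11)]
)

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}
_MU_NAMES = frozenset(f"mu{i}" for i in range(1, 11))

STATE_NAMES_FULL: tuple[str, ...] = (
    "IKAROS",
    "GFI1",
    "PU1",
    "FLT3",
    "IL7R",
    "E2A",
    "ZNF521",
    "EBF1",
    "PAX5",
    "CD19",
)

#: Degradation-rate symbol of each full-model state, in state order.
STATE_DEGRADATION: dict[str, str] = {
    name: f"mu{i + 1}" for i, name in enumerate(STATE_NAMES_FULL)
}


class ParameterError(ValueError):
    """A parameter file or parameter map violates the model contract."""


class ModelInputError(ValueError):
    """A state vector or input does not match the requested model."""


class ParameterSet(Mapping[str, float]):
    """Validated, immutable name->value map over the full kinetic symbol set.

    All values must be finite and non-negative, degradation rates
    (``mu1..mu10``) strictly positive, and the name set exactly
    :data:`PARAM_NAMES`.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        unknown = sorted(set(values) - set(PARAM_NAMES))
        if unknown:
            raise ParameterError(f"unknown parameter symbol(s): {', '.join(unknown)}")
        missing = sorted(set(PARAM_NAMES) - set(values))
        if missing:
            raise ParameterError(f"missing parameter symbol(s): {', '.join(missing)}")
        vals = {}
        bad = []
        for name in PARAM_NAMES:
            v = float(values[name])
            if not np.isfinite(v) or v < 0 or (name in _MU_NAMES and v == 0):
                bad.append(f"{name}={values[name]!r}")
            vals[name] = v
        if bad:
            raise ParameterError(
                "invalid parameter value(s) (must be finite, >=0, mu>0): "
                + ", ".join(bad)
            )
        self._values = vals

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ParameterSet({len(self)} symbols)"

    def __eq__(self, other) -> bool:
        if isinstance(other, ParameterSet):
            return self._values == other._values
        return NotImplemented

    # helpers ---------------------------------------------------------------
    def to_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = PARAM_NAMES if names is None else names
        return np.array([self._values[n] for n in names], dtype=float)

    def replace(self, **updates: float) -> "ParameterSet":
        vals = dict(self._values)
        for k, v in updates.items():
            if k not in _PARAM_INDEX:
                raise ParameterError(f"unknown parameter symbol(s): {k}")
            vals[k] = v
        return ParameterSet(vals)


@dataclass(frozen=True)
class EnvironmentalInputs:
    """Exogenous transcriptional activation of EBF1 and ZNF521.

    Physical ("accessible") operation requires both levels to be
    non-negative; numerical continuation may trace equilibria at negative
    values, which are then flagged inadmissible downstream.
    """

    t_ebf1: float = 0.0
    t_znf521: float = 0.0

    def as_tuple(self) -> tuple[float, float]:
        return (float(self.t_ebf1), float(self.t_znf521))


def _as_inputs(inputs) -> EnvironmentalInputs:
    if isinstance(inputs, EnvironmentalInputs):
        return inputs
    if inputs is None:
        return EnvironmentalInputs()
    t_e, t_z = inputs
    return EnvironmentalInputs(float(t_e), float(t_z))


# --------------------------------------------------------------------------
# symbolic model construction
# --------------------------------------------------------------------------

_P = {name: sp.Symbol(name, nonnegative=True) for name in PARAM_NAMES}
_X = {name: sp.Symbol("x_" + name) for name in STATE_NAMES_FULL}
_TE = sp.Symbol("T_EBF1")
_TZ = sp.Symbol("T_ZNF521")


def _full_equations(znf_repressor: sp.Expr | None, with_b4: bool = True):
    """The ten printed equations; ``znf_repressor`` is the heterodimer that
    represses ZNF521 alongside ``b3`` (PAX5 for the nominal model, E2A or
    IKAROS for hypotheses B and C, ``None`` for the ablation)."""
    p = _P
    ik, gf, pu, fl, il, j, z, e, px, cd = (_X[n] for n in STATE_NAMES_FULL)
    n_flt3 = (
        p["e0"] + p["e1"] * pu + p["e2"] * ik + p["e3"] * pu * ik
    )
    d_flt3 = (
        1
        + p["e1"] * pu
        + p["e2"] * ik
        + p["e3"] * pu * ik
        + p["e4"] * px
        + p["e5"] * pu * px
        + p["e6"] * ik * px
    )
    n_il7r = p["f0"] + p["f1"] * fl + p["f2"] * pu + p["f3"] * fl * pu
    d_il7r = 1 + p["f1"] * fl + p["f2"] * pu + p["f3"] * fl * pu
    rep = 0 if znf_repressor is None or not with_b4 else p["b4"] * e * znf_repressor
    n_znf = p["b0"] + p["b1"] * _TZ + p["b2"] * z
    d_znf = 1 + p["b1"] * _TZ + p["b2"] * z + p["b3"] * z * e + rep
    n_ebf1 = (
        p["a0"]
        + p["a1"] * _TE
        + p["a2"] * e
        + p["a3"] * px
        + p["a5"] * il
        + p["a6"] * e * il
        + p["a7"] * pu
        + p["a8"] * px * pu
        + p["a10"] * j
        + p["a11"] * j * e
        + p["a12"] * j * il
    )
    d_ebf1 = (
        1
        + p["a1"] * _TE
        + p["a2"] * e
        + p["a3"] * px
        + p["a4"] * z
        + p["a5"] * il
        + p["a6"] * e * il
        + p["a7"] * pu
        + p["a8"] * px * pu
        + p["a9"] * pu * z
        + p["a10"] * j
        + p["a11"] * j * e
        + p["a12"] * j * il
    )
    n_pax5 = p["c0"] + p["c1"] * e + p["c2"] * j + p["c3"] * e * j
    d_pax5 = 1 + p["c1"] * e + p["c2"] * j + p["c3"] * e * j
    return [
        p["i0"] - p["mu1"] * ik,
        (p["h0"] + p["h1"] * ik) / (1 + p["h1"] * ik) - p["mu2"] * gf,
        (p["g0"] + p["g1"] * pu) / (1 + p["g1"] * pu + p["g2"] * pu * gf)
        - p["mu3"] * pu,
        n_flt3 / d_flt3 - p["mu4"] * fl,
        n_il7r / d_il7r - p["mu5"] * il,
        (p["j0"] + p["j1"] * e) / (1 + p["j1"] * e) - p["mu6"] * j,
        n_znf / d_znf - p["mu7"] * z,
        n_ebf1 / d_ebf1 - p["mu8"] * e,
        n_pax5 / d_pax5 - p["mu9"] * px,
        (p["d0"] + p["d1"] * px) / (1 + p["d1"] * px) - p["mu10"] * cd,
    ]


def _submodule_equations(model_id: str):
    p = _P
    e, z, j, px, fl, il = (
        _X["EBF1"],
        _X["ZNF521"],
        _X["E2A"],
        _X["PAX5"],
        _X["FLT3"],
        _X["IL7R"],
    )
    pax5_c1 = (p["c0"] + p["c1"] * e) / (1 + p["c1"] * e) - p["mu9"] * px
    pax5_full = (p["c0"] + p["c1"] * e + p["c2"] * j + p["c3"] * e * j) / (
        1 + p["c1"] * e + p["c2"] * j + p["c3"] * e * j
    ) - p["mu9"] * px
    e2a = (p["j0"] + p["j1"] * e) / (1 + p["j1"] * e) - p["mu6"] * j
    flt3 = p["e0"] / (1 + p["e4"] * px) - p["mu4"] * fl
    il7r = (p["f0"] + p["f1"] * fl) / (1 + p["f1"] * fl) - p["mu5"] * il
    znf_b3e = lambda extra: (p["b0"] + p["b1"] * _TZ + p["b2"] * z) / (
        1 + p["b1"] * _TZ + p["b2"] * z + p["b3"] * e + extra
    ) - p["mu7"] * z

    if model_id == "ebf1_znf521":
        states = ("EBF1", "ZNF521")
        eqs = [
            (p["a0"] + p["a1"] * _TE + p["a2"] * e)
            / (1 + p["a1"] * _TE + p["a2"] * e + p["a4"] * e * z)
            - p["mu8"] * e,
            # printed degradation -mu7*x_EBF1 corrected to the equation's own state
            (p["b0"] + p["b1"] * _TZ + p["b2"] * z)
            / (1 + p["b1"] * _TZ + p["b2"] * z + p["b3"] * z * e)
            - p["mu7"] * z,
        ]
    elif model_id == "ebf1_e2a_pax5":
        states = ("EBF1", "E2A", "PAX5")
        n = p["a0"] + p["a1"] * _TE + p["a2"] * e + p["a10"] * j + p["a11"] * j * e
        eqs = [n / (1 + (n - p["a0"])) - p["mu8"] * e, e2a, pax5_full]
    elif model_id == "ebf1_pax5_flt3_il7r":
        states = ("EBF1", "PAX5", "FLT3", "IL7R")
        n = (
            p["a0"]
            + p["a1"] * _TE
            + p["a2"] * e
            + p["a3"] * px
            + p["a5"] * il
            + p["a6"] * e * il
        )
        eqs = [n / (1 + (n - p["a0"])) - p["mu8"] * e, pax5_c1, flt3, il7r]
    elif model_id == "ebf1_e2a_pax5_flt3_il7r":
        states = ("EBF1", "E2A", "PAX5", "FLT3", "IL7R")
        n = (
            p["a0"]
            + p["a1"] * _TE
            + p["a2"] * e
            + p["a3"] * px
            + p["a5"] * il
            + p["a6"] * e * il
            + p["a10"] * j
            + p["a11"] * j * e
            + p["a12"] * j * il
        )
        eqs = [n / (1 + (n - p["a0"])) - p["mu8"] * e, e2a, pax5_full, flt3, il7r]
    elif model_id == "znf521_ebf1_pax5_flt3_il7r":
        states = ("EBF1", "ZNF521", "PAX5", "FLT3", "IL7R")
        n = (
            p["a0"]
            + p["a1"] * _TE
            + p["a2"] * e
            + p["a3"] * px
            + p["a5"] * il
            + p["a6"] * e * il
        )
        # printed "(num) x (1 + ...)" implemented as division by the
        # saturating factor, consistent with the full model
        eqs = [
            n / (1 + (n - p["a0"]) + p["a4"] * e * z) - p["mu8"] * e,
            znf_b3e(0),
            pax5_c1,
            flt3,
            il7r,
        ]
    elif model_id == "znf521_ebf1_e2a_pax5":
        states = ("EBF1", "ZNF521", "E2A", "PAX5")
        n = (
            p["a0"]
            + p["a1"] * _TE
            + p["a2"] * e
            + p["a3"] * px
            + p["a10"] * j
            + p["a11"] * e * j
        )
        eqs = [
            n / (1 + (n - p["a0"]) + p["a4"] * e * z) - p["mu8"] * e,
            znf_b3e(0),
            e2a,
            pax5_full,
        ]
    elif model_id == "ebf1_pax5_znf521":
        states = ("EBF1", "ZNF521", "PAX5")
        n = p["a0"] + p["a1"] * _TE + p["a2"] * e + p["a3"] * px
        eqs = [
            n / (1 + (n - p["a0"]) + p["a4"] * e * z) - p["mu8"] * e,
            znf_b3e(p["b4"] * e * px),
            pax5_c1,
        ]
    else:  # pragma: no cover - guarded by MODEL_IDS
        raise KeyError(model_id)
    return states, eqs


@dataclass(frozen=True)
class ModelSpec:
    """One network variant: ordered states, equations and parameter manifest."""

    model_id: str
    states: tuple[str, ...]
    equations: tuple[sp.Expr, ...] = field(repr=False)
    inputs: tuple[str, ...] = ("T_EBF1", "T_ZNF521")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @functools.cached_property
    def required_parameters(self) -> tuple[str, ...]:
        syms = set().union(*(eq.free_symbols for eq in self.equations))
        names = {s.name for s in syms}
        return tuple(n for n in PARAM_NAMES if n in names)

    @functools.cached_property
    def _state_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(_X[s] if s in _X else sp.Symbol("x_" + s) for s in self.states)

    @functools.cached_property
    def _compiled(self):
        args = (
            list(self._state_symbols)
            + [_P[n] for n in self.required_parameters]
            + [_TE, _TZ]
        )
        f = sp.lambdify(args, list(self.equations), modules="numpy")
        jac_mat = sp.Matrix(self.equations).jacobian(sp.Matrix(self._state_symbols))
        jf = sp.lambdify(args, jac_mat, modules="numpy")
        dte = [sp.diff(eq, _TE) for eq in self.equations]
        dtz = [sp.diff(eq, _TZ) for eq in self.equations]
        df = sp.lambdify(args, [dte, dtz], modules="numpy")
        return f, jf, df

    # low-level evaluators (positional args: state, param array, inputs) ----
    def param_array(self, params: ParameterSet) -> np.ndarray:
        missing = [n for n in self.required_parameters if n not in params]
        if missing:  # pragma: no cover - ParameterSet is always complete
            raise ParameterError(f"missing parameter symbol(s): {', '.join(missing)}")
        return params.to_array(self.required_parameters)

    def _check_state(self, state) -> np.ndarray:
        x = np.asarray(state, dtype=float)
        if x.shape != (self.n_states,):
            raise ModelInputError(
                f"model '{self.model_id}' expects a state vector of length "
                f"{self.n_states} (states {self.states}), got shape {x.shape}"
            )
        return x

    def f(self, x: np.ndarray, p: np.ndarray, t_e: float, t_z: float) -> np.ndarray:
        return np.asarray(self._compiled[0](*x, *p, t_e, t_z), dtype=float)

    def jac(self, x: np.ndarray, p: np.ndarray, t_e: float, t_z: float) -> np.ndarray:
        return np.asarray(self._compiled[1](*x, *p, t_e, t_z), dtype=float)

    def df_dinput(
        self, x: np.ndarray, p: np.ndarray, t_e: float, t_z: float
    ) -> np.ndarray:
        """Partial derivatives of the rhs w.r.t. (T_EBF1, T_ZNF521), shape (2, n)."""
        return np.asarray(self._compiled[2](*x, *p, t_e, t_z), dtype=float)

    def state_index(self, name: str) -> int:
        try:
            return self.states.index(name)
        except ValueError:
            raise ModelInputError(
                f"model '{self.model_id}' has no state '{name}'"
            ) from None


def _build_canonical() -> dict[str, ModelSpec]:
    models: dict[str, ModelSpec] = {}
    full_defs = {
        "full_A": (_X["PAX5"], True),
        "full_no_pax5_znf521": (None, False),
        "full_B": (_X["E2A"], True),
        "full_C": (_X["IKAROS"], True),
    }
    for mid, (repressor, with_b4) in full_defs.items():
        eqs = _full_equations(repressor, with_b4)
        models[mid] = ModelSpec(mid, STATE_NAMES_FULL, tuple(eqs))
    for mid in (
        "ebf1_znf521",
        "ebf1_e2a_pax5",
        "ebf1_pax5_flt3_il7r",
        "ebf1_e2a_pax5_flt3_il7r",
        "znf521_ebf1_pax5_flt3_il7r",
        "znf521_ebf1_e2a_pax5",
        "ebf1_pax5_znf521",
    ):
        states, eqs = _submodule_equations(mid)
        models[mid] = ModelSpec(mid, states, tuple(eqs))
    return models


_MODELS = _build_canonical()
MODEL_IDS: tuple[str, ...] = tuple(_MODELS)


def list_models() -> dict[str, ModelSpec]:
    """Catalogue of all canonical model variants, keyed by identifier."""
    return dict(_MODELS)


def get_model(model: "str | ModelSpec") -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return _MODELS[model]
    except KeyError:
        raise ModelInputError(
            f"unknown model '{model}'; available: {', '.join(MODEL_IDS)}"
        ) from None


def custom_model(
    model_id: str,
    states: Sequence[str],
    equations: Sequence[sp.Expr],
    inputs: tuple[str, ...] = ("T_EBF1", "T_ZNF521"),
) -> ModelSpec:
    """Build an ad-hoc model from sympy expressions (used for toy systems).

    ``equations`` may reference state symbols ``x_<name>``, any symbol from
    :data:`PARAM_NAMES`, and the input symbols ``T_EBF1`` / ``T_ZNF521``.
    """
    return ModelSpec(model_id, tuple(states), tuple(sp.sympify(e) for e in equations),
                     inputs)


# --------------------------------------------------------------------------
# the uniform rhs / jacobian contract
# --------------------------------------------------------------------------

def rhs(model, state, params: ParameterSet, inputs=None) -> np.ndarray:
    """Time derivative dx/dt of ``model`` at ``state``.

    ``inputs`` is an :class:`EnvironmentalInputs` or ``(T_EBF1, T_ZNF521)``
    pair; omitted inputs default to zero.
    """
    spec = get_model(model)
    x = spec._check_state(state)
    t_e, t_z = _as_inputs(inputs).as_tuple()
    return spec.f(x, spec.param_array(params), t_e, t_z)


def jacobian(model, state, params: ParameterSet, inputs=None) -> np.ndarray:
    """State Jacobian J[i, j] = d(dx_i/dt)/dx_j (analytic, not numerical)."""
    spec = get_model(model)
    x = spec._check_state(state)
    t_e, t_z = _as_inputs(inputs).as_tuple()
    return spec.jac(x, spec.param_array(params), t_e, t_z)


def rhs_input_derivative(model, state, params: ParameterSet, inputs=None) -> np.ndarray:
    """Partial derivatives of the rhs w.r.t. the two environmental inputs."""
    spec = get_model(model)
    x = spec._check_state(state)
    t_e, t_z = _as_inputs(inputs).as_tuple()
    return spec.df_dinput(x, spec.param_array(params), t_e, t_z)


def production_bounds(model, params: ParameterSet, inputs=None) -> np.ndarray:
    """Upper bound of each production term over the non-negative orthant.

    Every printed production is N/D with D = 1 + (N - basal) + repressions,
    all terms non-negative, so it never exceeds max(1, basal + activation
    through the inputs).  The returned array bounds dx_i/dt + mu_i*x_i.
    """
    spec = get_model(model)
    t_e, t_z = _as_inputs(inputs).as_tuple()
    basal = {
        "IKAROS": params["i0"],
        "GFI1": params["h0"],
        "PU1": params["g0"],
        "FLT3": params["e0"],
        "IL7R": params["f0"],
        "E2A": params["j0"],
        "ZNF521": params["b0"] + params["b1"] * max(t_z, 0.0),
        "EBF1": params["a0"] + params["a1"] * max(t_e, 0.0),
        "PAX5": params["c0"],
        "CD19": params["d0"],
    }
    return np.array([max(1.0, basal.get(s, 1.0)) for s in spec.states])


def state_box(model, params: ParameterSet, inputs=None, margin: float = 1.5
              ) -> np.ndarray:
    """Invariant box ``[0, margin * bound_i / mu_i]`` per state (shape (n, 2))."""
    spec = get_model(model)
    bounds = production_bounds(spec, params, inputs)
    mus = np.array(
        [params[STATE_DEGRADATION.get(s, "mu1")] for s in spec.states]
    )
    hi = margin * bounds / mus
    return np.column_stack([np.zeros_like(hi), hi])


# --------------------------------------------------------------------------
# flat parameter files
# --------------------------------------------------------------------------

def load_parameters(source: "str | os.PathLike | io.TextIOBase") -> ParameterSet:
    """Read a flat ``symbol = value`` parameter file.

    One assignment per line; ``#`` starts a comment; symbols are
    case-sensitive and must cover the full set exactly (no silent defaults).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    values: dict[str, float] = {}
    problems: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            problems.append(f"line {lineno}: expected 'symbol = value', got {raw!r}")
            continue
        name, _, val = (t.strip() for t in line.partition("="))
        if name in values:
            problems.append(f"line {lineno}: duplicate symbol {name}")
            continue
        try:
            values[name] = float(val)
        except ValueError:
            problems.append(f"line {lineno}: non-numeric value for {name}: {val!r}")
    if problems:
        raise ParameterError("; ".join(problems))
    return ParameterSet(values)


def save_parameters(params: ParameterSet, path: "str | os.PathLike") -> None:
    """Write a :class:`ParameterSet` in the same flat key-value format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# kinetic parameters (units 1/s; Michaelis constants dimensionless)\n")
        for name in PARAM_NAMES:
            fh.write(f"{name} = {params[name]!r}\n")


@functools.lru_cache(maxsize=1)
def nominal_parameters() -> ParameterSet:
    """The package's calibrated nominal parameter set.

    The originally reported kinetic constants are not available in
    machine-readable form; this set was found with the package's own
    genetic-algorithm search (see :mod:`bswitch.bistability`), constrained to
    reproduce the qualitative two-attractor expression program and the
    irreversible commitment switch, and then frozen.
    """
    path = os.path.join(os.path.dirname(__file__), "data", "nominal_params.txt")
    return load_parameters(path)
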