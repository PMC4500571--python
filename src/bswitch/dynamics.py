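"""Time integration, equilibria and linear stability for the network models.

The kinetics are rational (saturating production, linear decay) and mildly
stiff near saturation, so the default integrator is stiff-capable (LSODA)
with tight tolerances (rtol 1e-8, atol 1e-10).  Equilibria are located by
multi-start damped Newton iteration from a seeded Latin-hypercube sample of
the forward-invariant box ``[0, 1.5 * bound/mu]`` and deduplicated in the
max-norm.  Stability is read off the analytic Jacobian's eigenvalues; a
``marginal`` flag is raised when an eigenvalue's real part is within 1e-7 of
the imaginary axis (fold neighbourhoods), and marginal points are treated as
unstable for branch bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.stats import qmc

from .model_core import (
    EnvironmentalInputs,
    ModelInputError,
    ParameterSet,
    get_model,
    state_box,
)

__all__ = [
    "Trajectory",
    "Equilibrium",
    "IntegrationError",
    "simulate",
    "find_equilibria",
    "classify_stability",
    "nullclines_2d",
]

#: residual norm below which a state counts as an equilibrium
RESIDUAL_TOL = 1e-9
#: max-norm distance below which two equilibria are considered identical
DEDUP_TOL = 1e-5
#: |Re(lambda)| band flagged as marginal (fold neighbourhood)
MARGINAL_BAND = 1e-7
#: coordinates above this (negative) threshold count as physical
ADMISSIBLE_SLACK = -1e-9


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message records the failure time."""


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: ``states[k]`` is the state at ``times[k]``."""

    times: np.ndarray
    states: np.ndarray
    model_id: str
    inputs: tuple[float, float]
    final_residual: float
    converged: bool

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its linearization.

    ``stability`` is ``stable`` iff every eigenvalue real part is strictly
    negative with margin; near-axis eigenvalues set ``marginal=True`` and the
    point is labelled ``unstable`` for bookkeeping.  ``admissible`` is False
    when any coordinate is negative (mathematically valid, physically not).
    """

    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    residual_norm: float
    admissible: bool
    marginal: bool = False

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def _inputs_tuple(inputs) -> tuple[float, float]:
    if isinstance(inputs, EnvironmentalInputs):
        return inputs.as_tuple()
    if inputs is None:
        return (0.0, 0.0)
    t_e, t_z = inputs
    return (float(t_e), float(t_z))


def simulate(
    model,
    params: ParameterSet,
    inputs=None,
    x0: Sequence[float] | None = None,
    t_end: float = 200.0,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from ``x0`` over ``[0, t_end]``.

    The final point carries a convergence flag (``||rhs|| < 1e-6`` at the
    last time), useful when the trajectory is expected to settle on an
    attractor.
    """
    spec = get_model(model)
    if t_end <= 0:
        raise ModelInputError("t_end must be positive")
    x0 = np.zeros(spec.n_states) if x0 is None else np.asarray(x0, dtype=float)
    spec._check_state(x0)
    t_e, t_z = _inputs_tuple(inputs)
    p = spec.param_array(params)
    sol = solve_ivp(
        lambda t, y: spec.f(y, p, t_e, t_z),
        (0.0, float(t_end)),
        x0,
        method=method,
        jac=lambda t, y: spec.jac(y, p, t_e, t_z),
        t_eval=np.linspace(0.0, float(t_end), int(n_points)),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration of '{spec.model_id}' failed at t={sol.t[-1]:.6g}: "
            f"{sol.message}"
        )
    final_res = float(np.linalg.norm(spec.f(sol.y[:, -1], p, t_e, t_z)))
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        model_id=spec.model_id,
        inputs=(t_e, t_z),
        final_residual=final_res,
        converged=final_res < 1e-6,
    )


def _newton_polish(spec, x, p, t_e, t_z, tol=RESIDUAL_TOL, max_iter=60):
    """Damped Newton on the rhs; returns (x, ||f||) or (None, inf)."""
    x = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        f = spec.f(x, p, t_e, t_z)
        nf = np.linalg.norm(f)
        if not np.isfinite(nf):
            return None, np.inf
        if nf < tol:
            return x, nf
        try:
            step = np.linalg.solve(spec.jac(x, p, t_e, t_z), -f)
        except np.linalg.LinAlgError:
            return None, np.inf
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * step
            f_new = spec.f(x_new, p, t_e, t_z)
            if np.isfinite(f_new).all() and np.linalg.norm(f_new) < nf:
                break
            lam *= 0.5
        else:
            return None, np.inf
        x = x + lam * step
    f = spec.f(x, p, t_e, t_z)
    nf = float(np.linalg.norm(f))
    return (x, nf) if nf < tol else (None, np.inf)


def _classify(spec, x, p, t_e, t_z, residual) -> Equilibrium:
    eig = np.linalg.eigvals(spec.jac(x, p, t_e, t_z))
    re = eig.real
    marginal = bool(np.any(np.abs(re) < MARGINAL_BAND))
    stable = bool(np.all(re < 0) and not marginal)
    return Equilibrium(
        state=np.asarray(x, dtype=float),
        eigenvalues=eig,
        stability="stable" if stable else "unstable",
        residual_norm=float(residual),
        admissible=bool(np.all(x >= ADMISSIBLE_SLACK)),
        marginal=marginal,
    )


def find_equilibria(
    model,
    params: ParameterSet,
    inputs=None,
    box: np.ndarray | None = None,
    n_starts: int = 200,
    seed: int = 0,
    residual_tol: float = RESIDUAL_TOL,
    dedup_tol: float = DEDUP_TOL,
) -> list[Equilibrium]:
    """Multi-start equilibrium search.

    Starts are a seeded Latin-hypercube over ``box`` (default: the invariant
    box from :func:`bswitch.model_core.state_box`).  Roots with a negative
    coordinate are kept but flagged inadmissible.  Returns a deduplicated
    list sorted by the first state coordinate; an empty list (no exception)
    when no start converges.
    """
    spec = get_model(model)
    if n_starts < 1:
        raise ModelInputError("n_starts must be >= 1")
    t_e, t_z = _inputs_tuple(inputs)
    p = spec.param_array(params)
    if box is None:
        box = state_box(spec, params, (t_e, t_z))
    box = np.asarray(box, dtype=float)
    if box.shape != (spec.n_states, 2):
        raise ModelInputError(f"box must have shape ({spec.n_states}, 2)")

    sampler = qmc.LatinHypercube(d=spec.n_states, seed=seed)
    unit = sampler.random(n=n_starts)
    starts = box[:, 0] + unit * (box[:, 1] - box[:, 0])
    # the origin and box corners are useful deterministic extra starts
    extra = [box[:, 0], box[:, 1], 0.5 * (box[:, 0] + box[:, 1])]
    all_starts = np.vstack([starts, extra])

    found: list[np.ndarray] = []
    residuals: list[float] = []
    for x0 in all_starts:
        x, nf = _newton_polish(spec, x0, p, t_e, t_z, tol=residual_tol)
        if x is None:
            sol = root(
                lambda y: spec.f(y, p, t_e, t_z),
                x0,
                jac=lambda y: spec.jac(y, p, t_e, t_z),
                method="hybr",
            )
            if sol.success:
                x, nf = _newton_polish(spec, sol.x, p, t_e, t_z, tol=residual_tol)
        if x is None:
            continue
        for known in found:
            if np.max(np.abs(known - x)) <= dedup_tol:
                break
        else:
            found.append(x)
            residuals.append(nf)
    if not found:
        return []
    idx = sorted(range(len(found)), key=lambda i: tuple(np.round(found[i], 8)))
    return [_classify(spec, found[i], p, t_e, t_z, residuals[i]) for i in idx]


def classify_stability(model, params: ParameterSet, inputs, eq_state) -> Equilibrium:
    """Eigenvalue-based stability label for a point that is an equilibrium.

    Precondition: ``||rhs(eq_state)|| <= 1e-6``; otherwise a
    :class:`ModelInputError` is raised.
    """
    spec = get_model(model)
    x = spec._check_state(eq_state)
    t_e, t_z = _inputs_tuple(inputs)
    p = spec.param_array(params)
    res = float(np.linalg.norm(spec.f(x, p, t_e, t_z)))
    if res > 1e-6:
        raise ModelInputError(
            f"state is not an equilibrium (||rhs|| = {res:.3g} > 1e-6)"
        )
    return _classify(spec, x, p, t_e, t_z, res)


def nullclines_2d(
    model,
    params: ParameterSet,
    inputs=None,
    box: np.ndarray | None = None,
    n_grid: int = 400,
) -> dict[str, np.ndarray]:
    """Nullclines of a two-state model as polylines.

    For each state ``i`` the locus ``dx_i/dt = 0`` is traced by scanning the
    first coordinate on a grid and root-solving the scalar equation in the
    second coordinate (every sign change is bracketed and refined with
    Brent's method to machine precision, so returned points satisfy the
    defining equation to well below 1e-8).  Returns ``{state_name: (m, 2)
    array}`` in ``(x_state0, x_state1)`` coordinates.
    """
    spec = get_model(model)
    if spec.n_states != 2:
        raise ModelInputError(
            f"nullclines_2d requires a 2-state model, got '{spec.model_id}' "
            f"with {spec.n_states} states"
        )
    t_e, t_z = _inputs_tuple(inputs)
    p = spec.param_array(params)
    if box is None:
        box = state_box(spec, params, (t_e, t_z))
    box = np.asarray(box, dtype=float)

    out: dict[str, np.ndarray] = {}
    xs = np.linspace(box[0, 0], box[0, 1], n_grid)
    ys = np.linspace(box[1, 0], box[1, 1], n_grid)
    for i, name in enumerate(spec.states):
        pts: list[tuple[float, float]] = []
        # scan along x, solve for y (and the transpose, to catch vertical arcs)
        for scan, solve_axis, grid in ((xs, 1, ys), (ys, 0, xs)):
            for s in scan:
                def g(u, s=s, solve_axis=solve_axis):
                    st = np.empty(2)
                    st[1 - solve_axis] = s
                    st[solve_axis] = u
                    return spec.f(st, p, t_e, t_z)[i]

                vals = np.array([g(u) for u in grid])
                sign = np.sign(vals)
                for k in np.nonzero(np.diff(sign) != 0)[0]:
                    if sign[k] == 0:
                        u = grid[k]
                    else:
                        u = brentq(g, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-15)
                    pt = (s, u) if solve_axis == 1 else (u, s)
                    pts.append(pt)
        arr = np.array(sorted(set(pts))) if pts else np.empty((0, 2))
        out[name] = arr
    return out
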