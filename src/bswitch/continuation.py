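"""Pseudo-arclength continuation of equilibrium branches and fold detection.

Equilibrium curves ``F(x, lambda) = 0`` are traced in the extended space
``u = (x, lambda)`` with a tangent predictor and a Moore-Penrose-style
bordered Newton corrector, which carries the branch smoothly around
saddle-node (fold / limit) points.  Folds are detected by a sign change of
the tangent's parameter component and refined by bisection along the
predictor arclength until the parameter is resolved to 1e-8.  Eigenvalues of
the state Jacobian are recorded at every accepted point, so branches carry
their own stability information and can be scanned for Hopf crossings.

The free parameter may be one of the two environmental inputs (the usual
case: ``T_EBF1``) or any kinetic constant.  Branches may be traced through
negative parameter values -- the physical domain is only entered at the
classification stage, where points below ``admissible_min`` (default 0) are
flagged inaccessible.  A bistable diagram whose bounding fold lies in the
inaccessible region is an *irreversible* switch: the two stable branches are
disconnected over the physical domain, so the transition cannot be undone by
that parameter alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_core import (
    EnvironmentalInputs,
    ModelInputError,
    PARAM_NAMES,
    ParameterSet,
    get_model,
)
from .dynamics import MARGINAL_BAND, find_equilibria, _inputs_tuple

__all__ = [
    "FoldPoint",
    "HopfPoint",
    "Branch",
    "BifurcationDiagram",
    "continue_branch",
    "build_diagram",
    "classify_switch",
    "hopf_scan",
]

#: residual enforced on every accepted branch point
BRANCH_RESIDUAL_TOL = 1e-10
#: parameter resolution of refined fold points
FOLD_PARAM_TOL = 1e-8
#: default step-size control (initial, min, max)
STEP_INIT, STEP_MIN, STEP_MAX = 1e-2, 1e-6, 5e-2


@dataclass(frozen=True)
class FoldPoint:
    """A limit point: the branch tangent turns around in the parameter."""

    param: float
    state: np.ndarray
    tangent: np.ndarray


@dataclass(frozen=True)
class HopfPoint:
    """A point where a complex-conjugate eigenvalue pair crosses the axis."""

    param: float
    state: np.ndarray
    frequency: float


@dataclass
class Branch:
    """An ordered equilibrium branch versus one free parameter."""

    model_id: str
    free_param: str
    params: np.ndarray          # (m,)
    states: np.ndarray          # (m, n)
    stable: np.ndarray          # (m,) bool
    eigenvalues: np.ndarray     # (m, n) complex
    folds: list[FoldPoint] = field(default_factory=list)
    stop_reason: str = "range_covered"

    def __len__(self) -> int:
        return len(self.params)

    def stable_segments(self, state_min: "float | None" = 0.0
                        ) -> list[tuple[float, float]]:
        """Parameter intervals (lo, hi) of maximal stable runs.

        With ``state_min = 0`` (the default for expression-level models) a
        run consists of points that are both stable and physical (all
        coordinates above ``state_min``); branches traced into the
        negative-state region thus do not contribute spurious bistability.
        Pass ``state_min=None`` for systems whose states may be negative.  A run boundary produced by a stability flip
        across a recorded fold is snapped to the refined fold parameter
        (stability changes exactly at the fold for this fold-only system,
        but accepted points straddle it by up to one arclength step).
        """
        ok = self.stable.copy()
        if state_min is not None:
            ok &= np.all(self.states >= state_min - 1e-9, axis=1)
        segs = []
        m = len(self.params)
        i = 0
        while i < m:
            if ok[i]:
                j = i
                while j + 1 < m and ok[j + 1]:
                    j += 1
                lam = self.params[i : j + 1]
                lo, hi = float(lam.min()), float(lam.max())
                for k in (i - 1, j):  # indices of flip segments at both ends
                    if 0 <= k < m - 1 and ok[k] != ok[k + 1]:
                        k_in = k if ok[k] else k + 1
                        k_out = k + 1 if ok[k] else k
                        if (state_min is not None
                                and self.stable[k_out]
                                and np.any(
                                    self.states[k_out] < state_min - 1e-9)):
                            # still stable, cut by admissibility: locate the
                            # zero crossing of the offending coordinate(s)
                            s_in = self.states[k_in] - state_min
                            s_out = self.states[k_out] - state_min
                            lam_c = self.params[k_out]
                            ts = [
                                s_in[c] / (s_in[c] - s_out[c])
                                for c in np.nonzero(s_out < -1e-9)[0]
                                if s_in[c] != s_out[c]
                            ]
                            if ts:
                                t0 = min(ts)
                                lam_c = self.params[k_in] + t0 * (
                                    self.params[k_out] - self.params[k_in]
                                )
                            lo = min(lo, float(lam_c))
                            hi = max(hi, float(lam_c))
                        else:
                            f = self._fold_near(k)
                            if f is not None and (
                                state_min is None
                                or np.all(f.state >= state_min - 1e-9)
                            ):
                                lo = min(lo, f.param)
                                hi = max(hi, f.param)
                segs.append((lo, hi))
                i = j + 1
            else:
                i += 1
        return segs

    @property
    def has_stable(self) -> bool:
        return bool(np.any(self.stable))

    def _fold_near(self, k: int) -> "FoldPoint | None":
        """The recorded fold lying between accepted points k and k+1, if any."""
        a = np.concatenate([[self.params[k]], self.states[k]])
        b = np.concatenate([[self.params[k + 1]], self.states[k + 1]])
        slack = 2.0 * np.max(np.abs(b - a)) + 1e-9
        best, best_d = None, np.inf
        for f in self.folds:
            q = np.concatenate([[f.param], f.state])
            d = max(np.max(np.abs(q - a)), np.max(np.abs(q - b)))
            if d < slack and d < best_d:
                best, best_d = f, d
        return best


@dataclass
class BifurcationDiagram:
    """Merged branches of one model versus one free parameter."""

    model_id: str
    free_param: str
    param_range: tuple[float, float]
    branches: list[Branch]
    admissible_min: float = 0.0
    state_min: "float | None" = 0.0
    switch_class: str = "monostable"
    bistable_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def folds(self) -> list[FoldPoint]:
        return [f for b in self.branches for f in b.folds]

    @property
    def visible_folds(self) -> list[FoldPoint]:
        """Folds on branches that carry stable points -- the limit points one
        would observe when continuing from an observable (stable) state, as
        opposed to folds buried on entirely unstable branches."""
        return _dedup_folds(
            [f for b in self.branches if b.has_stable for f in b.folds]
        )

    def stable_count(self, lam: float, admissible_only: bool = True) -> int:
        """Number of stable equilibria at ``lam`` read off the branches."""
        count = 0
        for b in self.branches:
            count += _branch_stable_hits(b, lam, admissible_only)
        return count


# --------------------------------------------------------------------------
# problem wrapper: F(x, lambda), J_x, dF/dlambda for any free parameter
# --------------------------------------------------------------------------

class _Problem:
    def __init__(self, spec, params: ParameterSet, inputs, free_param: str):
        self.spec = spec
        self.free = free_param
        self.t_e, self.t_z = _inputs_tuple(inputs)
        self.base = spec.param_array(params)
        if free_param in ("T_EBF1", "T_ZNF521"):
            self.kind = "input"
            self.idx = 0 if free_param == "T_EBF1" else 1
        elif free_param in PARAM_NAMES:
            if free_param not in spec.required_parameters:
                raise ModelInputError(
                    f"parameter '{free_param}' does not enter model "
                    f"'{spec.model_id}'"
                )
            self.kind = "param"
            self.idx = spec.required_parameters.index(free_param)
        else:
            raise ModelInputError(f"unknown free parameter '{free_param}'")

    def _eval_args(self, lam: float):
        if self.kind == "input":
            t_e = lam if self.idx == 0 else self.t_e
            t_z = lam if self.idx == 1 else self.t_z
            return self.base, t_e, t_z
        p = self.base.copy()
        p[self.idx] = lam
        return p, self.t_e, self.t_z

    def f(self, x: np.ndarray, lam: float) -> np.ndarray:
        p, t_e, t_z = self._eval_args(lam)
        return self.spec.f(x, p, t_e, t_z)

    def jac_x(self, x: np.ndarray, lam: float) -> np.ndarray:
        p, t_e, t_z = self._eval_args(lam)
        return self.spec.jac(x, p, t_e, t_z)

    def df_dlam(self, x: np.ndarray, lam: float) -> np.ndarray:
        if self.kind == "input":
            p, t_e, t_z = self._eval_args(lam)
            return self.spec.df_dinput(x, p, t_e, t_z)[self.idx]
        h = 1e-6 * max(1.0, abs(lam))
        return (self.f(x, lam + h) - self.f(x, lam - h)) / (2 * h)


def _tangent(prob: _Problem, x, lam, t_prev):
    n = len(x)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = prob.jac_x(x, lam)
    a[:n, n] = prob.df_dlam(x, lam)
    a[n] = t_prev
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    t = np.linalg.solve(a, rhs)
    t /= np.linalg.norm(t)
    if np.dot(t, t_prev) < 0:
        t = -t
    return t


def _correct(prob: _Problem, u_pred, t_ref, tol=BRANCH_RESIDUAL_TOL, max_iter=10):
    """Newton on [F; t_ref.(u - u_pred)] = 0.  Returns corrected u or None."""
    n = len(u_pred) - 1
    u = u_pred.copy()
    for _ in range(max_iter):
        fx = prob.f(u[:n], u[n])
        if not np.isfinite(fx).all():
            return None
        res = np.linalg.norm(fx)
        ortho = np.dot(t_ref, u - u_pred)
        if res < tol and abs(ortho) < 1e-12:
            return u
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = prob.jac_x(u[:n], u[n])
        a[:n, n] = prob.df_dlam(u[:n], u[n])
        a[n] = t_ref
        rhs = np.concatenate([fx, [ortho]])
        try:
            du = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            return None
        u = u - du
        if np.linalg.norm(du) > 1e6:
            return None
    fx = prob.f(u[:n], u[n])
    return u if np.linalg.norm(fx) < tol else None


def _eig_stable(prob: _Problem, x, lam):
    eig = np.linalg.eigvals(prob.jac_x(x, lam))
    re = eig.real
    marginal = bool(np.any(np.abs(re) < MARGINAL_BAND))
    return eig, bool(np.all(re < 0) and not marginal)


def _refine_fold(prob: _Problem, u_a, t_a, h_ab) -> FoldPoint | None:
    """Bisect the predictor arclength from ``u_a`` for the zero of the
    tangent's parameter component."""
    s_a = np.sign(t_a[-1]) or 1.0
    lo, hi = 0.0, h_ab
    u_best, t_best = None, None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        u_m = _correct(prob, u_a + mid * t_a, t_a)
        if u_m is None:
            hi = mid  # shrink toward the known-good end
            continue
        t_m = _tangent(prob, u_m[:-1], u_m[-1], t_a)
        u_best, t_best = u_m, t_m
        if np.sign(t_m[-1]) == s_a:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13 or abs(t_m[-1]) < FOLD_PARAM_TOL:
            break
    if u_best is None:
        return None
    return FoldPoint(param=float(u_best[-1]), state=u_best[:-1].copy(),
                     tangent=t_best.copy())


def continue_branch(
    model,
    params: ParameterSet,
    inputs,
    free_param: str,
    start_state: Sequence[float],
    start_param: float,
    param_range: tuple[float, float],
    direction: int = +1,
    step_init: float = STEP_INIT,
    step_min: float = STEP_MIN,
    step_max: float = STEP_MAX,
    max_steps: int = 5000,
    state_bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> Branch:
    """Trace one equilibrium branch from a known equilibrium.

    ``direction`` picks the initial orientation of the parameter component
    of the tangent.  The branch stops when the parameter leaves
    ``param_range``, when the state leaves ``state_bounds`` (used to abandon
    branches that wander far outside the physically meaningful box), on
    step-size underflow, on divergence, or after ``max_steps`` accepted
    points; the stop condition is recorded.
    """
    spec = get_model(model)
    prob = _Problem(spec, params, inputs, free_param)
    lo, hi = float(min(param_range)), float(max(param_range))
    x0 = np.asarray(start_state, dtype=float)
    spec._check_state(x0)
    lam0 = float(start_param)

    # the start must be (polishable to) an equilibrium
    u = np.concatenate([x0, [lam0]])
    t_seed = np.zeros(len(u))
    t_seed[-1] = 1.0 if direction >= 0 else -1.0
    u_corr = _correct(prob, u, t_seed)
    if u_corr is None or abs(u_corr[-1] - lam0) > 1e-9:
        res = float(np.linalg.norm(prob.f(x0, lam0)))
        if res > 1e-8:
            raise ModelInputError(
                f"start is not an equilibrium at {free_param}={lam0:.6g} "
                f"(||rhs|| = {res:.3g})"
            )
        u_corr = u
    u = u_corr

    try:
        t = _tangent(prob, u[:-1], u[-1], t_seed)
    except np.linalg.LinAlgError:
        raise ModelInputError(
            "singular Jacobian at the start point; begin continuation away "
            "from a fold"
        ) from None

    lams, xs, stables, eigs = [], [], [], []
    folds: list[FoldPoint] = []

    def record(u_pt, t_pt):
        eig, stab = _eig_stable(prob, u_pt[:-1], u_pt[-1])
        lams.append(float(u_pt[-1]))
        xs.append(u_pt[:-1].copy())
        stables.append(stab)
        eigs.append(eig)

    record(u, t)
    h = float(step_init)
    stop = "max_steps"
    for _ in range(max_steps):
        accepted = False
        while h >= step_min:
            u_new = _correct(prob, u + h * t, t)
            if u_new is not None:
                accepted = True
                break
            h *= 0.5
        if not accepted:
            stop = "step_underflow"
            break
        try:
            t_new = _tangent(prob, u_new[:-1], u_new[-1], t)
        except np.linalg.LinAlgError:
            stop = "singular_jacobian"
            break
        if np.sign(t_new[-1]) != np.sign(t[-1]) and t[-1] != 0:
            fold = _refine_fold(prob, u, t, h)
            if fold is not None:
                folds.append(fold)
        u, t = u_new, t_new
        record(u, t)
        if np.max(np.abs(u[:-1])) > 1e6:
            stop = "diverged"
            break
        if not (lo - 1e-12 <= u[-1] <= hi + 1e-12):
            stop = "range_covered"
            break
        if state_bounds is not None and (
            np.any(u[:-1] < state_bounds[0]) or np.any(u[:-1] > state_bounds[1])
        ):
            stop = "left_state_bounds"
            break
        h = min(h * 1.3, step_max)

    return Branch(
        model_id=spec.model_id,
        free_param=free_param,
        params=np.array(lams),
        states=np.array(xs),
        stable=np.array(stables, dtype=bool),
        eigenvalues=np.array(eigs),
        folds=folds,
        stop_reason=stop,
    )


# --------------------------------------------------------------------------
# diagram assembly
# --------------------------------------------------------------------------

def _branch_stable_hits(branch: Branch, lam: float, admissible_only: bool,
                        admissible_min: float = 0.0) -> int:
    """Stable crossings of the vertical line ``param = lam`` on a branch."""
    hits = 0
    p = branch.params
    for i in range(len(p) - 1):
        a, b = p[i], p[i + 1]
        if (a - lam) * (b - lam) <= 0 and a != b:
            if branch.stable[i] and branch.stable[i + 1]:
                if admissible_only and np.any(
                    np.minimum(branch.states[i], branch.states[i + 1]) < -1e-9
                ):
                    continue
                hits += 1
    return max(hits, 0)


def _branch_distance(branch: Branch, lam: float, x: np.ndarray) -> float:
    """Distance from a point to the branch polyline in (param, state) space.

    Projects onto every segment (not just vertices), so a point lying on the
    curve between accepted steps still reads as near-zero.
    """
    if len(branch) == 0:
        return np.inf
    pts = np.column_stack([branch.params, branch.states])
    q = np.concatenate([[lam], x])
    d_vertex = np.min(np.max(np.abs(pts - q), axis=1))
    if len(branch) == 1:
        return float(d_vertex)
    a = pts[:-1]
    seg = pts[1:] - a
    denom = np.einsum("ij,ij->i", seg, seg)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", q - a, seg) / denom, 0.0, 1.0)
    proj = a + t[:, None] * seg
    d_seg = np.min(np.max(np.abs(proj - q), axis=1))
    return float(min(d_vertex, d_seg))


def build_diagram(
    model,
    params: ParameterSet,
    inputs,
    free_param: str,
    param_range: tuple[float, float],
    seed: int = 0,
    n_starts: int = 120,
    admissible_min: float = 0.0,
    state_min: "float | None" = 0.0,
    n_probes: int = 5,
    merge_tol: float = 1e-5,
) -> BifurcationDiagram:
    """Continuation from every equilibrium found at probe parameter values.

    Equilibria are located by multi-start search at ``n_probes`` evenly
    spaced values of the free parameter (endpoints, midpoint, quarters by
    default); each seeds a bidirectional continuation, and branches tracing
    an already-covered curve are merged away.
    """
    spec = get_model(model)
    lo, hi = float(min(param_range)), float(max(param_range))
    probes = np.linspace(lo, hi, n_probes)
    t_e, t_z = _inputs_tuple(inputs)

    # generous state box for abandoning physically meaningless branches:
    # wide enough to keep the (negative-state) inaccessible fold region
    from .model_core import state_box

    box_inputs = (
        (max(t_e, hi), t_z) if free_param == "T_EBF1"
        else (t_e, max(t_z, hi)) if free_param == "T_ZNF521"
        else (t_e, t_z)
    )
    box = state_box(spec, params, box_inputs, margin=1.0)
    bounds = (-2.0 * box[:, 1] - 1.0, 3.0 * box[:, 1] + 1.0)

    branches: list[Branch] = []
    for lam in probes:
        if free_param == "T_EBF1":
            probe_inputs = (lam, t_z)
        elif free_param == "T_ZNF521":
            probe_inputs = (t_e, lam)
        else:
            probe_inputs = (t_e, t_z)
        probe_params = (
            params if free_param in ("T_EBF1", "T_ZNF521")
            else params.replace(**{free_param: float(max(lam, 0.0))})
        )
        if free_param not in ("T_EBF1", "T_ZNF521") and lam < 0:
            continue  # kinetic constants are non-negative by contract
        eqs = find_equilibria(
            spec, probe_params, probe_inputs, n_starts=n_starts, seed=seed
        )
        for eq in eqs:
            if not eq.admissible:
                continue
            covered = any(
                _branch_distance(b, lam, eq.state) < 5e-3 for b in branches
            )
            if covered:
                continue
            legs = []
            for direction in (+1, -1):
                try:
                    legs.append(
                        continue_branch(
                            spec, params, inputs, free_param,
                            eq.state, lam, (lo, hi), direction=direction,
                            state_bounds=bounds,
                        )
                    )
                except ModelInputError:
                    continue
            if not legs:
                continue
            branches.append(_join_legs(legs))

    branches = _merge_duplicates(branches, merge_tol)
    diagram = BifurcationDiagram(
        model_id=spec.model_id,
        free_param=free_param,
        param_range=(lo, hi),
        branches=branches,
        admissible_min=admissible_min,
        state_min=state_min,
    )
    cls, intervals = classify_switch(diagram, admissible_min)
    diagram.switch_class = cls
    diagram.bistable_intervals = intervals
    return diagram


def _dedup_folds(folds: list[FoldPoint]) -> list[FoldPoint]:
    out: list[FoldPoint] = []
    for f in folds:
        if not any(
            abs(f.param - g.param) < 1e-6
            and np.max(np.abs(f.state - g.state)) < 1e-4
            for g in out
        ):
            out.append(f)
    return out


def _join_legs(legs: list[Branch]) -> Branch:
    if len(legs) == 1:
        return legs[0]
    a, b = legs
    # A leg that wraps around a fold can re-cover the other leg's territory;
    # keep only the longer leg when the shorter one traces a covered curve.
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) > 1:
        probes = np.linspace(0, len(short) - 1, min(len(short), 12)).astype(int)
        if all(
            _branch_distance(long_, short.params[i], short.states[i]) < 2e-2
            for i in probes
        ):
            return long_
    return Branch(
        model_id=a.model_id,
        free_param=a.free_param,
        params=np.concatenate([b.params[::-1], a.params[1:]]),
        states=np.vstack([b.states[::-1], a.states[1:]]),
        stable=np.concatenate([b.stable[::-1], a.stable[1:]]),
        eigenvalues=np.vstack([b.eigenvalues[::-1], a.eigenvalues[1:]]),
        folds=_dedup_folds(b.folds + a.folds),
        stop_reason=f"{b.stop_reason}|{a.stop_reason}",
    )


def _merge_duplicates(branches: list[Branch], tol: float) -> list[Branch]:
    kept: list[Branch] = []
    for b in sorted(branches, key=len, reverse=True):
        probes = np.linspace(0, len(b) - 1, min(len(b), 12)).astype(int)
        dup = False
        for k in kept:
            if all(
                _branch_distance(k, b.params[i], b.states[i]) < max(2e-2, tol)
                for i in probes
            ):
                dup = True
                break
        if not dup:
            kept.append(b)
    return kept


def classify_switch(
    diagram: BifurcationDiagram, admissible_min: float = 0.0
) -> tuple[str, list[tuple[float, float]]]:
    """Classify a diagram as monostable / reversible / irreversible bistable.

    Bistability is read from overlaps of stable branch segments.  The switch
    is *irreversible* when a bistable region exists over the admissible
    domain but (at least) one of its bounding folds lies below
    ``admissible_min``: the inaccessible fold disconnects the two stable
    branches, so the committed state cannot be left by moving the parameter
    within its physical range.
    """
    if not diagram.branches:
        raise ModelInputError("cannot classify an empty diagram")
    segs = []
    for b in diagram.branches:
        segs.extend(b.stable_segments(diagram.state_min))
    # union of pairwise overlaps = parameter set with >= 2 stable equilibria
    overlaps = []
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            lo = max(segs[i][0], segs[j][0])
            hi = min(segs[i][1], segs[j][1])
            if lo < hi:
                overlaps.append((lo, hi))
    full_bistable = _interval_union(overlaps)
    range_lo, range_hi = diagram.param_range
    admissible = [
        (max(lo, admissible_min, range_lo), min(hi, range_hi))
        for lo, hi in full_bistable
        if min(hi, range_hi) > max(admissible_min, range_lo)
    ]
    if not admissible:
        return "monostable", []
    # a fold below admissible_min bounding an admissible bistable interval
    # renders the switch one-way
    irreversible = False
    for lo, hi in full_bistable:
        if hi <= admissible_min:
            continue
        if lo < admissible_min - 1e-12:
            irreversible = True
    return (
        "irreversible_bistable" if irreversible else "reversible_bistable",
        admissible,
    )


def _interval_union(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= out[-1][1] + 1e-12:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(iv) for iv in out]


# --------------------------------------------------------------------------
# Hopf scan
# --------------------------------------------------------------------------

def hopf_scan(branch: Branch, im_tol: float = 1e-6) -> list[HopfPoint]:
    """Flag parameter values where a complex pair crosses the imaginary axis.

    Works from the eigenvalues stored along the branch: between consecutive
    points, a change in the number of complex eigenvalues with positive real
    part (by +-2) marks a crossing, located by linear interpolation of the
    pair's real part (resolution is therefore the local step size; the
    expected result for this network is an empty list, so no polishing
    beyond interpolation is applied).
    """
    out: list[HopfPoint] = []

    def pos_complex(eig):
        return int(np.sum((eig.real > 0) & (np.abs(eig.imag) > im_tol)))

    for i in range(len(branch) - 1):
        e0, e1 = branch.eigenvalues[i], branch.eigenvalues[i + 1]
        d = pos_complex(e1) - pos_complex(e0)
        if abs(d) >= 2:
            # interpolate on the real part of the crossing pair
            cplx0 = e0[np.abs(e0.imag) > im_tol]
            cplx1 = e1[np.abs(e1.imag) > im_tol]
            r0 = np.max(cplx0.real) if len(cplx0) else 0.0
            r1 = np.max(cplx1.real) if len(cplx1) else 0.0
            w = r0 / (r0 - r1) if r0 != r1 else 0.5
            lam = branch.params[i] + w * (branch.params[i + 1] - branch.params[i])
            state = branch.states[i] + w * (branch.states[i + 1] - branch.states[i])
            freq = float(np.max(np.abs(np.concatenate([cplx0.imag, cplx1.imag])))
                         ) if (len(cplx0) or len(cplx1)) else 0.0
            out.append(HopfPoint(param=float(lam), state=state, frequency=freq))
    return out
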