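"""Hypothesis screening, the feedback-module ladder, and reprogramming.

Three analyses build directly on the continuation machinery:

* ``screen_variants`` compares the nominal network (variant A, carrying the
  putative PAX5 -| ZNF521 repression) against the alternative hypotheses
  (B: repression through E2A; C: through IKAROS) and the straight ablation
  (b4 = 0), all under the reversible-switch condition ``T_ZNF521 = 0.12``.
  A variant "supports the switch" when its diagram is bistable.
* ``submodule_ladder`` classifies the seven core feedback modules in
  increasing order of complexity, from the bare EBF1/ZNF521 mutual
  inhibition (single steady state, one inaccessible limit point) to the
  EBF1/PAX5/ZNF521 loop that carries the irreversible commitment switch.
* ``reprogram`` simulates a piecewise-constant schedule of the two
  environmental inputs and labels the final state by its nearest attractor,
  testing in-silico reversion of a committed pro-B-like state back to the
  multipotent LMPP state (raise ZNF521 activation, lower EBF1 activation).

Attractor identity follows the expression program: LMPP has FLT3 and ZNF521
above the cross-attractor midpoint with EBF1, PAX5 and CD19 below; pro-B is
the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelInputError, ParameterSet, get_model
from .dynamics import Equilibrium, Trajectory, find_equilibria, simulate
from .continuation import BifurcationDiagram, build_diagram

__all__ = [
    "ReprogrammingPlan",
    "ReprogrammingResult",
    "ScreenReport",
    "label_attractors",
    "screen_variants",
    "submodule_ladder",
    "reprogram",
    "reversibility_map",
]

LMPP_MARKERS = ("FLT3", "ZNF521")
PROB_MARKERS = ("EBF1", "PAX5", "CD19")

SCREEN_VARIANTS = ("full_A", "full_B", "full_C", "full_no_pax5_znf521")
LADDER_MODULES = (
    "ebf1_znf521",
    "ebf1_e2a_pax5",
    "ebf1_pax5_flt3_il7r",
    "ebf1_e2a_pax5_flt3_il7r",
    "znf521_ebf1_pax5_flt3_il7r",
    "znf521_ebf1_e2a_pax5",
    "ebf1_pax5_znf521",
)


def label_attractors(model, equilibria: list[Equilibrium]) -> dict[str, np.ndarray]:
    """Assign LMPP / proB labels to stable attractors by expression program.

    With two attractors, markers are compared against the cross-attractor
    midpoint; an attractor matching neither program is labelled
    ``intermediate``.  With a single attractor the comparison uses the
    available marker ordering (FLT3+ZNF521 versus EBF1+PAX5+CD19 totals).
    """
    spec = get_model(model)
    stable = [e for e in equilibria if e.is_stable and e.admissible]
    if not stable:
        return {}

    def marker_ix(names):
        return [spec.state_index(n) for n in names if n in spec.states]

    il, ip = marker_ix(LMPP_MARKERS), marker_ix(PROB_MARKERS)
    out: dict[str, np.ndarray] = {}
    if len(stable) >= 2:
        states = np.array([e.state for e in stable])
        mid = 0.5 * (states.max(axis=0) + states.min(axis=0))
        for e in stable:
            s = e.state
            lmpp_like = all(s[i] > mid[i] for i in il) and all(
                s[i] < mid[i] for i in ip
            )
            prob_like = all(s[i] < mid[i] for i in il) and all(
                s[i] > mid[i] for i in ip
            )
            name = "LMPP" if lmpp_like else "proB" if prob_like else "intermediate"
            base, k = name, 2
            while name in out:
                name, k = f"{base}_{k}", k + 1
            out[name] = s
    else:
        s = stable[0].state
        lm = float(np.sum(s[il])) if il else 0.0
        pb = float(np.sum(s[ip])) if ip else 0.0
        out["LMPP" if lm > pb else "proB"] = s
    return out


@dataclass
class ScreenReport:
    """Per-variant (or per-module) switch classification table."""

    table: pd.DataFrame
    diagrams: dict[str, BifurcationDiagram] = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - display helper
        return f"ScreenReport:\n{self.table}"


def _diagram_row(name, diagram: BifurcationDiagram, n_admissible: int) -> dict:
    vf = diagram.visible_folds
    interval = diagram.bistable_intervals[0] if diagram.bistable_intervals else None
    return dict(
        name=name,
        switch_class=diagram.switch_class,
        n_stable_states=n_admissible,
        n_visible_folds=len(vf),
        fold_params=";".join(f"{f.param:.6g}" for f in vf),
        negative_folds=sum(1 for f in vf if f.param < 0),
        bistable_lo=interval[0] if interval else np.nan,
        bistable_hi=interval[1] if interval else np.nan,
        supports_switch=diagram.switch_class != "monostable",
    )


def screen_variants(
    params: ParameterSet | dict[str, ParameterSet],
    inputs=(0.0, 0.12),
    param_range=(-1.5, 3.0),
    seed: int = 0,
    n_starts: int = 60,
) -> ScreenReport:
    """T_EBF1 diagrams for the A/B/C variants and the b4 = 0 ablation.

    ``params`` is either one shared ParameterSet or a per-variant mapping;
    a variant with no parameters is marked ``unevaluated``.
    """
    rows, diagrams = [], {}
    for variant in SCREEN_VARIANTS:
        ps = params.get(variant) if isinstance(params, dict) else params
        if ps is None:
            rows.append(dict(name=variant, switch_class="unevaluated",
                             supports_switch=False))
            continue
        d = build_diagram(variant, ps, inputs, "T_EBF1", param_range,
                          seed=seed, n_starts=n_starts)
        eqs = find_equilibria(variant, ps, inputs, n_starts=n_starts, seed=seed)
        n_adm = sum(1 for e in eqs if e.is_stable and e.admissible)
        rows.append(_diagram_row(variant, d, n_adm))
        diagrams[variant] = d
    return ScreenReport(pd.DataFrame(rows).set_index("name"), diagrams)


def submodule_ladder(
    params: ParameterSet,
    inputs=(0.0, 0.0),
    param_range=(-1.5, 3.0),
    seed: int = 0,
    n_starts: int = 60,
) -> ScreenReport:
    """Classify the seven core feedback modules at nominal parameters."""
    rows, diagrams = [], {}
    for module in LADDER_MODULES:
        d = build_diagram(module, params, inputs, "T_EBF1", param_range,
                          seed=seed, n_starts=n_starts)
        eqs = find_equilibria(module, params, inputs, n_starts=n_starts,
                              seed=seed)
        n_adm = sum(1 for e in eqs if e.is_stable and e.admissible)
        rows.append(_diagram_row(module, d, n_adm))
        diagrams[module] = d
    return ScreenReport(pd.DataFrame(rows).set_index("name"), diagrams)


# --------------------------------------------------------------------------
# reprogramming
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReprogrammingPlan:
    """Piecewise-constant schedule of the environmental inputs.

    ``segments`` is a sequence of (duration, T_EBF1, T_ZNF521); input levels
    must be non-negative (reprogramming acts through physical inputs).
    ``start_label`` names the attractor of the first segment's condition to
    start from.
    """

    segments: tuple[tuple[float, float, float], ...]
    start_label: str = "proB"
    target_label: str = "LMPP"

    def __post_init__(self):
        if not self.segments:
            raise ModelInputError("empty reprogramming schedule")
        for k, (dur, t_e, t_z) in enumerate(self.segments):
            if dur <= 0:
                raise ModelInputError(f"segment {k}: duration must be > 0")
            if t_e < 0 or t_z < 0:
                raise ModelInputError(
                    f"segment {k}: input levels must be >= 0"
                )


@dataclass
class ReprogrammingResult:
    trajectory: Trajectory
    final_label: str
    success: bool
    segment_ends: list[np.ndarray]


def reprogram(
    params: ParameterSet,
    plan: ReprogrammingPlan,
    model="full_A",
    start_state: np.ndarray | None = None,
    start_inputs=(0.0, 0.0),
    n_starts: int = 80,
    seed: int = 0,
    points_per_segment: int = 120,
) -> ReprogrammingResult:
    """Simulate a reprogramming schedule and label the final state.

    The start is the attractor named ``plan.start_label`` under the resting
    condition ``start_inputs`` (or an explicit ``start_state``); the
    schedule's segments are then applied in order.  The final state is
    labelled by the nearest attractor (max-norm) of the *last* segment's
    equilibrium set; if the two nearest attractors are closer than a factor
    2 apart in distance the label is ``undecided``.
    """
    spec = get_model(model)
    if start_state is None:
        eqs0 = find_equilibria(spec, params, start_inputs, n_starts=n_starts,
                               seed=seed)
        labels0 = label_attractors(spec, eqs0)
        if plan.start_label not in labels0:
            raise ModelInputError(
                f"no '{plan.start_label}' attractor at inputs {start_inputs}; "
                f"found {sorted(labels0)}"
            )
        state = labels0[plan.start_label]
    else:
        state = np.asarray(start_state, dtype=float)

    times, states = [], []
    t_offset = 0.0
    seg_ends = []
    for dur, t_e, t_z in plan.segments:
        traj = simulate(spec, params, (t_e, t_z), state, t_end=dur,
                        n_points=points_per_segment)
        times.append(traj.times + t_offset)
        states.append(traj.states)
        t_offset += dur
        state = traj.final_state
        seg_ends.append(state.copy())

    full = Trajectory(
        times=np.concatenate(times),
        states=np.vstack(states),
        model_id=spec.model_id,
        inputs=plan.segments[-1][1:],
        final_residual=float(
            np.linalg.norm(
                spec.f(state, spec.param_array(params), *plan.segments[-1][1:])
            )
        ),
        converged=True,
    )

    end_eqs = find_equilibria(spec, params, plan.segments[-1][1:],
                              n_starts=n_starts, seed=seed)
    labels = label_attractors(spec, end_eqs)
    if not labels:
        return ReprogrammingResult(full, "undecided", False, seg_ends)
    dists = {
        name: float(np.max(np.abs(state - s))) for name, s in labels.items()
    }
    ranked = sorted(dists, key=dists.get)
    final = ranked[0]
    if len(ranked) > 1 and dists[ranked[1]] < 2.0 * dists[ranked[0]]:
        final = "undecided"
    return ReprogrammingResult(
        trajectory=full,
        final_label=final,
        success=final == plan.target_label,
        segment_ends=seg_ends,
    )


def reversibility_map(
    params: ParameterSet,
    t_znf521_values,
    model="full_A",
    param_range=(-1.5, 3.0),
    seed: int = 0,
    n_starts: int = 60,
) -> pd.DataFrame:
    """Switch class of the T_EBF1 diagram at each ZNF521 activation level."""
    rows = []
    for tz in t_znf521_values:
        d = build_diagram(model, params, (0.0, float(tz)), "T_EBF1",
                          param_range, seed=seed, n_starts=n_starts)
        vf = d.visible_folds
        interval = d.bistable_intervals[0] if d.bistable_intervals else None
        # commitment threshold: the largest visible fold = loss of the
        # multipotent state as T_EBF1 rises
        thr = max((f.param for f in vf), default=np.nan)
        rows.append(dict(
            t_znf521=float(tz),
            switch_class=d.switch_class,
            commitment_threshold=thr,
            bistable_lo=interval[0] if interval else np.nan,
            bistable_hi=interval[1] if interval else np.nan,
        ))
    return pd.DataFrame(rows).set_index("t_znf521")
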