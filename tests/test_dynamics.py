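"""Integration, equilibrium finding, stability and nullclines."""

import numpy as np
import pytest
import sympy as sp
from scipy.optimize import brentq

import bswitch as bw


@pytest.fixture(scope="module")
def decay_model():
    """One-species reduction dx/dt = i0 - mu1 x."""
    x = sp.Symbol("x_u")
    return bw.custom_model("decay", ["u"], [sp.Symbol("i0") - sp.Symbol("mu1") * x])


def ones(**over):
    vals = {n: 1.0 for n in bw.PARAM_NAMES}
    vals.update(over)
    return bw.ParameterSet(vals)


# -- simulate ---------------------------------------------------------------

def test_ikaros_trajectory_matches_closed_form(nominal):
    """x(t) = i0/mu1 + (x0 - i0/mu1) exp(-mu1 t), independent of the rest."""
    x0 = np.full(10, 0.5)
    traj = bw.simulate("full_A", nominal, (0, 0), x0, t_end=20.0, n_points=150)
    i0, mu1 = nominal["i0"], nominal["mu1"]
    exact = i0 / mu1 + (0.5 - i0 / mu1) * np.exp(-mu1 * traj.times)
    assert np.max(np.abs(traj.states[:, 0] - exact)) < 1e-6


def test_simulate_converges_to_committed_attractor(nominal, attractors_tz0):
    """A pro-B-side start relaxes onto the committed equilibrium."""
    prob = attractors_tz0["proB"]
    x0 = prob * 0.8 + 0.05
    traj = bw.simulate("full_A", nominal, (0, 0), x0, t_end=400.0)
    assert traj.converged
    assert np.max(np.abs(traj.final_state - prob)) < 1e-4


def test_znf521_activation_arrests_commitment(nominal, attractors_tz0):
    """With ZNF521 strongly activated, an LMPP-side start keeps the
    multipotent program: ZNF521/FLT3 stay above their pro-B values and
    EBF1/PAX5/CD19 below."""
    lmpp, prob = attractors_tz0["LMPP"], attractors_tz0["proB"]
    traj = bw.simulate("full_A", nominal, (0.0, 0.5), lmpp * 0.9, t_end=300.0)
    spec = bw.get_model("full_A")
    final = traj.final_state
    for name in ("ZNF521", "FLT3"):
        i = spec.state_index(name)
        assert final[i] > prob[i]
    for name in ("EBF1", "PAX5", "CD19"):
        i = spec.state_index(name)
        assert final[i] < prob[i]


def test_integrator_tolerance_refinement(nominal):
    """Halving tolerances moves the final state by less than the coarser
    tolerance (the integration is resolved)."""
    x0 = np.full(10, 0.3)
    coarse = bw.simulate("full_A", nominal, (0, 0), x0, t_end=50.0,
                         rtol=1e-6, atol=1e-8)
    fine = bw.simulate("full_A", nominal, (0, 0), x0, t_end=50.0,
                       rtol=5e-7, atol=5e-9)
    assert np.max(np.abs(coarse.final_state - fine.final_state)) < 1e-6


def test_simulate_rejects_bad_horizon(nominal):
    with pytest.raises(bw.ModelInputError):
        bw.simulate("full_A", nominal, (0, 0), np.zeros(10), t_end=-1.0)


# -- find_equilibria --------------------------------------------------------

def test_one_species_equilibrium(decay_model):
    ps = ones(i0=0.6, mu1=2.0)
    eqs = bw.find_equilibria(decay_model, ps, (0, 0),
                             box=np.array([[0.0, 2.0]]), n_starts=20, seed=1)
    assert len(eqs) == 1
    eq = eqs[0]
    assert eq.state[0] == pytest.approx(0.3, abs=1e-9)
    assert eq.is_stable
    assert eq.eigenvalues[0].real == pytest.approx(-2.0, abs=1e-9)


def test_two_node_single_lmpp_point(nominal):
    """The bare EBF1/ZNF521 module has a single admissible equilibrium at
    rest, with ZNF521 dominant (the multipotent point)."""
    eqs = bw.find_equilibria("ebf1_znf521", nominal, (0, 0), n_starts=150,
                             seed=2)
    adm = [e for e in eqs if e.admissible]
    assert len(adm) == 1
    e, z = adm[0].state
    assert adm[0].is_stable
    assert z > e


def brute_force_grid_roots(spec, params, inputs, box, n=50, tol=1e-4):
    """Oracle: scan a 50x50 grid for cells where both derivative components
    change sign, then polish each candidate with alternating cell-local
    bisections (solve f0 = 0 for y at fixed x, then f1 = 0 for x at fixed
    y) -- a nullcline-intersection search independent of the Newton path."""
    p = spec.param_array(params)
    t_e, t_z = inputs
    xs = np.linspace(box[0, 0], box[0, 1], n)
    ys = np.linspace(box[1, 0], box[1, 1], n)
    hx, hy = xs[1] - xs[0], ys[1] - ys[0]
    roots = []
    for i in range(n - 1):
        for j in range(n - 1):
            corners = [(xs[i], ys[j]), (xs[i + 1], ys[j]),
                       (xs[i], ys[j + 1]), (xs[i + 1], ys[j + 1])]
            vals = np.array([spec.f(np.array(c), p, t_e, t_z) for c in corners])
            if not (vals[:, 0].min() < 0 < vals[:, 0].max()
                    and vals[:, 1].min() < 0 < vals[:, 1].max()):
                continue
            rect = [xs[i], xs[i + 1], ys[j], ys[j + 1]]
            for _ in range(60):  # subdivision bisection to ~1e-10
                xl, xr, yl, yr = rect
                gx = np.linspace(xl, xr, 5)
                gy = np.linspace(yl, yr, 5)
                fv = np.array(
                    [[spec.f(np.array([a, b]), p, t_e, t_z) for b in gy]
                     for a in gx]
                )
                found = None
                for a in range(4):
                    for b in range(4):
                        sub = fv[a : a + 2, b : b + 2].reshape(4, 2)
                        if (sub[:, 0].min() <= 0 <= sub[:, 0].max()
                                and sub[:, 1].min() <= 0 <= sub[:, 1].max()):
                            found = [gx[a], gx[a + 1], gy[b], gy[b + 1]]
                            break
                    if found:
                        break
                if found is None:
                    break
                rect = found
                if rect[1] - rect[0] < 1e-11 and rect[3] - rect[2] < 1e-11:
                    break
            r = np.array([0.5 * (rect[0] + rect[1]), 0.5 * (rect[2] + rect[3])])
            # the subdivision resolves the root far below the 1e-4 comparison
            # tolerance; accept it on a residual consistent with that scale
            if np.linalg.norm(spec.f(r, p, t_e, t_z)) < 1e-6:
                if not any(np.max(np.abs(r - q)) < tol for q in roots):
                    roots.append(r)
    return roots


def test_two_node_equilibria_match_grid_oracle(nominal):
    spec = bw.get_model("ebf1_znf521")
    box = np.array([[0.0, 1.4], [0.0, 1.4]])
    oracle = brute_force_grid_roots(spec, nominal, (0.0, 0.0), box)
    eqs = bw.find_equilibria(spec, nominal, (0, 0), box=box, n_starts=200,
                             seed=3)
    adm = [e.state for e in eqs if e.admissible]
    assert len(adm) == len(oracle)
    for r in oracle:
        assert min(np.max(np.abs(r - s)) for s in adm) < 1e-4


def test_equilibrium_count_stabilizes_with_starts(nominal):
    """Admissible equilibria (those inside the searched box) are already all
    found at 200 starts; 2000 starts adds nothing and moves nothing."""
    a = bw.find_equilibria("ebf1_pax5_znf521", nominal, (0, 0),
                           n_starts=200, seed=4)
    b = bw.find_equilibria("ebf1_pax5_znf521", nominal, (0, 0),
                           n_starts=2000, seed=4)
    adm_a = [e for e in a if e.admissible]
    adm_b = [e for e in b if e.admissible]
    assert len(adm_b) >= len(adm_a)  # count non-decreasing in n_starts
    assert len(adm_a) == len(adm_b)
    for ea in adm_a:
        assert min(np.max(np.abs(ea.state - eb.state)) for eb in adm_b) < 1e-6


def test_equilibria_are_fixed_points_of_the_flow(nominal, attractors_tz0):
    for state in attractors_tz0.values():
        traj = bw.simulate("full_A", nominal, (0, 0), state, t_end=10.0)
        assert np.max(np.abs(traj.final_state - state)) < 1e-7


# -- classify_stability -----------------------------------------------------

def test_classify_rejects_non_equilibrium(nominal):
    with pytest.raises(bw.ModelInputError, match="not an equilibrium"):
        bw.classify_stability("full_A", nominal, (0, 0), np.full(10, 0.7))


def test_stable_points_attract_perturbations(nominal, attractors_tz0):
    rng = np.random.default_rng(11)
    for state in attractors_tz0.values():
        eq = bw.classify_stability("full_A", nominal, (0, 0), state)
        assert eq.is_stable
        x0 = state + rng.uniform(-1e-3, 1e-3, 10)
        traj = bw.simulate("full_A", nominal, (0, 0), np.clip(x0, 0, None),
                           t_end=200.0)
        assert np.max(np.abs(traj.final_state - state)) < 1e-4


def test_middle_branch_saddle_is_unstable(nominal):
    """The full diagram's middle branch between the attractors carries at
    least one positive eigenvalue."""
    eqs = bw.find_equilibria("full_A", nominal, (0, 0), n_starts=300, seed=6)
    saddles = [e for e in eqs if e.admissible and not e.is_stable]
    assert saddles
    assert any(np.max(e.eigenvalues.real) > 0 for e in saddles)


# -- nullclines -------------------------------------------------------------

def test_nullclines_definition_and_intersection(nominal):
    box = np.array([[0.0, 1.4], [0.0, 1.4]])
    nc = bw.nullclines_2d("ebf1_znf521", nominal, (0, 0), box=box, n_grid=150)
    spec = bw.get_model("ebf1_znf521")
    p = spec.param_array(nominal)
    for i, name in enumerate(spec.states):
        pts = nc[name]
        assert len(pts) > 10
        for pt in pts[::7]:
            assert abs(spec.f(pt, p, 0.0, 0.0)[i]) < 1e-8
    # intersections of the two nullclines = equilibria (single LMPP point)
    eqs = bw.find_equilibria(spec, nominal, (0, 0), box=box, n_starts=150,
                             seed=8)
    adm = [e for e in eqs if e.admissible]
    assert len(adm) == 1
    d_ebf1 = np.min(np.max(np.abs(nc["EBF1"] - adm[0].state), axis=1))
    d_znf = np.min(np.max(np.abs(nc["ZNF521"] - adm[0].state), axis=1))
    assert max(d_ebf1, d_znf) < 2e-2  # nearest polyline vertices bracket it


def test_nullclines_require_two_states(nominal):
    with pytest.raises(bw.ModelInputError, match="2-state"):
        bw.nullclines_2d("full_A", nominal, (0, 0))
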