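"""Pseudo-arclength continuation: fold oracles, classification, Hopf scan."""

import numpy as np
import pytest

import bswitch as bw
from bswitch.continuation import classify_switch

FOLD_LAM = 2.0 / (3.0 * np.sqrt(3.0))   # cubic normal form fold |lambda|
FOLD_X = 1.0 / np.sqrt(3.0)


def ones(**over):
    vals = {n: 1.0 for n in bw.PARAM_NAMES}
    vals.update(over)
    return bw.ParameterSet(vals)


def cubic_start(lam):
    roots = np.roots([1.0, 0.0, -1.0, -lam])
    real = [r.real for r in roots if abs(r.imag) < 1e-12]
    return min(real)  # lower branch


# -- continue_branch --------------------------------------------------------

def test_linear_branch_is_a_line_without_folds(linear_model):
    ps = ones(mu1=2.0)
    br = bw.continue_branch(linear_model, ps, (0, 0), "T_EBF1",
                            [0.25], 0.5, (-1.0, 1.0), direction=+1)
    assert br.folds == []
    assert np.allclose(br.states[:, 0], br.params / 2.0, atol=1e-9)
    br_back = bw.continue_branch(linear_model, ps, (0, 0), "T_EBF1",
                                 [0.25], 0.5, (-1.0, 1.0), direction=-1)
    assert br_back.folds == []


def test_cubic_fold_locations_to_1e6(cubic_model):
    ps = ones()
    br = bw.continue_branch(cubic_model, ps, (0, 0), "T_EBF1",
                            [cubic_start(-1.0)], -1.0, (-1.0, 1.0),
                            direction=+1)
    assert len(br.folds) == 2
    lams = sorted(f.param for f in br.folds)
    assert lams[0] == pytest.approx(-FOLD_LAM, abs=1e-6)
    assert lams[1] == pytest.approx(+FOLD_LAM, abs=1e-6)
    xs = sorted(float(f.state[0]) for f in br.folds)
    assert xs[0] == pytest.approx(-FOLD_X, abs=1e-6)
    assert xs[1] == pytest.approx(+FOLD_X, abs=1e-6)


def test_branch_reversal_reproduces_folds(cubic_model):
    """Continuing from the opposite end finds the same fold parameters."""
    ps = ones()
    fwd = bw.continue_branch(cubic_model, ps, (0, 0), "T_EBF1",
                             [cubic_start(-1.0)], -1.0, (-1.0, 1.0),
                             direction=+1)
    bwd = bw.continue_branch(cubic_model, ps, (0, 0), "T_EBF1",
                             [-cubic_start(-1.0)], 1.0, (-1.0, 1.0),
                             direction=-1)
    f_fwd = sorted(f.param for f in fwd.folds)
    f_bwd = sorted(f.param for f in bwd.folds)
    assert np.allclose(f_fwd, f_bwd, atol=1e-6)


def test_branch_points_satisfy_residual_bound(full_diagram_tz0, nominal):
    spec = bw.get_model("full_A")
    p = spec.param_array(nominal)
    for b in full_diagram_tz0.branches:
        sample = np.linspace(0, len(b) - 1, min(len(b), 40)).astype(int)
        for i in sample:
            res = np.linalg.norm(spec.f(b.states[i], p, b.params[i], 0.0))
            assert res <= 1e-8


def test_fold_rank_deficiency(full_diagram_tz0, nominal):
    """At a refined fold the state Jacobian is numerically singular."""
    spec = bw.get_model("full_A")
    p = spec.param_array(nominal)
    assert full_diagram_tz0.visible_folds
    for f in full_diagram_tz0.visible_folds:
        sv = np.linalg.svd(spec.jac(f.state, p, f.param, 0.0),
                           compute_uv=False)
        assert sv[-1] < 1e-6


def test_start_must_be_equilibrium(cubic_model):
    with pytest.raises(bw.ModelInputError, match="not an equilibrium"):
        bw.continue_branch(cubic_model, ones(), (0, 0), "T_EBF1",
                           [5.0], -1.0, (-1.0, 1.0))


def test_free_kinetic_parameter_continuation(nominal):
    """Continuation in a kinetic constant (not an input) follows the same
    contract; for IKAROS the equilibrium is the line x = i0/mu1."""
    eqs = bw.find_equilibria("full_A", nominal, (0, 0), n_starts=80, seed=0)
    start = [e for e in eqs if e.is_stable and e.admissible][0]
    br = bw.continue_branch("full_A", nominal, (0, 0), "i0",
                            start.state, nominal["i0"], (0.05, 0.6),
                            direction=+1)
    assert len(br) > 3
    ik = br.states[:, 0]
    assert np.allclose(ik, br.params / nominal["mu1"], atol=1e-8)


# -- diagrams and classification --------------------------------------------

def test_cubic_diagram_single_s_branch(cubic_model):
    d = bw.build_diagram(cubic_model, ones(), (0, 0), "T_EBF1", (-1.0, 1.0),
                        seed=1, n_starts=40, admissible_min=-1.0,
                        state_min=None)
    assert len(d.branches) == 1
    assert len(d.branches[0].folds) == 2
    cls, intervals = classify_switch(d, admissible_min=-1.0)
    assert cls == "reversible_bistable"
    assert len(intervals) == 1
    lo, hi = intervals[0]
    assert lo == pytest.approx(-FOLD_LAM, abs=1e-5)
    assert hi == pytest.approx(+FOLD_LAM, abs=1e-5)


def test_cubic_classification_is_irreversible_on_restricted_domain(cubic_model):
    """With admissible_min = 0 the left fold of the cubic becomes
    inaccessible and the same diagram classifies as irreversible."""
    d = bw.build_diagram(cubic_model, ones(), (0, 0), "T_EBF1", (-1.0, 1.0),
                        seed=1, n_starts=40, admissible_min=-1.0,
                        state_min=None)
    cls, intervals = classify_switch(d, admissible_min=0.0)
    assert cls == "irreversible_bistable"
    assert intervals[0][0] == pytest.approx(0.0, abs=1e-12)


def test_monotone_branch_is_monostable(linear_model):
    d = bw.build_diagram(linear_model, ones(), (0, 0), "T_EBF1", (0.1, 1.0),
                        seed=1, n_starts=20)
    assert d.switch_class == "monostable"
    assert d.bistable_intervals == []


def test_empty_diagram_rejected():
    from bswitch.continuation import BifurcationDiagram

    with pytest.raises(bw.ModelInputError, match="empty"):
        classify_switch(BifurcationDiagram("x", "T_EBF1", (0, 1), []))


def test_diagram_matches_dense_equilibrium_counts(full_diagram_tz0, nominal):
    """At 25 admissible parameter values the diagram's stable-state count
    equals an independent multi-start count."""
    lams = np.linspace(0.0, 2.9, 25)
    for lam in lams:
        expected = full_diagram_tz0.stable_count(lam)
        eqs = bw.find_equilibria("full_A", nominal, (lam, 0.0),
                                 n_starts=120, seed=9)
        direct = sum(1 for e in eqs if e.is_stable and e.admissible)
        assert direct == expected, f"lambda={lam}"


# -- hopf scan --------------------------------------------------------------

def test_hopf_scan_empty_on_linear_branch(linear_model):
    br = bw.continue_branch(linear_model, ones(), (0, 0), "T_EBF1",
                            [0.25], 0.5, (-1.0, 1.0), direction=-1)
    assert bw.hopf_scan(br) == []


def test_hopf_scan_finds_normal_form_crossing(hopf_model):
    br = bw.continue_branch(hopf_model, ones(), (0, 0), "T_EBF1",
                            [0.0, 0.0], -0.5, (-0.5, 0.5), direction=+1)
    pts = bw.hopf_scan(br)
    assert len(pts) == 1
    assert pts[0].param == pytest.approx(0.0, abs=1e-4)
    assert pts[0].frequency == pytest.approx(1.0, abs=1e-2)


def test_full_model_branches_have_no_hopf(full_diagram_tz0):
    """The commitment switch is organized purely by folds; eigenvalue
    tracking along the nominal branches flags no Hopf crossing."""
    for b in full_diagram_tz0.branches:
        assert bw.hopf_scan(b) == []
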