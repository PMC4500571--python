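"""Model definitions: catalogue, parameter I/O, rhs and Jacobian contracts."""

import io

import numpy as np
import pytest

import bswitch as bw
from bswitch.model_core import PARAM_NAMES, STATE_NAMES_FULL

BASAL = ("a0", "b0", "c0", "d0", "e0", "f0", "g0", "h0", "i0", "j0")


def all_ones():
    return bw.ParameterSet({n: 1.0 for n in PARAM_NAMES})


# -- catalogue --------------------------------------------------------------

def test_catalogue_contents():
    models = bw.list_models()
    assert len(models) == 11
    assert models["full_A"].n_states == 10
    assert models["ebf1_pax5_znf521"].n_states == 3
    assert models["ebf1_znf521"].n_states == 2
    assert models["znf521_ebf1_pax5_flt3_il7r"].n_states == 5
    for spec in models.values():
        # every symbol in the equations is in the required manifest
        assert set(spec.required_parameters) <= set(PARAM_NAMES)
        assert len(spec.states) == len(set(spec.states))


def test_unknown_model_rejected():
    with pytest.raises(bw.ModelInputError, match="unknown model"):
        bw.get_model("full_D")


# -- parameter sets ---------------------------------------------------------

def test_parameter_file_roundtrip(tmp_path, nominal):
    path = tmp_path / "params.txt"
    bw.save_parameters(nominal, path)
    again = bw.load_parameters(path)
    assert dict(again) == dict(nominal)


def test_parameter_file_full_set_of_symbols():
    text = "\n".join(f"{n} = 1.0" for n in PARAM_NAMES)
    ps = bw.load_parameters(io.StringIO(text))
    assert len(ps) == len(PARAM_NAMES) == 53
    assert all(v == 1.0 for v in ps.values())


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda d: d.pop("b4"), "b4"),
        (lambda d: d.update(zz9=1.0), "zz9"),
        (lambda d: d.update(a2=-0.5), "a2"),
        (lambda d: d.update(mu3=0.0), "mu3"),
    ],
)
def test_parameter_validation_names_offender(mutate, message):
    vals = {n: 1.0 for n in PARAM_NAMES}
    mutate(vals)
    with pytest.raises(bw.ParameterError, match=message):
        bw.ParameterSet(vals)


def test_parameter_file_errors_name_line():
    with pytest.raises(bw.ParameterError, match="non-numeric"):
        bw.load_parameters(io.StringIO("a0 = spam"))


# -- rhs --------------------------------------------------------------------

def test_rhs_zero_basal_zero_state_is_zero():
    ps = all_ones().replace(**{n: 0.0 for n in BASAL})
    for mid in bw.MODEL_IDS:
        spec = bw.get_model(mid)
        dx = bw.rhs(spec, np.zeros(spec.n_states), ps, (0, 0))
        assert np.allclose(dx, 0.0, atol=1e-15), mid


def test_rhs_ikaros_closed_form():
    ps = all_ones().replace(i0=2.0, mu1=1.0)
    x = np.linspace(0.1, 1.0, 10)
    x[0] = 2.0  # i0 / mu1
    dx = bw.rhs("full_A", x, ps, (0.3, 0.7))
    assert dx[0] == pytest.approx(0.0, abs=1e-14)


def test_rhs_residual_at_found_attractors(nominal, attractors_tz0):
    for state in attractors_tz0.values():
        dx = bw.rhs("full_A", state, nominal, (0, 0))
        assert np.max(np.abs(dx)) < 1e-8


def test_rhs_dimension_mismatch():
    with pytest.raises(bw.ModelInputError, match="length 10"):
        bw.rhs("full_A", np.zeros(3), all_ones(), (0, 0))


# -- jacobian ---------------------------------------------------------------

def test_jacobian_ikaros_row():
    ps = all_ones().replace(mu1=0.7)
    x = np.random.default_rng(0).uniform(0.1, 1.0, 10)
    J = bw.jacobian("full_A", x, ps, (0.2, 0.1))
    assert J[0, 0] == pytest.approx(-0.7)
    assert np.allclose(J[0, 1:], 0.0)


@pytest.mark.parametrize("mid", bw.MODEL_IDS)
def test_jacobian_matches_finite_differences(mid, nominal):
    rng = np.random.default_rng(12345)
    spec = bw.get_model(mid)
    h = 1e-6
    for trial in range(10):
        x = rng.uniform(0.05, 1.2, spec.n_states)
        scale = rng.uniform(0.3, 3.0)
        ps = bw.ParameterSet({n: nominal[n] * scale for n in PARAM_NAMES})
        inputs = tuple(rng.uniform(0, 0.5, 2))
        J = bw.jacobian(spec, x, ps, inputs)
        Jfd = np.empty_like(J)
        for j in range(spec.n_states):
            e = np.zeros(spec.n_states)
            e[j] = h
            Jfd[:, j] = (
                bw.rhs(spec, x + e, ps, inputs) - bw.rhs(spec, x - e, ps, inputs)
            ) / (2 * h)
        denom = np.maximum(np.abs(Jfd), 1.0)
        assert np.max(np.abs(J - Jfd) / denom) < 1e-5, (mid, trial)


def test_two_node_swap_symmetry():
    """With mirrored parameters and inputs, the EBF1/ZNF521 module is
    symmetric under exchanging the two states."""
    vals = {n: 1.0 for n in PARAM_NAMES}
    vals.update(a0=0.1, a1=2.0, a2=3.0, a4=5.0,
                b0=0.1, b1=2.0, b2=3.0, b3=5.0, mu7=1.3, mu8=1.3)
    ps = bw.ParameterSet(vals)
    x = np.array([0.4, 0.9])
    f = bw.rhs("ebf1_znf521", x, ps, (0.25, 0.25))
    f_sw = bw.rhs("ebf1_znf521", x[::-1], ps, (0.25, 0.25))
    assert np.allclose(f, f_sw[::-1], atol=1e-14)
    J = bw.jacobian("ebf1_znf521", x, ps, (0.25, 0.25))
    J_sw = bw.jacobian("ebf1_znf521", x[::-1], ps, (0.25, 0.25))
    assert np.allclose(J, J_sw[::-1, ::-1], atol=1e-14)


# -- structural invariants --------------------------------------------------

@pytest.mark.parametrize("mid", bw.MODEL_IDS)
def test_nonnegative_forward_invariance(mid, nominal):
    """On any face x_i = 0 of the orthant the i-th derivative is >= 0."""
    rng = np.random.default_rng(777)
    spec = bw.get_model(mid)
    for _ in range(25):
        x = rng.uniform(0, 1.5, spec.n_states)
        i = rng.integers(spec.n_states)
        x[i] = 0.0
        dx = bw.rhs(spec, x, nominal, tuple(rng.uniform(0, 1, 2)))
        assert dx[i] >= 0.0


def test_production_bound_and_trajectory_box(nominal):
    """Productions never exceed the analytic bound, so trajectories stay in
    the box [0, bound/mu] once inside it."""
    rng = np.random.default_rng(5)
    spec = bw.get_model("full_A")
    bounds = bw.production_bounds(spec, nominal, (0.5, 0.5))
    mus = nominal.to_array([f"mu{i}" for i in range(1, 11)])
    for _ in range(50):
        x = rng.uniform(0, 2.0, 10)
        dx = bw.rhs(spec, x, nominal, (0.5, 0.5))
        assert np.all(dx + mus * x <= bounds + 1e-12)
    box = bw.state_box(spec, nominal, (0.5, 0.5))
    x0 = box[:, 1] * 0.99
    traj = bw.simulate(spec, nominal, (0.5, 0.5), x0, t_end=60.0)
    assert np.all(traj.states >= -1e-9)
    assert np.all(traj.states <= box[:, 1] + 1e-6)


def test_submodule_consistency_where_forms_match(nominal):
    """Zeroing the couplings absent from a sub-module reproduces the printed
    sub-module rhs for the equations whose published forms coincide."""
    rng = np.random.default_rng(9)
    full = bw.get_model("full_A")
    sub = bw.get_model("ebf1_pax5_flt3_il7r")
    ps = nominal.replace(e1=0, e2=0, e3=0, e5=0, e6=0, f2=0, f3=0, c2=0, c3=0)
    for _ in range(10):
        x_full = rng.uniform(0.05, 1.0, 10)
        sub_state = np.array([
            x_full[full.state_index("EBF1")],
            x_full[full.state_index("PAX5")],
            x_full[full.state_index("FLT3")],
            x_full[full.state_index("IL7R")],
        ])
        f_full = bw.rhs(full, x_full, ps, (0.2, 0.0))
        f_sub = bw.rhs(sub, sub_state, ps, (0.2, 0.0))
        # PAX5, FLT3, IL7R productions coincide once the extra inputs vanish
        for sub_ix, name in [(1, "PAX5"), (2, "FLT3"), (3, "IL7R")]:
            assert f_sub[sub_ix] == pytest.approx(
                f_full[full.state_index(name)], abs=1e-12), name
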