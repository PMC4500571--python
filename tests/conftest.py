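"""Shared fixtures: toy oracle models and session-scoped heavy computations."""

import numpy as np
import pytest
import sympy as sp

import bswitch as bw


@pytest.fixture(scope="session")
def nominal():
    return bw.nominal_parameters()


@pytest.fixture(scope="session")
def cubic_model():
    """Saddle-node normal form dx/dt = lambda + x - x^3 (lambda = T_EBF1).

    Analytic folds: 1 - 3x^2 = 0 -> x = +-1/sqrt(3), lambda = -+2/(3 sqrt 3).
    """
    x = sp.Symbol("x_u")
    lam = sp.Symbol("T_EBF1")
    return bw.custom_model("cubic_nf", ["u"], [lam + x - x**3])


@pytest.fixture(scope="session")
def linear_model():
    """dx/dt = lambda - mu1 * x: branch is the line x = lambda/mu1, no folds."""
    x = sp.Symbol("x_u")
    lam = sp.Symbol("T_EBF1")
    mu = sp.Symbol("mu1")
    return bw.custom_model("linear_toy", ["u"], [lam - mu * x])


@pytest.fixture(scope="session")
def toggle_model():
    """Symmetric two-gene toggle with Hill-2 repression.

    du = a2/(1 + v^2) - mu1 u, dv = a2/(1 + u^2) - mu2 v.  With mu = 1 the
    switch is bistable exactly when a2 > 2 (the symmetric state u = v = s,
    s(1 + s^2) = a2, is a saddle iff 2 s^2 / (1 + s^2) > 1, i.e. s > 1).
    """
    u, v = sp.Symbol("x_u"), sp.Symbol("x_v")
    a2, mu1, mu2 = sp.Symbol("a2"), sp.Symbol("mu1"), sp.Symbol("mu2")
    return bw.custom_model(
        "toggle", ["u", "v"],
        [a2 / (1 + v**2) - mu1 * u, a2 / (1 + u**2) - mu2 * v],
    )


@pytest.fixture(scope="session")
def hopf_model():
    """Planar supercritical-Hopf normal form; the origin loses stability at
    lambda = 0 through a complex pair lambda +- i."""
    u, v = sp.Symbol("x_u"), sp.Symbol("x_v")
    lam = sp.Symbol("T_EBF1")
    r2 = u**2 + v**2
    return bw.custom_model(
        "hopf_nf", ["u", "v"],
        [lam * u - v - u * r2, u + lam * v - v * r2],
    )


@pytest.fixture(scope="session")
def attractors_tz0(nominal):
    """The two nominal attractors at (T_EBF1, T_ZNF521) = (0, 0)."""
    eqs = bw.find_equilibria("full_A", nominal, (0, 0), n_starts=150, seed=0)
    labels = bw.label_attractors("full_A", eqs)
    assert set(labels) == {"LMPP", "proB"}
    return labels


@pytest.fixture(scope="session")
def full_diagram_tz0(nominal):
    return bw.build_diagram("full_A", nominal, (0.0, 0.0), "T_EBF1",
                            (-1.5, 3.0), seed=5, n_starts=60)


@pytest.fixture(scope="session")
def screen_report(nominal):
    """Variant screen at the reversible-switch condition T_ZNF521 = 0.12."""
    return bw.screen_variants(nominal, (0.0, 0.12), seed=1, n_starts=50)


@pytest.fixture(scope="session")
def ladder_report(nominal):
    """Feedback-module ladder at nominal parameters."""
    return bw.submodule_ladder(nominal, (0.0, 0.0), seed=1, n_starts=50)
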