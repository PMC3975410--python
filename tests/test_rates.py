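"""Mechanism rate-law algebra against an independent symbolic oracle."""

from __future__ import annotations

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from glycodyn.rates import (
    EnzymeKinetics,
    InhibitionSpec,
    activation_factor,
    enzymatic_rate,
    glycolysis_outlet_rate,
)

# independent symbolic forms of the five rate laws
A, B, I = sp.symbols("A B I", positive=True)
KA, KB, KI, V = sp.symbols("K_A K_B K_I V", positive=True)

ORACLE = {
    "uni_uni": V * A / (KA + A),
    "random_bibi": V * A * B / (KA * KB + KA * B + KB * A + A * B),
    "ordered_bibi": V * A * B / (KA * KB + KB * A + A * B),
    "pingpong_bibi": V * A * B / (KA * B + KB * A + A * B),
    "pingpong_terter": V * A * B**2 / (
        2 * KA * KB * B + 2 * KB * A * B + KA * B**2 * (1 + I / KI)
        + KB**2 * A + A * B**2
    ),
}

HALF_SAT_FRACTION = {
    "uni_uni": sp.Rational(1, 2),
    "random_bibi": sp.Rational(1, 4),
    "ordered_bibi": sp.Rational(1, 3),
    "pingpong_bibi": sp.Rational(1, 3),
    "pingpong_terter": sp.Rational(1, 7),
}


def _kin(mech, kcat=10.0, e0=0.5, km_a=0.3, km_b=0.7, **kw):
    subs = ["S1"] if mech == "uni_uni" else ["S1", "S2"]
    km = {"S1": km_a} if mech == "uni_uni" else {"S1": km_a, "S2": km_b}
    return EnzymeKinetics(reaction_id="r", k_cat=kcat, E_0=e0, K_m=km, **kw), subs


@pytest.mark.parametrize("mech", list(ORACLE))
def test_half_saturation_point(mech):
    """At [A]=Km_A, [B]=Km_B (no inhibitor) the rate is kcat*E0 / {2,4,3,3,7}."""
    kin, subs = _kin(mech)
    conc = {"S1": 0.3, "S2": 0.7}
    v = enzymatic_rate(mech, kin, subs, conc)
    expected = float(HALF_SAT_FRACTION[mech]) * kin.k_cat * kin.E_0
    assert v == pytest.approx(expected, rel=1e-12)
    # the symbolic oracle agrees
    expr = ORACLE[mech].subs({A: sp.Rational(3, 10), KA: sp.Rational(3, 10),
                              B: sp.Rational(7, 10), KB: sp.Rational(7, 10),
                              I: 0, KI: 1, V: 5})
    assert float(expr) == pytest.approx(v, rel=1e-12)


@given(
    mech=st.sampled_from(list(ORACLE)),
    a=st.floats(1e-3, 50.0),
    b=st.floats(1e-3, 50.0),
    km_a=st.floats(1e-2, 10.0),
    km_b=st.floats(1e-2, 10.0),
)
@settings(max_examples=120, deadline=None, derandomize=True)
def test_rate_matches_symbolic_oracle(mech, a, b, km_a, km_b):
    """Numeric evaluation agrees with the independently written algebra."""
    kin, subs = _kin(mech, km_a=km_a, km_b=km_b)
    conc = {"S1": a, "S2": b}
    v = enzymatic_rate(mech, kin, subs, conc)
    expr = ORACLE[mech].subs({A: a, B: b, KA: km_a, KB: km_b, I: 0, KI: 1,
                              V: kin.k_cat * kin.E_0})
    assert v == pytest.approx(float(expr), rel=1e-9)
    assert 0.0 <= v <= kin.k_cat * kin.E_0 + 1e-12


@given(
    mech=st.sampled_from(["random_bibi", "ordered_bibi", "pingpong_bibi"]),
    b=st.floats(1e-2, 20.0),
    km_a=st.floats(1e-2, 5.0),
    km_b=st.floats(1e-2, 5.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bibi_reduces_to_uni_uni_when_cosubstrate_saturates(mech, b, km_a, km_b):
    """With the first substrate saturating, every bi-bi law collapses to
    Michaelis-Menten in the second substrate."""
    kin, subs = _kin(mech, km_a=km_a, km_b=km_b)
    huge = 1e9
    v = enzymatic_rate(mech, kin, subs, {"S1": huge, "S2": b})
    vmax = kin.k_cat * kin.E_0
    assert v == pytest.approx(vmax * b / (km_b + b), rel=1e-5)


def test_terter_saturation_limit_is_squared_monod():
    """The ter-ter law (two B per turnover) saturates as B^2/(B+K_B)^2."""
    kin, subs = _kin("pingpong_terter", km_a=0.4, km_b=0.9)
    vmax = kin.k_cat * kin.E_0
    for b in (0.5, 2.0, 7.0):
        v = enzymatic_rate("pingpong_terter", kin, subs, {"S1": 1e9, "S2": b})
        assert v == pytest.approx(vmax * b**2 / (b + 0.9) ** 2, rel=1e-5)


def test_competitive_inhibition_equals_km_scaling():
    """[I]=K_i on substrate A gives exactly the uninhibited rate with
    Km_A doubled (oracle comparison of the two parameterizations)."""
    for mech in ("uni_uni", "random_bibi", "ordered_bibi", "pingpong_bibi"):
        kin, subs = _kin(mech, km_a=0.3)
        conc = {"S1": 0.8, "S2": 1.1, "X": 5.0}
        inh = [InhibitionSpec("competitive", "X", K_i=5.0, target_substrate="S1")]
        v_inh = enzymatic_rate(mech, kin, subs, conc, inhibitions=inh,
                               inhibitor_concentrations={"X": 5.0})
        kin2, _ = _kin(mech, km_a=0.6)
        v_scaled = enzymatic_rate(mech, kin2, subs, conc)
        assert v_inh == pytest.approx(v_scaled, rel=1e-12)


def test_non_competitive_scales_whole_rate():
    kin, subs = _kin("random_bibi")
    conc = {"S1": 0.8, "S2": 1.1}
    inh = [InhibitionSpec("non_competitive", "X", K_i=2.0)]
    v0 = enzymatic_rate("random_bibi", kin, subs, conc)
    v = enzymatic_rate("random_bibi", kin, subs, conc, inhibitions=inh,
                       inhibitor_concentrations={"X": 4.0})
    assert v == pytest.approx(v0 / 3.0, rel=1e-12)


def test_un_competitive_scales_bound_term():
    """Uni-uni with [I]=K_i: v = Vmax*A/(Km + 2A)."""
    kin, subs = _kin("uni_uni", km_a=0.3)
    inh = [InhibitionSpec("un_competitive", "X", K_i=1.5)]
    v = enzymatic_rate("uni_uni", kin, subs, {"S1": 0.9}, inhibitions=inh,
                       inhibitor_concentrations={"X": 1.5})
    vmax = kin.k_cat * kin.E_0
    assert v == pytest.approx(vmax * 0.9 / (0.3 + 2 * 0.9), rel=1e-12)


def test_terter_inhibitor_matches_printed_denominator():
    """The ter-ter inhibitory factor sits on the Km_A*B^2 term only."""
    kin, subs = _kin("pingpong_terter", km_a=0.4, km_b=0.9)
    inh = [InhibitionSpec("un_competitive", "X", K_i=0.5)]
    a, b, i_conc = 1.3, 0.6, 0.8
    v = enzymatic_rate("pingpong_terter", kin, subs, {"S1": a, "S2": b},
                       inhibitions=inh, inhibitor_concentrations={"X": i_conc})
    expr = ORACLE["pingpong_terter"].subs({
        A: a, B: b, KA: 0.4, KB: 0.9, I: i_conc, KI: 0.5,
        V: kin.k_cat * kin.E_0,
    })
    assert v == pytest.approx(float(expr), rel=1e-12)


def test_activation_half_saturation_halves_rate():
    """Any mechanism with the activator at K_A runs at half the
    unactivated rate."""
    for mech in ("uni_uni", "pingpong_bibi"):
        kin, subs = _kin(mech)
        conc = {"S1": 0.5, "S2": 0.9}
        v0 = enzymatic_rate(mech, kin, subs, conc)
        v = enzymatic_rate(mech, kin, subs, conc,
                           activator_concentration=0.25, K_A=0.25)
        assert v == pytest.approx(v0 / 2, rel=1e-12)
    assert activation_factor(0.25, 0.25) == 0.5


def test_hill_exponent_replaces_saturation_factor():
    kin = EnzymeKinetics("r", k_cat=10.0, E_0=0.5, K_m={"S1": 0.3},
                         hill_n=2.5, hill_species="S1")
    a = 0.7
    v = enzymatic_rate("uni_uni", kin, ["S1"], {"S1": a})
    assert v == pytest.approx(5.0 * a**2.5 / (0.3**2.5 + a**2.5), rel=1e-12)


def test_domain_errors():
    kin, subs = _kin("uni_uni")
    with pytest.raises(ValueError):
        enzymatic_rate("uni_uni", kin, subs, {"S1": -0.1})
    with pytest.raises(KeyError):
        enzymatic_rate("uni_uni", kin, subs, {})
    with pytest.raises(ValueError):
        enzymatic_rate("no_such_mechanism", kin, subs, {"S1": 1.0})
    with pytest.raises(ValueError):
        EnzymeKinetics("r", k_cat=-1.0, E_0=0.5, K_m={"S1": 0.3})
    with pytest.raises(ValueError):
        InhibitionSpec("competitive", "X", K_i=1.0)  # no target


def test_glycolysis_outlet_shape():
    assert glycolysis_outlet_rate(0.0, 10.0, 0.5, 2.0) == 0.0
    assert glycolysis_outlet_rate(0.5, 10.0, 0.5, 2.0) == pytest.approx(5.0)
    assert glycolysis_outlet_rate(50.0, 10.0, 0.5, 2.0) == pytest.approx(10.0, rel=1e-3)
    with pytest.raises(ValueError):
        glycolysis_outlet_rate(-1.0, 10.0, 0.5, 2.0)
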