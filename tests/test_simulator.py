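"""Coupled simulator: initialization, integration and diagnostics."""

from __future__ import annotations

import numpy as np
import pytest

from glycodyn.config import default_config
from glycodyn.growth import FeedSchedule
from glycodyn.model import CoupledModel, SimulationSpec
from glycodyn.nucleotides import NUCLEOTIDES
from glycodyn.rates import v_uni_uni

from conftest import rel_diff


def test_steady_state_initialization(session_model, initial_state):
    """Measured species keep their configured values; the 27 unmeasured
    intermediates satisfy |dC/dt| < 1e-6 mM/h at t=0; everything >= 0."""
    m = session_model
    ss = m.steady_state_init()
    for s in m.net.measured_species:
        assert ss[s.id] == s.initial_concentration
    assert all(v >= 0 for v in ss.values())
    assert len(ss) == 34
    y0 = initial_state
    d = m.rhs(0.0, y0)
    unmeasured_idx = [12 + m._dyn_index[s] for s in m.unmeasured]
    assert np.max(np.abs(d[unmeasured_idx])) < 1e-6


def test_steady_state_is_a_fixed_point_of_itself(fresh_model):
    """Re-solving from a solved state returns the same concentrations."""
    ss1 = fresh_model.steady_state_init()
    ss2 = fresh_model.steady_state_init()
    for k in ss1:
        assert ss2[k] == pytest.approx(ss1[k], rel=1e-6, abs=1e-9)


def test_linear_chain_closed_form_steady_state():
    """For a source -> A -> B -> C chain of irreversible Michaelis-Menten
    steps, each intermediate has the closed form C* = Km*s/(Vmax - s).
    The numerically solved chain matches it."""
    from scipy.optimize import root

    s = 2.0  # source flux, mM/h
    vmax = np.array([5.0, 7.0, 11.0])
    km = np.array([0.3, 0.8, 1.5])

    def residual(x):
        a, b, c = np.maximum(x, 0)
        v1 = v_uni_uni(vmax[0], a, km[0])
        v2 = v_uni_uni(vmax[1], b, km[1])
        v3 = v_uni_uni(vmax[2], c, km[2])
        return [s - v1, v1 - v2, v2 - v3]

    sol = root(residual, [0.1, 0.1, 0.1], method="hybr", options={"xtol": 1e-14})
    closed = km * s / (vmax - s)
    np.testing.assert_allclose(sol.x, closed, rtol=1e-8)


def test_zero_cell_culture_freezes_intracellular_state(fresh_model):
    cfg = default_config()
    cfg.raw["culture"]["initial"]["Xv"] = 0.0
    from glycodyn.config import load_config
    m = CoupledModel(load_config(cfg.raw))
    nsd0 = {sp.id: (sp.initial_concentration or 0.5)
            for sp in m.net.dynamic_species}
    y0 = np.concatenate([
        m.initial_culture_vector(),
        [m.config.nucleotides0[n] for n in NUCLEOTIDES],
        [nsd0[s] for s in m.species],
    ])
    res = m.simulate(SimulationSpec(t_span=(0, 24), rtol=1e-8, atol=1e-12), y0=y0)
    for col in m.species:
        assert res.nsd[col].std() == pytest.approx(0.0, abs=1e-9)
    for col in NUCLEOTIDES:
        assert res.nucleotides[col].std() == pytest.approx(0.0, abs=1e-9)


def test_tolerance_convergence(session_model, initial_state):
    """Halving rtol changes the solution by far less than the coarser
    tolerance."""
    t_eval = [0.0, 30.0, 60.0, 90.0, 120.0]
    r1 = session_model.simulate(
        SimulationSpec(rtol=1e-6, atol=1e-10, output_times=t_eval),
        y0=initial_state.copy())
    r2 = session_model.simulate(
        SimulationSpec(rtol=5e-7, atol=1e-10, output_times=t_eval),
        y0=initial_state.copy())
    assert rel_diff(r1.nsd.values, r2.nsd.values, floor=1e-3) < 1e-5
    assert rel_diff(r1.culture.values, r2.culture.values, floor=1e-3) < 1e-5


def test_independent_stiff_methods_agree(default_run, radau_run):
    """LSODA (switching BDF) and Radau IIA agree to 1e-6 relative on all
    concentrations above a 1e-3 mM numerical floor."""
    assert rel_diff(radau_run.nsd.values, default_run.nsd.values, 1e-3) < 1e-6
    assert rel_diff(radau_run.nucleotides.values,
                    default_run.nucleotides.values, 1e-3) < 1e-6
    assert rel_diff(radau_run.culture["Xv"].values,
                    default_run.culture["Xv"].values, 1.0) < 1e-6


def test_grid_independence(session_model, initial_state):
    """Doubling the output density does not change values at shared times."""
    coarse = session_model.simulate(
        SimulationSpec(output_times=np.arange(0, 121, 24.0)),
        y0=initial_state.copy())
    dense = session_model.simulate(
        SimulationSpec(output_times=np.arange(0, 121, 12.0)),
        y0=initial_state.copy())
    shared = np.isin(dense.time, coarse.time)
    assert rel_diff(dense.nsd.values[shared], coarse.nsd.values, 1e-6) < 1e-9


def test_flux_closure(default_run):
    """Glucose inlet + salvage = glycolysis outlet + transports +
    accumulation at every output time (1e-6 relative)."""
    assert default_run.flux_closure_residual.max() < 1e-6


def test_non_negative_trajectories(default_run):
    assert default_run.nsd.values.min() > -1e-9
    assert default_run.nucleotides.values.min() > -1e-9
    assert default_run.culture[["Xv", "Xd", "Glc_ext", "Gln_ext", "mAb"]].values.min() > -1e-9


def test_titer_non_decreasing(default_run):
    """Specific productivity is growth-independent, so batch titer never
    falls while viable cells are present."""
    mab = default_run.culture["mAb"].values
    assert np.all(np.diff(mab) > -1e-12)


def test_glycolysis_fraction_definition(default_run):
    """The diagnostic equals outlet / inlet recomputed from the flux table."""
    f = default_run.fluxes
    expect = f["GLYC_OUT"] / f["influx"]
    np.testing.assert_allclose(default_run.glycolysis_fraction.values,
                               expect.values, rtol=1e-12)


def test_outlet_disabled_gives_zero_fraction(fresh_model):
    # initialize with the outlet active (no steady state exists without
    # it), then switch it off for the short forward run
    y0 = fresh_model.initial_state()
    fresh_model.set_parameters({"kcat:E_glyc": 1e-30})
    res = fresh_model.simulate(
        SimulationSpec(t_span=(0, 1.0), output_times=[0.0, 1.0]), y0=y0)
    assert res.glycolysis_fraction.max() < 1e-12


def test_integration_failure_reports_time(fresh_model):
    with pytest.raises(ValueError):
        SimulationSpec(rtol=-1.0)
    with pytest.raises(ValueError):
        SimulationSpec(output_times=[500.0])  # outside the span


def test_observable_lookup(default_run):
    assert default_run.observable("UDP-GlcNAc").shape == default_run.time.shape
    with pytest.raises(KeyError):
        default_run.observable("nope")
    tidy = default_run.tidy(["Xv", "UDP-Glc"])
    assert set(tidy["variable"]) == {"Xv", "UDP-Glc"}
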