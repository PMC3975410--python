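"""Sobol total-effect estimation against closed-form benchmarks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from glycodyn.sensitivity import (
    SobolResult,
    SobolSpec,
    nsd_gsa_spec,
    significant_parameters,
    sobol_total_indices,
)


def ishigami(x, a=7.0, b=0.1):
    return math.sin(x[0]) + a * math.sin(x[1]) ** 2 + b * x[2] ** 4 * math.sin(x[0])


def ishigami_total_closed_form(a=7.0, b=0.1):
    """Analytic total-effect indices on [-pi, pi]^3."""
    pi = math.pi
    v1 = 0.5 * (1 + b * pi**4 / 5) ** 2
    v2 = a**2 / 8
    v13 = b**2 * pi**8 * 8 / 225
    v = v1 + v2 + v13
    return np.array([(v1 + v13) / v, v2 / v, v13 / v])


def box(params, lo, hi):
    return {p: (lo, hi) for p in params}


def test_ishigami_total_indices_within_bootstrap_ci():
    spec = SobolSpec(parameters=["x1", "x2", "x3"],
                     bounds=box(["x1", "x2", "x3"], -math.pi, math.pi),
                     n_base=2**12, seed=5, log_scale=False, outputs=["y"])
    res = sobol_total_indices(lambda x: [ishigami(x)], spec)
    expect = ishigami_total_closed_form()
    for i in range(3):
        assert res.ci_lo[i, 0] <= expect[i] <= res.ci_hi[i, 0], (
            f"ST{i+1}: closed form {expect[i]:.4f} outside "
            f"[{res.ci_lo[i, 0]:.4f}, {res.ci_hi[i, 0]:.4f}]"
        )
        assert res.total[i, 0] == pytest.approx(expect[i], abs=0.05)


def test_inert_parameter_index_shrinks_with_n():
    """An input with zero coefficient has total index -> 0 as N grows."""

    def f(x):
        return [2.0 * x[0] - 0.7 * x[1] + 0.0 * x[2]]

    est = {}
    for n in (2**9, 2**11):
        spec = SobolSpec(parameters=["a", "b", "inert"],
                         bounds=box(["a", "b", "inert"], 0.0, 1.0),
                         n_base=n, seed=2, log_scale=False)
        res = sobol_total_indices(f, spec)
        est[n] = abs(res.total[2, 0])
        assert est[n] < 0.01
        assert res.ci_lo[2, 0] <= 0.005
    assert est[2**11] <= est[2**9] + 1e-4


def test_product_function_is_symmetric():
    spec = SobolSpec(parameters=["x1", "x2"], bounds=box(["x1", "x2"], 0, 1),
                     n_base=2**11, seed=9, log_scale=False)
    res = sobol_total_indices(lambda x: [x[0] * x[1]], spec)
    s1, s2 = res.total[:, 0]
    assert s1 == pytest.approx(s2, abs=0.05)
    # each index lies inside the other's bootstrap interval
    assert res.ci_lo[0, 0] <= s2 <= res.ci_hi[0, 0]
    assert res.ci_lo[1, 0] <= s1 <= res.ci_hi[1, 0]


def _result(indices, params=("p1", "p2", "p3")):
    arr = np.array(indices, dtype=float).reshape(-1, 1)
    return SobolResult(parameters=list(params), outputs=["y"], total=arr,
                       ci_lo=arr - 0.01, ci_hi=arr + 0.01, threshold=0.036)


def test_significance_filter_and_order():
    res = _result([0.04, 0.5, 0.01])
    hits = res.significant("y")
    assert hits == [("p2", 0.5), ("p1", 0.04)]
    assert significant_parameters(_result([0.001, 0.0, 0.02]))["y"] == []


def test_significance_deterministic_tie_break():
    res = _result([0.2, 0.2, 0.5])
    assert [p for p, _ in res.significant("y")] == ["p3", "p1", "p2"]


def test_design_size_and_reproducibility():
    spec = SobolSpec(parameters=["a", "b"], bounds=box(["a", "b"], 1.0, 10.0),
                     n_base=64, seed=4)
    from glycodyn.sensitivity import saltelli_design
    X1, X2 = saltelli_design(spec), saltelli_design(spec)
    assert X1.shape == (64 * (2 + 2), 2)
    np.testing.assert_array_equal(X1, X2)
    assert X1.min() >= 1.0 and X1.max() <= 10.0


def test_excessive_failures_reported():
    spec = SobolSpec(parameters=["a"], bounds={"a": (0.0, 1.0)}, n_base=64,
                     log_scale=False, max_bad_fraction=0.01)

    def bad(x):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="non-finite"):
        sobol_total_indices(bad, spec)

    def half_bad(x):
        if x[0] > 0.5:
            raise RuntimeError("boom")
        return [x[0]]

    with pytest.raises(RuntimeError, match="non-finite"):
        sobol_total_indices(half_bad, spec)


def test_default_gsa_vector_excludes_glycolysis_enzyme(session_model):
    """The configured free set gives a 46-parameter GSA vector without
    the glycolysis outlet enzyme level (it dominates every output)."""
    spec, _func = nsd_gsa_spec(session_model, n_base=64, seed=0)
    assert len(spec.parameters) == 46
    assert "E0:E_glyc" not in spec.parameters
    assert spec.threshold == pytest.approx(0.036)
    # outputs: the 7 measurable NSDs at the 5 reporting times
    assert len(spec.outputs) == 35
    for p in spec.parameters:
        lo, hi = spec.bounds[p]
        nominal = session_model.get_parameter(p)
        assert lo == pytest.approx(nominal / 10) and hi == pytest.approx(nominal * 10)


def test_spec_validation():
    with pytest.raises(ValueError):
        SobolSpec(parameters=[], bounds={}, n_base=64)
    with pytest.raises(ValueError):
        SobolSpec(parameters=["a"], bounds={"a": (1, 2)}, n_base=100)  # not 2^k
    with pytest.raises(KeyError):
        SobolSpec(parameters=["a"], bounds={}, n_base=64)
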