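"""Weighted least-squares parameter estimation against time-course data.

The estimation contract is the objective

    chi^2(theta) = sum_i ((y_model(t_i; theta) - y_i) / sd_i)^2

over all records of a tidy dataset.  Minimization uses bounded
trust-region least squares (`scipy.optimize.least_squares`, TRF) on
log10-transformed parameters by default, with Latin-hypercube multistart;
the nominal parameter vector is always included as the first start.
Simulation failures at a parameter point are penalized, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from glycodyn.model import CoupledModel, SimulationSpec
from glycodyn.timeseries import TimeSeriesDataset

GROWTH_OBSERVABLES = {"Xv", "Xd", "Glc_ext", "Gln_ext", "mAb"}

PENALTY = 1e3


@dataclass
class EstimationSpec:
    """Free parameter set, bounds, transform and optimizer settings."""

    free_parameters: Sequence[str]
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None
    bounds_factor: float = 10.0
    transform: str = "log10"  # or "linear"
    multistart: int = 1
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    max_nfev: Optional[int] = None
    xtol: float = 1e-10
    ftol: float = 1e-10
    #: finite-difference step for the Jacobian (relative, in transformed
    #: space); must sit well above the ODE integration noise
    diff_step: float = 1e-4

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("free parameter set must be non-empty")
        if self.transform not in ("log10", "linear"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass
class StartResult:
    x0: Dict[str, float]
    objective: float
    success: bool
    message: str = ""


@dataclass
class FitResult:
    parameters: Dict[str, float]
    objective: float
    residuals: pd.DataFrame  # time_h, variable, residual (weighted)
    starts: List[StartResult] = field(default_factory=list)

    @property
    def per_variable_sse(self) -> pd.Series:
        return (self.residuals["residual"] ** 2).groupby(
            self.residuals["variable"]
        ).sum()


def _resolve_bounds(spec: EstimationSpec, nominal: Dict[str, float]):
    lo, hi = [], []
    for name in spec.free_parameters:
        if spec.bounds and name in spec.bounds:
            a, b = spec.bounds[name]
        else:
            a = nominal[name] / spec.bounds_factor
            b = nominal[name] * spec.bounds_factor
        if a <= 0 or b <= a:
            raise ValueError(f"invalid bounds for {name}: ({a}, {b})")
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


class _Objective:
    """Weighted residual vector for one dataset/model pair."""

    def __init__(self, model: CoupledModel, data: TimeSeriesDataset,
                 spec: EstimationSpec):
        self.model = model
        self.spec = spec
        df = data.data
        self.times = np.sort(df["time_h"].unique())
        self.df = df
        self.n = len(df)
        vars_used = set(df["variable"].unique())
        unknown = vars_used - set(CoupledModel.OBSERVABLES)
        if unknown:
            raise ValueError(f"observables not provided by the model: {sorted(unknown)}")
        self.growth_only = (
            vars_used <= GROWTH_OBSERVABLES
            and all(p.startswith("growth:") for p in spec.free_parameters)
        )
        t_end = float(self.times.max())
        self.sim_spec = SimulationSpec(
            t_span=(0.0, max(t_end, 1e-6)), output_times=self.times,
            rtol=spec.rtol, atol=spec.atol,
        )

    def _predictions(self) -> Dict[str, np.ndarray]:
        if self.growth_only:
            df = self.model.simulate_growth(self.sim_spec)
            return {v: df[v].to_numpy() for v in GROWTH_OBSERVABLES}
        res = self.model.simulate(self.sim_spec)
        return {v: res.observable(v) for v in set(self.df["variable"])}

    def residuals(self, values: Dict[str, float]) -> np.ndarray:
        try:
            self.model.set_parameters(values)
            pred = self._predictions()
        except Exception:
            return np.full(self.n, PENALTY)
        t_index = {t: i for i, t in enumerate(self.times)}
        out = np.empty(self.n)
        for k, row in enumerate(self.df.itertuples(index=False)):
            y_hat = pred[row.variable][t_index[row.time_h]]
            out[k] = (y_hat - row.value) / row.sd
        if not np.all(np.isfinite(out)):
            return np.full(self.n, PENALTY)
        return out


def fit_parameters(
    data: TimeSeriesDataset,
    spec: EstimationSpec,
    model: CoupledModel,
) -> FitResult:
    """Estimate the free parameters of ``model`` against ``data``.

    Returns the best multistart solution; every start's objective is
    logged in ``FitResult.starts``.  Reproducible given ``spec.seed``.
    """
    nominal = {p: model.get_parameter(p) for p in spec.free_parameters}
    lo, hi = _resolve_bounds(spec, nominal)
    obj = _Objective(model, data, spec)

    if spec.transform == "log10":
        to_x = np.log10
        from_x = lambda x: 10.0**x
    else:
        to_x = np.asarray
        from_x = np.asarray

    xlo, xhi = to_x(lo), to_x(hi)
    names = list(spec.free_parameters)

    starts = [np.clip(to_x(np.array([nominal[p] for p in names])), xlo, xhi)]
    if spec.multistart > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(spec.multistart - 1)
        starts.extend(xlo + unit * (xhi - xlo))

    def fun(x):
        return obj.residuals(dict(zip(names, from_x(x))))

    best = None
    log: List[StartResult] = []
    for x0 in starts:
        try:
            sol = least_squares(
                fun, x0, bounds=(xlo, xhi), method="trf",
                x_scale="jac", diff_step=spec.diff_step,
                xtol=spec.xtol, ftol=spec.ftol,
                max_nfev=spec.max_nfev,
            )
            f = float(np.sum(sol.fun**2))
            # the penalty vector is the only way every residual equals
            # the sentinel exactly
            ok = not bool(np.all(sol.fun == PENALTY))
            log.append(StartResult(dict(zip(names, from_x(x0))), f, ok,
                                   sol.message))
            if ok and (best is None or f < best[0]):
                best = (f, sol.x)
        except Exception as exc:  # pragma: no cover - defensive
            log.append(StartResult(dict(zip(names, from_x(x0))), np.inf,
                                   False, str(exc)))
    if best is None:
        raise RuntimeError("all multistart optimizations failed")

    f_best, x_best = best
    params = dict(zip(names, np.atleast_1d(from_x(x_best)).astype(float)))
    r = obj.residuals(params)
    resid = pd.DataFrame({
        "time_h": obj.df["time_h"].to_numpy(),
        "variable": obj.df["variable"].to_numpy(),
        "residual": r,
    })
    model.set_parameters(params)
    return FitResult(parameters=params, objective=float(np.sum(r**2)),
                     residuals=resid, starts=log)


def objective_at(
    data: TimeSeriesDataset, spec: EstimationSpec, model: CoupledModel,
    values: Mapping[str, float],
) -> float:
    """Chi-square objective at an arbitrary parameter point."""
    obj = _Objective(model, data, spec)
    r = obj.residuals(dict(values))
    return float(np.sum(r**2))
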