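"""Sobol total-effect global sensitivity analysis.

Total-effect indices are estimated directly on the model with the
Saltelli radial design: two independent quasi-random matrices A and B of
``N`` points each (scrambled Sobol' sequence) plus the ``k`` hybrid
matrices ``AB_i`` (A with column i replaced from B), for ``N*(k+2)``
model evaluations in total.  The Jansen estimator

    ST_i = E[(f(A) - f(AB_i))^2] / (2 * Var f)

is used, with bootstrap confidence intervals over the sample rows.
Parameters are sampled log-uniformly within multiplicative ranges around
their nominal values by default (x/÷10), mirroring how kinetic constants
are uncertain on a ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc

DEFAULT_THRESHOLD = 0.036  # lowest experimental error of the NSD assays


@dataclass
class SobolSpec:
    """Design of one total-effect GSA run."""

    parameters: Sequence[str]
    bounds: Mapping[str, Tuple[float, float]]
    n_base: int = 256  # base sample size N (power of two)
    seed: int = 0
    log_scale: bool = True
    outputs: Sequence[str] = ()  # labels of the model output vector
    threshold: float = DEFAULT_THRESHOLD
    n_boot: int = 200
    max_bad_fraction: float = 0.05

    def __post_init__(self) -> None:
        if len(self.parameters) == 0:
            raise ValueError("parameter set must be non-empty")
        if self.n_base < 64:
            raise ValueError("base sample size must be >= 64")
        if self.n_base & (self.n_base - 1):
            raise ValueError("base sample size must be a power of two")
        if self.threshold <= 0:
            raise ValueError("significance threshold must be > 0")
        for p in self.parameters:
            if p not in self.bounds:
                raise KeyError(f"no bounds for parameter {p!r}")


@dataclass
class SobolResult:
    """Total-effect indices with bootstrap confidence intervals."""

    parameters: List[str]
    outputs: List[str]
    total: np.ndarray  # (k, n_outputs)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    threshold: float

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.parameters):
            for j, o in enumerate(self.outputs):
                rows.append({
                    "parameter": p, "output": o,
                    "total_index": self.total[i, j],
                    "ci_lo": self.ci_lo[i, j], "ci_hi": self.ci_hi[i, j],
                })
        return pd.DataFrame(rows)

    def significant(self, output: str,
                    threshold: Optional[float] = None) -> List[Tuple[str, float]]:
        thr = self.threshold if threshold is None else threshold
        j = self.outputs.index(output)
        hits = [(p, float(self.total[i, j]))
                for i, p in enumerate(self.parameters)
                if self.total[i, j] > thr]
        # descending by index, deterministic tie-break by parameter id
        return sorted(hits, key=lambda t: (-t[1], t[0]))


def saltelli_design(spec: SobolSpec) -> np.ndarray:
    """The (N*(k+2), k) matrix of parameter points in physical units."""
    k = len(spec.parameters)
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=spec.seed)
    ab = sampler.random(spec.n_base)
    A, B = ab[:, :k], ab[:, k:]
    blocks = [A, B]
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    unit = np.vstack(blocks)
    lo = np.array([spec.bounds[p][0] for p in spec.parameters])
    hi = np.array([spec.bounds[p][1] for p in spec.parameters])
    if np.any(lo <= 0) and spec.log_scale:
        raise ValueError("log-scale sampling needs positive bounds")
    if spec.log_scale:
        return 10 ** (np.log10(lo) + unit * (np.log10(hi) - np.log10(lo)))
    return lo + unit * (hi - lo)


def _jansen(fa: np.ndarray, fb: np.ndarray, fab: np.ndarray) -> np.ndarray:
    """Total indices from f(A) (N,m), f(B) (N,m), f(AB) (k,N,m)."""
    var = np.var(np.concatenate([fa, fb], axis=0), axis=0, ddof=1)
    var = np.where(var > 0, var, np.nan)
    num = 0.5 * np.mean((fa[None, :, :] - fab) ** 2, axis=1)
    return num / var[None, :]


def sobol_total_indices(
    func: Callable[[np.ndarray], np.ndarray],
    spec: SobolSpec,
) -> SobolResult:
    """Estimate total-effect indices of ``func`` over the parameter box.

    ``func`` maps one parameter vector (len k) to a 1-D output vector;
    non-finite outputs are tolerated up to ``max_bad_fraction`` of the
    design (offending rows are imputed with the sample mean), beyond
    which a ``RuntimeError`` reports the offending points.
    """
    k = len(spec.parameters)
    X = saltelli_design(spec)
    N = spec.n_base

    Y = []
    for x in X:
        try:
            Y.append(np.atleast_1d(np.asarray(func(x), dtype=float)))
        except Exception:
            Y.append(None)
    try:
        m = next(len(y) for y in Y if y is not None)
    except StopIteration:
        raise RuntimeError(
            f"all {len(X)} model evaluations non-finite or failing"
        ) from None
    out = np.full((len(X), m), np.nan)
    for i, y in enumerate(Y):
        if y is not None:
            out[i] = y
    bad = ~np.all(np.isfinite(out), axis=1)
    if bad.mean() > spec.max_bad_fraction:
        idx = np.where(bad)[0][:10]
        raise RuntimeError(
            f"{bad.sum()} of {len(X)} model evaluations non-finite; "
            f"first offending design rows: {idx.tolist()}"
        )
    if bad.any():
        col_mean = np.nanmean(out, axis=0)
        out[bad] = col_mean

    fa = out[:N]
    fb = out[N: 2 * N]
    fab = out[2 * N:].reshape(k, N, m)

    total = _jansen(fa, fb, fab)

    rng = np.random.default_rng(spec.seed + 1)
    boots = np.empty((spec.n_boot, k, m))
    for b in range(spec.n_boot):
        idx = rng.integers(0, N, size=N)
        boots[b] = _jansen(fa[idx], fb[idx], fab[:, idx, :])
    ci_lo = np.nanpercentile(boots, 2.5, axis=0)
    ci_hi = np.nanpercentile(boots, 97.5, axis=0)

    outputs = list(spec.outputs) if spec.outputs else [
        f"y{j}" for j in range(m)
    ]
    if len(outputs) != m:
        raise ValueError(
            f"{m} outputs returned but {len(outputs)} output labels given"
        )
    return SobolResult(
        parameters=list(spec.parameters), outputs=outputs,
        total=total, ci_lo=ci_lo, ci_hi=ci_hi, threshold=spec.threshold,
    )


def significant_parameters(
    res: SobolResult, threshold: Optional[float] = None
) -> Dict[str, List[Tuple[str, float]]]:
    """Per-output parameter rankings above the significance threshold."""
    return {o: res.significant(o, threshold) for o in res.outputs}


# ---------------------------------------------------------------------------
# model adapter
# ---------------------------------------------------------------------------

def nsd_gsa_spec(
    model,
    n_base: int = 256,
    seed: int = 0,
    output_times: Sequence[float] = (20.0, 40.0, 60.0, 80.0, 120.0),
    factor: float = 10.0,
    threshold: float = DEFAULT_THRESHOLD,
    parameters: Optional[Sequence[str]] = None,
) -> Tuple[SobolSpec, Callable[[np.ndarray], np.ndarray]]:
    """Default GSA setup: the estimation free set against the 7 NSDs.

    Parameters come from the configured estimation free set (46 by
    default; the glycolysis outlet enzyme level is excluded by
    construction since it dominates all outputs).  Ranges are x/÷
    ``factor`` around nominal, log-uniform.  The output vector is the
    concentration of each measured NSD at each requested time.
    """
    from glycodyn.model import SimulationSpec

    free = list(parameters if parameters is not None else
                model.config.estimation.get("free_parameters", []))
    excluded = set(model.config.sensitivity.get("excluded", []))
    free = [p for p in free if p not in excluded]
    nominal = {p: model.get_parameter(p) for p in free}
    bounds = {p: (v / factor, v * factor) for p, v in nominal.items()}
    nsds = [s.id for s in model.net.measured_species]
    outputs = [f"{sp}@{t:g}h" for sp in nsds for t in output_times]
    sim = SimulationSpec(
        t_span=(0.0, max(output_times)), output_times=list(output_times),
        rtol=1e-6, atol=1e-9,
    )
    # initial intermediate concentrations are data-anchored: they are
    # solved once at the nominal parameters and held fixed across the
    # design, so each evaluation is a single forward integration
    y0 = model.initial_state()

    def func(x: np.ndarray) -> np.ndarray:
        model.set_parameters(dict(zip(free, x)))
        res = model.simulate(sim, y0=y0.copy())
        return np.concatenate([res.nsd[sp].to_numpy() for sp in nsds])

    spec = SobolSpec(parameters=free, bounds=bounds, n_base=n_base,
                     seed=seed, outputs=outputs, threshold=threshold)
    return spec, func
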