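"""Synthetic pseudo-experimental datasets.

Because no raw measurements are distributed with the underlying study,
this module generates datasets with the same structure as the reported
experiments: a ~120 h batch hybridoma culture sampled on a sparse grid,
with the observable panel of the culture figures (extracellular glucose
and glutamine, viable and dead cell densities, mAb titer), the six
intracellular nucleotides and the seven measurable nucleotide sugars.

Noise is multiplicative log-normal with a class-specific CV (cell counts
10%, extracellular metabolites 5%, nucleotides/NSDs 8%), and the recorded
standard deviation of NSD records never falls below 0.036 mM — the
detection-limit-scale error floor of the chromatographic assay.  Values
below a per-variable detection threshold are censored: flagged and
reported at the threshold, not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from glycodyn.model import CoupledModel, SimulationSpec
from glycodyn.timeseries import TimeSeriesDataset

CELL_VARS = ("Xv", "Xd")
METABOLITE_VARS = ("Glc_ext", "Gln_ext", "mAb")
NUCLEOTIDE_VARS = ("ADP", "AMP", "ATP", "CTP", "GTP", "UTP")
NSD_VARS = ("CMP-Neu5Ac", "GDP-Fuc", "GDP-Man", "UDP-GalNAc",
            "UDP-Gal", "UDP-Glc", "UDP-GlcNAc")

NSD_SD_FLOOR = 0.036  # mM


@dataclass
class SyntheticSpec:
    """Sampling design and noise model of one synthetic experiment."""

    times: Sequence[float] = tuple(np.arange(0.0, 121.0, 12.0))
    cv_cells: float = 0.10
    cv_metabolites: float = 0.05
    cv_nucleotides: float = 0.08
    cv_nsd: float = 0.08
    nsd_sd_floor: float = NSD_SD_FLOOR
    seed: int = 0
    truth_overlay: Dict[str, float] = field(default_factory=dict)
    detection_limits: Dict[str, float] = field(
        default_factory=lambda: {"GDP-Fuc": 0.036}
    )
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("cv_cells", "cv_metabolites", "cv_nucleotides", "cv_nsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def cv_of(self, var: str) -> float:
        if var in CELL_VARS:
            return self.cv_cells
        if var in METABOLITE_VARS:
            return self.cv_metabolites
        if var in NUCLEOTIDE_VARS:
            return self.cv_nucleotides
        if var in NSD_VARS:
            return self.cv_nsd
        raise KeyError(f"unknown observable {var!r}")


@dataclass
class SyntheticDataset:
    """A noisy dataset plus the truth that generated it."""

    dataset: TimeSeriesDataset
    truth_parameters: Dict[str, float]
    truth_trajectories: pd.DataFrame  # tidy noise-free values at sample times


def generate_dataset(
    spec: SyntheticSpec,
    model: CoupledModel,
    variables: Optional[Sequence[str]] = None,
) -> SyntheticDataset:
    """Simulate at the truth parameters and add measurement noise.

    Multiplicative log-normal noise: ``y_obs = y * exp(sigma*z - sigma^2/2)``
    with ``sigma^2 = ln(1 + CV^2)``, so the expectation of each record
    equals the noise-free value.  Reproducible given ``spec.seed``.
    """
    if spec.truth_overlay:
        model.set_parameters(spec.truth_overlay)
    truth_params = {}
    est = model.config.estimation.get("free_parameters", [])
    for p in est:
        truth_params[p] = model.get_parameter(p)
    truth_params.update(spec.truth_overlay)

    times = np.asarray(sorted(spec.times), dtype=float)
    sim = SimulationSpec(t_span=(float(times[0]), float(times[-1])),
                         output_times=times, rtol=spec.rtol, atol=spec.atol)
    res = model.simulate(sim)

    variables = list(variables) if variables is not None else list(
        CELL_VARS + METABOLITE_VARS + NUCLEOTIDE_VARS + NSD_VARS
    )
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    for var in variables:
        y = res.observable(var)
        cv = spec.cv_of(var)
        sigma = np.sqrt(np.log1p(cv * cv))
        z = rng.standard_normal(len(times))
        noisy = y * np.exp(sigma * z - 0.5 * sigma * sigma)
        limit = spec.detection_limits.get(var)
        for t, y_true, y_obs in zip(times, y, noisy):
            sd = cv * abs(y_obs)
            if var in NSD_VARS:
                sd = max(sd, spec.nsd_sd_floor)
            censored = limit is not None and y_obs < limit
            rows.append({
                "time_h": t, "variable": var,
                "value": limit if censored else y_obs,
                "sd": max(sd, 1e-12), "censored": censored,
            })
            truth_rows.append({"time_h": t, "variable": var, "value": y_true})
    ds = TimeSeriesDataset(pd.DataFrame(rows))
    return SyntheticDataset(
        dataset=ds,
        truth_parameters=truth_params,
        truth_trajectories=pd.DataFrame(truth_rows),
    )
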