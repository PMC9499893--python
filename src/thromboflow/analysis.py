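"""Post-processing: scaled activated-platelet levels, region aggregation,
clinical-comparison statistics and parameter sensitivity sweeps.

The model output is reported as *scaled AP*: the per-mille increase of the
activated-platelet concentration over its background value,
``1000 * (phi_a - phi_a0) / phi_a0``.  Region-averaged scaled AP is the
quantity compared against observed thrombus frequencies by ordinary least
squares, and region thrombus counts are tested against a uniform-by-chance
distribution with Pearson's chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, DegenerateRegressionError,
                     InsufficientDataError, ModelCollapseError, ValidationError)
from .fields import (FlowField, ModelParameters, RegionMask, SpeciesState,
                     StructuredGrid2D, uniform_state)
from .transport import SteadyResult, run_to_steady

__all__ = [
    "scaled_ap",
    "region_volume_average",
    "region_report",
    "linreg_r2",
    "chi2_uniform",
    "Case",
    "run_case",
    "sensitivity_sweep",
    "DEFAULT_SWEEP",
    "RegressionResult",
    "Chi2Result",
]


def scaled_ap(phi_a, phi_a0: float):
    """Per-mille increase of phi_a over the background value phi_a0.

    May be negative where phi_a dips below background.
    """
    if phi_a0 <= 0:
        raise ValidationError(f"phi_a0 must be positive, got {phi_a0}")
    return 1000.0 * (np.asarray(phi_a, dtype=float) - phi_a0) / phi_a0


def region_volume_average(field, regions: RegionMask, grid: StructuredGrid2D,
                          volumes: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Volume-weighted mean of a cell field over every named region.

    ``volumes`` optionally supplies per-cell volumes (defaults to the
    uniform grid cell volume, for which the weighted mean reduces to the
    plain mean).
    """
    field = grid.check_field(field, "field")
    if volumes is None:
        volumes = np.full(grid.shape, grid.cell_volume)
    else:
        volumes = grid.check_field(volumes, "volumes")
    out = {}
    for rid in regions.region_ids:
        mask = regions.mask(rid)
        if not np.any(mask):
            raise ConfigurationError(f"region {regions.names[rid]} is empty")
        w = volumes[mask]
        out[regions.names[rid]] = float(np.sum(field[mask] * w) / np.sum(w))
    return out


def region_report(state: SpeciesState, regions: RegionMask, grid: StructuredGrid2D,
                  phi_a0: float) -> pd.DataFrame:
    """Per-region table: name, volume, volume-averaged phi_a, scaled AP."""
    avgs = region_volume_average(state.phi_a, regions, grid)
    vols = regions.volumes(grid)
    rows = [
        {
            "region": regions.names[rid],
            "volume": vols[rid],
            "phi_a_avg": avgs[regions.names[rid]],
            "scaled_ap": float(scaled_ap(avgs[regions.names[rid]], phi_a0)),
        }
        for rid in regions.region_ids
    ]
    return pd.DataFrame(rows)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def linreg_r2(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with R^2 and the slope p value.

    ``R^2 = 1 - SS_res / SS_tot``; the p value is the two-sided test of a
    non-zero slope from the t distribution with n-2 degrees of freedom.
    A constant y yields R^2 = 0 by the sum-of-squares convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("predictor x is constant")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0)
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue**2), float(fit.pvalue))


class Chi2Result(NamedTuple):
    statistic: float
    p_value: float
    dof: int


def chi2_uniform(counts: Sequence[float]) -> Chi2Result:
    """Pearson chi-squared test of counts against the equal-probability null."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise InsufficientDataError("need counts for at least 2 categories")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if counts.sum() <= 0:
        raise InsufficientDataError("total count must be positive")
    stat, p = stats.chisquare(counts)
    return Chi2Result(float(stat), float(p), counts.size - 1)


@dataclass
class Case:
    """A complete runnable configuration: geometry, flow, regions, parameters."""

    grid: StructuredGrid2D
    flow: FlowField
    regions: RegionMask
    params: ModelParameters
    boundary_spec: Optional[Dict[str, str]] = None
    tau_field: Optional[np.ndarray] = None
    state0: Optional[SpeciesState] = None


def run_case(case: Case, params: Optional[ModelParameters] = None) -> SteadyResult:
    """Run a case to steady state, optionally with substituted parameters."""
    p = case.params if params is None else params
    state0 = case.state0 if case.state0 is not None else uniform_state(case.grid, p)
    return run_to_steady(state0, case.grid, case.flow, p, case.regions,
                         boundary_spec=case.boundary_spec, tau_field=case.tau_field)


#: The published sensitivity protocol: power-law constants at +-10%
#: (alpha additionally +-20%) and background activated fractions of
#: 1, 5, 10 and 20% of the fixed total platelet pool.
DEFAULT_SWEEP = {
    "alpha": [-0.2, -0.1, 0.1, 0.2],
    "beta": [-0.1, 0.1],
    "C": [-0.1, 0.1],
    "background_fraction": [0.01, 0.05, 0.10, 0.20],
    "use_reynolds_stress": [True],
}

_SWEEP_KEYS = ("alpha", "beta", "C", "background_fraction",
               "use_reynolds_stress", "ADP_t", "t_ADP")


def _perturbed_params(params: ModelParameters, name: str, value) -> ModelParameters:
    if name in ("alpha", "beta", "C"):
        base = getattr(params, name)
        return params.with_(**{name: base * (1.0 + value)})
    if name == "background_fraction":
        total = params.total_platelets0
        return params.with_(phi_a0=value * total, phi_b0=(1.0 - value) * total)
    if name == "use_reynolds_stress":
        return params.with_(use_reynolds_stress=bool(value))
    if name in ("ADP_t", "t_ADP"):
        return params.with_(**{name: value})
    raise ConfigurationError(f"unknown sweep parameter {name!r}; expected one of {_SWEEP_KEYS}")


def sensitivity_sweep(case: Case, sweep_spec: Optional[Dict[str, list]] = None) -> pd.DataFrame:
    """Run the baseline and every requested perturbation; tabulate scaled AP.

    ``sweep_spec`` maps parameter names to perturbation lists: fractional
    changes for ``alpha``/``beta``/``C``, activated fractions of the fixed
    total pool for ``background_fraction``, absolute values for ``ADP_t``/
    ``t_ADP``, booleans for ``use_reynolds_stress``.  Percent deviations are
    signed, relative to the unperturbed run of the same case.  Collapsed
    runs are recorded as failed rows and the sweep continues.
    """
    if sweep_spec is None:
        sweep_spec = DEFAULT_SWEEP
    for name in sweep_spec:
        if name not in _SWEEP_KEYS:
            raise ConfigurationError(f"unknown sweep parameter {name!r}; expected one of {_SWEEP_KEYS}")

    rows = []

    def append_rows(parameter, perturbation, params, baseline=None):
        try:
            result = run_case(case, params)
        except ModelCollapseError:
            for rid in case.regions.region_ids:
                rows.append({"parameter": parameter, "perturbation": perturbation,
                             "region": case.regions.names[rid], "scaled_ap": np.nan,
                             "pct_deviation": np.nan, "status": "collapsed"})
            return None
        avgs = result.region_averages()
        scaled = {name: float(scaled_ap(v, params.phi_a0)) for name, v in avgs.items()}
        for name, value in scaled.items():
            if baseline is None:
                pct = 0.0
            else:
                b = baseline[name]
                pct = 0.0 if value == b else (100.0 * (value - b) / b if b != 0 else np.inf)
            rows.append({"parameter": parameter, "perturbation": perturbation,
                         "region": name, "scaled_ap": value,
                         "pct_deviation": pct, "status": "ok"})
        return scaled

    baseline = append_rows("baseline", 0.0, case.params)
    if baseline is None:
        raise ModelCollapseError("baseline run collapsed; nothing to compare against")
    for parameter, values in sweep_spec.items():
        for value in values:
            append_rows(parameter, value, _perturbed_params(case.params, parameter, value),
                        baseline)
    return pd.DataFrame(rows, columns=["parameter", "perturbation", "region",
                                       "scaled_ap", "pct_deviation", "status"])
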