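"""Local and global univariate sensitivity analyses of the binding model.

Local: each rate constant and each initial concentration is raised 10%
above baseline (10 nM bispecific dose, 5e4 IL-6R and 5e4 IL-8R per cell),
and the change in the time-integral (AUC over 0-2 h) of the ternary-bound
and total-bound receptor is expressed per percent of parameter change.

Global: each rate constant is varied over +/- 2 decades around its fitted
value and the fractional receptor occupancy at 24 h is recorded per dose.

When kon_6R, kon_8R or kon_6R_star moves, the dependent kon_8R_star is by
default re-derived from the cycle constraint ("rederive"); a "frozen" mode
leaves it untouched instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import presets
from .assay import AssayProtocol, simulate_assay, summarize_occupancy
from .reaction_model import (
    CellLine,
    ModelOptions,
    RateConstantSet,
    apply_cycle_constraint,
)

__all__ = [
    "RATE_PARAMETERS",
    "CONCENTRATION_PARAMETERS",
    "SensitivityResult",
    "perturb_rates",
    "local_sensitivity",
    "global_sensitivity",
]

RATE_PARAMETERS = (
    "kon_6R",
    "kon_8R",
    "kon_6R_star",
    "kon_8R_star",
    "koff_6R",
    "koff_8R",
)
CONCENTRATION_PARAMETERS = ("antibody", "il6r", "il8r")

_BASELINE_DOSE = 10.0
_BASELINE_RECEPTORS = 5.0e4


@dataclass(frozen=True)
class SensitivityResult:
    """One parameter/metric entry of a sensitivity table."""

    parameter: str
    perturbation: float  # relative change (local) or log10 offset (global)
    output_metric: str
    value: float
    sensitivity: float = float("nan")  # %output change / %parameter change


def perturb_rates(
    params: RateConstantSet,
    name: str,
    factor: float,
    constraint_mode: str = "rederive",
) -> RateConstantSet:
    """Scale one rate constant by ``factor``.

    In "rederive" mode the dependent kon_8R_star is recomputed from the
    cycle constraint whenever one of its parents moves; perturbing
    kon_8R_star itself sets it directly (breaking the cycle, as a frozen
    perturbation necessarily does).
    """
    if constraint_mode not in ("rederive", "frozen"):
        raise ValueError(f"unknown constraint mode {constraint_mode!r}")
    if name not in RATE_PARAMETERS:
        raise ValueError(f"unknown rate parameter {name!r}")
    new = replace(params, **{name: getattr(params, name) * factor})
    if constraint_mode == "rederive" and name in ("kon_6R", "kon_8R", "kon_6R_star"):
        new = replace(
            new,
            kon_8R_star=apply_cycle_constraint(
                new.kon_6R, new.kon_8R, new.kon_6R_star
            ),
        )
    return new


def _auc_metrics(
    params: RateConstantSet,
    dose: float,
    il6r: float,
    il8r: float,
    duration: float,
    points: int,
    options: ModelOptions | None,
) -> dict[str, float]:
    cell = CellLine("sensitivity", il6r, il8r)
    protocol = AssayProtocol.analysis(horizon=duration)
    res = simulate_assay(
        presets.BS1, cell, dose, params, protocol, options,
        points_per_phase=points,
    )
    ternary_bound = 2.0 * res.states[:, 5]
    total_bound = res.states[:, 3] + res.states[:, 4] + ternary_bound
    return {
        "AUC_ternary": float(np.trapezoid(ternary_bound, res.time)),
        "AUC_total_bound": float(np.trapezoid(total_bound, res.time)),
    }


def local_sensitivity(
    params: RateConstantSet,
    dose: float = _BASELINE_DOSE,
    il6r: float = _BASELINE_RECEPTORS,
    il8r: float = _BASELINE_RECEPTORS,
    duration: float = 7200.0,
    perturbation: float = 0.10,
    constraint_mode: str = "rederive",
    points: int = 400,
    options: ModelOptions | None = None,
) -> pd.DataFrame:
    """+10% univariate perturbations, AUC-based, over a 2 h horizon.

    Returns a long table with columns parameter, perturbation,
    output_metric, baseline, value, sensitivity (%change of AUC per %change
    of parameter).
    """
    baseline = _auc_metrics(params, dose, il6r, il8r, duration, points, options)
    rows = []
    scenarios: list[tuple[str, RateConstantSet, float, float, float]] = []
    for name in RATE_PARAMETERS:
        scenarios.append(
            (name, perturb_rates(params, name, 1.0 + perturbation, constraint_mode),
             dose, il6r, il8r)
        )
    scenarios.append(("antibody", params, dose * (1.0 + perturbation), il6r, il8r))
    scenarios.append(("il6r", params, dose, il6r * (1.0 + perturbation), il8r))
    scenarios.append(("il8r", params, dose, il6r, il8r * (1.0 + perturbation)))

    for name, p, d, r6, r8 in scenarios:
        metrics = _auc_metrics(p, d, r6, r8, duration, points, options)
        for metric, value in metrics.items():
            base = baseline[metric]
            if perturbation == 0.0:
                sens = 0.0
            else:
                sens = ((value - base) / base) / perturbation if base != 0 else np.nan
            rows.append(
                {
                    "parameter": name,
                    "perturbation": perturbation,
                    "output_metric": metric,
                    "baseline": base,
                    "value": value,
                    "sensitivity": sens,
                }
            )
    return pd.DataFrame(rows)


def global_sensitivity(
    params: RateConstantSet,
    doses: Sequence[float] = (1.0, 10.0, 100.0),
    parameters: Iterable[str] = RATE_PARAMETERS,
    offsets: np.ndarray | None = None,
    il6r: float = _BASELINE_RECEPTORS,
    il8r: float = _BASELINE_RECEPTORS,
    horizon: float = 86400.0,
    constraint_mode: str = "rederive",
    options: ModelOptions | None = None,
) -> pd.DataFrame:
    """Occupancy at 24 h versus +/- 2-decade univariate rate offsets.

    Returns a long table (parameter, offset, dose_nM, metric, value) with
    metrics ``frac_ternary`` and ``frac_total``.  Receptor levels are
    initial values, not clamped, over the simulation.
    """
    if offsets is None:
        offsets = np.linspace(-2.0, 2.0, 41)
    cell = CellLine("sensitivity", il6r, il8r)
    protocol = AssayProtocol.analysis(horizon=horizon)
    rows = []
    for name in parameters:
        for offset in offsets:
            p = perturb_rates(params, name, 10.0 ** float(offset), constraint_mode)
            for dose in doses:
                res = simulate_assay(
                    presets.BS1, cell, dose, p, protocol, options,
                    points_per_phase=2,
                )
                occ = summarize_occupancy(res.terminal_state, cell, presets.BS1)
                rows.append(
                    {
                        "parameter": name,
                        "offset": float(offset),
                        "dose_nM": dose,
                        "metric": "frac_ternary",
                        "value": occ.frac_ternary,
                    }
                )
                rows.append(
                    {
                        "parameter": name,
                        "offset": float(offset),
                        "dose_nM": dose,
                        "metric": "frac_total",
                        "value": occ.frac_total,
                    }
                )
    return pd.DataFrame(rows)
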