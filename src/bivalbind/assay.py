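"""Binding-assay simulation and derived occupancy summaries.

Implements the two protocols used throughout the analysis:

* the *fitting* protocol — 2 h association, instantaneous washout of free
  antibody, then a 15 min detection incubation; and
* the *analysis* protocol — 24 h of free association with no washout.

plus comparative experiments: dose x receptor-expression grids, the
monovalent-restricted variant (cross-linking rates zeroed), and bispecific
vs monospecific-combination relative binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .reaction_model import (
    IL6R,
    IL8R,
    AntibodyConstruct,
    BindingNetwork,
    CellLine,
    ModelOptions,
    RateConstantSet,
    SpeciesState,
    build_rhs,
)

__all__ = [
    "AssayProtocol",
    "SimulationError",
    "SimulationResult",
    "OccupancySummary",
    "simulate_assay",
    "simulate_combination",
    "summarize_occupancy",
    "combination_occupancy",
    "total_bound_antibody",
    "dose_receptor_grid",
    "restrict_monovalent",
    "RelativeBinding",
    "relative_binding",
]

_DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class AssayProtocol:
    """Timing and washout semantics of a binding assay.

    All times in seconds.  ``washout_time`` defaults to the association
    duration; ``horizon`` defaults to ``washout_time + detection_duration``
    when a washout occurs, else to the association duration.
    """

    association_duration: float = 7200.0
    washout: bool = True
    washout_time: float | None = None
    detection_duration: float = 900.0
    horizon: float | None = None
    cells_per_well: float = 1.0e5
    clamp_washout: bool = False

    def __post_init__(self) -> None:
        if self.association_duration <= 0:
            raise ValueError("association_duration must be positive")
        wt = self.resolved_washout_time
        if self.washout and wt > self.resolved_horizon:
            raise ValueError("washout_time must not exceed horizon")

    @property
    def resolved_washout_time(self) -> float:
        return (
            self.washout_time
            if self.washout_time is not None
            else self.association_duration
        )

    @property
    def resolved_horizon(self) -> float:
        if self.horizon is not None:
            return self.horizon
        if self.washout:
            return self.resolved_washout_time + self.detection_duration
        return self.association_duration

    @classmethod
    def fitting(cls, **kwargs) -> "AssayProtocol":
        """2 h association + washout + 15 min detection (default values)."""
        return cls(**kwargs)

    @classmethod
    def analysis(cls, horizon: float = 86400.0, **kwargs) -> "AssayProtocol":
        """Long-horizon free association without washout (default 24 h)."""
        return cls(
            association_duration=horizon, washout=False, horizon=horizon, **kwargs
        )


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: np.ndarray | None = None,
                 last_time: float | None = None) -> None:
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclass
class SimulationResult:
    """Time grid plus species trajectories for one assay simulation."""

    time: np.ndarray
    states: np.ndarray  # shape (n_times, 6), canonical species order
    antibody: AntibodyConstruct
    cell_line: CellLine
    dose: float
    protocol: AssayProtocol
    params: RateConstantSet

    @property
    def terminal_state(self) -> SpeciesState:
        return SpeciesState.from_array(self.states[-1])

    def state_at(self, index: int) -> SpeciesState:
        return SpeciesState.from_array(self.states[index])

    def state_at_time(self, t: float) -> SpeciesState:
        idx = int(np.argmin(np.abs(self.time - t)))
        return SpeciesState.from_array(self.states[idx])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (antibody, cell_line, dose, time, species, value)."""
        from .reaction_model import SPECIES

        records = []
        for name, column in zip(SPECIES, self.states.T):
            units = "nM" if name == "free_ab" else "#/cell"
            records.append(
                pd.DataFrame(
                    {
                        "antibody": self.antibody.name,
                        "cell_line": self.cell_line.name,
                        "dose_nM": self.dose,
                        "time_s": self.time,
                        "species": name,
                        "value": column,
                        "units": units,
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def _atol_vector(network: BindingNetwork, cell_line: CellLine, dose: float) -> np.ndarray:
    """Per-species absolute tolerance, 1e-12 of each species' typical scale."""
    count_scale = max(cell_line.total_receptors, 1.0)
    ab_scale = max(dose, 1.0)
    atol = np.full(6, 1e-12 * count_scale)
    atol[0] = 1e-12 * ab_scale
    return atol


def _integrate_phase(
    network: BindingNetwork,
    y0: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray | None,
    rtol: float,
    atol: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    sol = solve_ivp(
        network,
        (t0, t1),
        y0,
        method="BDF",
        jac=network.jac,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else y0
        last_t = sol.t[-1] if sol.t.size else t0
        raise SimulationError(
            f"integration failed at t={last_t:.6g}s: {sol.message}",
            last_state=last,
            last_time=float(last_t),
        )
    return sol.t, sol.y.T


def _check_and_clip(states: np.ndarray, atol: np.ndarray) -> np.ndarray:
    floor = -100.0 * atol
    if np.any(states < floor[None, :]):
        worst = states.min()
        raise SimulationError(
            f"species went significantly negative (min {worst:.3e}); "
            "integration is unreliable"
        )
    return np.clip(states, 0.0, None)


def simulate_assay(
    antibody: AntibodyConstruct,
    cell_line: CellLine,
    dose: float,
    params: RateConstantSet,
    protocol: AssayProtocol | None = None,
    options: ModelOptions | None = None,
    points_per_phase: int = 200,
    rtol: float = _DEFAULT_RTOL,
) -> SimulationResult:
    """Integrate one antibody/cell-line/dose combination over the protocol.

    Antibody is added at t = 0.  If the protocol washes out, the free
    antibody concentration is reset to zero at ``washout_time`` and the
    integration continues — dissociated antibody re-enters the free pool
    afterwards unless ``protocol.clamp_washout`` holds it at zero.
    """
    protocol = protocol or AssayProtocol.fitting()
    options = options or ModelOptions()
    network = build_rhs(antibody, params, options)
    y0 = network.initial_state(cell_line, dose)
    atol = _atol_vector(network, cell_line, dose)
    horizon = protocol.resolved_horizon

    if protocol.washout and protocol.resolved_washout_time < horizon:
        phases = [(0.0, protocol.resolved_washout_time), (protocol.resolved_washout_time, horizon)]
    else:
        phases = [(0.0, horizon)]

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = y0
    for i, (t0, t1) in enumerate(phases):
        net = network
        if i == 1:
            y = y.copy()
            y[0] = 0.0  # washout: free antibody removed
            if protocol.clamp_washout:
                net = build_rhs(antibody, params, replace(options, clamp_antibody=True))
        t_eval = np.linspace(t0, t1, max(points_per_phase, 2))
        t, ys = _integrate_phase(net, y, t0, t1, t_eval, rtol, atol)
        if i == 1 and protocol.clamp_washout:
            ys[:, 0] = 0.0  # clamp semantics: free pool held at exactly zero
        y = ys[-1]
        times.append(t)
        states.append(ys)

    time = np.concatenate(times)
    traj = _check_and_clip(np.concatenate(states, axis=0), atol)
    return SimulationResult(time, traj, antibody, cell_line, dose, protocol, params)


def simulate_combination(
    antibodies: Sequence[AntibodyConstruct],
    cell_line: CellLine,
    total_dose: float,
    params: RateConstantSet,
    protocol: AssayProtocol | None = None,
    options: ModelOptions | None = None,
    ratio: float = 0.5,
    **kwargs,
) -> tuple[SimulationResult, SimulationResult]:
    """Simulate a two-monospecific combination sharing the cell's receptors.

    ``ratio`` is the fraction of the total dose given to the first antibody
    (default 1:1).  Because each monospecific targets a different receptor,
    the two sub-networks exchange no species and are integrated separately
    on the shared receptor pools.
    """
    if len(antibodies) != 2:
        raise ValueError("a combination consists of exactly two antibodies")
    ab_a, ab_b = antibodies
    if ab_a.is_bispecific or ab_b.is_bispecific:
        raise ValueError("combination antibodies must be monospecific")
    if ab_a.target == ab_b.target:
        raise ValueError("combination antibodies must target different receptors")
    res_a = simulate_assay(
        ab_a, cell_line, total_dose * ratio, params, protocol, options, **kwargs
    )
    res_b = simulate_assay(
        ab_b, cell_line, total_dose * (1.0 - ratio), params, protocol, options, **kwargs
    )
    return res_a, res_b


@dataclass(frozen=True)
class OccupancySummary:
    """Receptor-side view of the bound complexes.

    ``bound_*`` are receptor counts per cell; each ternary complex occupies
    two receptors.  Fractions are relative to the total receptor count
    (IL-6R + IL-8R), and ``occ_il6r``/``occ_il8r`` are per-receptor
    fractional occupancies.  ``undefined`` flags a receptor-free cell where
    fractions are reported as 0.
    """

    bound_binary: float
    bound_ternary: float
    bound_total: float
    frac_binary: float
    frac_ternary: float
    frac_total: float
    occ_il6r: float
    occ_il8r: float
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "bound_binary": self.bound_binary,
            "bound_ternary": self.bound_ternary,
            "bound_total": self.bound_total,
            "frac_binary": self.frac_binary,
            "frac_ternary": self.frac_ternary,
            "frac_total": self.frac_total,
            "occ_il6r": self.occ_il6r,
            "occ_il8r": self.occ_il8r,
            "undefined": self.undefined,
        }


def summarize_occupancy(
    state: SpeciesState,
    cell_line: CellLine,
    antibody: AntibodyConstruct | None = None,
) -> OccupancySummary:
    """Receptor-bound counts and fractional occupancies for one state.

    Binary-bound receptor is the sum of binary complex counts; ternary-bound
    receptor is twice the ternary complex count.  ``antibody`` determines how
    the ternary complex distributes over the two receptor pools (a
    homobivalent ternary holds two copies of the same receptor); when omitted
    the heterobivalent interpretation is used.
    """
    bound_binary = state.binary_ab_r1 + state.binary_ab_r2
    bound_ternary = 2.0 * state.ternary
    bound_total = bound_binary + bound_ternary

    if antibody is not None and antibody.is_homobivalent:
        if antibody.target == IL6R:
            r1_bound = state.binary_ab_r1 + 2.0 * state.ternary
            r2_bound = state.binary_ab_r2
        else:
            r1_bound = state.binary_ab_r1
            r2_bound = state.binary_ab_r2 + 2.0 * state.ternary
    else:
        r1_bound = state.binary_ab_r1 + state.ternary
        r2_bound = state.binary_ab_r2 + state.ternary

    total = cell_line.total_receptors
    if total <= 0:
        return OccupancySummary(
            bound_binary, bound_ternary, bound_total,
            0.0, 0.0, 0.0, 0.0, 0.0, undefined=True,
        )
    occ_il6r = r1_bound / cell_line.il6r_per_cell if cell_line.il6r_per_cell > 0 else 0.0
    occ_il8r = r2_bound / cell_line.il8r_per_cell if cell_line.il8r_per_cell > 0 else 0.0
    return OccupancySummary(
        bound_binary,
        bound_ternary,
        bound_total,
        bound_binary / total,
        bound_ternary / total,
        bound_total / total,
        occ_il6r,
        occ_il8r,
    )


def combination_occupancy(
    result_a: SimulationResult,
    result_b: SimulationResult,
    cell_line: CellLine | None = None,
) -> OccupancySummary:
    """Joint occupancy of a monospecific combination at the terminal time."""
    cell_line = cell_line or result_a.cell_line
    s_a = summarize_occupancy(result_a.terminal_state, cell_line, result_a.antibody)
    s_b = summarize_occupancy(result_b.terminal_state, cell_line, result_b.antibody)
    total = cell_line.total_receptors
    bound_binary = s_a.bound_binary + s_b.bound_binary
    bound_ternary = s_a.bound_ternary + s_b.bound_ternary
    bound_total = bound_binary + bound_ternary
    if total <= 0:
        return OccupancySummary(
            bound_binary, bound_ternary, bound_total,
            0.0, 0.0, 0.0, 0.0, 0.0, undefined=True,
        )
    return OccupancySummary(
        bound_binary,
        bound_ternary,
        bound_total,
        bound_binary / total,
        bound_ternary / total,
        bound_total / total,
        s_a.occ_il6r + s_b.occ_il6r,
        s_a.occ_il8r + s_b.occ_il8r,
    )


def total_bound_antibody(state: SpeciesState) -> float:
    """Antibodies bound per cell: each complex contains one antibody."""
    return state.binary_ab_r1 + state.binary_ab_r2 + state.ternary


def restrict_monovalent(params: RateConstantSet) -> RateConstantSet:
    """Zero both cross-linking rates to forbid ternary complex formation.

    Idempotent; the cycle constraint does not apply to the restricted set.
    """
    return replace(params, kon_6R_star=0.0, kon_8R_star=0.0)


def dose_receptor_grid(
    antibody_spec: AntibodyConstruct | Sequence[AntibodyConstruct],
    dose_grid: Iterable[float],
    receptor_grid: Iterable[tuple[float, float]],
    params: RateConstantSet,
    protocol: AssayProtocol | None = None,
    options: ModelOptions | None = None,
    ratio: float = 0.5,
    rtol: float = _DEFAULT_RTOL,
) -> pd.DataFrame:
    """Occupancy summaries over a dose x receptor-expression grid.

    ``antibody_spec`` is either a single construct or a pair of
    monospecifics simulated jointly at ``ratio`` of the total dose each.
    One long-horizon (default 24 h, no washout) simulation is run per grid
    cell; integrator failures are recorded per cell and the grid continues.
    """
    protocol = protocol or AssayProtocol.analysis()
    is_combo = not isinstance(antibody_spec, AntibodyConstruct)
    rows = []
    for il6r, il8r in receptor_grid:
        cell = CellLine(f"grid_{il6r:g}_{il8r:g}", il6r, il8r)
        for dose in dose_grid:
            row = {
                "dose_nM": dose,
                "il6r_per_cell": il6r,
                "il8r_per_cell": il8r,
                "error": "",
            }
            try:
                if is_combo:
                    res_a, res_b = simulate_combination(
                        antibody_spec, cell, dose, params, protocol, options,
                        ratio=ratio, points_per_phase=2, rtol=rtol,
                    )
                    summary = combination_occupancy(res_a, res_b, cell)
                    row["antibody"] = "+".join(ab.name for ab in antibody_spec)
                else:
                    res = simulate_assay(
                        antibody_spec, cell, dose, params, protocol, options,
                        points_per_phase=2, rtol=rtol,
                    )
                    summary = summarize_occupancy(
                        res.terminal_state, cell, antibody_spec
                    )
                    row["antibody"] = antibody_spec.name
                row.update(summary.as_dict())
            except SimulationError as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RelativeBinding:
    """Ratios of fractional occupancy: bispecific over monospecific combo.

    ``overall`` compares total-bound fractions; the per-receptor entries
    compare individual receptor occupancies.  0/0 is reported as 1 and
    flagged; finite/0 is reported as +inf.
    """

    overall: float
    il6r: float
    il8r: float
    flags: tuple[str, ...] = ()


def relative_binding(
    bsab: OccupancySummary, mabs: OccupancySummary
) -> RelativeBinding:
    """Element-wise occupancy ratio of a bispecific vs a monospecific combo."""
    flags = []

    def _ratio(num: float, den: float, label: str) -> float:
        if den == 0.0:
            if num == 0.0:
                flags.append(f"{label}:0/0")
                return 1.0
            return math.inf
        return num / den

    return RelativeBinding(
        overall=_ratio(bsab.frac_total, mabs.frac_total, "overall"),
        il6r=_ratio(bsab.occ_il6r, mabs.occ_il6r, "il6r"),
        il8r=_ratio(bsab.occ_il8r, mabs.occ_il8r, "il8r"),
        flags=tuple(flags),
    )
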