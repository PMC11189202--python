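"""Multi-start bounded least-squares estimation of the binding rates.

Five rate constants are free — kon_6R, kon_8R, kon_6R_star, koff_6R,
koff_8R — and the dependent IL-8R cross-linking rate follows from the
thermodynamic-cycle constraint.  Optimization runs in log10 space (the
admissible ranges span many orders of magnitude), from Latin-hypercube
log-uniform initial guesses, against dose-response tables normalized by one
of four schemes.  Cost is the sum of squared differences between the
normalized simulation output (terminal total bound antibody under the
fitting protocol) and the normalized measured signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import presets
from ._fastsim import simulate_design_bound
from .assay import AssayProtocol, SimulationError
from .reaction_model import ModelOptions, RateConstantSet
from .synthetic import DATA_COLUMNS, Design

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_GUESS_RANGES",
    "DEFAULT_BOUNDS",
    "NormalizationScheme",
    "SCHEMES",
    "NormalizedDataset",
    "normalize_dataset",
    "design_from_frame",
    "cost_function",
    "sum_of_squares",
    "lhs_initial_guesses",
    "FitResult",
    "run_multistart",
    "filter_and_select",
]

#: Free parameters, in optimization-vector order.
PARAM_NAMES = ("kon_6R", "kon_8R", "kon_6R_star", "koff_6R", "koff_8R")

#: Log-uniform initial-guess ranges (linear units).
DEFAULT_GUESS_RANGES = {
    "kon_6R": (1e-9, 1e-2),
    "kon_8R": (1e-9, 1e-2),
    "kon_6R_star": (1e-13, 1e-5),
    "koff_6R": (1e-7, 1e-2),
    "koff_8R": (1e-7, 1e-2),
}

#: Hard optimization bounds (linear units).
DEFAULT_BOUNDS = {
    "kon_6R": (1e-11, 1.0),
    "kon_8R": (1e-11, 1.0),
    "kon_6R_star": (1e-15, 1e-3),
    "koff_6R": (1e-9, 1.0),
    "koff_8R": (1e-9, 1.0),
}

#: Threshold (decades) below which an optimized point counts as "did not
#: move from its initial guess".
MOVE_TOL_LOG10 = 1e-6


def _ranges_array(ranges) -> np.ndarray:
    if isinstance(ranges, dict):
        arr = np.array([ranges[name] for name in PARAM_NAMES], dtype=float)
    else:
        arr = np.asarray(ranges, dtype=float)
    if arr.shape != (len(PARAM_NAMES), 2):
        raise ValueError(f"expected {len(PARAM_NAMES)}x2 ranges, got {arr.shape}")
    if np.any(arr <= 0):
        raise ValueError("ranges must be strictly positive (log-space sampling)")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("each range must satisfy lo < hi")
    return arr


@dataclass(frozen=True)
class NormalizationScheme:
    """How simulated and measured signals are put on a common scale.

    ``basis`` — "BS1": every antibody's signal in a cell line is divided by
    the BS1 reference of that cell line; "Ab": each antibody is divided by
    its own reference.  ``reference`` — "data": mean signal at the
    saturation doses determined from the measurements; "max": signal at the
    maximum dose.
    """

    basis: str = "BS1"
    reference: str = "data"

    def __post_init__(self) -> None:
        if self.basis not in ("BS1", "Ab"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.reference not in ("data", "max"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def key(self) -> str:
        return f"{'bs1' if self.basis == 'BS1' else 'ab'}_{self.reference}"


SCHEMES = {
    "bs1_data": NormalizationScheme("BS1", "data"),
    "bs1_max": NormalizationScheme("BS1", "max"),
    "ab_data": NormalizationScheme("Ab", "data"),
    "ab_max": NormalizationScheme("Ab", "max"),
}


@dataclass
class NormalizedDataset:
    """Replicate-averaged, normalized dose-response table.

    ``saturation_doses`` maps (reference antibody, cell line) to the doses
    whose mean signal served as the normalization denominator; the same
    doses normalize the simulation output under a "data" reference.
    """

    frame: pd.DataFrame  # columns: antibody, cell_line, dose_nM, value
    saturation_doses: dict[tuple[str, str], np.ndarray]
    scheme: NormalizationScheme

    def values_for(self, antibody: str, cell_line: str, doses: np.ndarray) -> np.ndarray:
        sub = self.frame[
            (self.frame["antibody"] == antibody)
            & (self.frame["cell_line"] == cell_line)
        ].set_index("dose_nM")["value"]
        try:
            return sub.loc[doses].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(
                f"dataset lacks doses for {antibody} x {cell_line}"
            ) from exc


def _saturation_doses(mean_by_dose: pd.Series, frac: float) -> np.ndarray:
    """Doses whose signal is within ``frac`` of the maximum (>= 2 doses)."""
    mean_by_dose = mean_by_dose.sort_index()
    peak = mean_by_dose.max()
    mask = mean_by_dose >= (1.0 - frac) * peak
    doses = mean_by_dose.index[mask].to_numpy(dtype=float)
    if doses.size < 2:
        doses = mean_by_dose.index.to_numpy(dtype=float)[-2:]
    return doses


def normalize_dataset(
    data: pd.DataFrame,
    scheme: NormalizationScheme | str = "bs1_data",
    saturation_frac: float = 0.05,
    average_replicates: bool = True,
) -> NormalizedDataset:
    """Normalize a raw dose-response table per cell line.

    With the default (BS1) basis every value is divided by the mean BS1
    signal at that cell line's saturation doses — the doses where BS1
    binding is within ``saturation_frac`` of its maximum (falling back to
    the top two doses).  The result is invariant to any overall scale
    factor of the raw signal.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    missing = set(("antibody", "cell_line", "dose_nM", "mfi")) - set(data.columns)
    if missing:
        raise ValueError(f"data table missing columns {sorted(missing)}")

    if average_replicates:
        frame = (
            data.groupby(["antibody", "cell_line", "dose_nM"], as_index=False)["mfi"]
            .mean()
        )
    else:
        frame = data[["antibody", "cell_line", "dose_nM", "mfi"]].copy()

    saturation: dict[tuple[str, str], np.ndarray] = {}
    denominators: dict[tuple[str, str], float] = {}
    for cell_line, cl_group in frame.groupby("cell_line"):
        if scheme.basis == "BS1":
            ref_frames = [("BS1", cl_group[cl_group["antibody"] == "BS1"])]
            if ref_frames[0][1].empty:
                raise ValueError(f"no BS1 rows for cell line {cell_line!r}")
        else:
            ref_frames = [
                (ab, cl_group[cl_group["antibody"] == ab])
                for ab in cl_group["antibody"].unique()
            ]
        for ref_ab, ref in ref_frames:
            mean_by_dose = ref.groupby("dose_nM")["mfi"].mean()
            doses = _saturation_doses(mean_by_dose, saturation_frac)
            denom = float(mean_by_dose.loc[doses].mean())
            if denom == 0.0:
                raise ValueError(
                    f"zero normalization denominator for {ref_ab} x {cell_line}"
                )
            saturation[(ref_ab, str(cell_line))] = doses
            denominators[(ref_ab, str(cell_line))] = denom

    def _denom(row) -> float:
        ref_ab = "BS1" if scheme.basis == "BS1" else row["antibody"]
        return denominators[(ref_ab, row["cell_line"])]

    out = frame.copy()
    out["value"] = out["mfi"] / out.apply(_denom, axis=1)
    out = out.drop(columns=["mfi"])
    if "replicate" in out.columns:
        out = out.drop(columns=["replicate"])
    return NormalizedDataset(out, saturation, scheme)


def design_from_frame(frame: pd.DataFrame, replicates: int = 1) -> Design:
    """Reconstruct a :class:`~bivalbind.synthetic.Design` from a data table.

    Antibody and cell-line names must be registered in the bundled
    fixtures; doses are taken (sorted) from the table.
    """
    combos = []
    for ab, cl in (
        frame[["antibody", "cell_line"]].drop_duplicates().itertuples(index=False)
    ):
        try:
            combos.append((presets.ANTIBODIES[ab], presets.CELL_LINES[cl]))
        except KeyError as exc:
            raise ValueError(f"unknown antibody or cell line {ab!r}/{cl!r}") from exc
    doses = np.sort(frame["dose_nM"].unique().astype(float))
    return Design(tuple(combos), doses, replicates=replicates)


def _normalize_simulation(
    bound: dict[tuple[str, str], np.ndarray],
    design: Design,
    scheme: NormalizationScheme,
    saturation_doses: dict[tuple[str, str], np.ndarray],
) -> dict[tuple[str, str], np.ndarray]:
    doses = design.doses
    refs: dict[tuple[str, str], float] = {}
    for (ab, cl), values in bound.items():
        ref_ab = "BS1" if scheme.basis == "BS1" else ab
        key = (ref_ab, cl)
        if key in refs:
            continue
        ref_values = bound.get(key)
        if ref_values is None:
            raise ValueError(f"design lacks reference combination {key}")
        if scheme.reference == "max":
            refs[key] = float(ref_values[np.argmax(doses)])
        else:
            sat = saturation_doses.get(key)
            if sat is None:
                raise ValueError(f"no saturation doses recorded for {key}")
            mask = np.isin(doses, sat)
            refs[key] = float(ref_values[mask].mean())
    out = {}
    for (ab, cl), values in bound.items():
        ref_ab = "BS1" if scheme.basis == "BS1" else ab
        denom = refs[(ref_ab, cl)]
        if not denom > 0:
            raise ValueError(f"non-positive simulation reference for {(ref_ab, cl)}")
        out[(ab, cl)] = values / denom
    return out


def cost_function(
    log_params: np.ndarray,
    norm_data: NormalizedDataset,
    scheme: NormalizationScheme | str | None = None,
    design: Design | None = None,
    protocol: AssayProtocol | None = None,
    options: ModelOptions | None = None,
    penalty: float = 1e3,
) -> np.ndarray:
    """Residual vector for one log10 parameter point.

    Simulates the fitting protocol per design point, normalizes the
    simulated bound antibody under the scheme, and returns the differences
    to the normalized data (one residual per point; sum of squares is the
    cost).  Simulation failures yield constant ``penalty`` residuals rather
    than raising.
    """
    if scheme is None:
        scheme = norm_data.scheme
    elif isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if design is None:
        design = design_from_frame(norm_data.frame)
    protocol = protocol or AssayProtocol.fitting()

    values = 10.0 ** np.asarray(log_params, dtype=float)
    try:
        params = RateConstantSet.from_cycle(*values)
        bound = simulate_design_bound(params, design, protocol, options)
        sim_norm = _normalize_simulation(
            bound, design, scheme, norm_data.saturation_doses
        )
    except (SimulationError, ValueError):
        return np.full(design.n_points, penalty)

    residuals = np.empty(design.n_points)
    pos = 0
    n_doses = design.doses.size
    for antibody, cell_line in design.combinations:
        data_vals = norm_data.values_for(antibody.name, cell_line.name, design.doses)
        sim_vals = sim_norm[(antibody.name, cell_line.name)]
        residuals[pos : pos + n_doses] = sim_vals - data_vals
        pos += n_doses
    if not np.all(np.isfinite(residuals)):
        return np.full(design.n_points, penalty)
    return residuals


def sum_of_squares(residuals: np.ndarray) -> float:
    return float(np.dot(residuals, residuals))


def lhs_initial_guesses(
    ranges=None, n: int = 300, seed: int | None = None
) -> np.ndarray:
    """Latin-hypercube log-uniform initial guesses, shape (n, 5).

    Each column is a stratified sample in log10 space: exactly one point in
    each of ``n`` equal-width log strata.  Reproducible under ``seed``.
    """
    arr = _ranges_array(ranges if ranges is not None else DEFAULT_GUESS_RANGES)
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=arr.shape[0], seed=seed)
    unit = sampler.random(n)
    lo = np.log10(arr[:, 0])
    hi = np.log10(arr[:, 1])
    return 10.0 ** (lo + unit * (hi - lo))


@dataclass
class FitResult:
    """Outcome of one optimization start."""

    params: RateConstantSet
    log10_params: np.ndarray
    cost: float
    converged: bool
    moved_from_guess: bool
    initial_guess: np.ndarray
    scheme: NormalizationScheme
    index: int
    optimality: float = math.nan
    status: int = 0
    message: str = ""
    nfev: int = 0

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "scheme": self.scheme.key,
            "cost": self.cost,
            "converged": self.converged,
            "moved_from_guess": self.moved_from_guess,
            "optimality": self.optimality,
            "status": self.status,
            "message": self.message,
            "nfev": self.nfev,
            "initial_guess": list(map(float, self.initial_guess)),
            **{name: float(10.0 ** lp) for name, lp in zip(PARAM_NAMES, self.log10_params)},
            "kon_8R_star": self.params.kon_8R_star,
        }


def _fit_one(
    index: int,
    guess: np.ndarray,
    log_lo: np.ndarray,
    log_hi: np.ndarray,
    norm_data: NormalizedDataset,
    scheme: NormalizationScheme,
    design: Design,
    protocol: AssayProtocol,
    options: ModelOptions | None,
    opt_tol: float,
    ls_kwargs: dict,
) -> FitResult:
    x0 = np.log10(guess)

    def fun(x):
        return cost_function(x, norm_data, scheme, design, protocol, options)

    try:
        res = least_squares(fun, x0, bounds=(log_lo, log_hi), **ls_kwargs)
    except Exception as exc:  # optimizer blow-ups are per-start, not fatal
        params = RateConstantSet.from_cycle(*guess)
        return FitResult(
            params, x0, math.inf, False, False, guess, scheme, index,
            message=f"optimizer error: {exc}",
        )
    x = res.x
    moved = bool(np.max(np.abs(x - x0)) >= MOVE_TOL_LOG10)
    # first-order optimality threshold scaled to the residual magnitude (the
    # gradient 2 J^T r cannot fall below the data's noise floor); an SSE at
    # integrator-noise level is a perfect fit and converged by definition
    sse = sum_of_squares(res.fun)
    grad_floor = 1e-3 * math.sqrt(sse / max(res.fun.size, 1))
    converged = bool(res.success) and bool(
        sse <= 1e-12 or res.optimality <= max(opt_tol, grad_floor)
    )
    params = RateConstantSet.from_cycle(*(10.0 ** x))
    return FitResult(
        params,
        x,
        sse,
        converged,
        moved,
        guess,
        scheme,
        index,
        optimality=float(res.optimality),
        status=int(res.status),
        message=str(res.message),
        nfev=int(res.nfev),
    )


def run_multistart(
    norm_data: NormalizedDataset,
    guesses: np.ndarray,
    bounds=None,
    scheme: NormalizationScheme | str | None = None,
    design: Design | None = None,
    protocol: AssayProtocol | None = None,
    options: ModelOptions | None = None,
    opt_tol: float = 1e-8,
    n_jobs: int = 1,
    **least_squares_kwargs,
) -> list[FitResult]:
    """One bounded log10-space least-squares solve per initial guess.

    Guesses outside the bounds are rejected up front.  Each start records
    its convergence status (optimizer success and first-order optimality
    below ``opt_tol``) and whether the solution moved from its guess.
    Optimizer exceptions are captured per start.
    """
    bounds_arr = _ranges_array(bounds if bounds is not None else DEFAULT_BOUNDS)
    guesses = np.atleast_2d(np.asarray(guesses, dtype=float))
    if guesses.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"guesses must have {len(PARAM_NAMES)} columns")
    if np.any(guesses < bounds_arr[:, 0]) or np.any(guesses > bounds_arr[:, 1]):
        raise ValueError("initial guesses must lie within the optimization bounds")

    if scheme is None:
        scheme = norm_data.scheme
    elif isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if design is None:
        design = design_from_frame(norm_data.frame)
    protocol = protocol or AssayProtocol.fitting()

    log_lo = np.log10(bounds_arr[:, 0])
    log_hi = np.log10(bounds_arr[:, 1])
    ls_kwargs = dict(
        method="trf",
        diff_step=1e-4,
        ftol=1e-12,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=400,
    )
    ls_kwargs.update(least_squares_kwargs)

    args = [
        (i, guesses[i], log_lo, log_hi, norm_data, scheme, design, protocol,
         options, opt_tol, ls_kwargs)
        for i in range(guesses.shape[0])
    ]
    if n_jobs == 1:
        return [_fit_one(*a) for a in args]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(delayed(_fit_one)(*a) for a in args)


def filter_and_select(
    results: Sequence[FitResult],
) -> tuple[list[FitResult], FitResult, pd.DataFrame]:
    """Discard non-converged / unmoved starts and pick the lowest-cost fit.

    Ties on cost break by lowest start index.  The summary table gives, per
    parameter, the best-fit value and the standard deviation of the
    log10-transformed optimized values across retained starts.
    """
    if not results:
        raise ValueError("no fit results supplied")
    retained = [r for r in results if r.converged and r.moved_from_guess]
    if not retained:
        raise ValueError(
            "all optimization starts were discarded (non-converged or unmoved); "
            "run more starts or widen tolerances"
        )
    best = min(retained, key=lambda r: (r.cost, r.index))
    logs = np.array([r.log10_params for r in retained])
    sd = logs.std(axis=0, ddof=1) if logs.shape[0] > 1 else np.zeros(logs.shape[1])
    summary = pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "best_fit": 10.0 ** best.log10_params,
            "median": 10.0 ** np.median(logs, axis=0),
            "sd_log10": sd,
            "n_retained": len(retained),
            "n_discarded": len(results) - len(retained),
        }
    )
    return retained, best, summary
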