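"""Mass-action reaction networks for bivalent antibody-receptor binding.

Two cell-surface receptors (IL-6R and IL-8R) are tracked in receptors/cell
while free antibody is tracked in nM; the two unit systems are coupled
through a volume-conversion constant ``alpha`` (nM per receptor/cell).
Antibodies carry two binding arms.  A heterobivalent antibody (one arm per
receptor) spans six species::

    Ab, R1, R2, Ab.R1, Ab.R2, R1.Ab.R2

while a homobivalent antibody (both arms against the same receptor) uses the
subset ``Ab, R, Ab.R, R.Ab.R``; the inapplicable slots of the canonical
six-species state stay identically zero.

The four elementary reactions of the heterobivalent network form a
thermodynamic cycle, so only three of the four association rate constants
are free: the fourth follows from detailed balance (see
:func:`apply_cycle_constraint`).  Dissociation rate constants are shared
between the first (binary) and second (cross-linking) binding steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AVOGADRO",
    "ALPHA_DEFAULT",
    "DEFAULT_CELLS_PER_WELL",
    "DEFAULT_WELL_VOLUME_L",
    "IL6R",
    "IL8R",
    "RECEPTORS",
    "SPECIES",
    "compute_alpha",
    "per_cell_to_nm",
    "nm_to_per_cell",
    "apply_cycle_constraint",
    "RateConstantSet",
    "EquilibriumConstants",
    "equilibrium_constants",
    "cross_arm_efficiency",
    "AntibodyConstruct",
    "CellLine",
    "SpeciesState",
    "ModelOptions",
    "BindingNetwork",
    "build_rhs",
]

AVOGADRO = 6.02214076e23

#: nM of free species contributed by one molecule per cell at the assay's
#: plating density (1e5 cells in ~200 uL); taken verbatim from the fitted
#: parameter table, recomputable via :func:`compute_alpha`.
ALPHA_DEFAULT = 8.3e-7
DEFAULT_CELLS_PER_WELL = 1.0e5
DEFAULT_WELL_VOLUME_L = 2.0e-4

IL6R = "IL6R"
IL8R = "IL8R"
RECEPTORS = (IL6R, IL8R)

#: Canonical state-vector layout.  Receptor slot 1 is IL-6R, slot 2 IL-8R.
SPECIES = (
    "free_ab",
    "free_r1",
    "free_r2",
    "binary_ab_r1",
    "binary_ab_r2",
    "ternary",
)

# Expected unit strings for serialized rate constants.
_RATE_UNITS = {
    "kon_6R": "nM^-1 s^-1",
    "kon_8R": "nM^-1 s^-1",
    "kon_6R_star": "(#/cell)^-1 s^-1",
    "kon_8R_star": "(#/cell)^-1 s^-1",
    "koff_6R": "s^-1",
    "koff_8R": "s^-1",
    "alpha": "nM/(#/cell)",
}


def compute_alpha(
    cells_per_well: float = DEFAULT_CELLS_PER_WELL,
    well_volume_l: float = DEFAULT_WELL_VOLUME_L,
) -> float:
    """Concentration (nM) corresponding to one molecule per cell.

    ``alpha = cells / (N_A * V) * 1e9``.  With the default plating density
    and well volume this evaluates to ~8.3e-7 nM/(#/cell).
    """
    if cells_per_well <= 0 or well_volume_l <= 0:
        raise ValueError("cells_per_well and well_volume_l must be positive")
    return cells_per_well / (AVOGADRO * well_volume_l) * 1e9


def per_cell_to_nm(count, alpha: float = ALPHA_DEFAULT):
    """Convert receptors(or complexes)/cell to nM."""
    return np.asarray(count) * alpha if np.ndim(count) else count * alpha


def nm_to_per_cell(conc, alpha: float = ALPHA_DEFAULT):
    """Convert nM to molecules/cell."""
    return np.asarray(conc) / alpha if np.ndim(conc) else conc / alpha


def apply_cycle_constraint(
    kon_6R: float, kon_8R: float, kon_6R_star: float
) -> float:
    """Derive the dependent IL-8R cross-linking rate from detailed balance.

    The four elementary binding reactions form a closed cycle, so the product
    of their equilibrium constants (inverting the two traversed in reverse)
    must be unity.  With dissociation rates shared between binding steps this
    collapses to equal cross-arm ratios for both receptors, giving::

        kon_8R* = kon_8R * (kon_6R* / kon_6R)

    Parameters are in nM^-1 s^-1 (first step) and (#/cell)^-1 s^-1
    (cross-linking); the returned rate is in (#/cell)^-1 s^-1.
    """
    for name, value in (
        ("kon_6R", kon_6R),
        ("kon_8R", kon_8R),
        ("kon_6R_star", kon_6R_star),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")
    return kon_8R * (kon_6R_star / kon_6R)


@dataclass(frozen=True)
class RateConstantSet:
    """Association/dissociation rate constants plus the unit conversion.

    First-step association rates are in nM^-1 s^-1, cross-linking rates in
    (#/cell)^-1 s^-1, dissociation rates in s^-1.  The same ``koff`` applies
    to binary and ternary complexes (shared-dissociation assumption).
    Cross-linking rates may be zero (monovalent restriction); everything else
    must be strictly positive.
    """

    kon_6R: float
    kon_8R: float
    kon_6R_star: float
    kon_8R_star: float
    koff_6R: float
    koff_8R: float
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self) -> None:
        for name in ("kon_6R", "kon_8R", "koff_6R", "koff_8R", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("kon_6R_star", "kon_8R_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_cycle(
        cls,
        kon_6R: float,
        kon_8R: float,
        kon_6R_star: float,
        koff_6R: float,
        koff_8R: float,
        alpha: float = ALPHA_DEFAULT,
    ) -> "RateConstantSet":
        """Build a set with ``kon_8R_star`` derived from the cycle constraint."""
        kon_8R_star = apply_cycle_constraint(kon_6R, kon_8R, kon_6R_star)
        return cls(kon_6R, kon_8R, kon_6R_star, kon_8R_star, koff_6R, koff_8R, alpha)

    # -- unit-converted views ------------------------------------------------
    @property
    def kon_6R_star_nm(self) -> float:
        """Cross-linking rate for IL-6R expressed in nM^-1 s^-1."""
        return self.kon_6R_star / self.alpha

    @property
    def kon_8R_star_nm(self) -> float:
        """Cross-linking rate for IL-8R expressed in nM^-1 s^-1."""
        return self.kon_8R_star / self.alpha

    # -- cycle diagnostics ---------------------------------------------------
    def cycle_product(self) -> float:
        """Product K1*K4/(K2*K3) of the reaction-cycle equilibrium constants.

        Evaluates to 1 exactly when the detailed-balance constraint holds.
        Cross-linking rates are converted to nM units before combination.
        """
        if self.kon_6R_star == 0 or self.kon_8R_star == 0:
            raise ValueError("cycle product undefined with zero cross-linking rates")
        k1 = self.koff_6R / self.kon_6R
        k2 = self.koff_8R / self.kon_8R
        k3 = self.koff_6R / self.kon_6R_star_nm
        k4 = self.koff_8R / self.kon_8R_star_nm
        return (k1 * k4) / (k2 * k3)

    def validate_cycle(self, rtol: float = 1e-10) -> None:
        """Raise if the cross-arm ratios of the two receptors disagree."""
        ratio_6 = self.kon_6R_star_nm / self.kon_6R
        ratio_8 = self.kon_8R_star_nm / self.kon_8R
        if not math.isclose(ratio_6, ratio_8, rel_tol=rtol):
            raise ValueError(
                "cycle constraint violated: cross-arm ratios "
                f"{ratio_6:.6e} (6R) vs {ratio_8:.6e} (8R)"
            )

    # -- serialization -------------------------------------------------------
    def to_config(self) -> dict:
        """Flat mapping with explicit unit strings, for YAML/TOML round-trips."""
        return {
            name: {"value": float(getattr(self, name)), "units": units}
            for name, units in _RATE_UNITS.items()
        }

    @classmethod
    def from_config(cls, config: dict) -> "RateConstantSet":
        """Load from :meth:`to_config` output, validating unit strings."""
        kwargs = {}
        for name, units in _RATE_UNITS.items():
            try:
                entry = config[name]
            except KeyError as exc:
                raise ValueError(f"missing rate constant {name!r}") from exc
            if isinstance(entry, dict):
                if entry.get("units") != units:
                    raise ValueError(
                        f"{name}: expected units {units!r}, got {entry.get('units')!r}"
                    )
                kwargs[name] = float(entry["value"])
            else:
                kwargs[name] = float(entry)
        return cls(**kwargs)


@dataclass(frozen=True)
class EquilibriumConstants:
    """Dissociation equilibrium constants (nM) for the four binding steps."""

    kd_6R: float
    kd_8R: float
    kd_6R_star: float
    kd_8R_star: float

    def as_dict(self) -> dict:
        return {
            "kd_6R": self.kd_6R,
            "kd_8R": self.kd_8R,
            "kd_6R_star": self.kd_6R_star,
            "kd_8R_star": self.kd_8R_star,
        }


def equilibrium_constants(params: RateConstantSet) -> EquilibriumConstants:
    """K_D = koff/kon for each binding step, in nM.

    Cross-linking rates are first converted to nM^-1 s^-1 via ``alpha``.
    """
    return EquilibriumConstants(
        kd_6R=params.koff_6R / params.kon_6R,
        kd_8R=params.koff_8R / params.kon_8R,
        kd_6R_star=params.koff_6R / params.kon_6R_star_nm,
        kd_8R_star=params.koff_8R / params.kon_8R_star_nm,
    )


def cross_arm_efficiency(params: RateConstantSet) -> float:
    """Dimensionless ratio of cross-linking to first-step association rate.

    Computed on the IL-6R arm; under the cycle constraint the IL-8R arm
    yields the same value.
    """
    return params.kon_6R_star_nm / params.kon_6R


@dataclass(frozen=True)
class AntibodyConstruct:
    """A bivalent antibody defined by the receptor targets of its two arms."""

    name: str
    arm_targets: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.arm_targets) != 2:
            raise ValueError("an antibody has exactly two arms")
        for target in self.arm_targets:
            if target not in RECEPTORS:
                raise ValueError(
                    f"unknown receptor {target!r}; expected one of {RECEPTORS}"
                )
        object.__setattr__(self, "arm_targets", tuple(self.arm_targets))

    @property
    def is_bispecific(self) -> bool:
        return self.arm_targets[0] != self.arm_targets[1]

    @property
    def is_homobivalent(self) -> bool:
        return not self.is_bispecific

    @property
    def target(self) -> str:
        """The single receptor of a homobivalent antibody."""
        if self.is_bispecific:
            raise ValueError(f"{self.name} is bispecific; no single target")
        return self.arm_targets[0]


@dataclass(frozen=True)
class CellLine:
    """Receptor expression of a cell line, in receptors/cell (0 if absent)."""

    name: str
    il6r_per_cell: float
    il8r_per_cell: float

    def __post_init__(self) -> None:
        if self.il6r_per_cell < 0 or self.il8r_per_cell < 0:
            raise ValueError("receptor counts must be non-negative")

    @property
    def total_receptors(self) -> float:
        return self.il6r_per_cell + self.il8r_per_cell

    def expression(self, receptor: str) -> float:
        if receptor == IL6R:
            return self.il6r_per_cell
        if receptor == IL8R:
            return self.il8r_per_cell
        raise ValueError(f"unknown receptor {receptor!r}")


@dataclass
class SpeciesState:
    """Snapshot of all model species.

    Free antibody in nM; receptors and complexes in molecules/cell.
    """

    free_ab: float
    free_r1: float
    free_r2: float
    binary_ab_r1: float
    binary_ab_r2: float
    ternary: float

    @classmethod
    def from_array(cls, y) -> "SpeciesState":
        return cls(*(float(v) for v in y))

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.free_ab,
                self.free_r1,
                self.free_r2,
                self.binary_ab_r1,
                self.binary_ab_r2,
                self.ternary,
            ]
        )


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches of the reaction network.

    statistical_factors
        Apply the factor-2 statistical weights of homobivalent antibodies
        (two identical arms double the first-association likelihood; a
        symmetric ternary complex has two dissociation routes back to the
        binary form).  Disable to probe sensitivity to this convention.
    clamp_antibody
        Freeze the free-antibody concentration (d[Ab]/dt = 0); used for
        excess-antibody limits and to hold the free pool at zero after a
        clamped washout.
    """

    statistical_factors: bool = True
    clamp_antibody: bool = False


class BindingNetwork:
    """Mass-action right-hand side for one antibody on one cell's receptors.

    Instances are callable as ``f(t, y)`` with ``y`` laid out per
    :data:`SPECIES`, and expose an analytic Jacobian for stiff integrators.
    Derivatives of the receptor- and antibody-conservation sums are zero by
    construction.
    """

    def __init__(
        self,
        antibody: AntibodyConstruct,
        params: RateConstantSet,
        options: ModelOptions | None = None,
    ) -> None:
        self.antibody = antibody
        self.params = params
        self.options = options or ModelOptions()
        if self.antibody.is_homobivalent:
            # receptor slot index: IL6R -> slot 1, IL8R -> slot 2
            self._slot = 1 if antibody.target == IL6R else 2

    # -- initial conditions --------------------------------------------------
    def initial_state(self, cell_line: CellLine, dose: float) -> np.ndarray:
        if dose < 0:
            raise ValueError("dose must be non-negative")
        return np.array(
            [dose, cell_line.il6r_per_cell, cell_line.il8r_per_cell, 0.0, 0.0, 0.0]
        )

    # -- dynamics ------------------------------------------------------------
    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        ab, r1, r2, b1, b2, ter = y
        out = np.zeros(6)
        if self.antibody.is_bispecific:
            v1 = p.kon_6R * r1 * ab
            v2 = p.kon_8R * r2 * ab
            v3 = p.kon_6R_star * r1 * b2  # R1 cross-links onto Ab.R2
            v4 = p.kon_8R_star * r2 * b1  # R2 cross-links onto Ab.R1
            out[3] = v1 - p.koff_6R * b1 - v4 + p.koff_8R * ter
            out[4] = v2 - p.koff_8R * b2 - v3 + p.koff_6R * ter
            out[5] = v3 + v4 - (p.koff_6R + p.koff_8R) * ter
            out[1] = -v1 + p.koff_6R * b1 - v3 + p.koff_6R * ter
            out[2] = -v2 + p.koff_8R * b2 - v4 + p.koff_8R * ter
            out[0] = p.alpha * (-v1 - v2 + p.koff_6R * b1 + p.koff_8R * b2)
        else:
            kon, kon_star, koff = self._homo_rates()
            f = 2.0 if self.options.statistical_factors else 1.0
            if self._slot == 1:
                r, b = r1, b1
            else:
                r, b = r2, b2
            v1 = f * kon * r * ab
            v2 = kon_star * r * b
            db = v1 - koff * b - v2 + f * koff * ter
            dter = v2 - f * koff * ter
            dr = -v1 + koff * b - v2 + f * koff * ter
            dab = p.alpha * (-v1 + koff * b)
            if self._slot == 1:
                out[1], out[3] = dr, db
            else:
                out[2], out[4] = dr, db
            out[5] = dter
            out[0] = dab
        if self.options.clamp_antibody:
            out[0] = 0.0
        return out

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        ab, r1, r2, b1, b2, ter = y
        J = np.zeros((6, 6))
        a = p.alpha
        if self.antibody.is_bispecific:
            k6, k8 = p.kon_6R, p.kon_8R
            k6s, k8s = p.kon_6R_star, p.kon_8R_star
            o6, o8 = p.koff_6R, p.koff_8R
            # d(free_ab)
            J[0] = [a * (-k6 * r1 - k8 * r2), -a * k6 * ab, -a * k8 * ab,
                    a * o6, a * o8, 0.0]
            # d(free_r1)
            J[1] = [-k6 * r1, -k6 * ab - k6s * b2, 0.0, o6, -k6s * r1, o6]
            # d(free_r2)
            J[2] = [-k8 * r2, 0.0, -k8 * ab - k8s * b1, -k8s * r2, o8, o8]
            # d(binary_ab_r1)
            J[3] = [k6 * r1, k6 * ab, -k8s * b1, -o6 - k8s * r2, 0.0, o8]
            # d(binary_ab_r2)
            J[4] = [k8 * r2, -k6s * b2, k8 * ab, 0.0, -o8 - k6s * r1, o6]
            # d(ternary)
            J[5] = [0.0, k6s * b2, k8s * b1, k8s * r2, k6s * r1, -(o6 + o8)]
        else:
            kon, kon_star, koff = self._homo_rates()
            f = 2.0 if self.options.statistical_factors else 1.0
            ir = self._slot  # receptor row/col
            ib = self._slot + 2  # binary row/col
            r = y[ir]
            b = y[ib]
            # d(free_ab)
            J[0, 0] = -a * f * kon * r
            J[0, ir] = -a * f * kon * ab
            J[0, ib] = a * koff
            # d(free_r)
            J[ir, 0] = -f * kon * r
            J[ir, ir] = -f * kon * ab - kon_star * b
            J[ir, ib] = koff - kon_star * r
            J[ir, 5] = f * koff
            # d(binary)
            J[ib, 0] = f * kon * r
            J[ib, ir] = f * kon * ab - kon_star * b
            J[ib, ib] = -koff - kon_star * r
            J[ib, 5] = f * koff
            # d(ternary)
            J[5, ir] = kon_star * b
            J[5, ib] = kon_star * r
            J[5, 5] = -f * koff
        if self.options.clamp_antibody:
            J[0] = 0.0
        return J

    def _homo_rates(self) -> tuple[float, float, float]:
        p = self.params
        if self._slot == 1:
            return p.kon_6R, p.kon_6R_star, p.koff_6R
        return p.kon_8R, p.kon_8R_star, p.koff_8R

    # -- conservation helpers ------------------------------------------------
    def receptor_conservation(self, y: np.ndarray) -> tuple[float, float]:
        """(IL-6R, IL-8R) totals implied by a state; constant in time."""
        ab, r1, r2, b1, b2, ter = y
        if self.antibody.is_bispecific:
            return r1 + b1 + ter, r2 + b2 + ter
        if self._slot == 1:
            return r1 + b1 + 2.0 * ter, r2
        return r1, r2 + b2 + 2.0 * ter

    def antibody_conservation(self, y: np.ndarray) -> float:
        """Total antibody in nM implied by a state; constant pre-washout."""
        ab, r1, r2, b1, b2, ter = y
        return ab + self.params.alpha * (b1 + b2 + ter)


def build_rhs(
    antibody: AntibodyConstruct,
    params: RateConstantSet,
    options: ModelOptions | None = None,
) -> BindingNetwork:
    """Construct the mass-action derivative function for an antibody.

    The returned :class:`BindingNetwork` is callable as ``f(t, y)`` and also
    provides an analytic Jacobian (``.jac``) and conservation helpers.
    Raises ``ValueError`` for arm targets outside the modelled receptors
    (validated at :class:`AntibodyConstruct` construction).
    """
    return BindingNetwork(antibody, params, options)
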