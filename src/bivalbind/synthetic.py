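"""Synthetic dose-response datasets with the assay's statistical structure.

The raw fluorescence measurements behind the published fit are not
deposited, so end-to-end testing uses datasets generated here from known
ground-truth rate constants: the forward model is the fitting-protocol
simulation (2 h association, washout, 15 min detection), the readout is the
terminal total bound antibody scaled to an arbitrary MFI-like unit, and
replicates receive independent multiplicative noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from ._fastsim import simulate_design_bound
from .assay import AssayProtocol
from .reaction_model import (
    AntibodyConstruct,
    CellLine,
    ModelOptions,
    RateConstantSet,
)

__all__ = [
    "Design",
    "default_design",
    "NoiseModel",
    "SyntheticDataset",
    "generate",
]

DATA_COLUMNS = ("antibody", "cell_line", "dose_nM", "replicate", "mfi")


@dataclass(frozen=True)
class Design:
    """Antibody x cell-line x dose layout of a binding assay."""

    combinations: tuple[tuple[AntibodyConstruct, CellLine], ...]
    doses: np.ndarray
    replicates: int = 3

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        object.__setattr__(self, "doses", doses)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)

    @property
    def n_points(self) -> int:
        """Fitted data points: combinations x doses (replicates averaged)."""
        return self.n_combinations * self.doses.size


def default_design(replicates: int = 3) -> Design:
    """The assay's fitted design: 11 log-spaced doses from 1e-2 to 1e3 nM
    across the 7 binding-competent antibody/cell-line combinations
    (77 points), 3 technical replicates."""
    doses = np.logspace(-2.0, 3.0, 11)
    combos = tuple(
        (presets.ANTIBODIES[ab], presets.CELL_LINES[cl])
        for ab, cl in presets.BINDING_COMPETENT_COMBINATIONS
    )
    return Design(combinations=combos, doses=doses, replicates=replicates)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement noise.

    ``multiplicative-gaussian`` draws ``value * max(0, 1 + sigma*N(0,1))``;
    ``multiplicative-lognormal`` draws ``value * exp(sigma*N(0,1))``;
    ``none`` reproduces the model output exactly.
    """

    kind: str = "multiplicative-gaussian"
    sigma: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative-gaussian", "multiplicative-lognormal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def multipliers(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0:
            return np.ones(shape)
        draws = rng.standard_normal(shape)
        if self.kind == "multiplicative-gaussian":
            return np.maximum(0.0, 1.0 + self.sigma * draws)
        return np.exp(self.sigma * draws)


@dataclass
class SyntheticDataset:
    """Generated MFI-like dose-response table plus its provenance."""

    frame: pd.DataFrame
    design: Design
    ground_truth: RateConstantSet
    scale: float
    noise: NoiseModel
    seed: int | None

    def write(self, path: str | Path) -> None:
        """CSV table plus a JSON sidecar with ground truth and seed."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = {
            "ground_truth": self.ground_truth.to_config(),
            "scale": self.scale,
            "noise": {"kind": self.noise.kind, "sigma": self.noise.sigma},
            "seed": self.seed,
            "replicates": self.design.replicates,
            "n_points": self.design.n_points,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def generate(
    design: Design,
    ground_truth: RateConstantSet,
    noise: NoiseModel | None = None,
    scale: float = 1.0e3,
    protocol: AssayProtocol | None = None,
    options: ModelOptions | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Forward-simulate a design and add per-replicate measurement noise.

    ``value = scale * bound_antibody(terminal) * noise multiplier``, drawn
    independently per replicate.  ``seed`` overrides ``noise.seed``;
    identical seeds give identical datasets.
    """
    noise = noise or NoiseModel()
    protocol = protocol or AssayProtocol.fitting()
    if scale <= 0:
        raise ValueError("scale must be positive")
    use_seed = seed if seed is not None else noise.seed
    rng = np.random.default_rng(use_seed)

    bound = simulate_design_bound(ground_truth, design, protocol, options)
    records = []
    for antibody, cell_line in design.combinations:
        clean = scale * bound[(antibody.name, cell_line.name)]
        mult = noise.multipliers((design.replicates, design.doses.size), rng)
        for rep in range(design.replicates):
            records.append(
                pd.DataFrame(
                    {
                        "antibody": antibody.name,
                        "cell_line": cell_line.name,
                        "dose_nM": design.doses,
                        "replicate": rep + 1,
                        "mfi": clean * mult[rep],
                    }
                )
            )
    frame = pd.concat(records, ignore_index=True)
    return SyntheticDataset(frame, design, ground_truth, scale, noise, use_seed)
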