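"""Bundled fixtures: antibody constructs, cell lines, and best-fit rates.

The receptor expression levels come from quantified flow cytometry on
transduced HEK 293T cell lines; the rate constants are the published
best-fit estimates for the tocilizumab/10H2/BS1 system with the dependent
IL-8R cross-linking rate derived from the thermodynamic-cycle constraint.
"""

from __future__ import annotations

from .reaction_model import (
    ALPHA_DEFAULT,
    IL6R,
    IL8R,
    AntibodyConstruct,
    CellLine,
    RateConstantSet,
)

__all__ = [
    "TOCILIZUMAB",
    "TENH2",
    "BS1",
    "ANTIBODIES",
    "CELL_LINES",
    "BEST_FIT_RATES",
    "best_fit_params",
    "BINDING_COMPETENT_COMBINATIONS",
]

TOCILIZUMAB = AntibodyConstruct("tocilizumab", (IL6R, IL6R))
TENH2 = AntibodyConstruct("10H2", (IL8R, IL8R))
BS1 = AntibodyConstruct("BS1", (IL6R, IL8R))

ANTIBODIES = {ab.name: ab for ab in (TOCILIZUMAB, TENH2, BS1)}

CELL_LINES = {
    "IL6R+": CellLine("IL6R+", 5.08e5, 0.0),
    "IL8R+": CellLine("IL8R+", 0.0, 1.30e6),
    "IL6R+IL8R+": CellLine("IL6R+IL8R+", 3.16e5, 6.18e5),
    "parental": CellLine("parental", 0.0, 0.0),
}

#: Best-fit independent rate constants (kon in nM^-1 s^-1, kon* in
#: (#/cell)^-1 s^-1, koff in s^-1).
BEST_FIT_RATES = {
    "kon_6R": 5.92e-6,
    "kon_8R": 9.03e-6,
    "kon_6R_star": 8.11e-8,
    "koff_6R": 5.61e-5,
    "koff_8R": 6.38e-5,
}

#: The 7 antibody x cell-line pairings where binding occurs (out of the
#: 12 combinations of 3 antibodies and 4 lines).
BINDING_COMPETENT_COMBINATIONS = (
    ("tocilizumab", "IL6R+"),
    ("tocilizumab", "IL6R+IL8R+"),
    ("10H2", "IL8R+"),
    ("10H2", "IL6R+IL8R+"),
    ("BS1", "IL6R+"),
    ("BS1", "IL8R+"),
    ("BS1", "IL6R+IL8R+"),
)


def best_fit_params(alpha: float = ALPHA_DEFAULT) -> RateConstantSet:
    """The published best-fit rate-constant set, cycle constraint applied."""
    return RateConstantSet.from_cycle(alpha=alpha, **BEST_FIT_RATES)
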