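"""Closed-form polymer-scaling predictions for monomer subdiffusion.

A monomer of a long chain cannot diffuse alone: to move a mean-square
distance it must drag the n(t) neighbouring monomers within that
distance, so its effective friction grows with time and the MSD becomes
subdiffusive.  For a chain whose radius of gyration scales as
R_g ~ N^nu (Flory exponent nu), the argument gives

    <r^2(t)> ~ t^(2 nu / (1 + 2 nu)).

The ideal (phantom) Rouse chain has nu = 1/2 and hence alpha = 1/2; an
excluded-volume chain in good solvent has nu = 3/5 (mean-field) or
nu ~= 0.588 (renormalisation-group), both giving alpha ~= 0.54.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ScalingPrediction:
    """A labelled (nu, alpha) pair; ``derived`` is False for literature
    constants stored rather than computed."""

    label: str
    nu: float | None
    alpha: float
    derived: bool = True


def rouse_exponent(nu: float) -> float:
    """Monomer MSD exponent alpha = 2*nu/(1 + 2*nu) for Flory exponent nu.

    Strictly increasing in nu, with alpha(1/2) = 1/2 and alpha(1) = 2/3.
    """
    if not 0 < nu <= 1:
        raise ValueError(f"Flory exponent nu must be in (0, 1], got {nu}")
    return 2 * nu / (1 + 2 * nu)


#: Literature monomer-MSD exponent for a semi-flexible polymer; stored as
#: a cited constant, not derived from the friction argument above.
SEMIFLEXIBLE_ALPHA = 0.75


def reference_exponents() -> pd.DataFrame:
    """Reference table of predicted monomer MSD exponents.

    Rows: ideal Rouse chain, excluded-volume chain at the mean-field
    nu = 3/5, the refined nu = 0.588, and the semi-flexible literature
    constant alpha = 3/4 (flagged, nu not applicable).
    """
    preds = [
        ScalingPrediction("ideal Rouse", 0.5, rouse_exponent(0.5)),
        ScalingPrediction("excluded volume (mean-field nu=3/5)", 3 / 5, rouse_exponent(3 / 5)),
        ScalingPrediction("excluded volume (refined nu=0.588)", 0.588, rouse_exponent(0.588)),
        ScalingPrediction("semi-flexible (literature constant)", None, SEMIFLEXIBLE_ALPHA, derived=False),
    ]
    return pd.DataFrame(
        {
            "label": [p.label for p in preds],
            "nu": [p.nu for p in preds],
            "alpha": [p.alpha for p in preds],
            "derived": [p.derived for p in preds],
        }
    )
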