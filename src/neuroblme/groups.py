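"""Population deterioration rates per diagnosis and their posterior ordering.

The population rate of volume change for each diagnosis is the baseline
(HC) age slope plus the group's interaction term:

    HC:  beta1        MCI: beta1 + beta4        AD: beta1 + beta5

computed draw-by-draw so the three arrays stay aligned on the same joint
posterior draw.  Ordering probabilities are Monte Carlo fractions of draws
in which one group's rate is strictly smaller than another's; for the
ventricle a larger slope means faster deterioration, for the hippocampus a
more negative slope does, so severity comparisons reverse sign between the
two regions (stated in output headers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws

__all__ = [
    "GroupSlopeDraws",
    "group_slopes",
    "ordering_probability",
    "pairwise_ordering_probabilities",
    "full_ordering_probability",
    "group_difference_table",
    "to_per_year",
]

#: sign by which a region's slope maps onto deterioration severity:
#: +1 means larger slope = worse (ventricle), -1 means more negative = worse
SEVERITY_SIGN = {"ventricle": 1.0, "hippocampus": -1.0}


@dataclass(frozen=True)
class GroupSlopeDraws:
    """Aligned posterior draws of the three group deterioration rates,
    in response units per standardised-age unit."""

    hc: np.ndarray
    mci: np.ndarray
    ad: np.ndarray
    region: str
    units: str = "volume-ICV per standardised-age unit"

    def __post_init__(self) -> None:
        if not (len(self.hc) == len(self.mci) == len(self.ad)):
            raise ValueError("group slope draws must share length")


def group_slopes(draws: PosteriorDraws) -> GroupSlopeDraws:
    """Per-draw group rates beta1, beta1+beta4, beta1+beta5."""
    b = draws.beta
    return GroupSlopeDraws(
        hc=b[:, 1].copy(),
        mci=b[:, 1] + b[:, 4],
        ad=b[:, 1] + b[:, 5],
        region=draws.region,
    )


def ordering_probability(slopes_a: np.ndarray, slopes_b: np.ndarray) -> float:
    """Monte Carlo estimate of P(a < b): the fraction of aligned joint
    draws in which ``a`` is strictly below ``b`` (ties count as 0)."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw arrays must share length")
    return float(np.mean(a - b < 0.0))


def pairwise_ordering_probabilities(slopes: GroupSlopeDraws) -> dict:
    """The three severity-ordered pairwise probabilities for one region.

    Each entry is the posterior probability that the less severe group
    deteriorates more slowly than the more severe one, in the region's
    severity direction (ventricle: larger slope worse; hippocampus: more
    negative slope worse).
    """
    sign = SEVERITY_SIGN[slopes.region]
    hc, mci, ad = sign * slopes.hc, sign * slopes.mci, sign * slopes.ad
    return {
        "P(HC slower than MCI)": ordering_probability(hc, mci),
        "P(MCI slower than AD)": ordering_probability(mci, ad),
        "P(HC slower than AD)": ordering_probability(hc, ad),
    }


def full_ordering_probability(slopes: GroupSlopeDraws) -> float:
    """P(HC, MCI, AD deteriorate in severity order), jointly per draw."""
    sign = SEVERITY_SIGN[slopes.region]
    hc, mci, ad = sign * slopes.hc, sign * slopes.mci, sign * slopes.ad
    return float(np.mean((hc < mci) & (mci < ad)))


def _summary(x: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(x)),
        "ci_low": float(np.quantile(x, 0.025)),
        "ci_high": float(np.quantile(x, 0.975)),
    }


def group_difference_table(slopes: GroupSlopeDraws) -> pd.DataFrame:
    """Posterior mean and 95% credible interval of each group rate and of
    the pairwise differences (computed per draw, then summarised).

    Units: volume-ICV per standardised-age unit (see :func:`to_per_year`
    for back-transformation to per-year rates).
    """
    rows = {
        "HC": _summary(slopes.hc),
        "MCI": _summary(slopes.mci),
        "AD": _summary(slopes.ad),
        "MCI-HC": _summary(slopes.mci - slopes.hc),
        "AD-HC": _summary(slopes.ad - slopes.hc),
        "AD-MCI": _summary(slopes.ad - slopes.mci),
    }
    out = pd.DataFrame(rows).T[["mean", "ci_low", "ci_high"]]
    out.index.name = f"{slopes.region} rate ({slopes.units})"
    return out


def to_per_year(values: np.ndarray, age_sd: float) -> np.ndarray:
    """Convert slopes from per-standardised-age to per-year units."""
    return np.asarray(values, dtype=float) / age_sd
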