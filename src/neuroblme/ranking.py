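"""Posterior ranking of individual deterioration rates.

Each participant's total deterioration slope under joint draw m is

    s_i,m = beta1_m + beta4_m * mbar_i + beta5_m * abar_i + b1_i,m

where (mbar_i, abar_i) are the participant's mean MCI/AD indicators over
their observed visits (so converters are weighted by how long they spent in
each diagnosis; stable participants have indicator 0 or 1).  Ranking all N
participants within every retained draw turns posterior uncertainty in the
slopes into a Monte Carlo distribution over ranks 1..N per participant,
from which median ranks and probabilities of sitting in an extreme quantile
(e.g. the worst 15%) follow directly.  Rank 1 is always the worst
deteriorator: the largest slope for the ventricle, the most negative for
the hippocampus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import participant_paths
from .model import PosteriorDraws

__all__ = [
    "IndividualSlopeDraws",
    "RankDistribution",
    "individual_slopes",
    "rank_direction",
    "rank_per_draw",
    "quantile_membership",
    "median_rank_table",
]


@dataclass(frozen=True)
class IndividualSlopeDraws:
    """M x N aligned draws of every participant's total slope."""

    slopes: np.ndarray            # M x N
    participant_ids: np.ndarray   # N
    path_labels: np.ndarray       # N, in {HC, MCI, AD, converter}
    region: str

    @property
    def n_participants(self) -> int:
        return self.slopes.shape[1]


@dataclass(frozen=True)
class RankDistribution:
    """M x N integer ranks; at every draw the row is a permutation of 1..N."""

    ranks: np.ndarray
    participant_ids: np.ndarray
    direction: str

    @property
    def n_participants(self) -> int:
        return self.ranks.shape[1]

    def median_ranks(self) -> np.ndarray:
        return np.median(self.ranks, axis=0)


def individual_slopes(
    draws: PosteriorDraws,
    dataset: pd.DataFrame,
    converter_rule: str = "mean_indicator",
) -> IndividualSlopeDraws:
    """Total (fixed group + random) slope draws per participant.

    ``converter_rule`` picks the group term for participants whose
    diagnosis changed: ``"mean_indicator"`` weights the MCI/AD interaction
    slopes by the mean observed indicators; ``"last"`` uses the final
    visit's diagnosis.  Stable participants are unaffected by the choice.
    """
    df = dataset.sort_values(["id", "visit"], kind="stable")
    ids = np.sort(df["id"].unique())
    if not np.array_equal(ids, draws.participant_ids):
        raise KeyError("dataset participant ids do not match the draws")

    m = (df["diagnosis"] == "MCI").astype(float)
    a = (df["diagnosis"] == "AD").astype(float)
    if converter_rule == "mean_indicator":
        mbar = m.groupby(df["id"]).mean().reindex(ids).to_numpy()
        abar = a.groupby(df["id"]).mean().reindex(ids).to_numpy()
    elif converter_rule == "last":
        last = df.groupby("id")["diagnosis"].last().reindex(ids)
        mbar = (last == "MCI").to_numpy(float)
        abar = (last == "AD").to_numpy(float)
    else:
        raise ValueError(f"unknown converter_rule {converter_rule!r}")

    fixed = (
        draws.beta[:, [1]]
        + draws.beta[:, [4]] * mbar[None, :]
        + draws.beta[:, [5]] * abar[None, :]
    )
    slopes = fixed + draws.random_effects[:, :, 1]
    paths = participant_paths(dataset).reindex(ids).to_numpy()
    return IndividualSlopeDraws(
        slopes=slopes, participant_ids=ids, path_labels=paths,
        region=draws.region,
    )


def rank_direction(region: str) -> str:
    """Worst-first sort direction: descending for the ventricle (largest
    slope = most atrophy), ascending for the hippocampus."""
    return {"ventricle": "descending", "hippocampus": "ascending"}[region]


def rank_per_draw(slopes: IndividualSlopeDraws,
                  direction: str | None = None) -> RankDistribution:
    """Rank all participants within every draw; rank 1 is worst.

    Ties (measure-zero for continuous draws) break in participant-id
    order via the stable sort.
    """
    if direction is None:
        direction = rank_direction(slopes.region)
    if direction not in ("descending", "ascending"):
        raise ValueError("direction must be 'descending' or 'ascending'")
    s = slopes.slopes if direction == "ascending" else -slopes.slopes
    order = np.argsort(s, axis=1, kind="stable")
    ranks = np.empty_like(order)
    M, N = order.shape
    rows = np.arange(M)[:, None]
    ranks[rows, order] = np.arange(1, N + 1)[None, :]
    return RankDistribution(
        ranks=ranks, participant_ids=slopes.participant_ids,
        direction=direction,
    )


def quantile_membership(ranks: RankDistribution, quantile: float) -> np.ndarray:
    """Per-participant probability of ranking within the worst ``quantile``
    fraction, i.e. P(rank <= ceil(quantile * N))."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    threshold = math.ceil(quantile * ranks.n_participants)
    return (ranks.ranks <= threshold).mean(axis=0)


def median_rank_table(
    ranks: RankDistribution,
    slopes: IndividualSlopeDraws,
    quantile: float = 0.15,
) -> pd.DataFrame:
    """League table of all participants, worst first.

    Columns: median rank, posterior mean slope with 95% credible interval,
    the probability of sitting in the worst ``quantile`` fraction, and the
    diagnosis-path label (HC/MCI/AD or 'converter' for any progression
    path).  Sorted by median rank, ties broken by participant id.
    """
    s = slopes.slopes
    table = pd.DataFrame(
        {
            "id": ranks.participant_ids,
            "path": slopes.path_labels,
            "median_rank": ranks.median_ranks(),
            "slope_mean": s.mean(axis=0),
            "slope_ci_low": np.quantile(s, 0.025, axis=0),
            "slope_ci_high": np.quantile(s, 0.975, axis=0),
            f"p_worst_{int(round(quantile * 100))}pct": quantile_membership(
                ranks, quantile
            ),
        }
    )
    return (
        table.sort_values(["median_rank", "id"], kind="stable")
        .reset_index(drop=True)
    )
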