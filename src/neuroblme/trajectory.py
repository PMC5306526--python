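"""Diagnosis-probability trajectories over age from volume centile bands.

Given an external prevalence table P(Dx | age) and the fitted mixed model,
the probability that a new individual of a given age whose volume falls in
centile band R carries each diagnosis follows from Bayes' rule:

    P(Dx | V in R, age) =  P(V in R | Dx, age) P(Dx | age)
                          ---------------------------------
                          sum_Dx' P(V in R | Dx', age) P(Dx' | age)

The likelihood terms are posterior-predictive band probabilities: the
fraction of retained joint draws under which a simulated new individual of
that diagnosis and age (fixed-effects mean + a fresh random-effect pair
from MVN(0, Sigma_m) + residual noise) lands inside the band.  Bands are
centile curves of the observed volumes over raw age, pooled across
diagnoses, estimated by quantile regression on a spline basis and made
non-crossing and age-monotone.  Repeating the whole pipeline with K
independently seeded fits gives a Monte Carlo standard-error interval
(mean +/- 1.96 sd of the K replicate estimates) for every trajectory
point.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DIAGNOSES
from .model import (
    MCMCConfig,
    ModelSpec,
    PosteriorDraws,
    REGIONS,
    gibbs_sample,
    rhat_summary,
)

__all__ = [
    "PrevalenceTable",
    "VolumeBand",
    "DEFAULT_PREVALENCE",
    "AGE_GRID",
    "CENTILES",
    "BAND_LABELS",
    "fit_centile_bands",
    "band_probability",
    "diagnosis_posterior",
    "interpolate_prevalence",
    "trajectory_with_mc_se",
]

logger = logging.getLogger(__name__)

#: age axis (raw years) on which bands and trajectories are evaluated
AGE_GRID = np.arange(60.0, 86.0, 1.0)
#: centile curves fitted to the pooled observed volumes
CENTILES = (0.15, 0.25, 0.50, 0.75)
#: the four bands those curves delimit (upper band capped at the empirical max)
BAND_LABELS = ("75-100th", "50-75th", "25-50th", "15-25th")


@dataclass(frozen=True)
class PrevalenceTable:
    """External age-specific diagnosis prevalences P(Dx | age) at knot ages."""

    ages: np.ndarray
    p_hc: np.ndarray
    p_mci: np.ndarray
    p_ad: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("knot ages must be strictly increasing")
        total = (
            np.asarray(self.p_hc) + np.asarray(self.p_mci) + np.asarray(self.p_ad)
        )
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("prevalences must sum to 1 at every knot age")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrevalenceTable":
        return cls(
            ages=df["age"].to_numpy(float),
            p_hc=df["p_hc"].to_numpy(float),
            p_mci=df["p_mci"].to_numpy(float),
            p_ad=df["p_ad"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "PrevalenceTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "p_hc": self.p_hc, "p_mci": self.p_mci,
             "p_ad": self.p_ad}
        )


# Synthetic stand-in prevalence table (the published age-specific rates this
# pipeline was designed around are not redistributable): HC probability
# declines with age while MCI and AD prevalence rise, rows summing to 1.
DEFAULT_PREVALENCE = PrevalenceTable(
    ages=np.array([60.0, 65.0, 70.0, 75.0, 80.0, 85.0]),
    p_hc=np.array([0.950, 0.920, 0.880, 0.820, 0.730, 0.620]),
    p_mci=np.array([0.040, 0.055, 0.075, 0.100, 0.140, 0.180]),
    p_ad=np.array([0.010, 0.025, 0.045, 0.080, 0.130, 0.200]),
)


def interpolate_prevalence(table: PrevalenceTable, age: float) -> np.ndarray:
    """P(HC), P(MCI), P(AD) at ``age`` by linear interpolation between
    knots, renormalised to sum to 1; knot ages reproduce the table rows."""
    ages = np.asarray(table.ages, dtype=float)
    if age < ages[0] - 1e-9 or age > ages[-1] + 1e-9:
        raise ValueError(f"age {age} outside the prevalence range "
                         f"[{ages[0]}, {ages[-1]}]")
    p = np.array(
        [
            np.interp(age, ages, table.p_hc),
            np.interp(age, ages, table.p_mci),
            np.interp(age, ages, table.p_ad),
        ]
    )
    return p / p.sum()


@dataclass(frozen=True)
class VolumeBand:
    """An age-indexed centile band: lower(age) <= volume <= upper(age)."""

    region: str
    label: str
    ages: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("band lower curve crosses upper curve")

    def lower_at(self, age: float) -> float:
        self._check_age(age)
        return float(np.interp(age, self.ages, self.lower))

    def upper_at(self, age: float) -> float:
        self._check_age(age)
        return float(np.interp(age, self.ages, self.upper))

    def _check_age(self, age: float) -> None:
        if age < self.ages[0] - 1e-9 or age > self.ages[-1] + 1e-9:
            raise ValueError(f"band {self.label!r} undefined at age {age}")

    def union(self, other: "VolumeBand") -> "VolumeBand":
        """Merge with an adjacent band into one wider band."""
        return VolumeBand(
            region=self.region,
            label=f"{self.label}+{other.label}",
            ages=self.ages,
            lower=np.minimum(self.lower, other.lower),
            upper=np.maximum(self.upper, other.upper),
        )


def _bspline_basis(x: np.ndarray, lo: float, hi: float,
                   n_interior: int = 2, degree: int = 3) -> np.ndarray:
    from scipy.interpolate import BSpline

    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def fit_centile_bands(
    dataset: pd.DataFrame,
    region: str,
    centiles: tuple = CENTILES,
    age_grid: np.ndarray = AGE_GRID,
) -> list[VolumeBand]:
    """Centile volume bands over raw age, pooled across diagnoses.

    Each centile curve is a quantile regression of observed volume on a
    cubic B-spline basis of age.  Curves are made monotone along age in
    the region's trend direction (ventricle non-decreasing, hippocampus
    non-increasing) by monotone rearrangement (sorting the fitted values
    over the age grid, which leaves an already-monotone curve untouched),
    then rendered non-crossing by rearrangement across centiles at every
    grid age.  Adjacent centiles delimit the bands; the top band's upper
    bound is the empirical maximum volume.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    col = REGIONS[region]
    y = dataset[col].to_numpy(float)
    age = dataset["age_years"].to_numpy(float)
    if len(y) < 30:
        raise ValueError("need at least 30 observations to fit centile bands")
    lo, hi = float(age_grid[0]), float(age_grid[-1])
    for w0 in np.arange(lo, hi, 5.0):
        if not np.any((age >= w0) & (age < w0 + 5.0 + 1e-9)):
            raise ValueError(
                f"no observations in age window [{w0}, {w0 + 5.0}]"
            )

    B = _bspline_basis(age, lo, hi)
    Bgrid = _bspline_basis(age_grid, lo, hi)
    centiles = tuple(sorted(centiles))
    curves = np.empty((len(centiles), len(age_grid)))
    for i, q in enumerate(centiles):
        params = QuantReg(y, B).fit(q=q).params
        curves[i] = Bgrid @ params
    # monotone over age in the trend direction (rearrangement: sort the
    # fitted values along the grid; identity for already-monotone curves)
    if region == "ventricle":
        curves = np.sort(curves, axis=1)
    else:
        curves = np.sort(curves, axis=1)[:, ::-1]
    # non-crossing: rearrange across centiles at each grid age
    curves = np.sort(curves, axis=0)
    # keep curves inside the observed volume range: values beyond it are
    # boundary extrapolation artefacts of the spline fit
    curves = np.clip(curves, float(y.min()), float(y.max()))

    top = np.full(len(age_grid), float(y.max()))
    bands = [
        VolumeBand(region, BAND_LABELS[0], age_grid, curves[-1], top)
    ]
    for k in range(len(centiles) - 1, 0, -1):
        label = BAND_LABELS[len(centiles) - k]
        bands.append(
            VolumeBand(region, label, age_grid, curves[k - 1], curves[k])
        )
    return bands


def band_probability(
    draws: PosteriorDraws,
    diagnosis: str,
    age: float,
    band: VolumeBand,
    seed: int | np.random.Generator = 0,
    include_random_effects: bool = True,
) -> float:
    """Posterior-predictive probability that a new individual's volume
    falls inside ``band`` at ``age``: the fraction of retained draws whose
    simulated response (fixed-effects mean, plus a fresh random-effect
    pair from MVN(0, Sigma_m) and residual noise when
    ``include_random_effects``) lies between the band curves.
    """
    if diagnosis not in DIAGNOSES:
        raise ValueError(f"unknown diagnosis {diagnosis!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(seed))
    )
    t = (age - draws.age_mean) / draws.age_sd
    m = 1.0 if diagnosis == "MCI" else 0.0
    a = 1.0 if diagnosis == "AD" else 0.0
    x = np.array([1.0, t, m, a, m * t, a * t])
    mean = draws.beta @ x
    if include_random_effects:
        S = draws.Sigma
        l11 = np.sqrt(S[:, 0, 0])
        with np.errstate(invalid="ignore", divide="ignore"):
            l21 = np.where(l11 > 0, S[:, 1, 0] / np.where(l11 > 0, l11, 1.0), 0.0)
        l22 = np.sqrt(np.maximum(S[:, 1, 1] - l21 ** 2, 0.0))
        z = rng.standard_normal((2, draws.n_draws))
        b0 = l11 * z[0]
        b1 = l21 * z[0] + l22 * z[1]
        y_rep = (
            mean + b0 + b1 * t
            + np.sqrt(draws.sigma2) * rng.standard_normal(draws.n_draws)
        )
    else:
        y_rep = mean
    lo, hi = band.lower_at(age), band.upper_at(age)
    return float(np.mean((y_rep >= lo) & (y_rep <= hi)))


def diagnosis_posterior(band_probs, prevalence) -> np.ndarray:
    """Bayes inversion: P(Dx | V in R, age) over (HC, MCI, AD).

    ``band_probs`` are the per-diagnosis band probabilities
    P(V in R | Dx, age) and ``prevalence`` the per-diagnosis prior
    P(Dx | age); both ordered (HC, MCI, AD).
    """
    L = np.asarray(band_probs, dtype=float)
    prior = np.asarray(prevalence, dtype=float)
    if L.shape != (3,) or prior.shape != (3,):
        raise ValueError("need one entry per diagnosis (HC, MCI, AD)")
    if np.any(L < 0) or np.any(L > 1):
        raise ValueError("band probabilities must lie in [0, 1]")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prevalence must sum to 1")
    numer = L * prior
    total = numer.sum()
    if total == 0.0:
        raise ZeroDivisionError(
            "all band probabilities are zero; the posterior is undefined"
        )
    return numer / total


def trajectory_with_mc_se(
    dataset: pd.DataFrame,
    region: str,
    prevalence: PrevalenceTable = DEFAULT_PREVALENCE,
    spec: ModelSpec | None = None,
    config: MCMCConfig | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    centiles: tuple = CENTILES,
    age_grid: np.ndarray = AGE_GRID,
    max_rhat: float = 1.1,
    max_retries: int = 3,
    include_random_effects: bool = True,
    replicate_seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Diagnosis trajectories with Monte Carlo standard-error intervals.

    Fits the model ``n_replicates`` times with independent seeds, runs the
    band-probability + Bayes-inversion pipeline for every (band, age,
    diagnosis) cell, and summarises across replicates: point estimate =
    replicate mean, interval = mean +/- 1.96 * sd (no sqrt(K) division; a
    conservative spread of the replicate estimates).  Replicates whose
    worst R-hat reaches ``max_rhat`` are rejected, logged, and re-run with
    a fresh seed.

    Returns a long table with columns region, band, age, diagnosis, p,
    lo, hi, n_replicates.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a Monte Carlo SE")
    if replicate_seeds is not None and len(replicate_seeds) != n_replicates:
        raise ValueError("replicate_seeds must have one entry per replicate")
    # bands are always fitted over the full age support; age_grid only
    # selects the evaluation ages
    bands = fit_centile_bands(dataset, region, centiles, AGE_GRID)
    if replicate_seeds is not None:
        rep_seqs = [np.random.SeedSequence(s) for s in replicate_seeds]
    else:
        rep_seqs = np.random.SeedSequence(seed).spawn(n_replicates)

    estimates = []  # each: (n_bands, n_ages, 3)
    for k in range(n_replicates):
        attempts = iter([rep_seqs[k]] + list(rep_seqs[k].spawn(max_retries)))
        for attempt in range(max_retries + 1):
            ss = next(attempts)
            fit_seed, pred_seed = ss.generate_state(2) % (2 ** 31)
            cfg = dataclasses.replace(
                config or MCMCConfig.test_profile(),
                seed=int(fit_seed), seed_per_chain=None,
            )
            draws = gibbs_sample(dataset, region, spec=spec, config=cfg)
            worst = max(rhat_summary(draws).values())
            if worst < max_rhat:
                break
            logger.warning(
                "trajectory replicate %d attempt %d rejected: max R-hat %.3f",
                k, attempt, worst,
            )
        else:
            raise RuntimeError(
                f"replicate {k} failed convergence after {max_retries} retries"
            )
        rng = np.random.Generator(np.random.PCG64(int(pred_seed)))
        grid = np.empty((len(bands), len(age_grid), 3))
        for bi, band in enumerate(bands):
            for ai, age in enumerate(age_grid):
                probs = [
                    band_probability(
                        draws, dx, float(age), band, seed=rng,
                        include_random_effects=include_random_effects,
                    )
                    for dx in DIAGNOSES
                ]
                prior = interpolate_prevalence(prevalence, float(age))
                grid[bi, ai] = diagnosis_posterior(probs, prior)
        estimates.append(grid)

    stack = np.stack(estimates)               # K x bands x ages x 3
    point = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    lo = point - 1.96 * sd
    hi = point + 1.96 * sd

    rows = []
    for bi, band in enumerate(bands):
        for ai, age in enumerate(age_grid):
            for di, dx in enumerate(DIAGNOSES):
                rows.append(
                    {
                        "region": region,
                        "band": band.label,
                        "age": float(age),
                        "diagnosis": dx,
                        "p": point[bi, ai, di],
                        "lo": lo[bi, ai, di],
                        "hi": hi[bi, ai, di],
                        "n_replicates": n_replicates,
                    }
                )
    return pd.DataFrame(rows)
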