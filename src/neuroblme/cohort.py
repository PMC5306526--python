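"""Synthetic longitudinal cohorts of brain-region volumes.

Emulates an ageing study in which ~260 participants, diagnosed healthy
control (HC), mild cognitive impairment (MCI) or Alzheimer's disease (AD),
are scanned at up to four visits roughly 18 months apart, with staged
dropout and a small number of "converters" whose diagnosis worsens during
follow-up.  Responses are intracranial-volume (ICV) normalised region
volumes: the lateral-ventricle fraction lies in (0, 1), and the hippocampus
fraction is scaled up by 100 to keep variance estimates away from zero.

Volumes are drawn from the random-intercept/random-slope linear
mixed-effects model that the inference modules fit:

    y_it = b0 + b1*t_it + b2*m_it + b3*a_it + b4*m_it*t_it + b5*a_it*t_it
           + u_0i + u_1i*t_it + e_it

with t_it the standardised age, (m, a) the MCI/AD indicators,
(u_0i, u_1i) ~ MVN(0, Sigma) per participant and e_it ~ N(0, sigma2).
Group sizes, converter paths, visit counts and retention are deterministic
given the design; only ages and volumes are stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DIAGNOSES",
    "COHORT_COLUMNS",
    "CohortDesign",
    "TrueParameters",
    "CohortDesignError",
    "CohortDataError",
    "DEFAULT_DESIGN",
    "DEFAULT_VENTRICLE_PARAMS",
    "DEFAULT_HIPPOCAMPUS_PARAMS",
    "default_true_parameters",
    "standardise_age",
    "generate_cohort",
    "validate_cohort",
    "write_cohort",
    "read_cohort",
    "converter_ids",
    "participant_paths",
]

DIAGNOSES = ("HC", "MCI", "AD")
_SEVERITY = {"HC": 0, "MCI": 1, "AD": 2}

#: canonical long-format column order, one row per visit
COHORT_COLUMNS = [
    "id",
    "visit",
    "age_years",
    "diagnosis",
    "ventricle_icv",
    "hippocampus_icv_x100",
]


class CohortDesignError(ValueError):
    """An internally inconsistent or infeasible cohort design."""


class CohortDataError(ValueError):
    """A cohort table violating the visit-record invariants."""


# Diagnosis sequences for the four converter paths, over max_visits visits.
# MCI->AD converters switch at the final visit; the two-step path spreads
# HC -> MCI -> AD across the four follow-ups.
_DEFAULT_CONVERTER_SCHEDULES = {
    "hc_mci": ("HC", "HC", "MCI", "MCI"),
    "hc_ad": ("HC", "HC", "AD", "AD"),
    "hc_mci_ad": ("HC", "MCI", "MCI", "AD"),
    "mci_ad": ("MCI", "MCI", "MCI", "AD"),
}


@dataclass(frozen=True)
class CohortDesign:
    """Deterministic skeleton of the cohort: group sizes, visits, dropout.

    ``retention_by_visit`` holds the fraction of the cohort still observed
    at each visit index (first entry 1).  Dropout is monotone: a participant
    observed at visit k was observed at all earlier visits.  Converters are
    always retained to the final visit so their designed diagnosis switch is
    observed.
    """

    n_hc_stable: int = 157
    n_mci_stable: int = 34
    n_ad_stable: int = 42
    n_conv_hc_mci: int = 8
    n_conv_hc_ad: int = 1
    n_conv_hc_mci_ad: int = 2
    n_conv_mci_ad: int = 16
    max_visits: int = 4
    visit_interval_years: float = 1.5
    retention_by_visit: tuple[float, ...] = (1.0, 241 / 260, 210 / 260, 179 / 260)
    n_single_visit: int = 19
    baseline_age_mean: float = 72.0
    baseline_age_sd: float = 6.0
    baseline_age_range: tuple[float, float] = (60.0, 85.0)
    converter_schedules: dict = field(
        default_factory=lambda: dict(_DEFAULT_CONVERTER_SCHEDULES)
    )

    @property
    def n_converters(self) -> int:
        return (
            self.n_conv_hc_mci
            + self.n_conv_hc_ad
            + self.n_conv_hc_mci_ad
            + self.n_conv_mci_ad
        )

    @property
    def n_total(self) -> int:
        return (
            self.n_hc_stable + self.n_mci_stable + self.n_ad_stable + self.n_converters
        )

    def retention_counts(self) -> np.ndarray:
        """Number of participants observed at each visit index."""
        counts = np.rint(np.asarray(self.retention_by_visit) * self.n_total)
        return counts.astype(int)

    def validate(self) -> None:
        counts = [
            self.n_hc_stable,
            self.n_mci_stable,
            self.n_ad_stable,
            self.n_conv_hc_mci,
            self.n_conv_hc_ad,
            self.n_conv_hc_mci_ad,
            self.n_conv_mci_ad,
        ]
        if any(c < 0 for c in counts):
            raise CohortDesignError("group counts must be non-negative")
        if self.max_visits < 1:
            raise CohortDesignError("max_visits must be >= 1")
        if len(self.retention_by_visit) != self.max_visits:
            raise CohortDesignError(
                "retention_by_visit must have one entry per visit index"
            )
        if abs(self.retention_by_visit[0] - 1.0) > 1e-12:
            raise CohortDesignError("retention at the first visit must be 1")
        ret = np.asarray(self.retention_by_visit)
        if np.any(np.diff(ret) > 1e-12):
            raise CohortDesignError("retention_by_visit must be non-increasing")
        if self.n_single_visit > self.n_total:
            raise CohortDesignError("n_single_visit exceeds the cohort size")
        rc = self.retention_counts()
        if self.max_visits >= 2 and self.n_total - rc[1] != self.n_single_visit:
            raise CohortDesignError(
                f"n_single_visit={self.n_single_visit} inconsistent with "
                f"retention at visit 2 ({rc[1]}/{self.n_total})"
            )
        # converters stay to the final visit, so the final retained count
        # must at least accommodate them
        if self.max_visits >= 2 and rc[-1] < self.n_converters:
            raise CohortDesignError(
                "final-visit retention smaller than the number of converters"
            )
        lo, hi = self.baseline_age_range
        if not (60.0 - 1e-9 <= lo < hi <= 85.0 + 1e-9):
            raise CohortDesignError("baseline_age_range must lie within [60, 85]")
        for path, schedule in self.converter_schedules.items():
            if len(schedule) != self.max_visits:
                raise CohortDesignError(
                    f"converter schedule for {path!r} must span max_visits visits"
                )
            sev = [_SEVERITY[d] for d in schedule]
            if any(b < a for a, b in zip(sev, sev[1:])):
                raise CohortDesignError(
                    f"converter schedule for {path!r} improves diagnosis"
                )


@dataclass(frozen=True)
class TrueParameters:
    """Generative parameters of the mixed model for one region.

    ``beta`` is (intercept, age slope, MCI offset, AD offset, MCI x age,
    AD x age) in response units per standardised-age unit; ``sigma2`` the
    residual variance; ``Sigma`` the 2x2 covariance of the random intercept
    and slope.  ``sigma2 = 0`` and ``Sigma = 0`` are permitted for the
    noise-free degenerate limit.
    """

    beta: tuple[float, ...]
    sigma2: float
    Sigma: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (6,):
            raise ValueError("beta must have 6 entries")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric 2x2")
        eig = np.linalg.eigvalsh(S)
        if np.any(eig < -1e-12):
            raise ValueError("Sigma must be positive semi-definite")

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    @property
    def Sigma_array(self) -> np.ndarray:
        return np.asarray(self.Sigma, dtype=float)


DEFAULT_DESIGN = CohortDesign()

# Ventricle: volumes around 3% of ICV, enlarging with age, faster under MCI
# and fastest under AD.  Hippocampus (x100 scale): around 0.45, shrinking
# with age, faster with worsening diagnosis.  Slope separations are sized so
# the posterior ordering of the three diagnosis groups is decisive on a
# cohort of the default size.
DEFAULT_VENTRICLE_PARAMS = TrueParameters(
    beta=(0.055, 0.005, 0.005, 0.012, 0.003, 0.008),
    sigma2=4.0e-6,
    Sigma=((2.5e-5, 2.5e-6), (2.5e-6, 6.25e-6)),
)
DEFAULT_HIPPOCAMPUS_PARAMS = TrueParameters(
    beta=(0.450, -0.010, -0.030, -0.060, -0.015, -0.040),
    sigma2=2.25e-4,
    Sigma=((1.6e-3, -9.0e-5), (-9.0e-5, 2.25e-4)),
)


def default_true_parameters(region: str) -> TrueParameters:
    if region == "ventricle":
        return DEFAULT_VENTRICLE_PARAMS
    if region == "hippocampus":
        return DEFAULT_HIPPOCAMPUS_PARAMS
    raise ValueError(f"unknown region {region!r}")


def standardise_age(ages) -> tuple[np.ndarray, float, float]:
    """Centre and scale ages to empirical mean 0, sd 1 (n-1 denominator).

    Returns ``(age_std, mean, sd)``; the constants allow back-transformation
    of model slopes to per-year units (divide by ``sd``).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least two ages to standardise")
    mean = float(ages.mean())
    sd = float(ages.std(ddof=1))
    if sd == 0.0:
        raise ValueError("ages are constant; standardisation is degenerate")
    return (ages - mean) / sd, mean, sd


def _assign_visit_counts(design: CohortDesign, rng: np.random.Generator,
                         is_converter: np.ndarray) -> np.ndarray:
    """Visit counts per participant matching the retention counts exactly.

    Converters keep all visits; the remaining dropout slots are assigned
    completely at random among stable participants.
    """
    n = design.n_total
    rc = design.retention_counts()
    # participants with exactly k visits, k = 1..max_visits
    exact = np.append(rc[:-1] - rc[1:], rc[-1])
    n_conv = int(is_converter.sum())
    if exact[-1] < n_conv:
        raise CohortDesignError("not enough final-visit slots for converters")
    stable_idx = np.flatnonzero(~is_converter)
    counts = np.full(n, design.max_visits, dtype=int)
    # stable participants to receive fewer than max_visits visits
    pool = rng.permutation(stable_idx)
    pos = 0
    for k, n_k in enumerate(exact[:-1], start=1):
        take = pool[pos: pos + n_k]
        if len(take) < n_k:
            raise CohortDesignError("dropout design infeasible for stable group")
        counts[take] = k
        pos += n_k
    return counts


def _simulate_region(X: np.ndarray, pid_index: np.ndarray, n_participants: int,
                     params: TrueParameters, rng: np.random.Generator) -> np.ndarray:
    t = X[:, 1]
    mean = X @ params.beta_array
    S = params.Sigma_array
    if np.allclose(S, 0.0):
        b = np.zeros((n_participants, 2))
    else:
        b = rng.multivariate_normal(np.zeros(2), S, size=n_participants,
                                    method="cholesky" if _is_pd(S) else "eigh")
    eps = (
        rng.normal(0.0, np.sqrt(params.sigma2), size=len(t))
        if params.sigma2 > 0
        else np.zeros(len(t))
    )
    return mean + b[pid_index, 0] + b[pid_index, 1] * t + eps


def _is_pd(S: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(S)
        return True
    except np.linalg.LinAlgError:
        return False


def generate_cohort(
    design: CohortDesign = DEFAULT_DESIGN,
    params_ventricle: TrueParameters = DEFAULT_VENTRICLE_PARAMS,
    params_hippocampus: TrueParameters = DEFAULT_HIPPOCAMPUS_PARAMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one synthetic cohort as a long-format visit table.

    The returned frame has columns :data:`COHORT_COLUMNS`, sorted by
    participant then visit.  Identical ``(design, params, seed)`` give a
    byte-identical table.
    """
    design.validate()
    rng = np.random.Generator(np.random.PCG64(seed))
    n = design.n_total

    groups = (
        ["HC"] * design.n_hc_stable
        + ["MCI"] * design.n_mci_stable
        + ["AD"] * design.n_ad_stable
        + ["hc_mci"] * design.n_conv_hc_mci
        + ["hc_ad"] * design.n_conv_hc_ad
        + ["hc_mci_ad"] * design.n_conv_hc_mci_ad
        + ["mci_ad"] * design.n_conv_mci_ad
    )
    is_converter = np.array([g not in DIAGNOSES for g in groups])
    visit_counts = _assign_visit_counts(design, rng, is_converter)

    lo, hi = design.baseline_age_range
    a, b_ = (
        (lo - design.baseline_age_mean) / design.baseline_age_sd,
        (hi - design.baseline_age_mean) / design.baseline_age_sd,
    )
    baseline_age = stats.truncnorm.rvs(
        a, b_, loc=design.baseline_age_mean, scale=design.baseline_age_sd,
        size=n, random_state=rng,
    )

    rows_id, rows_visit, rows_age, rows_dx = [], [], [], []
    for i, group in enumerate(groups):
        for v in range(visit_counts[i]):
            rows_id.append(i + 1)
            rows_visit.append(v + 1)
            rows_age.append(baseline_age[i] + v * design.visit_interval_years)
            if group in DIAGNOSES:
                rows_dx.append(group)
            else:
                rows_dx.append(design.converter_schedules[group][v])

    df = pd.DataFrame(
        {
            "id": rows_id,
            "visit": rows_visit,
            "age_years": rows_age,
            "diagnosis": rows_dx,
        }
    )
    age_std, _, _ = standardise_age(df["age_years"].to_numpy())
    m = (df["diagnosis"] == "MCI").to_numpy(float)
    a_ind = (df["diagnosis"] == "AD").to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), age_std, m, a_ind, m * age_std, a_ind * age_std]
    )
    pid_index = df["id"].to_numpy() - 1

    df["ventricle_icv"] = _simulate_region(X, pid_index, n, params_ventricle, rng)
    df["hippocampus_icv_x100"] = _simulate_region(
        X, pid_index, n, params_hippocampus, rng
    )
    df = df[COHORT_COLUMNS].reset_index(drop=True)
    return df


def participant_paths(dataset: pd.DataFrame) -> pd.Series:
    """Label each participant HC/MCI/AD (stable) or 'converter'."""
    def label(g: pd.DataFrame) -> str:
        dx = g.sort_values("visit")["diagnosis"].tolist()
        return dx[0] if len(set(dx)) == 1 else "converter"

    return (
        dataset.groupby("id", sort=True)[["visit", "diagnosis"]]
        .apply(label)
        .rename("path")
    )


def converter_ids(dataset: pd.DataFrame) -> np.ndarray:
    paths = participant_paths(dataset)
    return paths.index[paths == "converter"].to_numpy()


def validate_cohort(dataset: pd.DataFrame) -> None:
    """Check the visit-record invariants, naming the offending row."""
    missing = [c for c in COHORT_COLUMNS if c not in dataset.columns]
    if missing:
        raise CohortDataError(f"missing columns: {missing}")
    dx = dataset["diagnosis"]
    bad = ~dx.isin(DIAGNOSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortDataError(
            f"row {row}: unknown diagnosis label {dx.iloc[row]!r}"
        )
    v = dataset["ventricle_icv"].to_numpy(float)
    if np.any((v <= 0) | (v >= 1)):
        row = int(np.flatnonzero((v <= 0) | (v >= 1))[0])
        raise CohortDataError(f"row {row}: ventricle_icv outside (0, 1)")
    h = dataset["hippocampus_icv_x100"].to_numpy(float)
    if np.any(h <= 0):
        row = int(np.flatnonzero(h <= 0)[0])
        raise CohortDataError(f"row {row}: hippocampus_icv_x100 not positive")
    # optional explicit indicator columns must agree with the diagnosis label
    if "m" in dataset.columns and "a" in dataset.columns:
        m = dataset["m"].to_numpy(int)
        a = dataset["a"].to_numpy(int)
        bad = (m == 1) & (a == 1)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortDataError(f"row {row}: m and a indicators both set")
        expect_m = (dx == "MCI").to_numpy(int)
        expect_a = (dx == "AD").to_numpy(int)
        mism = (m != expect_m) | (a != expect_a)
        if mism.any():
            row = int(np.flatnonzero(mism)[0])
            raise CohortDataError(
                f"row {row}: indicators disagree with diagnosis label"
            )
    for pid, g in dataset.groupby("id", sort=False):
        g = g.sort_values("visit")
        ages = g["age_years"].to_numpy(float)
        if np.any(np.diff(ages) <= 0):
            raise CohortDataError(
                f"participant {pid}: visit ages not strictly increasing"
            )
        sev = g["diagnosis"].map(_SEVERITY).to_numpy()
        if np.any(np.diff(sev) < 0):
            raise CohortDataError(
                f"participant {pid}: diagnosis improves across visits"
            )


def write_cohort(dataset: pd.DataFrame, path) -> None:
    """Write the long-format CSV (UTF-8, header, full float precision)."""
    dataset.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Diagnosis labels are canonicalised (surrounding whitespace stripped,
    upper-cased) before validation, so ``"MCI "`` is accepted.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if "diagnosis" in df.columns:
        df["diagnosis"] = df["diagnosis"].astype(str).str.strip().str.upper()
    validate_cohort(df)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    return df[COHORT_COLUMNS + extra]
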