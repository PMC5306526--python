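"""Bayesian random-intercept/random-slope model and its Gibbs sampler.

The response for participant i at visit t is

    y_it = x_it' beta + z_it' b_i + e_it,
    e_it ~ N(0, sigma2),   b_i ~ MVN(0, Sigma),

with x_it = (1, t_it, m_it, a_it, m_it*t_it, a_it*t_it) for standardised age
t and MCI/AD indicators (m, a), and z_it = (1, t_it).  Semiconjugate priors

    beta ~ N(mu0, V0),  sigma2 ~ InvGamma(a0, b0),  Sigma ~ InvWishart(nu0, S0)

yield exact full conditionals, so the posterior is sampled by a blocked
Gibbs sweep: beta | b, sigma2 (multivariate normal), each b_i | beta, Sigma,
sigma2 (bivariate normal), sigma2 | beta, b (inverse gamma), Sigma | b
(inverse Wishart).  Chains are run independently from dispersed starting
values; burn-in is discarded and the remainder thinned per chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import validate_cohort

__all__ = [
    "REGIONS",
    "FIXED_EFFECT_NAMES",
    "SCALAR_PARAMETERS",
    "ModelSpec",
    "MCMCConfig",
    "DesignMatrices",
    "PosteriorDraws",
    "SamplerNumericalError",
    "build_design",
    "gibbs_sample",
    "gelman_rubin",
    "rhat_summary",
    "chain_summaries",
    "save_draws",
    "load_draws",
]

REGIONS = {"ventricle": "ventricle_icv", "hippocampus": "hippocampus_icv_x100"}
FIXED_EFFECT_NAMES = ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5")
#: scalar parameters monitored for convergence diagnostics
SCALAR_PARAMETERS = FIXED_EFFECT_NAMES + ("sigma2", "Sigma00", "Sigma01", "Sigma11")


class SamplerNumericalError(RuntimeError):
    """A full-conditional covariance failed to factorise."""


def _spd_check(name: str, M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc
    return M


@dataclass(frozen=True)
class ModelSpec:
    """Prior hyperparameters of the semiconjugate model.

    Defaults are weakly informative: a diffuse normal on the fixed effects,
    a near-flat inverse gamma on the residual variance and an inverse
    Wishart with the minimal proper degrees of freedom on the random-effects
    covariance.
    """

    prior_beta_mean: np.ndarray = field(
        default_factory=lambda: np.zeros(6)
    )
    prior_beta_cov: np.ndarray = field(
        default_factory=lambda: 1.0e6 * np.eye(6)
    )
    # The inverse-gamma rate and inverse-Wishart scale must be small relative
    # to the residual sum of squares and to sum_i b_i b_i' respectively, or
    # they dominate the variance components.  ICV-normalised volumes have
    # variances of order 1e-6..1e-3, so "vague" constants sized for
    # unit-scale responses (0.001, 0.01 I) are strongly informative here;
    # the defaults below are vague across both response scales.
    prior_sigma2_shape: float = 0.001
    prior_sigma2_rate: float = 1.0e-6
    prior_Sigma_df: float = 3.0
    prior_Sigma_scale: np.ndarray = field(
        default_factory=lambda: 1.0e-6 * np.eye(2)
    )

    def validate(self) -> None:
        if np.asarray(self.prior_beta_mean, dtype=float).shape != (6,):
            raise ValueError("prior_beta_mean must have 6 entries")
        _spd_check("prior_beta_cov", self.prior_beta_cov)
        _spd_check("prior_Sigma_scale", self.prior_Sigma_scale)
        if self.prior_sigma2_shape <= 0 or self.prior_sigma2_rate <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")
        if self.prior_Sigma_df <= 1:
            raise ValueError("inverse-Wishart df must exceed q - 1 = 1")

    @classmethod
    def autoscaled(cls, dataset: pd.DataFrame, region: str) -> "ModelSpec":
        """Weakly informative priors sized to the response scale.

        A fixed-constant "vague" prior cannot be vague for every response
        scale: an inverse-Wishart scale far above the random-effect
        variances inflates them, while a near-zero scale combined with the
        |Sigma|^-(nu+p+1)/2 factor traps weakly identified variance
        components at zero.  Here the inverse-Wishart scale is set to
        moment estimates of the random intercept/slope variances (from
        per-participant least-squares lines), with df = q + 2 = 4 so the
        prior mean equals that estimate at the weight of roughly one
        participant; the residual-variance rate is 0.001 times the pooled
        within-participant residual variance.  The fixed-effects prior
        stays diffuse.  Passing an explicit :class:`ModelSpec` overrides
        this (the sensitivity-analysis hook).
        """
        design = build_design(dataset)
        y = design.y[region]
        beta_ols, *_ = np.linalg.lstsq(design.X, y, rcond=None)
        e = y - design.X @ beta_ols
        marginal = max(float(np.var(e)), 1e-300)

        inter, slope, ss, df_resid = [], [], 0.0, 0
        for j in range(design.n_participants):
            mask = design.pid_index == j
            ej, tj = e[mask], design.t[mask]
            if len(ej) >= 3 and np.ptp(tj) > 0:
                coef = np.polyfit(tj, ej, 1)
                inter.append(coef[1] + coef[0] * tj.mean())
                slope.append(coef[0])
                r = ej - np.polyval(coef, tj)
                ss += float(r @ r)
                df_resid += len(ej) - 2
        sigma2_hat = ss / df_resid if df_resid > 0 else marginal
        sigma2_hat = max(sigma2_hat, 1e-6 * marginal)
        v0 = float(np.var(inter, ddof=1)) if len(inter) > 2 else marginal
        v1 = float(np.var(slope, ddof=1)) if len(slope) > 2 else marginal
        v0 = max(v0, 1e-4 * marginal)
        v1 = max(v1, 1e-4 * marginal)
        return cls(
            prior_sigma2_rate=0.001 * sigma2_hat,
            prior_Sigma_df=4.0,
            prior_Sigma_scale=np.diag([v0, v1]),
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule.  ``paper_profile`` is the full production schedule
    (2 chains x 300K iterations, 100K burn-in, thin 50, i.e. 8000 retained
    draws); ``test_profile`` is the reduced desk-scale schedule used by the
    test suite and examples."""

    n_chains: int = 2
    n_iterations: int = 300_000
    n_burnin: int = 100_000
    thin: int = 50
    seed: int = 0
    seed_per_chain: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if (
            self.seed_per_chain is not None
            and len(self.seed_per_chain) != self.n_chains
        ):
            raise ValueError("seed_per_chain must have one entry per chain")

    @property
    def n_retained(self) -> int:
        """Total retained draws M across chains."""
        return self.n_chains * ((self.n_iterations - self.n_burnin) // self.thin)

    def chain_seeds(self) -> list[np.random.SeedSequence]:
        if self.seed_per_chain is not None:
            return [np.random.SeedSequence(s) for s in self.seed_per_chain]
        return np.random.SeedSequence(self.seed).spawn(self.n_chains)

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "MCMCConfig":
        return cls(seed=seed)

    @classmethod
    def test_profile(cls, seed: int = 0) -> "MCMCConfig":
        return cls(
            n_chains=2, n_iterations=20_000, n_burnin=5_000, thin=10, seed=seed
        )


@dataclass(frozen=True)
class DesignMatrices:
    """Stacked design in participant-major, visit-ascending row order."""

    X: np.ndarray                 # n x 6 fixed-effects design
    t: np.ndarray                 # n, standardised age (= X[:, 1])
    pid_index: np.ndarray         # n, 0-based participant index per row
    participant_ids: np.ndarray   # N, sorted original ids
    y: dict                       # region -> n response vector
    age_mean: float
    age_sd: float

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)


def build_design(dataset: pd.DataFrame) -> DesignMatrices:
    """Assemble X, the random-effects blocks and responses from a cohort.

    Rows are ordered by (participant id, visit); diagnosis indicator columns
    are taken per visit, so converters change columns mid-follow-up.
    """
    validate_cohort(dataset)
    from .cohort import standardise_age

    df = dataset.sort_values(["id", "visit"], kind="stable").reset_index(drop=True)
    counts = df.groupby("id", sort=True).size()
    if (counts == 0).any():
        raise ValueError("participant with zero visits")
    age_std, age_mean, age_sd = standardise_age(df["age_years"].to_numpy())
    m = (df["diagnosis"] == "MCI").to_numpy(float)
    a = (df["diagnosis"] == "AD").to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), age_std, m, a, m * age_std, a * age_std]
    )
    ids = np.sort(df["id"].unique())
    pid_index = np.searchsorted(ids, df["id"].to_numpy())
    y = {region: df[col].to_numpy(float) for region, col in REGIONS.items()}
    return DesignMatrices(
        X=X, t=age_std, pid_index=pid_index, participant_ids=ids,
        y=y, age_mean=age_mean, age_sd=age_sd,
    )


@dataclass
class PosteriorDraws:
    """Retained joint posterior draws for one region.

    All arrays are aligned on the first (draw) axis; ``chain`` labels the
    chain each retained draw came from.  The age-standardisation constants
    of the fitted dataset are carried along for back-transformation.
    """

    beta: np.ndarray            # M x 6
    sigma2: np.ndarray          # M
    Sigma: np.ndarray           # M x 2 x 2
    random_effects: np.ndarray  # M x N x 2
    chain: np.ndarray           # M, 0-based chain label
    participant_ids: np.ndarray
    age_mean: float
    age_sd: float
    region: str

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_participants(self) -> int:
        return self.random_effects.shape[1]

    def scalar_parameter(self, name: str) -> np.ndarray:
        """Draws of one monitored scalar parameter, as a flat M vector."""
        if name in FIXED_EFFECT_NAMES:
            return self.beta[:, FIXED_EFFECT_NAMES.index(name)]
        if name == "sigma2":
            return self.sigma2
        if name.startswith("Sigma"):
            i, j = int(name[5]), int(name[6])
            return self.Sigma[:, i, j]
        raise KeyError(name)

    def by_chain(self, name: str) -> np.ndarray:
        """Draws of a scalar parameter as an (n_chains, draws) array."""
        x = self.scalar_parameter(name)
        labels = np.unique(self.chain)
        per = [x[self.chain == c] for c in labels]
        length = min(len(p) for p in per)
        return np.stack([p[:length] for p in per])


def _sample_invwishart(df: float, scale: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw a 2x2 inverse-Wishart matrix via the Bartlett decomposition.

    With A the Bartlett factor of Wishart(df, I) and L = chol(scale), the
    product B = L A^-T gives Sigma = B B^T ~ InvWishart(df, scale).  Working
    entirely in triangular factors keeps the draw positive definite even at
    extreme scales (no determinant cancellation).
    """
    try:
        L = np.linalg.cholesky(np.asarray(scale, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise SamplerNumericalError(
            "inverse-Wishart scale not positive definite"
        ) from exc
    a11 = math.sqrt(rng.chisquare(df))
    a22 = math.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    # A^-T for the lower-triangular Bartlett factor A
    inv_at = np.array([[1.0 / a11, -a21 / (a11 * a22)], [0.0, 1.0 / a22]])
    B = L @ inv_at
    S = B @ B.T
    # relative diagonal jitter keeps near-singular draws factorisable;
    # 1e-12 of the trace is far below Monte Carlo resolution
    S[0, 0] += 1e-12 * (S[0, 0] + S[1, 1])
    S[1, 1] += 1e-12 * (S[0, 0] + S[1, 1])
    return S


def _inv2_spd(M: np.ndarray) -> np.ndarray:
    """Inverse of a 2x2 SPD matrix via its Cholesky factor (stable at
    extreme scales)."""
    a, c = M[0, 0], M[1, 1]
    b = M[1, 0]
    if a <= 0:
        raise SamplerNumericalError("2x2 matrix not positive definite")
    l11 = math.sqrt(a)
    l21 = b / l11
    rest = c - l21 * l21
    if rest <= 0 or not np.isfinite(rest):
        raise SamplerNumericalError("2x2 matrix not positive definite")
    l22 = math.sqrt(rest)
    # T = inv(L); inv(M) = T^T T
    t11 = 1.0 / l11
    t21 = -l21 / (l11 * l22)
    t22 = 1.0 / l22
    return np.array(
        [[t11 * t11 + t21 * t21, t21 * t22], [t21 * t22, t22 * t22]]
    )


def _run_chain(design: DesignMatrices, y: np.ndarray, spec: ModelSpec,
               n_iterations: int, n_burnin: int, thin: int,
               seed_seq: np.random.SeedSequence):
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    X, t, pid = design.X, design.t, design.pid_index
    n, p = X.shape
    N = design.n_participants

    counts = np.bincount(pid, minlength=N).astype(float)
    sum_t = np.bincount(pid, weights=t, minlength=N)
    sum_t2 = np.bincount(pid, weights=t * t, minlength=N)
    XtX = X.T @ X

    V0inv = np.linalg.inv(np.asarray(spec.prior_beta_cov, dtype=float))
    mu0 = np.asarray(spec.prior_beta_mean, dtype=float)
    V0inv_mu0 = V0inv @ mu0
    a0, b0 = spec.prior_sigma2_shape, spec.prior_sigma2_rate
    nu0 = spec.prior_Sigma_df
    S0 = np.asarray(spec.prior_Sigma_scale, dtype=float)

    # dispersed start: least-squares beta with noise, inflated variances
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta
    s2_hat = max(float(resid0 @ resid0) / max(n - p, 1), 1e-12)
    beta = beta + rng.normal(scale=np.sqrt(s2_hat), size=p)
    sigma2 = s2_hat * math.exp(rng.normal(scale=0.5))
    Sigma = np.eye(2) * s2_hat * math.exp(rng.normal(scale=0.5))
    b = np.zeros((N, 2))

    n_keep = (n_iterations - n_burnin) // thin
    out_beta = np.empty((n_keep, p))
    out_sigma2 = np.empty(n_keep)
    out_Sigma = np.empty((n_keep, 2, 2))
    out_b = np.empty((n_keep, N, 2))
    keep = 0

    for it in range(n_iterations):
        # --- beta | b, sigma2 ---
        zb = b[pid, 0] + b[pid, 1] * t
        r = y - zb
        P = V0inv + XtX / sigma2
        try:
            Lp = np.linalg.cholesky(P)
        except np.linalg.LinAlgError as exc:
            raise SamplerNumericalError(
                f"beta update not positive definite at iteration {it}"
            ) from exc
        rhs = V0inv_mu0 + X.T @ r / sigma2
        w = np.linalg.solve(Lp, rhs)
        mean_beta = np.linalg.solve(Lp.T, w)
        beta = mean_beta + np.linalg.solve(Lp.T, rng.standard_normal(p))

        # --- b_i | beta, Sigma, sigma2 (vectorised 2x2 conjugate) ---
        e = y - X @ beta
        s0 = np.bincount(pid, weights=e, minlength=N)
        s1 = np.bincount(pid, weights=e * t, minlength=N)
        try:
            Sinv = _inv2_spd(Sigma)
        except SamplerNumericalError as exc:
            raise SamplerNumericalError(
                f"random-effect covariance not positive definite "
                f"at iteration {it}"
            ) from exc
        A11 = Sinv[0, 0] + counts / sigma2
        A12 = Sinv[0, 1] + sum_t / sigma2
        A22 = Sinv[1, 1] + sum_t2 / sigma2
        det = A11 * A22 - A12 * A12
        if np.any(det <= 0) or not np.all(np.isfinite(det)):
            raise SamplerNumericalError(
                f"random-effect update not positive definite at iteration {it}"
            )
        c11 = A22 / det
        c12 = -A12 / det
        c22 = A11 / det
        m0 = (c11 * s0 + c12 * s1) / sigma2
        m1 = (c12 * s0 + c22 * s1) / sigma2
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21 * l21, 0.0))
        z = rng.standard_normal((2, N))
        b[:, 0] = m0 + l11 * z[0]
        b[:, 1] = m1 + l21 * z[0] + l22 * z[1]

        # --- sigma2 | beta, b ---
        zb = b[pid, 0] + b[pid, 1] * t
        resid = e - zb
        shape = a0 + 0.5 * n
        rate = b0 + 0.5 * float(resid @ resid)
        sigma2 = rate / rng.gamma(shape)

        # --- Sigma | b ---
        Sigma = _sample_invwishart(nu0 + N, S0 + b.T @ b, rng)

        if it >= n_burnin and (it - n_burnin) % thin == 0 and keep < n_keep:
            out_beta[keep] = beta
            out_sigma2[keep] = sigma2
            out_Sigma[keep] = Sigma
            out_b[keep] = b
            keep += 1

    return out_beta[:keep], out_sigma2[:keep], out_Sigma[:keep], out_b[:keep]


def gibbs_sample(
    dataset: pd.DataFrame,
    region: str,
    spec: ModelSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Sample the joint posterior of the mixed model for one region.

    Runs ``config.n_chains`` independent chains from dispersed starting
    values, discards burn-in and thins each chain, and pools the retained
    draws with chain labels.  Reproducible given the config seeds.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if spec is None:
        spec = ModelSpec.autoscaled(dataset, region)
    config = config or MCMCConfig()
    spec.validate()
    design = build_design(dataset)
    y = design.y[region]

    betas, sigma2s, Sigmas, bs, labels = [], [], [], [], []
    for c, seed_seq in enumerate(config.chain_seeds()):
        ob, os2, oS, obi = _run_chain(
            design, y, spec, config.n_iterations, config.n_burnin,
            config.thin, seed_seq,
        )
        betas.append(ob)
        sigma2s.append(os2)
        Sigmas.append(oS)
        bs.append(obi)
        labels.append(np.full(len(os2), c, dtype=int))

    return PosteriorDraws(
        beta=np.concatenate(betas),
        sigma2=np.concatenate(sigma2s),
        Sigma=np.concatenate(Sigmas),
        random_effects=np.concatenate(bs),
        chain=np.concatenate(labels),
        participant_ids=design.participant_ids,
        age_mean=design.age_mean,
        age_sd=design.age_sd,
        region=region,
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is an (n_chains, n_draws) array of retained draws.  Uses the
    classic between/within variance ratio: with W the mean within-chain
    variance and B/n the variance of the chain means, the pooled variance
    estimate is (n-1)/n W + B/n and R-hat is the square root of its ratio
    to W.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    n = chains.shape[1]
    if n < 2:
        raise ValueError("chains too short for a variance estimate")
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else math.inf
    v_hat = (n - 1) / n * within + between_over_n
    return math.sqrt(v_hat / within)


def rhat_summary(draws: PosteriorDraws) -> dict:
    """R-hat for every monitored scalar parameter."""
    return {name: gelman_rubin(draws.by_chain(name)) for name in SCALAR_PARAMETERS}


def chain_summaries(draws: PosteriorDraws, acf_lags: int = 50):
    """Posterior summaries and autocorrelations of the scalar parameters.

    Returns ``(summary, acf)``: a table of mean, sd and the empirical 2.5%
    and 97.5% quantiles per parameter, and a lag x parameter table of
    autocorrelations (averaged over chains) at lags 1..``acf_lags``.
    """
    from statsmodels.tsa.stattools import acf as sm_acf

    rows, acf_cols = {}, {}
    for name in SCALAR_PARAMETERS:
        x = draws.scalar_parameter(name)
        rows[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
        }
        per_chain = draws.by_chain(name) if len(np.unique(draws.chain)) > 1 \
            else x[None, :]
        lags = min(acf_lags, per_chain.shape[1] - 1)
        acfs = []
        for row in per_chain:
            if np.std(row) == 0:
                acfs.append(np.zeros(lags))
            else:
                acfs.append(sm_acf(row, nlags=lags, fft=True)[1:])
        acf_cols[name] = np.mean(acfs, axis=0)
    summary = pd.DataFrame(rows).T[["mean", "sd", "q2.5", "q97.5"]]
    acf_df = pd.DataFrame(acf_cols)
    acf_df.index = np.arange(1, len(acf_df) + 1)
    acf_df.index.name = "lag"
    return summary, acf_df


def save_draws(draws: PosteriorDraws, directory) -> None:
    """Persist draws as two CSVs: scalars long-form, random effects wide.

    ``scalars.csv`` has one row per retained draw (chain, draw, beta0..5,
    sigma2, Sigma entries); ``random_effects.csv`` has columns
    ``b0_<id>``/``b1_<id>`` keyed by participant id, plus a metadata header
    carried in ``meta.csv``.
    """
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    M = draws.n_draws
    scalars = pd.DataFrame({"chain": draws.chain, "draw": np.arange(M)})
    for i, name in enumerate(FIXED_EFFECT_NAMES):
        scalars[name] = draws.beta[:, i]
    scalars["sigma2"] = draws.sigma2
    scalars["Sigma00"] = draws.Sigma[:, 0, 0]
    scalars["Sigma01"] = draws.Sigma[:, 0, 1]
    scalars["Sigma11"] = draws.Sigma[:, 1, 1]
    scalars.to_csv(d / "scalars.csv", index=False)

    re_cols = {"chain": draws.chain, "draw": np.arange(M)}
    for j, pid in enumerate(draws.participant_ids):
        re_cols[f"b0_{pid}"] = draws.random_effects[:, j, 0]
        re_cols[f"b1_{pid}"] = draws.random_effects[:, j, 1]
    pd.DataFrame(re_cols).to_csv(d / "random_effects.csv", index=False)

    pd.DataFrame(
        [{"region": draws.region, "age_mean": draws.age_mean,
          "age_sd": draws.age_sd}]
    ).to_csv(d / "meta.csv", index=False)


def load_draws(directory) -> PosteriorDraws:
    import pathlib

    d = pathlib.Path(directory)
    scalars = pd.read_csv(d / "scalars.csv")
    re = pd.read_csv(d / "random_effects.csv")
    meta = pd.read_csv(d / "meta.csv").iloc[0]
    pids = np.array(
        sorted({int(c[3:]) for c in re.columns if c.startswith("b0_")})
    )
    M = len(scalars)
    b = np.empty((M, len(pids), 2))
    for j, pid in enumerate(pids):
        b[:, j, 0] = re[f"b0_{pid}"]
        b[:, j, 1] = re[f"b1_{pid}"]
    Sigma = np.empty((M, 2, 2))
    Sigma[:, 0, 0] = scalars["Sigma00"]
    Sigma[:, 0, 1] = Sigma[:, 1, 0] = scalars["Sigma01"]
    Sigma[:, 1, 1] = scalars["Sigma11"]
    return PosteriorDraws(
        beta=scalars[list(FIXED_EFFECT_NAMES)].to_numpy(),
        sigma2=scalars["sigma2"].to_numpy(),
        Sigma=Sigma,
        random_effects=b,
        chain=scalars["chain"].to_numpy(),
        participant_ids=pids,
        age_mean=float(meta["age_mean"]),
        age_sd=float(meta["age_sd"]),
        region=str(meta["region"]),
    )
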