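"""Trait prior distributions and Bayesian trait meta-analysis.

The liana plant functional type is described by 32 parameters, each with a
prior probability distribution elicited on its *positive* storage scale
(parameters that are physically negative — rooting-depth intercept, P50,
stomatal-closure potential, turgor loss point — carry a ``negate`` flag and
are multiplied by -1 at use time).  Field observations of a trait are
combined with its prior through a two-level random-effects meta-analysis
(study-level random intercepts around an across-study mean) to produce a
posterior sample of the across-study mean, whose coefficient of variation
quantifies the remaining parameter uncertainty.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitDistribution",
    "TraitObservation",
    "TraitPosterior",
    "AllometricDataset",
    "MetaAnalysisSettings",
    "TraitMetaAnalysis",
    "AllometricPriorModel",
    "distribution_quantile",
    "coefficient_of_variation",
    "run_meta_analysis",
    "fit_allometric_prior",
    "load_prior_table",
    "load_classification",
]

_FAMILIES = ("uniform", "normal", "lognormal", "gamma", "beta", "weibull")


@dataclass(frozen=True)
class TraitDistribution:
    """A named prior: distribution family with constants (a, b).

    Parameterization: uniform(min=a, max=b); normal(mean=a, sd=b);
    lognormal(meanlog=a, sdlog=b); gamma(shape=a, rate=b); beta(a, b);
    weibull(shape=a, scale=b).
    """

    name: str
    family: str
    a: float
    b: float
    negate: bool = False
    units: str = ""

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        a, b = self.a, self.b
        if self.family == "uniform":
            if not a < b:
                raise ValueError(f"{self.name}: uniform requires a < b (a={a}, b={b})")
        elif self.family in ("normal", "lognormal"):
            if not b > 0:
                raise ValueError(f"{self.name}: {self.family} requires b > 0 (b={b})")
        else:
            if not (a > 0 and b > 0):
                raise ValueError(
                    f"{self.name}: {self.family} requires a > 0 and b > 0 (a={a}, b={b})"
                )

    @property
    def _frozen(self):
        frozen = object.__getattribute__(self, "__dict__").get("_frozen_cache")
        if frozen is not None:
            return frozen
        a, b = self.a, self.b
        if self.family == "uniform":
            frozen = stats.uniform(loc=a, scale=b - a)
        elif self.family == "normal":
            frozen = stats.norm(loc=a, scale=b)
        elif self.family == "lognormal":
            frozen = stats.lognorm(s=b, scale=math.exp(a))
        elif self.family == "gamma":
            frozen = stats.gamma(a=a, scale=1.0 / b)
        elif self.family == "beta":
            frozen = stats.beta(a, b)
        else:
            frozen = stats.weibull_min(c=a, scale=b)
        object.__setattr__(self, "_frozen_cache", frozen)
        return frozen

    def logpdf_scalar(self, x: float) -> float:
        """Fast scalar log-density (no scipy dispatch) for MCMC inner loops."""
        a, b = self.a, self.b
        f = self.family
        if f == "uniform":
            return -math.log(b - a) if a <= x <= b else -math.inf
        if f == "normal":
            z = (x - a) / b
            return -0.5 * z * z - math.log(b) - 0.9189385332046727
        if x <= 0:
            return -math.inf
        if f == "lognormal":
            z = (math.log(x) - a) / b
            return -0.5 * z * z - math.log(x * b) - 0.9189385332046727
        if f == "gamma":
            return a * math.log(b) - math.lgamma(a) + (a - 1.0) * math.log(x) - b * x
        if f == "beta":
            if x >= 1:
                return -math.inf
            return (
                (a - 1.0) * math.log(x)
                + (b - 1.0) * math.log(1.0 - x)
                + math.lgamma(a + b)
                - math.lgamma(a)
                - math.lgamma(b)
            )
        # weibull
        z = x / b
        return (
            math.log(a / b) + (a - 1.0) * math.log(z) - z**a
        )

    def ppf(self, p, signed: bool = False):
        """Quantile on the storage scale, or on the signed use scale.

        With ``signed=True`` and a negated trait the order-reversing identity
        Q_{-X}(p) = -Q_X(1 - p) is applied.
        """
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(f"{self.name}: probability must lie in (0, 1), got {p}")
        if signed and self.negate:
            return -self._frozen.ppf(1.0 - p)
        q = self._frozen.ppf(p)
        return q

    def pdf(self, x):
        return self._frozen.pdf(x)

    def logpdf(self, x):
        return self._frozen.logpdf(x)

    def rvs(self, size, rng):
        return self._frozen.rvs(size=size, random_state=rng)

    @property
    def median(self) -> float:
        return float(self._frozen.ppf(0.5))

    @property
    def sd(self) -> float:
        return float(self._frozen.std())

    @property
    def mean(self) -> float:
        return float(self._frozen.mean())

    @property
    def cv(self) -> float:
        return self.sd / abs(self.median)

    @property
    def support(self):
        return self._frozen.support()


def distribution_quantile(dist: TraitDistribution, p: float, signed: bool = False) -> float:
    """p-quantile of a trait prior (storage scale unless ``signed``)."""
    return float(dist.ppf(p, signed=signed))


@dataclass(frozen=True)
class TraitObservation:
    """One reported sample mean of a trait (storage scale, positive)."""

    trait: str
    mean: float
    se: float | None = None
    n: int | None = None
    study_id: str = "study-1"
    site_id: str = "site-1"

    def __post_init__(self):
        if not np.isfinite(self.mean):
            raise ValueError(f"{self.trait}: observation mean must be finite")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"{self.trait}: se must be > 0 when present (se={self.se})")
        if self.n is not None and not self.n >= 1:
            raise ValueError(f"{self.trait}: n must be >= 1 when present (n={self.n})")


class TraitPosterior:
    """Posterior sample of a trait's across-study mean.

    Carries the posterior draws, their empirical median and variance, the
    coefficient of variation sd/|median|, and provenance describing how the
    sample was obtained.
    """

    def __init__(self, trait, samples, source, provenance=None):
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError(f"{trait}: posterior sample is empty")
        self.trait = trait
        self.samples = samples
        self.source = source
        self.provenance = dict(provenance or {})

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def variance(self) -> float:
        return float(np.var(self.samples, ddof=1)) if self.samples.size > 1 else 0.0

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self)

    def ppf(self, p):
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(f"{self.trait}: probability must lie in (0, 1)")
        return np.quantile(self.samples, p)

    def credible_interval(self, level=0.95):
        alpha = (1.0 - level) / 2.0
        return tuple(np.quantile(self.samples, [alpha, 1.0 - alpha]))

    def summary(self) -> pd.Series:
        lo, hi = self.credible_interval()
        return pd.Series(
            {
                "trait": self.trait,
                "median": self.median,
                "sd": math.sqrt(self.variance),
                "cv": self.cv if self.median != 0 else np.nan,
                "ci2.5%": lo,
                "ci97.5%": hi,
                "n_draws": self.samples.size,
                "source": self.source,
            }
        )

    def __repr__(self):
        return (
            f"TraitPosterior({self.trait!r}, median={self.median:.4g}, "
            f"n={self.samples.size}, source={self.source!r})"
        )


def coefficient_of_variation(post: TraitPosterior) -> float:
    """CV = sqrt(Var[beta0]) / |median(beta0)| of the posterior draws."""
    med = post.median
    if med == 0:
        raise ValueError(f"{post.trait}: CV undefined, posterior median is zero")
    return math.sqrt(post.variance) / abs(med)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MetaAnalysisSettings:
    chains: int = 4
    draws: int = 5000
    burn_in: int = 1000
    seed: int = 20201129
    thin: int = 1


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an (n_chains, n_draws) array."""
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


class TraitMetaAnalysis:
    """Two-level random-effects meta-analysis of one trait.

    Model: obs_i ~ Normal(theta_{study(i)}, s_i^2); theta_j ~ Normal(beta0,
    tau^2); beta0 ~ prior (its stated family); tau^2 given a weakly
    informative scaled-inverse-chi-squared prior (1 df, scale half the prior
    sd).  Sampling is Metropolis-within-Gibbs: study effects and tau^2 are
    conjugate draws, beta0 mixes a random-walk and a prior-independence
    Metropolis proposal so the no-data and weak-data limits reduce exactly
    to the prior.  Missing standard errors are imputed from the prior sd
    (divided by sqrt(n) when n is known) and flagged in provenance.
    """

    def __init__(self, prior: TraitDistribution, observations):
        observations = list(observations)
        for o in observations:
            if o.trait != prior.name:
                raise ValueError(
                    f"observation trait {o.trait!r} does not match prior {prior.name!r}"
                )
        self.prior = prior
        self.observations = observations

    def fit(self, settings: MetaAnalysisSettings | None = None) -> TraitPosterior:
        st = settings or MetaAnalysisSettings()
        prior = self.prior
        rng_root = np.random.default_rng(st.seed)
        prov = {"seed": st.seed, "chains": st.chains, "draws": st.draws,
                "burn_in": st.burn_in, "n_obs": len(self.observations)}

        if not self.observations:
            draws = prior.rvs(st.chains * st.draws, rng_root)
            prov["note"] = "no observations; posterior equals the prior"
            return TraitPosterior(prior.name, draws, "prior-only", prov)

        y = np.array([o.mean for o in self.observations], dtype=float)
        imputed = [o.se is None for o in self.observations]
        s = np.array(
            [
                o.se
                if o.se is not None
                else (prior.sd / math.sqrt(o.n) if o.n else prior.sd)
                for o in self.observations
            ],
            dtype=float,
        )
        if any(imputed):
            prov["imputed_se"] = int(sum(imputed))
        studies = [o.study_id for o in self.observations]
        labels = sorted(set(studies))
        j_idx = np.array([labels.index(sid) for sid in studies])
        n_study = len(labels)

        chains = []
        for c in range(st.chains):
            rng = np.random.default_rng(rng_root.integers(0, 2**31 - 1))
            chains.append(self._run_chain(y, s, j_idx, n_study, st, rng))
        arr = np.array(chains)  # (chains, draws)
        rhat = _split_rhat(arr)
        prov["split_rhat"] = rhat
        if np.isfinite(rhat) and rhat > 1.1:
            msg = f"{prior.name}: meta-analysis chains may not have converged (split-Rhat={rhat:.3f})"
            warnings.warn(msg)
            prov["convergence_warning"] = msg
        return TraitPosterior(prior.name, arr.reshape(-1), "meta-analysis", prov)

    def _run_chain(self, y, s, j_idx, n_study, st, rng):
        prior = self.prior
        prec_obs = 1.0 / s**2
        sum_prec = np.bincount(j_idx, weights=prec_obs, minlength=n_study)
        sum_wy = np.bincount(j_idx, weights=prec_obs * y, minlength=n_study)
        sum_wy2 = np.bincount(j_idx, weights=prec_obs * y**2, minlength=n_study)

        def loglik_y(th):
            # sum_i (y_i - theta_j(i))^2 / s_i^2 up to a constant
            return -0.5 * float(np.sum(sum_wy2 - 2.0 * th * sum_wy + th**2 * sum_prec))

        prior_sd = prior.sd
        # tau^2 ~ scaled-inv-chi2(1 df) anchored at the observed study spread
        study_means = sum_wy / np.maximum(sum_prec, 1e-300)
        s0 = float(np.std(study_means, ddof=1)) if n_study >= 2 else 0.5 * prior_sd
        s0 = max(s0, 0.05 * prior_sd, 1e-12)
        a0, b0 = 0.5, 0.5 * s0**2

        beta0 = prior.median
        tau2 = s0**2
        theta = study_means.copy()
        theta[sum_prec == 0] = beta0
        step = 0.5 * prior_sd

        total = st.burn_in + st.draws * st.thin
        out = np.empty(st.draws)
        kept = 0
        accept = 0
        for it in range(total):
            # theta_j | rest (conjugate normal)
            post_prec = sum_prec + 1.0 / tau2
            post_mean = (sum_wy + beta0 / tau2) / post_prec
            theta = post_mean + rng.standard_normal(n_study) / np.sqrt(post_prec)
            # tau^2 | rest (conjugate inverse-gamma)
            sse = float(np.sum((theta - beta0) ** 2))
            tau2 = 1.0 / rng.gamma(a0 + n_study / 2.0, 1.0 / (b0 + 0.5 * sse))
            tau2 = max(tau2, 1e-12 * max(s0**2, 1e-30))
            # beta0 | theta, tau^2: independence MH from the Gaussian
            # conditional N(mean theta, tau^2/J); the Gaussian factor cancels
            # so acceptance reduces to the prior density ratio
            tbar = float(np.mean(theta))
            prop = tbar + math.sqrt(tau2 / n_study) * rng.standard_normal()
            lp1 = prior.logpdf_scalar(prop)
            if np.isfinite(lp1) and math.log(rng.random() + 1e-300) < (
                lp1 - prior.logpdf_scalar(beta0)
            ):
                beta0 = prop
            # beta0 | rest: translation Metropolis (beta0 and all theta_j move
            # together, so the likelihood enters only through the data term);
            # half the proposals draw beta0 fresh from the prior, which makes
            # the weak-data limit reduce exactly to prior sampling
            if rng.random() < 0.5:
                prop = beta0 + step * rng.standard_normal()
                log_hastings = 0.0
            else:
                prop = float(prior.rvs(1, rng)[0])
                # independence proposal from the prior: q ratio cancels the
                # prior ratio in the acceptance probability
                log_hastings = prior.logpdf_scalar(beta0) - prior.logpdf_scalar(prop)
            delta = prop - beta0
            lp1 = prior.logpdf_scalar(prop)
            if np.isfinite(lp1):
                log_alpha = (
                    lp1
                    - prior.logpdf_scalar(beta0)
                    + loglik_y(theta + delta)
                    - loglik_y(theta)
                    + log_hastings
                )
                if math.log(rng.random() + 1e-300) < log_alpha:
                    beta0 = prop
                    theta = theta + delta
                    accept += 1
            if it < st.burn_in:
                if (it + 1) % 100 == 0:  # crude step adaptation
                    rate = accept / (it + 1)
                    step *= 1.25 if rate > 0.45 else (0.8 if rate < 0.2 else 1.0)
            elif (it - st.burn_in) % st.thin == 0:
                out[kept] = beta0
                kept += 1
        return out[:kept]


def run_meta_analysis(
    prior: TraitDistribution, obs, settings: MetaAnalysisSettings | None = None
) -> TraitPosterior:
    """Functional wrapper around :class:`TraitMetaAnalysis`."""
    return TraitMetaAnalysis(prior, obs).fit(settings)


# ---------------------------------------------------------------------------
# Allometric data-informed priors
# ---------------------------------------------------------------------------


@dataclass
class AllometricDataset:
    """Paired (size, mass-or-depth) measurements for one allometric pair."""

    trait_pair: str  # e.g. "Bl", "Bs", "Rd"
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or self.x.size < 2:
            raise ValueError("x and y must be 1-D arrays of equal length >= 2")
        if np.any(self.x <= 0):
            raise ValueError(f"{self.trait_pair}: x must be strictly positive")
        if np.any(self.y <= 0):
            raise ValueError(f"{self.trait_pair}: y must be strictly positive")


class AllometricPriorModel:
    """Data-informed prior for a power-law allometry y = b1 * x^b2.

    OLS on log y = log b1 + b2 log x; posterior draws of (log b1, b2) from
    the bivariate-normal coefficient sampling distribution, intercept
    exponentiated afterwards.  Used for the liana allometric coefficient
    pairs where too few studies exist for the hierarchical meta-analysis.
    """

    def __init__(self, data: AllometricDataset):
        self.data = data

    def fit(self, n_draws: int = 4000, seed: int = 0):
        d = self.data
        if d.x.size < 3:
            raise ValueError(f"{d.trait_pair}: at least 3 points required")
        X = np.column_stack([np.ones_like(d.x), np.log(d.x)])
        ly = np.log(d.y)
        coef, res_ss, *_ = np.linalg.lstsq(X, ly, rcond=None)
        resid = ly - X @ coef
        dof = max(d.x.size - 2, 1)
        s2 = float(resid @ resid) / dof
        rng = np.random.default_rng(seed)
        prov = {"n_points": int(d.x.size), "sigma2": s2, "seed": seed}
        if s2 <= 1e-24:  # noiseless: degenerate point-mass posterior
            draws = np.tile(coef, (n_draws, 1))
        else:
            cov = s2 * np.linalg.inv(X.T @ X)
            draws = rng.multivariate_normal(coef, cov, size=n_draws)
        intercept = TraitPosterior(
            f"b1{d.trait_pair}", np.exp(draws[:, 0]), "allometric-fit", prov
        )
        slope = TraitPosterior(f"b2{d.trait_pair}", draws[:, 1], "allometric-fit", prov)
        return intercept, slope


def fit_allometric_prior(data: AllometricDataset, n_draws: int = 4000, seed: int = 0):
    return AllometricPriorModel(data).fit(n_draws=n_draws, seed=seed)


# ---------------------------------------------------------------------------
# Packaged tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("lianacomp.data").joinpath(name)


def load_prior_table(path=None) -> pd.DataFrame:
    """The packaged 32-parameter prior table (family, constants, medians)."""
    with importlib.resources.as_file(_data_path("priors.csv")) as p:
        return pd.read_csv(path or p)


def load_priors(path=None) -> dict[str, TraitDistribution]:
    df = load_prior_table(path)
    return {
        r["name"]: TraitDistribution(
            name=r["name"],
            family=r["family"],
            a=float(r["a"]),
            b=float(r["b"]),
            negate=bool(int(r["negate"])),
            units=str(r["units"]),
        )
        for _, r in df.iterrows()
    }


def load_classification(path=None) -> pd.DataFrame:
    """Parameter -> (competition, organ, process) classification table."""
    with importlib.resources.as_file(_data_path("classification.csv")) as p:
        return pd.read_csv(path or p)
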