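"""Sensitivity analysis, variance decomposition and Monte-Carlo ensembles.

The workflow around the simulator: each parameter is varied
one-at-a-time through the +/-1, 2, 3 SD quantiles of its distribution (all
others held at their medians), the model response is interpolated with a
monotone cubic Hermite spline g_p, and the parameter's contribution to
predictive uncertainty is the variance of the posterior sample pushed
through g_p.  Relative (partial) variances are aggregated over the
water/light competition, organ and process classifications to compare
below-ground and above-ground competition between lianas and trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .traits import TraitDistribution, TraitPosterior, load_classification

__all__ = [
    "DESIGN_Z",
    "sensitivity_design",
    "evaluate_design",
    "ResponseSpline",
    "fit_response_spline",
    "elasticity",
    "SensitivityResult",
    "SensitivityAnalysis",
    "DecompositionTable",
    "variance_decomposition",
    "EnsembleResult",
    "ensemble",
    "scenario_masks",
    "dry_season_mask",
    "select_young_patches",
]

log = logging.getLogger(__name__)

DESIGN_Z = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
DESIGN_PROBS = stats.norm.cdf(DESIGN_Z)


def sensitivity_design(dist) -> list[tuple[float, float]]:
    """The 7 (probability, value) pairs at the +/-1,2,3 SD normal-CDF levels.

    The SD steps are taken as probability levels through the trait's own
    quantile function (analytic for a prior, empirical for a posterior draw
    set), which keeps the design inside the support of skewed or bounded
    families.
    """
    values = np.asarray(dist.ppf(DESIGN_PROBS), dtype=float)
    if np.unique(values).size < 7:
        log.warning(
            "degenerate design for %s: %d distinct values",
            getattr(dist, "name", getattr(dist, "trait", "?")),
            np.unique(values).size,
        )
    return list(zip(DESIGN_PROBS.tolist(), values.tolist()))


def evaluate_design(runner, base_params: dict, trait: str, design) -> np.ndarray:
    """Run the model once per design value with all other parameters at
    their medians; failed runs are recorded as NaN."""
    responses = []
    for _, value in design:
        params = dict(base_params)
        params[trait] = value
        try:
            responses.append(float(runner(params)))
        except Exception as exc:  # failed run: keep going, spline over the rest
            log.warning("run failed for %s=%s: %s", trait, value, exc)
            responses.append(np.nan)
    return np.asarray(responses)


class ResponseSpline:
    """Monotone-slope-limited cubic Hermite interpolant with linear tails.

    Interpolates every design point exactly; beyond the outer nodes it
    continues linearly with the boundary derivative, avoiding spurious
    curvature when posterior tails exceed the design span.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        order = np.argsort(x)
        x, y = x[order], y[order]
        if np.any(np.diff(x) <= 0):
            raise ValueError("design values must be strictly increasing")
        if x.size < 4:
            raise ValueError(f"at least 4 valid design points required, got {x.size}")
        self.x, self.y = x, y
        self._p = PchipInterpolator(x, y, extrapolate=False)
        self._d = self._p.derivative()
        self._slope_lo = float(self._d(x[0]))
        self._slope_hi = float(self._d(x[-1]))

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = self._p(v)
        lo = v < self.x[0]
        hi = v > self.x[-1]
        out = np.where(lo, self.y[0] + self._slope_lo * (v - self.x[0]), out)
        out = np.where(hi, self.y[-1] + self._slope_hi * (v - self.x[-1]), out)
        return out if out.ndim else float(out)

    def derivative(self, v):
        v = np.asarray(v, dtype=float)
        out = self._d(np.clip(v, self.x[0], self.x[-1]))
        out = np.where(v < self.x[0], self._slope_lo, out)
        out = np.where(v > self.x[-1], self._slope_hi, out)
        return out if out.ndim else float(out)


def fit_response_spline(design_values, responses) -> ResponseSpline:
    return ResponseSpline(design_values, responses)


def elasticity(g: ResponseSpline, beta_median: float) -> float:
    """Normalized sensitivity g'(beta) * beta / g(beta) at the median."""
    g0 = float(g(beta_median))
    if g0 == 0.0:
        return float("nan")
    return float(g.derivative(beta_median)) * beta_median / g0


@dataclass
class SensitivityResult:
    """One-parameter sensitivity: design, responses, spline, elasticity and
    the output variance induced by the posterior sample."""

    trait: str
    design_quantiles: np.ndarray
    design_values: np.ndarray
    responses: np.ndarray
    spline: ResponseSpline
    elasticity: float
    variance: float
    median: float


class SensitivityAnalysis:
    """One-at-a-time quantile sensitivity over a set of traits.

    ``runner`` maps a {trait: value} parameter dict to a scalar model output
    and must be deterministic; ``distributions`` supplies the design (and,
    when a draw set is given, the posterior pushed through the spline).
    """

    def __init__(self, runner, distributions: dict, base_params: dict | None = None):
        self.runner = runner
        self.distributions = dict(distributions)
        if base_params is None:
            base_params = {
                t: float(np.median(d.samples) if isinstance(d, TraitPosterior) else d.median)
                for t, d in self.distributions.items()
            }
        self.base_params = dict(base_params)

    def fit(self) -> dict[str, SensitivityResult]:
        results = {}
        for trait, dist in self.distributions.items():
            design = sensitivity_design(dist)
            responses = evaluate_design(self.runner, self.base_params, trait, design)
            xs = np.array([v for _, v in design])
            spline = fit_response_spline(xs, responses)
            med = self.base_params[trait]
            if isinstance(dist, TraitPosterior):
                draws = dist.samples
            else:
                rng = np.random.default_rng(0)
                draws = dist.rvs(4000, rng)
            var = float(np.var(spline(draws), ddof=1))
            results[trait] = SensitivityResult(
                trait=trait,
                design_quantiles=DESIGN_PROBS.copy(),
                design_values=xs,
                responses=responses,
                spline=spline,
                elasticity=elasticity(spline, med),
                variance=var,
                median=med,
            )
        return results


class DecompositionTable:
    """Per-trait output variances, total and relative variances, and their
    aggregates over the competition/organ/process classifications."""

    def __init__(self, variances: dict[str, float], classification: pd.DataFrame | None = None):
        if not variances:
            raise ValueError("no variances to decompose")
        if classification is None:
            classification = load_classification()
        self.table = pd.DataFrame(
            {"trait": list(variances), "variance": list(variances.values())}
        )
        self.tot_var = float(self.table["variance"].sum())
        if self.tot_var <= 0:
            raise ValueError("total variance is zero; nothing to decompose")
        self.table["rel_var"] = self.table["variance"] / self.tot_var
        cls = classification.rename(columns={"name": "trait"})
        self.table = self.table.merge(cls, on="trait", how="left")
        for col in ("competition", "organ", "process"):
            self.table[col] = self.table[col].fillna("unclassified")

    def aggregate(self, by: str) -> pd.Series:
        if by not in ("competition", "organ", "process"):
            raise ValueError(f"cannot aggregate by {by!r}")
        return self.table.groupby(by)["rel_var"].sum().sort_values(ascending=False)

    @property
    def water_share(self) -> float:
        return float(self.aggregate("competition").get("water", 0.0))

    @property
    def light_share(self) -> float:
        return float(self.aggregate("competition").get("light", 0.0))

    def summary(self) -> pd.DataFrame:
        return self.table.sort_values("rel_var", ascending=False).reset_index(drop=True)


def variance_decomposition(
    splines: dict, posteriors: dict, classification: pd.DataFrame | None = None
) -> DecompositionTable:
    """Var[g_p(beta_p)] per trait from posterior draws through the splines;
    total variance is their sum and relative variances their fractions."""
    variances = {}
    for trait, g in splines.items():
        post = posteriors[trait]
        draws = post.samples if isinstance(post, TraitPosterior) else np.asarray(post)
        if draws.size == 0:
            raise ValueError(f"{trait}: empty posterior draw set")
        variances[trait] = float(np.var(g(draws), ddof=1))
    return DecompositionTable(variances, classification)


# ---------------------------------------------------------------------------
# Monte-Carlo ensembles
# ---------------------------------------------------------------------------


class EnsembleResult:
    """n joint-parameter Monte-Carlo runs with empirical envelopes."""

    def __init__(self, outputs: np.ndarray, params: pd.DataFrame, seed: int,
                 n_failed: int = 0):
        self.outputs = np.asarray(outputs, dtype=float)  # (n_runs, n_steps)
        self.params = params
        self.seed = seed
        self.n_failed = n_failed

    @property
    def n_effective(self):
        return self.outputs.shape[0]

    @property
    def median(self):
        return np.median(self.outputs, axis=0)

    def envelope(self, level=0.95):
        a = (1.0 - level) / 2.0
        return (
            np.quantile(self.outputs, a, axis=0),
            np.quantile(self.outputs, 1.0 - a, axis=0),
        )

    def ci_width(self, level=0.95):
        lo, hi = self.envelope(level)
        return hi - lo

    def ci_spread_ratio(self, other: "EnsembleResult", level=0.95):
        """Mean CI-width ratio self/other (posterior over prior < 1 signals
        successful constraining)."""
        num = self.ci_width(level)
        den = other.ci_width(level)
        ok = den > 0
        if not np.any(ok):
            return float("nan")
        return float(np.mean(num[ok] / den[ok]))


def ensemble(runner, distributions: dict, n: int = 250, seed: int = 0) -> EnsembleResult:
    """n runs with parameters jointly drawn (independently across traits)."""
    if n < 2:
        raise ValueError("ensemble needs n >= 2")
    rng = np.random.default_rng(seed)
    names = list(distributions)
    draws = {}
    for t in names:
        d = distributions[t]
        if isinstance(d, TraitPosterior):
            draws[t] = rng.choice(d.samples, size=n, replace=True)
        else:
            draws[t] = np.asarray(d.rvs(n, rng), dtype=float)
    params_df = pd.DataFrame(draws)
    rows, kept_idx = [], []
    for i in range(n):
        p = {t: float(params_df.iloc[i][t]) for t in names}
        try:
            out = np.atleast_1d(np.asarray(runner(p), dtype=float))
            rows.append(out)
            kept_idx.append(i)
        except Exception as exc:
            log.warning("ensemble run %d failed: %s", i, exc)
    if not rows:
        raise RuntimeError("all ensemble runs failed")
    width = max(r.size for r in rows)
    outputs = np.full((len(rows), width), np.nan)
    for j, r in enumerate(rows):
        outputs[j, : r.size] = r
    return EnsembleResult(outputs, params_df.iloc[kept_idx].reset_index(drop=True),
                          seed, n_failed=n - len(rows))


# ---------------------------------------------------------------------------
# Scenario masks: dry season and young patches
# ---------------------------------------------------------------------------


def dry_season_mask(monthly_precip: pd.Series) -> pd.DataFrame:
    """Dry (p < 100 mm) and strong-dry (p < 60 mm) month classification."""
    p = pd.Series(monthly_precip)
    return pd.DataFrame({"precip_mm": p, "dry": p < 100.0, "strong_dry": p < 60.0})


def _patch_metrics(forest) -> pd.DataFrame:
    rows = []
    for p in forest.patches:
        liana = sum(c.density for c in p.cohorts if c.pft == "liana")
        tree_d = sum(c.density for c in p.cohorts if c.pft != "liana")
        late = sum(c.density for c in p.cohorts if c.pft == "late")
        hts = [c.height for c in p.cohorts if c.pft != "liana"]
        rows.append(
            {
                "patch": p.id,
                "liana_density": liana,
                "late_share": late / tree_d if tree_d > 0 else 0.0,
                "height": max(hts) if hts else 0.0,
            }
        )
    return pd.DataFrame(rows)


def select_young_patches(forest, min_count: int = 1) -> list[str]:
    """Young-patch selection by three jointly relaxed criteria: highest
    initial liana density, lowest late-successional share, lowest canopy
    height.  Thresholds start at the most extreme values and are relaxed
    together until at least ``min_count`` patches qualify."""
    m = _patch_metrics(forest)
    if min_count > len(m):
        raise ValueError(f"min_count={min_count} exceeds patch count {len(m)}")
    for t in np.linspace(0.0, 1.0, 101):
        lo = m["liana_density"] >= m["liana_density"].quantile(1.0 - t)
        la = m["late_share"] <= m["late_share"].quantile(t)
        hi = m["height"] <= m["height"].quantile(t)
        sel = m[lo & la & hi]
        if len(sel) >= min_count:
            return sel["patch"].tolist()
    return m["patch"].tolist()


def scenario_masks(met: pd.DataFrame, forest, min_count: int = 1) -> dict:
    """The season x patch-age analysis masks: monthly dry/strong-dry flags
    and the young-patch id list."""
    met = met.copy()
    met["date"] = pd.to_datetime(met["date"])
    monthly = met.groupby(met["date"].dt.to_period("M"))["precip_mm"].sum()
    return {
        "dry_season": dry_season_mask(monthly),
        "young_patches": select_young_patches(forest, min_count=min_count),
    }
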