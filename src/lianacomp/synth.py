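"""Synthetic site data: meteorology, forest inventories, trait datasets.

Generators that emulate the statistical structure of the study inputs — a
seasonally moist tropical site with a marked dry season and heavy liana
infestation (BCI-like) and a wetter site with a short dry season and few
lianas (Paracou-like) — so that every pipeline stage can be exercised with
known ground truth.  All generators are deterministic under their seed and
emit the exact file dialects the io layer reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SiteTemplate",
    "BCI_TEMPLATE",
    "PARACOU_TEMPLATE",
    "get_template",
    "generate_met",
    "generate_inventory",
    "extrapolate_small_trees",
    "generate_trait_dataset",
]


@dataclass(frozen=True)
class SiteTemplate:
    """Aggregate features of a simulated forest site."""

    name: str
    annual_precip_mm: float
    annual_precip_sd: float
    strong_dry_months: tuple      # months with p < 60 mm (1..12)
    dry_months: tuple             # months with 60 <= p < 100 mm
    liana_density_ha: float       # stems/ha at the census DBH cutoff
    liana_dbh_range: tuple        # cm
    liana_basal_area_m2ha: float
    tree_density_ha: float        # stems/ha, DBH >= 10 cm
    tree_basal_area_m2ha: float
    tree_dbh_range: tuple = (10.0, 150.0)
    patch_area_m2: float = 400.0
    n_patches: int = 10
    mean_temp_c: float = 26.0

    def __post_init__(self):
        months = set(self.strong_dry_months) | set(self.dry_months)
        if not months <= set(range(1, 13)):
            raise ValueError("dry months must be within 1..12")
        if min(self.liana_density_ha, self.tree_density_ha) < 0:
            raise ValueError("densities must be >= 0")
        n_wet = 12 - len(months)
        if self.annual_precip_mm < 110.0 * n_wet + 100.0 * len(months):
            raise ValueError(
                f"{self.name}: annual precipitation too low for the dry-season structure"
            )


BCI_TEMPLATE = SiteTemplate(
    name="BCI",
    annual_precip_mm=2640.0,
    annual_precip_sd=94.0,
    strong_dry_months=(1, 2, 3),
    dry_months=(4,),
    liana_density_ha=1428.9,
    liana_dbh_range=(1.0, 15.0),
    liana_basal_area_m2ha=1.01,
    tree_density_ha=416.0,
    tree_basal_area_m2ha=26.7,
    patch_area_m2=400.0,
    n_patches=10,
    mean_temp_c=25.6,
)

PARACOU_TEMPLATE = SiteTemplate(
    name="Paracou",
    annual_precip_mm=3088.0,
    annual_precip_sd=117.0,
    strong_dry_months=(9, 10),
    dry_months=(8, 11),
    liana_density_ha=126.3,
    liana_dbh_range=(2.0, 15.0),
    liana_basal_area_m2ha=0.34,
    tree_density_ha=319.4,
    tree_basal_area_m2ha=19.2,
    patch_area_m2=4900.0,
    n_patches=10,
    mean_temp_c=26.0,
)


def get_template(name: str) -> SiteTemplate:
    key = name.lower()
    if key in ("bci", "bci-like"):
        return BCI_TEMPLATE
    if key in ("paracou", "paracou-like"):
        return PARACOU_TEMPLATE
    raise ValueError(f"unknown site template {name!r}")


# ---------------------------------------------------------------------------
# Meteorology
# ---------------------------------------------------------------------------


def _monthly_targets(template: SiteTemplate, rng) -> np.ndarray:
    """Monthly precipitation totals honouring the template's dry season and
    annual mean (with sampled interannual variability)."""
    annual = float(rng.normal(template.annual_precip_mm, template.annual_precip_sd))
    targets = np.zeros(12)
    for m in template.strong_dry_months:
        targets[m - 1] = rng.uniform(35.0, 55.0)
    for m in template.dry_months:
        targets[m - 1] = rng.uniform(65.0, 95.0)
    wet = [m for m in range(1, 13) if targets[m - 1] == 0.0]
    residual = annual - targets.sum()
    # mild unimodal wet-season shape centred away from the dry season
    phase = (np.mean([m - 1 for m in template.strong_dry_months]) + 6.0) % 12.0
    w = 1.0 + 0.25 * np.cos(2.0 * math.pi * (np.array([m - 1 for m in wet]) - phase) / 12.0)
    w = w / w.sum()
    alloc = residual * w
    # keep every wet month clearly out of the dry class
    alloc = np.maximum(alloc, 110.0)
    alloc *= residual / alloc.sum()
    alloc = np.maximum(alloc, 110.0)
    for m, v in zip(wet, alloc):
        targets[m - 1] = v
    return targets


def generate_met(template: SiteTemplate, years: int, seed: int) -> pd.DataFrame:
    """Daily meteorology: precipitation through a first-order wet/dry day
    chain that preserves monthly totals exactly, PAR/temperature/humidity
    with mild seasonality (drier months sunnier and less humid)."""
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2004-01-01", f"{2004 + years - 1}-12-31", freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))]
    rows = []
    for year in range(years):
        targets = _monthly_targets(template, rng)
        for month in range(1, 13):
            sel = dates[(dates.year == 2004 + year) & (dates.month == month)]
            n = len(sel)
            total = targets[month - 1]
            p_wet = float(np.clip(total / 350.0 + 0.15, 0.1, 0.92))
            p11 = min(0.92, p_wet + 0.2)
            p01 = np.clip(p_wet * (1.0 - p11) / max(1.0 - p_wet, 1e-6), 0.02, 0.95)
            wet = np.zeros(n, dtype=bool)
            state = rng.random() < p_wet
            for i in range(n):
                wet[i] = state
                state = rng.random() < (p11 if state else p01)
            if not wet.any():
                wet[rng.integers(0, n)] = True
            amounts = np.zeros(n)
            amounts[wet] = rng.gamma(0.8, 1.0, size=int(wet.sum()))
            amounts *= total / amounts.sum()
            par_base = 680.0 - 1.1 * min(total, 250.0)
            par = np.clip(rng.normal(par_base, 40.0, size=n), 250.0, 900.0)
            tair = template.mean_temp_c + 0.8 * math.cos(
                2.0 * math.pi * (month - 4) / 12.0
            ) + rng.normal(0.0, 0.3, size=n)
            rh = np.clip(
                0.64 + 0.0009 * min(total, 280.0) + rng.normal(0.0, 0.02, size=n),
                0.4,
                0.98,
            )
            for i, d in enumerate(sel):
                rows.append(
                    {
                        "date": d.strftime("%Y-%m-%d"),
                        "precip_mm": float(amounts[i]),
                        "par_umol_m2_s": float(par[i]),
                        "tair_C": float(tair[i]),
                        "rh_frac": float(rh[i]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inventory
# ---------------------------------------------------------------------------


def _powerlaw_exponent_for_basal_area(dmin, dmax, target_mean_d2):
    """Exponent of a truncated power-law DBH distribution f ~ d^-a matching
    the target mean squared diameter (two-moment matching)."""

    grid = np.linspace(dmin, dmax, 2000)

    def mean_d2(a):
        pdf = grid ** (-a)
        pdf /= np.trapezoid(pdf, grid)
        return np.trapezoid(pdf * grid**2, grid)

    lo, hi = 0.01, 8.0
    if not (mean_d2(hi) <= target_mean_d2 <= mean_d2(lo)):
        target = float(np.clip(target_mean_d2, mean_d2(hi), mean_d2(lo)))
    else:
        target = target_mean_d2
    return float(optimize.brentq(lambda a: mean_d2(a) - target, lo, hi))


def _sample_powerlaw(n, a, dmin, dmax, rng):
    u = rng.random(n)
    if abs(a - 1.0) < 1e-9:
        return dmin * (dmax / dmin) ** u
    p = 1.0 - a
    return (dmin**p + u * (dmax**p - dmin**p)) ** (1.0 / p)


def generate_inventory(template: SiteTemplate, seed: int) -> pd.DataFrame:
    """Stem table with heterogeneous patch-level liana loading.

    Tree DBHs follow a truncated power law whose exponent is solved so the
    census stem density and basal area are met jointly; small trees
    (1-10 cm) continue the fitted power law as density-multiplied
    representative stems.  Liana counts per patch carry a right-skewed
    (lognormal) multiplier normalized to preserve the site-mean density.
    """
    rng = np.random.default_rng(seed)
    area_ha = template.patch_area_m2 / 1e4
    rows = []
    # tree size distribution (DBH >= 10 cm)
    if template.tree_density_ha > 0:
        mean_d2 = (
            template.tree_basal_area_m2ha / template.tree_density_ha * 4.0 / math.pi * 1e4
        )
        a_tree = _powerlaw_exponent_for_basal_area(*template.tree_dbh_range, mean_d2)
    liana_mult = np.ones(template.n_patches)
    if template.liana_density_ha > 0:
        liana_mult = rng.lognormal(mean=0.0, sigma=1.0, size=template.n_patches)
        liana_mult /= liana_mult.mean()
    if template.liana_density_ha > 0:
        lo, hi = template.liana_dbh_range
        mean_d2_li = (
            template.liana_basal_area_m2ha / template.liana_density_ha * 4.0 / math.pi * 1e4
        )
        a_liana = _powerlaw_exponent_for_basal_area(lo, hi, mean_d2_li)
    stem = 0
    for ip in range(template.n_patches):
        pid = f"patch-{ip:02d}"
        if template.tree_density_ha > 0:
            n_big = int(round(template.tree_density_ha * area_ha))
            d = _sample_powerlaw(n_big, a_tree, *template.tree_dbh_range, rng)
            # mild rescale so the realized basal area matches the template
            d *= math.sqrt(mean_d2 / np.mean(d**2))
            d = np.clip(d, template.tree_dbh_range[0], None)
            wd = np.clip(rng.normal(0.58, 0.13, size=n_big), 0.25, 1.0)
            for i in range(n_big):
                rows.append((pid, f"t{stem}", "tree", float(d[i]), float(wd[i]), 1.0))
                stem += 1
            # small trees 1-10 cm: continue the power law, represented by
            # density-multiplied stems
            grid = np.linspace(*template.tree_dbh_range, 2000)
            norm_big = np.trapezoid(grid ** (-a_tree), grid)
            grid_s = np.linspace(1.0, 10.0, 500)
            n_small = n_big * np.trapezoid(grid_s ** (-a_tree), grid_s) / norm_big
            n_rep = 40
            d_s = _sample_powerlaw(n_rep, a_tree, 1.0, 10.0, rng)
            wd_s = np.clip(rng.normal(0.58, 0.13, size=n_rep), 0.25, 1.0)
            for i in range(n_rep):
                rows.append(
                    (pid, f"t{stem}", "tree", float(d_s[i]), float(wd_s[i]),
                     float(n_small / n_rep))
                )
                stem += 1
        if template.liana_density_ha > 0:
            n_li = int(round(template.liana_density_ha * area_ha * liana_mult[ip]))
            if n_li > 0:
                d = _sample_powerlaw(n_li, a_liana, *template.liana_dbh_range, rng)
                for i in range(n_li):
                    rows.append((pid, f"l{stem}", "liana", float(d[i]), np.nan, 1.0))
                    stem += 1
    return pd.DataFrame(
        rows,
        columns=["patch_id", "stem_id", "growth_form", "dbh_cm",
                 "wood_density_g_cm3", "density_multiplier"],
    )


def extrapolate_small_trees(
    density_by_dbh_class: pd.DataFrame, pft_shares: dict | None = None
) -> pd.DataFrame:
    """Fill the 1-10 cm DBH classes from a log-log linear fit to the
    observed classes at 10 cm and above.

    Input columns: ``dbh_mid`` (class midpoint, cm) and ``density_ha``.
    Returns the table with predicted 1-cm-wide classes (midpoints 1.5-9.5)
    appended, split across tree PFTs by ``pft_shares`` when given.
    """
    df = density_by_dbh_class.copy()
    obs = df[(df["dbh_mid"] >= 10.0) & (df["density_ha"] > 0)]
    if len(obs) < 2:
        raise ValueError("need at least 2 observed classes with dbh >= 10 cm")
    X = np.column_stack([np.ones(len(obs)), np.log(obs["dbh_mid"].to_numpy())])
    coef, *_ = np.linalg.lstsq(X, np.log(obs["density_ha"].to_numpy()), rcond=None)
    mids = np.arange(1.5, 10.0, 1.0)
    pred = np.exp(coef[0] + coef[1] * np.log(mids))
    new = pd.DataFrame({"dbh_mid": mids, "density_ha": pred, "extrapolated": True})
    if pft_shares:
        tot = sum(pft_shares.values())
        for pft, share in pft_shares.items():
            new[f"density_ha_{pft}"] = pred * share / tot
    df = df.copy()
    df["extrapolated"] = False
    out = pd.concat([new, df], ignore_index=True).sort_values("dbh_mid")
    out.attrs["loglog_slope"] = float(coef[1])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trait datasets
# ---------------------------------------------------------------------------


def generate_trait_dataset(
    trait: str,
    true_mean: float,
    between_study_sd: float,
    within_sd: float,
    n_studies: int,
    per_study_n: int = 10,
    obs_per_study: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic trait observations with known truth.

    Study means ~ Normal(true_mean, between^2); each study reports
    ``obs_per_study`` sample means ~ Normal(study mean, within^2 /
    per_study_n) with se = within / sqrt(per_study_n).
    """
    if min(between_study_sd, within_sd) < 0:
        raise ValueError("standard deviations must be >= 0")
    if min(n_studies, per_study_n, obs_per_study) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    se = within_sd / math.sqrt(per_study_n)
    rows = []
    for j in range(n_studies):
        theta = rng.normal(true_mean, between_study_sd)
        means = rng.normal(theta, se, size=obs_per_study)
        for i in range(obs_per_study):
            rows.append(
                {
                    "trait": trait,
                    "mean": float(means[i]),
                    "se": se if se > 0 else np.nan,
                    "n": per_study_n,
                    "study_id": f"study-{j:02d}",
                    "site_id": f"site-{j % 3}",
                }
            )
    return pd.DataFrame(rows)
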