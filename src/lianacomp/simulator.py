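"""Cohort/patch demographic simulator with liana climbing and competition.

A deliberately simplified stand-in for a full demographic vegetation model:
cohorts (density, DBH, biomass pools, plant water potentials) live in
patches that carry a layered soil column.  Light competition follows
Beer-Lambert extinction through the height-ordered canopy; soil water
competition emerges from layered root water uptake through the
two-compartment plant hydraulics of :mod:`lianacomp.physiology`.  Lianas
climb: cohorts above a DBH threshold track the tallest tree of their patch
plus a small height offset by shifting their DBH-height allometry by a
per-cohort offset (delta_dbh), which confers a light advantage without
self-supporting stem investment.

Physiology and hydraulics run daily (with sub-daily implicit water
transport); allocation, growth, mortality and recruitment run monthly.
Both the patch water budget and the cohort carbon budget close to floating
point accuracy and are recorded in ledgers for verification.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physiology as phys
from .physiology import PFTParameterSet

__all__ = [
    "SimulatorConfig",
    "SoilColumn",
    "Cohort",
    "Patch",
    "Forest",
    "ForestSimulation",
    "SimulationResults",
    "initialize_from_inventory",
    "default_pfts",
    "remove_lianas",
    "liana_share",
]

log = logging.getLogger(__name__)

KC = 12.011e-9  # kg C per umol C
SECONDS_DAYLIGHT = 12.0 * 3600.0
TREE_PFTS = ("early", "mid", "late")


@dataclass
class SimulatorConfig:
    """Physical and numerical constants of the simulator (all configurable)."""

    k_ext: float = 0.5              # Beer-Lambert canopy extinction coefficient
    h_offset: float = 0.5           # max liana overtopping of tallest tree, m
    dbh_threshold: float = 3.0      # canopy-reaching liana DBH threshold, cm
    interception_frac: float = 0.10  # canopy interception fraction of precip
    soil_evap_max: float = 2.0      # potential soil evaporation, mm/day
    c_xylem: float = 5.0            # xylem pathway calibration constant
    c_soilroot: float = 0.01        # soil-to-root pathway calibration constant
    ca_ppm: float = 370.0           # fixed atmospheric CO2, ppm
    substeps_per_day: int = 24      # hydraulic substeps (backward Euler)
    wd_cuts: tuple = (0.53, 0.71)   # wood-density class separators, g/cm3
    recruit_dbh: float = 1.0        # DBH of newly recruited cohorts, cm
    recruit_min_density: float = 1e-4  # min density to spawn a recruit cohort, /m2
    density_floor: float = 1e-8     # cohorts below this density are dropped
    merge_dbh_reltol: float = 0.08  # monthly same-PFT cohort fusion tolerance
    fuse_patches: bool = False      # fuse identical-composition patches at init
    soilk_exp: float = 6.0          # soil-wetness exponent of the root pathway
    # soil column (Clapp-Hornberger retention), clay-loam defaults
    soil_interfaces: tuple = (0.05, 0.15, 0.3, 0.5, 0.75, 1.0, 2.0, 4.0, 8.0)
    theta_sat: float = 0.48
    theta_res: float = 0.05
    theta_fc: float = 0.38          # field capacity; excess percolates down
    perc_rate: float = 0.3          # fraction of above-fc excess moved per day
    psi_sat: float = -0.5           # m H2O at saturation
    retention_b: float = 8.0
    theta_init_frac: float = 0.95   # initial theta as fraction of saturation


class SoilColumn:
    """Layered soil water store with Clapp-Hornberger retention."""

    def __init__(self, config: SimulatorConfig):
        edges = np.concatenate([[0.0], np.asarray(config.soil_interfaces)])
        self.edges = edges
        self.dz = np.diff(edges)  # m
        self.theta_sat = config.theta_sat
        self.theta_res = config.theta_res
        self.psi_sat = config.psi_sat
        self.b = config.retention_b
        self.theta = np.full(self.dz.size, config.theta_init_frac * config.theta_sat)

    @property
    def n_layers(self):
        return self.dz.size

    def psi(self):
        """Matric potential per layer, m H2O (<= psi_sat < 0)."""
        rel = np.clip(self.theta, 1e-6, self.theta_sat) / self.theta_sat
        return self.psi_sat * rel ** (-self.b)

    def water_mm(self):
        return float(np.sum(self.theta * self.dz) * 1000.0)

    def available_mm(self):
        """Extractable water above residual per layer, mm (= kg/m2)."""
        return np.maximum(self.theta - self.theta_res, 0.0) * self.dz * 1000.0

    def infiltrate(self, water_mm: float) -> float:
        """Tipping-bucket infiltration; returns drainage below the column."""
        w = water_mm / 1000.0  # m
        for i in range(self.n_layers):
            room = (self.theta_sat - self.theta[i]) * self.dz[i]
            take = min(room, w)
            self.theta[i] += take / self.dz[i]
            w -= take
            if w <= 0:
                break
        return w * 1000.0

    def percolate(self, rate: float, theta_fc: float) -> float:
        """Gravity drainage of water above field capacity, cascading down;
        returns the water leaving the column bottom, mm."""
        carry = 0.0  # m of water entering the layer from above
        for i in range(self.n_layers):
            self.theta[i] += carry / self.dz[i]
            carry = 0.0
            excess = max(self.theta[i] - theta_fc, 0.0) * self.dz[i]
            move = rate * excess
            # cap so the receiving layer cannot exceed saturation
            if i + 1 < self.n_layers:
                room = (self.theta_sat - self.theta[i + 1]) * self.dz[i + 1]
                move = min(move, max(room, 0.0))
            self.theta[i] -= move / self.dz[i]
            carry = move
        return carry * 1000.0

    def extract(self, per_layer_mm: np.ndarray) -> None:
        self.theta = self.theta - per_layer_mm / 1000.0 / self.dz

    def root_fractions(self, depth_m: float, root_beta: float) -> np.ndarray:
        """Root biomass fraction per layer.

        (1 - root_beta) of the roots follow a surface-concentrated
        exponential profile (e-folding depth a third of the rooting depth,
        truncated at the rooting depth); root_beta sits below the rooting
        depth, uniform over the remaining layers.  The exponential shape
        mirrors observed fine-root profiles, whose near-surface
        concentration drives dry-season topsoil depletion.
        """
        d = min(abs(depth_m), self.edges[-1])
        d = max(d, self.edges[1])  # roots occupy at least the top layer
        zs = d / 3.0
        top = np.minimum(self.edges[:-1], d)
        bot = np.minimum(self.edges[1:], d)
        mass = np.exp(-top / zs) - np.exp(-bot / zs)  # within rooting depth
        tot = mass.sum()
        frac = (1.0 - root_beta) * mass / tot if tot > 0 else np.zeros(self.n_layers)
        below = np.clip(self.edges[1:] - np.maximum(self.edges[:-1], d), 0.0, None)
        tot_below = below.sum()
        if tot_below > 0:
            frac += root_beta * below / tot_below
        else:
            frac += root_beta * mass / tot
        return frac / frac.sum()


_COHORT_SEQ = [0]


@dataclass
class Cohort:
    """A group of same-PFT, similar-DBH plants tracked as a density."""

    pft: str
    density: float          # plants per m2 ground
    dbh: float              # cm
    delta_dbh: float = 0.0  # liana climbing allometry shift, cm
    height: float = 0.0     # m
    bl: float = 0.0         # leaf carbon, kg C / plant
    bs: float = 0.0         # structural (stem) carbon
    br: float = 0.0         # fine-root carbon
    storage: float = 0.0
    psi_leaf: float = 0.0
    psi_stem: float = 0.0
    cb_window: list = field(default_factory=lambda: [1.0] * 12)
    id: int = field(default_factory=lambda: _COHORT_SEQ.__setitem__(0, _COHORT_SEQ[0] + 1) or _COHORT_SEQ[0])
    # monthly physiology accumulators (kg C or kg water per plant)
    acc: dict = field(default_factory=dict)

    def reset_acc(self):
        self.acc = {"gpp": 0.0, "pot_gpp": 0.0, "r_leaf": 0.0, "r_root": 0.0,
                    "transp": 0.0}


@dataclass
class Patch:
    id: str
    area_weight: float
    soil: SoilColumn
    cohorts: list = field(default_factory=list)
    age: float = 0.0
    recruit_pool: dict = field(default_factory=dict)  # pft -> kg C / m2

    def tallest_tree_height(self):
        h = [c.height for c in self.cohorts if not c.pft.startswith("liana")]
        return max(h) if h else None


@dataclass
class Forest:
    patches: list
    pfts: dict
    config: SimulatorConfig = field(default_factory=SimulatorConfig)

    def param(self, pft_name) -> PFTParameterSet:
        return self.pfts[pft_name]

    def cohort_lai(self, c: Cohort) -> float:
        return self.param(c.pft).SLA * c.bl * c.density

    def patch_lai(self, p: Patch) -> float:
        return sum(self.cohort_lai(c) for c in p.cohorts)

    def copy(self) -> "Forest":
        return copy.deepcopy(self)


def default_pfts(liana: str | PFTParameterSet = "posterior") -> dict:
    """Packaged parameter sets: three tree stages plus the liana PFT."""
    if isinstance(liana, PFTParameterSet):
        liana_set = liana
    elif liana == "posterior":
        liana_set = PFTParameterSet.liana_posterior()
    elif liana == "prior":
        liana_set = PFTParameterSet.liana_prior()
    else:
        raise ValueError("liana must be 'prior', 'posterior' or a PFTParameterSet")
    return {
        "early": PFTParameterSet.tree("early"),
        "mid": PFTParameterSet.tree("mid"),
        "late": PFTParameterSet.tree("late"),
        "liana": liana_set,
    }


# ---------------------------------------------------------------------------
# Initialization from inventory
# ---------------------------------------------------------------------------

_DBH_BIN_EDGES = np.array(
    [0.5, 1.5, 2.5, 4.0, 6.0, 8.5, 12.0, 17.0, 24.0, 34.0, 48.0, 68.0, 96.0, 200.0]
)


def _classify_tree(wd, cuts):
    if wd < cuts[0]:
        return "early"
    if wd < cuts[1]:
        return "mid"
    return "late"


def initialize_from_inventory(
    inventory: pd.DataFrame,
    pfts: dict | None = None,
    config: SimulatorConfig | None = None,
    patch_area_m2: float | dict = 400.0,
) -> Forest:
    """Build a Forest from a stem table.

    Trees are assigned to the early/mid/late PFT by wood density, stems of a
    PFT are merged into DBH-bin cohorts, tree heights come from allometry,
    and liana cohorts at or above the canopy DBH threshold are raised to the
    patch's tallest tree height plus the height offset with the
    corresponding delta_dbh recorded.
    """
    config = config or SimulatorConfig()
    pfts = pfts or default_pfts()
    required = {"patch_id", "stem_id", "growth_form", "dbh_cm"}
    missing = required - set(inventory.columns)
    if missing:
        raise ValueError(f"inventory missing columns: {sorted(missing)}")
    if (inventory["dbh_cm"] <= 0).any():
        bad = inventory.index[inventory["dbh_cm"] <= 0][0]
        raise ValueError(f"inventory row {bad}: dbh must be positive")
    mult = inventory.get("density_multiplier", pd.Series(1.0, index=inventory.index))

    patch_ids = list(dict.fromkeys(inventory["patch_id"]))
    patches = []
    for pid in patch_ids:
        sub = inventory[inventory["patch_id"] == pid]
        area = patch_area_m2[pid] if isinstance(patch_area_m2, dict) else patch_area_m2
        soil = SoilColumn(config)
        patch = Patch(id=str(pid), area_weight=1.0 / len(patch_ids), soil=soil)
        # trees
        trees = sub[sub["growth_form"] == "tree"]
        for stage in TREE_PFTS:
            pars = pfts[stage]
            wd = trees.get("wood_density_g_cm3", pd.Series(0.6, index=trees.index))
            mask = wd.apply(lambda w: _classify_tree(w, config.wd_cuts)) == stage
            _bin_into_cohorts(patch, trees[mask], mult, stage, pars, area)
        # lianas
        lianas = sub[sub["growth_form"] == "liana"]
        _bin_into_cohorts(patch, lianas, mult, "liana", pfts["liana"], area)
        # heights
        for c in patch.cohorts:
            pars = pfts[c.pft]
            c.height = float(phys.height_from_dbh(c.dbh, pars))
        tallest = patch.tallest_tree_height()
        for c in patch.cohorts:
            if c.pft != "liana" or c.dbh < config.dbh_threshold:
                continue
            if tallest is None:
                log.warning(
                    "patch %s: canopy liana (dbh=%.1f) but no trees; climbing cap inactive",
                    pid, c.dbh,
                )
                continue
            pars = pfts["liana"]
            target = min(tallest + config.h_offset, 0.98 * pars.h_max)
            c.height = target
            c.delta_dbh = float(phys.dbh_from_height(target, pars)) - c.dbh
        _init_pools_and_water(patch, pfts, config)
        patch.cohorts.sort(key=lambda c: -c.height)
        patches.append(patch)
    forest = Forest(patches=patches, pfts=dict(pfts), config=config)
    if config.fuse_patches:
        _fuse_patches(forest)
    return forest


def _bin_into_cohorts(patch, stems, mult, pft_name, pars, area):
    if stems.empty:
        return
    w = mult.loc[stems.index].to_numpy(dtype=float)
    d = stems["dbh_cm"].to_numpy(dtype=float)
    idx = np.digitize(d, _DBH_BIN_EDGES)
    for b in np.unique(idx):
        sel = idx == b
        density = float(w[sel].sum()) / area
        dbh = float(np.average(d[sel], weights=w[sel]))
        patch.cohorts.append(Cohort(pft=pft_name, density=density, dbh=dbh))


def _init_pools_and_water(patch, pfts, config):
    psi0 = SoilColumn(config).psi()[0]
    for c in patch.cohorts:
        pars = pfts[c.pft]
        c.bl = float(phys.leaf_biomass(c.dbh, pars))
        c.bs = float(phys.stem_biomass(c.dbh, pars))
        c.br = float(phys.fine_root_biomass(c.dbh, pars))
        c.storage = 0.0
        c.psi_stem = float(psi0)
        c.psi_leaf = float(psi0 - c.height)
        c.reset_acc()


def _fuse_patches(forest):
    """Merge patches with identical PFT composition signatures, area-weighted."""
    sig = {}
    for p in forest.patches:
        key = tuple(sorted({c.pft for c in p.cohorts}))
        sig.setdefault(key, []).append(p)
    fused = []
    for group in sig.values():
        if len(group) == 1:
            fused.append(group[0])
            continue
        base = group[0]
        wtot = sum(p.area_weight for p in group)
        for p in group[1:]:
            for c in p.cohorts:
                c2 = copy.deepcopy(c)
                c2.density *= p.area_weight / wtot
                base.cohorts.append(c2)
        for c in base.cohorts[: len(group[0].cohorts)]:
            c.density *= group[0].area_weight / wtot
        base.area_weight = wtot
        base.cohorts.sort(key=lambda c: -c.height)
        fused.append(base)
    forest.patches = fused


def remove_lianas(forest: Forest) -> Forest:
    """A copy of the forest with every liana cohort deleted."""
    out = forest.copy()
    for p in out.patches:
        p.cohorts = [c for c in p.cohorts if c.pft != "liana"]
        p.recruit_pool.pop("liana", None)
    return out


# ---------------------------------------------------------------------------
# Daily physiology + hydraulics
# ---------------------------------------------------------------------------


def _esat_pa(t_c):
    """Saturation vapour pressure, Pa (Tetens)."""
    return 610.78 * math.exp(17.27 * t_c / (t_c + 237.3))


class _MonthCache:
    """Flat per-cohort arrays rebuilt after each demography step."""

    def __init__(self, forest: Forest):
        cohorts = []
        patch_of = []
        for ip, p in enumerate(forest.patches):
            p.cohorts.sort(key=lambda c: -c.height)
            for c in p.cohorts:
                cohorts.append(c)
                patch_of.append(ip)
        self.cohorts = cohorts
        self.patch_of = np.array(patch_of, dtype=int)
        n = len(cohorts)
        self.n = n
        get = lambda attr: np.array([getattr(c, attr) for c in cohorts])
        self.density = get("density")
        self.height = get("height")
        self.bl, self.bs, self.br = get("bl"), get("bs"), get("br")
        self.psi_s = get("psi_stem")
        self.psi_l = get("psi_leaf")
        pars = [forest.param(c.pft) for c in cohorts]
        names = ["K_max", "K_exp", "P50", "rho", "SRA", "wood_capacitance",
                 "leaf_capacitance", "leaf_TLP"]
        self.pa = {nm: np.array([getattr(p, nm) for p in pars]) for nm in names}
        for nm in ["SLA", "quantum_efficiency", "V_m0", "dark_respiration",
                   "stomatal_slope", "gs_min", "stoma_psi_b", "stoma_psi_c",
                   "root_respiration", "root_beta"]:
            setattr(self, nm, np.array([getattr(p, nm) for p in pars]))
        self.la = self.SLA * self.bl  # leaf area per plant
        self.lai = self.la * self.density
        # cumulative LAI above each cohort within its patch (height-ordered)
        self.lai_above = np.zeros(n)
        self.ground_frac = np.ones(len(forest.patches))
        k = forest.config.k_ext
        for ip in range(len(forest.patches)):
            sel = np.flatnonzero(self.patch_of == ip)
            cum = np.concatenate([[0.0], np.cumsum(self.lai[sel])])
            self.lai_above[sel] = cum[:-1]
            self.ground_frac[ip] = math.exp(-k * cum[-1])
        # root fraction matrix per cohort (layers), and effective-psi weights
        nl = forest.patches[0].soil.n_layers if forest.patches else 0
        self.root_frac = np.zeros((n, nl))
        for i, (c, p) in enumerate(zip(cohorts, pars)):
            soil = forest.patches[self.patch_of[i]].soil
            depth = phys.rooting_depth(max(c.height, 0.5), p)
            self.root_frac[i] = soil.root_fractions(float(depth), p.root_beta)
        self.cap_s = np.maximum(self.pa["wood_capacitance"] * self.bs, 1e-9)
        self.cap_l = np.maximum(self.pa["leaf_capacitance"] * self.bl, 1e-9)

    def writeback(self):
        for i, c in enumerate(self.cohorts):
            c.psi_stem = float(self.psi_s[i])
            c.psi_leaf = float(self.psi_l[i])


def _daily_step(forest: Forest, cache: _MonthCache, met_row, water_rows, month_key):
    """One day of light competition, gas exchange, plant hydraulics and the
    patch soil water budget.  Returns per-PFT flux increments."""
    cfg = forest.config
    par_top = float(met_row["par_umol_m2_s"])
    precip = float(met_row["precip_mm"])
    tair = float(met_row["tair_C"])
    rh = float(met_row["rh_frac"])
    if not all(map(np.isfinite, (par_top, precip, tair, rh))):
        raise ValueError(f"non-finite met row: {dict(met_row)}")

    n = cache.n
    npatch = len(forest.patches)
    if n == 0:
        se = 0.0
        for ip, p in enumerate(forest.patches):
            se += p.area_weight * _soil_day(
                p, cfg, precip, 1.0, np.zeros(p.soil.n_layers),
                water_rows, month_key, 0.0, 0.0,
            )
        return {}, se

    par_i = par_top * np.exp(-cfg.k_ext * cache.lai_above)
    # stomatal drought-stress factor from current leaf potential
    b = -cache.stoma_psi_b
    f_sw = 1.0 / (1.0 + (np.minimum(cache.psi_l, 0.0) / b) ** cache.stoma_psi_c)
    f_sw = np.where(cache.psi_l <= -cache.pa["leaf_TLP"], 0.0, f_sw)
    alpha, vm = cache.quantum_efficiency, cache.V_m0
    gross = np.where(par_i > 0, f_sw * alpha * par_i * vm / (alpha * par_i + vm), 0.0)
    gross_pot = np.where(
        par_top > 0, alpha * par_top * vm / (alpha * par_top + vm), 0.0
    )
    r_leaf_rate = cache.dark_respiration * vm  # umol m-2 s-1, paid 24 h
    a_net = gross - r_leaf_rate
    gs = np.maximum(
        cache.stomatal_slope * np.maximum(a_net, 0.0) * rh / cfg.ca_ppm + cache.gs_min,
        cache.gs_min,
    )
    vpd_frac = max((1.0 - rh) * _esat_pa(tair) / 101325.0, 0.0)
    demand_day = phys.transpiration_demand(gs, vpd_frac) * cache.la * SECONDS_DAYLIGHT
    demand_rate = demand_day / 86400.0  # kg/s per plant, spread over the day

    # soil coupling: uptake follows root density weighted by layer wetness,
    # so a cohort drinks from (and hydraulically "feels") the layers its
    # roots occupy, not the largest water store in the column
    psi_layers = np.stack([p.soil.psi() for p in forest.patches])  # (npatch, nl)
    wet = np.stack(
        [
            np.clip(
                (p.soil.theta - p.soil.theta_res) / (p.soil.theta_sat - p.soil.theta_res),
                0.0,
                1.0,
            )
            for p in forest.patches
        ]
    )
    uptake_w = cache.root_frac * wet[cache.patch_of]
    usum = uptake_w.sum(axis=1, keepdims=True)
    uptake_w = np.where(usum > 0, uptake_w / np.where(usum > 0, usum, 1.0), cache.root_frac)
    psi_soil_eff = np.einsum("il,il->i", uptake_w, psi_layers[cache.patch_of])
    # Each cohort claims water per layer in proportion to its root-wetness
    # weights and its daily demand; claims are scaled down wherever a layer
    # cannot cover them, which caps extraction at the available water.
    alloc = np.zeros_like(cache.root_frac)  # kg/m2 ground allocated per cohort-layer
    for ip, p in enumerate(forest.patches):
        sel = np.flatnonzero(cache.patch_of == ip)
        if sel.size == 0:
            continue
        avail = p.soil.available_mm()  # kg/m2 per layer
        claim = (
            uptake_w[sel]
            * (cache.density[sel] * (2.0 * demand_day[sel] + 1e-9))[:, None]
        )
        tot = claim.sum(axis=0)
        scale = np.where(tot > avail, avail / np.where(tot > 0, tot, 1.0), 1.0)
        alloc[sel] = claim * scale[None, :]
    budget = alloc.sum(axis=1) / np.maximum(cache.density, 1e-300)  # kg per plant
    remaining = budget.copy()

    # sub-daily implicit hydraulics
    dt = 86400.0 / cfg.substeps_per_day
    psi_s, psi_l = cache.psi_s, cache.psi_l
    psi_s0, psi_l0 = psi_s.copy(), psi_l.copy()
    e_tot = np.zeros(n)
    x_tot = np.zeros(n)
    cx = np.full(n, cfg.c_xylem)
    # the soil-to-root pathway collapses as the rooted layers dry
    wet_eff = np.einsum("il,il->i", uptake_w, wet[cache.patch_of])
    cr = cfg.c_soilroot * np.clip(wet_eff, 0.0, 1.0) ** cfg.soilk_exp
    for _ in range(cfg.substeps_per_day):
        psi_s, psi_l, e, q1 = phys._hydraulic_substep_vec(
            psi_s, psi_l, psi_soil_eff, demand_rate, cache.height,
            cache.bl, cache.bs, cache.br, cache.pa, dt, cx, cr,
            np.maximum(remaining, 0.0),
        )
        e_tot += e * dt
        x_tot += q1 * dt
        remaining -= q1 * dt
    cache.psi_s, cache.psi_l = psi_s, psi_l

    # patch soil update + water ledger
    dstore = (cache.cap_s * (psi_s - psi_s0) + cache.cap_l * (psi_l - psi_l0)) * cache.density
    soil_evap_w = 0.0
    for ip, p in enumerate(forest.patches):
        sel = np.flatnonzero(cache.patch_of == ip)
        extraction_mm = np.zeros(p.soil.n_layers)
        transp = 0.0
        if sel.size:
            x_ground = x_tot[sel] * cache.density[sel]  # kg/m2
            asum = alloc[sel].sum(axis=1)
            wgt = alloc[sel] / np.where(asum > 0, asum, 1.0)[:, None]
            extraction_mm = (x_ground[:, None] * wgt).sum(axis=0)
            transp = float((e_tot[sel] * cache.density[sel]).sum())
        soil_evap_w += p.area_weight * _soil_day(
            p, cfg, precip, cache.ground_frac[ip], extraction_mm,
            water_rows, month_key, transp,
            float(dstore[sel].sum()) if sel.size else 0.0,
        )

    # flux and cohort accumulators
    gpp_day = gross * cache.la * SECONDS_DAYLIGHT * KC           # kg C /plant /day
    potgpp_day = gross_pot * cache.la * SECONDS_DAYLIGHT * KC
    rleaf_day = r_leaf_rate * cache.la * 86400.0 * KC
    rroot_day = cache.root_respiration * cache.br * 86400.0 * KC
    for i, c in enumerate(cache.cohorts):
        a = c.acc
        a["gpp"] += gpp_day[i]
        a["pot_gpp"] += potgpp_day[i]
        a["r_leaf"] += rleaf_day[i]
        a["r_root"] += rroot_day[i]
        a["transp"] += e_tot[i]
    # per-PFT daily totals, area-weighted to the site (kg/m2/day)
    out = {}
    w = np.array([forest.patches[ip].area_weight for ip in cache.patch_of])
    for pft in set(c.pft for c in cache.cohorts):
        sel = np.array([c.pft == pft for c in cache.cohorts])
        gw = w[sel] * cache.density[sel]
        out[pft] = {
            "gpp": float((gpp_day[sel] * gw).sum()),
            "r_leaf": float((rleaf_day[sel] * gw).sum()),
            "r_root": float((rroot_day[sel] * gw).sum()),
            "transp": float((e_tot[sel] * gw).sum()),
        }
    return out, soil_evap_w


def _soil_day(patch, cfg, precip, ground_frac, extraction_mm, water_rows,
              month_key, transp, dplant):
    soil = patch.soil
    w0 = soil.water_mm()
    interception = cfg.interception_frac * precip
    soil.extract(extraction_mm)
    drainage = soil.infiltrate(precip - interception)
    drainage += soil.percolate(cfg.perc_rate, cfg.theta_fc)
    avail_top = soil.available_mm()[0]
    pot = cfg.soil_evap_max * ground_frac
    rel = (soil.theta[0] - soil.theta_res) / (soil.theta_sat - soil.theta_res)
    soil_evap = float(min(pot * max(rel, 0.0), avail_top))
    soil.extract(np.concatenate([[soil_evap], np.zeros(soil.n_layers - 1)]))
    w1 = soil.water_mm()
    extraction = float(extraction_mm.sum())
    residual = precip - interception - drainage - soil_evap - extraction - (w1 - w0)
    water_rows.append(
        {
            "month": month_key, "patch": patch.id, "precip": precip,
            "interception": interception, "drainage": drainage,
            "soil_evap": soil_evap, "extraction": extraction,
            "transpiration": transp, "dplant_storage": dplant,
            "dsoil": w1 - w0, "residual": residual,
        }
    )
    return soil_evap


# ---------------------------------------------------------------------------
# Monthly demography
# ---------------------------------------------------------------------------


def _monthly_demography(forest: Forest, days_in_month: int, carbon_rows, month_key):
    """Allocation, growth, climbing height restriction, mortality and
    recruitment; returns the number of liana height-cap violations found
    after the step (always 0 unless the algorithm is broken)."""
    cfg = forest.config
    yfrac = days_in_month / 365.0
    violations = 0
    for patch in forest.patches:
        # grow every cohort in diameter first
        for c in patch.cohorts:
            pars = forest.param(c.pft)
            a = c.acc
            turnover = (pars.leaf_turnover * c.bl + pars.root_turnover * c.br) * yfrac
            cb_pre = a["gpp"] - a["r_leaf"] - a["r_root"] - turnover
            r_growth = pars.growth_respiration * max(cb_pre, 0.0)
            cb = cb_pre - r_growth
            available = c.storage + cb
            bl0, bs0, br0, st0 = c.bl, c.bs, c.br, c.storage
            repro = 0.0
            died = False
            if available > 0.0:
                repro = pars.reproduction_carbon * available
                growth = available - repro
                d = c.dbh
                dBl = pars.b1Bl * pars.b2Bl * d ** (pars.b2Bl - 1.0)
                dBs = pars.b1Bs * pars.b2Bs * d ** (pars.b2Bs - 1.0)
                dBr = pars.q * dBl
                denom = dBl + dBs + dBr
                c.dbh = d + growth / denom
                c.bl += growth * dBl / denom
                c.bs += growth * dBs / denom
                c.br += growth * dBr / denom
                c.storage = 0.0
                patch.recruit_pool[c.pft] = (
                    patch.recruit_pool.get(c.pft, 0.0) + repro * c.density
                )
            else:
                deficit = -available
                pool = c.bl + c.br + c.bs
                burn = min(deficit, 0.95 * pool)
                if pool > 0:
                    fb = burn / pool
                    c.bl -= fb * c.bl
                    c.br -= fb * c.br
                    c.bs -= fb * c.bs
                # burn covers the deficit exactly unless the cohort has
                # starved beyond its own biomass, in which case the residual
                # stays on the (dying) cohort's books
                c.storage = min(available + burn, 0.0)
                if c.storage < -1e-12:
                    died = True
            # mortality from the trailing carbon-balance ratio
            ratio = 0.0
            if a["pot_gpp"] > 0:
                ratio = min(max(a["gpp"] / a["pot_gpp"], 0.0), 1.0)
            c.cb_window = (c.cb_window + [ratio])[-12:]
            cbar = sum(c.cb_window) / len(c.cb_window)
            rate = pars.mort3 + pars.mort1 / (1.0 + math.exp(pars.mort2 * cbar))
            c.density *= math.exp(-rate * yfrac)
            if died:
                c.density = 0.0
            carbon_rows.append(
                {
                    "month": month_key, "patch": patch.id, "cohort": c.id,
                    "pft": c.pft, "gpp": a["gpp"], "r_leaf": a["r_leaf"],
                    "r_root": a["r_root"], "r_growth": r_growth,
                    "turnover": turnover, "repro": repro,
                    "d_struct": (c.bl - bl0) + (c.bs - bs0) + (c.br - br0),
                    "d_storage": c.storage - st0, "died": died,
                }
            )
            c.reset_acc()
        # heights: trees from allometry, then lianas capped by the canopy
        for c in patch.cohorts:
            if c.pft != "liana":
                c.height = float(phys.height_from_dbh(c.dbh, forest.param(c.pft)))
        tallest = patch.tallest_tree_height()
        for c in patch.cohorts:
            if c.pft != "liana":
                continue
            pars = forest.param(c.pft)
            potential = float(phys.height_from_dbh(c.dbh, pars, c.delta_dbh))
            if tallest is not None and c.dbh >= cfg.dbh_threshold:
                cap = min(tallest + cfg.h_offset, 0.98 * pars.h_max)
                if potential > cap:
                    c.height = cap
                    c.delta_dbh = float(phys.dbh_from_height(cap, pars)) - c.dbh
                else:
                    c.height = potential
            else:
                c.height = potential
            if (
                tallest is not None
                and c.dbh >= cfg.dbh_threshold
                and c.height > tallest + cfg.h_offset + 1e-9
            ):
                violations += 1
        # recruitment
        for pft, pool in list(patch.recruit_pool.items()):
            pars = forest.param(pft)
            cost = float(phys.structural_biomass(cfg.recruit_dbh, pars))
            dens = pool / cost
            if dens >= cfg.recruit_min_density:
                c = Cohort(pft=pft, density=dens, dbh=cfg.recruit_dbh)
                c.bl = float(phys.leaf_biomass(c.dbh, pars))
                c.bs = float(phys.stem_biomass(c.dbh, pars))
                c.br = float(phys.fine_root_biomass(c.dbh, pars))
                c.height = float(phys.height_from_dbh(c.dbh, pars))
                psi0 = float(patch.soil.psi()[0])
                c.psi_stem = psi0
                c.psi_leaf = psi0 - c.height
                c.reset_acc()
                patch.cohorts.append(c)
                patch.recruit_pool[pft] = 0.0
        # drop and merge
        patch.cohorts = [c for c in patch.cohorts if c.density > cfg.density_floor]
        _merge_cohorts(patch, cfg)
        patch.cohorts.sort(key=lambda c: -c.height)
    return violations


def _merge_cohorts(patch, cfg):
    merged = []
    by_pft = {}
    for c in sorted(patch.cohorts, key=lambda c: c.dbh):
        key = c.pft
        prev = by_pft.get(key)
        if prev is not None and abs(c.dbh - prev.dbh) <= cfg.merge_dbh_reltol * prev.dbh:
            wt = prev.density + c.density
            for attr in ("dbh", "delta_dbh", "height", "bl", "bs", "br",
                         "storage", "psi_leaf", "psi_stem"):
                setattr(prev, attr,
                        (getattr(prev, attr) * prev.density + getattr(c, attr) * c.density) / wt)
            prev.cb_window = [
                (a * prev.density + b * c.density) / wt
                for a, b in zip(prev.cb_window, c.cb_window)
            ]
            prev.density = wt
        else:
            merged.append(c)
            by_pft[key] = c
    patch.cohorts = merged


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


class SimulationResults:
    """Monthly fluxes, state snapshots and conservation ledgers of a run."""

    def __init__(self, fluxes, water_ledger, carbon_ledger, snapshots,
                 forest, height_violations):
        self.fluxes = fluxes
        self.water_ledger = water_ledger
        self.carbon_ledger = carbon_ledger
        self.snapshots = snapshots
        self.forest = forest
        self.height_violations = height_violations

    def water_closure_error(self) -> float:
        """Max |budget residual| / precip-scale over all patch-days."""
        w = self.water_ledger
        scale = np.maximum(w["precip"].abs(), 1.0)
        return float((w["residual"].abs() / scale).max())

    def carbon_closure_error(self) -> float:
        """Max relative error of GPP = costs + pool changes per cohort-month."""
        c = self.carbon_ledger
        lhs = c["gpp"]
        rhs = (c["r_leaf"] + c["r_root"] + c["r_growth"] + c["turnover"]
               + c["repro"] + c["d_struct"] + c["d_storage"])
        gross = (c["gpp"].abs() + c["r_leaf"].abs() + c["r_root"].abs()
                 + c["turnover"].abs() + c["d_struct"].abs() + c["d_storage"].abs())
        scale = np.maximum(gross, 1e-6)
        return float(((lhs - rhs).abs() / scale).max())

    def summary(self) -> pd.DataFrame:
        f = self.fluxes
        eco = f[f["pft"] == "ecosystem"]
        rows = []
        for pft in f["pft"].unique():
            sub = f[f["pft"] == pft]
            rows.append(
                {
                    "pft": pft,
                    "mean_gpp_kgC_m2_yr": sub["gpp"].mean() * 12.0,
                    "mean_npp_kgC_m2_yr": sub["npp"].mean() * 12.0,
                    "mean_transp_kg_m2_day": sub["transp"].mean(),
                    "mean_lai": sub["lai"].mean(),
                    "final_agb_kgC_m2": sub["agb"].iloc[-1],
                }
            )
        return pd.DataFrame(rows)

    def plot_fluxes(self, variable="gpp", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for pft, sub in self.fluxes.groupby("pft"):
            ax.plot(range(len(sub)), sub[variable], label=pft)
        ax.set_xlabel("month")
        ax.set_ylabel(variable)
        ax.legend()
        return ax


class ForestSimulation:
    """Run a forest under daily meteorology with monthly demography."""

    def __init__(self, forest: Forest, met: pd.DataFrame):
        need = {"date", "precip_mm", "par_umol_m2_s", "tair_C", "rh_frac"}
        missing = need - set(met.columns)
        if missing:
            raise ValueError(f"met missing columns: {sorted(missing)}")
        self.forest = forest.copy()
        met = met.copy()
        met["date"] = pd.to_datetime(met["date"])
        self.met = met.sort_values("date").reset_index(drop=True)

    def run(self, years: int = 5, seed: int = 0) -> SimulationResults:
        forest = self.forest
        met = self.met
        months = met.groupby(met["date"].dt.to_period("M"), sort=True)
        month_list = list(months)
        n_months = years * 12
        water_rows, carbon_rows, flux_rows, snapshots = [], [], [], []
        violations = 0
        for im in range(n_months):
            period, days = month_list[im % len(month_list)]
            key = f"{im:03d}|{period}"
            cache = _MonthCache(forest)
            acc = {}
            soil_evap = 0.0
            for _, row in days.iterrows():
                daily, se = _daily_step(forest, cache, row, water_rows, key)
                soil_evap += se
                for pft, d in daily.items():
                    tgt = acc.setdefault(pft, {k: 0.0 for k in d})
                    for k, v in d.items():
                        tgt[k] += v
            cache.writeback()
            ndays = len(days)
            # demography (uses and then resets the cohort accumulators);
            # growth respiration is charged there, so recover it for NPP
            rg = {}
            for p in forest.patches:
                for c in p.cohorts:
                    pars = forest.param(c.pft)
                    turn = (pars.leaf_turnover * c.bl + pars.root_turnover * c.br) * ndays / 365.0
                    cbp = c.acc["gpp"] - c.acc["r_leaf"] - c.acc["r_root"] - turn
                    rg[c.pft] = rg.get(c.pft, 0.0) + (
                        pars.growth_respiration * max(cbp, 0.0) * c.density * p.area_weight
                    )
            violations += _monthly_demography(forest, ndays, carbon_rows, key)
            # monthly flux records
            state = _state_by_pft(forest)
            eco = {"gpp": 0.0, "resp": 0.0, "transp": 0.0, "lai": 0.0, "agb": 0.0}
            for pft, d in acc.items():
                resp = d["r_leaf"] + d["r_root"] + rg.get(pft, 0.0)
                st = state.get(pft, {"lai": 0.0, "agb": 0.0, "density": 0.0})
                flux_rows.append(
                    {
                        "month": key, "month_index": im, "pft": pft,
                        "gpp": d["gpp"], "npp": d["gpp"] - resp, "resp_auto": resp,
                        "transp": d["transp"] / ndays, "lai": st["lai"],
                        "agb": st["agb"], "density": st["density"],
                    }
                )
                eco["gpp"] += d["gpp"]
                eco["resp"] += resp
                eco["transp"] += d["transp"] / ndays
                eco["lai"] += st["lai"]
                eco["agb"] += st["agb"]
            flux_rows.append(
                {
                    "month": key, "month_index": im, "pft": "ecosystem",
                    "gpp": eco["gpp"], "npp": eco["gpp"] - eco["resp"],
                    "resp_auto": eco["resp"],
                    "transp": eco["transp"] + soil_evap / ndays,
                    "lai": eco["lai"], "agb": eco["agb"], "density": np.nan,
                }
            )
            snapshots.append({"month": key, "by_pft": state})
        fluxes = pd.DataFrame(flux_rows)
        return SimulationResults(
            fluxes,
            pd.DataFrame(water_rows),
            pd.DataFrame(carbon_rows),
            snapshots,
            forest,
            violations,
        )


def _state_by_pft(forest: Forest):
    out = {}
    for p in forest.patches:
        for c in p.cohorts:
            d = out.setdefault(c.pft, {"lai": 0.0, "agb": 0.0, "density": 0.0})
            d["lai"] += forest.cohort_lai(c) * p.area_weight
            d["agb"] += (c.bl + c.bs) * c.density * p.area_weight
            d["density"] += c.density * p.area_weight
    return out


def run_simulation(forest, met, years=5, seed=0) -> SimulationResults:
    return ForestSimulation(forest, met).run(years=years, seed=seed)


def liana_share(fluxes: pd.DataFrame, variable: str = "gpp") -> pd.Series:
    """Monthly liana fraction of the ecosystem flux, NaN where the total
    is zero (flagged undefined)."""
    eco = fluxes[fluxes["pft"] == "ecosystem"].set_index("month_index")[variable]
    li = fluxes[fluxes["pft"] == "liana"].set_index("month_index")[variable]
    li = li.reindex(eco.index, fill_value=0.0)
    share = li / eco.where(eco != 0.0)
    share.name = f"liana_share_{variable}"
    return share
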