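"""Allometry, hydraulics, stomatal regulation and leaf carbon uptake.

Pure functions shared by the demographic simulator.  Water potentials are
carried in m H2O (1 MPa is roughly 102 m) and are never positive; the
gravitational head of a plant equals its height in metres.  Parameters that
are physically negative (P50, stoma_psi_b, leaf_TLP, b1Rd) are stored
positive in :class:`PFTParameterSet` and negated here at use time.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace, fields, asdict

import numpy as np

__all__ = [
    "PFTParameterSet",
    "HydraulicState",
    "leaf_biomass",
    "stem_biomass",
    "fine_root_biomass",
    "structural_biomass",
    "structural_biomass_derivative",
    "leaf_area",
    "height_from_dbh",
    "dbh_from_height",
    "rooting_depth",
    "stem_conductivity",
    "stomatal_stress",
    "leaf_assimilation",
    "stomatal_conductance",
    "hydraulic_substep",
]

MOL_C_KG = 12.011e-3  # kg C per mol
MOL_W_KG = 18.015e-3  # kg H2O per mol


@dataclass(frozen=True)
class PFTParameterSet:
    """One plant functional type: the 32 analysed parameters plus fixed
    structural constants (asymptotic height, residual stomatal conductance,
    carbon-balance mortality amplitude)."""

    growth_form: str  # "liana" or "tree"
    b1Bl: float
    b2Bl: float
    b1Bs: float
    b2Bs: float
    q: float
    b1Rd: float
    b2Rd: float
    b1Ht: float
    b2Ht: float
    reproduction_carbon: float
    root_beta: float
    SRA: float
    K_max: float
    K_exp: float
    P50: float
    wood_capacitance: float
    leaf_capacitance: float
    stoma_psi_b: float
    stoma_psi_c: float
    leaf_TLP: float
    V_m0: float
    quantum_efficiency: float
    stomatal_slope: float
    root_respiration: float
    dark_respiration: float
    growth_respiration: float
    mort2: float
    mort3: float
    leaf_turnover: float
    root_turnover: float
    SLA: float
    rho: float
    h_max: float = 35.0
    gs_min: float = 0.01
    mort1: float = 1.0

    def __post_init__(self):
        if self.growth_form not in ("liana", "tree"):
            raise ValueError(f"growth_form must be liana or tree, got {self.growth_form!r}")
        for f in fields(self):
            if f.name == "growth_form":
                continue
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{f.name} must be finite and >= 0 on storage scale, got {v}")
        for nm, lo, hi in [
            ("reproduction_carbon", 0.0, 1.0),
            ("growth_respiration", 0.0, 1.0),
        ]:
            v = getattr(self, nm)
            if not (lo < v < hi):
                raise ValueError(f"{nm} must lie in ({lo}, {hi}), got {v}")
        if not 0.0 <= self.root_beta < 1.0:
            raise ValueError(f"root_beta must lie in [0, 1), got {self.root_beta}")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "PFTParameterSet":
        kv = {}
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "key,value":
                raise ValueError(f"{path}: expected 'key,value' header")
            for line in fh:
                if not line.strip():
                    continue
                k, v = line.strip().split(",")
                kv[k] = v if k == "growth_form" else float(v)
        return cls(**kv)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key,value\n")
            for f in fields(self):
                fh.write(f"{f.name},{getattr(self, f.name)}\n")

    @classmethod
    def _packaged(cls, name) -> "PFTParameterSet":
        ref = importlib.resources.files("lianacomp.data").joinpath(name)
        with importlib.resources.as_file(ref) as p:
            return cls.from_file(p)

    @classmethod
    def liana_prior(cls):
        """Liana PFT at the prior medians of the trait table."""
        return cls._packaged("pft_liana_prior.csv")

    @classmethod
    def liana_posterior(cls):
        """Liana PFT at the meta-analysis posterior medians."""
        return cls._packaged("pft_liana_posterior.csv")

    @classmethod
    def tree(cls, stage: str):
        """Fixed tree PFT (stage in early/mid/late successional)."""
        if stage not in ("early", "mid", "late"):
            raise ValueError(f"tree stage must be early/mid/late, got {stage!r}")
        return cls._packaged(f"pft_tree_{stage}.csv")

    def replace(self, **kw) -> "PFTParameterSet":
        return replace(self, **kw)

    def asdict(self):
        return asdict(self)


@dataclass
class HydraulicState:
    """Leaf and stem water potentials, m H2O, <= 0."""

    psi_leaf: float = 0.0
    psi_stem: float = 0.0

    def __post_init__(self):
        if self.psi_leaf > 0 or self.psi_stem > 0:
            raise ValueError("water potentials must be <= 0")


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------


def _check_dbh(dbh):
    if np.any(np.asarray(dbh) <= 0):
        raise ValueError(f"dbh must be > 0, got {dbh}")


def leaf_biomass(dbh, params: PFTParameterSet):
    """Bl = b1Bl * dbh^b2Bl, kg C per plant."""
    _check_dbh(dbh)
    return params.b1Bl * np.asarray(dbh, dtype=float) ** params.b2Bl


def stem_biomass(dbh, params: PFTParameterSet):
    """Bs = b1Bs * dbh^b2Bs, kg C per plant."""
    _check_dbh(dbh)
    return params.b1Bs * np.asarray(dbh, dtype=float) ** params.b2Bs


def fine_root_biomass(dbh, params: PFTParameterSet):
    """Br = q * Bl, kg C per plant."""
    return params.q * leaf_biomass(dbh, params)


def structural_biomass(dbh, params: PFTParameterSet):
    """Bl + Bs + Br as a function of DBH."""
    return (1.0 + params.q) * leaf_biomass(dbh, params) + stem_biomass(dbh, params)


def structural_biomass_derivative(dbh, params: PFTParameterSet):
    """d(Bl + Bs + Br)/dDBH, used to convert growth carbon into a DBH increment."""
    _check_dbh(dbh)
    d = np.asarray(dbh, dtype=float)
    dBl = params.b1Bl * params.b2Bl * d ** (params.b2Bl - 1.0)
    dBs = params.b1Bs * params.b2Bs * d ** (params.b2Bs - 1.0)
    return (1.0 + params.q) * dBl + dBs


def leaf_area(dbh, params: PFTParameterSet):
    """Leaf area per plant, m^2 = SLA * Bl."""
    return params.SLA * leaf_biomass(dbh, params)


def height_from_dbh(dbh, params: PFTParameterSet, delta_dbh=0.0):
    """Saturating DBH-height allometry, optionally shifted by the liana
    climbing offset: h = h_max * (1 - exp(-b1Ht * (dbh + delta)^b2Ht))."""
    d = np.asarray(dbh, dtype=float) + np.asarray(delta_dbh, dtype=float)
    if np.any(np.asarray(dbh) <= 0) or np.any(d <= 0):
        raise ValueError("dbh and dbh + delta_dbh must be > 0")
    return params.h_max * (1.0 - np.exp(-params.b1Ht * d**params.b2Ht))


def dbh_from_height(height, params: PFTParameterSet):
    """Inverse of the height allometry (height strictly below h_max)."""
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0) or np.any(h >= params.h_max):
        raise ValueError(f"height must lie in (0, h_max={params.h_max})")
    return (-np.log(1.0 - h / params.h_max) / params.b1Ht) ** (1.0 / params.b2Ht)


def rooting_depth(height, params: PFTParameterSet):
    """Maximum rooting depth, m (negative, downward): -b1Rd * h^b2Rd."""
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValueError(f"height must be > 0, got {height}")
    return -params.b1Rd * h**params.b2Rd


# ---------------------------------------------------------------------------
# Hydraulics and gas exchange
# ---------------------------------------------------------------------------


def stem_conductivity(psi, params: PFTParameterSet):
    """Weibull-type xylem vulnerability curve.

    K(psi) = K_max * exp(-ln2 * (psi/P50)^K_exp); K(0) = K_max and
    K(P50) = K_max / 2 by construction.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise ValueError("psi must be <= 0")
    p50 = -params.P50  # stored positive
    return params.K_max * np.exp(-math.log(2.0) * (psi / p50) ** params.K_exp)


def stomatal_stress(psi_leaf, params: PFTParameterSet):
    """Soil-water stress factor in [0, 1] applied to gas exchange.

    f = 1 / (1 + (psi_leaf/stoma_psi_b)^stoma_psi_c), hard zero below the
    leaf turgor loss point.
    """
    psi = np.asarray(psi_leaf, dtype=float)
    if np.any(psi > 0):
        raise ValueError("psi_leaf must be <= 0")
    b = -params.stoma_psi_b
    f = 1.0 / (1.0 + (psi / b) ** params.stoma_psi_c)
    f = np.where(psi <= -params.leaf_TLP, 0.0, f)
    return f if f.ndim else float(f)


def leaf_assimilation(par, f_sw, params: PFTParameterSet):
    """Gross and net CO2 uptake per leaf area, umol C m-2 s-1.

    Gross assimilation is the light/capacity co-limited hyperbola
    f_sw * alpha*PAR*Vm / (alpha*PAR + Vm); leaf (dark) respiration
    dark_respiration * Vm is paid in light and dark; net = gross - resp.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("par must be >= 0")
    alpha, vm = params.quantum_efficiency, params.V_m0
    gross = f_sw * np.where(par > 0, alpha * par * vm / (alpha * par + vm), 0.0)
    r_leaf = params.dark_respiration * vm
    net = gross - r_leaf
    return (gross if gross.ndim else float(gross), net if np.ndim(net) else float(net))


def stomatal_conductance(a_net, rh, ca, params: PFTParameterSet):
    """Ball-Berry stomatal conductance, mol m-2 s-1, floored at gs_min."""
    if not ca > 0:
        raise ValueError("ca must be > 0")
    a = np.maximum(np.asarray(a_net, dtype=float), 0.0)
    gs = params.stomatal_slope * a * rh / ca + params.gs_min
    return np.maximum(gs, params.gs_min)


def transpiration_demand(gs, vpd_frac):
    """Water demand per leaf area, kg m-2 s-1 = 1.6 * gs * D * M_w."""
    return 1.6 * np.asarray(gs) * vpd_frac * MOL_W_KG


# ---------------------------------------------------------------------------
# Two-compartment plant water transport
# ---------------------------------------------------------------------------


def _conductances(psi_stem, height, bs, bl, br, params: PFTParameterSet,
                  c_xylem=5.0, c_soilroot=0.01):
    """Soil->stem and stem->leaf hydraulic conductances, kg s-1 per m H2O.

    Both scale with the vulnerability curve K(psi_stem) and a sapwood-area
    proxy (stem volume over height); the soil-root pathway additionally
    scales with fine-root area SRA*Br.  c_xylem and c_soilroot are the two
    configurable calibration constants of the plant water pathway.
    """
    k = stem_conductivity(psi_stem, params)
    a_sap = 2.0 * bs / (params.rho * 1000.0 * np.maximum(height, 0.5))
    g_sl = c_xylem * k * a_sap / np.maximum(height, 0.5)
    g_sr = c_soilroot * k * params.SRA * br / np.maximum(height, 0.5)
    return g_sr, g_sl


def hydraulic_substep(
    state: HydraulicState,
    soil_psi_eff: float,
    demand: float,
    height: float,
    bl: float,
    bs: float,
    br: float,
    params: PFTParameterSet,
    dt: float,
    c_xylem: float = 5.0,
    c_soilroot: float = 0.01,
    max_extraction: float = np.inf,
):
    """Advance the two-compartment (stem, leaf) water store by dt seconds.

    Backward-Euler update with conductances frozen at the current stem
    potential: flows soil->stem q1 = G_sr (psi_soil - psi_stem) and
    stem->leaf q2 = G_sl (psi_stem - psi_leaf - h) with gravitational head h
    (= height, m).  Realized transpiration is the demand capped so the leaf
    potential does not cross the turgor loss point within the step, and soil
    extraction is capped at ``max_extraction`` (kg over the step).  Storage
    follows psi through the capacitances (kg water per kg C per m H2O).

    Returns (new_state, realized_E_kg_s, extraction_kg_s); the update
    conserves water: extraction - transpiration = storage change.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    for v in (state.psi_leaf, state.psi_stem, soil_psi_eff, demand):
        if not np.isfinite(v):
            raise ValueError("non-finite hydraulic state")
    out = _hydraulic_substep_vec(
        np.array([state.psi_stem]),
        np.array([state.psi_leaf]),
        np.array([soil_psi_eff]),
        np.array([demand]),
        np.array([height]),
        np.array([bl]),
        np.array([bs]),
        np.array([br]),
        params_arrays_from(params, 1),
        dt,
        np.array([c_xylem]),
        np.array([c_soilroot]),
        np.array([max_extraction]),
    )
    ps, pl, e, q1 = (float(a[0]) for a in out)
    return HydraulicState(psi_leaf=pl, psi_stem=ps), e, q1


def params_arrays_from(params: PFTParameterSet, n: int) -> dict:
    """Broadcast the hydraulic parameter subset into arrays of length n."""
    names = ["K_max", "K_exp", "P50", "rho", "SRA", "wood_capacitance",
             "leaf_capacitance", "leaf_TLP"]
    return {nm: np.full(n, getattr(params, nm)) for nm in names}


def _hydraulic_substep_vec(psi_s, psi_l, psi_soil, demand, height, bl, bs, br,
                           pa, dt, c_xylem, c_soilroot, max_extraction):
    """Vectorized core of :func:`hydraulic_substep` (arrays per cohort)."""
    p50 = -pa["P50"]
    k = pa["K_max"] * np.exp(-math.log(2.0) * (psi_s / p50) ** pa["K_exp"])
    hh = np.maximum(height, 0.5)
    a_sap = 2.0 * bs / (pa["rho"] * 1000.0 * hh)
    g2 = c_xylem * k * a_sap / hh
    g1 = c_soilroot * k * pa["SRA"] * br / hh
    cs = np.maximum(pa["wood_capacitance"] * bs, 1e-9)
    cl = np.maximum(pa["leaf_capacitance"] * bl, 1e-9)
    tlp = -pa["leaf_TLP"]
    grav = height

    def solve(e_rate, g1_eff, q1_fixed=None):
        # backward Euler: Cs(x-ps)/dt = q1 - g2(x-y-grav); Cl(y-pl)/dt = g2(x-y-grav) - E
        # q1 = g1(psoil - x) unless fixed.
        A = cs / dt + (0.0 if q1_fixed is not None else g1_eff) + g2
        B = -g2
        C = -g2
        D = cl / dt + g2
        r1 = cs / dt * psi_s + (q1_fixed if q1_fixed is not None else g1_eff * psi_soil) + g2 * grav
        r2 = cl / dt * psi_l - g2 * grav - e_rate
        det = A * D - B * C
        x = (r1 * D - B * r2) / det
        y = (A * r2 - C * r1) / det
        return x, y

    x, y = solve(demand, g1)
    # cap transpiration so psi_leaf does not cross TLP within the step
    crossing = (y < tlp) & (psi_l > tlp)
    if np.any(crossing):
        # y fixed at TLP: solve stem eq alone, then E from the leaf budget
        A = cs / dt + g1 + g2
        x_fix = (cs / dt * psi_s + g1 * psi_soil + g2 * (tlp + grav)) / A
        e_fix = g2 * (x_fix - tlp - grav) - cl / dt * (tlp - psi_l)
        neg = e_fix < 0
        x0, y0 = solve(np.zeros_like(demand), g1)
        x = np.where(crossing, np.where(neg, x0, x_fix), x)
        y = np.where(crossing, np.where(neg, y0, tlp), y)
        e = np.where(crossing, np.where(neg, 0.0, e_fix), demand)
    else:
        e = demand.copy() if hasattr(demand, "copy") else np.asarray(demand, dtype=float)
    q1 = np.where(np.isfinite(g1), g1 * (psi_soil - x), 0.0)
    # cap soil extraction at the available water (kg over the step)
    over = q1 * dt > max_extraction
    if np.any(over):
        q1_cap = np.where(over, np.maximum(max_extraction, 0.0) / dt, q1)
        x2, y2 = solve(e, g1, q1_fixed=q1_cap)
        # re-apply the TLP cap under fixed inflow
        crossing2 = over & (y2 < tlp) & (psi_l > tlp)
        if np.any(crossing2):
            A = cs / dt + g2
            x_fix = (cs / dt * psi_s + q1_cap + g2 * (tlp + grav)) / A
            e_fix = g2 * (x_fix - tlp - grav) - cl / dt * (tlp - psi_l)
            neg = e_fix < 0
            x0, y0 = solve(np.zeros_like(demand), g1, q1_fixed=q1_cap)
            x2 = np.where(crossing2, np.where(neg, x0, x_fix), x2)
            y2 = np.where(crossing2, np.where(neg, y0, tlp), y2)
            e = np.where(crossing2, np.where(neg, 0.0, e_fix), e)
        x = np.where(over, x2, x)
        y = np.where(over, y2, y)
        q1 = np.where(over, q1_cap, q1)
    # keep potentials non-positive: cap inflow rather than clipping state.
    # With psi_stem pinned at 0 the leaf equation is solved alone (its
    # solution is <= 0 whenever psi_leaf <= 0, grav > 0 and E >= 0), then the
    # stem budget gives the limited inflow — both budgets close exactly.
    pos = x > 0
    if np.any(pos):
        y_fix = (cl / dt * psi_l - g2 * grav - e) / (cl / dt + g2)
        q1_lim = (0.0 - psi_s) * cs / dt + g2 * (0.0 - y_fix - grav)
        x = np.where(pos, 0.0, x)
        y = np.where(pos, y_fix, y)
        q1 = np.where(pos, q1_lim, q1)
    return x, y, e, q1
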