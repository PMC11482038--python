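"""Reduced-order, spatially explicit daily simulation of a forage stand.

Plants sit one per node on a toroidal lattice (default 20x20 at 400 plants
m^-2).  Each day the model advances development from thermal time (phytomer
production paced by the individual's phyllochron, slowed on shortening days
once the photoperiod falls below the individual's threshold), partitions
incident light per soil cell with a Beer-Lambert law over the local leaf-area
index and shares each cell's interception among the plants overlapping it,
weighted by leaf area and exponentially by height difference; converts
intercepted PAR to potential dry matter with a radiation-use efficiency;
derives an N demand from a critical N concentration; shares soil mineral N
per cell in proportion to root uptake capacities; and scales realised growth
multiplicatively by the nitrogen nutrition index (NNI) and the development
multiplier.  Four harvests cut shoots back to a residual fraction, and plants
far below the population mean shoot mass shortly after a harvest die.

This is an explicit zone-of-influence surrogate preserving the causal chain
trait -> local resource capture -> growth -> community outcome; it does not
attempt 3D morphogenesis, water limitation (FTSW is fixed at 1) or symbiotic
N fixation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CommunityDesign
from .traits import DEFAULT_MU, p_score, sample_population

__all__ = [
    "SimConfig",
    "Stand",
    "SoilState",
    "EnvironmentSeries",
    "RunResult",
    "make_environment",
    "init_stand",
    "light_partition",
    "n_uptake",
    "step_day",
    "harvest",
    "run_season",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """All tunable constants of the stand surrogate (SI units per plant/cell;
    yields reported as g m^-2)."""

    # -- stand ------------------------------------------------------------
    rows: int = 20
    cols: int = 20
    density: float = 400.0            # plants m^-2 (sets the domain area)
    init_shoot: float = 0.02          # g, seedling shoot mass
    init_root: float = 0.02           # g
    init_reserve: float = 0.05        # g, seed reserve
    init_leaf_area: float = 1.5e-4    # m^2
    init_height: float = 0.02         # m

    # -- environment ------------------------------------------------------
    season_length: int = 365
    sowing_doy: int = 90
    latitude_deg: float = 46.4        # study-site latitude (Lusignan)
    par_mean: float = 7.5             # MJ m^-2 day^-1, annual mean incident PAR
    par_amplitude: float = 5.5        # seasonal sinusoidal amplitude
    t_mean: float = 11.5              # degC, annual mean temperature
    t_amplitude: float = 7.5
    t_base: float = 5.0               # degC, base temperature for thermal time
    initial_soil_n: float = 1.5       # g N m^-2, homogeneous initial pool
    mineralisation: float = 0.04      # g N m^-2 day^-1
    fertilisation_nplus: float = 40.0  # g N m^-2 yr^-1 (= 400 kg N ha^-1) under N+

    # -- constants --------------------------------------------------------
    k_ext: float = 0.6                # Beer-Lambert extinction coefficient
    beta_height: float = 5.0          # m^-1, height-advantage weighting
    rue: float = 2.0                  # g MJ^-1
    n_crit: float = 0.03              # g N (g DM)^-1, critical N concentration
    maintenance_resp: float = 0.004   # g (g biomass)^-1 day^-1 at 10 degC effective
    senescence_rate: float = 0.015    # day^-1, leaf-area loss
    sla: float = 0.02                 # m^2 (g leaf)^-1
    leaf_fraction: float = 0.6        # leaf share of shoot growth
    shoot_frac_max: float = 0.7       # shoot allocation at NNI >= 1
    shoot_frac_min: float = 0.5       # shoot allocation at NNI <= 0.5
    reserve_fraction: float = 0.08    # share of growth routed to reserves
    remobilisation_rate: float = 0.1  # day^-1, reserve use after sowing/cuts
    remobilisation_days: int = 10
    dev_reduction: float = 0.2        # development multiplier below PPtresh_H
    leaf_area_coeff: float = 4.0e-6   # m^2 per (leaf-length unit)^2 per phytomer
    height_coeff: float = 0.010       # m per internode-length unit per phytomer
    height_per_gram: float = 0.4      # m of stem extension per g shoot growth
    root_colonisation: float = 6.0    # soil cells per (root g x EL_max_R unit)
    max_root_cells: int = 25          # own cell + two Moore rings

    # -- harvest / mortality ---------------------------------------------
    harvest_days: tuple = (60, 120, 180, 240)
    residual_fraction: float = 0.2
    mortality_delay: int = 30         # days after a harvest
    mortality_threshold: float = 0.05  # fraction of mean living shoot mass

    @property
    def n_plants(self) -> int:
        return self.rows * self.cols

    @property
    def domain_area(self) -> float:
        return self.n_plants / self.density

    @property
    def cell_area(self) -> float:
        return self.domain_area / self.n_plants


@dataclass
class Stand:
    """Per-plant state arrays (length n, aligned with lattice node index)."""

    species: np.ndarray        # 1 or 2
    traits: np.ndarray         # (n, n_traits)
    trait_names: tuple
    p_score: np.ndarray
    row: np.ndarray
    col: np.ndarray
    leaf_area: np.ndarray      # m^2
    pot_leaf_area: np.ndarray  # unexpanded phytomer leaf-area pool, m^2
    height: np.ndarray         # m
    pot_height: np.ndarray     # unextended internode pool, m
    shoot: np.ndarray          # g
    root: np.ndarray           # g
    reserve: np.ndarray        # g
    thermal: np.ndarray        # accumulated effective degree-days
    phytomers: np.ndarray
    cum_pari: np.ndarray       # MJ
    cum_nupt: np.ndarray       # g N
    nni: np.ndarray
    alive: np.ndarray          # bool
    produced: np.ndarray       # cumulative new dry matter, g
    respired: np.ndarray       # cumulative maintenance losses, g
    harvested: np.ndarray      # cumulative removed shoot mass, g

    def trait(self, name: str) -> np.ndarray:
        return self.traits[:, self.trait_names.index(name)]

    @property
    def n(self) -> int:
        return self.species.size


@dataclass
class SoilState:
    """Lattice of mineral-N pools plus the flux totals for mass balance."""

    mineral_n: np.ndarray      # g N per cell
    initial_total: float
    fert_in: float = 0.0
    mineralised_in: float = 0.0
    uptake_out: float = 0.0

    def balance_error(self) -> float:
        """Relative error of initial + inputs - uptake vs the current pool."""
        expected = self.initial_total + self.fert_in + self.mineralised_in - self.uptake_out
        scale = max(abs(expected), self.initial_total + self.fert_in + self.mineralised_in, 1e-12)
        return abs(self.mineral_n.sum() - expected) / scale


@dataclass
class EnvironmentSeries:
    """Daily driver series for one season of one treatment."""

    treatment: str
    par: np.ndarray            # MJ m^-2 day^-1 incident
    t_eff: np.ndarray          # effective degree-days
    photoperiod: np.ndarray    # hours
    shortening: np.ndarray     # bool, day-over-day photoperiod decrease
    fert: np.ndarray           # g N m^-2 applied that day
    season_length: int
    harvest_days: tuple


@dataclass
class RunResult:
    design: CommunityDesign
    plants: pd.DataFrame
    yields: dict               # species -> annual partial yield, g m^-2
    harvest_log: list          # (day, {species: g m^-2}, survivors)
    diagnostics: dict

    @property
    def ytot(self) -> float:
        return float(sum(self.yields.values()))

    @property
    def p50s(self) -> float:
        return self.yields.get(2, 0.0) / self.ytot


def _daylength_hours(doy: np.ndarray, latitude_deg: float) -> np.ndarray:
    decl = np.radians(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    lat = math.radians(latitude_deg)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 2.0 * np.degrees(np.arccos(cos_h)) / 15.0


def make_environment(treatment: str, config: SimConfig) -> EnvironmentSeries:
    """Build the daily PAR / temperature / photoperiod / fertilisation series.

    Incident PAR and air temperature follow smooth sinusoidal climatologies
    (peaks at the summer solstice and ~4 weeks later respectively); the
    photoperiod is computed from latitude and day of year.  Under N+ the
    annual fertiliser total is split equally between sowing and the day
    after each of the first three harvests.
    """
    if treatment not in ("0N", "N+"):
        raise ValueError(f"unknown treatment {treatment!r}")
    days = np.arange(config.season_length)
    doy = (config.sowing_doy - 1 + days) % 365 + 1
    par = config.par_mean + config.par_amplitude * np.cos(2 * np.pi * (doy - 172) / 365.0)
    temp = config.t_mean + config.t_amplitude * np.cos(2 * np.pi * (doy - 200) / 365.0)
    t_eff = np.maximum(0.0, temp - config.t_base)
    photoperiod = _daylength_hours(doy.astype(float), config.latitude_deg)
    shortening = np.empty(config.season_length, dtype=bool)
    shortening[1:] = np.diff(photoperiod) < 0
    shortening[0] = photoperiod[1] < photoperiod[0] if config.season_length > 1 else False
    fert = np.zeros(config.season_length)
    if treatment == "N+":
        events = [0] + [h + 1 for h in config.harvest_days[:3] if h + 1 < config.season_length]
        for day in events:
            fert[day] += config.fertilisation_nplus / len(events)
    return EnvironmentSeries(
        treatment=treatment,
        par=par,
        t_eff=t_eff,
        photoperiod=photoperiod,
        shortening=shortening,
        fert=fert,
        season_length=config.season_length,
        harvest_days=tuple(config.harvest_days),
    )


class _Lattice:
    """Precomputed toroidal neighbourhood index tables for one grid shape.

    ``zone`` maps each plant to the 9 cells of its zone of influence (own
    cell + Moore ring); ``root_cells`` lists the 25 candidate rooting cells
    in colonisation order (own cell, first ring, second ring).
    """

    _cache: dict = {}

    def __new__(cls, rows: int, cols: int):
        key = (rows, cols)
        if key not in cls._cache:
            obj = super().__new__(cls)
            obj._build(rows, cols)
            cls._cache[key] = obj
        return cls._cache[key]

    def _build(self, rows: int, cols: int):
        self.rows, self.cols = rows, cols
        n = rows * cols
        r = np.arange(n) // cols
        c = np.arange(n) % cols
        ring0 = [(0, 0)]
        ring1 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
        ring2 = [
            (dr, dc)
            for dr in range(-2, 3)
            for dc in range(-2, 3)
            if max(abs(dr), abs(dc)) == 2
        ]

        def flat(offsets):
            out = np.empty((n, len(offsets)), dtype=np.intp)
            for j, (dr, dc) in enumerate(offsets):
                out[:, j] = ((r + dr) % rows) * cols + (c + dc) % cols
            return out

        self.zone = flat(ring0 + ring1)               # (n, 9)
        self.root_cells = flat(ring0 + ring1 + ring2)  # (n, 25)
        self.moore = flat(ring1)                       # (n, 8), excludes self
        self.row, self.col = r, c


def init_stand(design: CommunityDesign, config: SimConfig | None = None):
    """Place and initialise plants and soil for one run.

    Plants occupy every lattice node.  Mixtures get exactly half of the
    nodes per species through a seeded random permutation; genotypes are
    drawn per species from its TraitSpec.  Soil starts homogeneous.
    Deterministic given (design, config).
    """
    config = config or SimConfig()
    lat = _Lattice(config.rows, config.cols)
    n = config.n_plants
    ss = np.random.SeedSequence(design.seed)
    place_rng, rng1, rng2 = (np.random.default_rng(s) for s in ss.spawn(3))

    if design.pure_species:
        species = np.full(n, design.pure_species, dtype=np.int8)
    else:
        if n % 2:
            raise ValueError("a 50/50 mixture needs an even plant count")
        species = np.repeat(np.array([1, 2], dtype=np.int8), n // 2)
        species = species[place_rng.permutation(n)]

    spec1, spec2 = design.spec_sp1, design.spec_sp2
    traits = np.empty((n, spec1.n_traits))
    scores = np.empty(n)
    for sp, spec, rng in ((1, spec1, rng1), (2, spec2, rng2)):
        idx = np.flatnonzero(species == sp)
        if idx.size:
            values = sample_population(spec, idx.size, rng)
            traits[idx] = values
            scores[idx] = p_score(values, spec)

    stand = Stand(
        species=species,
        traits=traits,
        trait_names=spec1.names,
        p_score=scores,
        row=lat.row.copy(),
        col=lat.col.copy(),
        leaf_area=np.full(n, config.init_leaf_area),
        pot_leaf_area=np.zeros(n),
        height=np.full(n, config.init_height),
        pot_height=np.zeros(n),
        shoot=np.full(n, config.init_shoot),
        root=np.full(n, config.init_root),
        reserve=np.full(n, config.init_reserve),
        thermal=np.zeros(n),
        phytomers=np.zeros(n),
        cum_pari=np.zeros(n),
        cum_nupt=np.zeros(n),
        nni=np.ones(n),
        alive=np.ones(n, dtype=bool),
        produced=np.zeros(n),
        respired=np.zeros(n),
        harvested=np.zeros(n),
    )
    cell_n = config.initial_soil_n * config.cell_area
    soil = SoilState(
        mineral_n=np.full(n, cell_n),
        initial_total=cell_n * n,
    )
    return stand, soil


def light_partition(stand: Stand, par_today: float, config: SimConfig) -> np.ndarray:
    """Per-plant intercepted PAR (MJ) for one day.

    Each plant spreads its leaf area evenly over its 9-cell zone of
    influence.  A cell intercepts I0 * area * (1 - exp(-k * LAI_cell)) and
    shares it among contributing plants proportionally to
    a_i * exp(beta * (H_i - Hbar_cell)) with Hbar the leaf-area-weighted
    mean height over the cell.  Total interception never exceeds incidence.
    """
    lat = _Lattice(config.rows, config.cols)
    n_cells = config.n_plants
    la = np.where(stand.alive, stand.leaf_area, 0.0)
    if not la.any():
        return np.zeros(stand.n)
    contrib = la / 9.0
    zone_flat = lat.zone.ravel()
    w_area = np.repeat(contrib, 9)
    area_c = np.bincount(zone_flat, weights=w_area, minlength=n_cells)
    lai_c = area_c / config.cell_area
    par_c = par_today * config.cell_area * -np.expm1(-config.k_ext * lai_c)
    hsum_c = np.bincount(zone_flat, weights=np.repeat(contrib * stand.height, 9), minlength=n_cells)
    hbar_c = np.divide(hsum_c, area_c, out=np.zeros(n_cells), where=area_c > 0)
    dh = stand.height[:, None] - hbar_c[lat.zone]
    w = contrib[:, None] * np.exp(config.beta_height * dh)
    w_c = np.bincount(zone_flat, weights=w.ravel(), minlength=n_cells)
    share = np.divide(par_c, w_c, out=np.zeros(n_cells), where=w_c > 0)
    return (w * share[lat.zone]).sum(axis=1)


def _root_cell_counts(stand: Stand, config: SimConfig) -> np.ndarray:
    el = stand.trait("EL_max_R")
    cells = 1 + np.floor(config.root_colonisation * el * stand.root)
    return np.clip(cells, 1, config.max_root_cells).astype(np.intp)


def n_uptake(
    stand: Stand, soil: SoilState, demand: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Per-plant mineral-N uptake (g N) for one day; decrements the soil.

    Each living plant spreads its root mass over its colonised cells (own
    cell plus Moore rings, in order, as allowed by root growth times its
    EL_max_R rate).  Per cell, a plant's uptake capacity is Vmax_2 x root
    mass in the cell; its desired draw is capped by its demand share.  Cells
    where desires exceed the pool share their N proportionally to
    capacities.  Uptake never exceeds demand and the soil is decremented by
    exactly what is taken.
    """
    lat = _Lattice(config.rows, config.cols)
    n_cells = config.n_plants
    ncells = _root_cell_counts(stand, config)
    active = (np.arange(config.max_root_cells)[None, :] < ncells[:, None]) & stand.alive[:, None]
    vmax = stand.trait("Vmax_2")
    # effective root length scales with the elongation rate: faster-growing
    # roots are longer per unit mass, so EL_max_R raises uptake capacity as
    # well as the colonised soil volume
    el_rel = stand.trait("EL_max_R") / DEFAULT_MU["EL_max_R"]
    cap_plant = np.where(stand.alive, vmax * stand.root * el_rel, 0.0)
    cap = np.where(active, (cap_plant / ncells)[:, None], 0.0)
    desired = np.minimum(cap, (np.maximum(demand, 0.0) / ncells)[:, None]) * active

    flat = lat.root_cells.ravel()
    cap_c = np.bincount(flat, weights=cap.ravel(), minlength=n_cells)
    des_c = np.bincount(flat, weights=desired.ravel(), minlength=n_cells)
    pool = soil.mineral_n
    scarce_c = des_c > pool
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_c = np.divide(pool, cap_c, out=np.zeros(n_cells), where=cap_c > 0)
    scarce_at = scarce_c[lat.root_cells]
    alloc = np.where(scarce_at, np.minimum(desired, cap * prop_c[lat.root_cells]), desired)
    uptake = alloc.sum(axis=1)
    removed_c = np.bincount(flat, weights=alloc.ravel(), minlength=n_cells)
    soil.mineral_n = np.maximum(pool - removed_c, 0.0)
    soil.uptake_out += float(uptake.sum())
    return uptake


def step_day(
    stand: Stand,
    soil: SoilState,
    env: EnvironmentSeries,
    day: int,
    config: SimConfig,
    days_since_cut: int,
) -> dict:
    """Advance every plant and the soil by one day; returns diagnostics."""
    alive = stand.alive

    # (1) development: thermal time, phytomer production, potential organs.
    pp_thresh = stand.trait("PPtresh_H")
    dev_mult = np.where(
        env.shortening[day] & (env.photoperiod[day] < pp_thresh),
        config.dev_reduction,
        1.0,
    )
    stand.thermal += env.t_eff[day] * dev_mult * alive
    total_phy = np.floor(stand.thermal / stand.trait("Phyllo_1"))
    new_phy = total_phy - stand.phytomers
    stand.phytomers = total_phy
    stand.pot_leaf_area += config.leaf_area_coeff * stand.trait("L_max_L") ** 2 * new_phy
    # internodes extend only as shoot growth supplies carbon (see step 7),
    # so suppressed plants stay short and size asymmetry can compound
    stand.pot_height += config.height_coeff * stand.trait("L_max_In") * new_phy

    # soil inputs for the day
    fert = env.fert[day] * config.cell_area
    miner = config.mineralisation * config.cell_area
    soil.mineral_n += fert + miner
    soil.fert_in += fert * soil.mineral_n.size
    soil.mineralised_in += miner * soil.mineral_n.size

    # (2)-(3) light partitioning and potential growth
    pari = light_partition(stand, env.par[day], config)
    stand.cum_pari += pari
    dm_pot = config.rue * pari

    # (4)-(6) N demand, uptake, NNI and realised growth
    demand = config.n_crit * dm_pot
    uptake = n_uptake(stand, soil, demand, config)
    stand.cum_nupt += uptake
    with np.errstate(invalid="ignore", divide="ignore"):
        nni = np.where(demand > 0, np.minimum(1.0, uptake / demand), 1.0)
    stand.nni = nni
    dm = dm_pot * nni * dev_mult
    stand.produced += dm

    # (7) allocation to shoot / root / reserve (+ reserve remobilisation
    # in the days following sowing or a cut)
    d_reserve = dm * config.reserve_fraction
    rem = dm - d_reserve
    span = config.shoot_frac_max - config.shoot_frac_min
    f_shoot = np.clip(
        config.shoot_frac_min + span * (nni - 0.5) / 0.5,
        config.shoot_frac_min,
        config.shoot_frac_max,
    )
    d_shoot = rem * f_shoot
    d_root = rem - d_shoot
    stand.reserve += d_reserve
    if days_since_cut < config.remobilisation_days:
        mobilised = config.remobilisation_rate * stand.reserve * alive
        stand.reserve -= mobilised
        d_shoot = d_shoot + mobilised
    stand.shoot += d_shoot
    stand.root += d_root
    d_leaf_area = np.minimum(
        stand.pot_leaf_area, config.sla * config.leaf_fraction * d_shoot
    )
    stand.leaf_area += d_leaf_area
    stand.pot_leaf_area -= d_leaf_area
    # stem extension per unit carbon scales with internode length: long-
    # internode genotypes gain more height per gram even when carbon binds
    in_rel = stand.trait("L_max_In") / DEFAULT_MU["L_max_In"]
    d_height = np.minimum(
        stand.pot_height, config.height_per_gram * in_rel * d_shoot
    )
    stand.height += d_height
    stand.pot_height -= d_height

    # (8) maintenance respiration (temperature-scaled): drawn from reserves
    # first, then shoot, then root.  Plants whose interception cannot cover
    # maintenance shrink -- the light compensation point that lets sustained
    # suppression become mortality.
    resp = config.maintenance_resp * (env.t_eff[day] / 10.0) * (
        stand.shoot + stand.root
    ) * alive
    from_reserve = np.minimum(stand.reserve, resp)
    stand.reserve -= from_reserve
    deficit = resp - from_reserve
    from_shoot = np.minimum(stand.shoot, deficit)
    stand.shoot -= from_shoot
    deficit -= from_shoot
    from_root = np.minimum(stand.root, deficit)
    stand.root -= from_root
    stand.respired += from_reserve + from_shoot + from_root

    # (9) leaf senescence
    stand.leaf_area *= np.where(alive, 1.0 - config.senescence_rate, 1.0)

    return {
        "pari_total": float(pari.sum()),
        "par_incident": float(env.par[day] * config.domain_area),
        "uptake_total": float(uptake.sum()),
    }


def harvest(stand: Stand, config: SimConfig) -> dict:
    """Cut living shoots back to the residual fraction.

    Removed shoot mass is credited per species; dead plants contribute
    nothing and keep their frozen state.  Reserves and roots are untouched.
    """
    rf = config.residual_fraction
    removed = np.where(stand.alive, stand.shoot * (1.0 - rf), 0.0)
    keep = np.where(stand.alive, rf, 1.0)
    stand.shoot = stand.shoot * keep
    stand.leaf_area = stand.leaf_area * keep
    stand.pot_leaf_area = stand.pot_leaf_area * keep
    stand.height = stand.height * keep
    stand.pot_height = stand.pot_height * keep
    stand.harvested += removed
    out = {}
    for sp in (1, 2):
        out[sp] = float(removed[stand.species == sp].sum())
    return out


def _apply_mortality(stand: Stand, config: SimConfig) -> int:
    """Kill plants far below the living population's mean shoot mass."""
    alive = stand.alive
    if not alive.any():
        return 0
    mean_shoot = stand.shoot[alive].mean()
    dying = alive & (stand.shoot < config.mortality_threshold * mean_shoot)
    if dying.any():
        stand.alive = alive & ~dying
        stand.leaf_area = np.where(dying, 0.0, stand.leaf_area)
        stand.pot_leaf_area = np.where(dying, 0.0, stand.pot_leaf_area)
    return int(dying.sum())


def plant_table(stand: Stand) -> pd.DataFrame:
    """Final per-plant table (genotype, position, resource capture, fate)."""
    df = pd.DataFrame(
        {
            "plant_id": np.arange(stand.n),
            "species": stand.species.astype(int),
            "row": stand.row,
            "col": stand.col,
        }
    )
    for j, name in enumerate(stand.trait_names):
        df[name] = stand.traits[:, j]
    df["p_score"] = stand.p_score
    df["final_biomass_g"] = stand.shoot + stand.root + stand.reserve
    df["production_g"] = stand.harvested
    df["cum_pari_MJ"] = stand.cum_pari
    df["cum_nupt_gN"] = stand.cum_nupt
    df["alive"] = stand.alive
    return df


def run_season(design: CommunityDesign, config: SimConfig | None = None) -> RunResult:
    """Simulate one full season of one design; deterministic given its seed.

    Steps every day, harvests at the scheduled days, applies the mortality
    rule a fixed delay after each harvest, and returns the final plant
    table, annual per-species partial yields (g m^-2) and conservation
    diagnostics (soil-N balance, light interception vs incidence, biomass
    accounting).
    """
    config = config or SimConfig()
    env = make_environment(design.environment, config)
    hdays = set(config.harvest_days)
    if any(h >= config.season_length for h in hdays):
        raise ValueError("harvest days must fall within the season")
    mort_days = {h + config.mortality_delay for h in config.harvest_days}
    stand, soil = init_stand(design, config)
    initial_mass = float((stand.shoot + stand.root + stand.reserve).sum())

    yields = {1: 0.0, 2: 0.0}
    harvest_log = []
    par_excess = 0.0
    last_cut = 0
    for day in range(config.season_length):
        diag = step_day(stand, soil, env, day, config, day - last_cut)
        if diag["par_incident"] > 0:
            par_excess = max(
                par_excess,
                (diag["pari_total"] - diag["par_incident"]) / diag["par_incident"],
            )
        if day in hdays:
            cut = harvest(stand, config)
            for sp in (1, 2):
                yields[sp] += cut[sp] / config.domain_area
            last_cut = day
            survivors = int(stand.alive.sum())
            harvest_log.append((day, {sp: cut[sp] / config.domain_area for sp in (1, 2)}, survivors))
            logger.info(
                "harvest day %d: Sp1 %.1f g/m2, Sp2 %.1f g/m2, %d survivors",
                day,
                cut[1] / config.domain_area,
                cut[2] / config.domain_area,
                survivors,
            )
        if day in mort_days:
            _apply_mortality(stand, config)

    final_mass = float((stand.shoot + stand.root + stand.reserve).sum())
    produced = float(stand.produced.sum())
    respired = float(stand.respired.sum())
    harvested = float(stand.harvested.sum())
    mass_scale = max(initial_mass + produced, 1e-12)
    diagnostics = {
        "n_balance_rel_err": soil.balance_error(),
        "par_excess_max": par_excess,
        "mass_balance_rel_err": abs(
            final_mass + harvested - (initial_mass + produced - respired)
        )
        / mass_scale,
        "survivors": int(stand.alive.sum()),
    }
    return RunResult(
        design=design,
        plants=plant_table(stand),
        yields=yields,
        harvest_log=harvest_log,
        diagnostics=diagnostics,
    )
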