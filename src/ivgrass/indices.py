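"""Community-, population- and plant-level indices of mixture performance.

Community level: total annual yield (Ytot), the species-2 biomass proportion
under 50/50 sowing (p50s), overyielding relative to the pure-stand average
(OY) and its Loreau-Hector additive partition into a complementarity effect
(CE, driven by the mean deviation of relative yields from the substitutive
0.5 expectation) and a selection effect (SE, the covariance between those
deviations and pure-stand yields).  The stabilising effect of intraspecific
variation (S_IV) compares the p50s drift of a community with and without
within-species variance.

Population level: the Gini coefficient of surviving individuals' biomass
(size inequality / competition asymmetry) and D5_param, the share of a
species' annual production contributed by the half of its sown individuals
with the highest values of one trait (0.5 = no within-species selection on
that trait).

Plant level: variances of the mean resource capture (cumulative intercepted
PAR or N uptake) of each plant's first-order kin and non-kin neighbours, an
index of the spatial heterogeneity of competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "YieldRecord",
    "overyielding",
    "complementarity_selection",
    "p50s",
    "stabilising_effect",
    "gini",
    "d5",
    "local_partition_variance",
    "compute_run_summary",
]

RESOURCE_COLUMNS = {"PARi": "cum_pari_MJ", "Nupt": "cum_nupt_gN"}


@dataclass(frozen=True)
class YieldRecord:
    """Annual partial yields of a binary mixture and its two pure stands.

    ``yp1``/``yp2`` are the partial yields of species 1 and 2 in mixture,
    ``ypur1``/``ypur2`` the pure-stand annual yields, all in g m^-2.
    """

    yp1: float
    yp2: float
    ypur1: float
    ypur2: float

    def __post_init__(self):
        for name in ("yp1", "yp2", "ypur1", "ypur2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def ytot(self) -> float:
        return self.yp1 + self.yp2


def overyielding(record: YieldRecord) -> float:
    """OY = Ytot - (Ypur1 + Ypur2) / 2."""
    return record.ytot - (record.ypur1 + record.ypur2) / 2.0


def complementarity_selection(record: YieldRecord) -> tuple:
    """Loreau-Hector additive partition of overyielding, (CE, SE).

    With relative yields RY_i = Yp_i / Ypur_i and their deviation
    dRY_i = RY_i - 0.5 from the 50/50 substitutive expectation:
    CE = 2 * mean(dRY) * mean(Ypur) and SE = 2 * Cov(dRY, Ypur), using the
    population (1/n) covariance so that CE + SE = OY exactly at n = 2.
    """
    if record.ypur1 <= 0 or record.ypur2 <= 0:
        raise ValueError(
            "complementarity/selection effects undefined: pure-stand yields "
            f"must be positive (got {record.ypur1}, {record.ypur2})"
        )
    ypur = np.array([record.ypur1, record.ypur2])
    dry = np.array([record.yp1, record.yp2]) / ypur - 0.5
    ce = 2.0 * dry.mean() * ypur.mean()
    se = 2.0 * float(np.mean(dry * ypur) - dry.mean() * ypur.mean())
    return float(ce), float(se)


def p50s(yp2: float, ytot: float) -> float:
    """Species-2 share of total annual mixture yield; 0.5 = stable mixture."""
    if ytot <= 0:
        raise ValueError("p50s undefined for non-positive total yield")
    return float(yp2) / float(ytot)


def stabilising_effect(p50s_low: float, p50s_high: float) -> float:
    """Signed stabilisation of species balance by intraspecific variation.

    Taking the low-IV run as the reference: positive values mean the
    high-IV community ends closer to the 50/50 sowing proportion, from the
    low-IV side; negative values mean a greater shift.  Antisymmetric under
    swapping the two arguments when both lie on the same side of 0.5.
    """
    for v in (p50s_low, p50s_high):
        if not 0.0 <= v <= 1.0:
            raise ValueError("p50s values must lie in [0, 1]")
    if p50s_low >= 0.5:
        return (p50s_low - 0.5) - (p50s_high - 0.5)
    return (0.5 - p50s_low) - (0.5 - p50s_high)


def gini(biomasses) -> float:
    """Gini coefficient of a biomass vector (pairwise mean difference form).

    G = sum_ij |x_i - x_j| / (2 n^2 xbar), over surviving individuals.
    0 = perfectly even sharing; (n-1)/n = one individual holds everything.
    Scale-invariant.  Computed via the sorted-vector identity, O(n log n).
    """
    x = np.asarray(biomasses, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("gini needs a 1-D vector of at least 2 individuals")
    if np.any(x < 0):
        raise ValueError("biomasses must be non-negative")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("gini undefined for an all-zero biomass vector")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * xs) / (n * n * mean))


def d5(param_values, biomasses, yp: float, plant_ids=None) -> float:
    """Share of a species' production from the top half by one trait value.

    The initial sown population (dead individuals included, with their
    frozen realised biomass) is ranked by the trait, descending, ties broken
    by ascending plant id; the top ceil(n/2) individuals' biomass summed and
    divided by the species' partial yield ``yp``.  0.5 = no within-species
    selection on the trait; above = positive selection of high values.
    """
    p = np.asarray(param_values, dtype=float)
    x = np.asarray(biomasses, dtype=float)
    if p.shape != x.shape or p.ndim != 1:
        raise ValueError("param_values and biomasses must be aligned 1-D vectors")
    if yp <= 0:
        raise ValueError("d5 undefined for non-positive partial yield")
    ids = np.arange(p.size) if plant_ids is None else np.asarray(plant_ids)
    order = np.lexsort((ids, -p))  # trait descending, id ascending
    k = (p.size + 1) // 2
    return float(x[order[:k]].sum() / yp)


def _neighbour_class_means(
    table: pd.DataFrame, resource_col: str
) -> tuple:
    """Per-focal mean resource of living kin / non-kin Moore neighbours.

    Returns (kin_means, nonkin_means, focal_species) arrays over living
    focal plants, NaN where a focal has no living neighbour of that class.
    The lattice is toroidal; its shape is inferred from the row/col columns.
    """
    rows = int(table["row"].max()) + 1
    cols = int(table["col"].max()) + 1
    if len(table) != rows * cols:
        raise ValueError("plant table does not cover a full lattice")
    idx = (table["row"].to_numpy() * cols + table["col"].to_numpy()).astype(int)
    shape = (rows, cols)
    sp = np.empty(shape)
    res = np.empty(shape)
    alive = np.zeros(shape, dtype=bool)
    sp.ravel()[idx] = table["species"].to_numpy()
    res.ravel()[idx] = table[resource_col].to_numpy()
    alive.ravel()[idx] = table["alive"].to_numpy().astype(bool)

    kin_sum = np.zeros(shape)
    kin_n = np.zeros(shape)
    non_sum = np.zeros(shape)
    non_n = np.zeros(shape)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb_sp = np.roll(np.roll(sp, dr, axis=0), dc, axis=1)
            nb_res = np.roll(np.roll(res, dr, axis=0), dc, axis=1)
            nb_alive = np.roll(np.roll(alive, dr, axis=0), dc, axis=1)
            kin = nb_alive & (nb_sp == sp)
            non = nb_alive & (nb_sp != sp)
            kin_sum += np.where(kin, nb_res, 0.0)
            kin_n += kin
            non_sum += np.where(non, nb_res, 0.0)
            non_n += non
    with np.errstate(invalid="ignore", divide="ignore"):
        kin_mean = np.where(kin_n > 0, kin_sum / kin_n, np.nan)
        non_mean = np.where(non_n > 0, non_sum / non_n, np.nan)
    return kin_mean[alive], non_mean[alive], sp[alive]


def _pooled_within_species_variance(values: np.ndarray, species: np.ndarray) -> float:
    """Variance of local means pooled within focal species.

    Pooling within species removes the between-species offset in mean
    resource capture, so the index reflects genuine spatial heterogeneity
    (a two-phase mosaic where every plant of a species sees the same class
    mean scores zero).  Pooled sum of squares divided by (n - k) with k the
    number of represented species; NaN entries (no neighbour of the class)
    are dropped.
    """
    mask = ~np.isnan(values)
    values, species = values[mask], species[mask]
    if values.size < 2:
        return float("nan")
    ss = 0.0
    groups = 0
    for sp in np.unique(species):
        v = values[species == sp]
        if v.size:
            ss += float(((v - v.mean()) ** 2).sum())
            groups += 1
    dof = values.size - groups
    return ss / dof if dof > 0 else float("nan")


def local_partition_variance(
    table: pd.DataFrame, resource: str = "PARi", mode: str = "focal_mean"
) -> tuple:
    """Spatial heterogeneity of local resource partitioning, (kin, non-kin).

    ``focal_mean`` (default): for each living focal plant, average the
    cumulative resource of its living first-order (Moore) kin and non-kin
    neighbours, then take the variance of those local means across focal
    plants with at least one neighbour of the class, pooled within focal
    species (see :func:`_pooled_within_species_variance`).  ``pairwise``:
    the same pooling applied to the raw per-neighbour values over all
    (focal, neighbour) pairs.  A class with no qualifying focal (e.g.
    non-kin in a pure stand) is reported as NaN, not zero.
    """
    if resource not in RESOURCE_COLUMNS:
        raise ValueError(f"resource must be one of {sorted(RESOURCE_COLUMNS)}")
    if mode not in ("focal_mean", "pairwise"):
        raise ValueError("mode must be 'focal_mean' or 'pairwise'")
    col = RESOURCE_COLUMNS[resource]
    if mode == "focal_mean":
        kin, non, focal_sp = _neighbour_class_means(table, col)
        return (
            _pooled_within_species_variance(kin, focal_sp),
            _pooled_within_species_variance(non, focal_sp),
        )
    kin_vals, kin_sp, non_vals, non_sp = _neighbour_pairs(table, col)
    return (
        _pooled_within_species_variance(kin_vals, kin_sp),
        _pooled_within_species_variance(non_vals, non_sp),
    )


def _neighbour_pairs(table: pd.DataFrame, resource_col: str) -> tuple:
    rows = int(table["row"].max()) + 1
    cols = int(table["col"].max()) + 1
    idx = (table["row"].to_numpy() * cols + table["col"].to_numpy()).astype(int)
    shape = (rows, cols)
    sp = np.empty(shape)
    res = np.empty(shape)
    alive = np.zeros(shape, dtype=bool)
    sp.ravel()[idx] = table["species"].to_numpy()
    res.ravel()[idx] = table[resource_col].to_numpy()
    alive.ravel()[idx] = table["alive"].to_numpy().astype(bool)
    kin_vals, kin_sp, non_vals, non_sp = [], [], [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb_sp = np.roll(np.roll(sp, dr, axis=0), dc, axis=1)
            nb_res = np.roll(np.roll(res, dr, axis=0), dc, axis=1)
            nb_alive = np.roll(np.roll(alive, dr, axis=0), dc, axis=1)
            pair = alive & nb_alive
            kin = pair & (nb_sp == sp)
            non = pair & (nb_sp != sp)
            kin_vals.append(nb_res[kin])
            kin_sp.append(sp[kin])
            non_vals.append(nb_res[non])
            non_sp.append(sp[non])
    return (
        np.concatenate(kin_vals),
        np.concatenate(kin_sp),
        np.concatenate(non_vals),
        np.concatenate(non_sp),
    )


def _species_correlation(sub: pd.DataFrame) -> float:
    """Pearson correlation of realised production with the genetic p_score."""
    live = sub[sub["alive"].astype(bool)]
    if len(live) < 3:
        return float("nan")
    x = live["production_g"].to_numpy()
    y = live["p_score"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compute_run_summary(
    plants: pd.DataFrame,
    yields: dict,
    trait_names,
    ypur1: float | None = None,
    ypur2: float | None = None,
    partition_mode: str = "focal_mean",
) -> dict:
    """Assemble the full per-run index row from a plant table and yields.

    ``yields`` maps species -> annual partial yield (g m^-2).  Pure-stand
    reference yields enable the OY/CE/SE block; otherwise those entries are
    NaN.  Per-plant ``production_g`` (annual harvested mass) is the biomass
    measure for Gini (survivors) and D5 (all sown individuals).
    """
    yp1, yp2 = float(yields.get(1, 0.0)), float(yields.get(2, 0.0))
    ytot = yp1 + yp2
    out = {"yp1": yp1, "yp2": yp2, "ytot": ytot}
    out["p50s"] = p50s(yp2, ytot) if ytot > 0 else float("nan")
    if ypur1 is not None and ypur2 is not None and ypur1 > 0 and ypur2 > 0:
        record = YieldRecord(yp1=yp1, yp2=yp2, ypur1=ypur1, ypur2=ypur2)
        out["oy"] = overyielding(record)
        out["ce"], out["se"] = complementarity_selection(record)
    else:
        out["oy"] = out["ce"] = out["se"] = float("nan")

    for sp in (1, 2):
        sub = plants[plants["species"] == sp]
        live = sub[sub["alive"].astype(bool)]
        key = f"gini_sp{sp}"
        if len(live) >= 2 and live["production_g"].sum() > 0:
            out[key] = gini(live["production_g"].to_numpy())
        else:
            out[key] = float("nan")
        # per-plant production is in g while partial yields are g m^-2;
        # the species' summed per-plant production is the same total, so
        # using it as the D5 denominator keeps the ratio unit-free.
        total_sp = sub["production_g"].sum()
        for name in trait_names:
            dkey = f"d5_sp{sp}_{name}"
            if len(sub) and total_sp > 0:
                out[dkey] = d5(
                    sub[name].to_numpy(),
                    sub["production_g"].to_numpy(),
                    float(total_sp),
                    plant_ids=sub["plant_id"].to_numpy(),
                )
            else:
                out[dkey] = float("nan")
        out[f"pscore_biomass_r_sp{sp}"] = (
            _species_correlation(sub) if len(sub) else float("nan")
        )
        out[f"survivors_sp{sp}"] = int(sub["alive"].astype(bool).sum())

    for resource, prefix in (("PARi", "pari"), ("Nupt", "nupt")):
        vk, vn = local_partition_variance(plants, resource, mode=partition_mode)
        out[f"var_{prefix}_kin"] = vk
        out[f"var_{prefix}_nonkin"] = vn
    return out
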