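"""Within-population quantitative-trait distributions.

A cultivar (or species) population is summarised by a :class:`TraitSpec`:
per-trait population means ``mu``, a coefficient-of-variation vector ``cv``
(sigma/mu, dimensionless), a pairwise correlation matrix ``mc`` and a sign
vector giving the direction in which larger trait values improve resource
acquisition.  Individual genotypes are single draws from the implied
multivariate normal distribution

    M = outer(mu * cv, mu * cv) * mc

taken once at sowing and kept for life.  Each individual can be summarised by
a dimensionless ``p_score``, the sign-adjusted mean of its standardised trait
values: positive scores mark individuals whose genotype favours resource
acquisition relative to the population average.

The default trait set contains six parameters of a forage-plant growth model,
three acting mainly on light acquisition (maximal leaf length ``L_max_L``,
maximal internode length ``L_max_In``, phyllochron ``Phyllo_1``) and three on
mineral-N acquisition (root uptake capacity ``Vmax_2``, root elongation rate
``EL_max_R``, photoperiod threshold for autumn slowdown ``PPtresh_H``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "Genotype",
    "build_covariance",
    "sample_population",
    "p_score",
    "population_table",
    "LIGHT_TRAITS",
    "NITROGEN_TRAITS",
    "DEFAULT_TRAIT_NAMES",
    "CV_LEVELS",
]

#: Traits whose main effect is on light capture.
LIGHT_TRAITS = ("L_max_L", "L_max_In", "Phyllo_1")
#: Traits whose main effect is on soil mineral-N capture.
NITROGEN_TRAITS = ("Vmax_2", "EL_max_R", "PPtresh_H")
DEFAULT_TRAIT_NAMES = LIGHT_TRAITS + NITROGEN_TRAITS

#: Default population means.  Units: leaf / internode lengths in cm,
#: phyllochron in degree-days, Vmax_2 in g N (g root)^-1 day^-1, root
#: colonisation rate in cm day^-1, photoperiod threshold in hours.
DEFAULT_MU = {
    "L_max_L": 10.0,
    "L_max_In": 3.0,
    "Phyllo_1": 40.0,
    "Vmax_2": 0.05,
    "EL_max_R": 2.0,
    "PPtresh_H": 11.5,
}

#: Direction in which a larger value improves resource acquisition: faster
#: phytomer production means a *smaller* phyllochron, and a *lower*
#: photoperiod threshold delays the autumn slowdown, hence their -1 signs.
DEFAULT_SIGNS = {
    "L_max_L": 1,
    "L_max_In": 1,
    "Phyllo_1": -1,
    "Vmax_2": 1,
    "EL_max_R": 1,
    "PPtresh_H": -1,
}

#: The three intraspecific-variation levels used throughout the virtual
#: experiment (very low, moderate, high coefficient of variation).
CV_LEVELS = (0.001, 0.15, 0.30)

#: Eigenvalues of the correlation matrix above this (negative) tolerance are
#: treated as zero; anything below is a hard error.
PSD_TOL = 1e-10

#: Multivariate draws with any component at or below this fraction of its
#: mean are rejected and redrawn (trait values are physical lengths/rates).
TRUNCATION_FLOOR = 0.01


@dataclass(frozen=True)
class TraitSpec:
    """Genetic blueprint of one species' population.

    Parameters
    ----------
    names : tuple of str
        Ordered trait identifiers.
    mu : ndarray
        Population mean per trait (strictly positive, trait units).
    signs : ndarray
        Per-trait direction (+1/-1) of the resource-acquisition benefit of
        increasing values.
    cv : ndarray
        Coefficient of variation (sigma/mu) per trait, non-negative.
    mc : ndarray
        Pairwise trait correlation matrix; symmetric, unit diagonal,
        positive semi-definite.
    """

    names: tuple
    mu: np.ndarray
    signs: np.ndarray
    cv: np.ndarray
    mc: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        for attr in ("mu", "signs", "cv", "mc"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, attr, arr)
        k = len(self.names)
        if not (self.mu.shape == self.signs.shape == self.cv.shape == (k,)):
            raise ValueError(
                f"names/mu/signs/cv must all have length {k}; got shapes "
                f"{self.mu.shape}, {self.signs.shape}, {self.cv.shape}"
            )
        if self.mc.shape != (k, k):
            raise ValueError(f"mc must be {k}x{k}, got {self.mc.shape}")
        if not np.all(self.mu > 0):
            raise ValueError("trait means mu must be strictly positive")
        if not np.all(self.cv >= 0):
            raise ValueError("cv values must be non-negative")
        if not np.all(np.isin(self.signs, (-1.0, 1.0))):
            raise ValueError("signs must be +1 or -1")
        if not np.allclose(self.mc, self.mc.T, atol=1e-12):
            raise ValueError("mc must be symmetric")
        if not np.allclose(np.diag(self.mc), 1.0, atol=1e-12):
            raise ValueError("mc must have a unit diagonal")
        if np.any(np.abs(self.mc) > 1 + 1e-12):
            raise ValueError("mc entries must lie in [-1, 1]")
        wmin = float(np.linalg.eigvalsh(self.mc).min())
        if wmin < -PSD_TOL:
            raise ValueError(
                "correlation matrix mc is not positive semi-definite: "
                f"smallest eigenvalue {wmin:.3e} < -{PSD_TOL:.0e}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_traits(self) -> int:
        return len(self.names)

    @property
    def sigma(self) -> np.ndarray:
        """Per-trait standard deviation mu * cv."""
        return self.mu * self.cv

    def index(self, name: str) -> int:
        return self.names.index(name)

    def replace(self, **changes) -> "TraitSpec":
        return dataclasses.replace(self, **changes)

    @classmethod
    def default(cls, cv: float = 0.15, mc: np.ndarray | None = None) -> "TraitSpec":
        """The reference six-trait forage population at a uniform CV level."""
        names = DEFAULT_TRAIT_NAMES
        k = len(names)
        return cls(
            names=names,
            mu=np.array([DEFAULT_MU[n] for n in names]),
            signs=np.array([DEFAULT_SIGNS[n] for n in names], dtype=float),
            cv=np.full(k, float(cv)),
            mc=np.eye(k) if mc is None else np.asarray(mc, dtype=float),
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mu": self.mu.tolist(),
            "signs": self.signs.tolist(),
            "cv": self.cv.tolist(),
            "mc": self.mc.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitSpec":
        return cls(
            names=tuple(d["names"]),
            mu=np.asarray(d["mu"], dtype=float),
            signs=np.asarray(d["signs"], dtype=float),
            cv=np.asarray(d["cv"], dtype=float),
            mc=np.asarray(d["mc"], dtype=float),
        )


@dataclass(frozen=True)
class Genotype:
    """One individual's trait-value vector and its population score."""

    values: np.ndarray
    p_score: float


def build_covariance(spec: TraitSpec) -> np.ndarray:
    """Covariance matrix implied by (mu, cv, mc).

    ``M[i, j] = (mu_i * cv_i) * (mu_j * cv_j) * mc[i, j]``.  The result is
    symmetric positive semi-definite whenever ``mc`` is (the TraitSpec
    constructor enforces that, naming the offending eigenvalue otherwise).
    """
    sigma = spec.sigma
    m = np.outer(sigma, sigma) * spec.mc
    return 0.5 * (m + m.T)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_population(spec: TraitSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` genotypes; returns an (n, n_traits) array.

    All parameters of an individual are drawn simultaneously from the
    multivariate normal N(mu, M) with M from :func:`build_covariance`.
    Vectors containing any component at or below ``TRUNCATION_FLOOR * mu``
    are rejected and redrawn whole, so returned trait values are strictly
    positive.  Deterministic given (spec, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    cov = build_covariance(spec)
    floor = TRUNCATION_FLOOR * spec.mu
    draws = rng.multivariate_normal(spec.mu, cov, size=n, method="eigh")
    for _ in range(1000):
        bad = np.flatnonzero((draws <= floor).any(axis=1))
        if bad.size == 0:
            return draws
        draws[bad] = rng.multivariate_normal(
            spec.mu, cov, size=bad.size, method="eigh"
        )
    raise RuntimeError(
        "could not draw all-positive genotypes; cv values are too large "
        "for the positivity floor"
    )


def sample_genotypes(spec: TraitSpec, n: int, seed) -> list:
    """Like :func:`sample_population` but as a list of :class:`Genotype`."""
    values = sample_population(spec, n, seed)
    scores = p_score(values, spec)
    return [Genotype(values=v, p_score=float(s)) for v, s in zip(values, scores)]


def p_score(values: np.ndarray, spec: TraitSpec, names=None) -> np.ndarray:
    """Sign-adjusted mean of standardised trait values.

    ``p_score = mean_n( S_n * (P_n - mu_n) / sigma_n )`` over the scored
    traits.  ``values`` may be a single genotype vector or an (n, k) array.
    Traits with zero sigma cannot be standardised and raise.
    """
    values = np.asarray(values, dtype=float)
    if names is None:
        idx = np.arange(spec.n_traits)
    else:
        idx = np.array([spec.index(n) for n in names])
    sigma = spec.sigma[idx]
    if np.any(sigma == 0):
        zero = [spec.names[i] for i in idx[sigma == 0]]
        raise ValueError(
            f"p_score undefined: traits {zero} have zero sigma (mu*cv)"
        )
    z = spec.signs[idx] * (values[..., idx] - spec.mu[idx]) / sigma
    return z.mean(axis=-1)


def population_table(
    spec: TraitSpec, n: int, seed, species: int = 1, start_id: int = 0
) -> pd.DataFrame:
    """Genotype table: plant_id, species, one column per trait, p_score."""
    values = sample_population(spec, n, seed)
    df = pd.DataFrame(values, columns=list(spec.names))
    df.insert(0, "species", species)
    df.insert(0, "plant_id", np.arange(start_id, start_id + n))
    df["p_score"] = p_score(values, spec)
    return df
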