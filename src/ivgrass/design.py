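"""Enumeration of the virtual competition experiment.

Binary communities pair a reference species (Sp1) with a second species (Sp2)
derived from it by shifting the means of one or more traits along a signed
divergence gradient (delta).  Nine diverging trait sets (six single-trait T1
variants, the three light traits T3L, the three nitrogen traits T3N, and the
six-trait trade-off T6) crossed with seven delta levels give the 63
communities of the full design, each run at three intraspecific-variation
(CV) levels, in two nitrogen environments, with seeded replicates, plus the
pure stands needed for overyielding partitioning.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import (
    CV_LEVELS,
    LIGHT_TRAITS,
    NITROGEN_TRAITS,
    TraitSpec,
)

__all__ = [
    "CommunityDesign",
    "TRAIT_SETS",
    "DELTA_GRID",
    "DELTA_UNIT",
    "ENVIRONMENTS",
    "make_species2",
    "enumerate_experiment",
    "design_table",
    "derive_seed",
    "pure_stand_key",
]

#: Seven signed levels of mean trait divergence between the two species.
DELTA_GRID = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)

#: One delta step shifts a trait mean by this relative amount (the moderate
#: CV), sign-adjusted so positive delta favours Sp2's resource acquisition.
DELTA_UNIT = 0.15

ENVIRONMENTS = ("0N", "N+")

#: The nine diverging trait sets of the full design.
TRAIT_SETS = {
    **{f"T1_{name}": (name,) for name in LIGHT_TRAITS + NITROGEN_TRAITS},
    "T3L": LIGHT_TRAITS,
    "T3N": NITROGEN_TRAITS,
    "T6": LIGHT_TRAITS + NITROGEN_TRAITS,
}


@dataclass(frozen=True)
class CommunityDesign:
    """One simulated run: a community x CV level x environment x replicate.

    ``pure_species`` is 0 for a 50/50 binary mixture, or 1/2 for the pure
    stand of the corresponding species (pure stands are simulated at the
    same CV level and environment as the mixtures they serve).
    """

    community_id: str
    trait_set: str
    delta: float
    spec_sp1: TraitSpec
    spec_sp2: TraitSpec
    cv_level: float
    environment: str
    replicate: int
    seed: int
    pure_species: int = 0

    def __post_init__(self):
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.pure_species not in (0, 1, 2):
            raise ValueError("pure_species must be 0, 1 or 2")


def make_species2(
    spec_sp1: TraitSpec,
    delta: float,
    trait_set: str,
    delta_unit: float = DELTA_UNIT,
) -> TraitSpec:
    """Derive Sp2 from Sp1 by shifting the means of the diverging traits.

    For each trait t in the set, ``mu2(t) = mu1(t) * (1 + S_t * d * delta_unit)``
    where d = delta, except for the nitrogen traits of the T6 trade-off set
    where d = -delta (positive delta then improves light acquisition at the
    cost of N acquisition).  CV vector and correlation matrix are copied.
    """
    if trait_set not in TRAIT_SETS:
        raise ValueError(
            f"unknown trait set {trait_set!r}; expected one of {sorted(TRAIT_SETS)}"
        )
    members = TRAIT_SETS[trait_set]
    mu2 = spec_sp1.mu.copy()
    for name in members:
        i = spec_sp1.index(name)
        d = float(delta)
        if trait_set == "T6" and name in NITROGEN_TRAITS:
            d = -d
        mu2[i] = spec_sp1.mu[i] * (1.0 + spec_sp1.signs[i] * d * delta_unit)
    if np.any(mu2 <= 0):
        bad = [spec_sp1.names[i] for i in np.flatnonzero(mu2 <= 0)]
        raise ValueError(f"delta={delta} drives mean(s) of {bad} non-positive")
    return spec_sp1.replace(mu=mu2)


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-run seed from the master seed and design coordinates.

    Hash-based, so replicate r of one design is unaffected by adding or
    removing other designs from the enumeration.  Kept below 2**31.
    """
    key = "|".join([str(int(master_seed))] + [str(p) for p in parts])
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF


def community_id(trait_set: str, delta: float) -> str:
    return f"{trait_set}_d{delta:+.2f}"


def pure_stand_key(trait_set: str, delta: float) -> str:
    """Identifier of the pure stand serving a mixture's Sp2.

    At delta = 0 Sp2 equals Sp1 exactly, so the Sp1 pure stand serves as
    its own reference.
    """
    if delta == 0:
        return "pure_Sp1"
    return f"pure_{community_id(trait_set, delta)}"


def enumerate_experiment(
    master_seed: int = 0,
    base_spec: TraitSpec | None = None,
    trait_sets=None,
    deltas=DELTA_GRID,
    cv_levels=CV_LEVELS,
    environments=ENVIRONMENTS,
    replicates: int = 9,
    delta_unit: float = DELTA_UNIT,
    include_pure: bool = True,
) -> list:
    """Enumerate every run of the (possibly restricted) virtual experiment.

    The default full design yields 9 trait-set variants x 7 delta levels
    = 63 communities, crossed with 3 CV levels x 2 environments x
    ``replicates`` replicates, plus the Sp1 pure stand and one pure stand
    per distinct Sp2 under matching conditions.  Each design carries a
    unique deterministic seed derived from ``master_seed``.
    """
    if replicates < 1:
        raise ValueError("replicate count must be >= 1")
    if trait_sets is None:
        trait_sets = tuple(TRAIT_SETS)
    for ts in trait_sets:
        if ts not in TRAIT_SETS:
            raise ValueError(f"unknown trait set {ts!r}")

    designs: list[CommunityDesign] = []
    pure_specs: dict[str, tuple[str, float, TraitSpec]] = {}

    for ts in trait_sets:
        for delta in deltas:
            cid = community_id(ts, delta)
            for cv in cv_levels:
                sp1 = TraitSpec.default(cv=cv) if base_spec is None else base_spec.replace(
                    cv=np.full(base_spec.n_traits, float(cv))
                )
                sp2 = make_species2(sp1, delta, ts, delta_unit=delta_unit)
                for env in environments:
                    for rep in range(1, replicates + 1):
                        designs.append(
                            CommunityDesign(
                                community_id=cid,
                                trait_set=ts,
                                delta=float(delta),
                                spec_sp1=sp1,
                                spec_sp2=sp2,
                                cv_level=float(cv),
                                environment=env,
                                replicate=rep,
                                seed=derive_seed(master_seed, cid, cv, env, rep, "mix"),
                            )
                        )
            if include_pure and delta != 0:
                pure_specs.setdefault(pure_stand_key(ts, delta), (ts, float(delta), None))

    if include_pure:
        # Sp1 pure stand (also serves every delta=0 Sp2) ...
        for cv in cv_levels:
            sp1 = TraitSpec.default(cv=cv) if base_spec is None else base_spec.replace(
                cv=np.full(base_spec.n_traits, float(cv))
            )
            for env in environments:
                for rep in range(1, replicates + 1):
                    designs.append(
                        CommunityDesign(
                            community_id="pure_Sp1",
                            trait_set="pure",
                            delta=0.0,
                            spec_sp1=sp1,
                            spec_sp2=sp1,
                            cv_level=float(cv),
                            environment=env,
                            replicate=rep,
                            seed=derive_seed(master_seed, "pure_Sp1", cv, env, rep, "pure"),
                            pure_species=1,
                        )
                    )
        # ... and one pure stand per distinct Sp2.
        for key, (ts, delta, _) in pure_specs.items():
            for cv in cv_levels:
                sp1 = TraitSpec.default(cv=cv) if base_spec is None else base_spec.replace(
                    cv=np.full(base_spec.n_traits, float(cv))
                )
                sp2 = make_species2(sp1, delta, ts, delta_unit=delta_unit)
                for env in environments:
                    for rep in range(1, replicates + 1):
                        designs.append(
                            CommunityDesign(
                                community_id=key,
                                trait_set=ts,
                                delta=delta,
                                spec_sp1=sp1,
                                spec_sp2=sp2,
                                cv_level=float(cv),
                                environment=env,
                                replicate=rep,
                                seed=derive_seed(master_seed, key, cv, env, rep, "pure"),
                                pure_species=2,
                            )
                        )
    return designs


def design_table(designs) -> pd.DataFrame:
    """Tabular view of an enumeration (one row per run)."""
    return pd.DataFrame(
        {
            "community_id": [d.community_id for d in designs],
            "trait_set": [d.trait_set for d in designs],
            "delta": [d.delta for d in designs],
            "cv_level": [d.cv_level for d in designs],
            "environment": [d.environment for d in designs],
            "replicate": [d.replicate for d in designs],
            "pure_species": [d.pure_species for d in designs],
            "seed": [d.seed for d in designs],
        }
    )
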