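"""Orchestration: design -> simulate -> indices -> compare across the grid.

``run_experiment`` executes an enumerated design (mixtures plus the pure
stands their overyielding partition needs), computes the per-run index
summary, pairs intraspecific-variation (IV) levels within each community x
environment x replicate cell to obtain the stabilising effect S_IV, and
returns tidy tables plus a manifest sufficient to reproduce any row.

Two pre-packaged campaigns back the package's headline checks:
``run_null_model_campaign`` (the delta = 0 slice, where species balance must
hover at 0.5) and ``run_direction_sweep`` (the scaled-down divergence x IV x
environment sweep behind the qualitative direction findings).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import (
    CV_LEVELS,
    DELTA_GRID,
    ENVIRONMENTS,
    TRAIT_SETS,
    design_table,
    enumerate_experiment,
    pure_stand_key,
)
from .indices import compute_run_summary, stabilising_effect
from .simulator import SimConfig, run_season

__all__ = [
    "ExperimentResult",
    "run_experiment",
    "summarise",
    "pair_stabilising_effect",
    "run_null_model_campaign",
    "run_direction_sweep",
]

logger = logging.getLogger(__name__)

#: Columns identifying a run within an experiment.
RUN_KEYS = [
    "community_id",
    "trait_set",
    "delta",
    "cv_level",
    "environment",
    "replicate",
    "pure_species",
    "seed",
]


@dataclass
class ExperimentResult:
    """Wide per-run table, long (run x index) table, S_IV pairs, manifest."""

    runs: pd.DataFrame
    long: pd.DataFrame
    s_iv: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(out / "runs.csv", index=False)
        self.long.to_csv(out / "runs_long.csv", index=False)
        self.s_iv.to_csv(out / "s_iv.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _run_one(design, sim_config):
    result = run_season(design, sim_config)
    row = {k: getattr(design, k) for k in RUN_KEYS}
    row["ypur_key"] = pure_stand_key(design.trait_set, design.delta) if not design.pure_species else ""
    summary = compute_run_summary(
        result.plants, result.yields, design.spec_sp1.names
    )
    row.update(summary)
    row.update({f"diag_{k}": v for k, v in result.diagnostics.items()})
    return row, result


def run_experiment(
    master_seed: int = 0,
    scale: float = 1.0,
    replicates: int | None = None,
    trait_sets=None,
    deltas=DELTA_GRID,
    cv_levels=CV_LEVELS,
    environments=ENVIRONMENTS,
    sim_config: SimConfig | None = None,
    include_pure: bool = True,
    out_dir=None,
) -> ExperimentResult:
    """Run the virtual experiment (or a slice of it) end to end.

    ``scale`` in (0, 1] shrinks the replicate count of the full 9-replicate
    campaign for desk-scale runs (the explicit ``replicates`` argument wins
    if given).  Runs that raise are logged, excluded, and counted in the
    manifest.  Deterministic given ``master_seed``.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    if replicates is None:
        replicates = max(1, round(9 * scale))
    sim_config = sim_config or SimConfig()
    designs = enumerate_experiment(
        master_seed=master_seed,
        trait_sets=trait_sets,
        deltas=deltas,
        cv_levels=cv_levels,
        environments=environments,
        replicates=replicates,
        include_pure=include_pure,
    )

    rows, failures = [], []
    pure_yields: dict = {}
    for design in designs:
        try:
            row, result = _run_one(design, sim_config)
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("run failed: %s", design.community_id)
            failures.append({"community_id": design.community_id, "seed": design.seed, "error": str(exc)})
            continue
        if design.pure_species:
            key = (design.community_id, design.cv_level, design.environment, design.replicate)
            pure_yields[key] = result.yields[design.pure_species]
        rows.append(row)
    runs = pd.DataFrame(rows)

    # attach pure-stand references and the OY / CE / SE block
    if include_pure and len(runs):
        from .indices import YieldRecord, complementarity_selection, overyielding

        mix = runs["pure_species"] == 0
        ypur1 = np.full(len(runs), np.nan)
        ypur2 = np.full(len(runs), np.nan)
        for i in runs.index[mix]:
            r = runs.loc[i]
            k1 = ("pure_Sp1", r["cv_level"], r["environment"], r["replicate"])
            k2 = (r["ypur_key"], r["cv_level"], r["environment"], r["replicate"])
            if r["ypur_key"] == "pure_Sp1":
                k2 = k1
            ypur1[i] = pure_yields.get(k1, np.nan)
            ypur2[i] = pure_yields.get(k2, np.nan)
        runs["ypur1"], runs["ypur2"] = ypur1, ypur2
        oy = np.full(len(runs), np.nan)
        ce = np.full(len(runs), np.nan)
        se = np.full(len(runs), np.nan)
        ok = mix & np.isfinite(ypur1) & np.isfinite(ypur2) & (ypur1 > 0) & (ypur2 > 0)
        for i in runs.index[ok]:
            rec = YieldRecord(
                yp1=runs.at[i, "yp1"],
                yp2=runs.at[i, "yp2"],
                ypur1=runs.at[i, "ypur1"],
                ypur2=runs.at[i, "ypur2"],
            )
            oy[i] = overyielding(rec)
            ce[i], se[i] = complementarity_selection(rec)
        runs["oy"], runs["ce"], runs["se"] = oy, ce, se

    s_iv = pair_stabilising_effect(runs) if len(runs) else pd.DataFrame()
    index_cols = [c for c in runs.columns if c not in RUN_KEYS + ["ypur_key"]]
    long = runs.melt(id_vars=RUN_KEYS, value_vars=index_cols, var_name="index", value_name="value") if len(runs) else pd.DataFrame()

    manifest = {
        "package_version": __version__,
        "master_seed": master_seed,
        "scale": scale,
        "replicates": replicates,
        "n_designs": len(designs),
        "n_runs": len(runs),
        "n_failures": len(failures),
        "failures": failures,
        "sim_config": asdict(sim_config),
        "design": design_table(designs).to_dict(orient="list"),
    }
    result = ExperimentResult(runs=runs, long=long, s_iv=s_iv, manifest=manifest)
    if out_dir is not None:
        result.write(out_dir)
    return result


def pair_stabilising_effect(
    runs: pd.DataFrame, reference_cv: float = 0.001
) -> pd.DataFrame:
    """S_IV per (community, environment, replicate) against the low-IV run.

    Pairs each mixture run at a CV level above the reference with the
    replicate-matched run of the same community and environment at the
    reference CV, and evaluates the stabilising effect on their p50s pair.
    """
    mix = runs[(runs["pure_species"] == 0) & runs["p50s"].notna()]
    ref = mix[mix["cv_level"] == reference_cv].set_index(
        ["community_id", "environment", "replicate"]
    )["p50s"]
    rows = []
    for _, r in mix[mix["cv_level"] != reference_cv].iterrows():
        key = (r["community_id"], r["environment"], r["replicate"])
        if key not in ref.index:
            continue
        rows.append(
            {
                "community_id": r["community_id"],
                "trait_set": r["trait_set"],
                "delta": r["delta"],
                "environment": r["environment"],
                "replicate": r["replicate"],
                "cv_level": r["cv_level"],
                "p50s_low": float(ref.loc[key]),
                "p50s_high": float(r["p50s"]),
                "s_iv": stabilising_effect(float(ref.loc[key]), float(r["p50s"])),
            }
        )
    return pd.DataFrame(rows)


def summarise(runs: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level means and dispersions per design cell.

    Groups mixture runs by (trait_set, delta, cv_level, environment) and
    reports mean and standard deviation of every numeric index.  Order of
    input rows does not matter.
    """
    if isinstance(runs, ExperimentResult):
        runs = runs.runs
    mix = runs[runs["pure_species"] == 0]
    value_cols = [
        c
        for c in mix.columns
        if c not in RUN_KEYS + ["ypur_key"] and pd.api.types.is_numeric_dtype(mix[c])
    ]
    grouped = mix.groupby(["trait_set", "delta", "cv_level", "environment"])[value_cols]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{col}_{stat}" for col, stat in out.columns]
    return out.reset_index().sort_values(
        ["trait_set", "delta", "cv_level", "environment"]
    ).reset_index(drop=True)


def run_null_model_campaign(
    master_seed: int = 0,
    replicates: int = 9,
    cv_levels=CV_LEVELS,
    environments=("N+",),
    trait_sets=None,
    sim_config: SimConfig | None = None,
) -> pd.DataFrame:
    """Replicated runs of every delta = 0 community (the null models).

    Both species share identical mean traits, so any departure of the mean
    p50s from 0.5 beyond Monte-Carlo noise indicates an artefactual
    asymmetry.  Returns the per-run table (no pure stands needed).
    """
    result = run_experiment(
        master_seed=master_seed,
        replicates=replicates,
        trait_sets=trait_sets,
        deltas=(0.0,),
        cv_levels=cv_levels,
        environments=environments,
        sim_config=sim_config,
        include_pure=False,
    )
    return result.runs


def run_direction_sweep(
    master_seed: int = 0,
    replicates: int = 3,
    cv_levels=(0.001, 0.30),
    environments=ENVIRONMENTS,
    trait_sets=None,
    deltas=DELTA_GRID,
    sim_config: SimConfig | None = None,
) -> ExperimentResult:
    """Scaled-down sweep over divergence, IV level and environment.

    Backs the qualitative direction checks: dominance monotone in delta,
    size inequality rising with IV, a non-negative mean stabilising effect,
    environment-dependent within-species selection and the biomass-p_score
    coupling.  No pure stands (none of those checks needs overyielding).
    """
    return run_experiment(
        master_seed=master_seed,
        replicates=replicates,
        trait_sets=trait_sets,
        deltas=deltas,
        cv_levels=cv_levels,
        environments=environments,
        sim_config=sim_config,
        include_pure=False,
    )
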