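"""End-to-end orchestration of the pond/ditch niche analysis.

``run_pipeline`` wires the stages together the way the study design
prescribes: read or simulate an isotope table, drop undersampled
groups, apply the fertilizer δ¹⁵N correction (always) and the maize
δ¹³C correction (second correction state), compute Layman metrics and
Bayesian niche summaries per correction state, maximum-likelihood
niche overlaps between pond and ditch FFGs for both states, toxic-unit
and nutrient summaries, and the bioenv + dbRDA linkage of per-site
Layman metrics to the environment.

Analysis-state conventions: community-level Bayesian Layman metrics
and the ordination consume the δ¹⁵N-only-corrected data (fertilization
is a general phenomenon; the carbon source is real signal), while the
FFG-level SEAc comparison and the second overlap column consume the
doubly-corrected data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from isoniche import bayes_niche, ecotox_chem, env_ordination
from isoniche.core_data import (
    FFG,
    SampleTable,
    WaterBodyType,
    filter_min_group_size,
    summarize_counts,
)
from isoniche.isotope_corrections import correct_d13C_maize, correct_d15N_fertilizer
from isoniche.layman_metrics import PointSet2D, layman_all
from isoniche.niche_overlap import ellipse_overlap, ml_ellipse
from isoniche.synthetic_data import ScenarioConfig, simulate_isotope_dataset, simulate_water_chemistry

logger = logging.getLogger("isoniche.pipeline")

CORRECTION_STATES = ("d15N_only", "d15N_and_d13C")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    scenario: ScenarioConfig | None = None
    table: SampleTable | None = None
    correction_states: tuple[str, ...] = CORRECTION_STATES
    grouping: str = "site_by_ffg"  # or "ffg_by_type"
    min_group_n: int = 3
    n_draws: int = 2000
    seed: int = 0
    overlap_p: float = 0.95
    excluded_env_vars: tuple[str, ...] = ("ec", "o2")
    n_perm: int = 199
    maize_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.correction_states:
            raise ValueError("at least one correction state is required")
        unknown = set(self.correction_states) - set(CORRECTION_STATES)
        if unknown:
            raise ValueError(f"unknown correction state(s): {sorted(unknown)}")
        if self.grouping not in {"site_by_ffg", "ffg_by_type"}:
            raise ValueError("grouping must be 'site_by_ffg' or 'ffg_by_type'")
        if (self.scenario is None) == (self.table is None):
            raise ValueError("provide exactly one of scenario or table")


def _group_pointsets(table: SampleTable, grouping: str) -> dict[str, PointSet2D]:
    """Split a table into (δ¹³C, δ¹⁵N) point clouds by the grouping scheme."""
    buckets: dict[str, list[list[float]]] = {}
    meta: dict[str, WaterBodyType] = {}
    for s in table:
        key = (
            f"{s.site_id}|{s.ffg.value}"
            if grouping == "site_by_ffg"
            else f"{s.wb_type.value}|{s.ffg.value}"
        )
        buckets.setdefault(key, []).append([s.d13C, s.d15N])
        meta[key] = s.wb_type
    return {
        k: PointSet2D(np.asarray(v), label=k) for k, v in sorted(buckets.items())
    }


def _community_of(group_label: str, table: SampleTable, grouping: str) -> str:
    if grouping == "ffg_by_type":
        return group_label.split("|")[0]
    site = group_label.split("|")[0]
    return table.site_types[site].value


def _checksum(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and return a manifest of output tables.

    The returned dict maps stage names to DataFrames (plus a
    ``manifest`` entry listing outputs with row counts and checksums).
    With ``out_dir`` set, each table is also written as CSV.
    """
    outputs: dict[str, pd.DataFrame] = {}

    # --- input ------------------------------------------------------------
    if cfg.scenario is not None:
        table = simulate_isotope_dataset(cfg.scenario)
        maize_sites = tuple(sorted(cfg.scenario.maize_sites)) or cfg.maize_sites
        chem, endpoints = (
            simulate_water_chemistry(cfg.scenario)
            if cfg.scenario.chem_spec is not None
            else ([], [])
        )
    else:
        table = cfg.table
        maize_sites = cfg.maize_sites
        chem, endpoints = [], []
    logger.info("input table: %d samples, seed=%s", len(table), cfg.seed)

    outputs["counts"] = summarize_counts(table).to_frame()

    # --- filtering --------------------------------------------------------
    table, dropped = filter_min_group_size(table, cfg.min_group_n)
    logger.info("filtered %d undersampled group(s)", len(dropped))

    # --- corrections ------------------------------------------------------
    n_corrected, report_n = correct_d15N_fertilizer(table)
    states: dict[str, SampleTable] = {}
    reports = [report_n.to_json_dict()]
    if "d15N_only" in cfg.correction_states:
        states["d15N_only"] = n_corrected
    if "d15N_and_d13C" in cfg.correction_states:
        if maize_sites:
            nc, report_c = correct_d13C_maize(n_corrected, maize_sites)
            reports.append(report_c.to_json_dict())
        else:  # no maize influence declared: states coincide
            nc = n_corrected
        states["d15N_and_d13C"] = nc
    outputs["corrections"] = pd.DataFrame(
        [{k: json.dumps(v) if isinstance(v, list) else v for k, v in r.items()}
         for r in reports]
    )

    # --- Layman metrics (per correction state) -----------------------------
    layman_rows = []
    for state, tbl in states.items():
        for key, ps in _group_pointsets(tbl, cfg.grouping).items():
            if len(ps) < 2:
                continue
            for metric, value in layman_all(ps).as_dict().items():
                layman_rows.append(
                    {"state": state, "group": key, "metric": metric, "value": value}
                )
    outputs["layman"] = pd.DataFrame(layman_rows)

    # --- Bayesian niches on the δ¹⁵N-only state ----------------------------
    primary_state = "d15N_only" if "d15N_only" in states else cfg.correction_states[0]
    seac_state = "d15N_and_d13C" if "d15N_and_d13C" in states else primary_state
    groups_primary = _group_pointsets(states[primary_state], cfg.grouping)
    sea_rows = []
    ensembles: dict[str, list[bayes_niche.PosteriorEnsemble]] = {}
    rng = np.random.default_rng(cfg.seed)
    for key, ps in _group_pointsets(states[seac_state], cfg.grouping).items():
        if len(ps) < 3 or np.any(ps.points.var(axis=0) == 0):
            continue
        ens = bayes_niche.fit_bivariate_posterior(
            ps, n_draws=cfg.n_draws, seed=int(rng.integers(2**31 - 1))
        )
        summ = bayes_niche.sea_metrics(ps, ens)
        sea_rows.append(
            {
                "state": seac_state,
                "group": key,
                "n": summ.n,
                "sea_c": summ.sea_c,
                "sea_b_mode": summ.sea_b_mode,
                "ci95_lo": summ.credible[95][0],
                "ci95_hi": summ.credible[95][1],
            }
        )
    outputs["sea"] = pd.DataFrame(sea_rows)

    # Bayesian Layman metrics over group centroids, communities = types
    for key, ps in groups_primary.items():
        if len(ps) < 3 or np.any(ps.points.var(axis=0) == 0):
            continue
        ens = bayes_niche.fit_bivariate_posterior(
            ps, n_draws=cfg.n_draws, seed=int(rng.integers(2**31 - 1))
        )
        community = _community_of(key, states[primary_state], cfg.grouping)
        ensembles.setdefault(community, []).append(ens)
    bl_rows = []
    if all(len(v) >= 2 for v in ensembles.values()) and ensembles:
        for community, res in bayes_niche.bayes_layman(ensembles).items():
            for metric, mode in res.modes.items():
                lo, hi = res.credible[metric][95]
                bl_rows.append(
                    {"community": community, "metric": metric, "mode": mode,
                     "ci95_lo": lo, "ci95_hi": hi}
                )
    outputs["layman_bayes"] = pd.DataFrame(bl_rows)

    # --- ML overlaps pond vs ditch per FFG, both states --------------------
    overlap_rows = []
    for state, tbl in states.items():
        type_groups = _group_pointsets(tbl, "ffg_by_type")
        for ffg in FFG:
            k_pond = f"pond|{ffg.value}"
            k_ditch = f"ditch|{ffg.value}"
            if k_pond not in type_groups or k_ditch not in type_groups:
                continue
            if len(type_groups[k_pond]) < 3 or len(type_groups[k_ditch]) < 3:
                continue
            e1 = ml_ellipse(type_groups[k_pond], p=cfg.overlap_p)
            e2 = ml_ellipse(type_groups[k_ditch], p=cfg.overlap_p)
            res = ellipse_overlap(e1, e2)
            overlap_rows.append({"state": state, "ffg": ffg.value, **res})
    outputs["overlap"] = pd.DataFrame(overlap_rows)

    # --- chemistry ---------------------------------------------------------
    type_map = {s: t.value for s, t in (cfg.scenario.sites if cfg.scenario else [])}
    if chem:
        site_chem = ecotox_chem.site_table(chem, type_map, endpoints)
        outputs["chemistry_sites"] = site_chem
        outputs["chemistry_summary"] = ecotox_chem.summaries_from_site_table(site_chem)

    # --- ordination: per-site Layman metrics vs environment ----------------
    if chem and len(set(type_map)) >= 4:
        per_site = {}
        for site in states[primary_state].sites():
            pts = np.asarray(
                [[s.d13C, s.d15N] for s in states[primary_state] if s.site_id == site]
            )
            per_site[site] = layman_all(PointSet2D(pts, label=site)).as_dict()
        metric_frame = pd.DataFrame(per_site).T
        site_chem = outputs["chemistry_sites"].set_index("site_id")
        env_cols = [
            c for c in ("temp", "ec", "ph", "o2", "nutrient_sum", "n_detections",
                        "tu_sum_invertebrate", "tu_sum_algae")
            if c in site_chem.columns and c not in cfg.excluded_env_vars
        ]
        env_frame = site_chem.loc[metric_frame.index, env_cols].astype(float)
        env_frame = env_frame.dropna(axis=1)
        env = env_ordination.zscore_env(env_ordination.EnvMatrix.from_frame(env_frame))
        response = env_ordination.dissimilarity(metric_frame, metric="mahalanobis")
        bio = env_ordination.bioenv_search(env, response)
        best = env.subset(list(bio.best_subset))
        fit = env_ordination.dbrda_fit(response, best)
        perm = env_ordination.permutation_test(
            response, best, n_perm=cfg.n_perm, seed=cfg.seed, scope="model"
        )
        outputs["bioenv"] = pd.DataFrame(
            [{"subset": "+".join(s), "rho": r} for s, r in bio.all_subsets[:20]]
        )
        outputs["dbrda"] = pd.DataFrame(
            {
                "axis": [f"dbRDA{i+1}" for i in range(fit.constrained_eigenvalues.size)],
                "eigenvalue": fit.constrained_eigenvalues,
                "prop_explained": fit.constrained_eigenvalues / fit.total_inertia,
            }
        )
        outputs["permutation"] = perm

    # --- manifest ----------------------------------------------------------
    manifest = pd.DataFrame(
        [
            {"output": name, "rows": len(df), "checksum": _checksum(df)}
            for name, df in outputs.items()
        ]
    )
    outputs["manifest"] = manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in outputs.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return outputs
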