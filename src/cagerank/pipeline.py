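"""Stage orchestration: simulate -> ingest -> network -> rate -> phenotypes
-> validity -> report.

Every statistical constant is a named configuration key with its study
default; stages write tidy CSV/JSON artifacts into the output directory and
a run manifest records the configuration hash and seeds so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import glicko, network, phenotypes as ph, validity
from .ethogram import (
    Behavior,
    CageMeta,
    SamplingScheme,
    contests_from_aggression,
    read_cages,
    read_events,
    read_scans,
)
from .simulate import SimConfig, simulate_study, write_study

log = logging.getLogger("cagerank")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    data_dir: str | None = None
    sim: SimConfig | None = None
    out_dir: str = "cagerank_out"
    seed: int = 0
    # statistical constants (study defaults)
    alpha: float = 0.05
    contrast_family_size: int = 6
    loading_threshold: float = 0.45
    eigenvalue_cutoff: float = 1.0
    response_window_s: float = 5.0
    glicko_init_rating: float = 2200.0
    glicko_init_rd: float = 300.0
    residualize_mode: str = "mixed"
    stages: tuple[str, ...] = (
        "simulate", "ingest", "network", "rate", "phenotypes", "validity", "report",
    )

    def __post_init__(self) -> None:
        if self.data_dir is None and self.sim is None:
            raise ValueError("need either data_dir or a sim config")

    def glicko_config(self) -> glicko.GlickoConfig:
        return glicko.GlickoConfig(
            init_rating=self.glicko_init_rating, init_rd=self.glicko_init_rd
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", None)
    sim = None
    if sim_raw is not None:
        if "scheme" in sim_raw:
            s = sim_raw["scheme"]
            sim_raw["scheme"] = SamplingScheme(
                window_s=s.get("window_s", 60.0),
                period_s=s.get("period_s", 300.0),
                days=tuple(s.get("days", (2, 7))),
            )
        for key in ("strains", "group_sizes"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimConfig(**sim_raw)
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(sim=sim, **raw)


def _config_hash(config: PipelineConfig) -> str:
    def stringify(o):
        if isinstance(o, dict):
            return {str(k): stringify(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [stringify(v) for v in o]
        return o

    blob = json.dumps(
        stringify(dataclasses.asdict(config)), sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the assembled report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data_dir = Path(config.data_dir) if config.data_dir else out / "sim_data"
    if "simulate" in config.stages and config.sim is not None:
        log.info("stage simulate: %d cages per arm", config.sim.n_cages_per_arm)
        cages, manifest = simulate_study(config.sim)
        write_study(cages, manifest, data_dir)

    # ---- ingest -----------------------------------------------------------
    for fname in ("cages.csv", "events.csv", "scans.csv"):
        if not (data_dir / fname).exists():
            raise FileNotFoundError(
                f"preflight: required input {data_dir / fname} is missing"
            )
    metas = read_cages(data_dir / "cages.csv")
    events_by_cage = {
        m.cage_id: read_events(data_dir / "events.csv", m) for m in metas
    }
    scans_by_cage = {m.cage_id: read_scans(data_dir / "scans.csv", m) for m in metas}
    log.info(
        "stage ingest: %d cages, %d events, %d scans",
        len(metas),
        sum(map(len, events_by_cage.values())),
        sum(map(len, scans_by_cage.values())),
    )

    report: dict = {"config_hash": _config_hash(config), "seed": config.seed}

    # ---- network ----------------------------------------------------------
    metrics_rows = []
    strength_rows = []
    socio_dir = out / "sociomatrices"
    socio_dir.mkdir(exist_ok=True)
    scopes = {
        "aggression": (Behavior.MEDIATED_AGGRESSION, Behavior.ESCALATED_AGGRESSION),
        "submission": (Behavior.SUBMISSION,),
        "investigation": (Behavior.INVESTIGATION,),
        "allogroom": (Behavior.ALLOGROOM,),
    }
    if "network" in config.stages:
        for m in metas:
            events = events_by_cage[m.cage_id]
            for scope, cats in scopes.items():
                recs = [e for e in events if e.category in cats]
                F = network.build_frequency_matrix(recs, m.mouse_ids, scope)
                F.to_csv(socio_dir / f"{m.cage_id}_{scope}.csv")
                for mouse in m.mouse_ids:
                    strength_rows.append(
                        {
                            "cage_id": m.cage_id,
                            "mouse": mouse,
                            "behavior_scope": scope,
                            "out_strength": network.out_strength(F, mouse),
                            "in_strength": network.in_strength(F, mouse),
                        }
                    )
                if scope == "aggression":
                    B = network.binarize(F)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        dc = network.directional_consistency(F)
                    metrics_rows.append(
                        {
                            "cage_id": m.cage_id,
                            "behavior_scope": scope,
                            "metric": "density",
                            "value": network.density(B),
                        }
                    )
                    metrics_rows.append(
                        {
                            "cage_id": m.cage_id,
                            "behavior_scope": scope,
                            "metric": "directional_consistency",
                            "value": dc,
                        }
                    )
        pd.DataFrame(metrics_rows).to_csv(out / "metrics.csv", index=False)
        pd.DataFrame(strength_rows).to_csv(out / "strengths.csv", index=False)
        log.info("stage network: %d metric rows", len(metrics_rows))

    # ---- ratings ----------------------------------------------------------
    ratings_rows = []
    if "rate" in config.stages:
        gconf = config.glicko_config()
        for m in metas:
            variants = glicko.glicko_variants(
                events_by_cage[m.cage_id], m.mouse_ids, gconf
            )
            for variant, net in variants.items():
                for mouse, change in net.items():
                    ratings_rows.append(
                        {
                            "cage_id": m.cage_id,
                            "mouse": mouse,
                            "variant": variant.replace("glicko_", ""),
                            "net_change": change,
                        }
                    )
        pd.DataFrame(ratings_rows).to_csv(out / "ratings.csv", index=False)
        log.info("stage rate: %d rating rows", len(ratings_rows))

    # ---- phenotypes -------------------------------------------------------
    pheno_df = None
    if "phenotypes" in config.stages:
        pheno_df = _phenotype_stage(data_dir, metas, scans_by_cage)
        pheno_df.to_csv(out / "phenotypes.csv", index=False)
        log.info("stage phenotypes: %d mice", len(pheno_df))

    # ---- validity ---------------------------------------------------------
    if "validity" in config.stages:
        if pheno_df is None or not ratings_rows:
            raise RuntimeError(
                "preflight: validity stage needs the phenotypes and rate stages"
            )
        vreport = _validity_stage(
            config, metas, events_by_cage, pheno_df,
            pd.DataFrame(ratings_rows), pd.DataFrame(strength_rows), out,
        )
        report["validity"] = vreport

    if "report" in config.stages:
        manifest = {
            "config_hash": report["config_hash"],
            "seed": config.seed,
            "n_cages": len(metas),
            "constants": {
                "alpha": config.alpha,
                "contrast_family_size": config.contrast_family_size,
                "loading_threshold": config.loading_threshold,
                "eigenvalue_cutoff": config.eigenvalue_cutoff,
                "response_window_s": config.response_window_s,
                "glicko_init_rating": config.glicko_init_rating,
                "glicko_init_rd": config.glicko_init_rd,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=1)
        with open(out / "validity_report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=1)
    return report


def _phenotype_stage(
    data_dir: Path, metas: Sequence[CageMeta], scans_by_cage: dict
) -> pd.DataFrame:
    grids = pd.read_csv(data_dir / "pals_grids.csv")
    tube = pd.read_csv(data_dir / "tube_trials.csv")
    morph = pd.read_csv(data_dir / "morphometrics.csv")
    ofm = pd.read_csv(data_dir / "ofm.csv")

    rows = []
    for m in metas:
        scans = scans_by_cage[m.cage_id]
        p_alone = ph.proportion_alone(scans)
        by_mouse: dict[str, list] = {}
        for s in scans:
            by_mouse.setdefault(s.mouse, []).append(s)
        for mouse in m.mouse_ids:
            sev = np.zeros((ph.GRID_SIZE, ph.GRID_SIZE), dtype=int)
            area = np.zeros((ph.GRID_SIZE, ph.GRID_SIZE))
            for _, g in grids[grids["mouse"] == mouse].iterrows():
                sev[int(g["row"]) - 1, int(g["col"]) - 1] = int(g["severity"])
                area[int(g["row"]) - 1, int(g["col"]) - 1] = float(g["area_pct"])
            regions = ph.pals_region_scores(
                ph.PALSGrid(mouse=mouse, severity=sev, area_pct=area)
            )
            trow = {"mouse": mouse, "cage_id": m.cage_id}
            trow.update(
                {
                    "posterior_pals": regions["posterior"],
                    "mid_pals": regions["mid"],
                    "anterior_pals": regions["anterior"],
                }
            )
            for _, t in tube[tube["mouse"] == mouse].iterrows():
                rec = ph.TubeTestRecord(
                    mouse=mouse, round=int(t["round"]),
                    wins=int(t["wins"]), competed=int(t["competed"]),
                )
                trow[f"tube_r{rec.round}"] = ph.tube_test_score(rec)
            mrow = morph[morph["mouse"] == mouse]
            if not mrow.empty:
                r = mrow.iloc[0]
                darcin = r["darcin_lfq"]
                rec = ph.MorphometricRecord(
                    mouse=mouse,
                    preputial_mg=float(r["preputial_mg"]),
                    body_length_mm=float(r["body_length_mm"]),
                    darcin_lfq=None if pd.isna(darcin) else float(darcin),
                )
                trow["preputial_ratio"] = ph.preputial_ratio(rec)
                trow["darcin"] = np.nan if rec.darcin_lfq is None else rec.darcin_lfq
            orow = ofm[ofm["mouse"] == mouse]
            if not orow.empty:
                r = orow.iloc[0]
                trow["ofm_distance_cm"] = float(r["distance_cm"])
                trow["ofm_center_pct"] = float(r["center_pct"])
                trow["ofm_boli"] = int(r["boli"])
            budget = ph.time_budget(by_mouse.get(mouse, []))
            if budget is not None:
                trow["p_active"] = budget["active"]
                trow["p_group_sleep"] = budget["group_sleep"]
                trow["p_solitary_sleep"] = budget["solitary_sleep"]
            trow["p_alone"] = p_alone.get(mouse, np.nan)
            trow["strain"] = m.strain.value
            trow["group_size"] = m.group_size
            rows.append(trow)
    return pd.DataFrame(rows)


def _validity_stage(
    config: PipelineConfig,
    metas: Sequence[CageMeta],
    events_by_cage: dict,
    pheno: pd.DataFrame,
    ratings: pd.DataFrame,
    strengths: pd.DataFrame,
    out: Path,
) -> dict:
    net = ratings.pivot_table(
        index=["cage_id", "mouse"], columns="variant", values="net_change"
    ).rename(columns={"agg": "glicko_agg_net", "sub": "glicko_sub_net"}).reset_index()
    table = pheno.merge(net, on=["cage_id", "mouse"], how="left")

    selected = validity.select_extremes(table)
    selected.to_csv(out / "selected_mice.csv", index=False)

    resid = validity.residualize(
        selected, validity.MEASURE_COLUMNS, mode=config.residualize_mode
    )
    spv = validity.subjects_per_variable(resid, validity.MEASURE_COLUMNS)
    fa = validity.ml_factor_analysis(
        resid[validity.MEASURE_COLUMNS],
        loading_threshold=config.loading_threshold,
        eigenvalue_cutoff=config.eigenvalue_cutoff,
    )
    fa.loadings.to_csv(out / "factor_loadings.csv")

    regs = {}
    for target in ("glicko_sub_net", "glicko_agg_net"):
        y = selected.loc[fa.scores.index, target]
        regs[target] = validity.convergent_regression(y, fa.scores)
        regs[target].to_csv(out / f"convergent_{target}.csv")

    # tube-test PC + discriminant model on the selected mice
    tube_pca = validity.pca(
        selected[["tube_r1", "tube_r2", "tube_r3"]],
        eigenvalue_cutoff=config.eigenvalue_cutoff,
    )
    disc_table = selected.loc[tube_pca.scores.index].copy()
    disc_table["tube_pc"] = tube_pca.scores["PC1"].values
    disc = validity.discriminant_model(disc_table)
    disc.to_csv(out / "discriminant_model.csv")

    # budget PC across all mice (time-budget condensation)
    budget_cols = ["p_active", "p_group_sleep", "p_solitary_sleep"]
    budget_pca = (
        validity.pca(table[budget_cols], eigenvalue_cutoff=config.eigenvalue_cutoff)
        if table[budget_cols].dropna().shape[0] >= 3
        else None
    )

    correlations = {
        "glicko_agg_vs_sub": validity.pearson_ci(
            selected["glicko_agg_net"], selected["glicko_sub_net"]
        )
    }
    wide = strengths[strengths["behavior_scope"].isin(["aggression", "investigation"])]
    piv = wide.pivot_table(
        index=["cage_id", "mouse"], columns="behavior_scope", values="out_strength"
    ).dropna()
    if len(piv) >= 4 and piv["aggression"].std() > 0 and piv["investigation"].std() > 0:
        correlations["investigation_vs_aggression_out_strength"] = validity.pearson_ci(
            piv["investigation"], piv["aggression"]
        )

    outcomes = []
    for m in metas:
        outcomes.extend(
            validity.submission_response_scan(
                events_by_cage[m.cage_id],
                window_s=config.response_window_s,
                strain=m.strain.value,
                cage_id=m.cage_id,
            )
        )
    logistic = validity.response_logistic(
        outcomes, alpha=config.alpha, family_size=config.contrast_family_size
    )
    logistic["contrasts"].to_csv(out / "response_contrasts.csv", index=False)

    return {
        "subjects_per_variable": spv,
        "n_complete_cases": int(
            resid[validity.MEASURE_COLUMNS].dropna().shape[0]
        ),
        "factor_analysis": {
            "n_factors": fa.n_factors,
            "loadings": fa.loadings,
            "eigenvalues": fa.eigenvalues,
            "pct_variance": fa.pct_variance,
            "membership": fa.membership,
            "loading_threshold": fa.loading_threshold,
        },
        "convergent_regressions": regs,
        "tube_pc": {
            "eigenvalues": tube_pca.eigenvalues,
            "loadings": tube_pca.loadings["PC1"],
            "n_retained": tube_pca.n_retained,
        },
        "budget_pc": (
            {
                "eigenvalues": budget_pca.eigenvalues,
                "loadings": budget_pca.loadings["PC1"],
                "n_retained": budget_pca.n_retained,
            }
            if budget_pca is not None
            else None
        ),
        "discriminant_model": disc,
        "discriminant_validity": bool((disc["p"] > config.alpha).all()),
        "correlations": correlations,
        "response_logistic": {
            "terms": logistic["terms"],
            "contrasts": logistic["contrasts"],
            "threshold": logistic["threshold"],
            "cell_probs": logistic["cell_probs"],
            "n": logistic["n"],
        },
    }
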