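"""Generative model of a cage study.

Each simulated cage gets a despotic hierarchy: the alpha performs a share
``despotism`` of all aggression and attacks are directed down-rank, so
directional consistency rises with despotism.  Aggression and investigation
events trigger submission responses from the recipient within a short
latency with configurable (strain, day)-specific probabilities.  Continuous
event streams are thinned through the 1-min-per-5-min all-occurrence
observation scheme; instantaneous scans, wound grids, tube-test trials,
morphometrics and open-field measures are generated with dominance- and
strain-linked structure so every downstream stage has a known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .ethogram import (
    Behavior,
    BehaviorEvent,
    CageMeta,
    SamplingScheme,
    ScanRecord,
    ScanState,
    Strain,
    write_cages,
    write_events,
    write_scans,
)
from .phenotypes import GRID_SIZE, MorphometricRecord, OFMRecord, PALSGrid, TubeTestRecord

__all__ = ["SimConfig", "SimCage", "simulate_cage", "emulate_sampling",
           "simulate_study", "write_study", "simulate_measure_table",
           "study_measure_table"]

DAY_S = 86400.0
NEST_CELL = (1, 1)


def _default_p_submit_attack() -> dict:
    return {"default": 0.7}


def _default_p_submit_investigation() -> dict:
    # strain A (SJL-like) on day 2 elevated, everything else low
    return {("SJL", 2): 0.6, "default": 0.2}


@dataclass(frozen=True)
class SimConfig:
    n_cages_per_arm: int = 6
    strains: tuple[str, str] = (Strain.SJL.value, Strain.ALBINO_B6.value)
    group_sizes: tuple[int, int] = (3, 5)
    #: share of cage aggression performed by the alpha
    despotism: float = 0.8
    #: continuous aggression events per mouse-hour
    aggression_rate: float = 0.5
    investigation_rate: float = 1.0
    allogroom_rate: float = 0.3
    #: probability a lower-ranked non-alpha attack is directed down-rank
    p_down_rank: float = 0.9
    p_submit_given_attack: dict = field(default_factory=_default_p_submit_attack)
    p_submit_given_investigation: dict = field(
        default_factory=_default_p_submit_investigation
    )
    #: mixing weight of investigation propensity toward aggression propensity
    investigation_coupling: float = 0.8
    #: coupling of the tube-test latent to dominance (0 reproduces the
    #: two-factor separation; near 1 merges the blocks)
    tube_coupling: float = 0.0
    tube_discrimination: float = 1.5
    p_tube_timeout: float = 0.05
    tube_replicates: int = 4
    tube_rounds: int = 3
    # additive strain shifts (strain B = albino-B6-like gets more darcin
    # and larger preputial ratio; strain A = SJL-like gets more wounding)
    beta_darcin: float = 1.5
    beta_preputial: float = 0.15
    beta_pals: float = 3.0
    # dominance slopes
    gamma_darcin: float = 1.2
    gamma_preputial: float = 0.2
    pals_per_attack: float = 0.35
    sd_darcin: float = 0.5
    sd_preputial: float = 0.05
    darcin_missing_p: float = 0.15
    submission_latency_max_s: float = 5.0
    #: 'uniform' latency in (0, max]; 'exponential' probes window misfit
    latency_model: str = "uniform"
    response_window_s: float = 5.0
    scheme: SamplingScheme = field(default_factory=SamplingScheme)
    scan_persistence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.despotism,
            self.p_down_rank,
            self.investigation_coupling,
            self.p_tube_timeout,
            self.darcin_missing_p,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not -1 <= self.tube_coupling <= 1:
            raise ValueError("tube_coupling must be in [-1, 1]")
        for v in list(self.p_submit_given_attack.values()) + list(
            self.p_submit_given_investigation.values()
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"submission probability {v} outside [0, 1]")

    def p_attack_response(self, strain: str, day: int) -> float:
        d = self.p_submit_given_attack
        return d.get((strain, day), d.get("default", 0.7))

    def p_investigation_response(self, strain: str, day: int) -> float:
        d = self.p_submit_given_investigation
        return d.get((strain, day), d.get("default", 0.2))


@dataclass
class SimCage:
    meta: CageMeta
    true_rank: dict[str, int]  # 1 = alpha
    events_continuous: list[BehaviorEvent]
    events: list[BehaviorEvent]  # after observation-window thinning
    scans: list[ScanRecord]
    pals_grids: list[PALSGrid]
    tube_records: list[TubeTestRecord]
    morphometrics: list[MorphometricRecord]
    ofm: list[OFMRecord]
    ground_truth: dict


def emulate_sampling(
    events: Sequence[BehaviorEvent], scheme: SamplingScheme
) -> list[BehaviorEvent]:
    """Keep events falling in the half-open observed windows
    [k*period, k*period + window); expected retention = window/period."""
    return [e for e in events if scheme.in_window(e.t)]


def _dominance(rank: int, n: int) -> float:
    """Map rank (1 = alpha) to [0, 1] with alpha at 1."""
    return (n - rank) / (n - 1)


def simulate_cage(
    config: SimConfig,
    cage_index: int,
    strain: str | None = None,
    group_size: int | None = None,
) -> SimCage:
    """Simulate one cage; arm follows ``cage_index`` unless overridden.

    Deterministic given (config.seed, cage_index).
    """
    arms = [(s, gs) for s in config.strains for gs in config.group_sizes]
    arm_strain, arm_size = arms[cage_index % len(arms)]
    strain = strain if strain is not None else arm_strain
    group_size = group_size if group_size is not None else arm_size

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(cage_index,))
    )
    n = group_size
    cage_id = f"C{cage_index:03d}"
    mice = tuple(f"{cage_id}_m{i + 1}" for i in range(n))
    meta = CageMeta(
        cage_id=cage_id,
        strain=Strain(strain),
        group_size=n,
        mouse_ids=mice,
        batch=cage_index // (len(arms)) + 1,
    )
    ranks = {m: i + 1 for i, m in enumerate(mice)}  # m1 is the alpha
    dom = np.array([_dominance(ranks[m], n) for m in mice])

    # aggression propensity: alpha takes share delta, rest split evenly
    agg_prop = np.full(n, (1.0 - config.despotism) / (n - 1))
    agg_prop[0] = config.despotism
    # investigation propensity: coupled mixture with an independent trait
    indep = rng.dirichlet(np.ones(n))
    inv_prop = config.investigation_coupling * agg_prop + (
        1 - config.investigation_coupling
    ) * indep
    inv_prop = inv_prop / inv_prop.sum()

    def latency() -> float:
        if config.latency_model == "exponential":
            return rng.exponential(config.submission_latency_max_s / 2)
        return rng.uniform(0.0, config.submission_latency_max_s)

    events: list[BehaviorEvent] = []
    hours = DAY_S / 3600.0
    for day in config.scheme.days:
        p_sub_att = config.p_attack_response(strain, day)
        p_sub_inv = config.p_investigation_response(strain, day)

        n_agg = rng.poisson(config.aggression_rate * n * hours)
        for _ in range(n_agg):
            t = rng.uniform(0.0, DAY_S)
            a = rng.choice(n, p=agg_prop)
            if a == 0:
                r = rng.integers(1, n)
            elif rng.random() < config.p_down_rank and a < n - 1:
                r = rng.integers(a + 1, n)  # strictly lower-ranked target
            else:
                r = rng.choice([i for i in range(n) if i != a])
            cat = (
                Behavior.ESCALATED_AGGRESSION
                if rng.random() < 0.5
                else Behavior.MEDIATED_AGGRESSION
            )
            events.append(BehaviorEvent(day, t, mice[a], mice[r], cat))
            if rng.random() < p_sub_att:
                events.append(
                    BehaviorEvent(
                        day, min(t + latency(), DAY_S), mice[r], mice[a],
                        Behavior.SUBMISSION,
                    )
                )

        n_inv = rng.poisson(config.investigation_rate * n * hours)
        for _ in range(n_inv):
            t = rng.uniform(0.0, DAY_S)
            a = rng.choice(n, p=inv_prop)
            r = rng.choice([i for i in range(n) if i != a])
            events.append(BehaviorEvent(day, t, mice[a], mice[r], Behavior.INVESTIGATION))
            if rng.random() < p_sub_inv:
                events.append(
                    BehaviorEvent(
                        day, min(t + latency(), DAY_S), mice[r], mice[a],
                        Behavior.SUBMISSION,
                    )
                )

        n_groom = rng.poisson(config.allogroom_rate * n * hours)
        for _ in range(n_groom):
            t = rng.uniform(0.0, DAY_S)
            a = int(rng.integers(n))
            r = rng.choice([i for i in range(n) if i != a])
            events.append(BehaviorEvent(day, t, mice[a], mice[r], Behavior.ALLOGROOM))

    events.sort(key=lambda e: (e.day, e.t))
    observed = emulate_sampling(events, config.scheme)

    # ---- instantaneous scans: sticky Markov over states, cells by state
    p_active = 0.35 + 0.25 * dom
    p_sol = 0.05 + 0.20 * dom
    states_order = [ScanState.ACTIVE, ScanState.GROUP_SLEEP, ScanState.SOLITARY_SLEEP]
    scans: list[ScanRecord] = []
    n_slots = int(DAY_S // config.scheme.period_s)
    all_cells = [(r, c) for r in (1, 2) for c in (1, 2, 3, 4)]
    non_nest = [c for c in all_cells if c != NEST_CELL]
    for i, mouse in enumerate(mice):
        stat = np.array([p_active[i], 1 - p_active[i] - p_sol[i], p_sol[i]])
        for day in config.scheme.days:
            state = states_order[rng.choice(3, p=stat)]
            solo_cell = non_nest[int(rng.integers(len(non_nest)))]
            for k in range(n_slots):
                if rng.random() > config.scan_persistence:
                    state = states_order[rng.choice(3, p=stat)]
                    solo_cell = non_nest[int(rng.integers(len(non_nest)))]
                if state is ScanState.GROUP_SLEEP:
                    cell = NEST_CELL
                elif state is ScanState.SOLITARY_SLEEP:
                    cell = solo_cell
                else:
                    cell = all_cells[int(rng.integers(len(all_cells)))]
                scans.append(
                    ScanRecord(day=day, t=k * config.scheme.period_s,
                               mouse=mouse, state=state, cell=cell)
                )

    # ---- phenotypes
    received = {m: 0 for m in mice}
    for e in events:
        if e.category in (Behavior.MEDIATED_AGGRESSION, Behavior.ESCALATED_AGGRESSION):
            received[e.recipient] += 1

    strain_b = 1.0 if strain == Strain.ALBINO_B6.value else 0.0
    morph: list[MorphometricRecord] = []
    ofm: list[OFMRecord] = []
    grids: list[PALSGrid] = []
    tube: list[TubeTestRecord] = []

    dom_z = (dom - dom.mean()) / dom.std() if n > 1 else dom * 0
    rho = config.tube_coupling
    tube_latent = rho * dom_z + np.sqrt(max(0.0, 1 - rho * rho)) * rng.normal(size=n)

    for i, mouse in enumerate(mice):
        darcin = (
            config.beta_darcin * strain_b
            + config.gamma_darcin * dom[i]
            + rng.normal(0, config.sd_darcin)
        )
        if rng.random() < config.darcin_missing_p:
            darcin = None
        body_len = rng.normal(95.0, 3.0)
        ratio = max(
            0.05,
            0.5
            + config.beta_preputial * strain_b
            + config.gamma_preputial * dom[i]
            + rng.normal(0, config.sd_preputial),
        )
        morph.append(
            MorphometricRecord(
                mouse=mouse,
                preputial_mg=ratio * body_len,
                body_length_mm=body_len,
                darcin_lfq=darcin,
            )
        )
        # OFM independent of everything (discriminant-validity null)
        ofm.append(
            OFMRecord(
                mouse=mouse,
                distance_cm=max(100.0, rng.normal(2500.0, 400.0)),
                center_pct=float(np.clip(rng.normal(15.0, 5.0), 0, 100)),
                boli=int(rng.poisson(3.0)),
            )
        )
        # wound grid: damage concentrated posterior, driven by received
        # attacks plus a strain shift
        severity = np.zeros((GRID_SIZE, GRID_SIZE), dtype=int)
        area = np.zeros((GRID_SIZE, GRID_SIZE))
        intensity = config.pals_per_attack * received[mouse] + config.beta_pals * (
            1.0 - strain_b
        ) * (received[mouse] > 0)
        n_wounds = min(int(rng.poisson(intensity)), 27)
        if n_wounds > 0:
            flat = rng.choice(27, size=n_wounds, replace=False)
            for f in flat:
                r, c = 6 + f // GRID_SIZE, f % GRID_SIZE  # posterior rows 7-9
                severity[r, c] = int(1 + min(3, rng.poisson(0.8)))
                area[r, c] = rng.uniform(5.0, 60.0)
        grids.append(PALSGrid(mouse=mouse, severity=severity, area_pct=area))

    pairs = list(combinations(range(n), 2))
    for rnd in range(1, config.tube_rounds + 1):
        wins = {m: 0 for m in mice}
        competed = {m: 0 for m in mice}
        for i, j in pairs:
            for _ in range(config.tube_replicates):
                competed[mice[i]] += 1
                competed[mice[j]] += 1
                if rng.random() < config.p_tube_timeout:
                    continue  # loss for both
                p_i = expit(
                    config.tube_discrimination * (tube_latent[i] - tube_latent[j])
                )
                if rng.random() < p_i:
                    wins[mice[i]] += 1
                else:
                    wins[mice[j]] += 1
        for m in mice:
            tube.append(
                TubeTestRecord(mouse=m, round=rnd, wins=wins[m], competed=competed[m])
            )

    ground_truth = {
        "ranks": ranks,
        "dominance": dict(zip(mice, dom.tolist())),
        "agg_propensity": dict(zip(mice, agg_prop.tolist())),
        "inv_propensity": dict(zip(mice, inv_prop.tolist())),
        "tube_latent": dict(zip(mice, tube_latent.tolist())),
        "received_attacks": received,
        "p_submit_given_attack": {
            f"day{d}": config.p_attack_response(strain, d) for d in config.scheme.days
        },
        "p_submit_given_investigation": {
            f"day{d}": config.p_investigation_response(strain, d)
            for d in config.scheme.days
        },
    }
    return SimCage(
        meta=meta,
        true_rank=ranks,
        events_continuous=events,
        events=observed,
        scans=scans,
        pals_grids=grids,
        tube_records=tube,
        morphometrics=morph,
        ofm=ofm,
        ground_truth=ground_truth,
    )


def simulate_study(config: SimConfig) -> tuple[list[SimCage], dict]:
    """Balanced 2 x 2 study: ``n_cages_per_arm`` cages per strain x size arm."""
    n_arms = len(config.strains) * len(config.group_sizes)
    cages = [
        simulate_cage(config, idx)
        for idx in range(config.n_cages_per_arm * n_arms)
    ]
    manifest = {
        "seed": config.seed,
        "n_cages": len(cages),
        "arms": [
            {"strain": s, "group_size": gs, "n": config.n_cages_per_arm}
            for s in config.strains
            for gs in config.group_sizes
        ],
        "config": _config_dict(config),
        "cage_seeds": {
            c.meta.cage_id: [config.seed, i] for i, c in enumerate(cages)
        },
    }
    return cages, manifest


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scheme"] = {
        "window_s": config.scheme.window_s,
        "period_s": config.scheme.period_s,
        "days": list(config.scheme.days),
    }
    for key in ("p_submit_given_attack", "p_submit_given_investigation"):
        d[key] = {
            (k if isinstance(k, str) else f"{k[0]}|{k[1]}"): v
            for k, v in d[key].items()
        }
    return d


def write_study(
    cages: Sequence[SimCage], manifest: dict, outdir: str | Path,
    include_continuous: bool = False,
) -> None:
    """Emit the CSV bundle consumed by the ingestion layer."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cages([c.meta for c in cages], out / "cages.csv")

    ev_frames, scan_frames = [], []
    for c in cages:
        for name, evs in (("events.csv", c.events),) + (
            (("events_continuous.csv", c.events_continuous),) if include_continuous else ()
        ):
            df = pd.DataFrame(
                [
                    {
                        "cage_id": c.meta.cage_id,
                        "day": e.day,
                        "t": e.t,
                        "actor": e.actor,
                        "recipient": e.recipient,
                        "category": e.category.value,
                        "subtype": e.subtype,
                    }
                    for e in evs
                ]
            )
            df["_file"] = name
            ev_frames.append(df)
        scan_frames.append(
            pd.DataFrame(
                [
                    {
                        "cage_id": c.meta.cage_id,
                        "day": s.day,
                        "t": s.t,
                        "mouse": s.mouse,
                        "state": s.state.value,
                        "row": s.cell[0],
                        "col": s.cell[1],
                    }
                    for s in c.scans
                ]
            )
        )
    ev_all = pd.concat(ev_frames, ignore_index=True)
    for name, grp in ev_all.groupby("_file"):
        grp.drop(columns="_file").to_csv(out / name, index=False)
    pd.concat(scan_frames, ignore_index=True).to_csv(out / "scans.csv", index=False)

    pd.DataFrame(
        [
            {
                "cage_id": c.meta.cage_id,
                "mouse": g.mouse,
                "row": r + 1,
                "col": cc + 1,
                "severity": int(g.severity[r, cc]),
                "area_pct": float(g.area_pct[r, cc]),
            }
            for c in cages
            for g in c.pals_grids
            for r in range(GRID_SIZE)
            for cc in range(GRID_SIZE)
            if g.severity[r, cc] > 0
        ],
        columns=["cage_id", "mouse", "row", "col", "severity", "area_pct"],
    ).to_csv(out / "pals_grids.csv", index=False)

    pd.DataFrame(
        [
            {
                "cage_id": c.meta.cage_id,
                "mouse": t.mouse,
                "round": t.round,
                "wins": t.wins,
                "competed": t.competed,
            }
            for c in cages
            for t in c.tube_records
        ]
    ).to_csv(out / "tube_trials.csv", index=False)

    pd.DataFrame(
        [
            {
                "cage_id": c.meta.cage_id,
                "mouse": m.mouse,
                "preputial_mg": m.preputial_mg,
                "body_length_mm": m.body_length_mm,
                "darcin_lfq": m.darcin_lfq if m.darcin_lfq is not None else np.nan,
            }
            for c in cages
            for m in c.morphometrics
        ]
    ).to_csv(out / "morphometrics.csv", index=False)

    pd.DataFrame(
        [
            {
                "cage_id": c.meta.cage_id,
                "mouse": o.mouse,
                "distance_cm": o.distance_cm,
                "center_pct": o.center_pct,
                "boli": o.boli,
            }
            for c in cages
            for o in c.ofm
        ]
    ).to_csv(out / "ofm.csv", index=False)

    truth = {c.meta.cage_id: c.ground_truth for c in cages}
    with open(out / "manifest.json", "w") as fh:
        json.dump({"manifest": manifest, "ground_truth": truth}, fh, indent=1)


def study_measure_table(cages: Sequence[SimCage], glicko_config=None) -> pd.DataFrame:
    """Per-mouse measure table for the validity stage, straight from
    simulated cages: phenotype scores plus both Glicko net changes."""
    from .glicko import GlickoConfig, glicko_variants
    from .phenotypes import pals_region_scores, preputial_ratio, tube_test_score

    glicko_config = glicko_config or GlickoConfig()
    rows = []
    for cage in cages:
        nets = glicko_variants(cage.events, cage.meta.mouse_ids, glicko_config)
        grids = {g.mouse: g for g in cage.pals_grids}
        morphs = {m.mouse: m for m in cage.morphometrics}
        ofms = {o.mouse: o for o in cage.ofm}
        tube = {}
        for t in cage.tube_records:
            tube.setdefault(t.mouse, {})[t.round] = tube_test_score(t)
        for mouse in cage.meta.mouse_ids:
            m = morphs[mouse]
            o = ofms[mouse]
            rows.append(
                {
                    "cage_id": cage.meta.cage_id,
                    "mouse": mouse,
                    "strain": cage.meta.strain.value,
                    "group_size": cage.meta.group_size,
                    "darcin": np.nan if m.darcin_lfq is None else m.darcin_lfq,
                    "preputial_ratio": preputial_ratio(m),
                    "posterior_pals": pals_region_scores(grids[mouse])["posterior"],
                    "tube_r1": tube[mouse][1],
                    "tube_r2": tube[mouse][2],
                    "tube_r3": tube[mouse][3],
                    "ofm_distance_cm": o.distance_cm,
                    "ofm_center_pct": o.center_pct,
                    "ofm_boli": o.boli,
                    "glicko_agg_net": nets["glicko_agg"][mouse],
                    "glicko_sub_net": nets["glicko_sub"][mouse],
                }
            )
    return pd.DataFrame(rows)


def simulate_measure_table(
    config: SimConfig, n_cages: int = 19, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fast phenotype-only study: the dominant/subordinate measure table.

    Generates one dominant (rank 1) and one subordinate (rank n) row per
    cage directly from the phenotype model, skipping event streams.  Used
    for replicate-heavy structure-recovery checks where the factor analysis
    is the object under test; the full :func:`simulate_cage` path feeds the
    same model through Glicko-based selection.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    rho = config.tube_coupling
    for c in range(n_cages):
        strain = config.strains[c % 2]
        gs = config.group_sizes[(c // 2) % 2]
        strain_b = 1.0 if strain == Strain.ALBINO_B6.value else 0.0
        for role, dom in (("dominant", 1.0), ("subordinate", 0.0)):
            dom_z = 1.0 if role == "dominant" else -1.0
            darcin = (
                config.beta_darcin * strain_b
                + config.gamma_darcin * dom
                + rng.normal(0, config.sd_darcin)
            )
            if rng.random() < config.darcin_missing_p:
                darcin = np.nan
            ratio = (
                0.5
                + config.beta_preputial * strain_b
                + config.gamma_preputial * dom
                + rng.normal(0, config.sd_preputial)
            )
            # subordinates accumulate the wounds
            received = rng.poisson(2.0 + 10.0 * (1 - dom))
            pals = (
                config.pals_per_attack * received
                + config.beta_pals * (1 - strain_b)
                + rng.normal(0, 1.0)
            )
            tube_latent = rho * dom_z + np.sqrt(max(0.0, 1 - rho * rho)) * rng.normal()
            n_trials = (gs - 1) * config.tube_replicates
            tube_scores = {}
            for rnd in range(1, config.tube_rounds + 1):
                p_win = expit(config.tube_discrimination * tube_latent)
                tube_scores[f"tube_r{rnd}"] = (
                    rng.binomial(n_trials, p_win * (1 - config.p_tube_timeout))
                    / n_trials
                )
            rows.append(
                {
                    "cage_id": f"C{c:03d}",
                    "mouse": f"C{c:03d}_{role[:3]}",
                    "role": role,
                    "strain": strain,
                    "group_size": gs,
                    "darcin": darcin,
                    "preputial_ratio": ratio,
                    "posterior_pals": max(0.0, pals),
                    **tube_scores,
                    "glicko_sub_net": 120.0 * dom_z + rng.normal(0, 20.0),
                    "glicko_agg_net": 130.0 * dom_z + rng.normal(0, 25.0),
                }
            )
    return pd.DataFrame(rows)
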