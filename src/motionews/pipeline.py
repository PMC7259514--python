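"""End-to-end orchestration: simulate -> EWS -> detect -> fit -> associate.

Two entry points mirror the two study designs the package emulates.
``run_experiment1`` generates blocks of synthetic attacker/defender
motion-capture trials, extracts first-PC velocity, computes windowed
EWS statistics and onset times, fits the variance-divergence power law
on block-averaged curves, and regresses onset times on EWS times.
``run_experiment3`` generates matched fold / step-control dot
trajectories, measures per-arm EWS detection rates before the
transition, and compares simulated-observer reaction times.  Reports
are plain dictionaries (JSON-serializable) carrying the config hash and
all seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from motionews.foldsim import SimConfig, generate_exp3_ensemble, simulate_fold_exp3
from motionews.synthetic_motion import MotionConfig, generate_block
from motionews.ews import (
    WindowSpec,
    compute_ews,
    detect_ar1_rise,
    detect_tau_rise,
    detect_var_rise,
)
from motionews.kinematics import (
    first_pc,
    center_of_mass,
    detect_onset,
    blocker_response,
    velocity,
)
from motionews.scaling import (
    baseline_max_threshold,
    extract_divergence_curve,
    average_block_curves,
    fit_powerlaw,
    median_exponent,
)
from motionews.stats import delta_regression, rt_compare

logger = logging.getLogger("motionews")

__all__ = ["RunConfig", "run_experiment1", "run_experiment3", "variance_scaling_study"]

REPORT_SCHEMA = "motionews-report-1"


@dataclass(frozen=True)
class RunConfig:
    """One config for an end-to-end run; every threshold surfaced.

    ``var_threshold`` is unit-bearing (squared signal units of the
    analyzed velocity); set it to None to derive the threshold from the
    early-trial variance ceiling instead (the rule used for signals
    whose units carry no absolute calibration).
    """

    motion: MotionConfig = field(default_factory=MotionConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    window_ms: float = 60.0
    scaling_window_ms: tuple[float, ...] = (40.0, 48.0, 60.0)
    subwindow_ms: float = 48.0
    offset_ms: float = 4.0
    ar1_threshold: float = 0.1
    tau_fold_change: float = 0.20
    var_threshold: Optional[float] = 1.5e-4
    onset_threshold: float = 0.05
    coverage: float = 0.81
    blocker_min_ews_s: float = 0.2
    block_size: int = 30
    n_blocks: int = 3
    exp3_n_per_arm: int = 100
    exp3_window_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ar1_threshold", "tau_fold_change", "onset_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.var_threshold is not None and self.var_threshold <= 0:
            raise ValueError("var_threshold must be positive or None")

    def sha1(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _detected_direction(trial) -> int:
    """Reach direction from the finger's net displacement along the axis."""
    f = trial.pos["finger"][:, 0]
    return 1 if f[-1] - f[0] >= 0 else -1


def analyze_trial(trial, cfg: RunConfig) -> dict:
    """Kinematics + EWS for one motion-capture trial.

    The first-PC score is rescaled by 1/sqrt(n_body_sensors) so that in
    the equal-loading regime its units match a single sensor's cm (and
    its velocity the cm/s of the onset rule and variance threshold).
    """
    rate = trial.rate
    pc = first_pc(trial)
    n_body = len(pc.sensors)
    proj = pc.projection / np.sqrt(n_body)
    v = velocity(proj, rate)
    w = WindowSpec(length_ms=cfg.window_ms, rate=rate)
    s = compute_ews(v, w, t0=float(trial.t[1]))
    com = center_of_mass(trial)
    direction = _detected_direction(trial)
    return {
        "ews": s,
        "percent": pc.percent,
        "ar1_rise": detect_ar1_rise(s, cfg.ar1_threshold),
        "tau_rise": detect_tau_rise(s, cfg.tau_fold_change),
        "var_rise": detect_var_rise(s, cfg.var_threshold)
        if cfg.var_threshold is not None
        else None,
        "body_onset": detect_onset(com, rate, cfg.onset_threshold),
        "finger_onset": detect_onset(trial.pos["finger"], rate, cfg.onset_threshold),
        "blocker_onset": blocker_response(
            trial.blocker_finger, direction, rate, cfg.onset_threshold
        ),
        "direction": direction,
        "truth": trial.truth,
    }


def _delta_or_none(ews_times, onset_times, coverage, min_ews=None):
    try:
        d = delta_regression(ews_times, onset_times, coverage, min_ews)
    except ValueError as exc:
        logger.warning("delta regression skipped: %s", exc)
        return None
    return {
        "slope": d.slope,
        "intercept_ms": d.intercept_ms,
        "intercept_se_ms": d.intercept_se,
        "mean_diff_ms": d.mean_diff_ms,
        "retained_fraction": d.retained_fraction,
        "n_used": d.n_used,
    }


def run_experiment1(cfg: RunConfig) -> dict:
    """Full synthetic motion-capture analysis; returns a JSON-able report."""
    mcfg = (
        cfg.motion
        if cfg.motion.seed is not None
        else replace(cfg.motion, seed=cfg.seed)
    )
    n_trials = cfg.n_blocks * cfg.block_size
    logger.info(
        "experiment 1: %d blocks x %d trials", cfg.n_blocks, cfg.block_size
    )
    trials = generate_block(mcfg, n_trials)
    results = [analyze_trial(tr, cfg) for tr in trials]

    finger = [r["finger_onset"] for r in results]
    body = [r["body_onset"] for r in results]
    blocker = [r["blocker_onset"] for r in results]
    com_leads = [
        (f - b) * 1000.0
        for f, b in zip(finger, body)
        if f is not None and b is not None
    ]

    deltas = {}
    for name in ("ar1_rise", "tau_rise", "var_rise"):
        ews_times = [r[name] for r in results]
        deltas[f"attacker_{name}"] = _delta_or_none(
            ews_times, finger, cfg.coverage
        )
        deltas[f"blocker_{name}"] = _delta_or_none(
            ews_times, blocker, cfg.coverage, cfg.blocker_min_ews_s
        )

    # variance-divergence scaling on block-averaged curves, per window size
    rate = trials[0].rate
    fits_all = []
    scaling_report = {}
    for wms in cfg.scaling_window_ms:
        w = WindowSpec(length_ms=wms, rate=rate)
        series = []
        for tr in trials:
            pc = first_pc(tr)
            proj = pc.projection / np.sqrt(len(pc.sensors))
            v = velocity(proj, rate)
            series.append(compute_ews(v, w, t0=float(tr.t[1])))
        thr = (
            cfg.var_threshold
            if cfg.var_threshold is not None
            else baseline_max_threshold(series)
        )
        curves = [extract_divergence_curve(s, thr) for s in series]
        try:
            avg, n_excl = average_block_curves(curves, cfg.block_size)
        except ValueError as exc:
            logger.warning("scaling skipped at %g ms: %s", wms, exc)
            continue
        fits = []
        for c in avg:
            try:
                fits.append(fit_powerlaw(c, cfg.subwindow_ms, cfg.offset_ms))
            except RuntimeError as exc:
                logger.warning("power-law fit failed: %s", exc)
        fits_all.extend(fits)
        scaling_report[f"{wms:g}ms"] = {
            "n_curves": len(avg),
            "n_trials_without_divergence": n_excl,
            "exponents": [f.n for f in fits],
        }

    report = {
        "schema": REPORT_SCHEMA,
        "experiment": 1,
        "config_sha1": cfg.sha1(),
        "seed": cfg.seed,
        "n_trials": n_trials,
        "counts": {
            "finger_onset": sum(f is not None for f in finger),
            "body_onset": sum(b is not None for b in body),
            "blocker_onset": sum(b is not None for b in blocker),
            "ar1_rise": sum(r["ar1_rise"] is not None for r in results),
            "tau_rise": sum(r["tau_rise"] is not None for r in results),
            "var_rise": sum(r["var_rise"] is not None for r in results),
        },
        "mean_com_lead_ms": float(np.mean(com_leads)) if com_leads else None,
        "com_lead_se_ms": float(np.std(com_leads, ddof=1) / np.sqrt(len(com_leads)))
        if len(com_leads) > 1
        else None,
        "delta_regressions": deltas,
        "scaling": scaling_report,
        "median_exponent": None,
        "mean_pc_percent": _mean_percent(results),
    }
    if fits_all:
        try:
            report["median_exponent"] = median_exponent(fits_all)
        except ValueError:
            pass
    return _jsonable(report)


def _mean_percent(results) -> dict:
    keys = results[0]["percent"].keys()
    return {
        k: float(np.mean([r["percent"][k] for r in results])) for k in keys
    }


def variance_scaling_study(
    sim: SimConfig,
    n_replicates: int = 10,
    n_per_replicate: int = 300,
    window_sizes_ms: tuple[float, ...] = (40.0, 48.0, 60.0),
    block_size: int = 30,
    subwindow_ms: float = 48.0,
    offset_ms: float = 4.0,
    seed: int = 0,
) -> dict:
    """Estimate the variance-divergence exponent of the fold simulation.

    Runs independent replicates of ``n_per_replicate`` fold
    trajectories (each replicate mirrors one participant-scale
    ensemble and derives its own divergence threshold from its
    early-trial variance ceiling), extracts the +-100 ms curves around
    each divergence, averages them in blocks synchronized on the
    divergence point, fits the power law on 48 ms / 4 ms sub-windows,
    and pools the fitted exponents across replicates and window sizes.
    Returns the pooled median over fits with |n| < 1.5, plus
    per-replicate medians and bookkeeping counts.
    """
    rate = 1.0 / sim.dt
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    fits_all = []
    rep_medians = []
    n_no_divergence = 0
    for rs in rep_seeds:
        children = np.random.SeedSequence(int(rs)).spawn(n_per_replicate)
        trajs = [
            simulate_fold_exp3(replace(sim, seed=None), rng=np.random.default_rng(c))
            for c in children
        ]
        rep_fits = []
        for wms in window_sizes_ms:
            w = WindowSpec(length_ms=wms, rate=rate)
            series = [compute_ews(tr.x, w) for tr in trajs]
            thr = baseline_max_threshold(series)
            curves = [extract_divergence_curve(s, thr) for s in series]
            avg, n_excl = average_block_curves(curves, block_size)
            n_no_divergence += n_excl
            for c in avg:
                try:
                    rep_fits.append(fit_powerlaw(c, subwindow_ms, offset_ms))
                except RuntimeError as exc:
                    logger.warning("power-law fit failed: %s", exc)
        fits_all.extend(rep_fits)
        try:
            rep_medians.append(median_exponent(rep_fits))
        except ValueError:
            rep_medians.append(float("nan"))
    return {
        "median_exponent": median_exponent(fits_all),
        "replicate_medians": rep_medians,
        "n_fits": len(fits_all),
        "n_trajectories": n_replicates * n_per_replicate,
        "n_trials_without_divergence": n_no_divergence,
    }


def run_experiment3(cfg: RunConfig) -> dict:
    """Matched fold vs step-control dot ensembles; rates and observer RTs."""
    if cfg.exp3_n_per_arm < 1:
        raise ValueError("exp3_n_per_arm must be at least 1")
    sim = cfg.sim if cfg.sim.seed is not None else replace(cfg.sim, seed=cfg.seed)
    logger.info("experiment 3: %d trajectories per arm", cfg.exp3_n_per_arm)
    pairs = generate_exp3_ensemble(sim, cfg.exp3_n_per_arm)
    rate = 1.0 / sim.dt
    w = WindowSpec(length_ms=cfg.exp3_window_ms, rate=rate)

    half_w = cfg.exp3_window_ms / 2000.0

    def arm_stats(trajs):
        pre_rates = {"ar1": 0, "tau": 0}
        rts = []
        for tr in trajs:
            s = compute_ews(tr.x, w)
            t_ar1 = detect_ar1_rise(s, cfg.ar1_threshold)
            t_tau = detect_tau_rise(s, cfg.tau_fold_change)
            # a detection counts as pre-transition only if its window
            # lies wholly before t*: centered windows otherwise leak
            # the transition itself half a window backward
            cut = tr.tstar_true - half_w
            pre_rates["ar1"] += t_ar1 is not None and t_ar1 < cut
            pre_rates["tau"] += t_tau is not None and t_tau < cut
            # simulated observer: directional motion evident at half plateau
            idx = np.flatnonzero(np.abs(tr.x) > sim.a / 2.0)
            if idx.size:
                rts.append(float(tr.t[idx[0]] * 1000.0))
        n = len(trajs)
        return {k: v / n for k, v in pre_rates.items()}, rts

    fold_rates, fold_rts = arm_stats([p[0] for p in pairs])
    ctrl_rates, ctrl_rts = arm_stats([p[1] for p in pairs])
    rt = None
    if len(fold_rts) >= 5 and len(ctrl_rts) >= 5:
        c = rt_compare(fold_rts, ctrl_rts)
        rt = {
            "u_stat": c.u_stat,
            "p_mw": c.p_mw,
            "effect_size": c.effect_size,
            "ks_stat": c.ks_stat,
            "p_ks": c.p_ks,
            "decile_diffs_ms": c.decile_diffs,
            "mean_diff_ms": float(np.mean(ctrl_rts) - np.mean(fold_rts)),
        }
    report = {
        "schema": REPORT_SCHEMA,
        "experiment": 3,
        "config_sha1": cfg.sha1(),
        "seed": cfg.seed,
        "n_per_arm": cfg.exp3_n_per_arm,
        "pre_transition_detection_rates": {
            "fold": fold_rates,
            "control": ctrl_rates,
        },
        "observer_rt": rt,
    }
    return _jsonable(report)
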