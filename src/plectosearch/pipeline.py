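"""End-to-end pipeline: ensemble generation through search kinetics.

Runs the full desk-scale analysis chain -- minicircle ensembles, topology
census, juxtaposition analysis, proxy-walker traces, transport-mode and
D1 analysis, twist-propagation landscape, and the MFPT/kMC search model --
and writes TSV tables plus one summary JSON with all seeds logged.  Any
stage failure aborts with the stage name; tables already written are
retained for inspection.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, juxtaposition, kinetics, topology, twistprop
from .chain import SimParams
from .config import RunConfig, dump_config
from .montecarlo import ensemble
from .walker import WalkerParams, simulate_walker


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage


def pipeline_run(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to
    ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config_resolved.yaml")
    summary: dict = {"seed": config.seed}

    stage = "ensemble"
    try:
        params = SimParams(
            bending_persistence=config.chain.bending_persistence,
            torsional_persistence=config.chain.torsional_persistence,
            temperature=config.chain.temperature,
            excluded_diameter=config.chain.excluded_diameter,
            box_edge=config.chain.box_edge,
            n_steps=config.chain.n_steps,
            frame_interval=config.chain.frame_interval,
            seed=config.seed,
        )
        ens = ensemble(config.chain.n_bp, config.chain.delta_lk, params,
                       config.chain.n_replicas)
        summary["ensemble_seeds"] = {
            str(dlk): [t.params.seed for t in trajs]
            for dlk, trajs in ens.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "topology_census"
    try:
        rows = []
        detections: dict = {}
        for dlk, trajs in ens.items():
            detections[dlk] = []
            for rep, traj in enumerate(trajs):
                det = juxtaposition.detect_trajectory(
                    traj, config.jp.n_c, config.jp.d_cutoff)
                detections[dlk].append(det)
                for k, frame in enumerate(traj.frames):
                    rep_t = topology.topology_report(frame, det[k],
                                                     delta_lk=dlk)
                    rows.append({
                        "delta_lk": dlk, "replica": rep, "frame": k,
                        "tw": rep_t.tw, "wr": rep_t.wr, "lk": rep_t.lk,
                        "sigma": rep_t.sigma, "rg": rep_t.rg,
                        "ellipticity": rep_t.ellipticity,
                        "n_jp": len(det[k]),
                        "shape": rep_t.shape_class,
                    })
        topo = pd.DataFrame(rows)
        topo.to_csv(out / "topology.tsv", sep="\t", index=False)
        census = (topo.groupby(["delta_lk", "shape"]).size()
                  / topo.groupby("delta_lk").size())
        summary["shape_census"] = {
            f"{dlk}:{shape}": float(v)
            for (dlk, shape), v in census.items()}
        summary["mean_abs_writhe"] = {
            str(d): float(v)
            for d, v in topo.groupby("delta_lk")["wr"]
                            .apply(lambda s: s.abs().mean()).items()}
        summary["mean_rg"] = {
            str(d): float(v)
            for d, v in topo.groupby("delta_lk")["rg"].mean().items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "juxtaposition"
    try:
        jp_rows = []
        for dlk, dets in detections.items():
            for rep, det in enumerate(dets):
                series = juxtaposition.track_jp_positions(
                    det, config.chain.n_bp, config.jp.link_threshold)
                for s in series:
                    jp_rows.append({
                        "delta_lk": dlk, "replica": rep,
                        "length": len(s),
                        "begin_first": s.begin_bp[0],
                        "end_first": s.end_bp[0],
                    })
        pd.DataFrame(jp_rows).to_csv(out / "jp_series.tsv", sep="\t",
                                     index=False)
        summary["mean_jp_count"] = {
            str(dlk): float(np.mean([len(d) for det in dets for d in det]))
            for dlk, dets in detections.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "walker"
    try:
        wp = WalkerParams(
            contact_strength=config.walker.contact_strength,
            screening_length=config.walker.screening_length,
            slide_step=config.walker.slide_step,
            hop_rate=config.walker.hop_rate,
            detach_rate=config.walker.detach_rate,
            jump_rate_at_jp=config.walker.jump_rate_at_jp,
            groove_coupling=config.walker.groove_coupling,
            steps_per_frame=config.walker.steps_per_frame,
            seed=config.seed + 1,
        )
        th = dynamics.ModeThresholds(
            r_slide=config.modes.r_slide, r_hop=config.modes.r_hop,
            rebind_window=config.modes.rebind_window,
            jump_sep=config.modes.jump_sep,
            jump_spatial_max=config.modes.jump_spatial_max)
        walk_stats = {}
        for dlk, trajs in ens.items():
            walk = simulate_walker(trajs[0], wp, config.jp.n_c,
                                   config.jp.d_cutoff)
            labels = dynamics.classify_frames(walk, th)
            prop = dynamics.mode_propensities(labels)
            try:
                d1 = dynamics.msd_d1(walk, labels).d1
            except ValueError:
                d1 = float("nan")
            walk_stats[str(dlk)] = {
                "propensities": prop,
                "d1_bp2_per_frame": d1,
                "n_unique_intersegmental":
                    dynamics.count_unique_intersegmental(labels,
                                                         walk.bp_index),
                "scanned_fraction_by_transfer":
                    dynamics.scanned_fraction_by_transfer(labels,
                                                          walk.bp_index),
            }
        summary["walker"] = walk_stats
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "twist_propagation"
    try:
        tp_stats = {}
        for dlk, trajs in ens.items():
            if len(trajs) >= 2 and min(len(t) for t in trajs) >= 100:
                land = twistprop.twist_autocorrelation(
                    trajs, max_lag=config.twistprop.max_lag,
                    c_thresh=config.twistprop.c_thresh)
                tp_stats[str(dlk)] = {
                    "mean_boundary_lag": float(land.boundary.mean())}
        summary["twist_propagation"] = tp_stats
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "search_kinetics"
    try:
        model = kinetics.SearchModel(
            L=config.search.L, k_on=config.search.k_on,
            k_off=config.search.k_off, u=config.search.u,
            k_t=config.search.k_t, target=config.search.target)
        curve = kinetics.ratio_curve(model)
        summary["t_ratio_vs_n_jp"] = {str(n): r for n, r in curve}
        one_jp = replace(model,
                         jp_links=kinetics.figure_layouts(model.L)[1])
        km = kinetics.kmc_fpt(one_jp, n_walkers=config.search.kmc_walkers,
                              seed=config.seed + 2)
        summary["kmc_mean_fpt_1jp"] = km.mean
        summary["kmc_stderr_1jp"] = km.stderr
        summary["analytic_mfpt_1jp"] = kinetics.mfpt_eq2(one_jp)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
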