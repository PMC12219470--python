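"""End-to-end orchestration: simulate -> detect -> register -> cross-talk ->
tracking -> spatial drift, with a reproducible manifest.

The dynamic channel's footprints and traces come straight from the
synthetic generator (matrix-factorization extraction is delegated to
external tools); the static channel is genuinely re-detected from a
rendered summary image and its traces are obtained by projecting the
noiseless synthetic scene onto the detected footprints, so detection,
registration and cross-talk estimation all run on estimated quantities.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, ExperimentConfig, load_config
from .core import DegenerateDataError
from .crosstalk import (
    CrosstalkEstimate,
    expected_crosstalk_ratio,
    fit_crosstalk,
    shuffled_null,
    summarize_crosstalk,
)
from .footprints import DetectionParams, detect_cells
from .registration import (
    GCAMP,
    STATIC,
    MatchPairs,
    match_centroids,
    propagate_gcamp_map,
    register_cross_channel,
    register_cross_session,
)
from .spatial import (
    normalized_rate_map,
    compute_rate_map,
    place_cell_test,
    pv_correlation,
    segment_trajectory,
)
from .synthetic import SyntheticSession, render_static_summary, simulate_experiment
from .tracking import (
    ActivityMatrix,
    build_activity_matrix,
    reactivation_rate,
    slope_vs_interval,
    tracking_probabilities,
)

__all__ = ["RunManifest", "run_full_analysis", "make_report"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    wall_time_s: float
    log: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "version": self.version,
                "outputs": self.outputs,
                "wall_time_s": round(self.wall_time_s, 3),
                "log": self.log,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _detection_params(ana: AnalysisConfig) -> DetectionParams:
    return DetectionParams(
        smoothing_sigma=ana.smoothing_sigma,
        min_distance=ana.min_distance,
        intensity_threshold=ana.threshold_quantile,
        radius_bounds=ana.radius_bounds,
        roundness_min=ana.roundness_min,
    )


def _project_onto_detections(
    detected, session: SyntheticSession
) -> np.ndarray:
    """Static traces for detected footprints via noiseless-scene projection.

    Equivalent to projecting the synthetic static movie onto the detected
    weights without materializing the movie: the projected trace is a
    footprint-overlap-weighted mixture of the planted per-cell traces.
    """
    src = session.footprints_static
    traces = session.static_traces.values
    out = np.zeros((len(detected), traces.shape[1]))
    for i, fp in enumerate(detected):
        total = fp.weights.sum()
        rows, cols = np.nonzero(fp.weights)
        w = fp.weights[rows, cols] / total
        for j, sfp in enumerate(src):
            overlap = sfp.weights[rows, cols]
            coef = float(w @ overlap)
            if coef > 0:
                out[i] += coef * traces[j]
    return out


def run_full_analysis(
    exp_cfg: ExperimentConfig | str | Path,
    ana_cfg: AnalysisConfig | None = None,
    out_dir: str | Path = "duoscope_results",
    spectra_paths: tuple[str, str, str] | None = None,
) -> RunManifest:
    """Run every stage on a simulated experiment and write result tables.

    ``exp_cfg`` may be an :class:`ExperimentConfig` or a YAML path with
    ``experiment:`` / ``analysis:`` sections. Deterministic for a fixed
    config: rerunning produces byte-identical CSVs.
    """
    t0 = time.monotonic()
    if not isinstance(exp_cfg, ExperimentConfig):
        exp_cfg, ana_cfg = load_config(exp_cfg)
    ana = ana_cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "t_s": round(time.monotonic() - t0, 2)})

    # ---- simulate -------------------------------------------------------
    stage("simulate")
    sessions, truth = simulate_experiment(exp_cfg)
    day_index = np.asarray(exp_cfg.day_indices)

    # ---- static-channel detection --------------------------------------
    stage("detect-static")
    params = _detection_params(ana)
    detected_static = []
    static_traces_det = []
    for ses in sessions:
        image = render_static_summary(ses, exp_cfg)
        fps_det = detect_cells(image, params)
        detected_static.append(fps_det)
        static_traces_det.append(_project_onto_detections(fps_det, ses))
    pd.DataFrame(
        {
            "session": range(exp_cfg.n_sessions),
            "n_planted": [exp_cfg.n_cells] * exp_cfg.n_sessions,
            "n_detected_static": [len(f) for f in detected_static],
            "n_gcamp": [len(s.footprints_gcamp) for s in sessions],
        }
    ).to_csv(out / "cell_counts.csv", index=False)

    # ---- registration ---------------------------------------------------
    stage("register")
    cross_channel: dict[int, MatchPairs] = {
        s: register_cross_channel(
            sessions[s].footprints_gcamp, detected_static[s], ana.max_dist_px
        )
        for s in range(exp_cfg.n_sessions)
    }
    static_map = register_cross_session(
        detected_static, ana.max_dist_px, day_index=day_index, channel=STATIC
    )
    full_map = propagate_gcamp_map(static_map, cross_channel)
    gcamp_map = register_cross_session(
        [s.footprints_gcamp for s in sessions], ana.max_dist_px,
        day_index=day_index, channel=GCAMP,
    )
    full_map.table.sort_values(["channel", "session", "local_index"]).to_csv(
        out / "registration_static_propagated.csv", index=False
    )
    gcamp_map.table.sort_values(["session", "local_index"]).to_csv(
        out / "registration_gcamp.csv", index=False
    )

    # ---- cross-talk -----------------------------------------------------
    stage("crosstalk")
    betas, null_rows = [], []
    for s, ses in enumerate(sessions):
        for ig, istatic, _ in cross_channel[s].pairs:
            g = ses.gcamp_fluor.values[ig]
            st = static_traces_det[s][istatic]
            try:
                betas.append(fit_crosstalk(g, st))
            except DegenerateDataError:
                continue
            null_rows.append(
                shuffled_null(
                    g, st, ana.n_crosstalk_shuffles,
                    seed=[11, exp_cfg.seed, s, ig],
                    min_shift_s=ana.crosstalk_min_shift_s, fps=exp_cfg.fps,
                )
            )
    expected = None
    if spectra_paths is not None:
        from .io import load_spectra_set

        expected = expected_crosstalk_ratio(load_spectra_set(*spectra_paths))
    est = CrosstalkEstimate(np.asarray(betas), np.asarray(null_rows), expected)
    summary = summarize_crosstalk(est)
    pd.DataFrame({"beta": est.coefficients,
                  "null_mean": est.null_coefficients.mean(axis=1)}).to_csv(
        out / "crosstalk_coefficients.csv", index=False, float_format=_FLOAT_FMT
    )
    with open(out / "crosstalk_summary.json", "w") as fh:
        json.dump(
            {
                "planted_alpha": truth.crosstalk_alpha,
                "observed_mean": summary.observed_mean,
                "observed_sd": summary.observed_sd,
                "null_mean": summary.null_mean,
                "null_sd": summary.null_sd,
                "paired_t": summary.paired_t,
                "paired_p": summary.paired_p,
                "one_sample_t": summary.one_sample_t,
                "one_sample_p": summary.one_sample_p,
                "expected_ratio": expected,
                "n_cells": int(est.coefficients.size),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    # ---- tracking probabilities ----------------------------------------
    stage("tracking")
    matrices: dict[str, ActivityMatrix] = {
        "gcamp": build_activity_matrix(gcamp_map, GCAMP),
        "static": build_activity_matrix(full_map, STATIC),
    }
    try:
        matrices["gcamp-stable"] = build_activity_matrix(
            full_map, GCAMP, subset=full_map.stable_ids
        )
    except DegenerateDataError:
        pass
    rows = []
    for name, am in matrices.items():
        pm = tracking_probabilities(am)
        rows += [
            {"inclusion": name, "m": m + 1, "p_m": pm[m]} for m in range(am.n_sessions)
        ]
    pd.DataFrame(rows).to_csv(out / "tracking_probability.csv", index=False,
                              float_format=_FLOAT_FMT)

    # ---- spatial: place cells per session ------------------------------
    stage("spatial")
    place_rows = []
    place_flags: list[np.ndarray] = []   # per session, per local gcamp cell
    norm_maps: list[np.ndarray] = []     # per session: (n_local, n_bins)
    for s, ses in enumerate(sessions):
        traj = segment_trajectory(
            ses.trajectory, ana.speed_threshold_cm_s,
            ana.speed_smooth_frames, ana.end_zone_cm,
        )
        n_local = ses.gcamp_events.n_cells
        flags = np.zeros(n_local, dtype=bool)
        maps = np.full((n_local, ana.n_spatial_bins), np.nan)
        for i in range(n_local):
            w = ses.gcamp_events.values[i]
            res = place_cell_test(
                w, traj,
                n_shuffles=ana.n_place_shuffles,
                percentile=ana.place_percentile,
                seed=[13, exp_cfg.seed, s, i],
                min_shift_s=ana.place_min_shift_s,
                bandwidth=ana.kde_bandwidth_cm,
                n_bins=ana.n_spatial_bins,
                occupancy_floor=ana.occupancy_floor,
            )
            flags[i] = res.is_place_cell
            if w.sum() > 0:
                rm = compute_rate_map(traj.linpos, w, ana.kde_bandwidth_cm,
                                      ana.n_spatial_bins, ana.occupancy_floor)
                maps[i] = normalized_rate_map(rm)
            place_rows.append(
                {
                    "session": s,
                    "local_index": i,
                    "spatial_information": res.spatial_information,
                    "stability": res.stability,
                    "si_p95": res.si_p95,
                    "stab_p95": res.stab_p95,
                    "is_place_cell": res.is_place_cell,
                    "silent": res.silent,
                }
            )
        place_flags.append(flags)
        norm_maps.append(maps)
    pd.DataFrame(place_rows).to_csv(out / "place_cells.csv", index=False,
                                    float_format=_FLOAT_FMT)

    # ---- drift: reactivation and PV correlation vs interval ------------
    stage("drift")
    inclusion_maps = {"all": gcamp_map, "stable": full_map}
    pc_gids = {}  # (inclusion, session) -> set of place-cell gids
    for name, rmap in inclusion_maps.items():
        for s in range(exp_cfg.n_sessions):
            l2g = rmap.local_to_global(s, GCAMP)
            gids = {g for loc, g in l2g.items() if place_flags[s][loc]}
            if name == "stable":
                gids &= set(full_map.stable_ids)
            pc_gids[(name, s)] = gids

    react_rows, pv_rows = [], []
    for name, rmap in inclusion_maps.items():
        am = build_activity_matrix(
            rmap, GCAMP,
            subset=full_map.stable_ids if name == "stable" else None,
        )
        gid_row = {g: i for i, g in enumerate(am.global_ids)}
        for a in range(exp_cfg.n_sessions):
            for b in range(a + 1, exp_cfg.n_sessions):
                interval = int(day_index[b] - day_index[a])
                pair_gids = sorted(pc_gids[(name, a)] | pc_gids[(name, b)])
                pair_rows = [gid_row[g] for g in pair_gids if g in gid_row]
                if len(pair_rows) >= 2:
                    sub = am.matrix[pair_rows][:, [a, b]]
                    n_a, n_b = sub[:, 0].sum(), sub[:, 1].sum()
                    n_2 = (sub[:, 0] & sub[:, 1]).sum()
                    if n_a and n_b:
                        react_rows.append(
                            {
                                "inclusion": name,
                                "session_a": a,
                                "session_b": b,
                                "interval_days": interval,
                                "n_cells": len(pair_rows),
                                "reactivation": 0.5 * (n_2 / n_a + n_2 / n_b),
                            }
                        )
                # population vectors
                l2g_a = rmap.local_to_global(a, GCAMP)
                l2g_b = rmap.local_to_global(b, GCAMP)
                g2l_a = {g: l for l, g in l2g_a.items()}
                g2l_b = {g: l for l, g in l2g_b.items()}
                n_pc = len(pair_gids)
                if n_pc < 2:
                    continue
                maps_a = np.full((n_pc, ana.n_spatial_bins), np.nan)
                maps_b = np.full((n_pc, ana.n_spatial_bins), np.nan)
                for i, g in enumerate(pair_gids):
                    if g in g2l_a:
                        maps_a[i] = norm_maps[a][g2l_a[g]]
                    if g in g2l_b:
                        maps_b[i] = norm_maps[b][g2l_b[g]]
                mode_list = (
                    [("all", "zero-fill"), ("all", "intersect"),
                     ("always-active", "intersect")]
                    if name == "all"
                    else [("stable", "zero-fill"), ("stable", "intersect")]
                )
                for inc_name, mode in mode_list:
                    try:
                        r = pv_correlation(maps_a, maps_b, mode=mode)
                    except DegenerateDataError:
                        continue
                    pv_rows.append(
                        {
                            "inclusion": inc_name,
                            "mode": mode,
                            "session_a": a,
                            "session_b": b,
                            "interval_days": interval,
                            "n_cells": n_pc,
                            "pv_correlation": r,
                        }
                    )
    react = pd.DataFrame(react_rows)
    pv = pd.DataFrame(pv_rows)
    react.to_csv(out / "reactivation.csv", index=False, float_format=_FLOAT_FMT)
    pv.to_csv(out / "pv_correlation.csv", index=False, float_format=_FLOAT_FMT)

    slope_rows = []
    for metric, df, col in (("reactivation", react, "reactivation"),
                            ("pv", pv, "pv_correlation")):
        if df.empty:
            continue
        keys = ["inclusion"] if metric == "reactivation" else ["inclusion", "mode"]
        for key, grp in df.groupby(keys):
            if grp["interval_days"].nunique() < 2 or len(grp) < 3:
                continue
            fit = slope_vs_interval(grp["interval_days"], grp[col])
            row = {"metric": metric, "slope": fit.slope, "intercept": fit.intercept,
                   "p_value": fit.p_value, "stderr": fit.stderr}
            for k, v in zip(keys, key if isinstance(key, tuple) else (key,)):
                row[k] = v
            slope_rows.append(row)
    pd.DataFrame(slope_rows).to_csv(out / "slopes.csv", index=False,
                                    float_format=_FLOAT_FMT)

    # ---- manifest -------------------------------------------------------
    stage("manifest")
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config={"experiment": exp_cfg.to_dict(), "analysis": ana.to_dict()},
        seeds={"experiment": exp_cfg.seed},
        version=__version__,
        outputs=outputs,
        wall_time_s=time.monotonic() - t0,
        log=log,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_report(results_dir: str | Path, report_dir: str | Path | None = None) -> list[Path]:
    """Render figures + per-figure CSVs from a results directory.

    Missing stage outputs are noted in ``report_notes.txt`` rather than
    raising; every plotted number is read back from the stage CSVs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    rep = Path(report_dir) if report_dir else res / "report"
    rep.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    notes: list[str] = []

    def _curve_panel(csv_name, value_col, group_cols, fname, ylabel):
        path = res / csv_name
        if not path.exists() or pd.read_csv(path).empty:
            notes.append(f"missing or empty {csv_name}; panel {fname} skipped")
            return
        df = pd.read_csv(path)
        agg = (
            df.groupby(group_cols + ["interval_days"])[value_col]
            .mean()
            .reset_index()
        )
        agg.to_csv(rep / f"{fname}.csv", index=False, float_format=_FLOAT_FMT)
        fig, ax = plt.subplots(figsize=(5, 4))
        for key, grp in agg.groupby(group_cols):
            label = key if isinstance(key, str) else "/".join(map(str, key))
            ax.plot(grp["interval_days"], grp[value_col], marker="o", label=label)
        ax.set_xlabel("interval (days)")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(rep / f"{fname}.png", dpi=120)
        plt.close(fig)
        written.extend([rep / f"{fname}.csv", rep / f"{fname}.png"])

    _curve_panel("reactivation.csv", "reactivation", ["inclusion"],
                 "reactivation_vs_interval", "reactivation rate")
    _curve_panel("pv_correlation.csv", "pv_correlation", ["inclusion", "mode"],
                 "pv_vs_interval", "PV correlation")

    tp = res / "tracking_probability.csv"
    if tp.exists():
        df = pd.read_csv(tp)
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, grp in df.groupby("inclusion"):
            ax.plot(grp["m"], grp["p_m"], marker="s", label=name)
        ax.set_xlabel("number of active sessions m")
        ax.set_ylabel("per-session probability p_m")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(rep / "tracking_probability.png", dpi=120)
        plt.close(fig)
        written.append(rep / "tracking_probability.png")
    else:
        notes.append("missing tracking_probability.csv")

    ct = res / "crosstalk_coefficients.csv"
    if ct.exists():
        df = pd.read_csv(ct)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.hist(df["beta"], bins=30, alpha=0.6, label="observed")
        ax.hist(df["null_mean"], bins=30, alpha=0.6, label="shuffled")
        ax.set_xlabel("cross-talk coefficient")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(rep / "crosstalk_distribution.png", dpi=120)
        plt.close(fig)
        written.append(rep / "crosstalk_distribution.png")
    else:
        notes.append("missing crosstalk_coefficients.csv")

    (rep / "report_notes.txt").write_text(
        "\n".join(notes) if notes else "all panels rendered\n"
    )
    written.append(rep / "report_notes.txt")
    return written
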