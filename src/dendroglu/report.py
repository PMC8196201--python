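"""Pipeline orchestration and run reports.

``run_pipeline`` executes detection -> mapping/classification ->
field-aligned pooling -> cluster analysis -> decoding on a session bundle
and assembles a ``RunReport``: a parameter echo, counts with 95% binomial
confidence intervals, test statistics, and the seeds used, all
reproducible from the stored intermediates.  Stage failures yield a
partial report with diagnostics rather than an exception.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import alignment as al
from . import clusters as cl
from . import detection as det
from . import mapping as mp
from .decoding import evaluate_decoder, train_decoder
from .session import AnalysisConfig, BehaviorSession, RoiTraceSet

__all__ = ["RunReport", "run_pipeline", "proportion_ci"]


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) binomial confidence interval."""
    if not (0 <= successes <= n):
        raise ValueError(f"successes={successes} outside [0, n={n}]")
    if n == 0:
        return 0.0, 1.0
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


@dataclass
class RunReport:
    """Per-stage results of one pipeline run."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "stages": self.stages, "errors": self.errors},
            indent=1, default=_jsonable))

    def summary(self) -> str:
        lines = [f"dendroglu run (seed={self.seed})"]
        for name, st in self.stages.items():
            keys = ", ".join(f"{k}={v}" for k, v in st.items()
                             if np.isscalar(v) or isinstance(v, (tuple, str)))
            lines.append(f"  [{name}] {keys}")
        for name, err in self.errors.items():
            lines.append(f"  [{name}] FAILED: {err.splitlines()[-1]}")
        return "\n".join(lines)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _stage(report: RunReport, name: str):
    def deco(fn):
        try:
            report.stages[name] = fn()
        except Exception:
            report.errors[name] = traceback.format_exc()
    return deco


def run_pipeline(
    behavior: BehaviorSession,
    traces: RoiTraceSet,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    out_dir=None,
) -> RunReport:
    """Full analysis of one session bundle; see the module docstring."""
    cfg = config or AnalysisConfig()
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    from . import __version__

    config_echo = cfg.to_dict()
    config_echo["dendroglu_version"] = __version__
    report = RunReport(config=config_echo, seed=seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    sub = traces.subtract_background()
    is_soma = (sub.roi_table["channel"] == "soma").to_numpy()
    dend = sub.select(~is_soma)
    soma = sub.select(is_soma) if is_soma.any() else None

    run_mask = det.run_period_mask(
        behavior, cfg.run_velocity_threshold, cfg.run_min_distance)
    state: dict = {}

    @_stage(report, "detect")
    def _detect():
        dff = det.compute_dff(dend, window_s=cfg.baseline_window_s,
                              percentile=cfg.baseline_percentile)
        excl = det.exclude_rois_and_frames(
            dend, dff, dim_threshold=cfg.dim_roi_counts,
            pos_std=cfg.frame_exclude_pos_std,
            neg_std=cfg.frame_exclude_neg_std)
        valid = run_mask & ~excl.frame_excluded
        keep = excl.valid_rois()
        model = det.fit_detection_model(
            det.DffTrace(dff.dff[:, keep], dff.baseline[:, keep],
                         dff.frame_rate, list(np.asarray(dff.roi_ids)[keep]),
                         dff.f0_invalid[keep]),
            valid=valid, config=cfg)
        events, sig_kept = model.detect(dff.dff[:, keep], valid=valid)
        sig = np.zeros_like(dff.dff)
        sig[:, keep] = sig_kept
        state.update(dff=dff, excl=excl, valid=valid, keep=keep,
                     model=model, events=events, sig=sig)
        n_sig = int(events["significant"].sum()) if len(events) else 0
        if out_dir is not None:
            events.to_csv(out_dir / "events.tsv", sep="\t", index=False)
        rates = det.input_rate_summary(sig, valid, dend.frame_rate)
        state["input_rates"] = rates
        return {
            "n_rois": int(dend.n_rois),
            "n_rois_excluded": int((~keep).sum()),
            "n_frames_excluded": int(excl.frame_excluded.sum()),
            "n_candidate_events": int(len(events)),
            "n_significant_events": n_sig,
            "mean_input_rate": float(np.nanmean(rates)) if rates.size else float("nan"),
        }

    @_stage(report, "classify_rois")
    def _classify():
        sig, valid, keep = state["sig"], state["valid"], state["keep"]
        labels, maps, fields = [], [], []
        for j in range(dend.n_rois):
            if not keep[j]:
                labels.append(None)
                maps.append(None)
                fields.append([])
                continue
            lab, smap = mp.classify_unit(
                sig[:, j], behavior, cfg.n_shuffles_roi,
                seed=int(rng.integers(2**31)), n_bins=cfg.n_bins,
                valid=valid, boxcar=cfg.boxcar_bins,
                activity_threshold=cfg.activity_threshold,
                shuffle_mode=cfg.shuffle_mode)
            labels.append(lab)
            maps.append(smap)
            fields.append(lab.fields)
        state.update(roi_labels=labels, roi_maps=maps, roi_fields=fields)
        names = [l.label for l in labels if l is not None]
        counts = {c: names.count(c) for c in ("place", "active_nonplace", "silent")}
        n = max(len(names), 1)
        cis = {c: proportion_ci(k, n) for c, k in counts.items()}
        if out_dir is not None:
            rows = []
            for j, lab in enumerate(labels):
                if lab is None:
                    continue
                for f in lab.fields:
                    rows.append((dend.roi_table.at[j, "roi_id"], f.start, f.end,
                                 f.peak_cm, f.width_cm, f.at_track_edge))
            pd.DataFrame(rows, columns=["roi_id", "start_bin", "end_bin",
                                        "peak_cm", "width_cm", "at_edge"]
                         ).to_csv(out_dir / "fields.tsv", sep="\t", index=False)
        return {"n_classified": len(names), "counts": counts,
                "ci95": {c: tuple(round(x, 4) for x in v) for c, v in cis.items()}}

    @_stage(report, "classify_somata")
    def _soma():
        if soma is None or soma.n_rois == 0:
            return {"n_cells": 0}
        dff = det.compute_dff(soma, window_s=cfg.baseline_window_s_soma,
                              percentile=cfg.baseline_percentile)
        model = det.fit_detection_model(dff, valid=run_mask, config=cfg)
        _, sig = model.detect(dff.dff, valid=run_mask)
        cells = {}
        for j in range(soma.n_rois):
            lab, smap = mp.classify_unit(
                sig[:, j], behavior, cfg.n_shuffles_soma,
                seed=int(rng.integers(2**31)), n_bins=cfg.n_bins,
                valid=run_mask, boxcar=cfg.boxcar_bins,
                activity_threshold=cfg.activity_threshold,
                shuffle_mode=cfg.shuffle_mode)
            cells[soma.roi_table.at[j, "cell_id"]] = (lab, smap)
        state["cells"] = cells
        names = [lab.label for lab, _ in cells.values()]
        return {"n_cells": len(names),
                "counts": {c: names.count(c)
                           for c in ("place", "active_nonplace", "silent")}}

    @_stage(report, "field_alignment")
    def _align():
        cells = state.get("cells", {})
        labels, maps = state["roi_labels"], state["roi_maps"]
        aligned = []
        for j, lab in enumerate(labels):
            if lab is None:
                continue
            cell = dend.roi_table.at[j, "cell_id"]
            if cell not in cells:
                continue
            soma_lab, _ = cells[cell]
            if soma_lab.label != "place":
                continue
            for f in soma_lab.fields:
                am = al.align_roi_map(maps[j], f)
                am.roi_class = lab.label
                am.roi_id = dend.roi_table.at[j, "roi_id"]
                aligned.append(am)
        if not aligned:
            return {"n_aligned_rois": 0}
        profile = al.total_input_profile(aligned, n_bins=min(
            40, max(4, sum(a.valid.sum() for a in aligned) // 20)))
        test = al.infield_outfield_test(profile)
        state["aligned"] = aligned
        return {"n_aligned_rois": len(aligned),
                "in_mean": round(test["in_mean"], 5),
                "out_mean": round(test["out_mean"], 5),
                "ranksum_p": round(test["p"], 5)}

    @_stage(report, "clusters")
    def _clusters():
        sig, keep = state["sig"], state["keep"]
        results = []
        n_in_clusters = 0
        n_considered = 0
        for branch, grp in dend.roi_table.groupby("branch_id", sort=False):
            cols = [j for j in grp.index if keep[j]]
            if not cols:
                continue
            order = sorted(cols, key=lambda j: dend.roi_table.at[j, "position_um"])
            A = det.bin_activity_matrix(sig[:, order], dend.frame_rate,
                                        cfg.coactivation_bin_s)
            try:
                est = cl.FunctionalClusterICA(
                    weight_threshold=cfg.ica_weight_threshold,
                    contributing_fraction=cfg.ica_contributing_fraction,
                    min_cluster_size=cfg.min_cluster_size,
                    random_state=int(rng.integers(2**31)),
                ).fit(A, branch_id=branch,
                      roi_ids=[dend.roi_table.at[j, "roi_id"] for j in order])
            except ValueError:
                continue   # branch below the active-ROI requirement
            ctrl = cl.cluster_shuffle_control(
                est, n_shuffles=cfg.n_shuffles_roi,
                seed=int(rng.integers(2**31)))
            results.append((branch, est, ctrl))
            n_considered += len(order)
            n_in_clusters += ctrl["original_rois_in_clusters"]
        state["cluster_results"] = results
        total_clusters = sum(len(e.clusters_) for _, e, _ in results)
        pct = 100.0 * n_in_clusters / n_considered if n_considered else float("nan")
        ci = (proportion_ci(n_in_clusters, n_considered)
              if n_considered else (float("nan"), float("nan")))
        return {"n_branches_analyzed": len(results),
                "n_clusters": total_clusters,
                "pct_rois_in_clusters": round(pct, 2),
                "pct_ci95": tuple(round(100 * x, 2) for x in ci)}

    @_stage(report, "decode")
    def _decode():
        sig, valid, keep = state["sig"], state["valid"], state["keep"]
        cols = np.flatnonzero(keep)
        if cols.size == 0:
            raise ValueError("no usable ROIs for decoding")
        model, test = train_decoder(
            sig[:, cols], behavior, split=0.8, n_bins=cfg.n_bins,
            dt=cfg.decoder_dt, rate_floor=cfg.rate_floor,
            occupancy_prior=cfg.occupancy_prior, valid=valid)
        res = evaluate_decoder(model, sig[:, cols], behavior, test, valid=valid)
        return {"n_windows": res["n_windows"],
                "median_error_cm": round(res["median_error_cm"], 2),
                "chance_median_error_cm": round(res["chance_median_error_cm"], 2)}

    if out_dir is not None:
        report.to_json(out_dir / "report.json")
        (out_dir / "report.txt").write_text(report.summary() + "\n")
    return report
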