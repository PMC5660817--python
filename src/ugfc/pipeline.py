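"""End-to-end detection cascade: enhance -> cluster -> refine (-> eval).

``run_pipeline`` executes the three stages in order on a gray image and
returns the final lesion mask plus a self-contained run report (effective
parameters, per-stage timings, clustering objective trace, level-set
iteration count).  The whole cascade is deterministic for a given image
and configuration.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import clustering, enhancement, levelset, metrics
from .config import PipelineConfig
from .errors import UGFCError

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    mask: np.ndarray
    metrics: metrics.MetricsRecord | None
    report: dict
    enhanced: np.ndarray
    roi: clustering.ROIMask | None
    state: clustering.ClusterState | None
    phi: np.ndarray | None


def run_pipeline(img: np.ndarray, cfg: PipelineConfig | None = None,
                 truth: np.ndarray | None = None) -> PipelineResult:
    """Run the full cascade on one image.

    With a ground-truth mask the overlap metrics are appended to the
    result.  An empty region of interest short-circuits refinement: the
    final mask is empty and the report carries ``empty_roi: True``.
    """
    if cfg is None:
        cfg = PipelineConfig()
    cfg.validate()
    img = np.asarray(img, dtype=float)
    report: dict = {"parameters": cfg.to_dict(), "timings": {}, "stages": []}

    t0 = time.perf_counter()
    if cfg.sets is not None:
        rules = enhancement.rule_base_from_knots(cfg.sets, L=cfg.levels)
    else:
        rules = enhancement.default_rule_base(L=cfg.levels)
    try:
        enhanced = enhancement.enhance_image(img, rules, float_output=True)
    except UGFCError as err:
        raise type(err)(f"enhancement stage: {err}") from err
    if cfg.levels != 256:
        # clustering operates on the 8-bit scale
        enhanced = enhanced / (cfg.levels - 1) * 255.0
    report["timings"]["enhance"] = time.perf_counter() - t0
    report["stages"].append("enhance")

    t0 = time.perf_counter()
    try:
        state = clustering.ugfc_cluster(
            enhanced, c=cfg.clusters, w=cfg.fuzzifier, rho=cfg.rho,
            theta_hard=cfg.theta_hard, gamma=cfg.gamma,
            max_iter=cfg.cluster_max_iter)
        roi = clustering.extract_roi(state, enhanced.shape, rule=cfg.roi_rule,
                                     exclude_border=cfg.exclude_border)
    except UGFCError as err:
        raise type(err)(f"clustering stage: {err}") from err
    report["timings"]["cluster"] = time.perf_counter() - t0
    report["stages"].append("cluster")
    report["cluster"] = {
        "iterations": state.t,
        "converged": state.converged,
        "centroids": state.centroids.tolist(),
        "masses": state.masses.tolist(),
        "objective_trace": [list(o) for o in state.objective_trace],
        "hard_count_trace": state.hard_count_trace,
        "selected_cluster": roi.selected_cluster,
    }

    if roi.empty:
        logger.warning("empty ROI; refinement skipped")
        report["empty_roi"] = True
        report["levelset"] = {"iterations": 0}
        rec = metrics.evaluate_masks(truth.astype(int), np.zeros_like(img, dtype=int)) \
            if truth is not None else None
        return PipelineResult(mask=np.zeros(img.shape, dtype=bool),
                              metrics=rec, report=report, enhanced=enhanced,
                              roi=roi, state=state, phi=None)
    report["empty_roi"] = False

    t0 = time.perf_counter()
    params = levelset.EvolutionParams(
        beta=cfg.beta, lambda_=cfg.lambda_, nu=cfg.nu, sigma=cfg.sigma,
        dt=cfg.dt, eps=cfg.eps, c0=cfg.c0, max_iter=cfg.iters,
        stop_tol=cfg.stop_tol, min_iter=cfg.min_iter)
    try:
        g = levelset.edge_indicator(enhanced, cfg.sigma)
        phi0 = levelset.init_phi(roi.mask, cfg.c0)
        phi, mask, n_iter = levelset.evolve(phi0, g, params)
    except UGFCError as err:
        raise type(err)(f"refinement stage: {err}") from err
    report["timings"]["refine"] = time.perf_counter() - t0
    report["stages"].append("refine")
    report["levelset"] = {"iterations": n_iter,
                          "final_internal_energy": levelset.internal_energy(phi)}

    rec = None
    if truth is not None:
        rec = metrics.evaluate_masks(np.asarray(truth).astype(int),
                                     mask.astype(int))
        report["metrics"] = rec.to_dict()
    return PipelineResult(mask=mask, metrics=rec, report=report,
                          enhanced=enhanced, roi=roi, state=state, phi=phi)


def fuzzifier_sweep(img: np.ndarray, truth: np.ndarray,
                    ws=(1.5, 1.6, 1.7, 1.8, 1.9),
                    cfg: PipelineConfig | None = None) -> dict[float, float]:
    """Segmentation Dice as a function of the fuzzifier w.

    Runs the full cascade once per value of ``w``, leaving every other
    parameter at its configured value; returns {w: dice}.
    """
    import dataclasses

    if cfg is None:
        cfg = PipelineConfig()
    out = {}
    for w in ws:
        res = run_pipeline(img, dataclasses.replace(cfg, fuzzifier=w),
                           truth=truth)
        out[float(w)] = res.metrics.dice
    return out


def write_trace_csv(state: clustering.ClusterState, path) -> None:
    """Dump the clustering trace: t, J_GC, J_CM, J_GFC, v_1..v_c, hard_count."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "J_GC", "J_CM", "J_GFC"]
                        + [f"v_{i + 1}" for i in range(state.c)]
                        + ["hard_count"])
        for t, (obj, v, hc) in enumerate(
                zip(state.objective_trace, state.centroid_trace,
                    state.hard_count_trace), start=1):
            writer.writerow([t, *obj, *v, hc])
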