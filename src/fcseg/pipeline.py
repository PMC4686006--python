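"""End-to-end segmentation pipeline.

Order of stages: monogenic signal (local phase) -> multi-scale feature
asymmetry + all-direction non-maximal suppression (edge map) -> feature-based
affinity -> absolute fuzzy connectedness from the seeds -> threshold ->
shape-based gap completion -> mean curvature flow regularisation.  Every
stage is deterministic, so rerunning with identical inputs gives
bit-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .completion import complete_object
from .features import FAParams, feature_asymmetry, modified_nms
from .fuzzyconn import (
    AffinityParams,
    ConnectivityMap,
    afc_connectivity,
    affinity,
    fit_object_stats,
    threshold_segmentation,
)
from .monogenic import BandpassSpec, PhaseMaps, monogenic_signal, phase_maps
from .regularise import MCFParams, mcf_smooth

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

#: seed counts beyond this trigger a warning (typical usage is 1-5 seeds)
MAX_TYPICAL_SEEDS = 5


@dataclass
class PipelineResult:
    """Final mask plus every intermediate of the pipeline."""

    mask: np.ndarray
    phase: PhaseMaps
    fa: np.ndarray
    edge: np.ndarray
    connectivity: ConnectivityMap
    fc_mask: np.ndarray  # thresholded connectivity, before completion
    completed_mask: np.ndarray  # after gap filling, before smoothing
    params: AffinityParams  # affinity parameters actually used
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    image: np.ndarray,
    seeds: list[tuple[int, int]],
    config: PipelineConfig | None = None,
    *,
    train_roi: np.ndarray | None = None,
) -> PipelineResult:
    """Segment `image` from `seeds` with the full feature-based pipeline.

    `train_roi` optionally refits the object phase statistics (m_o, sigma_o)
    from a region known to lie inside the object, mirroring the method's
    one-off training stage; otherwise the configured values are used.
    """
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image, dtype=float)
    rows, cols = image.shape
    for seed in seeds:
        if not (0 <= seed[0] < rows and 0 <= seed[1] < cols):
            raise ValueError(f"seed {seed} outside image of shape {image.shape}")
    if len(seeds) > MAX_TYPICAL_SEEDS:
        logger.warning("using %d seeds; typical usage is 1-%d", len(seeds), MAX_TYPICAL_SEEDS)

    timings: dict[str, float] = {}

    def _timed(stage: str, fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        timings[stage] = time.perf_counter() - start
        logger.info("stage %-12s %.3f s", stage, timings[stage])
        return out

    # local phase at the structure scale
    spec = BandpassSpec(config.phase.sigma)
    resp = _timed("monogenic", monogenic_signal, image, spec, padding=config.phase.padding)
    phase = phase_maps(resp, convention=config.phase.convention)

    # multi-scale edge map
    fa_params = FAParams(
        scales=tuple(BandpassSpec(s) for s in config.fa.scales),
        Ts=config.fa.Ts,
        epsilon=config.fa.epsilon,
        padding=config.phase.padding,
    )
    fa = _timed("features", feature_asymmetry, image, fa_params)
    edge = _timed("nms", modified_nms, fa, config.fa.nms_directions)

    # affinity and fuzzy connectedness
    m_o, sigma_o = config.fc.m_o, config.fc.sigma_o
    if train_roi is not None:
        m_o, sigma_o = fit_object_stats(phase.phase, train_roi)
        logger.info("trained object stats: m_o=%.4f sigma_o=%.4f", m_o, sigma_o)
    aff_params = AffinityParams(
        omega1=config.fc.omega1,
        omega2=config.fc.omega2,
        m_o=m_o,
        sigma_o=sigma_o,
        pair_edge=config.fc.pair_edge,
    )
    field_ = _timed("affinity", affinity, phase.phase, edge, aff_params)
    connectivity = _timed("connectivity", afc_connectivity, field_, seeds)
    fc_mask = threshold_segmentation(connectivity, config.fc.T_FC)

    # gap completion and regularisation
    completed = _timed(
        "completion",
        complete_object,
        fc_mask,
        t=config.completion.t,
        D=config.completion.D,
        min_gap_length=config.completion.min_gap_length,
        contact_tol=config.completion.contact_tol,
    )
    mcf_params = MCFParams(time_step=config.mcf.dt, n_iter=config.mcf.n_iter)
    mask = _timed("mcf", mcf_smooth, completed, mcf_params)

    return PipelineResult(
        mask=mask,
        phase=phase,
        fa=fa,
        edge=edge,
        connectivity=connectivity,
        fc_mask=fc_mask,
        completed_mask=completed,
        params=aff_params,
        timings=timings,
    )
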