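"""End-to-end pipeline orchestration and the phantom recovery benchmark.

The pipeline runs the full quantification chain on one volume:

    read/generate -> tissue (OOS) segmentation -> vessel (OOI) segmentation
    -> skeletonize -> distance map -> radius mapping -> graph -> pruning
    -> network + segment morphometry -> frequency-distribution fits

All stages are deterministic at a fixed seed; outputs (masks, skeleton,
segment CSV, network JSON, fit JSON) are written to the output directory
together with the serialized configuration and its hash, so two runs of
the same configuration produce byte-identical tables and reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distfit, morphometry, segmentation, vesselgraph, volio
from .phantom import PhantomSpec, generate_network, voxelize_geometry
from .skeleton import distance_map, map_radii, skeletonize
from .volio import BinaryMask, Volume3D

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline",
           "run_phantom_benchmark"]


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run.

    Exactly one of ``input_path`` and ``phantom`` must be set. ``oos_mode``
    selects how the tissue is separated from the non-tissue background:
    ``"inflexion"`` (histogram inflexion point, default), ``"ci"``
    (background mean − z·sd), a numeric gray level, or ``"none"`` (whole
    volume is tissue, for samples with no mounting-medium region).
    """

    input_path: str | None = None
    phantom: PhantomSpec | None = None
    alpha: float = 0.05
    oos_mode: str | float = "inflexion"
    prune_length_um: float | None = None  # default: one fine-voxel diagonal
    fd_on: str = "skeleton"
    fit_bin_width: float | None = None
    fit_offset: bool = True
    min_component_voxels: int = 27  # despeckle: drop OOI blobs below one 3x3x3 blob
    smooth_mask: bool = True  # 3^3 majority filter regularizing the mask edge
    out_dir: str | None = None
    seed: int = 0
    write_volumes: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.phantom is None):
            raise PipelineError("config", "set exactly one of input_path / phantom")
        if not 0 < self.alpha < 1:
            raise PipelineError("config", f"alpha must be in (0, 1), got {self.alpha}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise PipelineError("config", f"input file not found: {self.input_path}")
        if isinstance(self.oos_mode, str) and self.oos_mode not in (
            "inflexion", "ci", "none",
        ):
            raise PipelineError("config", f"bad oos_mode {self.oos_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_volumes", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    volume: Volume3D
    oos_mask: BinaryMask
    ooi_mask: BinaryMask
    oos_threshold: float
    fit: segmentation.GaussianFitResult
    decision: segmentation.ThresholdDecision
    skeleton: object
    graph: vesselgraph.VesselGraph
    records: list
    loop_count: int
    network: morphometry.NetworkMD
    fits: dict
    ground_truth: object | None = None
    geometry: object | None = None
    timings_s: dict = field(default_factory=dict)


def _stage(timings: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = round(dt, 3)
            if exc is None:
                logger.info("stage %-14s done in %.2fs", name, dt)
            else:
                logger.error("stage %-14s failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full quantification chain for one configuration."""
    config.validate()
    timings: dict[str, float] = {}
    truth = None
    geom = None

    with _stage(timings, "load"):
        if config.phantom is not None:
            spec = dataclasses.replace(config.phantom, seed=config.phantom.seed + config.seed)
            geom, truth = generate_network(spec)
            vol = voxelize_geometry(geom, spec)
        else:
            vol = volio.read_volume(config.input_path)

    with _stage(timings, "oos"):
        hist = segmentation.compute_histogram(vol)
        mode = config.oos_mode
        if mode == "none":
            oos_threshold = 0.0
            oos = BinaryMask(np.ones(vol.shape, dtype=bool), vol.spacing_um)
        else:
            if mode == "inflexion":
                oos_threshold = segmentation.find_inflexion_threshold(hist)
            elif mode == "ci":
                # isolate the tissue mode above the inflexion point, then set
                # the lower confidence limit mean - z*sd of its Gaussian fit
                t_infl = segmentation.find_inflexion_threshold(hist)
                rng0 = segmentation.auto_fit_range(hist, t_infl)
                fit0 = segmentation.fit_background_gaussian(hist, rng0)
                oos_threshold = segmentation.ci_threshold(
                    fit0, config.alpha, "lower"
                ).threshold
            else:
                oos_threshold = float(mode)
            oos = segmentation.binarize(vol, oos_threshold)

    with _stage(timings, "ooi"):
        hist_oos = segmentation.compute_histogram(vol, within=oos)
        fit_range = segmentation.auto_fit_range(hist_oos, oos_threshold)
        fit = segmentation.fit_background_gaussian(hist_oos, fit_range)
        decision = segmentation.ci_threshold(fit, config.alpha, "upper")
        logger.info(
            "OOI threshold = mean + %.3f*sd = %.2f + %.3f*%.2f = %.2f (alpha=%g)",
            decision.z_crit, fit.mean, decision.z_crit, fit.sd,
            decision.threshold, config.alpha,
        )
        ooi = segmentation.binarize(vol, decision)
        ooi.values &= oos.values
        if config.min_component_voxels > 1:
            # CI thresholding deliberately retains alpha/2 of the background as
            # salt noise; blobs below the resolvable vessel scale are removed
            from scipy import ndimage as _ndi

            lab, _n = _ndi.label(ooi.values, structure=np.ones((3, 3, 3)))
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            ooi.values = (sizes >= config.min_component_voxels)[lab]
        if config.smooth_mask:
            # majority vote over the 3x3x3 neighbourhood: strips the
            # single-voxel pimples and pits that gray-level noise puts on the
            # partial-volume edge and that thinning would turn into spurs
            from scipy import ndimage as _ndi

            ooi.values = _ndi.median_filter(
                ooi.values.astype(np.uint8), size=3
            ).astype(bool)
            ooi.values &= oos.values

    with _stage(timings, "skeletonize"):
        skel = skeletonize(ooi)
        dm = distance_map(ooi)
        radii = map_radii(skel, dm)

    with _stage(timings, "graph"):
        graph = vesselgraph.build_graph(skel, radii)
        prune_len = (
            config.prune_length_um
            if config.prune_length_um is not None
            else vesselgraph.default_prune_length(vol.spacing_um)
        )
        graph = vesselgraph.prune_graph(graph, prune_len, radius_aware=True)
        records, loop_count = vesselgraph.segment_records(graph)

    with _stage(timings, "morphometry"):
        network = morphometry.network_descriptors(ooi, oos, graph, skel, fd_on=config.fd_on)

    with _stage(timings, "distfit"):
        fits = {}
        samples = {
            "length": np.array([r.real_length_um for r in records]),
            "diameter": np.array([r.diameter_um for r in records]),
            "tortuosity": np.array([r.tortuosity for r in records]),
        }
        for name, values in samples.items():
            try:
                fd = distfit.frequency_distribution(
                    values, variable=name, bin_width=config.fit_bin_width
                )
                ranked = distfit.select_best_law(fd, offset=config.fit_offset)
                fits[name] = ranked
            except distfit.DistFitError as exc:
                logger.warning("distribution fit skipped for %s: %s", name, exc)
                fits[name] = []

    result = PipelineResult(
        config=config, volume=vol, oos_mask=oos, ooi_mask=ooi,
        oos_threshold=float(oos_threshold), fit=fit, decision=decision,
        skeleton=skel, graph=graph, records=records, loop_count=loop_count,
        network=network, fits=fits, ground_truth=truth, geometry=geom,
        timings_s=timings,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    import numpy as _np
    import scipy as _sp

    from . import __version__ as _pkg_version

    with open(out_dir / "config.json", "w") as fh:
        json.dump(
            {
                "config": cfg.to_dict(),
                "config_hash": cfg.config_hash(),
                "versions": {
                    "vesselvox": _pkg_version,
                    "numpy": _np.__version__,
                    "scipy": _sp.__version__,
                },
            },
            fh, indent=2, sort_keys=True, default=str,
        )
    if cfg.write_volumes:
        volio.write_volume(result.volume, out_dir / "volume.tif")
        volio.write_mask(result.oos_mask, out_dir / "oos_mask.tif")
        volio.write_mask(result.ooi_mask, out_dir / "ooi_mask.tif")
        volio.write_mask(result.skeleton, out_dir / "skeleton.tif")
    volio.write_segment_table(result.records, out_dir / "segments.csv")
    hist = segmentation.compute_histogram(result.volume)
    pd.DataFrame({"gray": hist.bin_centers, "count": hist.counts}).to_csv(
        out_dir / "histogram.csv", index=False
    )
    volio.write_report(
        result.network,
        result.fits,
        out_dir / "report.json",
        extra={
            "config_hash": cfg.config_hash(),
            "oos_threshold": result.oos_threshold,
            "ooi_threshold": result.decision.threshold,
            "z_crit": result.decision.z_crit,
            "background_fit": result.fit,
            "loop_count": result.loop_count,
        },
    )


def run_phantom_benchmark(
    specs: list[PhantomSpec],
    alpha: float = 0.05,
    sensitivity_delta: float | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Recovery benchmark: pipeline output against phantom ground truth.

    For every spec, runs the full pipeline and reports, per descriptor and
    seed, the ground-truth value, the recovered value and the error.
    Per-segment length and diameter are compared after nearest-endpoint
    matching of traced segments to ground-truth segments. With
    ``sensitivity_delta`` the ±delta gray-level threshold sensitivity of
    the main descriptors is appended.
    """
    if not specs:
        raise PipelineError("benchmark", "need at least one phantom spec")
    rows = []
    for spec in specs:
        cfg = PipelineConfig(phantom=spec, alpha=alpha, out_dir=None)
        res = run_pipeline(cfg)
        truth = res.ground_truth
        recovered_density = res.network.volume_density_pct
        rows.append(
            {
                "seed": spec.seed, "descriptor": "volume_density_pct",
                "truth": truth.volume_density_pct, "recovered": recovered_density,
                "error": recovered_density - truth.volume_density_pct,
            }
        )
        for name, true_val, rec_val in (
            ("segment_count", truth.segment_count, len(res.graph.segments)),
            (
                "node_count",
                sum(truth.node_degree_histogram.values()),
                res.graph.junction_count,
            ),
        ):
            rows.append(
                {
                    "seed": spec.seed, "descriptor": name,
                    "truth": float(true_val), "recovered": float(rec_val),
                    "error": (rec_val - true_val) / true_val if true_val else np.nan,
                }
            )
        match = match_segments(res, truth)
        if len(match):
            rows.append(
                {
                    "seed": spec.seed, "descriptor": "segment_length_relerr_median",
                    "truth": 0.0,
                    "recovered": float(match["length_rel_err"].abs().median()),
                    "error": float(match["length_rel_err"].abs().median()),
                }
            )
            rows.append(
                {
                    "seed": spec.seed, "descriptor": "diameter_err_um_median",
                    "truth": 0.0,
                    "recovered": float(match["diameter_err_um"].abs().median()),
                    "error": float(match["diameter_err_um"].abs().median()),
                }
            )
        if sensitivity_delta is not None:
            sens = segmentation.threshold_sensitivity(
                res.volume, res.oos_mask, res.decision, delta=sensitivity_delta
            )
            for _, r in sens.iterrows():
                rows.append(
                    {
                        "seed": spec.seed,
                        "descriptor": f"sensitivity:{r['descriptor']}",
                        "truth": 0.0,
                        "recovered": r["value_at_t"],
                        "error": max(
                            abs(r["pct_change_minus"]), abs(r["pct_change_plus"])
                        ),
                    }
                )
    report = pd.DataFrame(rows)
    summary = (
        report.groupby("descriptor")["error"].agg(["mean", "median", "std"]).reset_index()
    )
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_path, index=False, float_format="%.12g")
        summary.to_csv(
            out_path.with_name(out_path.stem + "_summary.csv"),
            index=False, float_format="%.12g",
        )
    return report


def match_segments(result: PipelineResult, truth) -> pd.DataFrame:
    """Match traced segments to ground-truth segments by nearest endpoints.

    Each traced (non-loop) segment is assigned the ground-truth segment
    minimizing the summed endpoint distance (both orientations tried); a
    match is accepted when that distance is below half the mean segment
    length. Returns per-match length and diameter errors.
    """
    from scipy.spatial.distance import cdist

    empty = pd.DataFrame(columns=["traced_id", "gt_id", "length_rel_err", "diameter_err_um"])
    recs = result.records
    gt = truth.segments
    if not recs or gt.empty or result.geometry is None:
        return empty
    if (gt["node_a"] < 0).any():  # tree segments carry no node indices
        return empty

    rows = []
    a_pts = np.array([[r.x0_um, r.y0_um, r.z0_um] for r in recs])
    b_pts = np.array([[r.x1_um, r.y1_um, r.z1_um] for r in recs])
    node_xyz = result.geometry.node_table[["x_um", "y_um", "z_um"]].to_numpy()
    ga = node_xyz[gt["node_a"].to_numpy()]
    gb = node_xyz[gt["node_b"].to_numpy()]
    d_aa = cdist(a_pts, ga) + cdist(b_pts, gb)
    d_ab = cdist(a_pts, gb) + cdist(b_pts, ga)
    # the two orientation-specific costs must pair endpoints of the SAME gt segment
    cost = np.minimum(d_aa, d_ab)
    tol = float(gt["euclidean_length_um"].mean()) / 2
    for i, rec in enumerate(recs):
        j = int(np.argmin(cost[i]))
        if cost[i, j] > 2 * tol:
            continue
        rows.append(
            {
                "traced_id": rec.id,
                "gt_id": int(gt["id"].iloc[j]),
                "length_rel_err": (rec.real_length_um - gt["real_length_um"].iloc[j])
                / gt["real_length_um"].iloc[j],
                "diameter_err_um": rec.diameter_um - 2 * gt["radius_um"].iloc[j],
            }
        )
    return pd.DataFrame(rows)
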