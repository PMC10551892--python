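"""Network-level morphometric descriptors.

Densities are normalized to the volume of the perfused tissue (the object
of study): vascular volume density as a percentage, and segment count,
node count and total centreline length per mm³ of tissue.

Connectivity is summarized by the furcation spectrum N(i) — the number of
junctions at which i segments meet (bifurcation i = 3, trifurcation
i = 4) — and by the node/segment ratio. For a closed meshwork (no
endpoints) the handshake identity fixes the segment count:

    S = (1/2) * sum_i N(i) * i

Space-filling is quantified by the Minkowski–Bouligand (box-counting)
fractal dimension, computed on the skeleton by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .skeleton import SkeletonVolume
from .vesselgraph import VesselGraph
from .volio import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityProfile",
    "NetworkMD",
    "MorphometryError",
    "volume_density",
    "normalized_counts",
    "connectivity_profile",
    "expected_segment_count",
    "fractal_dimension",
    "network_descriptors",
]


class MorphometryError(Exception):
    pass


@dataclass
class ConnectivityProfile:
    """Furcation spectrum of a vessel graph (endpoints excluded from N(i))."""

    n_by_degree: dict[int, int]  # N(i): junction count per furcation degree i
    node_count: int  # junctions
    endpoint_count: int
    segment_count: int
    node_segment_ratio: float
    pct_bifurcation: float
    pct_trifurcation: float


@dataclass
class NetworkMD:
    """Network-level morphometric descriptor bundle."""

    volume_density_pct: float
    segments_per_mm3: float
    nodes_per_mm3: float
    endpoints_per_mm3: float
    total_length_um_per_mm3: float
    connectivity: ConnectivityProfile
    fractal_dimension: float
    fractal_r_squared: float
    #: handshake-identity segment count (1/2 sum N(i)*i); only meaningful for
    #: closed meshworks, so reported only when the endpoint fraction is < 1%
    expected_segment_count: int | None = None


def volume_density(ooi: BinaryMask, oos: BinaryMask) -> float:
    """Vascular volume as a percentage of tissue volume (pure count ratio)."""
    if ooi.values.shape != oos.values.shape:
        raise MorphometryError("OOI and OOS masks differ in shape")
    n_oos = oos.count()
    if n_oos == 0:
        raise MorphometryError("OOS mask is empty")
    outside = int((ooi.values & ~oos.values).sum())
    if outside:
        logger.warning("%d OOI voxels outside OOS; intersecting", outside)
    n_ooi = int((ooi.values & oos.values).sum())
    return 100.0 * n_ooi / n_oos


def normalized_counts(
    graph: VesselGraph, oos_volume_mm3: float
) -> tuple[float, float, float]:
    """(segments/mm³, junction nodes/mm³, total real length µm/mm³)."""
    if oos_volume_mm3 <= 0:
        raise MorphometryError(f"OOS volume must be positive, got {oos_volume_mm3}")
    n_seg = len(graph.segments)
    n_nodes = graph.junction_count
    total_len = graph.total_length_um()
    return (n_seg / oos_volume_mm3, n_nodes / oos_volume_mm3, total_len / oos_volume_mm3)


def connectivity_profile(graph: VesselGraph) -> ConnectivityProfile:
    """Furcation spectrum N(i) over junction nodes; endpoints counted apart."""
    n_by_degree: dict[int, int] = {}
    for n in graph.nodes:
        if n.kind != "junction":
            continue
        n_by_degree[n.degree] = n_by_degree.get(n.degree, 0) + 1
    node_count = sum(n_by_degree.values())
    endpoint_count = graph.endpoint_count
    segment_count = len(graph.segments)
    return ConnectivityProfile(
        n_by_degree=dict(sorted(n_by_degree.items())),
        node_count=node_count,
        endpoint_count=endpoint_count,
        segment_count=segment_count,
        node_segment_ratio=node_count / segment_count if segment_count else float("nan"),
        pct_bifurcation=100.0 * n_by_degree.get(3, 0) / node_count if node_count else 0.0,
        pct_trifurcation=100.0 * n_by_degree.get(4, 0) / node_count if node_count else 0.0,
    )


def expected_segment_count(profile: ConnectivityProfile) -> int:
    """Closed-meshwork segment count ``S = (1/2) sum_i N(i) * i``."""
    total = sum(i * n for i, n in profile.n_by_degree.items())
    if total % 2:
        raise MorphometryError(
            f"sum of N(i)*i is odd ({total}); impossible for a closed graph"
        )
    return total // 2


def fractal_dimension(
    skel: SkeletonVolume | BinaryMask | np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Box-counting fractal dimension of a voxel structure.

    Boxes form a geometric ladder of edge lengths (powers of two, from 2
    voxels up to a quarter of the shortest image axis), with the box grid
    anchored at the image origin. Returns ``(fd, box_sizes, counts,
    r_squared)`` where ``fd`` is minus the slope of the least-squares line
    of log N(eps) against log eps. A warning is logged when the log-log fit
    has r² < 0.98.
    """
    values = skel if isinstance(skel, np.ndarray) else skel.values
    values = np.asarray(values, dtype=bool)
    if not values.any():
        raise MorphometryError("cannot compute fractal dimension of an empty structure")

    max_size = min(values.shape) // 4
    sizes = []
    size = 2
    while size <= max_size:
        sizes.append(size)
        size *= 2
    if len(sizes) < 3:
        raise MorphometryError(
            f"fewer than 3 usable box sizes for shape {values.shape}; need a larger volume"
        )

    counts = []
    for eps in sizes:
        pad = [(0, (-d) % eps) for d in values.shape]
        padded = np.pad(values, pad, mode="constant", constant_values=False)
        nz, ny, nx = (d // eps for d in padded.shape)
        blocks = padded.reshape(nz, eps, ny, eps, nx, eps).any(axis=(1, 3, 5))
        counts.append(int(blocks.sum()))

    sizes_arr = np.array(sizes, dtype=float)
    counts_arr = np.array(counts, dtype=float)
    log_eps = np.log(sizes_arr)
    log_n = np.log(counts_arr)
    slope, intercept = np.polyfit(log_eps, log_n, 1)
    pred = slope * log_eps + intercept
    ss_res = float(((log_n - pred) ** 2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.98:
        logger.warning("box-count log-log fit r^2 = %.3f < 0.98", r2)
    return -float(slope), sizes_arr, counts_arr, float(r2)


def network_descriptors(
    ooi: BinaryMask,
    oos: BinaryMask,
    graph: VesselGraph,
    skel: SkeletonVolume,
    fd_on: str = "skeleton",
) -> NetworkMD:
    """Assemble the full network-level descriptor bundle."""
    density = volume_density(ooi, oos)
    oos_volume_mm3 = oos.count() * oos.voxel_volume_um3 * 1e-9
    seg_d, node_d, len_d = normalized_counts(graph, oos_volume_mm3)
    profile = connectivity_profile(graph)
    if fd_on == "skeleton":
        fd, _, _, fd_r2 = fractal_dimension(skel)
    elif fd_on == "mask":
        fd, _, _, fd_r2 = fractal_dimension(ooi)
    else:
        raise MorphometryError(f"fd_on must be 'skeleton' or 'mask', got {fd_on!r}")
    expected_s = None
    n_nodes = profile.node_count + profile.endpoint_count
    if n_nodes and profile.endpoint_count / n_nodes < 0.01:
        try:
            expected_s = expected_segment_count(profile)
        except MorphometryError:
            expected_s = None
    return NetworkMD(
        volume_density_pct=density,
        segments_per_mm3=seg_d,
        nodes_per_mm3=node_d,
        endpoints_per_mm3=graph.endpoint_count / oos_volume_mm3,
        total_length_um_per_mm3=len_d,
        connectivity=profile,
        fractal_dimension=fd,
        fractal_r_squared=fd_r2,
        expected_segment_count=expected_s,
    )
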