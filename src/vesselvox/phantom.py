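"""Ground-truthed synthetic vascular phantoms.

The phantom generator builds vessel geometries with exactly known
morphometry and voxelizes them into grayscale volumes that reproduce the
statistical structure the segmentation pipeline assumes: a three-mode
histogram (dark non-tissue region, Gaussian-distributed unlabeled tissue,
bright labeled vessels) and partial-volume edge voxels in the proportion a
cylinder model predicts (≈ 2d/r intermediate voxels per interior voxel for
radius r at voxel pitch d).

Two topologies are provided, mirroring the two canonical vascular
patterns:

* ``meshwork`` — a capillary-bed-like, non-hierarchical network built on a
  jittered cubic lattice with random connectivity-preserving edge
  deletions. Every lattice node keeps degree >= 3, so the ground-truth
  graph is *closed* (no endpoints) and satisfies the handshake identity
  ``S = (1/2) sum_i N(i)*i`` exactly.
* ``tree`` — a rooted, arborescent, bifurcating network like an arterial
  tree; segment lengths are drawn from the exponential law.

Tortuosity is produced by bowing each straight chord with a smooth
half-sine perturbation of the given amplitude; amplitude 0 yields straight
segments of tortuosity exactly 1.

Default parameters emulate a capillary bed as imaged by light-sheet
microscopy of a cleared organ: diameters Gaussian around 5 µm (radius
2.5 ± 0.25 µm), mean segment length 12 µm, 8-bit gray model with tissue
background N(60, 8), non-tissue (mounting medium) N(10, 3), vessels at
gray 220.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .volio import Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "VesselGeometry",
    "GroundTruth",
    "PhantomError",
    "generate_network",
    "single_cylinder",
    "voxelize_geometry",
    "occupancy_volume",
    "region_labels",
]


class PhantomError(Exception):
    pass


@dataclass
class PhantomSpec:
    """Full description of a synthetic vascular phantom.

    ``radius_law`` is (mean, sd) of a Gaussian in µm (truncated > 0);
    ``length_law_mean_um`` is the mean of an exponential segment-length law
    (sampled literally for trees; for meshworks it sets the lattice pitch,
    node jitter providing the length spread). ``nontissue_margin_um`` is
    the thickness of the mounting-medium slab at low x used to exercise
    tissue/non-tissue segmentation.
    """

    topology: str = "meshwork"  # "meshwork" | "tree"
    domain_size_um: tuple[float, float, float] = (96.0, 96.0, 96.0)  # (x, y, z)
    voxel_spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_law: tuple[float, float] = (2.5, 0.25)  # Gaussian (mean, sd) µm
    length_law_mean_um: float = 12.0  # exponential mean µm
    tortuosity_amplitude: float = 0.0  # bow amplitude, µm
    background_gray: tuple[float, float] = (60.0, 8.0)  # tissue (mean, sd)
    nontissue_gray: tuple[float, float] = (10.0, 3.0)  # mounting medium
    vessel_gray: float = 220.0
    bit_depth: int = 8
    supersampling: int = 3  # subsamples per axis per voxel
    nontissue_margin_um: float = 0.0  # 0 disables the non-tissue slab
    edge_deletion_fraction: float = 0.15  # meshwork only
    node_jitter_fraction: float = 0.15  # of lattice pitch, meshwork only
    seed: int = 0

    def validate(self) -> None:
        if self.topology not in ("meshwork", "tree"):
            raise PhantomError(f"unknown topology {self.topology!r}")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise PhantomError("voxel spacings must be positive")
        if any(d <= 0 for d in self.domain_size_um):
            raise PhantomError("domain size must be positive")
        bg_mean, bg_sd = self.background_gray
        if not self.vessel_gray > bg_mean + 4 * bg_sd:
            raise PhantomError(
                "vessel gray must exceed background mean + 4 sd "
                f"({self.vessel_gray} <= {bg_mean + 4 * bg_sd})"
            )
        if self.radius_law[0] < min(self.voxel_spacing_um):
            raise PhantomError(
                f"mean radius {self.radius_law[0]} µm is below the finest voxel "
                f"spacing {min(self.voxel_spacing_um)} µm (unresolvable)"
            )
        if self.supersampling < 1:
            raise PhantomError("supersampling must be >= 1")
        if self.bit_depth not in (8, 16):
            raise PhantomError("bit depth must be 8 or 16")

    def rngs(self) -> tuple[np.random.Generator, np.random.Generator]:
        """Independent (geometry, noise) random streams derived from the seed."""
        g, n = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(g), np.random.default_rng(n)


@dataclass
class VesselGeometry:
    """Continuous ground-truth geometry: centreline polylines plus radii.

    Polylines are (N, 3) arrays of (x, y, z) points in µm; segments meet
    only at node-table points. ``node_table`` columns: x_um, y_um, z_um,
    degree, kind.
    """

    centerlines: list[np.ndarray]
    radii: np.ndarray
    node_table: pd.DataFrame


@dataclass
class GroundTruth:
    """Exact per-segment and network-level values for pipeline validation."""

    segments: pd.DataFrame  # id, real/euclidean length, radius, tortuosity
    node_degree_histogram: dict[int, int]  # N(i) over junction nodes
    endpoint_count: int
    network_volume_um3: float  # sum of L * pi * r^2 over segments
    tissue_volume_um3: float

    @property
    def segment_count(self) -> int:
        return len(self.segments)

    @property
    def volume_density_pct(self) -> float:
        return 100.0 * self.network_volume_um3 / self.tissue_volume_um3


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian draws truncated to > 0 by redrawing."""
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _bow_polyline(
    a: np.ndarray, b: np.ndarray, amplitude: float, normal: np.ndarray, n_pts: int
) -> np.ndarray:
    """Half-sine bow from a to b: endpoints fixed, peak offset = amplitude."""
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    chord = a[None, :] + t * (b - a)[None, :]
    if amplitude == 0.0:
        return chord
    return chord + amplitude * np.sin(np.pi * t) * normal[None, :]


def _perp_unit(rng: np.random.Generator, direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    v = rng.normal(size=3)
    v -= v.dot(d) * d
    norm = np.linalg.norm(v)
    while norm < 1e-9:
        v = rng.normal(size=3)
        v -= v.dot(d) * d
        norm = np.linalg.norm(v)
    return v / norm


def _polyline_stats(poly: np.ndarray) -> tuple[float, float]:
    steps = np.diff(poly, axis=0)
    real = float(np.sqrt((steps**2).sum(axis=1)).sum())
    eucl = float(np.linalg.norm(poly[-1] - poly[0]))
    return real, eucl


def _tissue_origin_x(spec: PhantomSpec) -> float:
    return spec.nontissue_margin_um


def _meshwork(spec: PhantomSpec, rng: np.random.Generator):
    import networkx as nx

    pitch = spec.length_law_mean_um
    r_clear = spec.radius_law[0] + max(spec.voxel_spacing_um)
    x0 = _tissue_origin_x(spec) + r_clear
    lims_lo = np.array([x0, r_clear, r_clear])
    lims_hi = np.array(spec.domain_size_um) - r_clear
    extent = lims_hi - lims_lo
    n_axis = np.floor(extent / pitch).astype(int) + 1
    if (n_axis < 2).any():
        raise PhantomError(
            f"domain {spec.domain_size_um} µm too small for lattice pitch {pitch} µm"
        )
    # centre the lattice in the tissue region
    origin = lims_lo + (extent - (n_axis - 1) * pitch) / 2

    jitter = spec.node_jitter_fraction * pitch
    coords = {}
    for ix in range(n_axis[0]):
        for iy in range(n_axis[1]):
            for iz in range(n_axis[2]):
                p = origin + pitch * np.array([ix, iy, iz])
                p = p + rng.uniform(-jitter, jitter, 3)
                coords[(ix, iy, iz)] = np.clip(p, lims_lo, lims_hi)

    g = nx.Graph()
    g.add_nodes_from(coords)
    for ix, iy, iz in coords:
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (ix + d[0], iy + d[1], iz + d[2])
            if nb in coords:
                g.add_edge((ix, iy, iz), nb)

    # random deletions preserving connectivity and min degree 3 (closed meshwork)
    edges = list(g.edges())
    rng.shuffle(edges)
    n_target = int(spec.edge_deletion_fraction * len(edges))
    removed = 0
    for u, v in edges:
        if removed >= n_target:
            break
        if g.degree(u) <= 3 or g.degree(v) <= 3:
            continue
        g.remove_edge(u, v)
        if nx.has_path(g, u, v):
            removed += 1
        else:
            g.add_edge(u, v)
    return g, coords


def _tree(spec: PhantomSpec, rng: np.random.Generator):
    """Rooted bifurcating tree grown from the low-x tissue face."""
    r_clear = spec.radius_law[0] + max(spec.voxel_spacing_um)
    lo = np.array([_tissue_origin_x(spec) + r_clear, r_clear, r_clear])
    hi = np.array(spec.domain_size_um) - r_clear
    if (hi - lo <= 0).any():
        raise PhantomError(f"domain {spec.domain_size_um} µm too small for a tree phantom")
    root = np.array([lo[0], (lo[1] + hi[1]) / 2, (lo[2] + hi[2]) / 2])
    edges = []  # (a, b) point pairs
    frontier = [(root, np.array([1.0, 0.0, 0.0]), 0)]
    max_depth = 6
    while frontier:
        p, d, depth = frontier.pop()
        length = rng.exponential(spec.length_law_mean_um)
        length = max(length, 2 * min(spec.voxel_spacing_um))
        q = p + length * d
        clipped = np.clip(q, lo, hi)
        terminal = depth >= max_depth or not np.allclose(clipped, q)
        q = clipped
        if np.linalg.norm(q - p) < min(spec.voxel_spacing_um):
            continue
        edges.append((p.copy(), q.copy()))
        if not terminal:
            axis = _perp_unit(rng, d)
            angle = math.radians(rng.uniform(25, 50))
            for sign in (1.0, -1.0):
                child = math.cos(angle) * d + sign * math.sin(angle) * axis
                child /= np.linalg.norm(child)
                frontier.append((q, child, depth + 1))
    if not edges:
        raise PhantomError("tree phantom produced no segments; domain too small")
    return edges


def generate_network(spec: PhantomSpec) -> tuple[VesselGeometry, GroundTruth]:
    """Generate a ground-truthed vessel geometry for the given phantom spec.

    Deterministic for a fixed seed: geometry and gray-level noise use
    independent streams derived from ``spec.seed``, so the same geometry
    can be re-rendered under a different noise realization.
    """
    spec.validate()
    rng, _ = spec.rngs()

    polylines: list[np.ndarray] = []
    node_rows = []
    seg_rows = []

    if spec.topology == "meshwork":
        g, coords = _meshwork(spec, rng)
        node_ids = {k: i for i, k in enumerate(sorted(coords))}
        radii = _truncated_normal(rng, *spec.radius_law, g.number_of_edges())
        edge_list = sorted(g.edges())
        for (u, v), r in zip(edge_list, radii):
            a, b = coords[u], coords[v]
            normal = _perp_unit(rng, b - a)
            n_pts = max(9, int(np.ceil(np.linalg.norm(b - a) / min(spec.voxel_spacing_um))) * 2 + 1)
            poly = _bow_polyline(a, b, spec.tortuosity_amplitude, normal, n_pts)
            polylines.append(poly)
            real, eucl = _polyline_stats(poly)
            seg_rows.append(
                {
                    "id": len(seg_rows),
                    "node_a": node_ids[u],
                    "node_b": node_ids[v],
                    "real_length_um": real,
                    "euclidean_length_um": eucl,
                    "radius_um": float(r),
                    "tortuosity": real / eucl,
                }
            )
        for k in sorted(coords):
            p = coords[k]
            deg = g.degree(k)
            node_rows.append(
                {
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2],
                    "degree": deg,
                    "kind": "junction" if deg >= 3 else "endpoint",
                }
            )
    else:  # tree
        edges = _tree(spec, rng)
        radii = _truncated_normal(rng, *spec.radius_law, len(edges))
        point_key = lambda p: tuple(np.round(p, 6))
        degree: dict[tuple, int] = {}
        pos: dict[tuple, np.ndarray] = {}
        for (a, b), r in zip(edges, radii):
            normal = _perp_unit(rng, b - a)
            n_pts = max(9, int(np.ceil(np.linalg.norm(b - a) / min(spec.voxel_spacing_um))) * 2 + 1)
            poly = _bow_polyline(a, b, spec.tortuosity_amplitude, normal, n_pts)
            polylines.append(poly)
            real, eucl = _polyline_stats(poly)
            for p in (a, b):
                k = point_key(p)
                degree[k] = degree.get(k, 0) + 1
                pos[k] = p
            seg_rows.append(
                {
                    "id": len(seg_rows),
                    "node_a": -1,
                    "node_b": -1,
                    "real_length_um": real,
                    "euclidean_length_um": eucl,
                    "radius_um": float(r),
                    "tortuosity": real / eucl,
                }
            )
        for k, p in pos.items():
            node_rows.append(
                {
                    "x_um": p[0],
                    "y_um": p[1],
                    "z_um": p[2],
                    "degree": degree[k],
                    "kind": "junction" if degree[k] >= 3 else "endpoint",
                }
            )

    segments = pd.DataFrame(seg_rows)
    nodes = pd.DataFrame(node_rows)
    geometry = VesselGeometry(
        centerlines=polylines,
        radii=segments["radius_um"].to_numpy(),
        node_table=nodes,
    )

    junctions = nodes[nodes["kind"] == "junction"]
    hist = junctions["degree"].value_counts().sort_index()
    degree_hist = {int(i): int(c) for i, c in hist.items()}
    tissue_vol = (spec.domain_size_um[0] - _tissue_origin_x(spec)) * (
        spec.domain_size_um[1] * spec.domain_size_um[2]
    )
    network_vol = float(
        (segments["real_length_um"] * np.pi * segments["radius_um"] ** 2).sum()
    )
    truth = GroundTruth(
        segments=segments,
        node_degree_histogram=degree_hist,
        endpoint_count=int((nodes["kind"] == "endpoint").sum()),
        network_volume_um3=network_vol,
        tissue_volume_um3=tissue_vol,
    )
    return geometry, truth


def single_cylinder(
    length_um: float = 100.0,
    radius_um: float = 5.0,
    spec: PhantomSpec | None = None,
    axis: str = "x",
) -> tuple[VesselGeometry, GroundTruth, PhantomSpec]:
    """A single straight axis-aligned cylinder phantom with two endpoints.

    The reference object for partial-volume and straightness checks: its
    tortuosity is exactly 1 and its volume exactly ``L * pi * r^2``. The
    cylinder is centred in the tissue region of a domain padded by 4 radii
    laterally and 2 radii axially.
    """
    if spec is None:
        spec = PhantomSpec()
    pad = 4 * radius_um
    margin = spec.nontissue_margin_um
    along = {"x": 0, "y": 1, "z": 2}[axis]
    size = [2 * pad, 2 * pad, 2 * pad]
    size[along] = length_um + 4 * radius_um + (margin if along == 0 else 0)
    spec = replace(
        spec,
        topology="meshwork",
        domain_size_um=tuple(size),
        radius_law=(radius_um, max(spec.radius_law[1], 1e-6)),
        tortuosity_amplitude=0.0,
    )
    centre = [s / 2 for s in size]
    if along == 0:
        centre[0] = margin + (size[0] - margin) / 2
    a = list(centre)
    b = list(centre)
    a[along] -= length_um / 2
    b[along] += length_um / 2
    poly = np.array([a, b], dtype=float)
    geom = VesselGeometry(
        centerlines=[poly],
        radii=np.array([radius_um]),
        node_table=pd.DataFrame(
            [
                {"x_um": a[0], "y_um": a[1], "z_um": a[2], "degree": 1, "kind": "endpoint"},
                {"x_um": b[0], "y_um": b[1], "z_um": b[2], "degree": 1, "kind": "endpoint"},
            ]
        ),
    )
    segments = pd.DataFrame(
        [
            {
                "id": 0,
                "node_a": 0,
                "node_b": 1,
                "real_length_um": length_um,
                "euclidean_length_um": length_um,
                "radius_um": radius_um,
                "tortuosity": 1.0,
            }
        ]
    )
    truth = GroundTruth(
        segments=segments,
        node_degree_histogram={},
        endpoint_count=2,
        network_volume_um3=length_um * np.pi * radius_um**2,
        tissue_volume_um3=(size[0] - margin) * size[1] * size[2],
    )
    return geom, truth, spec


# ---------------------------------------------------------------------------
# Voxelization


def _grid_shape(spec: PhantomSpec) -> tuple[int, int, int]:
    dx, dy, dz = spec.domain_size_um
    sx, sy, sz = spec.voxel_spacing_um
    return (int(round(dz / sz)), int(round(dy / sy)), int(round(dx / sx)))  # (z, y, x)


def occupancy_volume(geom: VesselGeometry, spec: PhantomSpec) -> np.ndarray:
    """Per-voxel occupancy fraction of the vessel lumen union, in [0, 1].

    Each voxel is subdivided into ``supersampling^3`` sample points; the
    occupancy is the fraction of samples inside any capsule (cylinder with
    hemispherical caps) around a centreline. Voxel centres sit at
    ``index * spacing``, so samples cover ``[(i-1/2)s, (i+1/2)s]``.
    """
    nz, ny, nx = _grid_shape(spec)
    s = spec.supersampling
    sx, sy, sz = spec.voxel_spacing_um

    hit = np.zeros((nz * s, ny * s, nx * s), dtype=bool)
    # supersample point k (0..n*s-1) along x sits at ((k + 0.5)/s - 0.5) * sx
    def axis_coords(n, step):
        return ((np.arange(n * s) + 0.5) / s - 0.5) * step

    xs, ys, zs = axis_coords(nx, sx), axis_coords(ny, sy), axis_coords(nz, sz)
    sub = np.array([sz / s, sy / s, sx / s])

    coarse = max(spec.voxel_spacing_um)
    for poly, radius in zip(geom.centerlines, geom.radii):
        if radius < 0.5 * coarse:
            logger.warning(
                "vessel radius %.2f µm under-resolved at voxel spacing %s µm",
                radius,
                spec.voxel_spacing_um,
            )
        pts = np.asarray(poly, dtype=float)
        for a, b in zip(pts[:-1], pts[1:]):
            # bounding box in supersample index space, with one-voxel margin
            lo = np.minimum(a, b) - radius - np.array([sx, sy, sz])
            hi = np.maximum(a, b) + radius + np.array([sx, sy, sz])
            ix0 = max(int(np.searchsorted(xs, lo[0])), 0)
            ix1 = min(int(np.searchsorted(xs, hi[0])), nx * s)
            iy0 = max(int(np.searchsorted(ys, lo[1])), 0)
            iy1 = min(int(np.searchsorted(ys, hi[1])), ny * s)
            iz0 = max(int(np.searchsorted(zs, lo[2])), 0)
            iz1 = min(int(np.searchsorted(zs, hi[2])), nz * s)
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
            X = xs[ix0:ix1][None, None, :]
            Y = ys[iy0:iy1][None, :, None]
            Z = zs[iz0:iz1][:, None, None]
            ab = b - a
            ab2 = float(ab.dot(ab))
            if ab2 == 0:
                d2 = (X - a[0]) ** 2 + (Y - a[1]) ** 2 + (Z - a[2]) ** 2
            else:
                t = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1] + (Z - a[2]) * ab[2]) / ab2
                np.clip(t, 0.0, 1.0, out=t)
                d2 = (
                    (X - a[0] - t * ab[0]) ** 2
                    + (Y - a[1] - t * ab[1]) ** 2
                    + (Z - a[2] - t * ab[2]) ** 2
                )
            hit[iz0:iz1, iy0:iy1, ix0:ix1] |= d2 <= radius**2

    occ = hit.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5))
    return occ


def region_labels(spec: PhantomSpec) -> np.ndarray:
    """0 = non-tissue slab, 1 = tissue, for every voxel of the phantom grid."""
    nz, ny, nx = _grid_shape(spec)
    sx = spec.voxel_spacing_um[0]
    x_centers = np.arange(nx) * sx
    tissue = x_centers >= spec.nontissue_margin_um
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[:, :, tissue] = 1
    return labels


def voxelize_geometry(geom: VesselGeometry, spec: PhantomSpec) -> Volume3D:
    """Render a geometry into a calibrated grayscale volume.

    Each voxel blends the vessel gray with a Gaussian background draw by
    its sub-voxel occupancy fraction; the non-tissue slab (x below the
    margin) gets mounting-medium gray statistics; values are clipped to the
    bit depth and rounded.
    """
    spec.validate()
    _, noise_rng = spec.rngs()
    occ = occupancy_volume(geom, spec)
    nz, ny, nx = occ.shape

    bg = noise_rng.normal(*spec.background_gray, size=occ.shape)
    if spec.nontissue_margin_um > 0:
        labels = region_labels(spec)
        nt = noise_rng.normal(*spec.nontissue_gray, size=occ.shape)
        bg = np.where(labels == 0, nt, bg)

    values = occ * spec.vessel_gray + (1.0 - occ) * bg
    max_gray = 2**spec.bit_depth - 1
    values = np.clip(np.rint(values), 0, max_gray)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return Volume3D(
        values=values.astype(dtype),
        spacing_um=spec.voxel_spacing_um,
        bit_depth=spec.bit_depth,
    )
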