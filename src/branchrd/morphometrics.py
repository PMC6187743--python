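"""Quantitative branch morphometry of simulated tissue fields.

Differentiated tissue is the super-level set Y >= Ya of the non-diffusing
commitment field (Ya = 0.5 by default).  This module turns that binary
region into numbers: global shape metrics, a centerline skeleton graph
(branch points, tips, generations, arc lengths), a five-class branching
pattern label, straight-line concentration profiles with prominence-based
peak counts, and the spatial separation between consecutive bifurcations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure
from skimage.morphology import skeletonize

__all__ = [
    "TissueRegion",
    "BranchStructure",
    "PatternClass",
    "ProfileLine",
    "ClassifierThresholds",
    "extract_tissue",
    "skeletonize_region",
    "classify_pattern",
    "extract_profile",
    "count_peaks",
    "bifurcation_separations",
]

PATTERN_LABELS = (
    "SPATIAL_SPILLOVER",
    "NO_BRANCH",
    "PARENT_ONLY",
    "SIDE_BRANCHING",
    "TIP_SPLITTING",
    "UNDETERMINED",
)

_STEP_WEIGHTS = {1: 1.0, 2: math.sqrt(2.0), 3: math.sqrt(3.0)}


# ---------------------------------------------------------------------------
# tissue region


@dataclass
class TissueRegion:
    """Thresholded tissue mask and global shape metrics of its largest
    26-connected component."""

    mask: np.ndarray
    Ya: float
    volume_fraction: float
    n_components: int
    largest_mask: np.ndarray | None
    principal_axis_ratio: float
    sphericity: float

    @property
    def empty(self) -> bool:
        return self.n_components == 0


def _principal_axis_ratio(mask: np.ndarray) -> float:
    coords = np.argwhere(mask)
    if len(coords) < 2:
        return 1.0
    cov = np.cov(coords.T)
    # half-voxel smoothing so a 1-voxel-thin object has finite extent
    cov += np.eye(3) / 12.0
    ev = np.sort(np.linalg.eigvalsh(cov))
    return float(math.sqrt(ev[-1] / max(ev[0], 1e-12)))


def _sphericity(mask: np.ndarray) -> float:
    """pi^(1/3) (6V)^(2/3) / A with A from a marching-cubes surface mesh."""
    volume = float(mask.sum())
    if volume < 2:
        return 1.0
    padded = np.pad(mask, 1).astype(float)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        return 1.0
    if area <= 0:
        return 1.0
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)


def extract_tissue(Y_field: np.ndarray, Ya: float = 0.5) -> TissueRegion:
    """Threshold Y at Ya and measure the largest 26-connected component.

    An empty mask is a valid result (n_components = 0), not an error.
    """
    if not (0 < Ya <= 1):
        raise ValueError(f"Ya must lie in (0, 1], got {Ya}")
    Y_field = np.asarray(Y_field)
    mask = Y_field >= Ya
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        return TissueRegion(mask=mask, Ya=Ya, volume_fraction=0.0,
                            n_components=0, largest_mask=None,
                            principal_axis_ratio=1.0, sphericity=1.0)
    sizes = np.bincount(labels.ravel())[1:]
    largest = labels == (int(np.argmax(sizes)) + 1)
    return TissueRegion(
        mask=mask,
        Ya=Ya,
        volume_fraction=float(mask.mean()),
        n_components=int(n),
        largest_mask=largest,
        principal_axis_ratio=_principal_axis_ratio(largest),
        sphericity=_sphericity(largest),
    )


# ---------------------------------------------------------------------------
# skeleton graph


@dataclass
class BranchStructure:
    """Centerline skeleton of a tissue region as a spatial graph.

    ``graph`` nodes are merged junction/endpoint voxels (attribute ``pos``);
    edges carry ``length`` (arc length along the voxel chain, 26-connected
    step metric 1 / sqrt(2) / sqrt(3)) and ``path`` (the voxel chain).
    ``generation`` maps each edge (u, v) to its depth from the root by
    breadth-first traversal (root edges are generation 0).
    """

    skeleton: np.ndarray
    graph: nx.Graph
    root: int | None
    branch_points: list = field(default_factory=list)
    tips: list = field(default_factory=list)
    generation: dict = field(default_factory=dict)

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def max_generation(self) -> int:
        return max(self.generation.values(), default=0)

    @property
    def empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


def _neighbors26(coord, skel_set):
    x, y, z = coord
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nb = (x + dx, y + dy, z + dz)
                if nb in skel_set:
                    yield nb, _STEP_WEIGHTS[abs(dx) + abs(dy) + abs(dz)]


def _voxel_graph(skel_set) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(skel_set)
    for v in skel_set:
        for nb, w in _neighbors26(v, skel_set):
            g.add_edge(v, nb, weight=w)
    return g


def skeletonize_region(
    region: TissueRegion,
    root_hint: tuple[float, float, float] | None = None,
) -> BranchStructure:
    """Medial-axis skeleton of the largest component, traced into a graph.

    Voxels of the thinned mask with degree != 2 are node voxels; node
    voxels adjacent to one another are merged into single graph nodes
    (junction-cluster fusion), and the degree-2 chains between them become
    edges with their summed step lengths.  The root is the node nearest
    ``root_hint`` (default: the mask's center of mass); generations are
    assigned by BFS from the root.
    """
    if region.empty or region.largest_mask is None:
        return BranchStructure(skeleton=np.zeros_like(region.mask), graph=nx.Graph(),
                               root=None)
    mask = region.largest_mask
    skel = skeletonize(mask)
    skel_set = set(map(tuple, np.argwhere(skel)))
    if not skel_set:
        return BranchStructure(skeleton=skel, graph=nx.Graph(), root=None)

    vg = _voxel_graph(skel_set)
    node_voxels = {v for v in vg if vg.degree(v) != 2}
    if not node_voxels:  # a pure cycle: pick an arbitrary voxel as node
        node_voxels = {next(iter(skel_set))}

    # merge adjacent node voxels into clusters (radius-1 junction fusion)
    cluster_graph = vg.subgraph(node_voxels)
    clusters = list(nx.connected_components(cluster_graph))
    cluster_id = {}
    for i, cl in enumerate(clusters):
        for v in cl:
            cluster_id[v] = i

    g = nx.Graph()
    for i, cl in enumerate(clusters):
        pos = tuple(np.mean(np.array(sorted(cl)), axis=0))
        # cluster degree counts chain connections, filled below
        g.add_node(i, pos=pos, voxels=sorted(cl))

    # trace degree-2 chains between clusters
    visited_edges = set()
    for v in node_voxels:
        for nb, w in _neighbors26(v, skel_set):
            if nb in node_voxels:
                # direct contact between different clusters
                ci, cj = cluster_id[v], cluster_id[nb]
                if ci != cj:
                    key = (min(ci, cj), max(ci, cj), "direct")
                    if key not in visited_edges:
                        visited_edges.add(key)
                        _add_edge(g, ci, cj, w, [v, nb])
                continue
            # walk the chain of degree-2 voxels
            path = [v, nb]
            length = w
            prev, cur = v, nb
            while cur not in node_voxels:
                nxts = [(u, wu) for u, wu in _neighbors26(cur, skel_set) if u != prev]
                if not nxts:
                    break  # dangling chain end (shouldn't happen post-thinning)
                (nxt, wn) = min(nxts, key=lambda t: t[1])
                path.append(nxt)
                length += wn
                prev, cur = cur, nxt
            if cur in node_voxels:
                ci, cj = cluster_id[v], cluster_id[cur]
                key = tuple(sorted((path[1], path[-2]))) if len(path) > 2 else (
                    min(ci, cj), max(ci, cj), "short")
                if key in visited_edges:
                    continue
                visited_edges.add(key)
                _add_edge(g, ci, cj, length, path)

    root = 0
    if g.number_of_nodes():
        hint = root_hint
        if hint is None:
            hint = tuple(np.mean(np.argwhere(mask), axis=0))
        root = min(
            g.nodes,
            key=lambda n: sum((a - b) ** 2 for a, b in zip(g.nodes[n]["pos"], hint)),
        )

    branch_points = [n for n in g if _node_degree(g, n) >= 3]
    tips = [n for n in g if _node_degree(g, n) == 1]

    # generation of an edge = number of branch points passed on the way from
    # the root to its upstream endpoint (inclusive); root edges are gen 0
    generation = {}
    if g.number_of_nodes():
        bp_set = set(branch_points)
        _, paths = nx.single_source_dijkstra(g, root, weight="length")
        for u, v in nx.bfs_edges(g, root):
            upstream_path = paths.get(u, [u])
            generation[(min(u, v), max(u, v))] = sum(
                1 for n in upstream_path if n in bp_set
            )

    return BranchStructure(skeleton=skel, graph=g, root=root,
                           branch_points=branch_points, tips=tips,
                           generation=generation)


def _node_degree(g: nx.Graph, n) -> int:
    # multi-edges between the same cluster pair are collapsed by nx.Graph;
    # count parallel chains recorded on the edge instead
    return sum(g.edges[n, m].get("multiplicity", 1) for m in g[n])


def _add_edge(g: nx.Graph, ci: int, cj: int, length: float, path) -> None:
    if ci == cj:
        return  # self-loop chain (tiny cycle); ignore for branch counting
    if g.has_edge(ci, cj):
        e = g.edges[ci, cj]
        e["multiplicity"] = e.get("multiplicity", 1) + 1
        e["length"] = min(e["length"], length)
    else:
        g.add_edge(ci, cj, length=float(length), path=list(path))


# ---------------------------------------------------------------------------
# pattern classification


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable decision thresholds of the five-class pattern cascade."""

    spillover_frac: float = 0.5
    sphere_min: float = 0.85
    axis_ratio_max: float = 1.5
    tip_zone: float = 0.25  # distal fraction of skeleton arc length
    symmetry_tol: float = 0.5  # relative arm-length imbalance for "near-symmetric"


@dataclass
class PatternClass:
    """A branching-pattern label plus the metric evidence that produced it."""

    label: str
    evidence: dict

    def __post_init__(self):
        assert self.label in PATTERN_LABELS


def classify_pattern(
    region: TissueRegion,
    structure: BranchStructure,
    thresholds: ClassifierThresholds | None = None,
) -> PatternClass:
    """Label a tissue region by a deterministic metric cascade.

    Order of tests: domain-filling occupancy -> SPATIAL_SPILLOVER; compact
    near-spherical blob -> NO_BRANCH; no skeleton branch point ->
    PARENT_ONLY; branch points concentrated in the distal tip zone with
    near-symmetric daughter arms -> TIP_SPLITTING; otherwise SIDE_BRANCHING.
    Total on any input; an empty region is NO_BRANCH-adjacent but reported
    as UNDETERMINED since there is no structure to classify.
    """
    th = thresholds or ClassifierThresholds()
    ev: dict = {
        "volume_fraction": region.volume_fraction,
        "n_components": region.n_components,
        "principal_axis_ratio": region.principal_axis_ratio,
        "sphericity": region.sphericity,
        "n_branch_points": structure.n_branch_points,
        "n_tips": structure.n_tips,
        "max_generation": structure.max_generation,
    }
    if region.empty:
        return PatternClass("UNDETERMINED", {**ev, "reason": "empty region"})
    if region.volume_fraction > th.spillover_frac:
        return PatternClass("SPATIAL_SPILLOVER", ev)
    if (region.sphericity > th.sphere_min
            and region.principal_axis_ratio < th.axis_ratio_max):
        return PatternClass("NO_BRANCH", ev)
    if structure.empty or structure.n_branch_points == 0:
        return PatternClass("PARENT_ONLY", ev)

    g = structure.graph
    dist = nx.single_source_dijkstra_path_length(g, structure.root, weight="length")
    max_dist = max(dist.values()) if dist else 0.0
    ev["skeleton_extent"] = max_dist
    if max_dist <= 0:
        return PatternClass("UNDETERMINED", {**ev, "reason": "degenerate skeleton"})

    bp_fracs = [dist[b] / max_dist for b in structure.branch_points]
    ev["branch_point_depth_fractions"] = [round(f, 3) for f in bp_fracs]
    distal = [f >= 1.0 - th.tip_zone for f in bp_fracs]

    def arms_symmetric(bp) -> bool:
        arm_lengths = []
        for nb in g[bp]:
            if dist.get(nb, 0.0) > dist[bp]:  # outward edge
                arm_lengths.append(g.edges[bp, nb]["length"])
        if len(arm_lengths) < 2:
            return False
        arm_lengths.sort()
        a, b = arm_lengths[-2], arm_lengths[-1]
        return (b - a) / max(b, 1e-9) <= th.symmetry_tol

    symmetric = [arms_symmetric(b) for b in structure.branch_points]
    ev["distal_branch_points"] = int(sum(distal))
    ev["symmetric_branch_points"] = int(sum(symmetric))

    n = structure.n_branch_points
    if sum(distal) > n / 2 and sum(symmetric) > n / 2:
        return PatternClass("TIP_SPLITTING", ev)
    return PatternClass("SIDE_BRANCHING", ev)


# ---------------------------------------------------------------------------
# profiles and peaks


@dataclass
class ProfileLine:
    """Concentration samples along a straight line (the transverse axis)."""

    axis_k_points: np.ndarray  # (n, 3) sample coordinates
    k: np.ndarray  # scalar arc-length coordinate along the line
    values: dict  # field name -> sampled 1D array

    def __len__(self) -> int:
        return len(self.k)


def extract_profile(
    fields: dict[str, np.ndarray],
    start: tuple[float, float, float],
    stop: tuple[float, float, float],
    n_samples: int = 100,
) -> ProfileLine:
    """Trilinear samples of one or more fields along the segment start-stop."""
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    seg = stop - start
    length = float(np.linalg.norm(seg))
    if length == 0:
        raise ValueError("degenerate (zero-length) profile line")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + t[:, None] * seg[None, :]
    shape = next(iter(fields.values())).shape
    for name, arr in fields.items():
        if arr.shape != shape:
            raise ValueError(f"field {name!r} shape mismatch")
    if (pts < -1e-9).any() or (pts > np.array(shape) - 1 + 1e-9).any():
        raise ValueError("profile line endpoints outside the domain")
    values = {
        name: ndimage.map_coordinates(arr, pts.T, order=1, mode="nearest")
        for name, arr in fields.items()
    }
    return ProfileLine(axis_k_points=pts, k=t * length, values=values)


def tip_transverse_line(
    region: TissueRegion,
    axis: int = 2,
    margin: float = 2.0,
) -> tuple[tuple, tuple]:
    """Endpoints of a line through the distal tip's widest transverse chord.

    The distal tip is the largest-``axis`` end of the largest component;
    the line runs perpendicular to ``axis`` through the widest chord of the
    tissue cross-section at that height, extended by ``margin`` voxels on
    each side.
    """
    if region.empty or region.largest_mask is None:
        raise ValueError("cannot place a tip line on an empty region")
    mask = region.largest_mask
    coords = np.argwhere(mask)
    tip_level = coords[:, axis].max()
    sl = coords[coords[:, axis] == tip_level]
    other = [i for i in range(3) if i != axis]
    # widest chord: take the transverse direction of larger spread
    spreads = [np.ptp(sl[:, i]) for i in other]
    tdir = other[int(np.argmax(spreads))]
    center = sl.mean(axis=0)
    lo, hi = sl[:, tdir].min() - margin, sl[:, tdir].max() + margin
    lo = max(lo, 0)
    hi = min(hi, mask.shape[tdir] - 1)
    start = center.copy()
    stop = center.copy()
    start[tdir] = lo
    stop[tdir] = hi
    return tuple(start), tuple(stop)


def count_peaks(profile: np.ndarray, prominence: float = 0.1) -> int:
    """Number of local maxima with relative prominence above ``prominence``.

    Prominence is measured relative to the profile's total range, so a flat
    profile has zero peaks and plateaus count once.
    """
    if prominence < 0:
        raise ValueError("prominence must be >= 0")
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 3:
        return 0
    rng = float(profile.max() - profile.min())
    if rng == 0:
        return 0
    peaks, _ = find_peaks(profile, prominence=max(prominence * rng, 1e-300))
    return int(len(peaks))


# ---------------------------------------------------------------------------
# bifurcation separations


def bifurcation_separations(structure: BranchStructure) -> dict:
    """Arc-length distances between consecutive branch points.

    For each parent->child pair of branch points adjacent along the graph
    (no other branch point on the connecting path), the centerline distance
    between them, in voxel units.  The root-to-first-branch-point distance
    is reported separately.
    """
    out = {"separations": [], "root_to_first": None}
    if structure.empty or structure.n_branch_points == 0:
        return out
    g = structure.graph
    dist = nx.single_source_dijkstra_path_length(g, structure.root, weight="length")
    bps = sorted(structure.branch_points, key=lambda b: dist[b])
    out["root_to_first"] = float(dist[bps[0]])
    bp_set = set(bps)
    for parent in bps:
        for child in bps:
            if dist[child] <= dist[parent]:
                continue
            try:
                path = nx.shortest_path(g, parent, child, weight="length")
            except nx.NetworkXNoPath:
                continue
            if any(n in bp_set for n in path[1:-1]):
                continue  # not consecutive
            if path[1] not in g[parent]:
                continue
            # child must be downstream of parent, not a sibling subtree
            if dist[path[1]] < dist[parent]:
                continue
            length = sum(g.edges[u, v]["length"] for u, v in zip(path, path[1:]))
            out["separations"].append(float(length))
    return out
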