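"""Nucleus segmentation and the pruned Delaunay neighbourhood network.

Nuclei are segmented by global Otsu thresholding of the (contrast-stretched)
nuclei channel; each connected component's boundary is traced with the
Moore-neighbour algorithm under Jacob's stopping criterion and its geometric
centre is the mean of its member pixel coordinates.  The centroids are then
triangulated (Delaunay), and highly obtuse triangles -- those whose largest
internal angle exceeds the per-image mean + 3 SD, or whose longest edge
exceeds the mean + 5 SD -- are pruned in a single pass.  The surviving edges
define the neighbouring system: cell pairs for internuclear profiles and cell
neighbourhoods for radial profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "NucleusRecord",
    "CellNetwork",
    "preprocess",
    "segment_nuclei",
    "build_network",
    "prune_obtuse_triangles",
]


@dataclass
class NucleusRecord:
    label: int
    centroid: np.ndarray  # (row, col), sub-pixel
    boundary: np.ndarray  # ordered closed 8-connected chain of (row, col)
    area: int


@dataclass
class CellNetwork:
    """Nucleus nodes, pruned Delaunay edges/triangles and removal log."""

    nodes: list[NucleusRecord]
    edges: set[tuple[int, int]]
    triangles: list[tuple[int, int, int]]
    removed_triangles: list[dict] = field(default_factory=list)
    orphan_edges: set[tuple[int, int]] = field(default_factory=set)
    degenerate: bool = False

    def centroid_of(self, label: int) -> np.ndarray:
        return self._index()[label].centroid

    def neighbors(self, label: int) -> list[int]:
        out = set()
        for a, b in self.edges:
            if a == label:
                out.add(b)
            elif b == label:
                out.add(a)
        return sorted(out)

    def _index(self) -> dict[int, NucleusRecord]:
        return {n.label: n for n in self.nodes}


def preprocess(image: np.ndarray, percentiles=(1.0, 99.0)) -> np.ndarray:
    """Percentile-clipped linear stretch of a single-channel image to [0, 255].

    The mapping is monotone (pixel ordering is preserved).  A constant image
    is returned unchanged with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    lo, hi = np.percentile(img, percentiles)
    if hi - lo < 1e-12:
        warnings.warn("constant image: preprocessing left it unchanged")
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0


# Moore neighbourhood in clockwise order starting from North.
_NEIGH = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour boundary trace of one connected component.

    Starts at the topmost-leftmost foreground pixel and stops, per Jacob's
    criterion, when the start pixel is re-entered with the same backtrack
    configuration as on entry.  Returns the ordered (row, col) chain.
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    fg = np.argwhere(padded)
    if fg.size == 0:
        raise ValueError("empty mask")
    start = tuple(fg[0])  # argwhere is raster (row-major) ordered
    backtrack = (start[0], start[1] - 1)  # entered scanning left-to-right
    chain = [start]
    p, b = start, backtrack
    first_state = (start, backtrack)
    max_steps = 4 * int(padded.sum()) + 8
    for _ in range(max_steps):
        rel = (b[0] - p[0], b[1] - p[1])
        idx = _NEIGH.index(rel)
        nxt = None
        for k in range(1, 9):
            d = _NEIGH[(idx + k) % 8]
            cand = (p[0] + d[0], p[1] + d[1])
            if padded[cand]:
                nxt = cand
                prev_d = _NEIGH[(idx + k - 1) % 8]
                b = (p[0] + prev_d[0], p[1] + prev_d[1])
                break
        if nxt is None:  # isolated single pixel
            break
        p = nxt
        if (p, b) == first_state:
            break
        chain.append(p)
    return np.array(chain, dtype=float) - 1.0  # undo padding offset


def segment_nuclei(image: np.ndarray, min_area: int = 30) -> list[NucleusRecord]:
    """Otsu threshold -> connected components -> boundary trace + centroid.

    Components smaller than ``min_area`` pixels are discarded as noise specks.
    Raises if no nucleus survives.
    """
    img = np.asarray(image, dtype=float)
    thr = threshold_otsu(img)
    mask = img > thr
    labels = cc_label(mask, connectivity=2)
    records: list[NucleusRecord] = []
    out_label = 0
    for lbl in range(1, labels.max() + 1):
        comp = labels == lbl
        area = int(comp.sum())
        if area < min_area:
            continue
        coords = np.argwhere(comp)
        centroid = coords.mean(axis=0)
        boundary = _moore_trace(comp)
        out_label += 1
        records.append(
            NucleusRecord(
                label=out_label, centroid=centroid, boundary=boundary, area=area
            )
        )
    if not records:
        raise ValueError("no nuclei found above the Otsu threshold")
    return records


def _triangle_stats(points: np.ndarray, tri: tuple[int, int, int]):
    """(largest internal angle [rad], longest edge length) of one triangle."""
    p = points[list(tri)]
    sides = np.array(
        [
            np.linalg.norm(p[1] - p[2]),
            np.linalg.norm(p[0] - p[2]),
            np.linalg.norm(p[0] - p[1]),
        ]
    )
    a, bb, c = sides
    angles = []
    for opp, s1, s2 in ((a, bb, c), (bb, a, c), (c, a, bb)):
        cosang = np.clip((s1**2 + s2**2 - opp**2) / (2 * s1 * s2), -1.0, 1.0)
        angles.append(np.arccos(cosang))
    return max(angles), sides.max()


def prune_obtuse_triangles(points: np.ndarray, triangles):
    """Single-pass removal of outlier triangles from a triangulation.

    A triangle is removed when its largest internal angle phi exceeds
    mean(phi) + 3 SD(phi), or its longest edge theta exceeds
    mean(theta) + 5 SD(theta), with the statistics computed once over all
    triangles of this image.  A lone triangle is always kept (SD undefined).
    Returns ``(kept, removed)`` where removed entries carry the reason.
    """
    triangles = [tuple(int(v) for v in t) for t in triangles]
    if len(triangles) <= 1:
        return list(triangles), []
    stats = np.array([_triangle_stats(points, t) for t in triangles])
    phi, theta = stats[:, 0], stats[:, 1]
    tol_phi = phi.mean() + 3.0 * phi.std() + 1e-9 * (1.0 + abs(phi.mean()))
    tol_theta = theta.mean() + 5.0 * theta.std() + 1e-9 * (1.0 + abs(theta.mean()))
    kept, removed = [], []
    for t, ph, th in zip(triangles, phi, theta):
        reasons = []
        if ph > tol_phi:
            reasons.append("obtuse_angle")
        if th > tol_theta:
            reasons.append("long_edge")
        if reasons:
            removed.append(
                {"triangle": t, "reason": "+".join(reasons), "phi": float(ph), "theta": float(th)}
            )
        else:
            kept.append(t)
    return kept, removed


def build_network(
    centroids: np.ndarray, records: list[NucleusRecord] | None = None
) -> CellNetwork:
    """Delaunay triangulation of nucleus centroids with outlier pruning.

    With fewer than 3 centroids no triangulation exists: two nuclei yield the
    single pair edge (flagged orphan); collinear point sets yield a degenerate
    network with no triangles.  Triangle/edge vertices refer to node labels.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 two-dimensional centroids")
    if records is None:
        records = [
            NucleusRecord(
                label=i + 1,
                centroid=pts[i],
                boundary=np.empty((0, 2)),
                area=0,
            )
            for i in range(len(pts))
        ]
    labels = [r.label for r in records]

    def lab(i: int) -> int:
        return labels[i]

    if len(pts) == 2:
        e = tuple(sorted((lab(0), lab(1))))
        return CellNetwork(
            nodes=records, edges={e}, triangles=[], orphan_edges={e}
        )
    try:
        tri = Delaunay(pts)
        simplices = [tuple(s) for s in tri.simplices]
    except QhullError:
        return CellNetwork(nodes=records, edges=set(), triangles=[], degenerate=True)
    kept_idx, removed_idx = prune_obtuse_triangles(pts, simplices)
    kept = [tuple(sorted(lab(v) for v in t)) for t in kept_idx]
    removed = [
        {**r, "triangle": tuple(sorted(lab(v) for v in r["triangle"]))}
        for r in removed_idx
    ]
    edges: set[tuple[int, int]] = set()
    for t in kept:
        a, b, c = t
        edges.update({(a, b), (a, c), (b, c)})
    return CellNetwork(
        nodes=records, edges=edges, triangles=kept, removed_triangles=removed
    )
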