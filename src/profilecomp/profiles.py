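"""Internuclear (IN) beams, radial (RD) fans and the profile matrix Y.

An IN beam between two neighbouring nuclei A and B consists of n
quasi-parallel sampling lines flanking the internuclear axis.  The nucleus
diameters perpendicular to the axis intersect the two boundaries at
x^A, x^B (on A) and y^A, y^B (on B); line i runs from

    x_i = x^A + i/(n-1) * (x^B - x^A)      (a point swept across A's diameter)

to the matching point y_i swept across B's diameter, so every line starts
inside nucleus A, crosses the shared cell-cell interface near its midpoint,
and ends inside nucleus B.  Each line is sampled at m_i points, m_i being the
centroid distance rounded to the nearest pixel.

An RD fan anchors m equi-angular rays at a nucleus centroid; each ray ends at
its first intersection with a closed periodic spline through the neighbouring
centroids, which bounds the cell's territory.

All profiles are length-normalised with bi-cubic interpolation onto N sample
positions (default 101, so the midpoint is index 50) and packed side-by-side
as the columns of an N x M matrix Y.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString, LinearRing

from .network import CellNetwork, NucleusRecord

__all__ = [
    "INBeam",
    "RDFan",
    "ProfileMatrix",
    "in_beam_endpoints",
    "sample_profile",
    "rd_boundary_spline",
    "rd_profiles",
    "normalize_length",
    "assemble_matrix",
    "extract_in_profiles",
    "extract_rd_profiles",
]

logger = logging.getLogger(__name__)

DEFAULT_N_LINES = 10
DEFAULT_N_RAYS = 36
DEFAULT_PROFILE_LEN = 101


@dataclass
class INBeam:
    pair: tuple[int, int]
    anchors: dict  # {"xA", "xB", "yA", "yB"} 2-D points
    starts: np.ndarray  # (n_lines, 2) line start points (on A's diameter)
    ends: np.ndarray  # (n_lines, 2) line end points (on B's diameter)
    n_lines: int
    native_length: int  # m_i = round(||c_A - c_B||), shared by the beam
    raw_profiles: list[np.ndarray] = field(default_factory=list)
    fallback_anchors: bool = False
    clipped: bool = False


@dataclass
class RDFan:
    cell: int
    center: np.ndarray
    n_rays: int
    boundary_spline: np.ndarray  # dense closed polyline (K, 2)
    ray_ends: np.ndarray  # (n_rays, 2)
    native_lengths: np.ndarray  # per-ray r_i
    raw_profiles: list[np.ndarray] = field(default_factory=list)


@dataclass
class ProfileMatrix:
    """Length-normalised profiles packed as columns of Y (N samples x M)."""

    Y: np.ndarray
    kind: str  # "IN" | "RD"
    provenance: list[str]
    native_lengths: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.Y.shape[1]


def _perp(u: np.ndarray) -> np.ndarray:
    return np.array([-u[1], u[0]])


def _chord_ends(nucleus: NucleusRecord, direction: np.ndarray):
    """Intersections of the line through the centroid along ``direction``
    with the nucleus boundary, ordered (negative side, positive side).

    Falls back to centroid +/- mean boundary radius when the boundary is
    unavailable or the probe misses it.
    """
    c = np.asarray(nucleus.centroid, dtype=float)
    boundary = np.asarray(nucleus.boundary, dtype=float)
    if len(boundary) >= 4:
        span = np.ptp(boundary, axis=0).max() * 4.0 + 10.0
        probe = LineString([tuple(c - span * direction), tuple(c + span * direction)])
        try:
            ring = LinearRing(boundary)
            inter = probe.intersection(ring)
            pts = []
            for geom in getattr(inter, "geoms", [inter]):
                if geom.is_empty:
                    continue
                pts.extend(np.asarray(geom.coords))
            if len(pts) >= 2:
                pts = np.asarray(pts)
                proj = (pts - c) @ direction
                return pts[np.argmin(proj)], pts[np.argmax(proj)], False
        except Exception:  # degenerate ring -> fall back
            pass
    if len(boundary) > 0:
        radius = float(np.linalg.norm(boundary - c, axis=1).mean())
    else:
        radius = 1.0
    return c - radius * direction, c + radius * direction, True


def in_beam_endpoints(
    nucleus_a: NucleusRecord, nucleus_b: NucleusRecord, n: int = DEFAULT_N_LINES
) -> INBeam:
    """Anchor points and the n sampling lines of the beam between two nuclei.

    Line 0 connects the negative-side diameter ends of the two nuclei, line
    n-1 the positive-side ends; intermediate start/end points are affine in i.
    """
    if n < 2:
        raise ValueError("a beam needs at least 2 lines")
    cA = np.asarray(nucleus_a.centroid, dtype=float)
    cB = np.asarray(nucleus_b.centroid, dtype=float)
    d = np.linalg.norm(cB - cA)
    if d < 1e-9:
        raise ValueError("coincident nucleus centroids")
    u = (cB - cA) / d
    v = _perp(u)
    xA, xB, fbA = _chord_ends(nucleus_a, v)
    yA, yB, fbB = _chord_ends(nucleus_b, v)
    i = np.arange(n)[:, None] / (n - 1)
    starts = xA[None, :] + i * (xB - xA)[None, :]
    ends = yA[None, :] + i * (yB - yA)[None, :]
    return INBeam(
        pair=(nucleus_a.label, nucleus_b.label),
        anchors={"xA": xA, "xB": xB, "yA": yA, "yB": yB},
        starts=starts,
        ends=ends,
        n_lines=n,
        native_length=max(2, round(d)),
        fallback_anchors=fbA or fbB,
    )


def sample_profile(
    image: np.ndarray,
    start,
    end,
    n_samples: int | None = None,
    with_flag: bool = False,
):
    """Evenly spaced bi-cubic sub-pixel samples of ``image`` along a segment.

    ``n_samples`` defaults to the segment length rounded to the nearest
    pixel.  Sample points falling outside the frame are clipped to it (the
    flag reports whether clipping occurred).
    """
    img = np.asarray(image, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    seg = np.linalg.norm(end - start)
    if seg < 1e-12:
        raise ValueError("degenerate segment: start == end")
    if n_samples is None:
        n_samples = max(2, round(seg))
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = start[None, :] + t * (end - start)[None, :]
    lim = np.array([img.shape[0] - 1, img.shape[1] - 1], dtype=float)
    clipped_pts = np.clip(pts, 0.0, lim)
    was_clipped = bool(np.any(clipped_pts != pts))
    values = map_coordinates(img, clipped_pts.T, order=3, mode="nearest")
    if with_flag:
        return values, was_clipped
    return values


def rd_boundary_spline(
    cell: int, network: CellNetwork, n_dense: int = 1024
) -> np.ndarray | None:
    """Closed periodic cubic spline through the neighbouring centroids.

    Neighbours are sorted by angle around the cell centroid; the spline is
    parameterised by that angle and densely sampled into a closed polyline.
    Cells with fewer than 3 neighbours (image-border cells) are excluded and
    ``None`` is returned.
    """
    nbrs = network.neighbors(cell)
    if len(nbrs) < 3:
        logger.info("cell %s excluded from RD analysis (%d neighbours)", cell, len(nbrs))
        return None
    c = network.centroid_of(cell)
    pts = np.array([network.centroid_of(k) for k in nbrs], dtype=float)
    ang = np.arctan2(pts[:, 0] - c[0], pts[:, 1] - c[1])
    order = np.argsort(ang)
    ang, pts = ang[order], pts[order]
    # strictly increasing parameter, closed periodically
    if np.any(np.diff(ang) <= 1e-9):
        ang = ang + np.arange(len(ang)) * 1e-9
    t = np.append(ang, ang[0] + 2.0 * math.pi)
    y = np.vstack([pts, pts[:1]])
    spline = CubicSpline(t, y, axis=0, bc_type="periodic")
    dense = spline(np.linspace(t[0], t[-1], n_dense, endpoint=False))
    return dense


def _first_ray_hit(center, direction, polyline) -> float | None:
    """Distance along a ray to its first crossing of a closed polyline."""
    P = polyline
    Q = np.roll(polyline, -1, axis=0)
    d = Q - P
    w = direction
    denom = w[0] * d[:, 1] - w[1] * d[:, 0]  # cross(w, d)
    rel = P - center
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0]) / denom
        s = (rel[:, 0] * w[1] - rel[:, 1] * w[0]) / -denom
    ok = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1.0 + 1e-9) & (t > 1e-9)
    if not ok.any():
        return None
    return float(t[ok].min())  # first-intersection rule: smallest r


def rd_profiles(
    cell: int,
    boundary_spline: np.ndarray,
    image: np.ndarray,
    m: int = DEFAULT_N_RAYS,
    center=None,
    network: CellNetwork | None = None,
) -> RDFan | None:
    """Sample m equi-angular radial profiles out to the boundary spline.

    Ray i leaves the centroid at angle 2*pi*i/m; its terminal point is the
    first intersection with the spline and its native length r_i the rounded
    centroid-to-intersection distance.  Returns ``None`` (cell excluded) when
    any ray fails to intersect, e.g. for a centroid outside its own spline.
    """
    if center is None:
        if network is None:
            raise ValueError("need either center or network")
        center = network.centroid_of(cell)
    c = np.asarray(center, dtype=float)
    ends, lengths, profs = [], [], []
    for i in range(m):
        theta = 2.0 * math.pi * i / m
        w = np.array([math.sin(theta), math.cos(theta)])
        r = _first_ray_hit(c, w, boundary_spline)
        if r is None:
            logger.info("cell %s excluded from RD analysis (ray misses spline)", cell)
            return None
        y_i = c + r * w
        r_i = max(2, round(r))
        ends.append(y_i)
        lengths.append(r_i)
        profs.append(sample_profile(image, c, y_i, n_samples=r_i))
    return RDFan(
        cell=cell,
        center=c,
        n_rays=m,
        boundary_spline=boundary_spline,
        ray_ends=np.array(ends),
        native_lengths=np.array(lengths),
        raw_profiles=profs,
    )


def normalize_length(profile: np.ndarray, n_samples: int = DEFAULT_PROFILE_LEN) -> np.ndarray:
    """Cubic resampling of a profile onto ``n_samples`` even positions.

    The interpolant spans the full native extent, so the endpoints are
    preserved exactly; short profiles fall back to the highest interpolation
    order their length supports.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("profile must be 1-D with native length >= 2")
    x = np.linspace(0.0, 1.0, len(y))
    xi = np.linspace(0.0, 1.0, n_samples)
    if len(y) >= 4:
        return CubicSpline(x, y)(xi)
    kind = {2: "linear", 3: "quadratic"}[len(y)]
    return interp1d(x, y, kind=kind)(xi)


def assemble_matrix(items, n_samples: int = DEFAULT_PROFILE_LEN) -> ProfileMatrix:
    """Normalise and pack beams or fans into a single profile matrix.

    IN beams contribute ``n_lines`` columns per cell pair, RD fans ``m``
    columns per included cell.  Mixing the two kinds is an error.  Columns
    are floored at zero: fluorescence intensities are non-negative, so any
    undershoot is bi-cubic interpolation ringing, and a negative sample would
    break the Poisson fidelity model downstream.
    """
    items = list(items)
    if not items:
        raise ValueError("no profiles to assemble")
    kinds = {type(it).__name__ for it in items}
    if kinds == {"INBeam"}:
        kind = "IN"
    elif kinds == {"RDFan"}:
        kind = "RD"
    else:
        raise ValueError(f"cannot mix profile kinds: {kinds}")
    cols, prov, native = [], [], []
    for it in items:
        if kind == "IN":
            for i, p in enumerate(it.raw_profiles):
                cols.append(normalize_length(p, n_samples))
                prov.append(f"pair:{it.pair[0]}-{it.pair[1]}:line:{i}")
                native.append(it.native_length)
        else:
            for i, p in enumerate(it.raw_profiles):
                cols.append(normalize_length(p, n_samples))
                prov.append(f"cell:{it.cell}:ray:{i}")
                native.append(int(it.native_lengths[i]))
    return ProfileMatrix(
        Y=np.maximum(np.column_stack(cols), 0.0),
        kind=kind,
        provenance=prov,
        native_lengths=np.array(native),
    )


def extract_in_profiles(
    image: np.ndarray,
    network: CellNetwork,
    n_lines: int = DEFAULT_N_LINES,
) -> list[INBeam]:
    """Sample the IN beams of every network edge on the marker channel."""
    idx = {r.label: r for r in network.nodes}
    beams = []
    for a, b in sorted(network.edges):
        beam = in_beam_endpoints(idx[a], idx[b], n_lines)
        clipped = False
        for s, e in zip(beam.starts, beam.ends):
            vals, flag = sample_profile(
                image, s, e, n_samples=beam.native_length, with_flag=True
            )
            clipped |= flag
            beam.raw_profiles.append(vals)
        beam.clipped = clipped
        beams.append(beam)
    return beams


def extract_rd_profiles(
    image: np.ndarray,
    network: CellNetwork,
    m: int = DEFAULT_N_RAYS,
) -> list[RDFan]:
    """Sample the RD fan of every interior cell (>= 3 neighbours)."""
    fans = []
    for rec in network.nodes:
        spline = rd_boundary_spline(rec.label, network)
        if spline is None:
            continue
        fan = rd_profiles(rec.label, spline, image, m=m, center=rec.centroid)
        if fan is not None:
            fans.append(fan)
    return fans
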