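"""Seeded synthetic two-channel fluorescence images of confluent cell populations.

The generator places nuclei on a jittered grid, partitions the frame into
confluent cell regions (a Voronoi tessellation of the nucleus centroids, each
cell clipped to its own random ellipse), and paints one of three marker
localisation prototypes into each cell:

``membrane``
    a bright ring hugging the cell-cell boundary (E-cadherin-like),
``cytoplasm``
    a smooth field rising from the nucleus toward, but dropping at, the
    boundary (tubulin-like),
``organelle``
    a compact perinuclear annulus with a near-dark cytosol (mitochondria-like).

Poisson shot noise can be applied per channel, so the images resemble
photon-limited fluorescence micrographs.  Ground truth (sub-pixel nucleus
centroids, labelled nucleus masks, the cell-region label image) is returned
alongside the rendered channels, which makes the samples usable as oracles for
segmentation, network construction and profile extraction.

Intensities are carried as floats on an 8-bit-like [0, 255] "a.u." scale.
Coordinates are 0-based ``(row, col)`` with pixel centres at integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

__all__ = [
    "PopulationConfig",
    "SyntheticSample",
    "generate_population",
    "render_marker",
    "add_poisson_noise",
    "warped_profile_stack",
]

MARKER_MODES = ("membrane", "cytoplasm", "organelle")
INTENSITY_MAX = 255.0


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of one synthetic cell population.

    Defaults describe a 512x512 field with 30 confluent cells, nucleus
    semi-axes of 7-12 px inside cell ellipses of 28-48 px, and a membrane
    marker rendered as a Gaussian ridge of ~2 px half-width on a base of
    10 a.u. peaking at 200 a.u.
    """

    image_height: int = 512
    image_width: int = 512
    n_cells: int = 30
    nucleus_axes_range: tuple[float, float] = (7.0, 12.0)
    cell_axes_range: tuple[float, float] = (28.0, 48.0)
    jitter: float = 8.0
    marker_mode: str = "membrane"
    membrane_width: float = 2.0
    base_intensity: float = 10.0
    peak_intensity: float = 200.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.marker_mode not in MARKER_MODES:
            raise ValueError(f"unknown marker_mode {self.marker_mode!r}")
        if not (0 < self.nucleus_axes_range[0] <= self.nucleus_axes_range[1]):
            raise ValueError("invalid nucleus_axes_range")
        if not (0 < self.cell_axes_range[0] <= self.cell_axes_range[1]):
            raise ValueError("invalid cell_axes_range")
        if self.nucleus_axes_range[1] >= self.cell_axes_range[0]:
            raise ValueError("nucleus axes must be smaller than cell axes")
        for v in (self.base_intensity, self.peak_intensity):
            if not (0.0 <= v <= INTENSITY_MAX):
                raise ValueError("intensities must lie in [0, 255]")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass
class SyntheticSample:
    """Rendered channels plus ground truth for one population."""

    nuclei_channel: np.ndarray
    marker_channel: np.ndarray
    true_centroids: np.ndarray  # (n_cells, 2) sub-pixel (row, col)
    nucleus_masks: np.ndarray  # labelled int array, 0 = background
    cell_labels: np.ndarray  # labelled int array, every pixel assigned
    config: PopulationConfig = field(repr=False)


def _ellipse_mask(shape, center, axes, theta):
    """Boolean mask of a rotated ellipse (row, col) on a grid of `shape`."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _place_centroids(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid placement with bounded retries against nucleus overlap."""
    h, w, n = config.image_height, config.image_width, config.n_cells
    ncols = max(1, math.ceil(math.sqrt(n * w / h)))
    nrows = math.ceil(n / ncols)
    sy, sx = h / nrows, w / ncols
    margin = config.nucleus_axes_range[1] + 2.0
    sites = [
        ((i + 0.5) * sy, (j + 0.5) * sx) for i in range(nrows) for j in range(ncols)
    ]
    order = rng.permutation(len(sites))[:n]
    base = np.array([sites[k] for k in order])
    min_sep = 2.0 * config.nucleus_axes_range[1] + 2.0
    for _ in range(50):
        jit = rng.uniform(-config.jitter, config.jitter, size=base.shape)
        cand = base + jit
        cand[:, 0] = np.clip(cand[:, 0], margin, h - 1 - margin)
        cand[:, 1] = np.clip(cand[:, 1], margin, w - 1 - margin)
        d = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_sep:
            return cand
    raise RuntimeError(
        f"could not place {n} non-overlapping nuclei in a "
        f"{h}x{w} frame after bounded retries"
    )


def render_marker(
    cell_region: np.ndarray,
    mode: str,
    config: PopulationConfig,
    nucleus_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Render the marker intensity patch for one cell region.

    Parameters
    ----------
    cell_region
        Boolean mask of the cell's territory (full-frame).
    mode
        One of ``membrane``, ``cytoplasm``, ``organelle``.
    nucleus_mask
        Boolean mask of this cell's nucleus; required geometry for the
        perinuclear ``organelle`` pattern (approximated from the deep region
        interior when absent).

    Returns a full-frame float array that is zero outside ``cell_region``.
    """
    region = np.asarray(cell_region, dtype=bool)
    if not region.any():
        raise ValueError("empty cell region")
    base, peak, w = (
        config.base_intensity,
        config.peak_intensity,
        max(config.membrane_width, 0.5),
    )
    out = np.zeros(region.shape, dtype=float)
    # distance (px) from each region pixel to the nearest non-region pixel;
    # pixels adjacent to the boundary have d == 1
    d = distance_transform_edt(region)
    if mode == "membrane":
        out[region] = base + (peak - base) * np.exp(
            -0.5 * ((d[region] - 1.0) / w) ** 2
        )
    elif mode == "cytoplasm":
        d_peak = 1.0 + 2.0 * w  # intensity crest sits just inside the boundary
        out[region] = base + (peak - base) * np.exp(
            -0.5 * ((d[region] - d_peak) / (2.0 * w)) ** 2
        )
    elif mode == "organelle":
        if nucleus_mask is None:
            nucleus_mask = d >= 0.6 * d.max()
        dn = distance_transform_edt(~np.asarray(nucleus_mask, dtype=bool))
        r0 = 1.0 + w  # annulus centre just outside the nuclear envelope
        floor = 0.05 * base
        vals = np.full(region.sum(), floor)
        outside = dn[region] > 0
        vals[outside] += peak * np.exp(-0.5 * ((dn[region][outside] - r0) / w) ** 2)
        out[region] = vals
    else:
        raise ValueError(f"unknown marker mode {mode!r}")
    return out


def add_poisson_noise(image: np.ndarray, seed: int) -> np.ndarray:
    """Replace every pixel by a Poisson draw with mean equal to the clean value.

    Output is clipped to the [0, 255] intensity range. Raises on negative input.
    """
    img = np.asarray(image, dtype=float)
    if (img < 0).any():
        raise ValueError("Poisson noise requires non-negative intensities")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(img).astype(float)
    return np.clip(noisy, 0.0, INTENSITY_MAX)


def generate_population(config: PopulationConfig) -> SyntheticSample:
    """Generate one synthetic two-channel population with ground truth.

    The same config (including seed) reproduces byte-identical channels.
    """
    rng = np.random.default_rng(config.seed)
    h, w, n = config.image_height, config.image_width, config.n_cells
    centroids = _place_centroids(config, rng)

    # nuclei: rotated ellipses, guaranteed disjoint by the placement separation
    nucleus_masks = np.zeros((h, w), dtype=np.int32)
    nuc_params = []
    for k in range(n):
        a, b = rng.uniform(*config.nucleus_axes_range, size=2)
        theta = rng.uniform(0.0, math.pi)
        nuc_params.append((a, b, theta))
        m = _ellipse_mask((h, w), centroids[k], (a, b), theta)
        nucleus_masks[m] = k + 1

    # confluent cell regions: Voronoi cells clipped to per-cell ellipses,
    # leftovers reassigned to the nearest covering ellipse (else nearest
    # centroid) so the partition tiles the frame without gaps
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr[None] - centroids[:, 0, None, None]) ** 2 + (
        cc[None] - centroids[:, 1, None, None]
    ) ** 2
    inside = np.zeros((n, h, w), dtype=bool)
    for k in range(n):
        a, b = rng.uniform(*config.cell_axes_range, size=2)
        theta = rng.uniform(0.0, math.pi)
        inside[k] = _ellipse_mask((h, w), centroids[k], (a, b), theta)
    d2_masked = np.where(inside, d2, np.inf)
    covered = inside.any(axis=0)
    lab = np.where(covered, np.argmin(d2_masked, axis=0), np.argmin(d2, axis=0))
    cell_labels = (lab + 1).astype(np.int32)

    # nuclei channel: bright smoothed ellipses on a dim background
    nuclei = config.base_intensity + (
        config.peak_intensity - config.base_intensity
    ) * gaussian_filter((nucleus_masks > 0).astype(float), sigma=1.0)

    marker = np.zeros((h, w), dtype=float)
    for k in range(n):
        region = cell_labels == k + 1
        if not region.any():  # pragma: no cover - placement prevents this
            continue
        patch = render_marker(
            region, config.marker_mode, config, nucleus_mask=nucleus_masks == k + 1
        )
        marker[region] = patch[region]

    nuclei = np.clip(nuclei, 0.0, INTENSITY_MAX)
    marker = np.clip(marker, 0.0, INTENSITY_MAX)
    if config.poisson_noise:
        sub = rng.integers(0, 2**31 - 1, size=2)
        nuclei = add_poisson_noise(nuclei, int(sub[0]))
        marker = add_poisson_noise(marker, int(sub[1]))

    return SyntheticSample(
        nuclei_channel=nuclei,
        marker_channel=marker,
        true_centroids=centroids,
        nucleus_masks=nucleus_masks,
        cell_labels=cell_labels,
        config=config,
    )


def _monotone_cubic_warp(rng: np.random.Generator, strength: float):
    """Draw a random monotone cubic warp g:[0,1]->[0,1], g(0)=0, g(1)=1.

    The warp is a cubic Bezier with sorted interior control values (which
    guarantees monotonicity), blended with the identity by ``strength`` in
    [0, 1].  At strength 1 the typical mid-profile displacement is ~0.15.
    """
    b1, b2 = np.sort(rng.uniform(0.0, 1.0, size=2))
    s = float(strength)

    def g(x, b1=b1, b2=b2, s=s):
        x = np.asarray(x, dtype=float)
        bez = 3.0 * b1 * x * (1.0 - x) ** 2 + 3.0 * b2 * x**2 * (1.0 - x) + x**3
        return (1.0 - s) * x + s * bez

    return g


def warped_profile_stack(
    n_samples: int = 101,
    n_profiles: int = 30,
    peak: float = 100.0,
    seed: int = 0,
    noise: str = "poisson",
    warp_strength: float = 0.6,
    bump_width: float = 0.12,
):
    """Stack of warped copies of a smooth template, the study condition for
    the compensation benchmarks.

    Each column is ``y_j(x_i) = f(g_j(x_i))`` (plus optional noise) for a
    smooth Gaussian-bump template ``f`` centred at 0.5 and a random monotone
    cubic warp ``g_j``.  Defaults follow the benchmark conditions used
    throughout the test-suite: 30 profiles, Poisson noise at peak 100.

    Returns ``(Y, f_grid, f_func)`` where ``f_grid`` is the clean template on
    the uniform ``n_samples`` grid and ``f_func`` evaluates it anywhere.
    """
    if noise not in ("poisson", "awgn", "none"):
        raise ValueError(f"unknown noise kind {noise!r}")
    rng = np.random.default_rng(seed)
    baseline = 0.1 * peak

    def f(x):
        return baseline + (peak - baseline) * np.exp(
            -0.5 * ((np.asarray(x) - 0.5) / bump_width) ** 2
        )

    x = np.linspace(0.0, 1.0, n_samples)
    Y = np.empty((n_samples, n_profiles))
    for j in range(n_profiles):
        g = _monotone_cubic_warp(rng, warp_strength)
        Y[:, j] = f(np.clip(g(x), 0.0, 1.0))
    if noise == "poisson":
        Y = rng.poisson(Y).astype(float)
    elif noise == "awgn":
        Y = Y + rng.normal(0.0, math.sqrt(peak) / 2.0, size=Y.shape)
    return Y, f(x), f
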