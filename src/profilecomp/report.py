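"""End-user outputs: summaries, maps, virtual-cell renderings, full pipeline.

The summaries and maps are the quantitative deliverables (mean +/- SD curves
with the peak position/value, intensity heatmaps); the virtual cell pair and
polar virtual cell turn an estimated internuclear or radial template into an
idealised image of a "typical" cell pair or cell.  ``run_pipeline`` chains
segmentation, network construction, profile extraction, compensation and
summarisation into one deterministic report bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
import imageio.v3 as iio
import matplotlib.pyplot as plt
from matplotlib import cm

from . import align, network as network_mod, profiles as profiles_mod
from .align import AlignmentParams, IdealProfile
from .synthgen import SyntheticSample

__all__ = [
    "ProfileSummary",
    "summarize",
    "render_map",
    "virtual_cell_pair",
    "virtual_cell_polar",
    "polar_overview",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class ProfileSummary:
    mean: np.ndarray
    sd: np.ndarray
    peak_position: int
    peak_value: float
    n_profiles_used: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean"] = self.mean.tolist()
        d["sd"] = self.sd.tolist()
        return d


def summarize(profile_map: np.ndarray, omega=None) -> ProfileSummary:
    """Row-wise mean and SD over the valid (omega = 1) columns.

    The peak is the argmax of the mean; ties resolve to the smallest index
    (logged).
    """
    Y = np.asarray(profile_map, dtype=float)
    if Y.size == 0:
        raise ValueError("empty map")
    if omega is None:
        omega = np.ones(Y.shape[1])
    valid = np.asarray(omega, dtype=float) > 0
    if not valid.any():
        raise ValueError("all columns excluded")
    sub = Y[:, valid]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1)
    peak = int(np.argmax(mean))
    if np.count_nonzero(mean == mean[peak]) > 1:
        logger.info("peak tie resolved to smallest index %d", peak)
    return ProfileSummary(
        mean=mean,
        sd=sd,
        peak_position=peak,
        peak_value=float(mean[peak]),
        n_profiles_used=int(valid.sum()),
    )


def render_map(profile_map: np.ndarray, out_png: str | Path | None = None) -> np.ndarray:
    """Intensity-scaled heatmap (rows = positions, columns = profiles).

    Returns the RGB uint8 image; also writes it as PNG when a path is given.
    """
    Y = np.asarray(profile_map, dtype=float)
    if Y.size == 0:
        raise ValueError("empty map")
    lo, hi = Y.min(), Y.max()
    norm = np.zeros_like(Y) if hi - lo < 1e-15 else (Y - lo) / (hi - lo)
    rgba = cm.viridis(norm)
    img = (rgba[..., :3] * 255).astype(np.uint8)
    if out_png is not None:
        iio.imwrite(Path(out_png), img)
    return img


def virtual_cell_pair(
    profile: IdealProfile | np.ndarray,
    nucleus_radius: float = 20.0,
    distance: float = 100.0,
    pad: int = 12,
) -> np.ndarray:
    """Idealised image of a typical cell pair coloured by the IN template.

    Two template nuclei sit a fixed distance apart; every internuclear chord
    of the beam band is coloured by f at its normalised position (nucleus
    interiors are masked to zero, as the marker is not nuclear).
    """
    f = profile.evaluate if isinstance(profile, IdealProfile) else profile
    R = nucleus_radius
    h = int(2 * (R + pad)) + 1
    w = int(distance + 2 * pad) + 1
    cy = (h - 1) / 2.0
    xA, xB = float(pad), float(pad + distance)
    img = np.zeros((h, w), dtype=float)
    rr, cc = np.mgrid[0:h, 0:w]
    band = (np.abs(rr - cy) <= R) & (cc >= xA) & (cc <= xB)
    t = np.clip((cc - xA) / (xB - xA), 0.0, 1.0)
    img[band] = np.asarray(f(t[band]), dtype=float)
    for cx in (xA, xB):
        img[(rr - cy) ** 2 + (cc - cx) ** 2 <= R**2] = 0.0
    return img


def virtual_cell_polar(
    profile: IdealProfile | np.ndarray, radius: float = 60.0, pad: int = 8
) -> np.ndarray:
    """Radially symmetric virtual cell: pixel at normalised radius r gets f(r)."""
    f = profile.evaluate if isinstance(profile, IdealProfile) else profile
    size = int(2 * (radius + pad)) + 1
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    r = np.hypot(rr - c, cc - c) / radius
    img = np.zeros((size, size), dtype=float)
    inside = r <= 1.0
    img[inside] = np.asarray(f(r[inside]), dtype=float)
    return img


def polar_overview(rd_map: np.ndarray, out_png: str | Path) -> None:
    """Polar plot of all compensated RD columns (cosmetic QC figure)."""
    Y = np.asarray(rd_map, dtype=float)
    n = Y.shape[0]
    r = np.linspace(0.0, 1.0, n)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    m = Y.shape[1]
    for j in range(m):
        theta = np.full(n, 2 * np.pi * j / m)
        ax.scatter(theta, r, c=Y[:, j], s=2, cmap="viridis")
    fig.savefig(out_png, dpi=100)
    plt.close(fig)


def _mean_sd_figure(summary: ProfileSummary, title: str, out_png: Path) -> None:
    pos = np.arange(len(summary.mean))
    fig, ax = plt.subplots()
    ax.plot(pos, summary.mean, color="C0", label="mean")
    ax.fill_between(
        pos,
        summary.mean - summary.sd,
        summary.mean + summary.sd,
        alpha=0.3,
        color="C0",
        label="+/- SD",
    )
    ax.set_xlabel("profile position")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_title(title)
    ax.legend()
    fig.savefig(out_png, dpi=100)
    plt.close(fig)


def run_pipeline(
    sample,
    out_dir: str | Path | None = None,
    n_lines: int = profiles_mod.DEFAULT_N_LINES,
    n_rays: int = profiles_mod.DEFAULT_N_RAYS,
    profile_len: int = profiles_mod.DEFAULT_PROFILE_LEN,
    noise_model: str = "poisson",
    min_area: int = 30,
    do_rd: bool = True,
    align_kwargs: dict | None = None,
) -> dict:
    """Full workflow: network -> extraction -> alignment -> summaries.

    ``sample`` is a SyntheticSample or a ``(nuclei_channel, marker_channel)``
    pair.  Returns a JSON-serialisable bundle with per-kind summaries; when
    ``out_dir`` is given, figures and CSV/JSON artefacts are written there.
    Stage failures are re-raised with the stage name attached.
    """
    if isinstance(sample, SyntheticSample):
        nuclei, marker = sample.nuclei_channel, sample.marker_channel
    else:
        nuclei, marker = sample
    align_kwargs = dict(align_kwargs or {})
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    enhanced = stage("preprocess", network_mod.preprocess, nuclei)
    records = stage("segment", network_mod.segment_nuclei, enhanced, min_area)
    centroids = np.array([r.centroid for r in records])
    net = stage("network", network_mod.build_network, centroids, records)
    bundle: dict = {
        "n_nuclei": len(records),
        "n_edges": len(net.edges),
        "n_triangles": len(net.triangles),
        "n_removed_triangles": len(net.removed_triangles),
        "noise_model": noise_model,
    }

    beams = stage("extract_in", profiles_mod.extract_in_profiles, marker, net, n_lines)
    if beams:
        pm = stage("assemble_in", profiles_mod.assemble_matrix, beams, profile_len)
        params = AlignmentParams.for_kind("IN", noise_model=noise_model, **align_kwargs)
        state, ideal = stage("align_in", align.compensate, pm, params)
        cmap = align.compensated_map(state, pm)
        summ = summarize(cmap, state.omega)
        raw = summarize(pm.Y)
        bundle["in"] = {
            "summary": summ.to_dict(),
            "raw_peak_position": raw.peak_position,
            "n_profiles": pm.n_profiles,
            "n_outliers": int(len(state.omega) - state.omega.sum()),
            "iterations": state.iterations,
        }
        if out is not None:
            render_map(cmap, out / "in_map_compensated.png")
            render_map(pm.Y, out / "in_map_raw.png")
            _mean_sd_figure(summ, "compensated IN profile", out / "in_mean_sd.png")
            iio.imwrite(
                out / "virtual_cell_pair.png",
                render_map(virtual_cell_pair(ideal))[..., :3],
            )
            np.savetxt(
                out / "in_ideal_profile.csv",
                np.column_stack(
                    [np.arange(profile_len), ideal(np.linspace(0, 1, profile_len))]
                ),
                delimiter=",",
                header="position,intensity",
                comments="",
            )

    if do_rd:
        fans = stage("extract_rd", profiles_mod.extract_rd_profiles, marker, net, n_rays)
        if fans:
            pm_rd = stage("assemble_rd", profiles_mod.assemble_matrix, fans, profile_len)
            params_rd = AlignmentParams.for_kind(
                "RD", noise_model=noise_model, **align_kwargs
            )
            state_rd, ideal_rd = stage("align_rd", align.compensate, pm_rd, params_rd)
            cmap_rd = align.compensated_map(state_rd, pm_rd)
            summ_rd = summarize(cmap_rd, state_rd.omega)
            bundle["rd"] = {
                "summary": summ_rd.to_dict(),
                "n_profiles": pm_rd.n_profiles,
                "n_cells_used": len(fans),
                "n_outliers": int(len(state_rd.omega) - state_rd.omega.sum()),
                "iterations": state_rd.iterations,
            }
            if out is not None:
                render_map(cmap_rd, out / "rd_map_compensated.png")
                _mean_sd_figure(
                    summ_rd, "compensated RD profile", out / "rd_mean_sd.png"
                )
                iio.imwrite(
                    out / "virtual_cell_polar.png",
                    render_map(virtual_cell_polar(ideal_rd))[..., :3],
                )
        else:
            bundle["rd"] = None
            logger.info("no interior cells: RD analysis skipped")

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
    return bundle
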