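"""Readers and writers for the pipeline's on-disk artefacts.

Profile matrices travel as CSV (one column per profile, provenance in the
header, kind/native lengths in comment lines) or as an HDF5 group; networks
and ground-truth centroids as JSON; images as TIFF/PNG via tifffile/imageio.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .network import CellNetwork, NucleusRecord
from .profiles import ProfileMatrix
from .synthgen import SyntheticSample

__all__ = [
    "save_profile_matrix_csv",
    "load_profile_matrix_csv",
    "save_profile_matrix_h5",
    "load_profile_matrix_h5",
    "network_to_json",
    "network_from_json",
    "save_sample",
    "save_alignment_h5",
    "load_image",
]


def save_profile_matrix_csv(matrix: ProfileMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind={matrix.kind}\n")
        fh.write("# native_lengths=" + ",".join(map(str, matrix.native_lengths)) + "\n")
        pd.DataFrame(matrix.Y, columns=matrix.provenance).to_csv(fh, index=False)


def load_profile_matrix_csv(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    with open(path) as fh:
        kind = fh.readline().strip().split("=", 1)[1]
        native = np.array(
            [int(v) for v in fh.readline().strip().split("=", 1)[1].split(",")]
        )
        df = pd.read_csv(fh)
    return ProfileMatrix(
        Y=df.to_numpy(float),
        kind=kind,
        provenance=list(df.columns),
        native_lengths=native,
    )


def save_profile_matrix_h5(matrix: ProfileMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=matrix.Y)
        f.create_dataset("native_lengths", data=matrix.native_lengths)
        f.create_dataset(
            "provenance", data=np.array(matrix.provenance, dtype=h5py.string_dtype())
        )
        f.attrs["kind"] = matrix.kind


def load_profile_matrix_h5(path: str | Path) -> ProfileMatrix:
    with h5py.File(path, "r") as f:
        return ProfileMatrix(
            Y=f["Y"][...],
            kind=str(f.attrs["kind"]),
            provenance=[s.decode() for s in f["provenance"][...]],
            native_lengths=f["native_lengths"][...],
        )


def network_to_json(net: CellNetwork, path: str | Path) -> None:
    payload = {
        "nodes": [
            {
                "label": n.label,
                "centroid": list(map(float, n.centroid)),
                "area": n.area,
                "boundary": np.asarray(n.boundary).tolist(),
            }
            for n in net.nodes
        ],
        "edges": sorted(map(list, net.edges)),
        "triangles": sorted(map(list, net.triangles)),
        "removed_triangles": [
            {**r, "triangle": list(r["triangle"])} for r in net.removed_triangles
        ],
        "orphan_edges": sorted(map(list, net.orphan_edges)),
        "degenerate": net.degenerate,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def network_from_json(path: str | Path) -> CellNetwork:
    payload = json.loads(Path(path).read_text())
    nodes = [
        NucleusRecord(
            label=n["label"],
            centroid=np.array(n["centroid"], dtype=float),
            boundary=np.array(n["boundary"], dtype=float).reshape(-1, 2),
            area=n["area"],
        )
        for n in payload["nodes"]
    ]
    return CellNetwork(
        nodes=nodes,
        edges={tuple(e) for e in payload["edges"]},
        triangles=[tuple(t) for t in payload["triangles"]],
        removed_triangles=[
            {**r, "triangle": tuple(r["triangle"])}
            for r in payload["removed_triangles"]
        ],
        orphan_edges={tuple(e) for e in payload["orphan_edges"]},
        degenerate=payload["degenerate"],
    )


def save_sample(sample: SyntheticSample, out_dir: str | Path) -> None:
    """Write channels (TIFF), labelled masks, ground truth and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "nuclei.tif", sample.nuclei_channel.astype(np.float32))
    tifffile.imwrite(out / "marker.tif", sample.marker_channel.astype(np.float32))
    tifffile.imwrite(out / "nucleus_masks.tif", sample.nucleus_masks)
    tifffile.imwrite(out / "cell_labels.tif", sample.cell_labels)
    (out / "centroids.json").write_text(
        json.dumps({"true_centroids": sample.true_centroids.tolist()}, indent=2)
    )
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(sample.config), indent=2)
    )


def save_alignment_h5(state, ideal, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X_star", data=state.X)
        f.create_dataset("c", data=state.c)
        f.create_dataset("omega", data=state.omega)
        f.create_dataset("energy_trace", data=state.energy_trace)
        f.attrs["iterations"] = state.iterations
        f.attrs["L"] = ideal.L
        f.attrs["symmetric"] = ideal.symmetric


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse RGB to intensity
        img = img[..., :3].mean(axis=-1)
    return img
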