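import logging

import numpy as np
import pytest

import profilecomp as pc

logging.getLogger("profilecomp").setLevel(logging.ERROR)


def circle_record(label, center, radius, n=720):
    """Analytic circular nucleus boundary for geometry oracles."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    boundary = np.column_stack(
        [center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)]
    )
    return pc.NucleusRecord(
        label=label,
        centroid=np.asarray(center, dtype=float),
        boundary=boundary,
        area=int(np.pi * radius**2),
    )


@pytest.fixture(scope="session")
def small_membrane_sample():
    """Noiseless 9-cell membrane-marker population (256x256)."""
    cfg = pc.PopulationConfig(
        image_height=256,
        image_width=256,
        n_cells=9,
        nucleus_axes_range=(6.0, 9.0),
        cell_axes_range=(30.0, 48.0),
        jitter=6.0,
        poisson_noise=False,
        seed=7,
    )
    return pc.generate_population(cfg)


@pytest.fixture(scope="session")
def membrane_network(small_membrane_sample):
    s = small_membrane_sample
    records = pc.segment_nuclei(pc.preprocess(s.nuclei_channel))
    net = pc.build_network(np.array([r.centroid for r in records]), records)
    return records, net


@pytest.fixture(scope="session")
def compass_network():
    """A centre cell with 4 neighbours at the compass points, distance 20."""
    c = np.array([50.0, 50.0])
    pts = [c, c + [20, 0], c - [20, 0], c + [0, 20], c - [0, 20]]
    records = [
        pc.NucleusRecord(label=i + 1, centroid=np.asarray(p, float),
                         boundary=np.empty((0, 2)), area=0)
        for i, p in enumerate(pts)
    ]
    edges = {(1, 2), (1, 3), (1, 4), (1, 5)}
    return pc.CellNetwork(nodes=records, edges=edges, triangles=[])
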