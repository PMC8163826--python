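import warnings

import numpy as np
import pytest

from latticectx.synthetic import (
    build_icosahedron,
    build_polyhedron,
    build_tube,
    render_density,
)


@pytest.fixture(scope="session")
def tube_graph():
    return build_tube(10, 5, 80.0)


@pytest.fixture(scope="session")
def t1_graph():
    return build_icosahedron(1, 80.0)


@pytest.fixture(scope="session")
def t3_graph():
    return build_icosahedron(3, 80.0)


@pytest.fixture(scope="session")
def poly42_graph():
    return build_polyhedron(42, 0.0, seed=1)


@pytest.fixture(scope="session")
def tube_scene(tube_graph):
    """Rendered noise-free tube volume plus voxel-space ground truth."""
    vol, truth = render_density(tube_graph, 4.0, (128, 128, 96))
    return vol, truth


@pytest.fixture(scope="session")
def small_tube_scene():
    """Small tube at coarse voxels for matching tests."""
    g = build_tube(10, 5, 80.0)
    vol, truth = render_density(g, 6.0, (80, 80, 72))
    return vol, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full simulate->match->network->classify run on a polyhedron."""
    import json

    from latticectx.pipeline import default_config, run_pipeline

    out_dir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = default_config("polyhedron", seed=1)
    cfg["simulate"]["box"] = 144
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_pipeline(cfg, out_dir)
    with open(out / "summary.json") as fh:
        return json.load(fh), out
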