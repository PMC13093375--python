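"""Shared fixtures: small worked examples and one default synthetic run.

The default world (100×100 grid, 60 paleo slices, 10 indicator + 40 focal
species, master seed 42) is expensive enough to build once per session; the
planted-signal tests all read from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from paleorefugia.grid import Grid, MaskLayer, RasterLayer
from paleorefugia.pipeline import AnalysisParams, PipelineResult, analyze_world
from paleorefugia.synthetic import SimulationConfig, simulate_world
from paleorefugia.trees import Phylogeny

MASTER_SEED = 42

#: the worked three-taxon tree used across the metric examples
WORKED_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def grid4() -> Grid:
    return Grid(n_rows=4, n_cols=4, origin_x=0.0, origin_y=18.0, cell_size=4.5)


@pytest.fixture
def worked_tree() -> Phylogeny:
    return Phylogeny.from_newick(WORKED_NEWICK)


@pytest.fixture(scope="session")
def default_world():
    return simulate_world(SimulationConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def default_result(default_world) -> PipelineResult:
    return analyze_world(default_world, AnalysisParams())


def make_layer(values, cell_size=4.5, variable="x") -> RasterLayer:
    values = np.asarray(values, dtype=float)
    grid = Grid(n_rows=values.shape[0], n_cols=values.shape[1],
                origin_x=0.0, origin_y=values.shape[0] * cell_size, cell_size=cell_size)
    return RasterLayer(grid, values, variable)


def make_mask(values, cell_size=4.5, role="study_area") -> MaskLayer:
    layer = make_layer(values, cell_size)
    return MaskLayer(layer.grid, layer.values, role)
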