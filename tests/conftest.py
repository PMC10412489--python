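"""Shared fixtures: synthetic trees and solved comparative runs.

Expensive paired solves are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from corovast import make_synthetic_tree
from corovast.geometry import Segment, VesselTree
from corovast.pipeline import RunConfig, run_pipeline


def uniform_tube(diameter_mm: float, length_mm: float, n: int = 121,
                 seg_id: str = "tube") -> Segment:
    s = np.linspace(0.0, length_mm, n)
    area = np.full(n, math.pi * (diameter_mm / 2.0) ** 2)
    return Segment(seg_id, seg_id, None, np.column_stack([s, area]),
                   is_outlet=True)


def single_tube_tree(diameter_mm: float = 3.0,
                     length_mm: float = 30.0) -> VesselTree:
    return VesselTree([uniform_tube(diameter_mm, length_mm)])


@pytest.fixture(scope="session")
def left_healthy() -> VesselTree:
    tree, lesions = make_synthetic_tree("left", [], seed=1)
    assert not lesions
    return tree


@pytest.fixture(scope="session")
def d1_pair():
    """Stenotic left tree with one 60% proximal D1 lesion + healthy truth."""
    sten, truth = make_synthetic_tree("left", [("D1", "prox", 60, 10)],
                                      seed=1)
    healthy, _ = make_synthetic_tree("left", [], seed=1)
    return sten, healthy, truth


@pytest.fixture(scope="session")
def d1_result(d1_pair):
    """Full comparative run on the D1-lesion tree (auto reconstruction)."""
    sten, _, _ = d1_pair
    return run_pipeline(sten.copy(), RunConfig(seed=1))
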