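"""Shared fixtures: small phantoms and cached pipeline runs.

Heavy artifacts (a full capillary-phantom pipeline run) are session-scoped
so the suite generates them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselvox import PhantomSpec, generate_network, voxelize_geometry
from vesselvox.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def capillary_spec() -> PhantomSpec:
    """Capillary-bed meshwork: diameter ~5 µm, 12 µm pitch, 96³ µm domain."""
    return PhantomSpec(seed=1, nontissue_margin_um=12.0)


@pytest.fixture(scope="session")
def capillary_network(capillary_spec):
    return generate_network(capillary_spec)


@pytest.fixture(scope="session")
def capillary_volume(capillary_spec, capillary_network):
    geom, _ = capillary_network
    return voxelize_geometry(geom, capillary_spec)


@pytest.fixture(scope="session")
def capillary_result(capillary_spec):
    """Full pipeline run on the capillary phantom (segmentation -> fits)."""
    return run_pipeline(PipelineConfig(phantom=capillary_spec))
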