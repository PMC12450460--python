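"""Shared fixtures: the synthetic verification plate run once per session."""

from __future__ import annotations

import numpy as np
import pytest

import blotquant as bq


@pytest.fixture(scope="session")
def fixture_cfg():
    return bq.default_fixture()


@pytest.fixture(scope="session")
def fixture_scene(fixture_cfg):
    """(image, per-well truth table) of the default synthetic plate."""
    return bq.simulate_plate(fixture_cfg)


@pytest.fixture(scope="session")
def corrected_image(fixture_scene):
    """Background-corrected fixture image (sigma 2, ball radius 35)."""
    image, _ = fixture_scene
    return bq.correct(image)


@pytest.fixture(scope="session")
def pipeline_result(corrected_image):
    """Ranked sample table from the full correct -> quantify -> normalize run,
    merged with the true per-sample expression amplitudes."""
    geometry = bq.default_fixture_geometry()
    measurements = bq.measure_plate(corrected_image, geometry)
    plate_map = bq.default_fixture_plate_map()
    table = bq.process_plate(plate_map, measurements)
    truth = bq.default_fixture_truth()
    return table.merge(truth, on="sample")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
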