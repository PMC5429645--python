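"""Shared fixtures: small column models and phantom specs for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from punctforce.tissue_model import PatientModel, ThresholdSet, default_table
from punctforce.volumes import Trajectory, Volume3D


@pytest.fixture(scope="session")
def table():
    return default_table()


def make_column_model(
    layers: list[tuple[int, int]],
    spacing: float = 1.0,
    nxy: int = 3,
    table=None,
) -> PatientModel:
    """Fully labeled model of stacked layers along +z.

    ``layers`` lists (tissue code, voxel count) from the z = 0 face inward.
    With voxel centers at k*spacing, the boundary into the layer starting at
    voxel k0 lies at world z = (k0 - 0.5) * spacing.
    """
    nz = sum(n for _, n in layers)
    values = np.empty((nxy, nxy, nz), dtype=np.int16)
    k = 0
    for code, n in layers:
        values[:, :, k : k + n] = code
        k += n
    vol = Volume3D(values, (spacing, spacing, spacing))
    return PatientModel(labels=vol, table=table or default_table())


def column_trajectory(model: PatientModel, n_samples: int = 2000, margin_voxels: int = 1) -> Trajectory:
    """Axial trajectory through the column center, voxel 0 to near the end."""
    s = model.labels.spacing[0]
    c = (model.labels.shape[0] // 2) * s
    length = (model.labels.shape[2] - 1 - margin_voxels) * model.labels.spacing[2]
    return Trajectory(
        entry=(c, c, 0.0),
        direction=(0.0, 0.0, 1.0),
        length=length,
        n_samples=n_samples,
        max_length=length,
    )


@pytest.fixture()
def column_model_factory():
    return make_column_model


@pytest.fixture(scope="session")
def tiny_threshold_set():
    return ThresholdSet()
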