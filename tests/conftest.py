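"""Shared fixtures: small tissue models and fields used across the suite."""

import numpy as np
import pytest

from fpfdm import bloch_fdm as b
from fpfdm import fieldmap as fm
from fpfdm import geometry as g


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sparse_perturber_model():
    """16³ grid with 20 scattered single-voxel perturbers (label 1)."""
    rs = np.random.default_rng(1)
    labels = np.zeros((16, 16, 16), dtype=np.int8)
    labels.ravel()[rs.choice(16**3, 20, replace=False)] = 1
    return g.TissueModel(labels, 2.0)


@pytest.fixture(scope="session")
def voxel_sphere_model():
    """48³ grid holding a voxelized sphere of radius 8 voxels on a center."""
    n, vs = 48, 1.0
    c = (np.arange(n) + 0.5) * vs
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    ctr = (n / 2 + 0.5) * vs
    rr = np.sqrt((X - ctr) ** 2 + (Y - ctr) ** 2 + (Z - ctr) ** 2)
    labels = (rr <= 8.0).astype(np.int8)
    return g.TissueModel(labels, vs), ctr


@pytest.fixture(scope="session")
def cylinder_model_and_field():
    """One random-cylinder structure (validation geometry) plus its field."""
    scene = g.generate_random_cylinders(10.0, 0.02, 500.0, seed=11, check_grid=48)
    model = g.voxelize(scene, 48)
    kernel = fm.perturber_kernel(48, model.voxel_size)
    field = fm.compute_field(model, g.LABEL_VASCULAR, 4 * np.pi * 1e-7, 1.5, kernel)
    return model, field


@pytest.fixture(scope="session")
def ge_sequence():
    return b.SequenceParams("GE", 60.0, dt=0.2)
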