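import numpy as np
import pytest

import decograd as dg


@pytest.fixture(scope="session")
def planted_connectome():
    """Small planted-axis connectome shared across tests."""
    conn, truth = dg.synth_connectome(n_vertices=300, seed=11)
    return conn, truth


@pytest.fixture(scope="session")
def principal_gradient(planted_connectome):
    conn, truth = planted_connectome
    grads = dg.gradients_from_connectome(conn, seed=11)
    return grads.components[:, 0], truth.latent_axis


@pytest.fixture(scope="session")
def small_world():
    """Coupled synthetic world at test scale."""
    return dg.synth_world(n_vertices=400, n_studies=150, n_topics=8, vocab_size=160, seed=5)


def smooth_sphere_map(mesh, seed, n_bumps=5, scale=0.6):
    """Random smooth map on the sphere: a few Gaussian bumps."""
    rng = np.random.default_rng(seed)
    values = np.zeros(mesh.n_vertices)
    for _ in range(n_bumps):
        c = rng.standard_normal(3)
        c /= np.linalg.norm(c)
        chord2 = ((mesh.coordinates - c) ** 2).sum(axis=1)
        values += rng.normal() * np.exp(-chord2 / (2 * scale**2))
    return values
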