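"""Shared fixtures: small synthetic phase spaces and dose grids."""

import numpy as np
import pytest

from linacqa.phasespace import DECODED_DTYPE, PHOTON, PhaseSpace
from linacqa.synthetic import DoseModel, field_grid_spec, generate_dose_grid


def make_phasespace(n=1000, seed=0, n_histories=None, r_max=6.5, e_max=6.0,
                    kinds=(PHOTON,)):
    """Random in-memory phase space with forward-going particles."""
    rng = np.random.default_rng(seed)
    rec = np.empty(n, dtype=DECODED_DTYPE)
    rec["kind"] = rng.choice(kinds, n)
    rec["energy"] = rng.uniform(0.05, e_max, n)
    r = r_max * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    rec["x"] = r * np.cos(phi)
    rec["y"] = r * np.sin(phi)
    theta = rng.uniform(0, np.pi / 3, n)
    psi = rng.uniform(0, 2 * np.pi, n)
    rec["u"] = np.sin(theta) * np.cos(psi)
    rec["v"] = np.sin(theta) * np.sin(psi)
    rec["w"] = np.cos(theta)
    rec["weight"] = rng.uniform(0.2, 2.0, n)
    rec["new_history"] = rng.random(n) < 0.5
    rec["new_history"][0] = True
    return PhaseSpace.from_records(
        rec, z_plane=26.70,
        n_original_histories=n_histories or int(rec["new_history"].sum()),
    )


@pytest.fixture
def small_ps():
    return make_phasespace(n=2000, seed=42)


@pytest.fixture(scope="session")
def dose_model():
    return DoseModel(field_side=10.0)


@pytest.fixture(scope="session")
def noiseless_grid(dose_model):
    origin, voxel, dims = field_grid_spec(dose_model, z_max=32.0)
    return generate_dose_grid(dose_model, origin, voxel, dims, seed=0)
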