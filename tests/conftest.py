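import numpy as np
import pandas as pd
import pytest

from fretensemble import (ConjugateModelParams, SelectionSet,
                          SpectralModelParams, Trajectory,
                          gen_conjugate_trajectory, gen_transitions)


def make_trajectory(coords, names=None, res_ids=None, res_names=None,
                    chains=None, times=None):
    """Trajectory from a raw (n_frames, n_atoms, 3) array with a filled-in
    atom table."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    atoms = pd.DataFrame({
        "name": names or [f"C{i + 1}" for i in range(n_atoms)],
        "element": ["C"] * n_atoms,
        "res_id": res_ids if res_ids is not None else [1] * n_atoms,
        "res_name": res_names or ["UNK"] * n_atoms,
        "chain": chains or ["A"] * n_atoms,
    })
    return Trajectory(atoms, coords, times=times)


def hexagon(center, radius=1.39, normal_axis=2):
    """Planar hexagon with given center; plane perpendicular to the
    chosen axis."""
    ang = np.radians(np.arange(6) * 60.0)
    pts = np.zeros((6, 3))
    in_plane = [i for i in range(3) if i != normal_axis]
    pts[:, in_plane[0]] = radius * np.cos(ang)
    pts[:, in_plane[1]] = radius * np.sin(ang)
    return pts + np.asarray(center, dtype=float)


@pytest.fixture(scope="session")
def two_mode_ensemble():
    """The reference two-population conjugate ensemble: 10 +/- 1 A at 90%
    and 30 +/- 3 A at 10%, n = 1000, fixed seed."""
    params = ConjugateModelParams(n_frames=1000, seed=42)
    traj, selections, labels = gen_conjugate_trajectory(params)
    return params, traj, selections, labels


@pytest.fixture(scope="session")
def two_mode_transitions(two_mode_ensemble):
    _, traj, selections, _ = two_mode_ensemble
    return gen_transitions(traj, selections, SpectralModelParams(seed=43))
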