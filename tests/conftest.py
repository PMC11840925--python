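import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from glutx import Trajectory, default_config, detect_exchanges, simulate
from glutx.zones import net_transits

DEFAULT_SEEDS = (1, 2, 3, 4, 5)
DEFAULT_FRAMES = 1000


def make_trajectory(zs, times=None, ids=None, box=None):
    """Trajectory from a (F, N) Z matrix with X = Y = 0."""
    zs = np.asarray(zs, dtype=float)
    F, N = zs.shape
    pos = np.zeros((F, N, 3))
    pos[:, :, 2] = zs
    return Trajectory(
        times=np.arange(F, dtype=float) if times is None else np.asarray(times, float),
        ligand_ids=[f"L{i}" for i in range(N)] if ids is None else list(ids),
        positions=pos,
        box=box,
    )


def random_walk_z(n_ligands, n_frames, seed, lo=-30.0, hi=30.0, step=4.0):
    """Reflected random walks on [lo, hi], one column per ligand."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(lo, hi, size=n_ligands)
    out = np.empty((n_frames, n_ligands))
    out[0] = z
    for f in range(1, n_frames):
        z = z + rng.normal(0, step, size=n_ligands)
        z = np.where(z > hi, 2 * hi - z, z)
        z = np.where(z < lo, 2 * lo - z, z)
        out[f] = np.clip(z, lo, hi)
    return out


@pytest.fixture(scope="session")
def phase_runs():
    """Full-default fluid and gel replicas, shared across the suite.

    Returns {phase: {"seeds": [...], "events": [...], "transits": [...]}}
    with per-seed exchange-event and complete-transit counts at the
    default study conditions (56 ligands, 1000 frames x 1 ns).
    """
    out = {}
    for phase in ("fluid", "gel"):
        events, transits = [], []
        for seed in DEFAULT_SEEDS:
            traj = simulate(default_config(phase, n_frames=DEFAULT_FRAMES, seed=seed))
            events.append(len(detect_exchanges(traj, classify=False)))
            transits.append(len(net_transits(traj)[0]))
        out[phase] = {
            "seeds": list(DEFAULT_SEEDS),
            "events": events,
            "transits": transits,
            "duration_ns": float(DEFAULT_FRAMES - 1),
        }
    return out


@pytest.fixture(scope="session")
def small_fluid_run():
    """A short default-geometry fluid trajectory for smoke checks."""
    return simulate(default_config("fluid", n_frames=200, seed=7))
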