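import numpy as np
import pytest

from topogel import (CompressionSchedule, ForceField, IntegratorParams,
                     SimulationConfig, build_initial_ring, compress,
                     run_with_reconnection)
from topogel.model import radius_for_density


def quaternion_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def lk_crossing_oracle(a, b, rng):
    """Independent linking-number oracle: signed over-crossings in a generic
    projection (sum over crossings where curve a passes over curve b)."""
    rot = quaternion_rotation(rng)
    a = a @ rot.T
    b = b @ rot.T
    tot = 0.0
    na, nb = len(a), len(b)
    for i in range(na):
        p = a[i, :2]
        r = a[(i + 1) % na, :2] - p
        for j in range(nb):
            q = b[j, :2]
            s = b[(j + 1) % nb, :2] - q
            den = r[0] * s[1] - r[1] * s[0]
            if abs(den) < 1e-14:
                continue
            t = ((q[0] - p[0]) * s[1] - (q[1] - p[1]) * s[0]) / den
            u = ((q[0] - p[0]) * r[1] - (q[1] - p[1]) * r[0]) / den
            if 0 < t < 1 and 0 < u < 1:
                za = a[i, 2] + t * (a[(i + 1) % na, 2] - a[i, 2])
                zb = b[j, 2] + u * (b[(j + 1) % nb, 2] - b[j, 2])
                if za > zb:
                    tot += np.sign(den)
    return tot


def equilibrated_melt(n_beads, stiffness, seed, run_length=60.0,
                      sample_interval=5.0, compression_time=40.0):
    """Compress a single ring to monomer density 0.7 and run reconnection."""
    cfg = SimulationConfig(
        n_beads=n_beads, stiffness=stiffness,
        sphere_radius=radius_for_density(n_beads, 0.7), seed=seed,
        run_length=run_length, sample_interval=sample_interval,
        compression_time=compression_time, equilibration_time=5.0,
    )
    state = build_initial_ring(cfg)
    ff = ForceField(bending_k=stiffness)
    ip = IntegratorParams(timestep=cfg.timestep, seed=seed)
    sched = CompressionSchedule(state.box.radius, cfg.sphere_radius,
                                cfg.compression_time, cfg.equilibration_time)
    state = compress(state, sched, ff, ip)
    record = run_with_reconnection(state, cfg, ff, ip, store_snapshots=True)
    return cfg, ff, ip, record


@pytest.fixture(scope="session")
def melt_k0():
    """A small fully flexible melt at the study density, with its trajectory."""
    return equilibrated_melt(n_beads=120, stiffness=0.0, seed=11)
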