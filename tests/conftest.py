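import math

import numpy as np
import pytest

from rsaquant import Point2D, RootRecord, RootSystem, SyntheticSpec


def ray(angle_deg: float, length: float, n: int = 5,
        origin=(0.0, 0.0)) -> np.ndarray:
    """Straight polyline from origin at `angle_deg` from the downward
    vertical (y-down frame, positive toward +x)."""
    t = np.linspace(0.0, length, n)
    a = math.radians(angle_deg)
    return np.column_stack([origin[0] + t * math.sin(a),
                            origin[1] + t * math.cos(a)])


def make_system(seminal_angles, length=100.0, laterals=(),
                plant_id="p1", seed=(0.0, 0.0)) -> RootSystem:
    """System of straight seminal rays plus optional laterals.

    `laterals` is a sequence of (parent_index, base_fraction, angle, length).
    """
    roots = [RootRecord(f"s{i + 1}", 1, None, ray(a, length, origin=seed))
             for i, a in enumerate(seminal_angles)]
    for j, (pi, frac, ang, ln) in enumerate(laterals):
        parent = roots[pi].polyline
        seg = np.linspace(0, 1, len(parent))
        base_idx = int(round(frac * (len(parent) - 1)))
        base = parent[base_idx]
        roots.append(RootRecord(f"l{j + 1}", 2, f"s{pi + 1}",
                                ray(ang, ln, origin=base)))
    return RootSystem(plant_id=plant_id, seed_origin=Point2D(*seed),
                      roots=roots)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def straight_spec():
    """Noise-free, straight, lateral-free generator conditions."""
    return SyntheticSpec(noise_sd=0.0, gravitropism_rate=0.0,
                         lateral_density=0.0)
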