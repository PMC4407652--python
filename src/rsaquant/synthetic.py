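"""Synthetic wheat-seedling root systems with recorded ground truth.

The generator emulates the architecture of a 9-day wheat seedling grown on a
germination-paper pouch, as seen by 2-D image analysis: 2–6 first-order
(seminal) roots fan out from the seed point, each grown as a correlated
random walk whose heading relaxes toward the downward vertical
(gravitropism), with second-order (lateral) roots placed by a Poisson
process along each seminal beyond a basal zone.  Every stochastic choice is
recorded as ground truth at generation time so that downstream trait
extraction can be tested for recovery.

The heading recursion for one root is

    theta_k = a * theta_{k-1} + eps_k,      a = 1 - gravitropism_rate * step

with ``eps_k ~ N(0, noise_sd^2)``; it is evaluated in closed form
(``theta_k = a^k (theta_0 + sum_j eps_j a^-j)``) so that whole populations
generate in seconds.  Headings are measured from the downward vertical
(degrees, positive toward +x); the seed sits at (0, 0) in the emitted frame.

Randomness is split per plant with ``numpy.random.SeedSequence`` keyed on
(root seed, line index, replicate), so a population is stable under partial
regeneration and bit-identical across runs for the same (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull as _QhullHull
from scipy.spatial import QhullError

from .architecture import Point2D, RootRecord, RootSystem
from . import geometry


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters (all lengths in px, angles in degrees).

    seminal_count_range
        inclusive [lo, hi] of the per-plant seminal-root count.
    seminal_length_log_mean / seminal_length_log_sd
        log-normal parameters of seminal root length.
    fan_half_angle
        maximum emergence angle from the downward vertical; emergence
        headings are drawn uniformly in ±fan_half_angle.
    gravitropism_rate
        fractional decay of the heading toward vertical, per px grown.
    lateral_density
        expected lateral roots per px of seminal root beyond the basal zone.
    lateral_length_mean
        mean of the exponential lateral-root length distribution.
    basal_zone
        px of seminal root (from the seed) bearing no laterals.
    step
        arc-length spacing of emitted polyline vertices.
    noise_sd
        s.d. of the per-step heading jitter (degrees per step).
    """

    seminal_count_range: tuple[int, int] = (2, 6)
    seminal_length_log_mean: float = math.log(300.0)
    seminal_length_log_sd: float = 0.3
    fan_half_angle: float = 40.0
    gravitropism_rate: float = 0.005
    lateral_density: float = 0.02
    lateral_length_mean: float = 40.0
    basal_zone: float = 60.0
    step: float = 2.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.seminal_count_range
        if not (1 <= lo <= hi):
            raise ValueError("seminal_count_range must satisfy 1 <= lo <= hi")
        if not (0.0 < self.fan_half_angle < 90.0):
            raise ValueError("fan_half_angle must lie in (0, 90) degrees")
        for name in ("seminal_length_log_sd", "lateral_density", "noise_sd",
                     "gravitropism_rate", "basal_zone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("lateral_length_mean", "step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_overrides(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """True quantities recorded while generating one plant."""

    plant_id: str
    seminal_count: int
    lateral_count: int
    root_lengths: dict[str, float]
    root_orders: dict[str, int]
    emergence_angles: dict[str, float]       # seminal root -> heading (deg)
    tip_positions: dict[str, Point2D]
    min_x: float
    max_x: float
    min_y: float
    max_y: float
    hull_area_px2: float                     # independent (Qhull) hull area
    line_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for root_id, length in self.root_lengths.items():
            tip = self.tip_positions[root_id]
            rows.append({
                "plant_id": self.plant_id,
                "line_id": self.line_id,
                "root_id": root_id,
                "order": self.root_orders[root_id],
                "true_length_px": length,
                "true_emergence_angle_deg": self.emergence_angles.get(root_id),
                "tip_x": tip.x, "tip_y": tip.y,
            })
        return pd.DataFrame(rows)


@dataclass
class PopulationGroundTruth:
    """Ground truth for a generated population, with tabular export."""

    per_plant: list[GroundTruth] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([gt.to_frame() for gt in self.per_plant],
                         ignore_index=True)


def _grow_root(base: np.ndarray, heading_deg: float, length: float,
               spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Grow one root as a gravitropic correlated random walk.

    Returns the polyline vertices including the base; the final vertex lands
    exactly at arc length ``length``.
    """
    n_full = int(length // spec.step)
    remainder = length - n_full * spec.step
    steps = np.full(n_full, spec.step)
    if remainder > 1e-9:
        steps = np.append(steps, remainder)
    n = len(steps)
    if n == 0:
        steps = np.array([length])
        n = 1
    a = 1.0 - spec.gravitropism_rate * spec.step
    eps = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 \
        else np.zeros(n)
    # segment j uses the heading *entering* it: theta_0 for the first segment
    if a == 1.0:
        headings = heading_deg + np.concatenate([[0.0], np.cumsum(eps[:-1])])
    else:
        k = np.arange(n)
        powers = a ** k
        inner = np.concatenate([[0.0], np.cumsum(eps[:-1] / (a ** np.arange(1, n)))])
        headings = powers * (heading_deg + inner)
    rad = np.radians(headings)
    deltas = np.column_stack([steps * np.sin(rad), steps * np.cos(rad)])
    return np.vstack([base, base + np.cumsum(deltas, axis=0)])


def generate_system(spec: SyntheticSpec, seed,
                    plant_id: str = "plant1",
                    line_id: str | None = None,
                    experiment_id: str | None = None
                    ) -> tuple[RootSystem, GroundTruth]:
    """Generate one root system and its ground truth, deterministically.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    origin = np.array([0.0, 0.0])

    lo, hi = spec.seminal_count_range
    n_seminal = int(rng.integers(lo, hi + 1))
    # emergence headings: uniform within the fan, symmetric about vertical
    emergence = rng.uniform(-spec.fan_half_angle, spec.fan_half_angle,
                            size=n_seminal)
    seminal_lengths = rng.lognormal(spec.seminal_length_log_mean,
                                    spec.seminal_length_log_sd, size=n_seminal)

    roots: list[RootRecord] = []
    lengths: dict[str, float] = {}
    orders: dict[str, int] = {}
    headings: dict[str, float] = {}
    tips: dict[str, Point2D] = {}

    lateral_counter = 0
    for i in range(n_seminal):
        sid = f"{plant_id}.s{i + 1}"
        poly = _grow_root(origin, float(emergence[i]),
                          float(seminal_lengths[i]), spec, rng)
        roots.append(RootRecord(sid, 1, None, poly))
        lengths[sid] = float(seminal_lengths[i])
        orders[sid] = 1
        headings[sid] = float(emergence[i])
        tips[sid] = Point2D(float(poly[-1, 0]), float(poly[-1, 1]))

        # Poisson lateral placement beyond the basal zone
        branch_span = max(float(seminal_lengths[i]) - spec.basal_zone, 0.0)
        n_lat = int(rng.poisson(spec.lateral_density * branch_span)) \
            if branch_span > 0 and spec.lateral_density > 0 else 0
        if n_lat == 0:
            continue
        stations = np.sort(rng.uniform(spec.basal_zone,
                                       float(seminal_lengths[i]), size=n_lat))
        cum = geometry.cumulative_arclength(poly)
        for s in stations:
            lateral_counter += 1
            lid = f"{plant_id}.l{lateral_counter}"
            base = np.array(geometry.point_at_arclength(poly, float(s),
                                                        clamp=True))
            # local parent heading from the segment containing the station
            j = min(int(np.searchsorted(cum, s, side="right")), len(poly) - 1)
            d = poly[j] - poly[j - 1]
            parent_heading = math.degrees(math.atan2(d[0], d[1]))
            side = rng.choice([-1.0, 1.0])
            branch_angle = rng.uniform(45.0, 90.0)
            lat_heading = parent_heading + side * branch_angle
            lat_length = float(rng.exponential(spec.lateral_length_mean))
            lat_length = max(lat_length, spec.step)  # keep polylines non-degenerate
            lat_poly = _grow_root(base, lat_heading, lat_length, spec, rng)
            roots.append(RootRecord(lid, 2, sid, lat_poly))
            lengths[lid] = lat_length
            orders[lid] = 2
            tips[lid] = Point2D(float(lat_poly[-1, 0]), float(lat_poly[-1, 1]))

    system = RootSystem(plant_id=plant_id, seed_origin=Point2D(0.0, 0.0),
                        roots=roots, line_id=line_id,
                        experiment_id=experiment_id)
    system.validate()

    all_points = np.vstack([r.polyline for r in roots])
    try:
        hull_area = float(_QhullHull(all_points).volume)  # 2-D: volume = area
    except QhullError:
        hull_area = 0.0
    truth = GroundTruth(
        plant_id=plant_id,
        seminal_count=n_seminal,
        lateral_count=lateral_counter,
        root_lengths=lengths,
        root_orders=orders,
        emergence_angles=headings,
        tip_positions=tips,
        min_x=float(all_points[:, 0].min()),
        max_x=float(all_points[:, 0].max()),
        min_y=float(all_points[:, 1].min()),
        max_y=float(all_points[:, 1].max()),
        hull_area_px2=hull_area,
        line_id=line_id,
    )
    return system, truth


def generate_population(spec_per_line: dict[str, SyntheticSpec], reps: int,
                        seed: int, experiment_id: str | None = None
                        ) -> tuple[list[RootSystem], PopulationGroundTruth]:
    """Generate ``reps`` plants per line with stable per-plant substreams.

    Plant ``r`` of line index ``i`` draws from SeedSequence(seed, i, r), so
    adding lines or reps never perturbs previously generated plants.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    systems: list[RootSystem] = []
    truths = PopulationGroundTruth()
    for i, (line_id, spec) in enumerate(spec_per_line.items()):
        for r in range(reps):
            plant_id = f"{line_id}_p{r + 1:03d}"
            seq = np.random.SeedSequence([int(seed), i, r])
            system, truth = generate_system(
                spec, seq, plant_id=plant_id, line_id=line_id,
                experiment_id=experiment_id)
            systems.append(system)
            truths.per_plant.append(truth)
    return systems, truths
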