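"""The 25-trait root-system-architecture vector for a single seedling.

Traits (units after scaling by ``mm_per_px``):

========  =======================================================================
RTLA      total length of all roots (mm)
RTLS      total length of seminal roots (mm)
RTLL      total length of lateral roots (mm)
RSC       number of seminal roots
RLC       number of lateral roots
RMW       maximum width of the root system (mm)
RMD       maximum depth of the root system, measured from the seed (mm)
RMWD      width/depth ratio (RMW / RMD)
RCMX/Y    centre of mass, horizontal/vertical coordinate relative to the seed (mm)
RCH       area of the convex hull enclosing the root system (mm^2)
RCHCX/Y   hull centroid, horizontal/vertical coordinate relative to the seed (mm)
RAE1/2    emergence angle, outermost / second pair of seminal roots at 30 px (deg)
RAE951/2  idem at 95 px (= 15 mm at the default scale)
RAE251/2  idem at 25% of each root's own length
RAE501/2  idem at 50%
RAE751/2  idem at 75%
RAE1001/2 idem at the root tip (100%)
========  =======================================================================

Angle semantics: for each seminal root take the point at the given arc
length (or fraction of that root's own length), form the vector from the
seed origin to that point, and measure its signed angle from the downward
vertical (positive toward +x).  Ranking seminal roots by this signed angle,
the *outermost* pair is the minimum- and maximum-rank root and the *second*
pair is ranks 2 and n−1.  The reported value is the absolute angle between
the two chosen vectors, in degrees within [0°, 360°) — the emergence angle
subtended at the seed, not a tangent angle.

Undefined values (too few seminal roots, zero depth, degenerate hull) are
NaN with a reason code in ``TraitVector.flags``, never silent zeros.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import Point2D, RootSystem
from .errors import ValidationError
from . import geometry

#: the canonical trait names, in canonical column order
TRAIT_NAMES: tuple[str, ...] = (
    "RTLA", "RTLS", "RTLL", "RSC", "RLC",
    "RMW", "RMD", "RMWD",
    "RCMX", "RCMY",
    "RCH", "RCHCX", "RCHCY",
    "RAE1", "RAE2", "RAE951", "RAE952",
    "RAE251", "RAE252", "RAE501", "RAE502",
    "RAE751", "RAE752", "RAE1001", "RAE1002",
)

#: (trait-name stem for outermost/second pair, measurement point)
ANGLE_MEASUREMENTS: tuple[tuple[str, str, dict], ...] = (
    ("RAE1", "RAE2", {"fixed_px": 0}),       # index into fixed_angle_points
    ("RAE951", "RAE952", {"fixed_px": 1}),
    ("RAE251", "RAE252", {"fraction": 0}),   # index into angle_fractions
    ("RAE501", "RAE502", {"fraction": 1}),
    ("RAE751", "RAE752", {"fraction": 2}),
    ("RAE1001", "RAE1002", {"fraction": 3}),
)

#: default scale: the fixed angle-measurement point sits at 95 px = 15 mm
DEFAULT_MM_PER_PX = 15.0 / 95.0


@dataclass(frozen=True)
class TraitConfig:
    """Parameters that make the trait definitions concrete.

    mm_per_px
        image scale (mm per pixel); lengths scale linearly, areas
        quadratically.  The default follows from the fixed angle-measurement
        point being specified both as 95 px and as 15 mm.
    sample_interval
        arc-length step (px) used to resample roots for the centre of mass
        and the convex hull.
    fixed_angle_points
        arc lengths (px) of the two fixed-point angle measurements.
    angle_fractions
        per-root length fractions of the four relative angle measurements.
    degenerate_area_tol
        hull area (px^2) below which the hull is treated as collinear.
    """

    mm_per_px: float = DEFAULT_MM_PER_PX
    sample_interval: float = 1.0
    fixed_angle_points: tuple[float, ...] = (30.0, 95.0)
    angle_fractions: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    degenerate_area_tol: float = geometry.DEGENERATE_AREA_TOL

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if len(self.fixed_angle_points) != 2 or any(
                s <= 0 for s in self.fixed_angle_points):
            raise ValueError("fixed_angle_points must be two positive arc lengths")
        if len(self.angle_fractions) != 4 or any(
                not (0.0 < f <= 1.0) for f in self.angle_fractions):
            raise ValueError("angle_fractions must be four fractions in (0, 1]")


@dataclass
class TraitVector:
    """The 25 named trait values for one plant, plus degeneracy flags."""

    plant_id: str
    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)
    line_id: str | None = None
    experiment_id: str | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "plant_id": self.plant_id,
            "line_id": self.line_id,
            "experiment_id": self.experiment_id,
        }
        row.update({name: self.values[name] for name in TRAIT_NAMES})
        return row


def classify_roots(system: RootSystem) -> RootSystem:
    """Validate the seminal/lateral labelling of a system.

    Checks structural invariants (unique ids, at least one seminal, every
    lateral's parent is a seminal in the same system) and returns the system
    unchanged; raises :class:`ValidationError` otherwise.
    """
    system.validate()
    return system


def _signed_angle_from_vertical(dx: float, dy: float) -> float:
    """Signed angle (deg) of a vector from the downward vertical, in
    (−180, 180], positive toward +x.  y is the image-frame down axis."""
    return math.degrees(math.atan2(dx, dy))


def _angle_points(system: RootSystem, *, fixed_px: float | None = None,
                  fraction: float | None = None):
    """Per-seminal measurement points and their signed angles from vertical.

    Returns (signed_angles, clamped) where ``clamped`` flags roots shorter
    than a fixed-px measurement point (measured at the tip instead).
    """
    if (fixed_px is None) == (fraction is None):
        raise ValueError("specify exactly one of fixed_px or fraction")
    seed = system.seed_origin
    angles: list[float] = []
    clamped = False
    for root in system.seminal_roots:
        if fixed_px is not None:
            length = geometry.polyline_length(root.polyline)
            if fixed_px > length:
                clamped = True
            p = geometry.point_at_arclength(root.polyline, fixed_px, clamp=True)
        else:
            p = geometry.point_at_fraction(root.polyline, fraction)
        angles.append(_signed_angle_from_vertical(p.x - seed.x, p.y - seed.y))
    return np.asarray(angles), clamped


def seminal_pair_angle(system: RootSystem, pair: str = "outermost", *,
                       fixed_px: float | None = None,
                       fraction: float | None = None):
    """Emergence angle between a pair of seminal roots at one measurement point.

    ``pair`` is ``"outermost"`` (extreme-rank roots; needs >= 2 seminals) or
    ``"second"`` (ranks 2 and n−1; needs >= 4).  Returns ``(angle_deg, flag)``
    where ``flag`` is ``None``, a reason code for an undefined (NaN) value,
    or ``"clamped_to_tip"`` when a fixed measurement point fell beyond a
    root's tip and was measured at the tip.
    """
    if pair not in ("outermost", "second"):
        raise ValueError(f"pair must be 'outermost' or 'second', got {pair!r}")
    n_needed = 2 if pair == "outermost" else 4
    seminals = system.seminal_roots
    if len(seminals) < n_needed:
        return math.nan, "insufficient_seminal_roots"
    angles, clamped = _angle_points(system, fixed_px=fixed_px, fraction=fraction)
    order = np.argsort(angles, kind="stable")
    if pair == "outermost":
        lo, hi = order[0], order[-1]
    else:
        lo, hi = order[1], order[-2]
    value = float(abs(angles[hi] - angles[lo])) % 360.0
    return value, ("clamped_to_tip" if clamped else None)


def compute_traits(system: RootSystem, config: TraitConfig | None = None) -> TraitVector:
    """Compute the full 25-trait vector for one plant.

    Lengths and areas are computed in pixels and converted with
    ``config.mm_per_px`` (areas by its square).  Centre-of-mass and
    hull-centroid coordinates are reported relative to the seed origin, with
    x positive rightward and y positive downward (deeper).
    """
    config = config or TraitConfig()
    classify_roots(system)
    if not system.roots:
        raise ValidationError(f"plant {system.plant_id!r}: no roots",
                              plant_id=system.plant_id)
    mm = config.mm_per_px
    seed = system.seed_origin
    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    len_s = sum(geometry.polyline_length(r.polyline) for r in system.seminal_roots)
    len_l = sum(geometry.polyline_length(r.polyline) for r in system.lateral_roots)
    values["RTLS"] = len_s * mm
    values["RTLL"] = len_l * mm
    values["RTLA"] = (len_s + len_l) * mm
    values["RSC"] = float(len(system.seminal_roots))
    values["RLC"] = float(len(system.lateral_roots))

    # one regular-interval sample cloud drives extent, centre of mass and hull
    sampled = np.vstack([
        geometry.resample(r.polyline, config.sample_interval, r.root_id).points
        for r in system.roots
    ])
    width, depth = geometry.extent(sampled, seed)
    values["RMW"] = width * mm
    values["RMD"] = depth * mm
    if depth > 0:
        values["RMWD"] = width / depth
    else:
        values["RMWD"] = math.nan
        flags["RMWD"] = "zero_depth"

    com = geometry.center_of_mass(system.all_polylines(), config.sample_interval)
    values["RCMX"] = (com.x - seed.x) * mm
    values["RCMY"] = (com.y - seed.y) * mm

    hull = geometry.convex_hull(sampled)
    area_px2 = abs(geometry.signed_area(hull))
    if hull.degenerate or area_px2 <= config.degenerate_area_tol:
        values["RCH"] = 0.0
        flags["RCH"] = "degenerate_hull"
        centroid = Point2D(*hull.vertices.mean(axis=0))
        flags["RCHCX"] = flags["RCHCY"] = "degenerate_hull"
    else:
        values["RCH"] = area_px2 * mm * mm
        centroid = geometry.hull_centroid(hull, config.degenerate_area_tol)
    values["RCHCX"] = (centroid.x - seed.x) * mm
    values["RCHCY"] = (centroid.y - seed.y) * mm

    for outer_name, second_name, where in ANGLE_MEASUREMENTS:
        if "fixed_px" in where:
            kwargs = {"fixed_px": config.fixed_angle_points[where["fixed_px"]]}
        else:
            kwargs = {"fraction": config.angle_fractions[where["fraction"]]}
        for name, pair in ((outer_name, "outermost"), (second_name, "second")):
            value, flag = seminal_pair_angle(system, pair, **kwargs)
            values[name] = value
            if flag is not None:
                flags[name] = flag

    assert set(values) == set(TRAIT_NAMES)
    return TraitVector(plant_id=system.plant_id, values=values, flags=flags,
                       line_id=system.line_id, experiment_id=system.experiment_id)
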