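"""Domain model for extracted root architectures.

A :class:`RootSystem` is one seedling: a seed origin plus a set of roots,
each an ordered 2-D polyline in the image frame (pixels, x positive
rightward, y positive *downward* — i.e. deeper into the pouch).  Roots carry
an order label: first-order (seminal) roots emerge from the seed, second-order
(lateral) roots branch from a seminal parent.  Only these two orders exist in
the supported dialect; wheat seedlings at the two-leaf stage have no deeper
branching.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ValidationError

SEMINAL = 1
LATERAL = 2


class Point2D(NamedTuple):
    """A 2-D point in image coordinates (px; y increases downward)."""

    x: float
    y: float


def as_point_array(points: Iterable | np.ndarray) -> np.ndarray:
    """Coerce a point sequence to a float64 ``(n, 2)`` array."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1 and arr.size == 2:
        arr = arr.reshape(1, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("point coordinates must be finite")
    return arr


@dataclass
class RootRecord:
    """One root: identifier, order label, optional parent, and its polyline."""

    root_id: str
    order: int
    parent_id: str | None
    polyline: np.ndarray

    def __post_init__(self) -> None:
        self.polyline = as_point_array(self.polyline)

    @property
    def is_seminal(self) -> bool:
        return self.order == SEMINAL

    @property
    def is_lateral(self) -> bool:
        return self.order == LATERAL

    def validate(self) -> None:
        if self.order not in (SEMINAL, LATERAL):
            raise ValidationError(
                f"root {self.root_id!r}: unsupported order {self.order} "
                "(only 1 = seminal, 2 = lateral)", root_id=self.root_id)
        if self.order == SEMINAL and self.parent_id is not None:
            raise ValidationError(
                f"root {self.root_id!r}: seminal roots cannot have a parent",
                root_id=self.root_id)
        if self.order == LATERAL and self.parent_id is None:
            raise ValidationError(
                f"root {self.root_id!r}: lateral root lacks a parent_id",
                root_id=self.root_id)
        if len(self.polyline) < 2:
            raise ValidationError(
                f"root {self.root_id!r}: polyline needs >= 2 points",
                root_id=self.root_id)
        seg = np.diff(self.polyline, axis=0)
        if float(np.hypot(seg[:, 0], seg[:, 1]).sum()) <= 0.0:
            raise ValidationError(
                f"root {self.root_id!r}: polyline has zero total length",
                root_id=self.root_id)


@dataclass
class RootSystem:
    """One plant's extracted architecture."""

    plant_id: str
    seed_origin: Point2D
    roots: list[RootRecord] = field(default_factory=list)
    line_id: str | None = None
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        self.seed_origin = Point2D(float(self.seed_origin[0]),
                                   float(self.seed_origin[1]))

    @property
    def seminal_roots(self) -> list[RootRecord]:
        return [r for r in self.roots if r.is_seminal]

    @property
    def lateral_roots(self) -> list[RootRecord]:
        return [r for r in self.roots if r.is_lateral]

    def all_polylines(self) -> list[np.ndarray]:
        return [r.polyline for r in self.roots]

    def validate(self) -> None:
        """Check structural invariants; raise ValidationError on the first hit."""
        ids = [r.root_id for r in self.roots]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"plant {self.plant_id!r}: duplicate root_id(s) {dup}",
                plant_id=self.plant_id)
        seminal_ids = set()
        for r in self.roots:
            r.validate()
            if r.is_seminal:
                seminal_ids.add(r.root_id)
        if not seminal_ids:
            raise ValidationError(
                f"plant {self.plant_id!r}: no first-order (seminal) root",
                plant_id=self.plant_id)
        for r in self.roots:
            if r.is_lateral and r.parent_id not in seminal_ids:
                raise ValidationError(
                    f"root {r.root_id!r}: parent_id {r.parent_id!r} does not "
                    "refer to a seminal root in the same system",
                    root_id=r.root_id, plant_id=self.plant_id)

    def translated(self, dx: float, dy: float) -> "RootSystem":
        """Return a copy shifted by (dx, dy); useful for frame changes."""
        return RootSystem(
            plant_id=self.plant_id,
            seed_origin=Point2D(self.seed_origin.x + dx, self.seed_origin.y + dy),
            roots=[RootRecord(r.root_id, r.order, r.parent_id,
                              r.polyline + np.array([dx, dy]))
                   for r in self.roots],
            line_id=self.line_id,
            experiment_id=self.experiment_id,
        )

    def mirrored(self) -> "RootSystem":
        """Reflect about the vertical axis through the seed origin."""
        sx = self.seed_origin.x

        def flip(poly: np.ndarray) -> np.ndarray:
            out = poly.copy()
            out[:, 0] = 2.0 * sx - out[:, 0]
            return out

        return RootSystem(
            plant_id=self.plant_id,
            seed_origin=self.seed_origin,
            roots=[RootRecord(r.root_id, r.order, r.parent_id, flip(r.polyline))
                   for r in self.roots],
            line_id=self.line_id,
            experiment_id=self.experiment_id,
        )
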