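"""Axis-aligned boxes in 0-based, half-open pixel coordinates.

All rectangles in this package use the convention [x0, x1) x [y0, y1):
``x1 - x0`` is the width in pixels and two boxes sharing an edge do not
overlap. This keeps widths closed-form and adjacency unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned lesion rectangle, 0-based half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"box coordinates must be non-negative: {self}")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"box must have positive width and height: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def translate(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def intersect(self, other: "BoundingBox") -> Optional["BoundingBox"]:
        """Intersection box, or None when the interiors are disjoint."""
        x0 = max(self.x0, other.x0)
        y0 = max(self.y0, other.y0)
        x1 = min(self.x1, other.x1)
        y1 = min(self.y1, other.y1)
        if x1 <= x0 or y1 <= y0:
            return None
        return BoundingBox(x0, y0, x1, y1)

    def intersection_area(self, other: "BoundingBox") -> int:
        inter = self.intersect(other)
        return 0 if inter is None else inter.area

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def within(self, width: int, height: int) -> bool:
        """True when the box lies inside a width x height pixel grid."""
        return self.x1 <= width and self.y1 <= height
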