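"""Floor-zone geometry and zone-occupancy assignment.

The pen floor is divided into three virtual zones: a *drinking* zone — an
axis-aligned rectangle centred on the nipple-drinker water line whose
width is one body length of a three-week-old broiler; a *feeding* zone —
a disc centred on the tube feeder whose radius is the feeder radius plus
one body length; and the *rest/exercise* zone — everything else inside
the pen's overall detection rectangle.

A detected region is assigned to the drinking or feeding zone only when
*strictly more than half* of its pixels fall inside that zone; ties and
everything else go to rest.  Fractions are computed by exact pixel
membership, never by bounding-box approximation.

Pixel conventions: origin top-left, x rightward, y downward, 0-based.
Rectangle bounds are inclusive integer pixel coordinates; a pixel (x, y)
belongs to a disc when (x-cx)^2 + (y-cy)^2 <= r^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

DRINKING = "drinking"
FEEDING = "feeding"
REST = "rest"
ZONE_LABELS = (DRINKING, FEEDING, REST)


class ZoneConfigError(ValueError):
    """Raised when a zone-geometry configuration violates an invariant."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with inclusive integer pixel bounds."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ZoneConfigError(f"degenerate rectangle {self.as_tuple()}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0 + 1

    @property
    def height(self) -> int:
        return self.y1 - self.y0 + 1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def membership(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Boolean membership of pixel coordinates in the rectangle."""
        return (
            (xs >= self.x0) & (xs <= self.x1) & (ys >= self.y0) & (ys <= self.y1)
        )


@dataclass(frozen=True)
class Disc:
    """Disc in pixel coordinates (centre may be fractional)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ZoneConfigError(f"disc radius must be positive, got {self.radius}")

    def membership(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return (xs - self.cx) ** 2 + (ys - self.cy) ** 2 <= self.radius**2

    def bounding_rect_inside(self, rect: Rect) -> bool:
        return (
            self.cx - self.radius >= rect.x0
            and self.cx + self.radius <= rect.x1
            and self.cy - self.radius >= rect.y0
            and self.cy + self.radius <= rect.y1
        )


@dataclass(frozen=True)
class ZoneGeometry:
    """Pen rectangle plus drinking-rectangle and feeding-disc zones.

    ``body_length_px`` is the calibration length (one body length of a
    three-week-old broiler, in pixels) from which the drinking-rect
    width and the feeding-disc margin were derived; it is carried for
    provenance and config round-tripping.
    """

    pen_rect: Rect
    drinking_rect: Rect
    feeding_disc: Disc
    body_length_px: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.pen_rect.contains_rect(self.drinking_rect):
            raise ZoneConfigError(
                f"drinking_rect {self.drinking_rect.as_tuple()} is not inside "
                f"pen_rect {self.pen_rect.as_tuple()}"
            )
        if not self.feeding_disc.bounding_rect_inside(self.pen_rect):
            raise ZoneConfigError(
                f"feeding_disc (centre ({self.feeding_disc.cx}, "
                f"{self.feeding_disc.cy}), r={self.feeding_disc.radius}) is not "
                f"inside pen_rect {self.pen_rect.as_tuple()}"
            )
        if self._rect_disc_overlap():
            raise ZoneConfigError(
                "drinking_rect and feeding_disc overlap; zones must be disjoint"
            )

    def _rect_disc_overlap(self) -> bool:
        r = self.drinking_rect
        d = self.feeding_disc
        # distance from disc centre to the closest point of the rectangle
        dx = max(r.x0 - d.cx, 0.0, d.cx - r.x1)
        dy = max(r.y0 - d.cy, 0.0, d.cy - r.y1)
        return dx * dx + dy * dy <= d.radius**2

    def to_dict(self) -> dict:
        return {
            "pen_rect": list(self.pen_rect.as_tuple()),
            "drinking_rect": list(self.drinking_rect.as_tuple()),
            "feeding_disc": {
                "center": [self.feeding_disc.cx, self.feeding_disc.cy],
                "radius": self.feeding_disc.radius,
            },
            "body_length_px": self.body_length_px,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ZoneGeometry":
        try:
            pen = Rect(*(int(v) for v in doc["pen_rect"]))
            drink = Rect(*(int(v) for v in doc["drinking_rect"]))
            disc_doc = doc["feeding_disc"]
            disc = Disc(
                float(disc_doc["center"][0]),
                float(disc_doc["center"][1]),
                float(disc_doc["radius"]),
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise ZoneConfigError(f"malformed zone configuration: {exc}") from exc
        return cls(pen, drink, disc, float(doc.get("body_length_px", 30.0)))


def default_zone_geometry(
    image_width: int = 480,
    image_height: int = 360,
    body_length_px: float | None = None,
    feeder_radius_px: float | None = None,
) -> ZoneGeometry:
    """Pen layout proportional to a single experimental pen.

    The water line runs horizontally near the top wall (drinking
    rectangle spans the pen width, height = one body length); the tube
    feeder hangs right of centre; everything else is rest/exercise.
    The calibration lengths default to 30 px body length and 40 px
    feeder radius at 480x360 and scale with the canvas.
    """
    scale = min(image_width / 480.0, image_height / 360.0)
    if body_length_px is None:
        body_length_px = 30.0 * scale
    if feeder_radius_px is None:
        feeder_radius_px = 40.0 * scale
    margin = max(4, image_width // 60)
    pen = Rect(margin, margin, image_width - margin - 1, image_height - margin - 1)
    water_y = pen.y0 + int(round(1.5 * body_length_px))
    half = int(round(body_length_px / 2))
    drink = Rect(pen.x0, water_y - half, pen.x1, water_y + half)
    disc_r = feeder_radius_px + body_length_px
    cx = pen.x0 + 0.62 * (pen.x1 - pen.x0)
    cy = pen.y0 + 0.62 * (pen.y1 - pen.y0)
    return ZoneGeometry(pen, drink, Disc(cx, cy, disc_r), body_length_px)


def load_zone_config(path: str | Path) -> ZoneGeometry:
    """Load and validate a YAML/JSON zone-geometry document."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ZoneConfigError(f"zone config {path} did not parse to a mapping")
    return ZoneGeometry.from_dict(doc)


def save_zone_config(geom: ZoneGeometry, path: str | Path) -> None:
    path = Path(path)
    doc = geom.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def zone_fractions(
    xs: np.ndarray, ys: np.ndarray, geom: ZoneGeometry
) -> tuple[float, float]:
    """Fraction of the pixel set inside the drinking rect / feeding disc."""
    n = len(xs)
    if n == 0:
        return 0.0, 0.0
    f_drink = float(np.count_nonzero(geom.drinking_rect.membership(xs, ys))) / n
    f_feed = float(np.count_nonzero(geom.feeding_disc.membership(xs, ys))) / n
    return f_drink, f_feed


def assign_zone_pixels(xs: np.ndarray, ys: np.ndarray, geom: ZoneGeometry) -> str:
    """Zone label for a pixel set under the strict >50% majority rule."""
    f_drink, f_feed = zone_fractions(xs, ys, geom)
    if f_drink > 0.5:
        return DRINKING
    if f_feed > 0.5:
        return FEEDING
    return REST


def assign_zone(region, geom: ZoneGeometry) -> str:
    """Zone label for a segmented region (see :func:`assign_zone_pixels`)."""
    return assign_zone_pixels(region.xs, region.ys, geom)


@dataclass
class ZoneCounts:
    """Per-frame bird counts in the three floor zones.

    ``rest`` is defined as ``total - d_num - f_num``; when per-region
    counting overshoots (rest would go negative) the value is clamped to
    zero and the frame is flagged via ``overshoot``.
    """

    frame_id: str
    d_num: int
    f_num: int
    rest: int
    total: int
    overshoot: bool = False
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_totals(
        cls, frame_id: str, total: int, d_num: int, f_num: int
    ) -> "ZoneCounts":
        rest = total - d_num - f_num
        if rest < 0:
            return cls(
                frame_id,
                d_num,
                f_num,
                0,
                total,
                overshoot=True,
                warnings=[
                    f"frame {frame_id}: drinking+feeding counts "
                    f"({d_num}+{f_num}) exceed total {total}; rest clamped to 0"
                ],
            )
        return cls(frame_id, d_num, f_num, rest, total)

    def by_zone(self) -> dict[str, int]:
        return {DRINKING: self.d_num, FEEDING: self.f_num, REST: self.rest}


def apportion_region_count(
    xs: np.ndarray, ys: np.ndarray, count: int, geom: ZoneGeometry
) -> dict[str, int]:
    """Distribute a multi-bird region's count across zones.

    A merged region holding several birds can straddle a zone boundary
    with its occupants on opposite sides; giving the whole count to one
    majority zone then systematically mis-attributes birds.  Instead the
    count is apportioned to the zone pixel fractions of the region by
    the largest-remainder method, which is the consistent estimator of
    how many of the merged birds stand in each zone.  Remainder ties are
    resolved conservatively: rest, then drinking, then feeding.
    """
    f_drink, f_feed = zone_fractions(xs, ys, geom)
    quotas = {
        DRINKING: count * f_drink,
        FEEDING: count * f_feed,
        REST: count * (1.0 - f_drink - f_feed),
    }
    alloc = {z: int(np.floor(q)) for z, q in quotas.items()}
    remaining = count - sum(alloc.values())
    order = sorted(
        (REST, DRINKING, FEEDING),
        key=lambda z: quotas[z] - alloc[z],
        reverse=True,
    )
    for z in order[:remaining]:
        alloc[z] += 1
    return alloc


def frame_distribution(
    regions: Sequence,
    counts: Sequence[int],
    geom: ZoneGeometry,
    frame_id: str = "",
) -> ZoneCounts:
    """Sum per-region bird counts into per-zone totals for one frame.

    A single-bird region goes entirely to its strict-majority zone (the
    >50% body rule); a multi-bird region's count is apportioned across
    zones by its zone pixel fractions (see
    :func:`apportion_region_count`), since the strict rule is defined
    for an individual bird's body, not for a merged group.
    """
    if len(regions) != len(counts):
        raise ValueError(
            f"got {len(regions)} regions but {len(counts)} per-region counts"
        )
    d_num = 0
    f_num = 0
    total = 0
    for region, count in zip(regions, counts):
        total += count
        if count <= 1:
            label = assign_zone(region, geom)
            if label == DRINKING:
                d_num += count
            elif label == FEEDING:
                f_num += count
        else:
            alloc = apportion_region_count(region.xs, region.ys, count, geom)
            d_num += alloc[DRINKING]
            f_num += alloc[FEEDING]
    return ZoneCounts.from_totals(frame_id, total, d_num, f_num)


def write_zone_counts_csv(rows: Iterable[ZoneCounts], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "frame_id": z.frame_id,
                "D_num": z.d_num,
                "F_num": z.f_num,
                "rest": z.rest,
                "total": z.total,
            }
            for z in rows
        ],
        columns=["frame_id", "D_num", "F_num", "rest", "total"],
    )
    df.to_csv(path, index=False)


def read_zone_counts_csv(path: str | Path) -> list[ZoneCounts]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        ZoneCounts(
            frame_id=str(r.frame_id),
            d_num=int(r.D_num),
            f_num=int(r.F_num),
            rest=int(r.rest),
            total=int(r.total),
        )
        for r in df.itertuples()
    ]
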