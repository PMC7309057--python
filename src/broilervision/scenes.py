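"""Synthetic top-view pen scenes with exact ground truth.

The generator emulates what the detection pipeline sees in a real
grow-out pen: light-coloured broilers rendered as filled ellipses on a
darker litter background, growing day by day, optionally crossed by a
water line and a feeder hanging chain (the dominant occluders in field
imagery), with optional touching clusters (crowding) and wing-spread
area inflation — the documented failure modes of area-based counting.

Every scene carries its exact ground truth: per-bird centroid, ellipse
axes, orientation, zone label (by the same strict >50% pixel-majority
rule the analysis uses), occluded fraction, and per-zone true counts.
Scenes are bit-identical under a fixed seed.

What the generator does *not* emulate: photorealistic plumage texture,
lighting flicker, dust, shadows, or bird posture beyond an ellipse.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from skimage import draw

from broilervision import zones as zmod
from broilervision.segmentation import FrameImage
from broilervision.zones import ZoneGeometry, default_zone_geometry


class SceneConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Raised when non-overlapping bird placement fails after bounded retries."""


@dataclass(frozen=True)
class OccluderSpec:
    """A piece of pen equipment drawn over the birds.

    ``kind`` is ``feeder_chain`` or ``water_line``; ``path`` is a
    polyline in pixel coordinates; the occluder covers every pixel
    within ``thickness / 2`` of the polyline.
    """

    kind: str
    path: tuple[tuple[float, float], ...]
    thickness: int = 6
    color: tuple[int, int, int] = (70, 70, 78)

    def __post_init__(self) -> None:
        if self.kind not in ("feeder_chain", "water_line"):
            raise SceneConfigError(f"unknown occluder kind {self.kind!r}")
        if self.thickness < 1:
            raise SceneConfigError("occluder thickness must be >= 1")
        if len(self.path) < 2:
            raise SceneConfigError("occluder path needs at least 2 points")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one rendered pen scene.

    Defaults describe one experimental pen at desk scale: a 480x360
    canvas, 19 birds (21 stocked minus 2 sampled for health checks),
    white birds on brown litter, additive Gaussian pixel noise of
    sd 8 on the 8-bit scale.  Single-bird top-view area grows linearly
    from ``bird_area_d18`` to ``bird_area_d35`` pixels across the
    d18-d35 observation window.  Occluders, crowding and wing spread
    are off by default and enabled explicitly to study failure modes.
    """

    image_width: int = 480
    image_height: int = 360
    day: int = 24
    n_birds: int = 19
    zone_geometry: ZoneGeometry | None = None
    occluders: tuple[OccluderSpec, ...] = ()
    crowding_fraction: float = 0.0
    wing_spread_prob: float = 0.0
    wing_spread_factor: float = 1.8
    seed: int = 0
    bird_color_mean: tuple[int, int, int] = (235, 230, 222)
    litter_color_mean: tuple[int, int, int] = (120, 96, 70)
    noise_sd: float = 8.0
    bird_area_d18: float = 300.0
    bird_area_d35: float = 900.0
    bird_area_rel_sd: float = 0.06
    axis_ratio: float = 1.6
    pinned_positions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_birds < 0:
            raise SceneConfigError("n_birds must be >= 0")
        for name in ("crowding_fraction", "wing_spread_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SceneConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.image_width < 1 or self.image_height < 1:
            raise SceneConfigError("image dimensions must be positive")
        if self.bird_area_d18 <= 0 or self.bird_area_d35 <= 0:
            raise SceneConfigError("bird areas must be positive")
        if self.axis_ratio < 1.0:
            raise SceneConfigError("axis_ratio must be >= 1")

    def geometry(self) -> ZoneGeometry:
        geom = self.zone_geometry or default_zone_geometry(
            self.image_width, self.image_height
        )
        pen = geom.pen_rect
        if (
            pen.x0 < 0
            or pen.y0 < 0
            or pen.x1 >= self.image_width
            or pen.y1 >= self.image_height
        ):
            raise SceneConfigError(
                f"pen rectangle {pen.as_tuple()} does not fit inside the "
                f"{self.image_width}x{self.image_height} image"
            )
        return geom

    def mean_bird_area(self, day: int | None = None) -> float:
        """Mean single-bird top-view area (px) on a given day, linear growth."""
        d = self.day if day is None else day
        slope = (self.bird_area_d35 - self.bird_area_d18) / (35 - 18)
        return max(50.0, self.bird_area_d18 + (d - 18) * slope)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["zone_geometry"] = self.geometry().to_dict()
        doc["occluders"] = [dataclasses.asdict(o) for o in self.occluders]
        return doc


@dataclass
class BirdRecord:
    bird_id: int
    centroid: tuple[float, float]  # (x, y)
    axes: tuple[float, float]  # (semi-major a, semi-minor b)
    orientation_deg: float
    zone: str
    occluded_fraction: float
    crowded: bool = False
    wing_spread: bool = False
    area_px: int = 0
    # rasterised ellipse pixels (full body, before occlusion)
    xs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ys: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass
class GroundTruth:
    """Exact per-scene truth emitted alongside every rendered frame."""

    frame_id: str
    birds: list[BirdRecord]
    per_zone_true_counts: dict[str, int]
    total: int
    shape: tuple[int, int]
    occluder_mask: np.ndarray | None = None

    def foreground_mask(self) -> np.ndarray:
        """Union of all bird body pixels (occluders not subtracted)."""
        mask = np.zeros(self.shape, dtype=bool)
        for b in self.birds:
            mask[b.ys, b.xs] = True
        return mask

    def visible_foreground_mask(self) -> np.ndarray:
        mask = self.foreground_mask()
        if self.occluder_mask is not None:
            mask &= ~self.occluder_mask
        return mask


def _bird_pixels(
    cx: float, cy: float, a: float, b: float, theta_deg: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    # skimage rotates row/col radii; orientation measured from +x axis
    ys, xs = draw.ellipse(
        cy, cx, b, a, shape=shape, rotation=np.deg2rad(theta_deg)
    )
    return xs.astype(np.int64), ys.astype(np.int64)


def _sample_axes(cfg: SceneConfig, rng: np.random.Generator, day: int) -> tuple[float, float, float]:
    """(a, b, area) for one bird on ``day``; area is the analytic ellipse area."""
    area = cfg.mean_bird_area(day) * max(
        0.3, 1.0 + cfg.bird_area_rel_sd * rng.standard_normal()
    )
    b = np.sqrt(area / (np.pi * cfg.axis_ratio))
    return cfg.axis_ratio * b, b, area


def _support_radius(a: float, b: float, theta_deg: float, phi: float) -> float:
    """Centre-to-boundary distance of an ellipse along direction ``phi``."""
    psi = phi - np.deg2rad(theta_deg)
    return (a * b) / np.hypot(b * np.cos(psi), a * np.sin(psi))


#: Touching birds overlap slightly: centre distance is this fraction of
#: the two boundary radii along the joining line.
_TOUCH_FACTOR = 0.93


def _attach_position(
    rng: np.random.Generator,
    anchors: list[tuple[float, float, float, float, float]],
    a_new: float,
    b_new: float,
    theta_new: float,
) -> tuple[float, float] | None:
    """Position for one bird joining a touching cluster.

    ``anchors`` holds (x, y, a, b, theta) of already-placed cluster
    birds.  The new bird is attached to a uniformly chosen anchor at
    just-touching distance (with a slight silhouette overlap) along a
    random direction, rejecting positions that dig deeply into any
    other member.  Returns None when no valid attachment was found in a
    bounded number of tries.
    """
    for _ in range(50):
        ax, ay, a_a, b_a, th_a = anchors[int(rng.integers(len(anchors)))]
        phi = rng.uniform(0, 2 * np.pi)
        r_anchor = _support_radius(a_a, b_a, th_a, phi)
        r_new = _support_radius(a_new, b_new, theta_new, phi + np.pi)
        dist = _TOUCH_FACTOR * (r_anchor + r_new) * (1.0 + rng.uniform(-0.02, 0.02))
        x, y = ax + dist * np.cos(phi), ay + dist * np.sin(phi)
        ok = True
        for ox, oy, o_a, o_b, o_th in anchors:
            if ox == ax and oy == ay:
                continue
            d = np.hypot(x - ox, y - oy)
            line = float(np.arctan2(y - oy, x - ox))
            r_o = _support_radius(o_a, o_b, o_th, line)
            r_n = _support_radius(a_new, b_new, theta_new, line + np.pi)
            if d < 0.85 * (r_o + r_n):
                ok = False
                break
        if ok:
            return (x, y)
    return None


_MAX_RETRIES = 1000


def generate_scene(
    config: SceneConfig, frame_id: str | None = None
) -> tuple[FrameImage, GroundTruth]:
    """Render one pen scene and its exact ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    image and ground truth.
    """
    geom = config.geometry()
    pen = geom.pen_rect
    h, w = config.image_height, config.image_width
    rng = np.random.default_rng(config.seed)
    if frame_id is None:
        frame_id = f"scene-d{config.day}-s{config.seed}"

    # --- sample per-bird sizes, orientations, and flags -----------------
    n = config.n_birds
    birds: list[BirdRecord] = []
    sizes = []  # (a, b, theta_deg, wing_spread)
    for i in range(n):
        a, b, _ = _sample_axes(config, rng, config.day)
        wing = bool(rng.random() < config.wing_spread_prob)
        if wing:
            scale = np.sqrt(config.wing_spread_factor)
            a, b = a * scale, b * scale
        theta = float(rng.uniform(0.0, 180.0))
        sizes.append((a, b, theta, wing))

    n_pinned = min(len(config.pinned_positions), n)
    n_crowded = min(int(round(config.crowding_fraction * n)), n - n_pinned)

    placed: list[dict] = []  # {'x','y','a','cluster','i'}

    def overlaps(x: float, y: float, a: float, cluster: int) -> bool:
        for p in placed:
            if cluster >= 0 and p["cluster"] == cluster:
                continue
            if (p["x"] - x) ** 2 + (p["y"] - y) ** 2 <= (p["a"] + a + 3.0) ** 2:
                return True
        return False

    def random_center(a: float) -> tuple[float, float]:
        pad = a + 2.0
        if pen.x0 + pad >= pen.x1 - pad or pen.y0 + pad >= pen.y1 - pad:
            raise PlacementError(
                f"bird of semi-major axis {a:.1f} px cannot fit inside the pen"
            )
        return (
            rng.uniform(pen.x0 + pad, pen.x1 - pad),
            rng.uniform(pen.y0 + pad, pen.y1 - pad),
        )

    def inside_pen(x: float, y: float, a: float) -> bool:
        pad = a + 2.0
        return (
            pen.x0 + pad <= x <= pen.x1 - pad and pen.y0 + pad <= y <= pen.y1 - pad
        )

    idx = 0
    # pinned birds first (scaffolding for occlusion scenarios)
    for i in range(n_pinned):
        a, b, theta, wing = sizes[idx]
        x, y = config.pinned_positions[i]
        placed.append({"x": x, "y": y, "a": a, "cluster": -1, "i": idx})
        idx += 1
    # crowded birds in touching clusters of 2-3
    cluster_id = 0
    remaining_crowded = n_crowded
    while remaining_crowded > 0:
        size = int(min(remaining_crowded, rng.integers(2, 4)))
        if remaining_crowded - size == 1:
            size = min(remaining_crowded, 3)  # avoid a dangling 1-bird "cluster"
        seed_a, seed_b, seed_th, _w = sizes[idx]
        for attempt in range(_MAX_RETRIES + 1):
            if attempt == _MAX_RETRIES:
                raise PlacementError(
                    f"failed to place crowded cluster after {_MAX_RETRIES} retries"
                )
            sx, sy = random_center(3 * seed_a)  # room for neighbours
            if not overlaps(sx, sy, seed_a, cluster_id):
                break
        anchors = [(sx, sy, seed_a, seed_b, seed_th)]
        placed.append({"x": sx, "y": sy, "a": seed_a, "cluster": cluster_id, "i": idx})
        idx += 1
        for _ in range(size - 1):
            a_m, b_m, th_m, _w = sizes[idx]
            for attempt in range(_MAX_RETRIES + 1):
                if attempt == _MAX_RETRIES:
                    raise PlacementError(
                        f"failed to attach crowded bird after {_MAX_RETRIES} retries"
                    )
                pos = _attach_position(rng, anchors, a_m, b_m, th_m)
                if pos is None:
                    continue
                mx, my = pos
                if inside_pen(mx, my, a_m) and not overlaps(mx, my, a_m, cluster_id):
                    break
            anchors.append((mx, my, a_m, b_m, th_m))
            placed.append({"x": mx, "y": my, "a": a_m, "cluster": cluster_id, "i": idx})
            idx += 1
        remaining_crowded -= size
        cluster_id += 1
    # remaining singles by rejection sampling
    while idx < n:
        a, b, _th, _w = sizes[idx]
        for attempt in range(_MAX_RETRIES + 1):
            if attempt == _MAX_RETRIES:
                raise PlacementError(
                    f"failed to place bird {idx} after {_MAX_RETRIES} retries; "
                    "reduce n_birds or enable crowding"
                )
            x, y = random_center(a)
            if not overlaps(x, y, a, -2):
                break
        placed.append({"x": x, "y": y, "a": a, "cluster": -1, "i": idx})
        idx += 1

    # --- rasterise ------------------------------------------------------
    shape = (h, w)
    for p in placed:
        a, b, theta, wing = sizes[p["i"]]
        xs, ys = _bird_pixels(p["x"], p["y"], a, b, theta, shape)
        birds.append(
            BirdRecord(
                bird_id=len(birds),
                centroid=(p["x"], p["y"]),
                axes=(a, b),
                orientation_deg=theta,
                zone="",
                occluded_fraction=0.0,
                crowded=p["cluster"] >= 0,
                wing_spread=wing,
                area_px=len(xs),
                xs=xs,
                ys=ys,
            )
        )

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(config.litter_color_mean, dtype=np.float64)
    for bird in birds:
        img[bird.ys, bird.xs] = np.asarray(config.bird_color_mean, dtype=np.float64)

    occ_mask = None
    if config.occluders:
        occ_mask = np.zeros(shape, dtype=bool)
        for spec in config.occluders:
            m = _occluder_mask(spec, shape)
            occ_mask |= m
            img[m] = np.asarray(spec.color, dtype=np.float64)

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # --- ground truth ---------------------------------------------------
    counts = {zmod.DRINKING: 0, zmod.FEEDING: 0, zmod.REST: 0}
    for bird in birds:
        bird.zone = zmod.assign_zone_pixels(bird.xs, bird.ys, geom)
        counts[bird.zone] += 1
        if occ_mask is not None and bird.area_px:
            covered = int(np.count_nonzero(occ_mask[bird.ys, bird.xs]))
            bird.occluded_fraction = covered / bird.area_px

    truth = GroundTruth(
        frame_id=frame_id,
        birds=birds,
        per_zone_true_counts=counts,
        total=len(birds),
        shape=shape,
        occluder_mask=occ_mask,
    )
    frame = FrameImage(pixels, day=config.day, frame_id=frame_id)
    return frame, truth


def _occluder_mask(spec: OccluderSpec, shape: tuple[int, int]) -> np.ndarray:
    """Pixels within thickness/2 of the polyline (capsule rasterisation)."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    half = spec.thickness / 2.0
    pts = [np.asarray(p, dtype=np.float64) for p in spec.path]
    for p0, p1 in zip(pts[:-1], pts[1:]):
        x0 = int(np.floor(min(p0[0], p1[0]) - half - 1))
        x1 = int(np.ceil(max(p0[0], p1[0]) + half + 1))
        y0 = int(np.floor(min(p0[1], p1[1]) - half - 1))
        y1 = int(np.ceil(max(p0[1], p1[1]) + half + 1))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w - 1), min(y1, h - 1)
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        gx, gy = np.meshgrid(xs, ys)
        d = p1 - p0
        length2 = float(d @ d)
        if length2 == 0:
            dist2 = (gx - p0[0]) ** 2 + (gy - p0[1]) ** 2
        else:
            t = ((gx - p0[0]) * d[0] + (gy - p0[1]) * d[1]) / length2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (gx - (p0[0] + t * d[0])) ** 2 + (gy - (p0[1] + t * d[1])) ** 2
        mask[y0 : y1 + 1, x0 : x1 + 1] |= dist2 <= half * half
    return mask


def generate_area_count_pairs(
    config: SceneConfig,
    n_samples: int,
    cluster_sizes: tuple[int, int] = (1, 4),
) -> list[tuple[float, int]]:
    """Merged-blob (area, true count) training pairs.

    Each sample rasterises 1..k bird ellipses placed with the same
    touching-cluster rule the scene generator uses, measures the union
    pixel area, adds a small boundary-noise jitter, and pairs it with
    the exact number of birds merged.  Reproducible under the config
    seed.
    """
    if n_samples < 1:
        raise SceneConfigError("n_samples must be >= 1")
    lo, hi = cluster_sizes
    if lo < 1 or hi < lo:
        raise SceneConfigError(f"invalid cluster size range {cluster_sizes}")
    rng = np.random.default_rng(config.seed)
    # scratch canvas comfortably larger than any cluster
    a_max = np.sqrt(
        config.mean_bird_area(35) * 1.6 * config.wing_spread_factor / np.pi
    ) * config.axis_ratio
    side = int(np.ceil(10 * a_max)) + 8
    pairs: list[tuple[float, int]] = []
    for _ in range(n_samples):
        k = int(rng.integers(lo, hi + 1))
        canvas = np.zeros((side, side), dtype=bool)
        cx0 = cy0 = side / 2.0
        anchors: list[tuple[float, float, float, float, float]] = []
        for j in range(k):
            a, b, _area = _sample_axes(config, rng, config.day)
            theta = float(rng.uniform(0.0, 180.0))
            if j == 0:
                cx, cy = cx0, cy0
            else:
                pos = None
                while pos is None:
                    pos = _attach_position(rng, anchors, a, b, theta)
                cx, cy = pos
            anchors.append((cx, cy, a, b, theta))
            xs, ys = _bird_pixels(cx, cy, a, b, theta, (side, side))
            canvas[ys, xs] = True
        area = float(np.count_nonzero(canvas))
        area += rng.normal(0.0, 0.02 * area)  # boundary/segmentation jitter
        pairs.append((max(area, 1.0), k))
    return pairs


def sample_single_bird_areas(
    config: SceneConfig, n_samples: int, day: int | None = None
) -> list[float]:
    """Rasterised single-bird areas, as used for the per-day reference area."""
    rng = np.random.default_rng(config.seed)
    d = config.day if day is None else day
    a_max = np.sqrt(config.mean_bird_area(35) * 1.6 / np.pi) * config.axis_ratio
    side = int(np.ceil(4 * a_max)) + 8
    out = []
    for _ in range(n_samples):
        a, b, _area = _sample_axes(config, rng, d)
        theta = float(rng.uniform(0.0, 180.0))
        xs, _ys = _bird_pixels(side / 2, side / 2, a, b, theta, (side, side))
        out.append(float(len(xs)))
    return out


# ---------------------------------------------------------------------------
# file round-tripping


def write_scene(
    frame: FrameImage,
    truth: GroundTruth,
    config: SceneConfig,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write PNG + per-bird CSV + JSON sidecar; returns the file map."""
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = frame.frame_id
    png = out_dir / f"{stem}.png"
    csv = out_dir / f"{stem}.birds.csv"
    sidecar = out_dir / f"{stem}.json"
    Image.fromarray(frame.pixels, mode="RGB").save(png)
    pd.DataFrame(
        [
            {
                "id": b.bird_id,
                "centroid_x": b.centroid[0],
                "centroid_y": b.centroid[1],
                "axis_a": b.axes[0],
                "axis_b": b.axes[1],
                "orientation_deg": b.orientation_deg,
                "zone": b.zone,
                "occluded_fraction": b.occluded_fraction,
            }
            for b in truth.birds
        ],
        columns=[
            "id",
            "centroid_x",
            "centroid_y",
            "axis_a",
            "axis_b",
            "orientation_deg",
            "zone",
            "occluded_fraction",
        ],
    ).to_csv(csv, index=False)
    sidecar.write_text(
        json.dumps(
            {
                "frame_id": stem,
                "day": config.day,
                "per_zone_true_counts": truth.per_zone_true_counts,
                "total": truth.total,
                "config": config.to_dict(),
            },
            indent=2,
            default=float,
        )
        + "\n"
    )
    return {"image": str(png), "birds": str(csv), "sidecar": str(sidecar)}
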