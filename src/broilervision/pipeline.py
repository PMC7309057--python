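"""End-to-end frame processing: segmentation -> counting -> zones.

Glues the detection front end (GB channel pair + 2-D Otsu + cleanup),
the per-day reference-area normalisation, the BP counting network, and
the zone-assignment rule into a single per-frame call, plus overlay
rendering for visual audits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from broilervision import zones as zmod
from broilervision.counting import BPModel, ReferenceArea, count_region
from broilervision.segmentation import (
    GB,
    BinaryMask,
    ChannelPair,
    FrameImage,
    Region,
    segment_frame,
)
from broilervision.zones import ZoneCounts, ZoneGeometry, frame_distribution


@dataclass
class FrameResult:
    frame_id: str
    mask: BinaryMask
    regions: list[Region]
    counts: list[int]
    zone_counts: ZoneCounts


def process_frame(
    image: FrameImage,
    geom: ZoneGeometry,
    ref: ReferenceArea,
    model: BPModel | None = None,
    pair: ChannelPair = GB,
    levels: int = 256,
    erosion_radius: int = 1,
    min_area: int | None = None,
) -> FrameResult:
    """Segment one frame, count birds per region, assign counts to zones."""
    mask, regions = segment_frame(
        image,
        geom,
        pair=pair,
        levels=levels,
        erosion_radius=erosion_radius,
        min_area=min_area,
    )
    counts = [count_region(r, ref, model) for r in regions]
    zc = frame_distribution(regions, counts, geom, frame_id=image.frame_id)
    return FrameResult(
        frame_id=image.frame_id,
        mask=mask,
        regions=regions,
        counts=counts,
        zone_counts=zc,
    )


def process_frames(
    images: Sequence[FrameImage],
    geom: ZoneGeometry,
    refs: Mapping[int, ReferenceArea] | ReferenceArea,
    model: BPModel | None = None,
    **seg_kwargs,
) -> list[FrameResult]:
    """Process many frames, looking up the reference area per frame day."""
    out = []
    for image in images:
        ref = refs if isinstance(refs, ReferenceArea) else refs[image.day]
        out.append(process_frame(image, geom, ref, model, **seg_kwargs))
    return out


def render_overlay(
    image: FrameImage, result: FrameResult, geom: ZoneGeometry
) -> np.ndarray:
    """RGB overlay: zone outlines, region boxes, and per-zone counts."""
    from PIL import Image, ImageDraw

    im = Image.fromarray(image.pixels, mode="RGB")
    drawer = ImageDraw.Draw(im)
    pen = geom.pen_rect
    drawer.rectangle(pen.as_tuple(), outline=(0, 255, 255), width=2)
    drawer.rectangle(geom.drinking_rect.as_tuple(), outline=(255, 0, 0), width=2)
    d = geom.feeding_disc
    drawer.ellipse(
        (d.cx - d.radius, d.cy - d.radius, d.cx + d.radius, d.cy + d.radius),
        outline=(255, 255, 0),
        width=2,
    )
    for region, count in zip(result.regions, result.counts):
        zone = zmod.assign_zone(region, geom)
        color = {
            zmod.DRINKING: (255, 0, 0),
            zmod.FEEDING: (255, 255, 0),
            zmod.REST: (0, 255, 255),
        }[zone]
        drawer.rectangle(region.bbox, outline=color, width=1)
        if count > 1:
            drawer.text((region.bbox[0], region.bbox[1]), str(count), fill=color)
    zc = result.zone_counts
    drawer.text(
        (pen.x0 + 4, pen.y1 - 14),
        f"D={zc.d_num} F={zc.f_num} rest={zc.rest} total={zc.total}",
        fill=(255, 255, 255),
    )
    return np.asarray(im)


def save_overlay(
    image: FrameImage, result: FrameResult, geom: ZoneGeometry, path: str | Path
) -> None:
    from PIL import Image

    Image.fromarray(render_overlay(image, result, geom), mode="RGB").save(path)
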