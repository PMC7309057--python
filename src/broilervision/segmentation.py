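"""Bird segmentation: channel-pair classification + two-dimensional Otsu.

The detection front end converts a top-view RGB pen image into a cleaned
binary foreground mask in four steps:

1. *Non-target removal* — pixels outside the pen's overall detection
   rectangle are painted with a background sentinel and excluded from
   every downstream histogram.
2. *Channel-pair feature* — each pixel is mapped to a 2-D feature, by
   default its quantised (G, B) value pair; the classical variant that
   pairs a channel value with its 3x3 neighbourhood mean is also
   available.
3. *Two-dimensional Otsu* — the threshold pair (t1, t2) maximising the
   between-class scatter (trace criterion) over the joint histogram,
   with the two classes defined by the quadrant split: the candidate
   foreground class is {feature1 > t1 and feature2 > t2}, the background
   class is everything else.  Foreground polarity is auto-selected: the
   class whose mean feature lies farther from the median pen feature
   becomes foreground (white birds on brown litter, or the reverse).
4. *Morphological cleanup* — erosion with a disc structuring element to
   cut thin background connections, then removal of small components.

Regions are 8-connected components returned in deterministic
(ymin, xmin) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from broilervision.zones import Rect, ZoneGeometry

CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}

#: Sentinel colour painted outside the detection area.
SENTINEL_COLOR = (0, 0, 0)


class SegmentationError(ValueError):
    pass


@dataclass
class FrameImage:
    """An 8-bit RGB top-view pen frame.

    ``valid_mask`` marks pixels that take part in histograms and
    thresholding; it is ``None`` for a raw frame and is set by
    :func:`remove_nontarget`.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    day: int = 24
    frame_id: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise SegmentationError(
                f"expected an HxWx3 image, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise SegmentationError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def valid(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid_mask


@dataclass(frozen=True)
class ChannelPair:
    """Which two channels (or channel vs neighbourhood mean) to histogram."""

    first: str = "G"
    second: str = "B"
    mode: str = "joint"  # "joint" | "value_vs_neighborhood"

    def __post_init__(self) -> None:
        if self.first not in CHANNEL_INDEX or self.second not in CHANNEL_INDEX:
            raise SegmentationError(f"unknown channel in pair {self}")
        if self.mode not in ("joint", "value_vs_neighborhood"):
            raise SegmentationError(f"unknown channel-pair mode {self.mode!r}")
        if self.mode == "joint" and self.first == self.second:
            raise SegmentationError("joint mode requires two distinct channels")


GB = ChannelPair("G", "B", "joint")


@dataclass
class JointHistogram:
    bins: np.ndarray  # L x L counts
    levels: int
    pair: ChannelPair

    @property
    def total(self) -> int:
        return int(self.bins.sum())


@dataclass
class BinaryMask:
    mask: np.ndarray  # H x W bool
    provenance: dict = field(default_factory=dict)


@dataclass
class Region:
    """A connected foreground component."""

    region_id: int
    xs: np.ndarray  # pixel x coordinates
    ys: np.ndarray  # pixel y coordinates
    area: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (xmin, ymin, xmax, ymax) inclusive


@dataclass
class Otsu2DResult:
    t1: int
    t2: int
    objective: float
    degenerate: bool = False

    @property
    def thresholds(self) -> tuple[int, int]:
        return (self.t1, self.t2)


def remove_nontarget(image: FrameImage, pen: ZoneGeometry | Rect) -> FrameImage:
    """Blank everything outside the pen's overall detection rectangle.

    Outside pixels are set to the sentinel colour and excluded (via
    ``valid_mask``) from all downstream histograms and thresholding.
    """
    rect = pen.pen_rect if isinstance(pen, ZoneGeometry) else pen
    h, w = image.shape
    if rect.x0 < 0 or rect.y0 < 0 or rect.x1 >= w or rect.y1 >= h:
        raise SegmentationError(
            f"pen rectangle {rect.as_tuple()} exceeds image bounds {w}x{h}"
        )
    valid = np.zeros((h, w), dtype=bool)
    valid[rect.y0 : rect.y1 + 1, rect.x0 : rect.x1 + 1] = True
    pixels = image.pixels.copy()
    pixels[~valid] = SENTINEL_COLOR
    return FrameImage(pixels, image.day, image.frame_id, valid_mask=valid)


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    # map [0,255] onto [0, levels) with equal-width bins
    return (values.astype(np.int64) * levels) // 256


def channel_features(
    image: FrameImage, pair: ChannelPair, levels: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel quantised feature pair (full H x W arrays)."""
    c1 = image.pixels[:, :, CHANNEL_INDEX[pair.first]]
    if pair.mode == "joint":
        c2 = image.pixels[:, :, CHANNEL_INDEX[pair.second]]
        f2 = _quantize(c2, levels)
    else:
        neigh = ndi.uniform_filter(c1.astype(np.float64), size=3, mode="nearest")
        f2 = _quantize(np.clip(np.rint(neigh), 0, 255).astype(np.int64), levels)
    f1 = _quantize(c1, levels)
    return f1, f2


def build_joint_histogram(
    image: FrameImage, pair: ChannelPair = GB, levels: int = 256
) -> JointHistogram:
    """L x L histogram of the channel-pair feature over valid pixels."""
    if not (2 <= levels <= 256):
        raise SegmentationError(f"levels must be in [2, 256], got {levels}")
    valid = image.valid()
    if not valid.any():
        raise SegmentationError("no valid pixels to histogram")
    f1, f2 = channel_features(image, pair, levels)
    flat = f1[valid] * levels + f2[valid]
    bins = np.bincount(flat, minlength=levels * levels).reshape(levels, levels)
    return JointHistogram(bins=bins, levels=levels, pair=pair)


def _quadrant_stats(bins: np.ndarray):
    """Suffix sums over the foreground quadrant for every threshold pair.

    Returns, for each (t1, t2), the probability mass and the two first
    moments of the class {i > t1, j > t2}.
    """
    levels = bins.shape[0]
    w = bins.astype(np.float64)
    total = w.sum()
    w /= total
    i = np.arange(levels, dtype=np.float64)
    # suffix[i, j] = sum over (>=i, >=j); foreground at (t1,t2) is suffix[t1+1, t2+1]
    def suffix(a: np.ndarray) -> np.ndarray:
        s = np.cumsum(np.cumsum(a[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
        out = np.zeros((levels + 1, levels + 1))
        out[:levels, :levels] = s
        return out

    s_p = suffix(w)
    s_mi = suffix(w * i[:, None])
    s_mj = suffix(w * i[None, :])
    p_fg = s_p[1:, 1:]
    mi_fg = s_mi[1:, 1:]
    mj_fg = s_mj[1:, 1:]
    mu_i = float((w.sum(axis=1) * i).sum())
    mu_j = float((w.sum(axis=0) * i).sum())
    return p_fg, mi_fg, mj_fg, mu_i, mu_j


def otsu_2d(hist: JointHistogram) -> Otsu2DResult:
    """Threshold pair maximising the 2-D between-class scatter criterion.

    The criterion is tr(S_b) = P_bg ||mu_bg - mu||^2 + P_fg ||mu_fg - mu||^2
    where the foreground class at (t1, t2) is the quadrant
    {i > t1 and j > t2} of the joint histogram and the background class
    is its complement.  Ties are broken by the smallest (t1, then t2).
    Degenerate histograms (all mass in one bin) return that bin's level
    pair with objective 0.
    """
    bins = hist.bins
    if bins.sum() == 0:
        raise SegmentationError("empty histogram")
    nz = np.argwhere(bins > 0)
    if len(nz) == 1:
        i, j = (int(v) for v in nz[0])
        return Otsu2DResult(i, j, 0.0, degenerate=True)

    p_fg, mi_fg, mj_fg, mu_i, mu_j = _quadrant_stats(bins)
    p_bg = 1.0 - p_fg
    valid = (p_fg > 0) & (p_bg > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mui_fg = mi_fg / p_fg
        muj_fg = mj_fg / p_fg
        mui_bg = (mu_i - mi_fg) / p_bg
        muj_bg = (mu_j - mj_fg) / p_bg
        obj = p_fg * ((mui_fg - mu_i) ** 2 + (muj_fg - mu_j) ** 2) + p_bg * (
            (mui_bg - mu_i) ** 2 + (muj_bg - mu_j) ** 2
        )
    obj = np.where(valid, obj, -np.inf)
    if not np.isfinite(obj).any():
        # mass spread over several bins but no quadrant split separates it
        i, j = (int(v) for v in nz[0])
        return Otsu2DResult(i, j, 0.0, degenerate=True)
    flat = int(np.argmax(obj))  # row-major argmax = smallest (t1, t2) on ties
    t1, t2 = divmod(flat, bins.shape[0])
    return Otsu2DResult(int(t1), int(t2), float(obj[t1, t2]))


def otsu_2d_brute_force(hist: JointHistogram) -> Otsu2DResult:
    """Exhaustive-search reference for :func:`otsu_2d` (slow, small L only)."""
    bins = hist.bins.astype(np.float64)
    total = bins.sum()
    if total == 0:
        raise SegmentationError("empty histogram")
    levels = bins.shape[0]
    w = bins / total
    i_idx, j_idx = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    mu_i = float((w * i_idx).sum())
    mu_j = float((w * j_idx).sum())
    best = None
    for t1 in range(levels):
        for t2 in range(levels):
            fg = (i_idx > t1) & (j_idx > t2)
            p1 = w[fg].sum()
            p0 = 1.0 - p1
            if p1 <= 0 or p0 <= 0:
                continue
            m1i = (w * i_idx)[fg].sum() / p1
            m1j = (w * j_idx)[fg].sum() / p1
            m0i = (mu_i - p1 * m1i) / p0
            m0j = (mu_j - p1 * m1j) / p0
            obj = p1 * ((m1i - mu_i) ** 2 + (m1j - mu_j) ** 2) + p0 * (
                (m0i - mu_i) ** 2 + (m0j - mu_j) ** 2
            )
            if best is None or obj > best[0] + 1e-15:
                best = (obj, t1, t2)
    if best is None:
        nz = np.argwhere(bins > 0)[0]
        return Otsu2DResult(int(nz[0]), int(nz[1]), 0.0, degenerate=True)
    return Otsu2DResult(best[1], best[2], best[0])


def apply_threshold(
    image: FrameImage,
    pair: ChannelPair,
    thresholds: tuple[int, int],
    levels: int = 256,
    polarity: str = "auto",
) -> BinaryMask:
    """Binarise the frame at a 2-D threshold pair.

    The quadrant class is {feature1 > t1 and feature2 > t2}.  With
    ``polarity='auto'`` the foreground is whichever of quadrant /
    complement has its mean feature farther from the median pen feature
    (ties go to the smaller class); ``'quadrant'`` and ``'complement'``
    force the choice.
    """
    t1, t2 = thresholds
    if not (0 <= t1 < levels and 0 <= t2 < levels):
        raise SegmentationError(f"thresholds {thresholds} outside [0, {levels})")
    f1, f2 = channel_features(image, pair, levels)
    valid = image.valid()
    quad = (f1 > t1) & (f2 > t2) & valid
    if polarity == "quadrant":
        fg = quad
    elif polarity == "complement":
        fg = valid & ~quad
    elif polarity == "auto":
        fg = _auto_polarity(f1, f2, valid, quad)
    else:
        raise SegmentationError(f"unknown polarity {polarity!r}")
    return BinaryMask(
        mask=fg,
        provenance={
            "pair": (pair.first, pair.second, pair.mode),
            "thresholds": (int(t1), int(t2)),
            "levels": levels,
            "polarity": polarity,
        },
    )


def _auto_polarity(
    f1: np.ndarray, f2: np.ndarray, valid: np.ndarray, quad: np.ndarray
) -> np.ndarray:
    comp = valid & ~quad
    n_quad = int(quad.sum())
    n_comp = int(comp.sum())
    if n_quad == 0:
        return quad  # nothing above threshold; empty foreground
    if n_comp == 0:
        return quad
    med = np.array([np.median(f1[valid]), np.median(f2[valid])])
    mean_quad = np.array([f1[quad].mean(), f2[quad].mean()])
    mean_comp = np.array([f1[comp].mean(), f2[comp].mean()])
    d_quad = float(np.linalg.norm(mean_quad - med))
    d_comp = float(np.linalg.norm(mean_comp - med))
    if d_quad > d_comp:
        return quad
    if d_comp > d_quad:
        return comp
    return quad if n_quad <= n_comp else comp


def morphological_cleanup(
    mask: BinaryMask, erosion_radius: int = 1, min_area: int = 30
) -> BinaryMask:
    """Erode with a disc structuring element, then drop small components.

    ``erosion_radius=1`` uses the 4-neighbourhood cross (disc of radius
    1); components with area strictly below ``min_area`` are removed.
    """
    if erosion_radius < 0 or min_area < 0:
        raise SegmentationError("erosion_radius and min_area must be >= 0")
    out = mask.mask
    if erosion_radius > 0:
        out = morphology.erosion(out, morphology.disk(erosion_radius)).astype(bool)
    if min_area > 0:
        # max_size removes components with area <= value, so min_area - 1
        # keeps exactly the components with area >= min_area
        out = morphology.remove_small_objects(
            out, max_size=min_area - 1, connectivity=2
        )
    prov = dict(mask.provenance)
    prov["morphology"] = {"erosion_radius": erosion_radius, "min_area": min_area}
    return BinaryMask(mask=out, provenance=prov)


def extract_regions(mask: BinaryMask) -> list[Region]:
    """8-connected components in deterministic (ymin, xmin) bbox order."""
    labels = measure.label(mask.mask, connectivity=2)
    regions: list[Region] = []
    for prop in measure.regionprops(labels):
        ys, xs = prop.coords[:, 0], prop.coords[:, 1]
        ymin, xmin, ymax, xmax = prop.bbox  # half-open
        regions.append(
            Region(
                region_id=0,
                xs=xs.astype(np.int64),
                ys=ys.astype(np.int64),
                area=int(prop.area),
                centroid=(float(prop.centroid[1]), float(prop.centroid[0])),
                bbox=(int(xmin), int(ymin), int(xmax) - 1, int(ymax) - 1),
            )
        )
    regions.sort(key=lambda r: (r.bbox[1], r.bbox[0]))
    for idx, region in enumerate(regions):
        region.region_id = idx
    return regions


def segment_frame(
    image: FrameImage,
    geom: ZoneGeometry,
    pair: ChannelPair = GB,
    levels: int = 256,
    erosion_radius: int = 1,
    min_area: int | None = None,
    polarity: str = "auto",
) -> tuple[BinaryMask, list[Region]]:
    """Full detection front end: non-target removal through regions.

    ``min_area=None`` scales the default 30 px (at 1440x1080) with
    image area.
    """
    h, w = image.shape
    if min_area is None:
        min_area = max(1, int(round(30 * (h * w) / (1440 * 1080))))
    cropped = remove_nontarget(image, geom)
    hist = build_joint_histogram(cropped, pair, levels)
    thr = otsu_2d(hist)
    mask = apply_threshold(cropped, pair, thr.thresholds, levels, polarity)
    mask.provenance["otsu"] = {
        "thresholds": thr.thresholds,
        "objective": thr.objective,
        "degenerate": thr.degenerate,
    }
    cleaned = morphological_cleanup(mask, erosion_radius, min_area)
    return cleaned, extract_regions(cleaned)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray((mask.mask.astype(np.uint8)) * 255, mode="L").save(path)


def write_regions_csv(
    regions: Sequence[Region], frame_id: str, path: str | Path
) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "frame_id": frame_id,
                "region_id": r.region_id,
                "area": r.area,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "xmin": r.bbox[0],
                "ymin": r.bbox[1],
                "xmax": r.bbox[2],
                "ymax": r.bbox[3],
            }
            for r in regions
        ],
        columns=[
            "frame_id",
            "region_id",
            "area",
            "centroid_x",
            "centroid_y",
            "xmin",
            "ymin",
            "xmax",
            "ymax",
        ],
    )
    df.to_csv(path, index=False)


def read_image(path: str | Path, day: int = 24, frame_id: str | None = None) -> FrameImage:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return FrameImage(arr, day=day, frame_id=frame_id or Path(path).stem)
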