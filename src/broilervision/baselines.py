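"""Clustering segmentation baselines: K-means and fuzzy c-means.

These are the classical pixel-clustering alternatives the 2-D Otsu
front end is compared against.  Both cluster per-pixel (R, G, B)
vectors; the bird cluster is then selected by the same polarity rule
the thresholding pipeline uses (the cluster whose centre lies farthest
from the median pen colour).

K-means is Lloyd's algorithm with seeded initialisation; an emptied
cluster is re-seeded from the pixel farthest from its assigned centre.
FCM uses the standard alternating updates with fuzzifier ``m``
(membership ``u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1))``, centres as
membership-weighted means); a pixel at zero distance from a centre gets
full membership in that centre.

A timing harness reports wall-clock per method per image.  Timings are
informational only — they depend entirely on the hardware running them
and are never asserted against.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from broilervision.segmentation import BinaryMask, FrameImage


class BaselineError(ValueError):
    pass


@dataclass
class ClusteringResult:
    labels: np.ndarray  # H x W int
    centers: np.ndarray  # k x 3
    iterations: int
    converged: bool
    objective: float
    memberships: np.ndarray | None = None  # FCM only: k x N
    objective_trace: list[float] | None = None


def _pixel_matrix(image: FrameImage) -> tuple[np.ndarray, np.ndarray]:
    valid = image.valid()
    return image.pixels[valid].astype(np.float64), valid


def _init_centers(
    data: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded initial centres drawn from *distinct* pixel colours.

    Sampling raw pixels can return duplicate colour vectors (a flat
    background dominates most pen frames), which stalls the alternating
    updates; distinct colours guarantee a meaningful first assignment.
    """
    uniq = np.unique(data, axis=0)
    if len(uniq) >= k:
        return uniq[rng.choice(len(uniq), size=k, replace=False)].astype(np.float64)
    centers = data[rng.choice(len(data), size=k, replace=False)].astype(np.float64)
    centers += rng.normal(0, 1e-3, size=centers.shape)  # break exact ties
    return centers


def _bird_cluster(centers: np.ndarray, data: np.ndarray) -> int:
    """Polarity rule: the centre farthest from the median pen colour."""
    med = np.median(data, axis=0)
    return int(np.argmax(np.linalg.norm(centers - med, axis=1)))


def _labels_to_mask(
    labels_flat: np.ndarray, bird: int, valid: np.ndarray, provenance: dict
) -> BinaryMask:
    mask = np.zeros(valid.shape, dtype=bool)
    mask[valid] = labels_flat == bird
    return BinaryMask(mask=mask, provenance=provenance)


def kmeans_segment(
    image: FrameImage,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[ClusteringResult, BinaryMask]:
    """Lloyd's K-means on per-pixel RGB vectors; deterministic under seed."""
    if k < 2:
        raise BaselineError("k must be >= 2")
    data, valid = _pixel_matrix(image)
    n = len(data)
    if n < k:
        raise BaselineError(f"only {n} pixels for k={k} clusters")
    rng = np.random.default_rng(seed)
    centers = _init_centers(data, k, rng)
    labels = np.zeros(n, dtype=np.int64)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new_centers[j] = data[sel].mean(axis=0)
            else:
                # documented rule: re-seed an emptied cluster from the
                # pixel farthest from its current centre
                far = int(d2[np.arange(n), labels].argmax())
                new_centers[j] = data[far]
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            converged = True
            break
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    objective = float(d2[np.arange(n), labels].sum())
    label_img = np.full(valid.shape, -1, dtype=np.int64)
    label_img[valid] = labels
    bird = _bird_cluster(centers, data)
    result = ClusteringResult(
        labels=label_img,
        centers=centers,
        iterations=it,
        converged=converged,
        objective=objective,
    )
    mask = _labels_to_mask(
        labels, bird, valid, {"method": "kmeans", "k": k, "seed": seed}
    )
    return result, mask


def fcm_segment(
    image: FrameImage,
    c: int = 3,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[ClusteringResult, BinaryMask]:
    """Fuzzy c-means on per-pixel RGB vectors with maximum-membership
    defuzzification; deterministic under seed."""
    if c < 2:
        raise BaselineError("c must be >= 2")
    if m <= 1:
        raise BaselineError("fuzzifier m must be > 1")
    data, valid = _pixel_matrix(image)
    n = len(data)
    if n < c:
        raise BaselineError(f"only {n} pixels for c={c} clusters")
    rng = np.random.default_rng(seed)
    centers = _init_centers(data, c, rng)
    expo = 2.0 / (m - 1.0)
    trace: list[float] = []
    converged = False
    u = np.full((c, n), 1.0 / c)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((centers[:, None, :] - data[None, :, :]) ** 2).sum(axis=2)  # c x n
        zero = d2 <= 1e-24
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)
            u = inv / inv.sum(axis=0, keepdims=True)
        # zero distance -> full membership in that centre
        any_zero = zero.any(axis=0)
        if any_zero.any():
            u[:, any_zero] = 0.0
            first = zero[:, any_zero].argmax(axis=0)
            u[first, np.nonzero(any_zero)[0]] = 1.0
        um = u**m
        trace.append(float((um * d2).sum()))
        new_centers = (um @ data) / um.sum(axis=1, keepdims=True)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            converged = True
            break
    d2 = ((centers[:, None, :] - data[None, :, :]) ** 2).sum(axis=2)
    objective = float((u**m * d2).sum())
    labels = u.argmax(axis=0)
    label_img = np.full(valid.shape, -1, dtype=np.int64)
    label_img[valid] = labels
    bird = _bird_cluster(centers, data)
    result = ClusteringResult(
        labels=label_img,
        centers=centers,
        iterations=it,
        converged=converged,
        objective=objective,
        memberships=u,
        objective_trace=trace,
    )
    mask = _labels_to_mask(
        labels, bird, valid, {"method": "fcm", "c": c, "m": m, "seed": seed}
    )
    return result, mask


def timing_harness(
    images: Sequence[FrameImage],
    methods: dict[str, Callable[[FrameImage], object]] | None = None,
    csv_path: str | Path | None = None,
):
    """Wall-clock per method per image (informational only).

    Returns a DataFrame with columns frame_id, method, seconds.
    """
    import pandas as pd

    from broilervision.segmentation import segment_frame
    from broilervision.zones import default_zone_geometry

    if not images:
        raise BaselineError("timing harness needs at least one image")
    if methods is None:
        h, w = images[0].shape

        def _otsu(img: FrameImage):
            geom = default_zone_geometry(img.shape[1], img.shape[0])
            return segment_frame(img, geom)

        methods = {
            "gb_otsu2d": _otsu,
            "kmeans": lambda img: kmeans_segment(img),
            "fcm": lambda img: fcm_segment(img),
        }
    rows = []
    for image in images:
        for name, fn in methods.items():
            t0 = time.perf_counter()
            fn(image)
            rows.append(
                {
                    "frame_id": image.frame_id,
                    "method": name,
                    "seconds": time.perf_counter() - t0,
                }
            )
    df = pd.DataFrame(rows, columns=["frame_id", "method", "seconds"])
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df
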