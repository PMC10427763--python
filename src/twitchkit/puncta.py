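"""AChR/BTX nucleus scoring, receptor-cluster shape, and smFISH spot counts.

Three measurement families share this module: (1) classifying myonuclei as
AChR-positive from the mean α-bungarotoxin intensity over each nucleus,
against a background level taken from the modal histogram bin of all nucleus
means; (2) shape descriptors (area, circularity, roundness) of receptor
clusters; (3) counting binarized smFISH spots inside perinuclear regions —
the stretch of myotube within ±50 µm arc length of a myonucleus — with
per-area normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .morphometry import project_to_polyline

__all__ = [
    "NucleusIntensityRecord",
    "ClusterShape",
    "SpotCountRecord",
    "nucleus_btx_means",
    "btx_background",
    "classify_high_btx",
    "cluster_shape",
    "perinuclear_region",
    "count_spots",
]


@dataclass(frozen=True)
class NucleusIntensityRecord:
    nucleus_id: int
    mean_btx: float
    is_high: bool = False


@dataclass(frozen=True)
class ClusterShape:
    area: float  # µm²
    perimeter: float  # µm
    circularity: float  # 4π·area / perimeter²
    roundness: float  # 4·area / (π·major_axis²)
    major_axis: float  # µm
    reliable: bool = True  # False below the minimum measurable size


@dataclass(frozen=True)
class SpotCountRecord:
    region_id: int
    spot_count: int
    normalizer: float  # µm² (myonucleus area or myotube-region area)
    density: float  # count / µm²


def nucleus_btx_means(
    btx_image: np.ndarray, dapi_labels: np.ndarray
) -> list[NucleusIntensityRecord]:
    """Mean BTX intensity over each labelled nucleus region."""
    if btx_image.shape != dapi_labels.shape:
        raise ValueError("BTX image and label image must have the same shape")
    img = np.asarray(btx_image, dtype=float)
    return [
        NucleusIntensityRecord(
            nucleus_id=int(rp.label), mean_btx=float(img[rp.slice][rp.image].mean())
        )
        for rp in measure.regionprops(dapi_labels)
    ]


def btx_background(means, histogram_bins: int = 64) -> float:
    """Background BTX level: center of the modal bin of the nucleus means.

    The histogram spans [min, max] of the per-nucleus means; on a tie the
    lower bin wins.  Requires at least 10 nuclei for a meaningful mode.
    """
    values = np.asarray(
        [m.mean_btx if isinstance(m, NucleusIntensityRecord) else m for m in means],
        dtype=float,
    )
    if values.size < 10:
        raise ValueError(
            "need at least 10 nuclei to estimate the BTX background; pool images"
        )
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        warnings.warn("all nucleus means identical; returning that value", stacklevel=2)
        return lo
    counts, edges = np.histogram(values, bins=histogram_bins, range=(lo, hi))
    k = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    return float(0.5 * (edges[k] + edges[k + 1]))


def classify_high_btx(
    records: list[NucleusIntensityRecord], background: float, factor: float = 2.0
) -> tuple[list[NucleusIntensityRecord], float]:
    """Flag AChR-positive nuclei: mean BTX strictly above ``factor`` × background.

    Returns the updated records and the proportion of high nuclei.
    """
    if background <= 0:
        raise ValueError("background must be > 0")
    out = [replace(r, is_high=r.mean_btx > factor * background) for r in records]
    prop = sum(r.is_high for r in out) / len(out) if out else float("nan")
    return out, prop


def cluster_shape(
    mask: np.ndarray, pixel_size: float, min_area_px: int = 5
) -> ClusterShape:
    """Shape descriptors of a single receptor cluster.

    ``circularity = 4π·area/perimeter²`` and ``roundness = 4·area/(π·major²)``
    with the major axis from the second-moment ellipse fit.  The mask must be
    one connected component; clusters below ``min_area_px`` are measured but
    flagged unreliable (their digitized perimeter is meaningless).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        raise ValueError("empty cluster mask")
    if n > 1:
        raise ValueError("mask has multiple components; split them first")
    rp = measure.regionprops(labels)[0]
    area = rp.area * pixel_size**2
    perim = rp.perimeter * pixel_size
    major = rp.axis_major_length * pixel_size
    reliable = rp.area >= min_area_px and perim > 0 and major > 0
    circ = 4.0 * np.pi * area / perim**2 if perim > 0 else float("nan")
    # digitization can push the ratio marginally past the continuous bound
    roundness = min(4.0 * area / (np.pi * major**2), 1.0) if major > 0 else float("nan")
    return ClusterShape(
        area=float(area),
        perimeter=float(perim),
        circularity=float(circ),
        roundness=float(roundness),
        major_axis=float(major),
        reliable=bool(reliable),
    )


def perinuclear_region(
    centroid: tuple[float, float],
    centerline: np.ndarray,
    tube_mask: np.ndarray,
    pixel_size: float,
    half_length: float = 50.0,
    max_centroid_distance: float = 25.0,
) -> np.ndarray:
    """Myotube pixels within ±``half_length`` µm arc length of a nucleus.

    ``centroid`` and ``centerline`` are in µm (x, y); the band is cut from
    ``tube_mask`` by projecting every tube pixel to its arc-length position
    along the centerline.  A nucleus farther than ``max_centroid_distance``
    from the centerline raises, since its band would be meaningless.
    """
    centerline = np.asarray(centerline, dtype=float)
    s0, d0 = project_to_polyline(np.array([centroid], dtype=float), centerline)
    if d0[0] > max_centroid_distance:
        raise ValueError(
            f"nucleus {d0[0]:.1f} µm from the centerline (limit {max_centroid_distance} µm)"
        )
    mask = np.asarray(tube_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.zeros_like(mask)
    pts = np.column_stack([cols, rows]).astype(float) * pixel_size
    s, _ = project_to_polyline(pts, centerline)
    keep = np.abs(s - s0[0]) <= half_length
    region = np.zeros_like(mask)
    region[rows[keep], cols[keep]] = True
    if half_length == 0 or not region.any():
        warnings.warn("degenerate perinuclear band (zero nominal length)", stacklevel=2)
    return region


def count_spots(
    fish_mask: np.ndarray,
    region_mask: np.ndarray,
    normalizer: float,
    min_area: int = 1,
    max_area: int | None = None,
    region_id: int = 0,
) -> SpotCountRecord:
    """Count binarized smFISH spots whose centroid lies inside the region.

    Spots are 8-connected components of ``fish_mask`` with pixel area in
    ``[min_area, max_area]``; membership of boundary-straddling spots is
    decided by the centroid (counted once, in the region holding the
    centroid).  ``density = count / normalizer`` with the caller-supplied
    normalizing area (myonucleus area or myotube-region area, per probe).
    """
    if fish_mask.shape != region_mask.shape:
        raise ValueError("masks must have the same shape")
    if normalizer <= 0:
        raise ValueError("normalizer area must be > 0")
    labels = measure.label(fish_mask, connectivity=2)
    region = np.asarray(region_mask, dtype=bool)
    count = 0
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        if max_area is not None and rp.area > max_area:
            continue
        cy, cx = rp.centroid
        r, c = int(round(cy)), int(round(cx))
        if 0 <= r < region.shape[0] and 0 <= c < region.shape[1] and region[r, c]:
            count += 1
    return SpotCountRecord(
        region_id=region_id,
        spot_count=count,
        normalizer=float(normalizer),
        density=count / float(normalizer),
    )
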