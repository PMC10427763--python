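"""Structural maturation metrics from α-actinin and DAPI channels.

The α-actinin mask gives the myotube footprint: its proportional area, the
length of its medial-axis skeleton, and the average width as total area
divided by skeleton length.  DAPI components overlapping the actinin mask
are myonuclei; their count normalizes to a density per mm², and per-tube
nucleus positions projected onto the centerline give the mean neighbour
spacing and its coefficient of variation (spacing uniformity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure, morphology, restoration

__all__ = [
    "SegmentedScene",
    "MorphometryResult",
    "NucleusRecord",
    "preprocess",
    "width_metrics",
    "assign_myonuclei",
    "nuclei_spacing",
    "skeleton_length",
    "skeleton_centerline",
    "project_to_polyline",
]


@dataclass
class SegmentedScene:
    """Binarized channels of one field of view plus calibration/provenance."""

    actinin_mask: np.ndarray
    dapi_mask: np.ndarray
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.actinin_mask.shape != self.dapi_mask.shape:
            raise ValueError("masks must have the same shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class NucleusRecord:
    label: int
    centroid: tuple[float, float]  # (x, y) px
    area_px: int
    is_myonucleus: bool
    actinin_overlap: float  # overlapping fraction of the nucleus area


@dataclass
class MorphometryResult:
    proportional_area: float
    skeleton_length: float  # µm
    average_width: float  # µm
    myonuclei_count: int
    myonuclei_density: float  # per mm²
    spacing_mean: float | None = None  # µm
    spacing_cov: float | None = None


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    raw: np.ndarray,
    background_radius: float = 50,
    min_area: int = 64,
) -> np.ndarray:
    """Binarize a fluorescence channel.

    Max-projects 3D stacks, removes slowly varying background with a
    rolling-ball filter, thresholds with Otsu's method and drops objects
    smaller than ``min_area`` px.  An empty or constant channel yields an
    empty mask with a warning.
    """
    img = np.asarray(raw, dtype=float)
    if img.ndim == 3:
        img = img.max(axis=0)
    if img.ndim != 2:
        raise ValueError("expected a 2D image or a 3D stack")
    if img.max() == img.min():
        warnings.warn("constant image; returning an empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    if background_radius and background_radius > 0:
        img = img - restoration.rolling_ball(img, radius=background_radius)
    th = filters.threshold_otsu(img)
    # refine to the midpoint of the induced class means: identical for
    # well-behaved histograms, but keeps the threshold out of a background
    # cluster that collapses into a single histogram bin
    for _ in range(8):
        lo, hi = img[img <= th], img[img > th]
        if lo.size == 0 or hi.size == 0:
            break
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - th) <= 1e-9 * max(1.0, abs(th)):
            break
        th = new
    mask = img > th
    # drop objects below the minimum area (the new skimage parameter removes
    # components of size <= max_size)
    return morphology.remove_small_objects(mask, max_size=int(min_area) - 1)


# ---------------------------------------------------------------------------
# skeleton / width


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    kernel = np.ones((3, 3))
    return ndimage.convolve(skel.astype(int), kernel, mode="constant") - skel


def _prune_endpoints(skel: np.ndarray, iterations: int) -> np.ndarray:
    """Iteratively shave endpoint pixels (degree ≤ 1 in 8-connectivity)."""
    out = skel.copy()
    for _ in range(iterations):
        endpoints = out & (_neighbour_counts(out) <= 1)
        if not endpoints.any():
            break
        out = out & ~endpoints
    return out


def _prune_spurs(skel: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Remove terminal skeleton branches shorter than the local object width.

    A terminal branch runs from an endpoint to the nearest junction (degree
    ≥ 3) pixel; if its chain length is below twice the distance-transform
    radius at the junction it is a digitization spur, not a real centerline
    segment, and is removed.  Branches of junction-free skeletons (simple
    paths) are never pruned.
    """
    out = skel.copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbour_counts(out)
        coords = np.argwhere(out & (counts == 1))
        for r0, c0 in coords:
            if not out[r0, c0]:
                continue
            branch = [(r0, c0)]
            prev = None
            cur = (r0, c0)
            junction = None
            while True:
                nbrs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if not (dr == 0 and dc == 0)
                    and 0 <= cur[0] + dr < out.shape[0]
                    and 0 <= cur[1] + dc < out.shape[1]
                    and out[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if counts[nxt] >= 3:
                    junction = nxt
                    break
                branch.append(nxt)
                prev, cur = cur, nxt
            if junction is None:
                continue  # simple path (or loop); keep
            length = sum(
                np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(branch, branch[1:])
            ) + np.hypot(branch[-1][0] - junction[0], branch[-1][1] - junction[1])
            if length < 2.0 * dist[junction]:
                for r, c in branch:
                    out[r, c] = False
                changed = True
    return out


def skeleton_length(skel: np.ndarray, pixel_size: float = 1.0) -> float:
    """Chain length of a skeleton: 1 per 4-connected step, √2 per diagonal."""
    s = skel.astype(bool)
    straight = (s[:, :-1] & s[:, 1:]).sum() + (s[:-1, :] & s[1:, :]).sum()
    diag = (s[:-1, :-1] & s[1:, 1:]).sum() + (s[:-1, 1:] & s[1:, :-1]).sum()
    # a diagonal adjacency bridged by a 4-connected corner is a shortcut, not a step
    corner = ((s[:-1, :-1] & s[1:, 1:]) & (s[:-1, 1:] | s[1:, :-1])).sum()
    corner += ((s[:-1, 1:] & s[1:, :-1]) & (s[:-1, :-1] | s[1:, 1:])).sum()
    diag = max(diag - corner, 0)
    return float(straight + np.sqrt(2.0) * diag) * pixel_size


def width_metrics(
    actinin_mask: np.ndarray, pixel_size: float, prune: bool = True
) -> tuple[float, float, float]:
    """(proportional_area, skeleton_length µm, average_width µm) of a mask.

    The average width is the total foreground area divided by the length of
    the pruned centerline skeleton — the standard area/centerline estimator
    for ribbon-like objects.  Terminal spurs shorter than the local width
    are pruned so corner artifacts do not inflate the length, and the chain
    length is extended by the local radius at each endpoint (the skeleton of
    a ribbon stops half a width short of each end).
    """
    from scipy import ndimage

    mask = np.asarray(actinin_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    proportional_area = float(mask.sum()) / mask.size
    skel = morphology.skeletonize(mask)
    dist = ndimage.distance_transform_edt(mask)
    if prune:
        pruned = _prune_spurs(skel, dist)
        if pruned.any():
            skel = pruned
    length_px = skeleton_length(skel, 1.0)
    endpoints = skel & (_neighbour_counts(skel) <= 1)
    length_px += float(dist[endpoints].sum())
    length_um = length_px * pixel_size
    area_um2 = float(mask.sum()) * pixel_size**2
    if length_um == 0:
        raise ValueError("skeleton length is zero; mask too small to measure width")
    return proportional_area, length_um, area_um2 / length_um


# ---------------------------------------------------------------------------
# myonuclei


def assign_myonuclei(
    dapi_mask: np.ndarray,
    actinin_mask: np.ndarray,
    pixel_size: float,
    min_overlap: float = 0.5,
    min_area: int = 9,
) -> tuple[list[NucleusRecord], float]:
    """Designate DAPI components inside the actinin footprint as myonuclei.

    A nucleus is a myonucleus when at least ``min_overlap`` of its area lies
    on the actinin mask (boundary inclusive).  Returns per-nucleus records
    and the myonuclei density per mm² of image area.
    """
    if dapi_mask.shape != actinin_mask.shape:
        raise ValueError("masks must have the same shape")
    labels = measure.label(dapi_mask, connectivity=2)
    records: list[NucleusRecord] = []
    actinin = np.asarray(actinin_mask, dtype=bool)
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        sl = rp.slice
        overlap = float(np.logical_and(rp.image, actinin[sl]).sum()) / rp.area
        cy, cx = rp.centroid
        records.append(
            NucleusRecord(
                label=rp.label,
                centroid=(float(cx), float(cy)),
                area_px=int(rp.area),
                is_myonucleus=overlap >= min_overlap,
                actinin_overlap=overlap,
            )
        )
    n_myo = sum(r.is_myonucleus for r in records)
    area_mm2 = dapi_mask.size * (pixel_size**2) * 1e-6
    return records, n_myo / area_mm2


# ---------------------------------------------------------------------------
# spacing


def project_to_polyline(
    points: np.ndarray, polyline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length position and distance of each point relative to a polyline.

    Returns ``(s, d)`` where ``s`` is the arc length (same units as the
    coordinates) of the nearest point on the polyline and ``d`` the
    perpendicular distance to it.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or len(poly) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    if np.any(seg_len == 0):
        keep = seg_len > 0
        seg_vec = seg_vec[keep]
        poly = np.concatenate([poly[:1], poly[1:][keep]])
        seg_len = seg_len[keep]
    s_start = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    best_d = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    for (x0, y0), (dx, dy), L, s0 in zip(poly[:-1], seg_vec, seg_len, s_start):
        ux, uy = dx / L, dy / L
        proj = np.clip((pts[:, 0] - x0) * ux + (pts[:, 1] - y0) * uy, 0.0, L)
        d = np.hypot(pts[:, 0] - (x0 + proj * ux), pts[:, 1] - (y0 + proj * uy))
        closer = d < best_d
        best_d[closer] = d[closer]
        best_s[closer] = s0 + proj[closer]
    return best_s, best_d


def nuclei_spacing(
    centroids: np.ndarray,
    centerline: np.ndarray | None = None,
    method: str = "arc",
    ddof: int = 0,
) -> tuple[float, float]:
    """Mean neighbour distance and its coefficient of variation for one tube.

    With ``method='arc'`` (default) centroids are projected to their
    arc-length position along the tube centerline and neighbour distances
    are consecutive arc-length gaps after sorting; ``method='euclidean'``
    uses straight-line distances between consecutively sorted centroids.
    The CoV uses the population SD (``ddof=0``) by default.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least 2 centroids to measure spacing")
    if method == "arc":
        if centerline is None:
            raise ValueError("arc-length spacing requires a centerline")
        s, _ = project_to_polyline(pts, centerline)
        order = np.argsort(s)
        gaps = np.diff(s[order])
    elif method == "euclidean":
        if centerline is not None:
            s, _ = project_to_polyline(pts, centerline)
            order = np.argsort(s)
        else:
            order = np.argsort(pts[:, 0])
        sorted_pts = pts[order]
        gaps = np.linalg.norm(np.diff(sorted_pts, axis=0), axis=1)
    else:
        raise ValueError("method must be 'arc' or 'euclidean'")
    mean = float(gaps.mean())
    if mean == 0:
        raise ValueError("zero mean neighbour distance; CoV undefined")
    return mean, float(gaps.std(ddof=ddof)) / mean


# ---------------------------------------------------------------------------
# centerline extraction


def skeleton_centerline(mask: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Ordered (x, y) centerline of a ribbon-like mask, in physical units.

    Prunes the medial axis, then walks the longest path between skeleton
    endpoints.  Intended for simple (unbranched after pruning) tubes.
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    skel = morphology.skeletonize(mask)
    if not skel.any():
        raise ValueError("empty skeleton")
    dist = ndimage.distance_transform_edt(mask)
    pruned = _prune_spurs(skel, dist)
    if not pruned.any():
        pruned = skel
    coords = np.argwhere(pruned)  # (row, col)
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)
    ends = [i for i, n in enumerate(nbrs) if len(n) <= 1]
    start = ends[0] if ends else 0

    def bfs_farthest(src: int):
        prev = {src: None}
        queue = [src]
        last = src
        while queue:
            nxt = []
            for node in queue:
                for j in nbrs[node]:
                    if j not in prev:
                        prev[j] = node
                        nxt.append(j)
                        last = j
            queue = nxt
        return last, prev

    far, _ = bfs_farthest(start)
    end, prev = bfs_farthest(far)
    path = []
    node: int | None = end
    while node is not None:
        path.append(node)
        node = prev[node]
    rc = coords[path[::-1]]
    return np.column_stack([rc[:, 1], rc[:, 0]]).astype(float) * pixel_size


def measure_scene(scene: SegmentedScene) -> MorphometryResult:
    """All morphometry metrics of one segmented field of view."""
    prop, skel_len, width = width_metrics(scene.actinin_mask, scene.pixel_size)
    records, density = assign_myonuclei(
        scene.dapi_mask, scene.actinin_mask, scene.pixel_size
    )
    myo = [r for r in records if r.is_myonucleus]
    spacing_mean = spacing_cov = None
    if len(myo) >= 2:
        try:
            centerline = skeleton_centerline(scene.actinin_mask, scene.pixel_size)
            pts = np.array([r.centroid for r in myo]) * scene.pixel_size
            spacing_mean, spacing_cov = nuclei_spacing(pts, centerline)
        except ValueError:
            pass
    return MorphometryResult(
        proportional_area=prop,
        skeleton_length=skel_len,
        average_width=width,
        myonuclei_count=len(myo),
        myonuclei_density=density,
        spacing_mean=spacing_mean,
        spacing_cov=spacing_cov,
    )
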