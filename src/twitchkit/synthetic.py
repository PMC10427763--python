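"""Synthetic fixtures with exact ground truth.

Everything the measurement modules consume can be generated here: contracting
textured-tube movies, displacement traces with known twitch timing, 4-channel
maturation images (α-actinin / DAPI / BTX / smFISH) with known geometry, and
qPCR Ct tables with known fold changes.  All randomness flows through one
``numpy.random.Generator`` seeded explicitly, so identical seeds give
bit-identical outputs.

The movies use a per-tube fixed random speckle texture (so windowed
cross-correlation has structure to lock onto) translated rigidly along the
tube axis by the waveform's instantaneous displacement; rigid motion keeps
the ground-truth trace of every nucleus exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .piv import DisplacementTrace, MovieStack

__all__ = [
    "WaveformSpec",
    "TubeSpec",
    "NucleusSpec",
    "PunctumSpec",
    "SceneSpec",
    "TwitchGroundTruth",
    "generate_trace",
    "generate_movie",
    "generate_morphology_image",
    "generate_ct_table",
    "make_tube_scene",
    "speckle",
    "write_movie",
    "write_scene",
]

WAVEFORM_KINDS = ("sine", "asymmetric_twitch", "flat", "fatigue_decay")


# ---------------------------------------------------------------------------
# waveforms


@dataclass(frozen=True)
class WaveformSpec:
    """Stimulation/contraction waveform of a paced myotube.

    The displacement is a rectified periodic wave: within each period the
    tube moves away from rest and back, rising for ``acceleration_fraction``
    of the period and relaxing for the remainder.  ``fatigue_decay``
    multiplies the amplitude by ``exp(-t / decay_time)``, emulating fatigue
    under continuous stimulation.  ``onset`` seconds of quiescence (noise
    only) precede the first twitch, providing the pre-stimulation baseline
    the fatigue analysis requires.
    """

    kind: str = "sine"
    frequency: float = 5.0  # Hz
    amplitude: float = 1.0  # µm peak displacement
    acceleration_fraction: float = 0.5
    decay_time: float = math.inf  # s; e-folding of the fatigue envelope
    noise_sd: float = 0.0  # µm
    duration: float = 2.0  # s
    sample_interval: float = 0.02  # s (20 ms/frame acquisition)
    onset: float = 0.0  # s of pre-stimulation baseline

    def __post_init__(self) -> None:
        if self.kind not in WAVEFORM_KINDS:
            raise ValueError(f"kind must be one of {WAVEFORM_KINDS}")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.kind != "flat":
            if self.frequency * self.sample_interval >= 0.5:
                raise ValueError(
                    "frequency * sample_interval must be < 0.5 (Nyquist)"
                )
            if not 0.0 < self.acceleration_fraction < 1.0:
                raise ValueError("acceleration_fraction must be in (0, 1)")
        if self.decay_time <= 0:
            raise ValueError("decay_time must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.sample_interval))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval

    def envelope(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "fatigue_decay" and math.isfinite(self.decay_time):
            return np.exp(-np.maximum(t - self.onset, 0.0) / self.decay_time)
        return np.ones_like(np.asarray(t, dtype=float))

    def clean_values(self, t: np.ndarray) -> np.ndarray:
        """Noise-free waveform displacement (µm) at times ``t``."""
        t = np.asarray(t, dtype=float)
        if self.kind == "flat" or self.amplitude == 0:
            return np.zeros_like(t)
        af = 0.5 if self.kind in ("sine", "fatigue_decay") else self.acceleration_fraction
        ts = t - self.onset
        phase = np.mod(ts * self.frequency, 1.0)
        rising = phase < af
        y = np.empty_like(t)
        y[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / af))
        y[~rising] = 0.5 * (1.0 + np.cos(np.pi * (phase[~rising] - af) / (1.0 - af)))
        y[ts < 0] = 0.0
        return self.amplitude * self.envelope(t) * y


@dataclass(frozen=True)
class TwitchGroundTruth:
    """True timing of one contraction cycle of a generated waveform."""

    start_time: float
    peak_time: float
    end_time: float
    amplitude: float
    acceleration_time: float
    relaxation_time: float


def _ground_truth_events(spec: WaveformSpec) -> list[TwitchGroundTruth]:
    if spec.kind == "flat" or spec.amplitude == 0:
        return []
    af = 0.5 if spec.kind in ("sine", "fatigue_decay") else spec.acceleration_fraction
    period = 1.0 / spec.frequency
    events = []
    k = 0
    while spec.onset + (k + 1) * period <= spec.duration + 1e-12:
        start = spec.onset + k * period
        peak = start + af * period
        end = start + period
        amp = float(spec.amplitude * spec.envelope(np.array([peak]))[0])
        events.append(
            TwitchGroundTruth(
                start_time=start,
                peak_time=peak,
                end_time=end,
                amplitude=amp,
                acceleration_time=af * period,
                relaxation_time=(1.0 - af) * period,
            )
        )
        k += 1
    return events


def generate_trace(
    spec: WaveformSpec, seed: int
) -> tuple[DisplacementTrace, list[TwitchGroundTruth]]:
    """Sample a displacement trace and return it with its true twitch list."""
    rng = np.random.default_rng(seed)
    t = spec.times()
    y = spec.clean_values(t)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    vel = np.abs(np.diff(y)) / spec.sample_interval
    trace = DisplacementTrace(
        times=t, displacement=y, velocity=vel, source=f"synthetic:{spec.kind}"
    )
    return trace, _ground_truth_events(spec)


# ---------------------------------------------------------------------------
# scene geometry


@dataclass(frozen=True)
class TubeSpec:
    """One myotube: a centerline polyline (µm, (x, y) vertices) and a width (µm)."""

    centerline: tuple[tuple[float, float], ...]
    width: float


@dataclass(frozen=True)
class NucleusSpec:
    center: tuple[float, float]  # µm
    radius: float  # µm
    tube: int | None = None  # parent tube index
    high_btx: bool = False  # AChR-positive nucleus


@dataclass(frozen=True)
class PunctumSpec:
    center: tuple[float, float]  # µm
    radius: float  # µm
    intensity: float = 150.0


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one field of view, all coordinates in µm.

    ``btx_background`` is the mean BTX intensity of an ordinary nucleus;
    AChR-positive nuclei are rendered at ``btx_high_multiple`` times that
    level, giving the two-component intensity design the BTX classifier is
    meant to resolve.
    """

    image_size: tuple[int, int]  # (height, width) px
    pixel_size: float  # µm/px
    tubes: tuple[TubeSpec, ...] = ()
    nuclei: tuple[NucleusSpec, ...] = ()
    puncta: tuple[PunctumSpec, ...] = ()
    background_level: float = 10.0
    noise_sd: float = 0.0
    btx_background: float = 100.0
    btx_high_multiple: float = 3.0
    texture_grain: float = 3.0  # px; speckle autocorrelation scale
    foreground_level: float = 150.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size too small")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        ext_x = w * self.pixel_size
        ext_y = h * self.pixel_size
        for tube in self.tubes:
            if tube.width <= 0:
                raise ValueError("tube width must be > 0")
            for x, y in tube.centerline:
                if not (0 <= x <= ext_x and 0 <= y <= ext_y):
                    raise ValueError("tube centerline outside image bounds")
        for nuc in self.nuclei:
            if nuc.radius <= 0:
                raise ValueError("nucleus radius must be > 0")
            x, y = nuc.center
            if not (0 <= x <= ext_x and 0 <= y <= ext_y):
                raise ValueError("nucleus outside image bounds")
        for p in self.puncta:
            if p.radius <= 0:
                raise ValueError("punctum radius must be > 0")
        # nuclei sharing a tube must be unambiguously separable
        by_tube: dict[int, list[NucleusSpec]] = {}
        for nuc in self.nuclei:
            if nuc.tube is not None:
                by_tube.setdefault(nuc.tube, []).append(nuc)
        for members in by_tube.values():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    min_sep = a.radius + b.radius + 2 * self.pixel_size
                    d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                    if d < min_sep:
                        raise ValueError(
                            f"nuclei closer than the minimum separation {min_sep:.3g} µm"
                        )

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        return self.image_size[1] * self.pixel_size, self.image_size[0] * self.pixel_size


def _pixel_coords_um(scene: SceneSpec):
    h, w = scene.image_size
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    return xs * scene.pixel_size, ys * scene.pixel_size


def _polyline_distance(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance of each point (px, py) to a polyline (vectorized over segments)."""
    best = np.full(px.shape, np.inf)
    for (x0, y0), (x1, y1) in zip(poly[:-1], poly[1:]):
        dx, dy = x1 - x0, y1 - y0
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            d = np.hypot(px - x0, py - y0)
        else:
            t = np.clip(((px - x0) * dx + (py - y0) * dy) / seg2, 0.0, 1.0)
            d = np.hypot(px - (x0 + t * dx), py - (y0 + t * dy))
        np.minimum(best, d, out=best)
    return best


def tube_mask(scene: SceneSpec, tube: TubeSpec) -> np.ndarray:
    """Boolean ribbon mask of one tube (pixels within width/2 of the centerline)."""
    px, py = _pixel_coords_um(scene)
    poly = np.asarray(tube.centerline, dtype=float)
    return _polyline_distance(px, py, poly) <= tube.width / 2.0


def _disk_mask(scene: SceneSpec, center: tuple[float, float], radius: float) -> np.ndarray:
    px, py = _pixel_coords_um(scene)
    return np.hypot(px - center[0], py - center[1]) <= radius


def speckle(shape: tuple[int, int], rng: np.random.Generator, grain: float = 3.0) -> np.ndarray:
    """Smoothed uniform random speckle in [0, 1] with the given grain size (px)."""
    raw = rng.uniform(0.0, 1.0, size=shape)
    tex = ndimage.gaussian_filter(raw, sigma=grain / 2.0, mode="wrap")
    lo, hi = tex.min(), tex.max()
    if hi > lo:
        tex = (tex - lo) / (hi - lo)
    return tex


# ---------------------------------------------------------------------------
# movie generation


def generate_movie(
    spec: WaveformSpec, scene: SceneSpec, seed: int
) -> tuple[MovieStack, dict[int, DisplacementTrace]]:
    """Render a contracting-tube movie and the exact trace of every nucleus.

    Each tube is a speckle-textured ribbon translated rigidly along its mean
    axis by the waveform's instantaneous displacement; frames are sampled
    from the static texture at subpixel offsets with bilinear interpolation.
    The returned ground truth maps nucleus index to its exact
    displacement-magnitude trace (identical to the waveform, since motion is
    rigid).
    """
    if not scene.tubes or not any(n.tube is not None for n in scene.nuclei):
        raise ValueError("scene must contain at least one tube with one nucleus")
    rng = np.random.default_rng(seed)
    h, w = scene.image_size
    t = spec.times()
    disp_um = spec.clean_values(t)

    # static reference image: background + textured ribbons
    base = np.full((h, w), scene.background_level, dtype=float)
    masks, axes = [], []
    for tube in scene.tubes:
        m = tube_mask(scene, tube)
        tex = speckle((h, w), rng, scene.texture_grain)
        base = np.where(m, scene.background_level + scene.foreground_level * tex, base)
        poly = np.asarray(tube.centerline, dtype=float)
        axis = poly[-1] - poly[0]
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("degenerate tube centerline")
        masks.append(m)
        axes.append(axis / norm)

    # margin check: the displaced ribbon must stay inside the frame
    max_disp_px = float(np.max(np.abs(disp_um))) / scene.pixel_size
    fg = np.logical_or.reduce(masks)
    rows = np.any(fg, axis=1)
    cols = np.any(fg, axis=0)
    margins = (
        np.argmax(cols),
        w - 1 - (len(cols) - 1 - np.argmax(cols[::-1])),
        np.argmax(rows),
        h - 1 - (len(rows) - 1 - np.argmax(rows[::-1])),
    )
    if max_disp_px > min(margins) + 0.5:
        raise ValueError(
            f"peak displacement {max_disp_px:.1f} px exceeds the image margin {min(margins)} px"
        )

    # all tubes share the waveform; a single-tube axis sets the direction
    axis = axes[0]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((len(t), h, w), dtype=float)
    for i, d_um in enumerate(disp_um):
        d_px = d_um / scene.pixel_size
        # content moved by +d ⇒ sample the reference at x − d
        frames[i] = ndimage.map_coordinates(
            base, [yy - d_px * axis[1], xx - d_px * axis[0]], order=1, mode="nearest"
        )
    if scene.noise_sd > 0:
        frames += rng.normal(0.0, scene.noise_sd, size=frames.shape)

    stack = MovieStack(
        frames=frames, pixel_size=scene.pixel_size, frame_interval=spec.sample_interval
    )
    vel = np.abs(np.diff(disp_um)) / spec.sample_interval
    truth = {
        i: DisplacementTrace(
            times=t.copy(),
            displacement=np.abs(disp_um),
            velocity=vel.copy(),
            source=f"nucleus:{i}",
        )
        for i, nuc in enumerate(scene.nuclei)
        if nuc.tube is not None
    }
    return stack, truth


# ---------------------------------------------------------------------------
# morphology images


def generate_morphology_image(scene: SceneSpec, seed: int) -> tuple[dict, dict]:
    """Render the 4 maturation channels and every ground-truth quantity.

    Returns ``(channels, truth)`` where ``channels`` maps
    ``actinin|dapi|btx|fish`` to 2D float images and ``truth`` records the
    planted geometry: per-tube width and centerline, nucleus centers/radii/
    tube assignments, the BTX class of each nucleus and the high proportion,
    and punctum centers.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.image_size
    bg = scene.background_level

    tube_masks = [tube_mask(scene, t) for t in scene.tubes]
    actinin = np.full((h, w), bg, dtype=float)
    for m in tube_masks:
        actinin[m] = bg + scene.foreground_level

    dapi = np.full((h, w), bg, dtype=float)
    btx = np.full((h, w), bg, dtype=float)
    n_high = 0
    for nuc in scene.nuclei:
        m = _disk_mask(scene, nuc.center, nuc.radius)
        dapi[m] = bg + scene.foreground_level
        level = scene.btx_background * (scene.btx_high_multiple if nuc.high_btx else 1.0)
        btx[m] = level
        n_high += bool(nuc.high_btx)

    fish = np.full((h, w), bg, dtype=float)
    for p in scene.puncta:
        m = _disk_mask(scene, p.center, p.radius)
        fish[m] = bg + p.intensity

    channels = {"actinin": actinin, "dapi": dapi, "btx": btx, "fish": fish}
    if scene.noise_sd > 0:
        for key in channels:
            channels[key] = channels[key] + rng.normal(0.0, scene.noise_sd, size=(h, w))

    truth = {
        "tubes": [
            {
                "centerline_um": [list(pt) for pt in t.centerline],
                "width_um": t.width,
                "mask_area_um2": float(m.sum()) * scene.pixel_size**2,
            }
            for t, m in zip(scene.tubes, tube_masks)
        ],
        "nuclei": [
            {
                "center_um": list(n.center),
                "radius_um": n.radius,
                "tube": n.tube,
                "high_btx": bool(n.high_btx),
            }
            for n in scene.nuclei
        ],
        "puncta": [{"center_um": list(p.center), "radius_um": p.radius} for p in scene.puncta],
        "high_btx_proportion": (n_high / len(scene.nuclei)) if scene.nuclei else float("nan"),
        "n_myonuclei": sum(1 for n in scene.nuclei if n.tube is not None),
    }
    return channels, truth


def make_tube_scene(
    image_size: tuple[int, int] = (128, 256),
    pixel_size: float = 0.25,
    width_um: float = 15.0,
    n_nuclei: int = 3,
    margin_um: float = 12.0,
    high_btx_every: int | None = None,
    n_puncta: int = 0,
    puncta_seed: int = 0,
    noise_sd: float = 0.0,
    **kwargs,
) -> SceneSpec:
    """One straight horizontal tube spanning the field, nuclei equally spaced.

    Convenience builder used throughout the tests and the acceptance runs;
    ``high_btx_every`` flags every k-th nucleus as AChR-positive, and
    ``n_puncta`` scatters non-touching smFISH puncta inside the tube.
    """
    h, w = image_size
    ext_x, ext_y = w * pixel_size, h * pixel_size
    y_mid = ext_y / 2.0
    x0, x1 = margin_um, ext_x - margin_um
    centerline = ((x0, y_mid), (x1, y_mid))
    tube = TubeSpec(centerline=centerline, width=width_um)
    nuclei = []
    if n_nuclei == 1:
        xs = np.array([(x0 + x1) / 2.0])
    elif n_nuclei > 1:
        xs = np.linspace(x0 + 10.0, x1 - 10.0, n_nuclei)
    else:
        xs = np.array([])
    if n_nuclei > 0:
        for i, x in enumerate(xs):
            high = high_btx_every is not None and i % high_btx_every == 0
            nuclei.append(NucleusSpec(center=(float(x), y_mid), radius=2.5, tube=0, high_btx=high))
    puncta = []
    if n_puncta > 0:
        rng = np.random.default_rng(puncta_seed)
        placed: list[tuple[float, float]] = []
        r = 0.5  # µm
        min_sep = 2 * r + 3 * pixel_size  # keep components disjoint after rendering
        tries = 0
        while len(placed) < n_puncta and tries < 100000:
            tries += 1
            x = rng.uniform(x0 + 2, x1 - 2)
            y = rng.uniform(y_mid - width_um / 2 + 1.5, y_mid + width_um / 2 - 1.5)
            if all(math.hypot(x - a, y - b) >= min_sep for a, b in placed):
                placed.append((x, y))
        if len(placed) < n_puncta:
            raise ValueError("could not place the requested number of puncta")
        puncta = [PunctumSpec(center=c, radius=r) for c in placed]
    return SceneSpec(
        image_size=image_size,
        pixel_size=pixel_size,
        tubes=(tube,),
        nuclei=tuple(nuclei),
        puncta=tuple(puncta),
        noise_sd=noise_sd,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# qPCR tables


def generate_ct_table(
    effects: dict[str, float],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    housekeeping: str = "HPRT",
    base_ct: float = 25.0,
    housekeeping_ct: float = 20.0,
) -> "pd.DataFrame":
    """Ct table for control/treated groups with a housekeeping gene.

    ``effects`` maps gene name to the true log2 fold change of the treated
    group; Ct values are built so that the expected 2^−ΔΔCt equals
    ``2**effect`` (lower Ct = more transcript).
    """
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("control", "treated"):
        for rep in range(n_replicates):
            sample = f"{group}_{rep + 1}"
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": housekeeping,
                    "ct": housekeeping_ct + rng.normal(0, noise_sd) if noise_sd else housekeeping_ct,
                }
            )
            for gene, log2fc in effects.items():
                ct = base_ct - (log2fc if group == "treated" else 0.0)
                if noise_sd:
                    ct += rng.normal(0, noise_sd)
                rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def write_movie(path: str | Path, stack: MovieStack, truth: dict | None = None) -> None:
    """Write a movie as multi-page TIFF with a JSON calibration sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {"pixel_size_um": stack.pixel_size, "frame_interval_s": stack.frame_interval}
    if truth is not None:
        meta["ground_truth"] = {
            str(k): {"times_s": v.times.tolist(), "displacement_um": v.displacement.tolist()}
            for k, v in truth.items()
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def write_scene(path: str | Path, channels: dict, truth: dict, pixel_size: float) -> None:
    """Write channels as one multi-channel TIFF plus a JSON geometry sidecar."""
    import tifffile

    path = Path(path)
    order = ["actinin", "dapi", "btx", "fish"]
    stack = np.stack([channels[k] for k in order if k in channels]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {"pixel_size_um": pixel_size, "channels": [k for k in order if k in channels]}
    meta["ground_truth"] = truth
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
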