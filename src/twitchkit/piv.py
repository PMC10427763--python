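"""Particle image velocimetry on time-lapse movies of contracting myotubes.

The displacement field between two frames is estimated by windowed FFT
cross-correlation with multipass window deformation: a coarse pass (64 px
interrogation windows by default) predicts the field, the image of the second
frame is warped by the interpolated prediction, and a finer pass (32 px)
measures the residual.  Each vector gets a 3-point Gaussian subpixel fit and
is validated with the normalized median test; invalid vectors are replaced by
the mean of their valid neighbours and flagged.

A nucleus (or any reference point) is tracked through the sequence of fields
by Lagrangian integration, yielding a displacement/velocity trace in physical
units — the raw input of the twitch-kinetics analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

__all__ = [
    "MovieStack",
    "PivConfig",
    "VectorField",
    "DisplacementTrace",
    "correlate_pair",
    "movie_to_fields",
    "track_point",
    "analyze_movie",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class MovieStack:
    """Calibrated grayscale frame sequence.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Grayscale intensities; converted to float64.
    pixel_size : float
        Physical size of one pixel in µm.
    frame_interval : float
        Time between consecutive frames in s.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class PivConfig:
    """PIV engine parameters.

    ``pass_windows`` are the interrogation window sizes of the successive
    passes (decreasing powers of two); the defaults reproduce the two-phase
    64 → 32 px scheme used for the contractility assay.
    """

    pass_windows: tuple[int, ...] = (64, 32)
    overlap_fraction: float = 0.5
    subpixel: str = "gauss3"
    validation_threshold: float = 2.0
    validation_eps: float = 0.1
    max_displacement: float | None = None

    def __post_init__(self) -> None:
        ws = tuple(int(w) for w in self.pass_windows)
        if not ws:
            raise ValueError("pass_windows must not be empty")
        for w in ws:
            if w < 4 or (w & (w - 1)) != 0:
                raise ValueError(f"window size {w} is not a power of two >= 4")
        if any(b >= a for a, b in zip(ws, ws[1:])):
            raise ValueError("pass_windows must be strictly decreasing")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subpixel != "gauss3":
            raise ValueError("only the 'gauss3' subpixel estimator is available")
        object.__setattr__(self, "pass_windows", ws)


@dataclass
class VectorField:
    """Displacement field for one frame pair on a regular window grid.

    Coordinates are 0-based pixel coordinates, origin at the top-left corner,
    x increasing rightwards (columns) and y downwards (rows); u and v are the
    per-frame displacement components along x and y in px/frame.
    """

    x: np.ndarray  # (nx,) window-center x coordinates
    y: np.ndarray  # (ny,) window-center y coordinates
    u: np.ndarray  # (ny, nx)
    v: np.ndarray  # (ny, nx)
    valid: np.ndarray  # (ny, nx) bool; False where correlation failed validation
    replaced: np.ndarray  # (ny, nx) bool; True where interpolated from neighbours

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def interpolate(self, point: tuple[float, float]) -> tuple[float, float]:
        """Bilinear interpolation of (u, v) at a pixel coordinate ``(x, y)``.

        The point must lie inside the grid hull; raises ``ValueError``
        otherwise.
        """
        px, py = float(point[0]), float(point[1])
        if not (self.x[0] <= px <= self.x[-1] and self.y[0] <= py <= self.y[-1]):
            raise ValueError("point outside the vector-field grid hull")
        ix = min(int(np.searchsorted(self.x, px, side="right")) - 1, len(self.x) - 2)
        iy = min(int(np.searchsorted(self.y, py, side="right")) - 1, len(self.y) - 2)
        ix = max(ix, 0)
        iy = max(iy, 0)
        tx = (px - self.x[ix]) / (self.x[ix + 1] - self.x[ix])
        ty = (py - self.y[iy]) / (self.y[iy + 1] - self.y[iy])
        out = []
        for comp in (self.u, self.v):
            c00 = comp[iy, ix]
            c01 = comp[iy, ix + 1]
            c10 = comp[iy + 1, ix]
            c11 = comp[iy + 1, ix + 1]
            out.append(
                (1 - ty) * ((1 - tx) * c00 + tx * c01)
                + ty * ((1 - tx) * c10 + tx * c11)
            )
        return float(out[0]), float(out[1])


@dataclass
class DisplacementTrace:
    """Time series of a tracked reference point.

    ``displacement`` is the distance (µm) of the point from its initial
    position; ``velocity`` holds the per-interval instantaneous speed in µm/s
    (one element fewer than ``times``).
    """

    times: np.ndarray
    displacement: np.ndarray
    velocity: np.ndarray
    source: str = "point"
    truncated: bool = False
    positions: np.ndarray | None = None  # (n, 2) tracked (x, y) in px, if known

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times and displacement must have equal length")
        if self.velocity.shape[0] not in (0, self.times.shape[0] - 1):
            raise ValueError("velocity must have length len(times) - 1")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("trace too short to define a sample interval")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# correlation engine


def _window_grid(shape: tuple[int, int], win: int, overlap: float):
    """Top-left corners and centers of fully interior interrogation windows."""
    h, w = shape
    step = max(1, int(round(win * (1.0 - overlap))))
    if h < win or w < win:
        raise ValueError(f"frame {shape} smaller than interrogation window {win}")
    x0 = np.arange(0, w - win + 1, step)
    y0 = np.arange(0, h - win + 1, step)
    return x0, y0, x0 + (win - 1) / 2.0, y0 + (win - 1) / 2.0


def _extract_windows(img: np.ndarray, x0: np.ndarray, y0: np.ndarray, win: int):
    """Stack all interrogation windows into a (ny*nx, win, win) array."""
    rows = y0[:, None] + np.arange(win)[None, :]
    cols = x0[:, None] + np.arange(win)[None, :]
    # fancy-index: (ny, win) rows x (nx, win) cols -> (ny, nx, win, win)
    out = img[rows[:, None, :, None], cols[None, :, None, :]]
    return out.reshape(-1, win, win)


def _gauss3(cm: np.ndarray, cc: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Three-point Gaussian peak interpolation with parabolic fallback.

    ``cm``, ``cc``, ``cp`` are correlation values at the integer peak and its
    two neighbours along one axis.  Returns the fractional offset in (-1, 1).
    """
    frac = np.zeros_like(cc)
    pos = (cm > 0) & (cc > 0) & (cp > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm, lc, lp = np.log(cm[pos]), np.log(cc[pos]), np.log(cp[pos])
        denom = lm - 2 * lc + lp
        g = np.where(denom != 0, 0.5 * (lm - lp) / denom, 0.0)
        frac[pos] = g
        # parabolic fit where the log stencil is unusable
        npos = ~pos
        denom2 = cm[npos] - 2 * cc[npos] + cp[npos]
        frac[npos] = np.where(denom2 != 0, 0.5 * (cm[npos] - cp[npos]) / denom2, 0.0)
    return np.clip(frac, -0.999, 0.999)


def _correlate_windows(wa: np.ndarray, wb: np.ndarray):
    """Batched circular FFT cross-correlation peak of window pairs.

    Returns per-window (du, dv) displacement of ``wb`` relative to ``wa`` and
    a boolean mask of windows with usable correlation energy.
    """
    win = wa.shape[-1]
    a = wa - wa.mean(axis=(-2, -1), keepdims=True)
    b = wb - wb.mean(axis=(-2, -1), keepdims=True)
    energy = (a.std(axis=(-2, -1)) > 0) & (b.std(axis=(-2, -1)) > 0)
    fa = sfft.rfft2(a)
    fb = sfft.rfft2(b)
    corr = sfft.irfft2(np.conj(fa) * fb, s=(win, win))
    corr = sfft.fftshift(corr, axes=(-2, -1))
    n = corr.shape[0]
    flat = corr.reshape(n, -1)
    peak = np.argmax(flat, axis=1)
    py, px = np.unravel_index(peak, (win, win))
    # clamp the integer peak off the border so the 3-point stencil exists
    py = np.clip(py, 1, win - 2)
    px = np.clip(px, 1, win - 2)
    idx = np.arange(n)
    cc = corr[idx, py, px]
    fx = _gauss3(corr[idx, py, px - 1], cc, corr[idx, py, px + 1])
    fy = _gauss3(corr[idx, py - 1, px], cc, corr[idx, py + 1, px])
    du = px + fx - win // 2
    dv = py + fy - win // 2
    du[~energy] = 0.0
    dv[~energy] = 0.0
    return du, dv, energy


def _normalized_median_test(u: np.ndarray, v: np.ndarray, eps: float, threshold: float):
    """Westerweel–Scarano normalized median test; True where the vector passes."""
    ny, nx = u.shape
    resid = np.zeros((ny, nx))
    for comp in (u, v):
        padded = np.full((ny + 2, nx + 2), np.nan)
        padded[1:-1, 1:-1] = comp
        neigh = np.stack(
            [
                padded[1 + dy : 1 + dy + ny, 1 + dx : 1 + dx + nx]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if not (dy == 0 and dx == 0)
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(neigh, axis=0)
            rm = np.nanmedian(np.abs(neigh - med), axis=0)
        r = np.abs(comp - med) / (rm + eps)
        resid += r**2
    return np.sqrt(resid) <= threshold


def _replace_invalid(u: np.ndarray, v: np.ndarray, valid: np.ndarray):
    """Replace invalid vectors by the mean of their valid 8-neighbours."""
    ny, nx = u.shape
    u2, v2 = u.copy(), v.copy()
    replaced = np.zeros_like(valid)
    bad = np.argwhere(~valid)
    for iy, ix in bad:
        ys = slice(max(iy - 1, 0), min(iy + 2, ny))
        xs = slice(max(ix - 1, 0), min(ix + 2, nx))
        m = valid[ys, xs]
        if m.any():
            u2[iy, ix] = u[ys, xs][m].mean()
            v2[iy, ix] = v[ys, xs][m].mean()
        else:
            u2[iy, ix] = 0.0
            v2[iy, ix] = 0.0
        replaced[iy, ix] = True
    return u2, v2, replaced


def _densify(field_x, field_y, u, v, shape):
    """Bilinear interpolation of a grid field to a dense per-pixel field.

    Pixels outside the grid hull take the value of the nearest grid node
    (constant extrapolation), which is the standard predictor for window
    deformation near the frame borders.
    """
    h, w = shape
    yy = np.clip(np.arange(h, dtype=float), field_y[0], field_y[-1])
    xx = np.clip(np.arange(w, dtype=float), field_x[0], field_x[-1])
    iy = np.clip(np.searchsorted(field_y, yy, side="right") - 1, 0, len(field_y) - 2)
    ix = np.clip(np.searchsorted(field_x, xx, side="right") - 1, 0, len(field_x) - 2)
    ty = (yy - field_y[iy]) / (field_y[iy + 1] - field_y[iy])
    tx = (xx - field_x[ix]) / (field_x[ix + 1] - field_x[ix])
    ty = ty[:, None]
    tx = tx[None, :]
    out = []
    for comp in (u, v):
        c00 = comp[np.ix_(iy, ix)]
        c01 = comp[np.ix_(iy, ix + 1)]
        c10 = comp[np.ix_(iy + 1, ix)]
        c11 = comp[np.ix_(iy + 1, ix + 1)]
        out.append((1 - ty) * ((1 - tx) * c00 + tx * c01) + ty * ((1 - tx) * c10 + tx * c11))
    return out[0], out[1]


def correlate_pair(
    frame_a: np.ndarray, frame_b: np.ndarray, config: PivConfig | None = None
) -> VectorField:
    """Estimate the displacement field from ``frame_a`` to ``frame_b``.

    Multipass FFT cross-correlation: the first pass correlates zero-mean
    interrogation windows directly; each subsequent pass warps ``frame_b`` by
    the dense-interpolated previous-pass field (window deformation) and
    measures the residual on a finer grid.  Vectors failing the normalized
    median test are replaced by the mean of their valid neighbours and carry
    ``valid=False``/``replaced=True`` flags.
    """
    if config is None:
        config = PivConfig()
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if a.ndim != 2:
        raise ValueError("frames must be 2D grayscale arrays")

    dense_u = dense_v = None
    result: VectorField | None = None
    for p, win in enumerate(config.pass_windows):
        x0, y0, cx, cy = _window_grid(a.shape, win, config.overlap_fraction)
        if dense_u is None:
            b_eff = b
            pred_u = np.zeros((len(cy), len(cx)))
            pred_v = np.zeros((len(cy), len(cx)))
        else:
            h, w = a.shape
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            b_eff = ndimage.map_coordinates(
                b, [yy + dense_v, xx + dense_u], order=1, mode="nearest"
            )
            pred_u = dense_u[np.ix_(cy.astype(int), cx.astype(int))]
            pred_v = dense_v[np.ix_(cy.astype(int), cx.astype(int))]

        wa = _extract_windows(a, x0, y0, win)
        wb = _extract_windows(b_eff, x0, y0, win)
        du, dv, energy = _correlate_windows(wa, wb)
        shape2 = (len(y0), len(x0))
        u = pred_u + du.reshape(shape2)
        v = pred_v + dv.reshape(shape2)
        valid = energy.reshape(shape2)

        # reject physically impossible vectors before the median test
        limit = config.max_displacement if config.max_displacement is not None else win / 2
        valid &= np.hypot(u, v) <= limit
        if valid.size > 1:
            valid &= _normalized_median_test(
                u, v, config.validation_eps, config.validation_threshold
            )
        u, v, replaced = _replace_invalid(u, v, valid)

        if p < len(config.pass_windows) - 1:
            dense_u, dense_v = _densify(cx, cy, u, v, a.shape)
        result = VectorField(x=cx, y=cy, u=u, v=v, valid=valid, replaced=replaced)
    assert result is not None
    return result


def movie_to_fields(stack: MovieStack, config: PivConfig | None = None) -> list[VectorField]:
    """One displacement field per consecutive frame pair (n_frames − 1 total)."""
    return [
        correlate_pair(stack.frames[i], stack.frames[i + 1], config)
        for i in range(stack.n_frames - 1)
    ]


def track_point(
    fields: list[VectorField],
    start: tuple[float, float],
    pixel_size: float,
    frame_interval: float,
    source: str = "point",
) -> DisplacementTrace:
    """Lagrangian tracking of a reference point through the field sequence.

    The position is advanced each interval by the bilinearly interpolated
    field at the current position; displacement is the distance from the
    initial position in µm.  If the trajectory leaves the grid hull the trace
    is truncated at the exit and flagged.
    """
    if not fields:
        raise ValueError("no vector fields to track through")
    f0 = fields[0]
    if not (f0.x[0] <= start[0] <= f0.x[-1] and f0.y[0] <= start[1] <= f0.y[-1]):
        raise ValueError("start point outside the vector-field grid hull")
    pos = np.array(start, dtype=float)
    origin = pos.copy()
    times = [0.0]
    disp = [0.0]
    vel = []
    positions = [pos.copy()]
    truncated = False
    for k, fld in enumerate(fields):
        try:
            du, dv = fld.interpolate((pos[0], pos[1]))
        except ValueError:
            truncated = True
            break
        pos = pos + [du, dv]
        step = float(np.hypot(du, dv))
        times.append((k + 1) * frame_interval)
        disp.append(float(np.linalg.norm(pos - origin)) * pixel_size)
        vel.append(step * pixel_size / frame_interval)
        positions.append(pos.copy())
    return DisplacementTrace(
        times=np.array(times),
        displacement=np.array(disp),
        velocity=np.array(vel),
        source=source,
        truncated=truncated,
        positions=np.array(positions),
    )


def analyze_movie(
    stack: MovieStack,
    point: tuple[float, float],
    config: PivConfig | None = None,
    source: str = "point",
) -> tuple[list[VectorField], DisplacementTrace]:
    """Convenience: PIV on every frame pair, then track ``point``."""
    fields = movie_to_fields(stack, config)
    trace = track_point(fields, point, stack.pixel_size, stack.frame_interval, source)
    return fields, trace
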