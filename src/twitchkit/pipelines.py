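"""End-to-end pipelines binding the analysis modules together.

``run_contractility`` takes a calibrated movie to a displacement trace,
per-twitch events and a kinetics summary; ``run_morphology`` takes the
fluorescence channels of one field of view to morphometry, AChR scoring and
smFISH spot tables.  All CSV outputs embed the package version and the
config hash, and numeric values are written at 9 significant digits so reruns
diff cleanly.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__, kinetics, morphometry, puncta
from .config import RunConfig
from .piv import MovieStack, movie_to_fields, track_point
from skimage import measure

__all__ = ["run_contractility", "run_morphology", "write_csv", "read_movie"]

log = logging.getLogger("twitchkit")


def write_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """Write a DataFrame with a provenance header (version + config hash)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# twitchkit {__version__}\n# config_hash {config.hash}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_movie(path: str | Path, config: RunConfig) -> MovieStack:
    frames = tifffile.imread(path)
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page grayscale TIFF movie")
    return MovieStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )


def run_contractility(
    movie: str | Path | MovieStack,
    config: RunConfig,
    point: tuple[float, float],
    outdir: str | Path | None = None,
) -> dict:
    """Movie → PIV fields → tracked trace → twitch kinetics.

    ``point`` is the reference myonucleus in pixel coordinates.  Returns a
    dict with the trace, events, summary and fields; when ``outdir`` is
    given, writes ``trace.csv``, ``events.csv``, ``summary.csv`` and a long
    ``fields.csv`` archive.
    """
    if isinstance(movie, (str, Path)):
        stack = read_movie(movie, config)
    else:
        stack = movie
    log.info(
        "contractility run: %d frames, px=%g µm, dt=%g s, point=%s, config=%s",
        stack.n_frames, stack.pixel_size, stack.frame_interval, point, config.hash,
    )
    fields = movie_to_fields(stack, config.piv_config())
    trace = track_point(fields, point, stack.pixel_size, stack.frame_interval)
    summary = kinetics.summarize(
        trace,
        window=config.kinetics_window,
        prominence_fraction=config.prominence_fraction,
        baseline_window=config.baseline_window,
    )
    events = kinetics.dissect_twitches(
        trace, kinetics.detect_extrema(trace, config.prominence_fraction)
    )
    result = {"trace": trace, "events": events, "summary": summary, "fields": fields}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pos = trace.positions if trace.positions is not None else np.full((len(trace.times), 2), np.nan)
        trace_df = pd.DataFrame(
            {
                "t": trace.times,
                "x": pos[:, 0],
                "y": pos[:, 1],
                "displacement_um": trace.displacement,
                "velocity_um_s": np.concatenate([[np.nan], trace.velocity]),
            }
        )
        write_csv(trace_df, outdir / "trace.csv", config)
        write_csv(pd.DataFrame([dataclasses.asdict(e) for e in events]), outdir / "events.csv", config)
        write_csv(pd.DataFrame([dataclasses.asdict(summary)]), outdir / "summary.csv", config)
        rows = []
        for k, f in enumerate(fields):
            yy, xx = np.meshgrid(f.y, f.x, indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "frame_pair": k,
                        "x": xx.ravel(),
                        "y": yy.ravel(),
                        "u": f.u.ravel(),
                        "v": f.v.ravel(),
                        "valid": f.valid.ravel().astype(int),
                        "replaced": f.replaced.ravel().astype(int),
                    }
                )
            )
        write_csv(pd.concat(rows, ignore_index=True), outdir / "fields.csv", config)
    return result


def _load_channel(src) -> np.ndarray | None:
    if src is None:
        return None
    if isinstance(src, (str, Path)):
        return np.asarray(tifffile.imread(src), dtype=float)
    return np.asarray(src, dtype=float)


def run_morphology(
    channels: dict,
    config: RunConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Channels → masks → morphometry → AChR scoring → smFISH spot counts.

    ``channels`` maps ``actinin``/``dapi`` (required) and optionally
    ``btx``/``fish`` to file paths or arrays.  Missing optional channels skip
    the corresponding outputs with a warning instead of failing the run.
    """
    actinin_raw = _load_channel(channels.get("actinin"))
    dapi_raw = _load_channel(channels.get("dapi"))
    if actinin_raw is None or dapi_raw is None:
        raise ValueError("both 'actinin' and 'dapi' channels are required")
    btx_raw = _load_channel(channels.get("btx"))
    fish_raw = _load_channel(channels.get("fish"))
    for name, ch in (("dapi", dapi_raw), ("btx", btx_raw), ("fish", fish_raw)):
        if ch is not None and ch.shape[-2:] != actinin_raw.shape[-2:]:
            raise ValueError(f"channel {name!r} shape {ch.shape} != actinin {actinin_raw.shape}")

    actinin_mask = morphometry.preprocess(
        actinin_raw, config.background_radius, config.mask_min_area
    )
    dapi_mask = morphometry.preprocess(
        dapi_raw, config.background_radius, config.nucleus_min_area
    )
    scene = morphometry.SegmentedScene(
        actinin_mask=actinin_mask,
        dapi_mask=dapi_mask,
        pixel_size=config.pixel_size,
        provenance={"config_hash": config.hash},
    )
    morpho = morphometry.measure_scene(scene)
    result: dict = {"morphometry": morpho, "scene": scene}

    nuclei, density = morphometry.assign_myonuclei(
        dapi_mask, actinin_mask, config.pixel_size,
        config.min_overlap, config.nucleus_min_area,
    )
    myonuclei = [r for r in nuclei if r.is_myonucleus]

    # AChR / BTX scoring
    if btx_raw is not None and len(nuclei) >= 10:
        labels = measure.label(dapi_mask, connectivity=2)
        records = puncta.nucleus_btx_means(btx_raw, labels)
        myo_ids = {r.label for r in myonuclei}
        records = [r for r in records if r.nucleus_id in myo_ids]
        if len(records) >= 10:
            background = puncta.btx_background(records, config.histogram_bins)
            records, proportion = puncta.classify_high_btx(
                records, background, config.btx_factor
            )
            result["achr"] = {
                "records": records,
                "background": background,
                "high_proportion": proportion,
            }
    if "achr" not in result and btx_raw is not None:
        warnings.warn("too few myonuclei for BTX scoring; AChR output skipped", stacklevel=2)
    elif btx_raw is None:
        warnings.warn("no BTX channel; AChR output skipped", stacklevel=2)

    # smFISH spots in perinuclear bands
    if fish_raw is not None and myonuclei:
        fish_mask = morphometry.preprocess(
            fish_raw, config.background_radius, config.spot_min_area
        )
        try:
            centerline = morphometry.skeleton_centerline(actinin_mask, config.pixel_size)
        except ValueError:
            centerline = None
        spot_records = []
        if centerline is not None:
            for r in myonuclei:
                centroid_um = (r.centroid[0] * config.pixel_size, r.centroid[1] * config.pixel_size)
                try:
                    band = puncta.perinuclear_region(
                        centroid_um, centerline, actinin_mask, config.pixel_size,
                        config.perinuclear_half_length,
                    )
                except ValueError:
                    continue
                band_area = float(band.sum()) * config.pixel_size**2
                if band_area == 0:
                    continue
                spot_records.append(
                    puncta.count_spots(
                        fish_mask, band, band_area,
                        config.spot_min_area, config.spot_max_area, region_id=r.label,
                    )
                )
        result["spots"] = spot_records
    elif fish_raw is None:
        warnings.warn("no FISH channel; spot output skipped", stacklevel=2)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_csv(pd.DataFrame([dataclasses.asdict(morpho)]), outdir / "morphometry.csv", config)
        if "achr" in result:
            df = pd.DataFrame([dataclasses.asdict(r) for r in result["achr"]["records"]])
            df["background"] = result["achr"]["background"]
            df["high_proportion"] = result["achr"]["high_proportion"]
            write_csv(df, outdir / "achr.csv", config)
        if result.get("spots"):
            write_csv(
                pd.DataFrame([dataclasses.asdict(r) for r in result["spots"]]),
                outdir / "spots.csv", config,
            )
    return result
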