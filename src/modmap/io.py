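"""Reading and writing movies, ROI masks, event catalogs and ground truth.

Movies travel as HDF5 (float32 dataset ``movie`` with ``pixel_um``,
``frame_rate_hz`` and ``kind`` attributes) or multi-page TIFF (uint16,
linearly scaled; the scale and metadata are stored in the ImageDescription
tag as JSON).  ROI masks are 8-bit PNG/TIFF images where nonzero means
inside.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .containers import EventCatalog, Movie, RoiMask

__all__ = [
    "save_movie_h5",
    "load_movie_h5",
    "save_movie_tiff",
    "load_movie_tiff",
    "load_movie",
    "load_roi_mask",
    "save_roi_mask",
    "save_events_h5",
    "load_events_h5",
    "save_ground_truth",
    "load_ground_truth",
]


def save_movie_h5(path: str | Path, movie: Movie, truth=None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("movie", data=movie.data.astype(np.float32), compression="gzip")
        d.attrs["pixel_um"] = movie.pixel_um
        d.attrs["frame_rate_hz"] = movie.frame_rate_hz
        d.attrs["kind"] = movie.kind
        if truth is not None:
            save_ground_truth(f, truth)


def load_movie_h5(path: str | Path) -> Movie:
    with h5py.File(path, "r") as f:
        d = f["movie"]
        return Movie(
            data=d[...],
            pixel_um=float(d.attrs["pixel_um"]),
            frame_rate_hz=float(d.attrs["frame_rate_hz"]),
            kind=str(d.attrs.get("kind", "raw")),
        )


def save_movie_tiff(path: str | Path, movie: Movie) -> None:
    data = np.asarray(movie.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    scaled = np.round((data - lo) / scale).astype(np.uint16)
    meta = {
        "pixel_um": movie.pixel_um,
        "frame_rate_hz": movie.frame_rate_hz,
        "kind": movie.kind,
        "offset": lo,
        "scale": scale,
    }
    tifffile.imwrite(path, scaled, photometric="minisblack", description=json.dumps(meta))


def load_movie_tiff(
    path: str | Path,
    pixel_um: float | None = None,
    frame_rate_hz: float | None = None,
    kind: str | None = None,
) -> Movie:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if "scale" in meta:
        data = data.astype(np.float32) * np.float32(meta["scale"]) + np.float32(
            meta.get("offset", 0.0)
        )
    else:
        data = data.astype(np.float32)
    if data.ndim == 2:
        data = data[None]
    px = pixel_um if pixel_um is not None else meta.get("pixel_um")
    fr = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if px is None or fr is None:
        raise ValueError(
            "pixel_um and frame_rate_hz must be given when the TIFF carries no metadata"
        )
    return Movie(data, float(px), float(fr), kind=kind or meta.get("kind", "raw"))


def load_movie(path: str | Path, **kwargs) -> Movie:
    """Dispatch on file extension (.h5/.hdf5 or .tif/.tiff)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return load_movie_h5(path)
    if suffix in (".tif", ".tiff"):
        return load_movie_tiff(path, **kwargs)
    raise ValueError(f"unsupported movie format {suffix!r}")


def load_roi_mask(path: str | Path, pixel_um: float) -> RoiMask:
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) -> any channel nonzero
        arr = arr.max(axis=-1)
    return RoiMask(arr != 0, pixel_um)


def save_roi_mask(path: str | Path, roi: RoiMask) -> None:
    arr = (roi.mask.astype(np.uint8)) * 255
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def save_events_h5(path: str | Path, catalog: EventCatalog, extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("events")
        g.create_dataset("intervals", data=catalog.intervals.astype(np.int64))
        g.attrs["n_active_frames"] = catalog.n_active_frames
        if catalog.event_frames_raw is not None:
            g.create_dataset(
                "frames_raw",
                data=catalog.event_frames_raw.astype(np.float32),
                compression="gzip",
            )
        for key, val in (extra or {}).items():
            f.attrs[key] = val


def load_events_h5(path: str | Path) -> EventCatalog:
    with h5py.File(path, "r") as f:
        g = f["events"]
        frames = g["frames_raw"][...] if "frames_raw" in g else None
        return EventCatalog(
            intervals=g["intervals"][...],
            event_frames_raw=frames,
            n_active_frames=int(g.attrs.get("n_active_frames", 0)),
        )


def save_ground_truth(h5file, truth) -> None:
    """Write a synthetic ground truth into an open HDF5 file (group 'truth')."""
    g = h5file.create_group("truth")
    g.create_dataset("component_maps", data=truth.component_maps.astype(np.float32))
    g.create_dataset("event_times", data=truth.event_times.astype(np.int64))
    g.create_dataset("event_weights", data=truth.event_weights)
    for key in (
        "true_wavelength_mm",
        "pixel_um",
        "n_frames",
        "event_amplitude",
        "module_floor",
        "noise_sd",
        "drift_amplitude",
        "decay_tau_s",
        "rise_frames",
        "baseline_level",
        "rng_seed",
    ):
        g.attrs[key] = getattr(truth, key)


def load_ground_truth(path: str | Path):
    from .synthetic import GroundTruth

    with h5py.File(path, "r") as f:
        g = f["truth"]
        kwargs = {k: g.attrs[k] for k in g.attrs}
        return GroundTruth(
            component_maps=g["component_maps"][...],
            event_times=g["event_times"][...],
            event_weights=g["event_weights"][...],
            **{
                k: (int(v) if k in ("n_frames", "rise_frames", "rng_seed") else float(v))
                for k, v in kwargs.items()
            },
        )
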