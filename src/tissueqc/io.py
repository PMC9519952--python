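"""File interfaces: HDF5 scan containers, TIFF image stacks, CSV tables.

Layouts
-------
FLIm scan HDF5: dataset ``decays[ny, nx, nch, nt]`` with attrs ``dt_ps``,
``pixel_pitch_um`` and ``band_edges_nm`` (nch x 2).

RF volume HDF5: dataset ``rf[nframes, nsamples, nlines]`` with attrs
``fs_hz``, ``line_pitch_um``, ``frame_spacing_um``.

Lifetime maps are written as 32-bit float TIFF (one per channel, NaN =
missing pixel); B-mode stacks and masks as multi-page 8-bit TIFF with a
JSON sidecar recording voxel size and processing configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .bmode import BModeVolume, RFFrame, RFVolume
from .flim import SPECTRAL_BANDS, LifetimeMap, RoiStats
from .voids import MaskVolume, VoidResult

__all__ = [
    "write_flim_scan",
    "read_flim_scan",
    "write_rf_volume",
    "read_rf_volume",
    "write_lifetime_map",
    "read_lifetime_map",
    "write_bmode_volume",
    "read_bmode_volume",
    "write_mask_volume",
    "void_result_row",
    "roi_stats_row",
]


def write_flim_scan(
    path: str | Path,
    decays: np.ndarray,
    dt_ps: float = 80.0,
    pixel_pitch_um: float = 20.0,
    channels: tuple[int, ...] | None = None,
) -> None:
    """Write a multichannel decay scan (ny, nx, nch, nt) to HDF5."""
    decays = np.asarray(decays)
    if decays.ndim == 3:
        decays = decays[:, :, None, :]
    if decays.ndim != 4:
        raise ValueError("decays must have shape (ny, nx, nch, nt)")
    nch = decays.shape[2]
    channels = channels or tuple(range(1, nch + 1))
    edges = np.array([SPECTRAL_BANDS[c].wavelength_range for c in channels])
    with h5py.File(path, "w") as f:
        d = f.create_dataset("decays", data=decays, compression="gzip")
        d.attrs["dt_ps"] = dt_ps
        d.attrs["pixel_pitch_um"] = pixel_pitch_um
        d.attrs["band_edges_nm"] = edges
        d.attrs["channels"] = np.asarray(channels)


def read_flim_scan(path: str | Path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        d = f["decays"]
        meta = {
            "dt_ps": float(d.attrs["dt_ps"]),
            "pixel_pitch_um": float(d.attrs["pixel_pitch_um"]),
            "band_edges_nm": np.asarray(d.attrs["band_edges_nm"]),
            "channels": tuple(int(c) for c in d.attrs["channels"]),
        }
        return d[()], meta


def write_rf_volume(path: str | Path, vol: RFVolume) -> None:
    rf = np.stack([f.rf for f in vol.frames])
    f0 = vol.frames[0]
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rf", data=rf, compression="gzip")
        d.attrs["fs_hz"] = f0.fs
        d.attrs["line_pitch_um"] = f0.line_pitch
        d.attrs["frame_spacing_um"] = vol.frame_spacing


def read_rf_volume(path: str | Path) -> RFVolume:
    with h5py.File(path, "r") as f:
        d = f["rf"]
        rf = d[()]
        frames = [
            RFFrame(rf[i], fs=float(d.attrs["fs_hz"]), line_pitch=float(d.attrs["line_pitch_um"]), frame_index=i)
            for i in range(rf.shape[0])
        ]
        return RFVolume(frames, frame_spacing=float(d.attrs["frame_spacing_um"]))


def write_lifetime_map(path: str | Path, lt_map: LifetimeMap) -> None:
    """32-bit float TIFF; lifetime plane first, intensity plane second."""
    stack = np.stack([lt_map.grid, lt_map.intensity]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "pixel_pitch_um": lt_map.pixel_pitch,
            "channel": lt_map.band.channel_id if lt_map.band else None,
        },
    )


def read_lifetime_map(path: str | Path, pixel_pitch: float = 20.0, channel: int | None = None) -> LifetimeMap:
    stack = tifffile.imread(path).astype(float)
    band = SPECTRAL_BANDS[channel] if channel else None
    return LifetimeMap(grid=stack[0], intensity=stack[1], pixel_pitch=pixel_pitch, band=band)


def write_bmode_volume(path: str | Path, vol: BModeVolume, config: dict | None = None) -> None:
    """Multi-page 8-bit TIFF plus a JSON sidecar with voxel size/config."""
    path = Path(path)
    tifffile.imwrite(path, vol.as_array())
    sidecar = {
        "voxel_size_um": list(vol.voxel_size),
        "dynamic_range_db": vol.frames[0].dynamic_range,
        "config": config or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bmode_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return stack, meta


def write_mask_volume(path: str | Path, mask: MaskVolume) -> None:
    tifffile.imwrite(Path(path), (mask.voxels * np.uint8(255)))


def void_result_row(result: VoidResult, sample_id: str = "", day: int | None = None) -> pd.DataFrame:
    """One CSV-ready row of void volumetry output."""
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "day": day,
                "total_mm3": result.total_volume,
                "void_mm3": result.void_volume,
                "void_percent": result.void_percent,
            }
        ]
    )


def roi_stats_row(stats: RoiStats, channel: int | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": channel,
                "mean_lt_ns": stats.mean_lt,
                "sd_lt_ns": stats.sd_lt,
                "n_pixels": stats.n_pixels,
                "roi_row": stats.roi_center[0],
                "roi_col": stats.roi_center[1],
                "roi_radius_px": stats.roi_radius,
            }
        ]
    )
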