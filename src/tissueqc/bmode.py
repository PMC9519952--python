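"""Ultrasound backscatter microscopy (UBM) B-mode reconstruction.

Raw pulse-echo RF A-lines (sampled at 400 MHz) are band-pass filtered
(20-60 MHz, zero phase), envelope detected via the analytic signal,
resampled to a 5 x 5 µm pixel grid, and log-compressed to 8-bit images
with 60 dB dynamic range.  Axial depth follows from a configurable speed
of sound (1540 m/s soft-tissue convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from skimage.transform import resize

__all__ = [
    "RFFrame",
    "RFVolume",
    "BModeFrame",
    "BModeVolume",
    "ReconstructionConfig",
    "bandpass_rf",
    "envelope",
    "log_compress",
    "interpolate_bmode",
    "reconstruct_volume",
]

SPEED_OF_SOUND = 1540.0  # m/s, soft-tissue convention


@dataclass
class RFFrame:
    """One frame of raw RF data: axial samples x lateral A-lines."""

    rf: np.ndarray
    fs: float = 400e6  # Hz
    line_pitch: float = 20.0  # µm
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=float)
        if self.rf.ndim != 2:
            raise ValueError("rf must be 2-D (n_samples_axial x n_lines)")
        if self.rf.shape[0] < 16:
            raise ValueError("need >= 16 axial samples")
        if self.fs <= 0 or self.line_pitch <= 0:
            raise ValueError("fs and line_pitch must be positive")

    @property
    def axial_pitch_um(self) -> float:
        """Axial sample spacing in µm (two-way travel)."""
        return SPEED_OF_SOUND / (2.0 * self.fs) * 1e6


@dataclass
class RFVolume:
    """Ordered stack of RF frames with uniform elevational spacing."""

    frames: list[RFFrame]
    frame_spacing: float = 200.0  # µm

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty RF volume")
        f0 = self.frames[0]
        for f in self.frames[1:]:
            if f.rf.shape != f0.rf.shape or f.fs != f0.fs or f.line_pitch != f0.line_pitch:
                raise ValueError("all frames must share fs, dimensions and line_pitch")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")


@dataclass
class BModeFrame:
    """8-bit log-compressed B-mode image."""

    image: np.ndarray
    pixel_size: tuple[float, float] = (5.0, 5.0)  # µm (axial, lateral)
    dynamic_range: float = 60.0  # dB

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.dtype != np.uint8:
            raise ValueError("B-mode image must be uint8")
        if min(self.pixel_size) <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class BModeVolume:
    """Stack of B-mode frames; voxel_size = (axial, lateral, elevational) µm."""

    frames: list[BModeFrame]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty B-mode volume")
        shape = self.frames[0].image.shape
        if any(f.image.shape != shape for f in self.frames):
            raise ValueError("inconsistent frame dimensions")

    def as_array(self) -> np.ndarray:
        """(n_frames, ny, nx) uint8 stack."""
        return np.stack([f.image for f in self.frames])


@dataclass(frozen=True)
class ReconstructionConfig:
    """Processing parameters of the B-mode chain."""

    band: tuple[float, float] = (20e6, 60e6)  # Hz
    filter_order: int = 4  # Butterworth order (per band edge)
    dynamic_range: float = 60.0  # dB
    target_pixel: tuple[float, float] = (5.0, 5.0)  # µm
    speed_of_sound: float = SPEED_OF_SOUND  # m/s
    volume_norm: bool = False  # normalize log compression volume-wide


def bandpass_rf(frame: RFFrame, low: float = 20e6, high: float = 60e6, order: int = 4) -> RFFrame:
    """Zero-phase Butterworth band-pass along the axial axis.

    Forward-backward (filtfilt) application preserves echo depth
    registration; the effective magnitude response is the squared
    Butterworth response.
    """
    if not 0 < low < high < frame.fs / 2:
        raise ValueError(f"band edges ({low}, {high}) invalid for fs={frame.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=frame.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, frame.rf, axis=0)
    return replace(frame, rf=filtered)


def envelope(frame: RFFrame) -> np.ndarray:
    """Envelope of the RF: magnitude of the analytic signal, axial axis."""
    return np.abs(sps.hilbert(frame.rf, axis=0))


def log_compress(env: np.ndarray, dynamic_range: float = 60.0, env_max: float | None = None) -> np.ndarray:
    """Log-compress an envelope image to 8 bits.

    pixel = clip(255 * (20 log10(env/env_max) + DR) / DR, 0, 255),
    rounded half-up, so the maximum maps to 255 and signals at or below
    -DR dB map to 0.  ``env_max`` defaults to the frame maximum; pass a
    volume-wide maximum for volume-normalized compression.
    """
    env = np.asarray(env, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative")
    if env_max is None:
        env_max = float(env.max())
    if env_max <= 0:
        raise ValueError("all-zero envelope cannot be log-compressed")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / env_max)
    scaled = np.clip(255.0 * (db + dynamic_range) / dynamic_range, 0.0, 255.0)
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up: deterministic


def interpolate_bmode(
    img: np.ndarray,
    native_pixel: tuple[float, float],
    target_pixel: tuple[float, float] = (5.0, 5.0),
) -> np.ndarray:
    """Bilinear resampling onto the target (axial, lateral) pixel grid.

    Output dimensions are chosen so the physical extent is preserved
    within one target pixel.
    """
    if min(target_pixel) <= 0 or min(native_pixel) <= 0:
        raise ValueError("pixel sizes must be positive")
    img = np.asarray(img, dtype=float)
    ny = max(2, int(round(img.shape[0] * native_pixel[0] / target_pixel[0])))
    nx = max(2, int(round(img.shape[1] * native_pixel[1] / target_pixel[1])))
    if (ny, nx) == img.shape:
        return img.copy()
    return resize(img, (ny, nx), order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def reconstruct_volume(vol: RFVolume, cfg: ReconstructionConfig | None = None) -> BModeVolume:
    """Full B-mode chain: bandpass → envelope → resample → log-compress.

    Envelope images are resampled from their native (c/2fs x line_pitch)
    grid to the target pixel size before log compression.  Deterministic:
    identical input and config give bit-identical output.
    """
    cfg = cfg or ReconstructionConfig()
    envs = []
    for frame in vol.frames:
        f = bandpass_rf(frame, *cfg.band, order=cfg.filter_order)
        env = envelope(f)
        native = (cfg.speed_of_sound / (2.0 * frame.fs) * 1e6, frame.line_pitch)
        envs.append(interpolate_bmode(env, native, cfg.target_pixel))
    env_max = max(float(e.max()) for e in envs) if cfg.volume_norm else None
    frames = [
        BModeFrame(
            log_compress(e, cfg.dynamic_range, env_max=env_max),
            pixel_size=cfg.target_pixel,
            dynamic_range=cfg.dynamic_range,
        )
        for e in envs
    ]
    voxel = (cfg.target_pixel[0], cfg.target_pixel[1], vol.frame_spacing)
    return BModeVolume(frames=frames, voxel_size=voxel)
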