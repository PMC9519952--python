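"""Seeded synthetic phantoms with known ground truth.

Generators emulating the statistical structure of the four instrument
data classes the analysis modules consume: FLIm decay raster scans,
UBM RF frame stacks with speckle and scatterer-free voids, biphasic
stress-relaxation records, and linked optical/destructive sample tables.
Every generator is a pure function of its spec (seed included):
identical spec gives bit-identical output.  Random streams are derived
from the user seed through fixed per-generator labels so adding a
phantom class never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .bmode import RFFrame, RFVolume
from .mechanics import BiphasicParams, RampHoldProtocol, StressRecord, biphasic_forward

__all__ = [
    "FlimPhantomSpec",
    "RfPhantomSpec",
    "LinkedDatasetSpec",
    "gen_flim_phantom",
    "gen_rf_phantom",
    "gen_stress_relaxation",
    "gen_linked_dataset",
]

# fixed substream labels, one per generator
_LABEL_FLIM = 101
_LABEL_RF = 102
_LABEL_MECH = 103
_LABEL_LINKED = 104


# ---------------------------------------------------------------------------
# FLIm phantom


@dataclass(frozen=True)
class FlimPhantomSpec:
    """Spec for a raster scan of fluorescence decays.

    The grid holds a uniform base tissue of lifetime ``base_lifetime``
    with optional circular patches of different lifetime; a margin of
    ``background_margin`` pixels around the edge carries zero signal
    (instrument background only), exercising the low-signal path.
    Decays are mono-exponential (optionally bi-exponential) convolved
    with a Gaussian instrument response and sampled at ``dt_ps``.
    """

    shape: tuple[int, int] = (32, 32)  # (ny, nx)
    pixel_pitch: float = 20.0  # µm
    base_lifetime: float = 4.0  # ns
    patches: tuple[tuple[float, float, float, float], ...] = ()  # (cy, cx, r, tau_ns)
    background_margin: int = 0  # px of zero-signal border
    peak_counts: float = 1000.0
    baseline_counts: float = 10.0  # dc offset before the decay
    noise: str = "poisson"  # 'poisson' | 'gaussian' | 'none'
    gaussian_sigma: float = 5.0  # counts, for noise='gaussian'
    irf_fwhm_ps: float = 400.0
    dt_ps: float = 80.0
    n_samples: int = 1250  # 100 ns window at 80 ps
    onset_index: int = 40  # decay onset sample
    tau2_ns: float | None = None  # second component (bi-exponential option)
    amp2_frac: float = 0.0  # amplitude fraction of the second component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lifetime <= 0 or any(p[3] <= 0 for p in self.patches):
            raise ValueError("lifetimes must be positive")
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError("noise must be 'poisson', 'gaussian' or 'none'")


def _decay_shape(tau_ns: float, spec: FlimPhantomSpec) -> np.ndarray:
    """Noise-free unit-peak decay: exponential (+optional 2nd component)
    convolved with a Gaussian IRF."""
    dt = spec.dt_ps * 1e-3  # ns per sample
    t = np.arange(spec.n_samples) * dt
    ideal = np.zeros(spec.n_samples)
    on = spec.onset_index
    ideal[on:] = np.exp(-(t[on:] - t[on]) / tau_ns)
    if spec.tau2_ns is not None and spec.amp2_frac > 0:
        ideal[on:] = (1 - spec.amp2_frac) * ideal[on:] + spec.amp2_frac * np.exp(
            -(t[on:] - t[on]) / spec.tau2_ns
        )
    sigma = spec.irf_fwhm_ps * 1e-3 / 2.35482 / dt  # samples
    if sigma > 0.05:
        half = int(np.ceil(4 * sigma))
        kx = np.arange(-half, half + 1)
        kern = np.exp(-0.5 * (kx / sigma) ** 2)
        kern /= kern.sum()
        full = np.convolve(ideal, kern)
        ideal = full[half : half + spec.n_samples]
    peak = ideal.max()
    return ideal / peak if peak > 0 else ideal


def gen_flim_phantom(spec: FlimPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a decay scan and its ground-truth lifetime field.

    Returns
    -------
    scan : ndarray, shape (ny, nx, nt)
        Per-pixel decay waveforms (counts), background pixels carry the
        baseline only.
    truth : ndarray, shape (ny, nx)
        True lifetime (ns) per pixel; NaN in the zero-signal background.
    """
    rng = np.random.default_rng([spec.seed, _LABEL_FLIM])
    ny, nx = spec.shape
    truth = np.full((ny, nx), float(spec.base_lifetime))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cy, cx, r, tau in spec.patches:
        truth[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = tau
    m = spec.background_margin
    if m > 0:
        bg = np.ones((ny, nx), dtype=bool)
        bg[m : ny - m, m : nx - m] = False
        truth[bg] = np.nan

    # one decay template per distinct lifetime
    templates = {tau: _decay_shape(tau, spec) for tau in np.unique(truth[np.isfinite(truth)])}
    scan = np.full((ny, nx, spec.n_samples), float(spec.baseline_counts))
    for tau, templ in templates.items():
        sel = truth == tau
        scan[sel] += spec.peak_counts * templ

    if spec.noise == "poisson":
        scan = rng.poisson(np.clip(scan, 0, None)).astype(float)
    elif spec.noise == "gaussian":
        scan = scan + rng.normal(0.0, spec.gaussian_sigma, size=scan.shape)
    return scan, truth


# ---------------------------------------------------------------------------
# RF speckle phantom


@dataclass(frozen=True)
class RfPhantomSpec:
    """Spec for a raster-scanned RF volume of a tissue slab with voids.

    Axes: z = axial (depth), x = lateral (A-lines), y = elevational
    (frames).  A box-shaped tissue slab filled with randomly placed
    point scatterers sits inside the scanned volume; voids are
    scatterer-free ellipsoids (density multiplier 0 by default).  Each
    A-line is the axial convolution of the binned scatterer
    reflectivity with a Gabor pulse at the transducer center frequency.
    """

    depth_um: float = 1800.0  # axial extent z
    width_um: float = 2000.0  # lateral extent x
    elev_um: float = 1600.0  # elevational extent y
    line_pitch: float = 20.0  # µm
    frame_spacing: float = 200.0  # µm
    fs: float = 400e6  # Hz
    center_freq: float = 42e6  # Hz
    fractional_bandwidth: float = 0.4
    speed_of_sound: float = 1540.0  # m/s
    # the slab spans the full elevational extent (the scan samples an
    # interior band of the construct); in-plane margins leave dark
    # background for the total-mask segmentation
    tissue_z: tuple[float, float] = (300.0, 1500.0)  # µm
    tissue_x: tuple[float, float] = (200.0, 1800.0)
    tissue_y: tuple[float, float] = (0.0, 1600.0)
    scatterer_density: float = 30000.0  # per mm³ (fully developed speckle)
    amplitude_dist: str = "rayleigh"  # 'rayleigh' | 'uniform'
    voids: tuple[tuple[float, float, float, float, float, float, float], ...] = ()
    # each void: (cz, cx, cy, az, ax, ay, density_multiplier), µm
    lateral_sigma: float = 30.0  # µm, one-way lateral beam width
    elev_sigma: float = 60.0  # µm, elevational beam width
    noise_floor: float = 0.01  # additive noise sigma / tissue RF rms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be >= 0")
        for v in self.voids:
            cz, cx, cy, az, ax, ay, _ = v
            if not (
                0 <= cz - az and cz + az <= self.depth_um
                and 0 <= cx - ax and cx + ax <= self.width_um
                and 0 <= cy - ay and cy + ay <= self.elev_um
            ):
                raise ValueError("void ellipsoid extends outside the volume")

    @property
    def n_lines(self) -> int:
        return int(round(self.width_um / self.line_pitch))

    @property
    def n_frames(self) -> int:
        return int(round(self.elev_um / self.frame_spacing))

    @property
    def n_samples(self) -> int:
        return int(round(2 * self.depth_um * 1e-6 / self.speed_of_sound * self.fs))

    def tissue_volume_mm3(self) -> float:
        dz = self.tissue_z[1] - self.tissue_z[0]
        dx = self.tissue_x[1] - self.tissue_x[0]
        dy = self.tissue_y[1] - self.tissue_y[0]
        return dz * dx * dy * 1e-9

    def void_fraction_percent(self) -> float:
        """Analytic ground-truth void fraction of the tissue slab."""
        v = sum(
            4.0 / 3.0 * np.pi * az * ax * ay * 1e-9
            for (_, _, _, az, ax, ay, mult) in self.voids
            if mult == 0.0
        )
        return 100.0 * v / self.tissue_volume_mm3()

    def with_centered_void(self, fraction_percent: float) -> "RfPhantomSpec":
        """Spec with one centered ellipsoidal void of the given tissue
        fraction, semi-axes proportional to the tissue half-extents."""
        from dataclasses import replace

        if fraction_percent == 0:
            return replace(self, voids=())
        dz = self.tissue_z[1] - self.tissue_z[0]
        dx = self.tissue_x[1] - self.tissue_x[0]
        dy = self.tissue_y[1] - self.tissue_y[0]
        # ellipsoid with semi-axes s*(dz,dx,dy)/2: fraction = (pi/6) s^3
        s = (fraction_percent / 100.0 * 6.0 / np.pi) ** (1.0 / 3.0)
        if s >= 1.0:
            raise ValueError("void fraction too large for an inscribed ellipsoid")
        void = (
            0.5 * (self.tissue_z[0] + self.tissue_z[1]),
            0.5 * (self.tissue_x[0] + self.tissue_x[1]),
            0.5 * (self.tissue_y[0] + self.tissue_y[1]),
            0.5 * s * dz,
            0.5 * s * dx,
            0.5 * s * dy,
            0.0,
        )
        return replace(self, voids=(void,))


def _gabor_pulse(spec: RfPhantomSpec) -> np.ndarray:
    """Gaussian-enveloped tone at the transducer center frequency."""
    sigma_f = spec.fractional_bandwidth * spec.center_freq / 2.35482
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(4 * sigma_t * spec.fs))
    t = np.arange(-half, half + 1) / spec.fs
    return np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(2 * np.pi * spec.center_freq * t)


def gen_rf_phantom(spec: RfPhantomSpec) -> tuple[RFVolume, dict]:
    """Generate an RF frame stack and exact ground-truth masks.

    Scatterers are placed by a seeded uniform point process in the
    tissue slab; those falling inside a void ellipsoid are thinned by
    the void's density multiplier.  Each scatterer deposits its
    amplitude, weighted by Gaussian lateral/elevational beam profiles,
    at its two-way arrival sample on nearby A-lines of its nearest
    frame; frames are then convolved axially with the Gabor pulse and
    white noise is added at ``noise_floor`` times the tissue RF rms.

    Returns the RFVolume and a truth dict with the analytic void
    fraction and the tissue/void boolean masks voxelized on the scan
    grid (z: axial samples, x: lines, y: frames).
    """
    rng = np.random.default_rng([spec.seed, _LABEL_RF])
    n_s, n_l, n_f = spec.n_samples, spec.n_lines, spec.n_frames

    n_scat = rng.poisson(spec.scatterer_density * spec.tissue_volume_mm3())
    z = rng.uniform(spec.tissue_z[0], spec.tissue_z[1], n_scat)
    x = rng.uniform(spec.tissue_x[0], spec.tissue_x[1], n_scat)
    y = rng.uniform(spec.tissue_y[0], spec.tissue_y[1], n_scat)
    if spec.amplitude_dist == "rayleigh":
        amp = rng.rayleigh(1.0, n_scat)
    elif spec.amplitude_dist == "uniform":
        amp = rng.uniform(0.5, 1.5, n_scat)
    else:
        raise ValueError(f"unknown amplitude_dist {spec.amplitude_dist!r}")

    keep = np.ones(n_scat, dtype=bool)
    for cz, cx, cy, az, ax, ay, mult in spec.voids:
        inside = ((z - cz) / az) ** 2 + ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
        if mult <= 0:
            keep &= ~inside
        else:
            thin = rng.uniform(size=n_scat) < mult
            keep &= ~inside | thin
    z, x, y, amp = z[keep], x[keep], y[keep], amp[keep]

    # two-way arrival sample and frame/line assignment
    iz = np.round(2 * z * 1e-6 / spec.speed_of_sound * spec.fs).astype(int)
    ok = (iz >= 0) & (iz < n_s)
    z, x, y, amp, iz = z[ok], x[ok], y[ok], amp[ok], iz[ok]
    frame_pos = (np.arange(n_f) + 0.5) * spec.frame_spacing
    line_pos = (np.arange(n_l) + 0.5) * spec.line_pitch

    pulse = _gabor_pulse(spec)
    frames_rf = []
    for fi in range(n_f):
        w_e = np.exp(-0.5 * ((y - frame_pos[fi]) / spec.elev_sigma) ** 2)
        sel = w_e > 1e-3
        refl = np.zeros((n_s, n_l))
        if sel.any():
            xs, izs, amps, wes = x[sel], iz[sel], amp[sel] * w_e[sel], w_e[sel]
            il0 = np.floor(xs / spec.line_pitch - 0.5).astype(int)
            for doff in range(-2, 4):  # ±3-line lateral footprint
                il = il0 + doff
                valid = (il >= 0) & (il < n_l)
                w_l = np.exp(
                    -0.5 * ((xs[valid] - line_pos[il[valid]]) / spec.lateral_sigma) ** 2
                )
                np.add.at(refl, (izs[valid], il[valid]), amps[valid] * w_l)
        rf = fftconvolve(refl, pulse[:, None], mode="same")
        frames_rf.append(rf)

    rms = float(np.sqrt(np.mean(np.concatenate([f.ravel() for f in frames_rf]) ** 2)))
    noise_sigma = spec.noise_floor * (rms if rms > 0 else 1.0)
    frames = [
        RFFrame(
            rf + rng.normal(0.0, noise_sigma, size=rf.shape),
            fs=spec.fs,
            line_pitch=spec.line_pitch,
            frame_index=i,
        )
        for i, rf in enumerate(frames_rf)
    ]
    vol = RFVolume(frames, frame_spacing=spec.frame_spacing)

    # voxelized truth on the scan grid (frames, samples, lines)
    zz = (np.arange(n_s) + 0.5) / spec.fs * spec.speed_of_sound / 2 * 1e6
    tissue = np.zeros((n_f, n_s, n_l), dtype=bool)
    voidm = np.zeros_like(tissue)
    Z = zz[None, :, None]
    X = line_pos[None, None, :]
    Y = frame_pos[:, None, None]
    tissue |= (
        (Z >= spec.tissue_z[0]) & (Z <= spec.tissue_z[1])
        & (X >= spec.tissue_x[0]) & (X <= spec.tissue_x[1])
        & (Y >= spec.tissue_y[0]) & (Y <= spec.tissue_y[1])
    )
    for cz, cx, cy, az, ax, ay, mult in spec.voids:
        if mult == 0.0:
            voidm |= ((Z - cz) / az) ** 2 + ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0
    voidm &= tissue
    truth = {
        "void_fraction_percent": spec.void_fraction_percent(),
        "tissue_mask": tissue,
        "void_mask": voidm,
        "mask_voxel_size": (
            spec.speed_of_sound / (2 * spec.fs) * 1e6,
            spec.line_pitch,
            spec.frame_spacing,
        ),
    }
    return vol, truth


# ---------------------------------------------------------------------------
# mechanics


def gen_stress_relaxation(
    p: BiphasicParams,
    proto: RampHoldProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_points: int = 400,
) -> StressRecord:
    """Synthetic stress-relaxation record: forward model plus
    multiplicative Gaussian noise of relative SD ``noise_sigma``."""
    t = proto.time_grid(n_points)
    sigma = biphasic_forward(p, proto, t)
    if noise_sigma > 0:
        rng = np.random.default_rng([seed, _LABEL_MECH])
        sigma = sigma * (1.0 + rng.normal(0.0, noise_sigma, size=sigma.shape))
    return StressRecord(t, sigma)


# ---------------------------------------------------------------------------
# linked optical/destructive dataset


@dataclass(frozen=True)
class LinkedDatasetSpec:
    """Spec for a matched non-destructive / destructive sample table.

    Per-channel lifetimes are drawn from Gaussians; biochemistry and
    moduli are generated through linear links plus Gaussian noise.  The
    default noise SDs put the population R² of each link near 0.7,
    matching the strength of correlation such calibrations typically
    show.
    """

    n_samples: int = 6  # per treatment group
    timepoints: tuple[int, ...] = (7, 14, 21, 28)
    treatments: tuple[str, ...] = ("CTL", "TGF", "LAP")
    ch2_mean: float = 4.0  # ns
    ch2_sd: float = 0.35
    ch3_mean: float = 4.5  # ns
    ch3_sd: float = 0.35
    slope_collagen: float = 2.0  # %ww per ns (CH2 → collagen)
    intercept_collagen: float = 1.0
    slope_gag: float = 1.5  # %ww per ns (CH3 → GAG)
    intercept_gag: float = 0.5
    slope_modulus: float = 150.0  # kPa per ns (CH3 → compressive modulus)
    intercept_modulus: float = 50.0
    noise_collagen: float = 0.458  # SDs giving population R² ≈ 0.7
    noise_gag: float = 0.344
    noise_modulus: float = 34.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples * len(self.treatments) * len(self.timepoints) < 3:
            raise ValueError("need at least 3 rows")
        for s in (self.noise_collagen, self.noise_gag, self.noise_modulus):
            if s < 0:
                raise ValueError("noise SDs must be non-negative")


def gen_linked_dataset(spec: LinkedDatasetSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a linked-sample table and its generating truth.

    Returns a tidy DataFrame (sample_id, timepoint, group, ch2_lt,
    ch3_lt, collagen_ww, gag_ww, compressive_modulus) and a dict of the
    generating slopes/intercepts/noise SDs.
    """
    rng = np.random.default_rng([spec.seed, _LABEL_LINKED])
    rows = []
    for g in spec.treatments:
        for s in range(spec.n_samples):
            for day in spec.timepoints:
                ch2 = rng.normal(spec.ch2_mean, spec.ch2_sd)
                ch3 = rng.normal(spec.ch3_mean, spec.ch3_sd)
                ch2, ch3 = abs(ch2), abs(ch3)  # lifetimes are positive
                col = spec.slope_collagen * ch2 + spec.intercept_collagen
                gag = spec.slope_gag * ch3 + spec.intercept_gag
                mod = spec.slope_modulus * ch3 + spec.intercept_modulus
                if spec.noise_collagen > 0:
                    col += rng.normal(0, spec.noise_collagen)
                if spec.noise_gag > 0:
                    gag += rng.normal(0, spec.noise_gag)
                if spec.noise_modulus > 0:
                    mod += rng.normal(0, spec.noise_modulus)
                rows.append(
                    {
                        "sample_id": f"{g}-{s:02d}",
                        "timepoint": day,
                        "group": g,
                        "ch2_lt": ch2,
                        "ch3_lt": ch3,
                        "collagen_ww": col,
                        "gag_ww": gag,
                        "compressive_modulus": mod,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "slope_collagen": spec.slope_collagen,
        "intercept_collagen": spec.intercept_collagen,
        "slope_gag": spec.slope_gag,
        "intercept_gag": spec.intercept_gag,
        "slope_modulus": spec.slope_modulus,
        "intercept_modulus": spec.intercept_modulus,
        "noise": {
            "collagen": spec.noise_collagen,
            "gag": spec.noise_gag,
            "modulus": spec.noise_modulus,
        },
    }
    return table, truth
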