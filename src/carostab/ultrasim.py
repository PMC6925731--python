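"""Synthetic B-mode sequences with known wall motion and known rigid disturbance.

The simulator is a 2D convolutional speckle model: a persistent population of
random sub-resolution scatterers (positions in mm, echo amplitudes taken from
a tissue template and vessel-wall layer multipliers) is splatted onto the
pixel grid, convolved with an axially oscillating / laterally smooth complex
point-spread function, envelope-detected and log-compressed.  Fully developed
speckle emerges from the random scatterer phases; partial frame-to-frame
speckle decorrelation is produced by a per-frame elevational jitter of the
scatterers weighted by an elevational beam profile, emulating the strong
frame-to-frame speckle turnover of independently regenerated phantoms while
keeping the macro structure of the scene.

Per frame, wall-band scatterers move with the pulsating wall (tissue far from
the wall stays put), then the frame's global rigid disturbance — the
common-mode signal registration must recover — is applied to *all*
scatterers before rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import ArgumentError, ImageSequence, MotionTrajectory, RigidDisturbance

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScattererSet:
    """Random scatterer phantom: positions (mm) and echo amplitudes.

    ``positions`` has shape (n, 3): (row_mm, col_mm, elev_mm).  The
    population is persistent over a sequence; only positions move.
    """

    positions: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ArgumentError("positions must be an (n, 3) array")
        if self.amplitudes.shape != (self.positions.shape[0],):
            raise ArgumentError("one amplitude per scatterer required")
        if np.any(self.amplitudes < 0):
            raise ArgumentError("amplitudes must be nonnegative")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class WallModel:
    """Horizontal two-interface vessel wall in longitudinal section.

    The lumen is a band of half-width ``radius_mm`` around ``center_row_mm``;
    the wall layers (intima, media, adventitia) sit symmetrically on both
    sides with the given thicknesses and echogenicity multipliers.  The wall
    axis undulates gently along the vessel (amplitude
    ``undulation_amp_mm``): real carotid walls are never perfectly straight,
    and the resulting interface geometry is what anchors longitudinal block
    matching at the macro level.
    """

    center_row_mm: float
    radius_mm: float
    thicknesses_mm: tuple = (0.10, 0.25, 0.40)
    layer_multipliers: tuple = (1.5, 0.5, 1.7)
    lumen_multiplier: float = 0.02
    undulation_amp_mm: float = 0.12
    undulation_wavelength_mm: float = 2.5
    undulation_phase: float = 0.7

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ArgumentError("lumen radius must be positive")
        if any(t <= 0 for t in self.thicknesses_mm):
            raise ArgumentError("layer thicknesses must be positive")

    @property
    def outer_radius_mm(self) -> float:
        return self.radius_mm + sum(self.thicknesses_mm)

    @property
    def outer_reach_mm(self) -> float:
        """Largest distance from the nominal axis to the outer wall."""
        return self.outer_radius_mm + self.undulation_amp_mm

    def center_at(self, col_mm: np.ndarray) -> np.ndarray:
        """Row position of the (undulating) vessel axis at each column."""
        return (self.center_row_mm + self.undulation_amp_mm
                * np.sin(2.0 * np.pi * np.asarray(col_mm, dtype=float)
                         / self.undulation_wavelength_mm
                         + self.undulation_phase))

    def axis_distance(self, row_mm: np.ndarray, col_mm: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(row_mm, dtype=float) - self.center_at(col_mm))

    def multiplier(self, row_mm: np.ndarray, col_mm: np.ndarray = 0.0) -> np.ndarray:
        """Echogenicity multiplier at a scatterer position."""
        d = self.axis_distance(row_mm, col_mm)
        out = np.ones_like(d)
        out[d < self.radius_mm] = self.lumen_multiplier
        lo = self.radius_mm
        for t, m in zip(self.thicknesses_mm, self.layer_multipliers):
            sel = (d >= lo) & (d < lo + t)
            out[sel] = m
            lo += t
        return out


@dataclass
class RenderConfig:
    """Rendering parameters of the convolutional speckle model.

    The PSF is a complex kernel: Gaussian envelope (axial/lateral std in mm)
    modulated axially at wavelength ``psf_lambda_mm`` (0.308 mm = 5 MHz pulse
    at 1540 m/s); the envelope image is its magnitude response.  Output is
    log-compressed over ``dynamic_range_db`` into ``bit_depth`` bits.
    """

    shape: tuple = (200, 192)
    pixel_spacing_mm: float = 0.05
    psf_lambda_mm: float = 0.308
    psf_sigma_ax_mm: float = 0.15
    psf_sigma_lat_mm: float = 0.30
    elev_sigma_mm: float = 0.50
    dynamic_range_db: float = 50.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixel_spacing_mm <= 0:
            raise ArgumentError("pixel spacing must be positive")
        if self.dynamic_range_db <= 0:
            raise ArgumentError("dynamic range must be positive")

    @property
    def extent_mm(self) -> tuple:
        return (self.shape[0] * self.pixel_spacing_mm,
                self.shape[1] * self.pixel_spacing_mm)

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1


# ---------------------------------------------------------------------------
# ground-truth signal generators
# ---------------------------------------------------------------------------


def make_wall_trajectory(n_frames: int, duration_s: float, n_cardiac_cycles: int,
                         amp_rad_mm: float = 0.35,
                         amp_long_mm: float = 0.25) -> MotionTrajectory:
    """Smooth pulsatile wall motion: n_cardiac_cycles distension pulses.

    The radial component is a sin^4 pulse train (one peak per cardiac cycle,
    returning to baseline at each cycle end); the longitudinal component is a
    zero-mean forward/backward excursion within each cycle.  The trajectory
    describes the displacement of the tracked (deep) wall: positive radial
    values move it away from the lumen centre, i.e. toward increasing row.
    """
    if n_frames < 2:
        raise ArgumentError("need at least 2 frames")
    if n_cardiac_cycles < 1:
        raise ArgumentError("need at least one cardiac cycle")
    if duration_s <= 0:
        raise ArgumentError("duration must be positive")
    if amp_rad_mm < 0 or amp_long_mm < 0:
        raise ArgumentError("amplitudes must be nonnegative")
    t = np.arange(n_frames) * (duration_s / n_frames)
    phase = np.pi * n_cardiac_cycles * t / duration_s
    d_rad = amp_rad_mm * np.sin(phase) ** 4
    d_long = amp_long_mm * np.sin(2.0 * phase) * np.sin(phase) ** 2
    return MotionTrajectory(d_long, d_rad, t)


def make_disturbance(n_frames: int, duration_s: float,
                     drift_amp=(0.8, 0.35, 1.2),
                     glitch_rate: float = 2.5,
                     glitch_amp=(0.35, 0.20, 0.60),
                     seed: int | None = None) -> RigidDisturbance:
    """Global rigid disturbance: smooth respiratory drift plus probe-jitter glitches.

    ``drift_amp`` and ``glitch_amp`` are per-component amplitudes
    (longitudinal mm, radial mm, rotation deg); scalars broadcast.  The drift
    spans one respiratory cycle over ``duration_s``; glitches are sparse
    short Gaussian bumps with Poisson(glitch_rate * duration) count,
    random sign and random sub-0.05 s width.  Deterministic per seed.
    """
    if seed is None:
        raise ArgumentError("a seed is required for reproducibility")
    if n_frames < 2 or duration_s <= 0:
        raise ArgumentError("need >= 2 frames and positive duration")
    drift_amp = np.broadcast_to(np.asarray(drift_amp, dtype=float), (3,)).copy()
    glitch_amp = np.broadcast_to(np.asarray(glitch_amp, dtype=float), (3,)).copy()
    if glitch_rate < 0 or np.any(drift_amp < 0) or np.any(glitch_amp < 0):
        raise ArgumentError("rates and amplitudes must be nonnegative")

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * (duration_s / n_frames)
    u = t / duration_s  # one respiratory cycle
    s1 = np.sin(np.pi * u) ** 2          # = (1 - cos 2 pi u) / 2
    s2 = np.sin(2.0 * np.pi * u) ** 2
    curves = np.stack([
        drift_amp[0] * s1,
        drift_amp[1] * (0.7 * s1 + 0.3 * s2),
        drift_amp[2] * (0.8 * s1 - 0.2 * np.sin(2.0 * np.pi * u)),
    ])

    n_glitches = int(rng.poisson(glitch_rate * duration_s))
    for _ in range(n_glitches):
        t0 = rng.uniform(0.05 * duration_s, 0.95 * duration_s)
        width = rng.uniform(0.015, 0.040)
        bump = np.exp(-0.5 * ((t - t0) / width) ** 2)
        for comp in range(3):
            scale = rng.uniform(0.5, 1.0) * glitch_amp[comp]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            curves[comp] += sign * scale * bump

    curves -= curves[:, :1]  # frame 1 exactly (0, 0, 0)
    return RigidDisturbance(curves[0], curves[1], curves[2], t,
                            n_glitches=n_glitches)


# ---------------------------------------------------------------------------
# phantom construction and rendering
# ---------------------------------------------------------------------------


def make_tissue_template(shape: tuple, seed: int, base: float = 0.55,
                         contrast: float = 0.30, blob_sigma_px: float = 14.0,
                         band_rows=(0.10, 0.16, 0.24, 0.78, 0.86, 0.93),
                         band_gain: float = 0.55,
                         n_reflectors: int = 6) -> np.ndarray:
    """Synthetic echogenicity map of peri-vascular tissue.

    The far-from-wall bands must carry the abundant structural and geometric
    information real neck tissue has — layered fascia at slightly oblique
    angles, muscle texture, small bright fibrous reflectors — because the
    disturbance registration anchors on exactly that.  The map combines
    smooth random blobs (low-pass-filtered noise), fascia-like streaks with
    random small tilts and thicknesses, and compact bright reflectors.
    Values in (0, 1].
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    blobs = ndimage.gaussian_filter(rng.standard_normal(shape), blob_sigma_px)
    blobs /= max(np.abs(blobs).max(), 1e-12)
    template = base + contrast * blobs
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    for frac in band_rows:
        # fascia sheets: nearly uniform brightness along the vessel (tissue
        # is longitudinally homogeneous in echo), but geometrically tilted
        # and undulating — the longitudinal information is in the geometry
        r0 = frac * (rows - 1)
        slope = rng.uniform(-0.12, 0.12)          # up to ~7 deg tilt
        bend_amp = rng.uniform(1.0, 3.0)
        bend_cycles = rng.uniform(0.8, 2.0)
        centre = (r0 + slope * (c - cols / 2.0)
                  + bend_amp * np.sin(2 * np.pi * bend_cycles * c / cols
                                      + rng.uniform(0, 2 * np.pi)))
        width = rng.uniform(1.0, 2.5)
        profile = np.exp(-0.5 * ((r - centre) / width) ** 2)
        along = 1.0 + 0.15 * ndimage.gaussian_filter1d(
            rng.standard_normal(cols), 25.0) / 0.2
        template += band_gain * rng.uniform(0.7, 1.2) * profile \
            * np.clip(along, 0.5, 1.5)
    # a few compact bright reflectors (fibrous nodes / small vessel walls)
    for _ in range(n_reflectors):
        rr = rng.uniform(0.05, 0.95) * rows
        cc = rng.uniform(0.05, 0.95) * cols
        sr = rng.uniform(1.0, 2.5)
        sc = rng.uniform(2.0, 6.0)
        template += rng.uniform(0.2, 0.45) * np.exp(
            -0.5 * (((r - rr) / sr) ** 2 + ((c - cc) / sc) ** 2))
    return np.clip(template, 0.05, 1.0)


def make_phantom(template, wall_model: WallModel | None, n_scatterers: int,
                 seed: int, pixel_spacing_mm: float = 0.05,
                 extent_mm: tuple | None = None, margin_mm: float = 1.5,
                 elev_halfwidth_mm: float = 1.0,
                 wall_long_mod: float = 0.5,
                 wall_long_scale_mm: float = 0.8) -> ScattererSet:
    """Draw a persistent scatterer population over the imaged slab.

    Positions are uniform over the slab (image extent plus ``margin_mm`` on
    every side so motion never drags empty space into view); each scatterer's
    amplitude is the template gray level at its initial position times the
    wall-layer multiplier.  ``template`` may be a 2D gray image (sampled
    bilinearly, indexed by ``pixel_spacing_mm``) or a scalar for a flat slab
    (then ``extent_mm`` = (rows_mm, cols_mm) is required).

    Wall-layer echogenicity is additionally modulated along the vessel axis
    (relative amplitude ``wall_long_mod``, correlation length
    ``wall_long_scale_mm``): real intima/media/adventitia are longitudinally
    heterogeneous, and this is what lets block matching discriminate
    longitudinal lags at the macro-texture level.
    """
    if n_scatterers < 1:
        raise ArgumentError("need at least one scatterer")
    if np.isscalar(template):
        if extent_mm is None:
            raise ArgumentError("extent_mm is required for a flat template")
        flat_value = float(template)
        template_arr = None
    else:
        template_arr = np.asarray(template, dtype=float)
        if template_arr.size == 0:
            raise ArgumentError("template image is empty")
        if extent_mm is None:
            extent_mm = (template_arr.shape[0] * pixel_spacing_mm,
                         template_arr.shape[1] * pixel_spacing_mm)

    rng = np.random.default_rng(seed)
    rows_mm, cols_mm = extent_mm
    r = rng.uniform(-margin_mm, rows_mm + margin_mm, n_scatterers)
    c = rng.uniform(-margin_mm, cols_mm + margin_mm, n_scatterers)
    e = rng.uniform(-elev_halfwidth_mm, elev_halfwidth_mm, n_scatterers)

    if template_arr is None:
        amp = np.full(n_scatterers, flat_value)
    else:
        coords = np.vstack([r / pixel_spacing_mm, c / pixel_spacing_mm])
        amp = ndimage.map_coordinates(template_arr, coords, order=1,
                                      mode="nearest")
    if wall_model is not None:
        amp = amp * wall_model.multiplier(r, c)
        if wall_long_mod > 0:
            d = wall_model.axis_distance(r, c)
            in_wall = ((d >= wall_model.radius_mm)
                       & (d < wall_model.outer_radius_mm))
            n_knots = max(4, int(np.ceil((cols_mm + 2 * margin_mm)
                                         / wall_long_scale_mm)) + 3)
            knots = rng.standard_normal(n_knots)
            grid = np.linspace(-margin_mm, cols_mm + margin_mm, n_knots)
            mod = np.interp(c, grid, knots)
            mod = mod / max(np.abs(knots).max(), 1e-12)
            amp = np.where(in_wall, amp * (1.0 + wall_long_mod * mod), amp)
    return ScattererSet(np.column_stack([r, c, e]), np.clip(amp, 0.0, None))


def _psf_kernel(config: RenderConfig) -> np.ndarray:
    """Complex PSF: Gaussian envelope, axial carrier exp(2j pi r / lambda)."""
    s = config.pixel_spacing_mm
    nr = int(np.ceil(4.0 * config.psf_sigma_ax_mm / s))
    nc = int(np.ceil(4.0 * config.psf_sigma_lat_mm / s))
    r = (np.arange(-nr, nr + 1) * s)[:, None]
    c = (np.arange(-nc, nc + 1) * s)[None, :]
    envelope = np.exp(-0.5 * (r / config.psf_sigma_ax_mm) ** 2
                      - 0.5 * (c / config.psf_sigma_lat_mm) ** 2)
    return envelope * np.exp(2j * np.pi * r / config.psf_lambda_mm)


def _splat(scatterers: ScattererSet, config: RenderConfig) -> np.ndarray:
    """Bilinear deposition of elevation-weighted amplitudes on the pixel grid."""
    rows, cols = config.shape
    s = config.pixel_spacing_mm
    r = scatterers.positions[:, 0] / s
    c = scatterers.positions[:, 1] / s
    w = scatterers.amplitudes * np.exp(
        -0.5 * (scatterers.positions[:, 2] / config.elev_sigma_mm) ** 2)
    inside = (r > -1) & (r < rows) & (c > -1) & (c < cols)
    r, c, w = r[inside], c[inside], w[inside]
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    grid = np.zeros((rows + 2, cols + 2))
    np.add.at(grid, (r0 + 1, c0 + 1), w * (1 - fr) * (1 - fc))
    np.add.at(grid, (r0 + 2, c0 + 1), w * fr * (1 - fc))
    np.add.at(grid, (r0 + 1, c0 + 2), w * (1 - fr) * fc)
    np.add.at(grid, (r0 + 2, c0 + 2), w * fr * fc)
    return grid[1:rows + 1, 1:cols + 1]


def render_envelope(scatterers: ScattererSet, config: RenderConfig) -> np.ndarray:
    """Pre-compression echo envelope (magnitude of the complex RF image)."""
    rf = signal.fftconvolve(_splat(scatterers, config), _psf_kernel(config),
                            mode="same")
    return np.abs(rf)


def log_compress(envelope: np.ndarray, config: RenderConfig,
                 ref: float | None = None) -> np.ndarray:
    """Map the envelope to display levels over the configured dynamic range."""
    envelope = np.asarray(envelope, dtype=float)
    if ref is None:
        ref = envelope.max()
    if ref <= 0:  # no echo at all -> uniform minimum
        return np.zeros(envelope.shape, dtype=np.uint8 if config.bit_depth <= 8
                        else np.uint16)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(envelope / ref)
    level = np.clip((db + config.dynamic_range_db) / config.dynamic_range_db,
                    0.0, 1.0) * config.max_intensity
    dtype = np.uint8 if config.bit_depth <= 8 else np.uint16
    return np.round(level).astype(dtype)


def render_bmode(scatterers: ScattererSet, config: RenderConfig,
                 ref: float | None = None) -> np.ndarray:
    """Log-compressed B-mode frame of a scatterer set."""
    return log_compress(render_envelope(scatterers, config), config, ref=ref)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def wall_weight(row_mm: np.ndarray, col_mm: np.ndarray,
                wall_model: WallModel, taper_mm: float = 0.5) -> np.ndarray:
    """Fraction of the wall displacement a scatterer receives.

    1 inside the vessel band (lumen + layers), linearly tapering to 0 over
    ``taper_mm`` beyond the outer wall so far tissue stays put.
    """
    d = wall_model.axis_distance(row_mm, col_mm)
    outer = wall_model.outer_radius_mm
    return np.clip(1.0 - (d - outer) / taper_mm, 0.0, 1.0)


def simulate_sequence(scatterers: ScattererSet, wall_model: WallModel | None,
                      trajectory: MotionTrajectory,
                      disturbance: RigidDisturbance,
                      config: RenderConfig, seed: int,
                      elev_jitter_mm: float = 0.25,
                      taper_mm: float = 0.5):
    """Render a sequence: wall motion on wall-band scatterers, rigid disturbance on all.

    Per frame k the wall-band scatterers move by the trajectory (radial
    displacement is mirrored across the lumen centre so the vessel distends;
    the trajectory itself is the displacement of the deep wall), then the
    frame's rigid disturbance rotates (about the image centre) and shifts
    *all* scatterers, then a fresh elevational jitter decorrelates the
    speckle and the frame is rendered.  Returns
    ``(ImageSequence, trajectory, disturbance)`` with the ground truths
    passed through unchanged.
    """
    if trajectory.n_frames != disturbance.n_frames:
        raise ArgumentError("trajectory and disturbance must have equal frame counts")
    n = trajectory.n_frames
    rng = np.random.default_rng(seed)
    s = config.pixel_spacing_mm
    centre = np.array([(config.shape[0] - 1) * s / 2.0,
                       (config.shape[1] - 1) * s / 2.0])
    base = scatterers.positions
    if wall_model is not None:
        weight = wall_weight(base[:, 0], base[:, 1], wall_model, taper_mm)
        rad_sign = np.sign(base[:, 0] - wall_model.center_at(base[:, 1]))
        rad_sign[rad_sign == 0] = 1.0
    else:
        weight = np.zeros(scatterers.n)
        rad_sign = np.ones(scatterers.n)

    frames = np.empty((n,) + tuple(config.shape), dtype=np.uint8
                      if config.bit_depth <= 8 else np.uint16)
    ref = None
    dt = trajectory.times_s[1] - trajectory.times_s[0] if n > 1 else 1.0
    for k in range(n):
        pos = base[:, :2].copy()
        pos[:, 0] += weight * rad_sign * trajectory.d_rad_mm[k]
        pos[:, 1] += weight * trajectory.d_long_mm[k]
        R = _rotation_matrix(disturbance.theta_deg[k])
        t = np.array([disturbance.d_rad_mm[k], disturbance.d_long_mm[k]])
        pos = (pos - centre) @ R.T + centre + t
        elev = base[:, 2] + rng.normal(0.0, elev_jitter_mm, scatterers.n)
        moved = ScattererSet(np.column_stack([pos, elev]),
                             scatterers.amplitudes)
        env = render_envelope(moved, config)
        if ref is None:
            ref = env.max()
        frames[k] = log_compress(env, config, ref=ref)
    seq = ImageSequence(frames, config.pixel_spacing_mm, float(dt))
    return seq, trajectory, disturbance


# ---------------------------------------------------------------------------
# study profiles
# ---------------------------------------------------------------------------


@dataclass
class SimProfile:
    """Named set of simulation conditions for the synthetic study."""

    name: str = "default"
    n_frames: int = 200
    duration_s: float = 3.2
    n_cardiac_cycles: int = 4
    shape: tuple = (280, 256)
    pixel_spacing_mm: float = 0.05
    wall_center_row_mm: float = 7.0
    lumen_radius_mm: float = 1.25
    amp_rad_mm: float = 0.35
    amp_long_mm: float = 0.25
    drift_amp: tuple = (0.8, 0.35, 1.2)
    glitch_rate: float = 2.5
    glitch_amp: tuple = (0.35, 0.20, 0.60)
    scatterer_density_per_mm2: float = 300.0
    elev_jitter_mm: float = 0.25
    taper_mm: float = 0.5
    wall_thicknesses_mm: tuple = (0.10, 0.25, 0.40)

    def wall_model(self) -> WallModel:
        return WallModel(self.wall_center_row_mm, self.lumen_radius_mm,
                         self.wall_thicknesses_mm)

    def render_config(self) -> RenderConfig:
        return RenderConfig(shape=self.shape,
                            pixel_spacing_mm=self.pixel_spacing_mm)

    def n_scatterers(self, margin_mm: float = 1.5) -> int:
        rows_mm = self.shape[0] * self.pixel_spacing_mm + 2 * margin_mm
        cols_mm = self.shape[1] * self.pixel_spacing_mm + 2 * margin_mm
        return int(self.scatterer_density_per_mm2 * rows_mm * cols_mm)


PROFILES = {
    "default": SimProfile(),
    "fast": SimProfile(
        name="fast", n_frames=64, shape=(224, 192),
        wall_center_row_mm=5.6, lumen_radius_mm=0.9,
        wall_thicknesses_mm=(0.10, 0.20, 0.30), taper_mm=0.4,
        drift_amp=(0.5, 0.25, 0.8), glitch_amp=(0.30, 0.15, 0.50),
        scatterer_density_per_mm2=250.0,
    ),
    # minimal profile for smoke tests
    "tiny": SimProfile(
        name="tiny", n_frames=8, shape=(100, 80),
        wall_center_row_mm=2.4, lumen_radius_mm=0.55,
        wall_thicknesses_mm=(0.08, 0.12, 0.20), taper_mm=0.25,
        amp_rad_mm=0.2, amp_long_mm=0.15,
        drift_amp=(0.3, 0.15, 0.5), glitch_amp=(0.15, 0.10, 0.3),
        scatterer_density_per_mm2=250.0,
    ),
}


def simulate_dataset(profile="default", seed: int = 0,
                     with_clean: bool = True) -> dict:
    """Simulate the full study input: disturbed sequence, ground truths, and
    (optionally) the matched disturbance-free rendering of the same phantom.

    The clean and disturbed sequences share the scatterer population and the
    per-frame elevational jitter draws, so they differ only by the rigid
    disturbance.
    """
    prof = PROFILES[profile] if isinstance(profile, str) else profile
    ss = np.random.SeedSequence(seed)
    seed_template, seed_phantom, seed_dist, seed_jitter = ss.spawn(4)

    template = make_tissue_template(prof.shape,
                                    seed_template.generate_state(1)[0] % 2**31)
    wall = prof.wall_model()
    render = prof.render_config()
    phantom = make_phantom(template, wall, prof.n_scatterers(),
                           seed_phantom.generate_state(1)[0] % 2**31,
                           pixel_spacing_mm=prof.pixel_spacing_mm)
    motion = make_wall_trajectory(prof.n_frames, prof.duration_s,
                                  prof.n_cardiac_cycles, prof.amp_rad_mm,
                                  prof.amp_long_mm)
    disturbance = make_disturbance(prof.n_frames, prof.duration_s,
                                   prof.drift_amp, prof.glitch_rate,
                                   prof.glitch_amp,
                                   seed=seed_dist.generate_state(1)[0] % 2**31)
    jseed = seed_jitter.generate_state(1)[0] % 2**31
    seq, _, _ = simulate_sequence(phantom, wall, motion, disturbance, render,
                                  seed=jseed, elev_jitter_mm=prof.elev_jitter_mm,
                                  taper_mm=prof.taper_mm)
    out = {"profile": prof, "template": template, "phantom": phantom,
           "wall_model": wall, "render_config": render,
           "sequence": seq, "motion": motion, "disturbance": disturbance}
    if with_clean:
        zero = RigidDisturbance.zeros(motion.times_s)
        clean, _, _ = simulate_sequence(phantom, wall, motion, zero, render,
                                        seed=jseed,
                                        elev_jitter_mm=prof.elev_jitter_mm,
                                        taper_mm=prof.taper_mm)
        out["clean_sequence"] = clean
    return out
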