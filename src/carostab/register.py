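"""Rigid registration of far-from-wall subimages and sequence alignment.

The probe/breathing disturbance is common-mode: it moves the whole image,
while the wall's own motion is confined to the vessel band.  Two horizontal
subimage bands far from the wall (top and bottom of each frame) therefore see
only the disturbance.  Each band of frame k is rigidly registered against the
same band of frame 1 on a feature surface (intensity, phase, orientation or
the confidence-combined image); the upper and lower estimates are averaged —
which also cancels the translation each band picks up from rotation about the
image centre — and every frame is resampled through the inverse transform.

Registration maximizes the normalized cross-correlation over rigid
transforms in two stages: a coarse rotation grid with exhaustive integer
translation search per angle, then a derivative-free local refinement with
bilinear interpolation, scoring overlap pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal

from .core import (ArgumentError, DegenerateInputError, ImageSequence,
                   RigidDisturbance)
from . import monogenic, srad

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SubimageSpec:
    """Horizontal bands (fractions of the frame height) used for registration."""

    upper_frac: float = 0.30
    lower_frac: float = 0.30
    wall_band: tuple | None = None  # (first_row, last_row) excluded rows

    def band_slices(self, n_rows: int) -> tuple:
        upper_rows = int(np.floor(self.upper_frac * n_rows))
        lower_rows = int(np.floor(self.lower_frac * n_rows))
        if upper_rows < 2 or lower_rows < 2:
            raise ArgumentError("subimage bands must be at least 2 rows tall")
        upper = slice(0, upper_rows)
        lower = slice(n_rows - lower_rows, n_rows)
        if self.wall_band is not None:
            w0, w1 = self.wall_band
            if upper.stop > w0 or lower.start < w1 + 1:
                raise ArgumentError("subimage bands overlap the wall band")
        return upper, lower


@dataclass
class RigidTransform:
    """Rigid transform in pixel/degree units; pivot = image (subimage) centre."""

    d_col: float = 0.0
    d_row: float = 0.0
    theta_deg: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.d_col, self.d_row, self.theta_deg])


@dataclass
class SearchBounds:
    """Search bounds of the rigid registration (px / deg)."""

    shift_row: float = 30.0
    shift_col: float = 30.0
    theta: float = 5.0
    theta_step: float = 0.5


@dataclass
class RegistrationResult:
    """Per-frame registration output: band transforms and their average."""

    upper: RigidTransform
    lower: RigidTransform
    averaged: RigidTransform
    score_upper: float
    score_lower: float


# ---------------------------------------------------------------------------
# rigid warps
# ---------------------------------------------------------------------------


def _rot(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def apply_rigid(image: np.ndarray, transform: RigidTransform,
                order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Move image content by the transform: p' = R (p - c) + c + t."""
    image = np.asarray(image, dtype=float)
    c = (np.array(image.shape) - 1) / 2.0
    R = _rot(transform.theta_deg)
    t = np.array([transform.d_row, transform.d_col])
    return ndimage.affine_transform(image, R.T, offset=c - R.T @ (c + t),
                                    order=order, cval=cval)


def unapply_rigid(image: np.ndarray, transform: RigidTransform,
                  order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample through the inverse transform: undoes :func:`apply_rigid`."""
    image = np.asarray(image, dtype=float)
    c = (np.array(image.shape) - 1) / 2.0
    R = _rot(transform.theta_deg)
    t = np.array([transform.d_row, transform.d_col])
    return ndimage.affine_transform(image, R, offset=c + t - R @ c,
                                    order=order, cval=cval)


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    n = int(mask.sum())
    if n < 16:
        return -np.inf
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    den = np.sqrt((av**2).sum() * (bv**2).sum())
    if den == 0:
        return -np.inf
    return float((av * bv).sum() / den)


def ncc_score(ref: np.ndarray, flt: np.ndarray,
              transform: RigidTransform) -> float:
    """Overlap-only NCC between ref and the float warped back by the transform."""
    warped = unapply_rigid(flt, transform)
    valid = unapply_rigid(np.ones_like(np.asarray(flt, dtype=float)), transform)
    mask = valid > 0.999
    return _masked_ncc(np.asarray(ref, dtype=float), warped, mask)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def _integral(img: np.ndarray) -> np.ndarray:
    out = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=out[1:, 1:])
    return out


def translation_ncc_map(ref: np.ndarray, flt: np.ndarray,
                        max_row: int, max_col: int,
                        origin: tuple = (0, 0)) -> np.ndarray:
    """Exact overlap-normalized cross-correlation over an integer-shift grid.

    ``flt`` is a (possibly cropped) image whose pixel (0, 0) nominally sits
    at ``origin`` in ``ref`` coordinates.  Entry (a + max_row, b + max_col)
    of the returned map is the NCC between ``flt`` and the region of ``ref``
    it covers when its content is displaced by (a, b), normalized over the
    actual overlap only (the statistics come from integral images, the cross
    term from one FFT correlation).  Non-overlapping or flat placements
    score -inf.
    """
    ref = np.asarray(ref, dtype=float)
    flt = np.asarray(flt, dtype=float)
    R, C = ref.shape
    r, c = flt.shape
    o0, o1 = origin
    # cross-correlation: xc[k, l] = sum_{i,j} flt[i,j] * ref[i+k, j+l]
    full = signal.fftconvolve(ref, flt[::-1, ::-1], mode="full")
    ii_ref = _integral(ref)
    ii_ref2 = _integral(ref**2)
    ii_flt = _integral(flt)
    ii_flt2 = _integral(flt**2)

    def rect(ii, r0, r1, c0, c1):
        return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]

    out = np.full((2 * max_row + 1, 2 * max_col + 1), -np.inf)
    for ai, a in enumerate(range(-max_row, max_row + 1)):
        fr0 = max(0, -(o0 + a))
        fr1 = min(r, R - o0 - a)
        if fr1 - fr0 < 2:
            continue
        for bi, b in enumerate(range(-max_col, max_col + 1)):
            fc0 = max(0, -(o1 + b))
            fc1 = min(c, C - o1 - b)
            if fc1 - fc0 < 2:
                continue
            rr0, rc0 = fr0 + o0 + a, fc0 + o1 + b
            rr1, rc1 = fr1 + o0 + a, fc1 + o1 + b
            n = (fr1 - fr0) * (fc1 - fc0)
            s_f = rect(ii_flt, fr0, fr1, fc0, fc1)
            s_f2 = rect(ii_flt2, fr0, fr1, fc0, fc1)
            s_r = rect(ii_ref, rr0, rr1, rc0, rc1)
            s_r2 = rect(ii_ref2, rr0, rr1, rc0, rc1)
            s_rf = full[r - 1 + o0 + a, c - 1 + o1 + b]
            var_f = s_f2 - s_f**2 / n
            var_r = s_r2 - s_r**2 / n
            if var_f <= 1e-12 * max(s_f2, 1.0) or var_r <= 1e-12 * max(s_r2, 1.0):
                continue
            out[ai, bi] = (s_rf - s_r * s_f / n) / np.sqrt(var_f * var_r)
    return out


def register_rigid(ref_feat: np.ndarray, float_feat: np.ndarray,
                   bounds: SearchBounds | None = None,
                   refine: bool = True):
    """Find the rigid transform maximizing NCC between two feature images.

    Stage 1 scans a coarse rotation grid; at each angle the best integer
    translation comes from an exhaustive overlap-normalized cross-correlation
    of the de-rotated float band against the reference band.  Stage 2 refines
    (d_col, d_row, theta) with a derivative-free simplex search at 0.01 px /
    0.01 deg granularity, scoring overlap pixels only.

    Returns ``(RigidTransform, score)``.
    """
    bounds = bounds or SearchBounds()
    ref = np.asarray(ref_feat, dtype=float)
    flt = np.asarray(float_feat, dtype=float)
    if ref.shape != flt.shape:
        raise ArgumentError("feature images must have the same shape")
    if ref.std() == 0 or flt.std() == 0:
        raise DegenerateInputError("flat feature image cannot be registered")

    rows, cols = ref.shape
    mr = int(bounds.shift_row)
    mc = int(bounds.shift_col)
    if rows < 8 or cols < 8:
        raise ArgumentError("subimage too small for registration")

    n_steps = int(np.floor(bounds.theta / bounds.theta_step + 1e-9))
    thetas = bounds.theta_step * np.arange(-n_steps, n_steps + 1)  # includes 0
    best = (-np.inf, 0.0, 0.0, 0.0)  # score, d_row, d_col, theta
    for theta in thetas:
        if theta == 0.0:
            flt_rot = flt
            pad = 0
        else:
            flt_rot = unapply_rigid(flt, RigidTransform(0.0, 0.0, theta))
            pad = int(np.ceil(np.sin(np.deg2rad(abs(theta)))
                              * max(rows, cols) / 2.0)) + 1
            pad = min(pad, (min(rows, cols) - 8) // 2)
            if pad > 0:
                flt_rot = flt_rot[pad:rows - pad, pad:cols - pad]
        ncc_map = translation_ncc_map(ref, flt_rot, mr, mc,
                                      origin=(pad, pad))
        pos = np.unravel_index(np.argmax(ncc_map), ncc_map.shape)
        score = float(ncc_map[pos])
        if score > best[0]:
            # content displaced by s satisfies flt_rot(p) = ref(p - s),
            # i.e. flt pixels align with ref at lag -s
            s = -np.array([pos[0] - mr, pos[1] - mc], dtype=float)
            t = _rot(theta) @ s
            best = (score, t[0], t[1], float(theta))

    if not np.isfinite(best[0]):
        raise DegenerateInputError("no valid registration candidate found")
    transform = RigidTransform(d_col=best[2], d_row=best[1], theta_deg=best[3])
    score = ncc_score(ref, flt, transform)

    if refine:
        def neg(x):
            return -ncc_score(ref, flt, RigidTransform(x[0], x[1], x[2]))

        lims = np.array([bounds.shift_col, bounds.shift_row, bounds.theta])
        steps = np.array([0.6, 0.6, 0.3])
        x0 = np.clip(transform.as_array(), -lims, lims - steps)
        simplex = np.vstack([x0, x0 + np.diag(steps)])
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            bounds=[(-l, l) for l in lims],
            options={"xatol": 0.01, "fatol": 1e-9, "maxiter": 250,
                     "initial_simplex": simplex})
        if -res.fun >= score:
            transform = RigidTransform(*res.x)
            score = -res.fun
    return transform, score


# ---------------------------------------------------------------------------
# subimage extraction, per-frame disturbance estimation, alignment
# ---------------------------------------------------------------------------


def extract_subimages(frame: np.ndarray, spec: SubimageSpec | None = None):
    """Cut the upper and lower far-from-wall bands out of a frame (row slices)."""
    spec = spec or SubimageSpec()
    upper, lower = spec.band_slices(np.asarray(frame).shape[0])
    return np.asarray(frame)[upper], np.asarray(frame)[lower]


def average_transforms(upper: RigidTransform,
                       lower: RigidTransform) -> RigidTransform:
    """Component-wise mean of the two band estimates."""
    return RigidTransform(*((upper.as_array() + lower.as_array()) / 2.0))


def _auto_mono_config(band_rows: int, sigma1: float | None) -> monogenic.MonogenicConfig:
    """Bandpass scale for a subimage band.

    Desk-scale bands are a few tens of rows tall, so the scale sits just
    above the speckle cell (a few px) and is capped well below the band
    height; very small bands shrink it further.
    """
    if sigma1 is None:
        sigma1 = float(np.clip(band_rows / 12.0, 2.5, 4.0))
    return monogenic.MonogenicConfig(sigma1=sigma1)


def build_feature_stack(subimages: np.ndarray, filter_kind: str,
                        feature_mode: str,
                        srad_config: srad.SRADConfig | None = None,
                        mono_config: monogenic.MonogenicConfig | None = None,
                        regions=None) -> np.ndarray:
    """Filter + feature-extract a stack of subimages for registration.

    ``filter_kind`` is one of ``none`` / ``srad_w1`` / ``srad_w2``;
    ``feature_mode`` one of the monogenic feature modes.  ``regions`` gives
    the per-frame homogeneous region (band coordinates) for the SRAD speckle
    scale.
    """
    subimages = np.asarray(subimages, dtype=float)
    n, rows, cols = subimages.shape
    if filter_kind not in ("none", "srad_w1", "srad_w2"):
        raise ArgumentError(f"unknown filter kind {filter_kind!r}")
    if filter_kind != "none":
        weight = 1 if filter_kind == "srad_w1" else 2
        if srad_config is None:
            side = int(min(20, rows - 2, cols - 2))
            region = ((rows - side) // 2, (cols - side) // 2, side, side)
            srad_config = srad.SRADConfig(homogeneous_region=region,
                                          longitudinal_weight=weight)
        else:
            srad_config = srad.SRADConfig(
                time_step=srad_config.time_step,
                n_iterations=srad_config.n_iterations,
                grid_spacing=srad_config.grid_spacing,
                homogeneous_region=srad_config.homogeneous_region,
                longitudinal_weight=weight,
                longitudinal_axis=srad_config.longitudinal_axis)
        filtered = srad.srad_filter_sequence(subimages, srad_config,
                                             regions=regions)
    else:
        filtered = subimages
    if feature_mode == "intensity":
        return filtered
    mono_config = mono_config or _auto_mono_config(rows, None)
    out = np.empty_like(filtered)
    for k in range(n):
        out[k] = monogenic.make_feature_image(filtered[k], mono_config,
                                              feature_mode)
    return out


def estimate_disturbance(sequence, mode, spec: SubimageSpec | None = None,
                         bounds: SearchBounds | None = None,
                         srad_config: srad.SRADConfig | None = None,
                         mono_config: monogenic.MonogenicConfig | None = None,
                         region_offsets=None, refine: bool = True):
    """Per-frame common-mode rigid disturbance of a sequence, frame 1 as reference.

    ``mode`` is a ``(filter_kind, feature_mode)`` pair or a method-variant
    name (e.g. ``"swpom"``).  ``region_offsets`` optionally gives known
    per-frame (d_row, d_col) pixel offsets (e.g. a preset disturbance) used
    to propagate the SRAD homogeneous region; ``"auto"`` estimates them from
    frame moments, ``None`` keeps the region fixed.

    Returns a list of :class:`RegistrationResult`, one per frame (frame 1 is
    the identity).
    """
    frames = sequence.frames if hasattr(sequence, "frames") else np.asarray(sequence)
    if frames.shape[0] < 2:
        raise ArgumentError("need at least two frames")
    if isinstance(mode, str):
        from .pipeline import VARIANTS  # late import avoids a module cycle
        key = mode.upper()
        if key not in VARIANTS:
            raise ArgumentError(f"unknown variant {mode!r}")
        filter_kind, feature_mode = VARIANTS[key]
    else:
        filter_kind, feature_mode = mode
    spec = spec or SubimageSpec()
    bounds = bounds or SearchBounds()

    upper_sl, lower_sl = spec.band_slices(frames.shape[1])
    results = []
    for band_sl in (upper_sl, lower_sl):
        band = frames[:, band_sl, :]
        regions = None
        if filter_kind != "none" and region_offsets is not None:
            rows, cols = band.shape[1:]
            side = int(min(20, rows - 2, cols - 2))
            region = ((rows - side) // 2, (cols - side) // 2, side, side)
            offs = ("auto" if isinstance(region_offsets, str)
                    else np.asarray(region_offsets, dtype=float))
            regions = srad.propagate_region(band, region, offs)
        feats = build_feature_stack(band, filter_kind, feature_mode,
                                    srad_config=srad_config,
                                    mono_config=mono_config, regions=regions)
        band_results = [(RigidTransform(), 1.0)]
        for k in range(1, frames.shape[0]):
            band_results.append(register_rigid(feats[0], feats[k], bounds,
                                               refine=refine))
        results.append(band_results)

    out = []
    for (tu, su), (tl, sl_) in zip(results[0], results[1]):
        out.append(RegistrationResult(tu, tl, average_transforms(tu, tl),
                                      su, sl_))
    return out


def results_to_disturbance(results, pixel_spacing_mm: float,
                           times_s) -> RigidDisturbance:
    """Convert averaged per-frame transforms (px/deg) to physical units."""
    d_col = np.array([r.averaged.d_col for r in results])
    d_row = np.array([r.averaged.d_row for r in results])
    theta = np.array([r.averaged.theta_deg for r in results])
    return RigidDisturbance(d_col * pixel_spacing_mm, d_row * pixel_spacing_mm,
                            theta, np.asarray(times_s, dtype=float))


def disturbance_to_transforms(disturbance: RigidDisturbance,
                              pixel_spacing_mm: float):
    """Physical disturbance -> per-frame pixel/degree transforms."""
    return [RigidTransform(d_col=dl / pixel_spacing_mm,
                           d_row=dr / pixel_spacing_mm, theta_deg=th)
            for dl, dr, th in zip(disturbance.d_long_mm,
                                  disturbance.d_rad_mm,
                                  disturbance.theta_deg)]


def align_sequence(sequence, transforms) -> ImageSequence:
    """Resample every frame through the inverse of its estimated transform.

    ``transforms`` may be a list of :class:`RigidTransform` (px/deg), a list
    of :class:`RegistrationResult` (their averaged transforms are used) or a
    :class:`RigidDisturbance` (converted using the sequence pixel spacing).
    Rotation is about the image centre; bilinear interpolation; out-of-bounds
    pixels are 0.  Frame 1 is returned unchanged.
    """
    if isinstance(sequence, ImageSequence):
        frames = sequence.frames
        spacing = sequence.pixel_spacing_mm
        interval = sequence.frame_interval_s
    else:
        frames = np.asarray(sequence)
        spacing, interval = 1.0, 1.0
    if isinstance(transforms, RigidDisturbance):
        transforms = disturbance_to_transforms(transforms, spacing)
    else:
        transforms = [t.averaged if isinstance(t, RegistrationResult) else t
                      for t in transforms]
    if len(transforms) != frames.shape[0]:
        raise ArgumentError("one transform per frame required")
    aligned = np.empty(frames.shape, dtype=float)
    aligned[0] = frames[0]
    for k in range(1, frames.shape[0]):
        aligned[k] = unapply_rigid(frames[k], transforms[k])
    return ImageSequence(aligned, spacing, interval)
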