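"""NCC block-matching speckle tracking of the arterial wall.

A reference block (ROI) straddling the blood/wall interface is selected in
frame 1; in every later frame the block with the highest normalized
correlation coefficient inside a bounded search region is located, and the
displacement of its position is the wall motion for that frame.  The
reference block is never updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArgumentError, DegenerateInputError, ImageSequence, MotionTrajectory


@dataclass
class ROISpec:
    """Reference block: top-left (row, col) and size (rows x cols).

    Should straddle the blood/wall interface; greater radial (row) extent
    improves tracking because intensity is more heterogeneous in depth.
    """

    row: int
    col: int
    height: int = 60
    width: int = 80

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ArgumentError("ROI must be at least 2x2")

    def slices(self) -> tuple:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))


@dataclass
class SearchSpec:
    """Search region: maximum displacement per axis (px), optional subpixel fit."""

    max_displacement: int = 20
    subpixel: bool = False

    def __post_init__(self) -> None:
        if self.max_displacement < 1:
            raise ArgumentError("search bound must be positive")


def ncc(R_block: np.ndarray, F_block: np.ndarray) -> float:
    """Normalized correlation coefficient between two equally shaped blocks.

    NCC = sum((R - mean R)(F - mean F)) / sqrt(sum(R - mean R)^2 sum(F - mean F)^2),
    in [-1, 1]; invariant to affine intensity changes of either block.
    """
    R = np.asarray(R_block, dtype=float)
    F = np.asarray(F_block, dtype=float)
    if R.shape != F.shape:
        raise ArgumentError("blocks must have equal shapes")
    dR = R - R.mean()
    dF = F - F.mean()
    den = np.sqrt((dR**2).sum() * (dF**2).sum())
    if den == 0:
        raise DegenerateInputError("zero-variance block in NCC")
    return float((dR * dF).sum() / den)


def block_match(ref_frame: np.ndarray, float_frame: np.ndarray,
                roi: ROISpec, search: SearchSpec | None = None):
    """Displacement of the ROI between a reference frame and a float frame.

    Exhaustive integer search over the (2S+1)^2 displacement grid; ties are
    broken by the smallest displacement magnitude, then row-major order.
    Returns ``(d_col, d_row, peak, on_boundary)``; with ``search.subpixel``
    a 1D parabolic fit through the peak and its axis neighbours refines each
    coordinate.  A zero-variance reference block, or a float frame in which
    every candidate block is flat, raises :class:`DegenerateInputError`.
    """
    search = search or SearchSpec()
    ref = np.asarray(ref_frame, dtype=float)
    flt = np.asarray(float_frame, dtype=float)
    S = search.max_displacement
    rs, cs = roi.slices()
    if (rs.start - S < 0 or cs.start - S < 0
            or rs.stop + S > flt.shape[0] or cs.stop + S > flt.shape[1]):
        raise ArgumentError("ROI plus search window must fit inside the frame")

    block = ref[rs, cs]
    dB = block - block.mean()
    nB = (dB**2).sum()
    if nB == 0:
        raise DegenerateInputError("zero-variance reference block")

    scores = np.full((2 * S + 1, 2 * S + 1), -np.inf)
    for i, dr in enumerate(range(-S, S + 1)):
        for j, dc in enumerate(range(-S, S + 1)):
            cand = flt[rs.start + dr:rs.stop + dr, cs.start + dc:cs.stop + dc]
            dC = cand - cand.mean()
            nC = (dC**2).sum()
            if nC == 0:
                continue
            scores[i, j] = (dB * dC).sum() / np.sqrt(nB * nC)
    if not np.isfinite(scores).any():
        raise DegenerateInputError("all candidate blocks have zero variance")

    peak = scores.max()
    ties = np.argwhere(scores >= peak - 1e-12)
    d = ties - S
    mag = (d**2).sum(axis=1)
    best = ties[np.lexsort((ties[:, 1], ties[:, 0], mag))[0]]
    d_row = float(best[0] - S)
    d_col = float(best[1] - S)
    on_boundary = max(abs(d_row), abs(d_col)) >= S
    peak = float(scores[tuple(best)])

    if search.subpixel and not on_boundary:
        i, j = best
        for axis, (m1, p1) in enumerate(((scores[i - 1, j], scores[i + 1, j]),
                                         (scores[i, j - 1], scores[i, j + 1]))):
            if np.isfinite(m1) and np.isfinite(p1):
                denom = m1 - 2 * peak + p1
                if denom < 0:
                    delta = 0.5 * (m1 - p1) / denom
                    if axis == 0:
                        d_row += float(delta)
                    else:
                        d_col += float(delta)
    return d_col, d_row, peak, on_boundary


def track_sequence(aligned_seq, roi: ROISpec, search: SearchSpec | None = None,
                   pixel_spacing_mm: float | None = None):
    """Track the frame-1 ROI through a sequence; returns the wall trajectory.

    Every frame is matched against frame 1 (the reference block is fixed).
    Displacements are converted to mm with the pixel spacing.  Returns
    ``(MotionTrajectory, n_boundary_hits)``.
    """
    if isinstance(aligned_seq, ImageSequence):
        frames = aligned_seq.frames
        spacing = pixel_spacing_mm or aligned_seq.pixel_spacing_mm
        times = aligned_seq.times_s
    else:
        frames = np.asarray(aligned_seq)
        spacing = pixel_spacing_mm or 1.0
        times = np.arange(frames.shape[0], dtype=float)
    d_long = np.zeros(frames.shape[0])
    d_rad = np.zeros(frames.shape[0])
    n_boundary = 0
    for k in range(1, frames.shape[0]):
        dc, dr, _, hit = block_match(frames[0], frames[k], roi, search)
        d_long[k] = dc * spacing
        d_rad[k] = dr * spacing
        n_boundary += int(hit)
    return MotionTrajectory(d_long, d_rad, np.asarray(times, dtype=float)), n_boundary
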