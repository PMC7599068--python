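"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: cell tables with
multinomial bin occupancy, clustered vs scattered 3D point clouds,
optokinetic eye-angle traces with resetting saccades, binary video frames
with two eye ellipses, and fluorescence intensity stacks.  Each generator
is a pure function of its seed, and the generating parameters are
recorded as a :class:`SyntheticTruth` so downstream estimates can be
checked against truth (parameter recovery).

Coordinate conventions: micrometres, midline at x = 0 with x increasing
laterally, z = 0 ventral with z increasing dorsally.  The nominal
anatomical extents spanned by generated occupancy datasets are
``DV_EXTENT_UM`` and ``ML_EXTENT_UM``; they are recorded in the truth
sidecar so binning can be anchored to them exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .io import validate_cell_table
from .okr import EyeTrace

__all__ = [
    "SyntheticTruth",
    "DV_EXTENT_UM",
    "ML_EXTENT_UM",
    "subrng",
    "shift_grid",
    "gen_occupancy_dataset",
    "gen_clustered_nucleus",
    "gen_eye_trace",
    "gen_eye_frames",
    "gen_intensity_stack",
]

#: Nominal dorsoventral extent (μm) of generated occupancy datasets.
DV_EXTENT_UM = (0.0, 60.0)
#: Nominal mediolateral extent (μm): midline to lateral-most.
ML_EXTENT_UM = (0.0, 40.0)
#: Rostrocaudal span (μm) — uninformative axis, uniform fill.
_Y_EXTENT_UM = (0.0, 30.0)


def subrng(seed: int, tag: str) -> np.random.Generator:
    """Child generator derived from a master seed and a string tag.

    The master seed and a CRC of the tag are combined into a
    ``SeedSequence``, so distinct pipeline stages draw from independent
    streams while remaining a pure function of the master seed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated occupancy dataset.

    Attributes
    ----------
    occupancy_probs : (n_z, n_x) array
        Bin occupancy probabilities; non-negative, sums to 1.
    n_larvae : int
    cells_per_larva : (low, high) inclusive range of per-larva counts.
        Default 20-60 cells covers the per-larva range implied by the
        pooled totals of the emulated experiment (~278 cells / 19 larvae
        to ~399 / 22).
    scatter_factor : float >= 1, dilation of point-cloud spread.
    gain_true : dict, true OKR gains when relevant.
    seed : int
    """

    occupancy_probs: np.ndarray
    n_larvae: int = 19
    cells_per_larva: tuple[int, int] = (20, 60)
    scatter_factor: float = 1.0
    gain_true: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.occupancy_probs, dtype=float)
        if p.ndim != 2:
            raise ValueError("occupancy_probs must be a 2D grid")
        if np.any(p < 0):
            raise ValueError("occupancy_probs must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"occupancy_probs must sum to 1 within 1e-12 (got {p.sum()!r})"
            )
        if self.scatter_factor < 1:
            raise ValueError("scatter_factor must be >= 1")
        lo, hi = self.cells_per_larva
        if not (0 < lo <= hi):
            raise ValueError("cells_per_larva must be a positive (low, high) range")
        self.occupancy_probs = p

    def to_dict(self) -> dict[str, Any]:
        return {
            "occupancy_probs": self.occupancy_probs.tolist(),
            "n_larvae": self.n_larvae,
            "cells_per_larva": list(self.cells_per_larva),
            "scatter_factor": self.scatter_factor,
            "gain_true": self.gain_true,
            "seed": self.seed,
            "z_extent_um": list(DV_EXTENT_UM),
            "x_extent_um": list(ML_EXTENT_UM),
        }


def shift_grid(probs: np.ndarray, dz: int = 0, dx: int = 0) -> np.ndarray:
    """Shift an occupancy grid by whole bins along DV (dz) and ML (dx).

    Zero-filled (non-circular) shift followed by renormalisation.  If the
    shift pushes any probability mass off the grid a ValueError is raised,
    since the truncated grid would no longer realise the intended mean
    shift exactly.
    """
    p = np.asarray(probs, dtype=float)
    out = np.zeros_like(p)
    nz, nx = p.shape
    src_z = slice(max(0, -dz), min(nz, nz - dz))
    src_x = slice(max(0, -dx), min(nx, nx - dx))
    dst_z = slice(max(0, dz), min(nz, nz + dz))
    dst_x = slice(max(0, dx), min(nx, nx + dx))
    out[dst_z, dst_x] = p[src_z, src_x]
    if abs(out.sum() - p.sum()) > 1e-12:
        raise ValueError("shift pushes probability mass off the grid")
    return out / out.sum()


def gen_occupancy_dataset(
    truth: SyntheticTruth,
    genotype: str = "wildtype",
) -> pd.DataFrame:
    """Cell table drawn from a known bin-occupancy distribution.

    For each larva a cell count is drawn uniformly from
    ``truth.cells_per_larva``, bins are drawn multinomially from
    ``truth.occupancy_probs``, and continuous coordinates are placed
    uniformly within each bin's extent (anchored to the nominal extents,
    so re-binning against those extents recovers the sampled bins
    exactly).  Sides are assigned alternately per larva.
    """
    rng = subrng(truth.seed, f"occupancy:{genotype}")
    n_z, n_x = truth.occupancy_probs.shape
    flat_p = truth.occupancy_probs.ravel()
    z_lo, z_hi = DV_EXTENT_UM
    x_lo, x_hi = ML_EXTENT_UM
    dz = (z_hi - z_lo) / n_z
    dx = (x_hi - x_lo) / n_x

    rows = []
    lo, hi = truth.cells_per_larva
    for larva in range(truth.n_larvae):
        n_cells = int(rng.integers(lo, hi + 1))
        bins = rng.choice(n_z * n_x, size=n_cells, p=flat_p)
        z_bin, x_bin = np.unravel_index(bins, (n_z, n_x))
        # uniform within bin; strict interior keeps re-binning exact
        u = rng.uniform(1e-9, 1 - 1e-9, size=(n_cells, 3))
        z = z_lo + (z_bin + u[:, 0]) * dz
        x = x_lo + (x_bin + u[:, 1]) * dx
        y = _Y_EXTENT_UM[0] + u[:, 2] * (_Y_EXTENT_UM[1] - _Y_EXTENT_UM[0])
        sides = np.where(rng.random(n_cells) < 0.5, "left", "right")
        for i in range(n_cells):
            rows.append(
                (f"larva{larva:03d}", genotype, sides[i],
                 x[i], y[i], z[i], "negative", "IO")
            )
    df = pd.DataFrame(
        rows,
        columns=["larva_id", "genotype", "side", "x_um", "y_um", "z_um",
                 "marker", "label"],
    )
    return validate_cell_table(df)


def gen_clustered_nucleus(
    n_cells: int,
    centers: Sequence[Sequence[float]],
    sd: float,
    scatter_factor: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """3D Gaussian-mixture point cloud emulating a motor nucleus.

    ``scatter_factor`` >= 1 dilates the per-axis standard deviation,
    emulating the sparser arrangement seen when cell-cell adhesion is
    perturbed.  Returns an (n_cells, 3) array in μm.
    """
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4 (hull/tessellation need non-degenerate input)")
    if scatter_factor < 1:
        raise ValueError("scatter_factor must be >= 1")
    rng = subrng(seed, "clustered_nucleus")
    centers_arr = np.atleast_2d(np.asarray(centers, dtype=float))
    idx = rng.integers(0, len(centers_arr), size=n_cells)
    noise = rng.standard_normal((n_cells, 3)) * sd * scatter_factor
    return centers_arr[idx] + noise


def gen_eye_trace(
    gain_nasal: float = 0.8,
    gain_temporal: float = 0.5,
    stim_speed: float = 10.0,
    reversal_period: float = 6.0,
    duration: float = 60.0,
    saccade_rate: float = 0.2,
    noise_sd: float = 0.0,
    sample_rate: float = 100.0,
    seed: int = 0,
    rest_angle: float = 0.0,
    gain_scale: tuple[float, float] = (1.0, 1.0),
) -> EyeTrace:
    """Synthetic OKR session: triangular-wave stimulus, slow tracking
    phases, instantaneous resetting saccades, additive angle noise.

    The grating moves at constant speed, reversing direction every
    ``reversal_period`` seconds (default 6 s; sampling default 100 Hz).
    During slow phases each eye integrates gain x stimulus velocity,
    where the gain is ``gain_nasal`` when the eye moves toward the nose
    and ``gain_temporal`` otherwise.  Saccades occur as a Poisson process
    and reset the eye to ``rest_angle`` within one sample.  True
    slow-phase masks and clean angles are recorded in ``trace.truth``.
    ``gain_scale`` multiplies both gains per (left, right) eye, to
    emulate a strong/weak-eye asymmetry.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if duration < 2 * reversal_period:
        raise ValueError("duration must cover at least two stimulus reversals")
    rng = subrng(seed, "eye_trace")
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    t = np.arange(n) * dt
    phase = np.floor(t / reversal_period).astype(int)
    stim_v = stim_speed * np.where(phase % 2 == 0, 1.0, -1.0)
    reversal_times = np.arange(reversal_period, duration, reversal_period)

    from .okr import NASAL_SIGN

    angles = {}
    slow_masks = {}
    scale = {"left": gain_scale[0], "right": gain_scale[1]}
    for eye in ("left", "right"):
        nasal_sign = NASAL_SIGN[eye]
        angle = np.empty(n)
        slow = np.ones(n, dtype=bool)
        a = rest_angle
        saccade_hits = rng.random(n) < saccade_rate * dt
        for i in range(n):
            if saccade_hits[i]:
                a = rest_angle
                slow[i] = False
            else:
                v = stim_v[i]
                g = gain_nasal if v * nasal_sign > 0 else gain_temporal
                a = a + scale[eye] * g * v * dt
            angle[i] = a
        angles[eye] = angle
        slow_masks[eye] = slow

    noise_l = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    noise_r = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    return EyeTrace(
        t=t,
        angle_left=angles["left"] + noise_l,
        angle_right=angles["right"] + noise_r,
        stimulus_velocity=stim_v,
        reversal_times=reversal_times,
        sample_rate=sample_rate,
        truth={
            "gain_nasal": gain_nasal,
            "gain_temporal": gain_temporal,
            "gain_scale": dict(zip(("left", "right"), gain_scale)),
            "clean_angle": {k: v.copy() for k, v in angles.items()},
            "slow_mask": slow_masks,
            "seed": seed,
        },
    )


def _ellipse_mask(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    angle_deg: float,
) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse.

    ``angle_deg`` is the major-axis angle, CCW-positive with the image
    y-axis pointing up — the same convention :func:`okr.eye_orientation`
    reports.
    """
    rr, cc = np.indices(shape)
    x = cc - center_rc[1]
    y = -(rr - center_rc[0])
    th = np.radians(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def gen_eye_frames(
    angles: tuple[float, float],
    axes: tuple[float, float] = (14.0, 7.0),
    image_size: tuple[int, int] = (120, 160),
    noise_frac: float = 0.0,
    seed: int = 0,
    centers: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Binary frame with two eye ellipses at stated orientations.

    ``angles`` are the (left, right) eye angles in degrees; ``axes`` the
    (semi-major, semi-minor) lengths in px; ``centers`` optional (row,
    col) eye positions, defaulting to mid-height quarter positions.
    ``noise_frac`` > 0 adds salt specks strictly smaller than the eyes.
    Ellipses must fit inside the frame (not touching the border) and
    must not overlap.
    """
    h, w = image_size
    semi_major, semi_minor = axes
    if centers is None:
        centers = [(h / 2.0, w * 0.25), (h / 2.0, w * 0.75)]
    frame = np.zeros((h, w), dtype=np.uint8)
    masks = []
    for (angle, center) in zip(angles, centers):
        m = _ellipse_mask((h, w), center, semi_major, semi_minor, angle)
        r0, c0 = center
        border = m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
        if border or (r0 - semi_major < -1 or r0 + semi_major > h
                      or c0 - semi_major < -1 or c0 + semi_major > w):
            raise ValueError("ellipse does not fit inside the frame")
        masks.append(m)
    if (masks[0] & masks[1]).any():
        raise ValueError("eye ellipses overlap")
    frame[masks[0] | masks[1]] = 1

    if noise_frac > 0:
        rng = subrng(seed, "eye_frames")
        eye_area = masks[0].sum()
        n_specks = max(1, int(noise_frac * h * w / 50))
        speck_r = max(1, int(np.sqrt(eye_area) / 8))
        for _ in range(n_specks):
            r = int(rng.integers(speck_r, h - speck_r))
            c = int(rng.integers(speck_r, w - speck_r))
            speck = _ellipse_mask((h, w), (r, c), speck_r, speck_r, 0.0)
            # keep specks detached from the eyes so component areas stay honest
            grown = np.zeros_like(speck)
            grown[max(0, r - speck_r - 1):r + speck_r + 2,
                  max(0, c - speck_r - 1):c + speck_r + 2] = True
            if (grown & (masks[0] | masks[1])).any():
                continue
            frame[speck] = 1
    return frame


def gen_intensity_stack(
    roi_mean: float = 2000.0,
    bg_mean: float = 500.0,
    noise_sd: float = 50.0,
    n_slices: int = 9,
    shape: tuple[int, int] = (64, 64),
    roi_masks: dict[str, np.ndarray] | None = None,
    bg_masks: Sequence[np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray], list[np.ndarray]]:
    """Fluorescence stack with known ROI and background intensities.

    Voxels inside the per-side ROI masks are drawn from
    N(roi_mean, noise_sd); everything else (including the three
    background masks) from N(bg_mean, noise_sd).  Default masks are two
    lateral rectangles per slice (left/right ROIs) and three small
    background patches.  Returns ``(stack, roi_masks, bg_masks)``.
    """
    h, w = shape
    if roi_masks is None:
        left = np.zeros((n_slices, h, w), dtype=bool)
        right = np.zeros((n_slices, h, w), dtype=bool)
        left[:, h // 4: h // 2, w // 8: 3 * w // 8] = True
        right[:, h // 4: h // 2, 5 * w // 8: 7 * w // 8] = True
        roi_masks = {"left": left, "right": right}
    if bg_masks is None:
        bg_masks = []
        for k in range(3):
            m = np.zeros((n_slices, h, w), dtype=bool)
            c = (k + 1) * w // 4
            m[:, 3 * h // 4: 3 * h // 4 + 4, c: c + 4] = True
            bg_masks.append(m)
    bg_masks = list(bg_masks)

    roi_union = np.zeros((n_slices, h, w), dtype=bool)
    for m in roi_masks.values():
        roi_union |= m
    for m in bg_masks:
        if (m & roi_union).any():
            raise ValueError("background masks must be disjoint from ROI masks")

    rng = subrng(seed, "intensity_stack")
    stack = np.full((n_slices, h, w), float(bg_mean))
    stack[roi_union] = roi_mean
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack, roi_masks, bg_masks
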