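"""Pixelwise height reconstruction from SAIM angle stacks.

Inverts the affine interference model ``I_j = A f(theta_j, H) + B`` for every
pixel of a multi-angle image stack, then reduces dye/reference height maps to
per-cell glycocalyx thickness (dye-layer height minus substrate fibronectin
height over a square subregion).

The objective is separable: for fixed H the model is linear in (A, B), so the
residual sum of squares profiles to a 1-D function of H. That profile is
oscillatory (the interference fringes alias heights one period apart), so the
fitter scans H on a coarse grid over the configured bounds, keeps the best few
local minima as seeds, and polishes each seed with a bracketed golden-section
search on the continuous profile. The coarse seeds themselves remain in the
candidate set, so the returned optimum is never worse than any seed. Among
near-equal minima the smallest H wins, making the fit fully deterministic.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyROIError, InvalidInputError
from .optics import AngleGrid, OpticalStackConfig, phase_shift, reflection_te

__all__ = [
    "AngleImageStack",
    "FitOptions",
    "PixelFit",
    "HeightMap",
    "ThicknessResult",
    "fit_pixel",
    "fit_stack",
    "quantify_thickness",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class AngleImageStack:
    """Intensity stack indexed (angle, row, col) with its acquisition grid."""

    grid: AngleGrid
    intensities: np.ndarray
    channel: str = ""
    d_oxide_nm: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise InvalidInputError("intensities must be 3-D (angle, row, col)")
        if arr.shape[0] != len(self.grid):
            raise InvalidInputError(
                f"stack has {arr.shape[0]} pages but grid has {len(self.grid)} angles"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidInputError("intensities must be finite and >= 0")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the two-stage height fit.

    ``h_bounds_nm`` is the admissible height window (heights outside alias
    into it through the fringe period); ``coarse_step_nm`` the scan pitch of
    the seeding grid; ``n_seeds`` how many coarse local minima are polished;
    ``xtol_nm`` the bracket width at which polishing stops (also bounded by
    ``max_iter``); ``amplitude_floor`` the minimum fitted A for a pixel to
    enter the quality mask; ``n_workers`` splits rows across threads without
    changing any result.
    """

    h_bounds_nm: tuple[float, float] = (0.0, 300.0)
    coarse_step_nm: float = 1.0
    n_seeds: int = 3
    xtol_nm: float = 1e-5
    max_iter: int = 200
    sse_rel_tol: float = 1e-10
    tie_rel_tol: float = 1e-9
    amplitude_floor: float = 0.0
    n_workers: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.h_bounds_nm
        if not (0 <= lo < hi):
            raise InvalidInputError("h_bounds_nm must satisfy 0 <= lo < hi")
        if self.coarse_step_nm <= 0 or self.n_seeds < 1:
            raise InvalidInputError("coarse_step_nm must be > 0 and n_seeds >= 1")


@dataclass
class PixelFit:
    """Result of the three-parameter fit at one pixel."""

    height_nm: float
    amplitude: float
    offset: float
    sse: float
    converged: bool
    degenerate: bool = False
    n_starts_used: int = 0


@dataclass
class HeightMap:
    """Per-pixel fit results over an image.

    ``heights_nm`` carries NaN at pixels excluded by ``quality_mask`` (never a
    silent zero); ``heights_raw_nm`` keeps the unmasked best-effort fit.
    """

    heights_nm: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    sse: np.ndarray
    quality_mask: np.ndarray
    heights_raw_nm: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights_nm.shape


@dataclass
class ThicknessResult:
    """Glycocalyx thickness over one subregion: dye height minus reference height."""

    roi_id: str
    mean_height_dye_nm: float
    mean_height_reference_nm: float
    thickness_nm: float
    n_pixels_used: int


def _sum0(x: np.ndarray) -> np.ndarray:
    """Sequential sum over axis 0.

    numpy's reduction order over the leading axis depends on the array's
    trailing width, so the same pixel summed inside blocks of different
    widths can round differently. Accumulating row by row gives every pixel
    a bitwise-identical result no matter how pixels are blocked — the basis
    of the determinism and parallelism contracts.
    """
    out = x[0].astype(float, copy=True)
    for k in range(1, x.shape[0]):
        out = out + x[k]
    return out


def _phase_coefficients(config: OpticalStackConfig, grid: AngleGrid):
    """Per-angle reflection coefficients and phase-per-nm factors."""
    r = reflection_te(config, grid.angles_deg).r_te
    c = phase_shift(config, grid.angles_deg, 1.0)  # phi per nm of height
    return np.atleast_1d(r), np.atleast_1d(c)


def _f_of_heights(r: np.ndarray, c: np.ndarray, heights: np.ndarray) -> np.ndarray:
    """Excitation probability, shape (n_angles, *heights.shape)."""
    phi = np.multiply.outer(c, heights)
    re_r = np.real(r).reshape((-1,) + (1,) * heights.ndim)
    im_r = np.imag(r).reshape((-1,) + (1,) * heights.ndim)
    return 1.0 + 2.0 * re_r * np.cos(phi) - 2.0 * im_r * np.sin(phi) + re_r**2 + im_r**2


def _coarse_scan(r, c, h_grid, intensities, stats):
    """SSE of the profiled objective on the coarse height grid.

    Returns (amp, off, sse) with shape (n_H, n_pix). The cross term is
    accumulated with elementwise reductions per grid height (not a matrix
    product) so every pixel's result is bitwise independent of how pixels
    are blocked — the basis of the parallelism contract.
    """
    f = _f_of_heights(r, c, h_grid)  # (n_angles, n_H)
    n = f.shape[0]
    s_f = _sum0(f)[:, None]
    s_ff = _sum0(f * f)[:, None]
    n_pix = intensities.shape[1]
    s_fi = np.empty((len(h_grid), n_pix))
    for k in range(len(h_grid)):
        s_fi[k] = _sum0(f[:, k, None] * intensities)
    s_i, s_ii = stats
    den = n * s_ff - s_f**2
    den = np.where(den == 0, np.finfo(float).tiny, den)
    amp = (n * s_fi - s_f * s_i[None, :]) / den
    off = (s_i[None, :] - amp * s_f) / n
    sse = np.maximum(s_ii[None, :] - amp * s_fi - off * s_i[None, :], 0.0)
    return amp, off, sse


def _sse_at(r, c, heights, intensities, stats):
    """Profiled (A, B, SSE) at one height per pixel; heights shape (n_pix,)."""
    f = _f_of_heights(r, c, heights)  # (n_angles, n_pix)
    n = f.shape[0]
    s_f = _sum0(f)
    s_ff = _sum0(f * f)
    s_fi = _sum0(f * intensities)
    s_i, s_ii = stats
    den = n * s_ff - s_f**2
    den = np.where(den == 0, np.finfo(float).tiny, den)
    amp = (n * s_fi - s_f * s_i) / den
    off = (s_i - amp * s_f) / n
    sse = np.maximum(s_ii - amp * s_fi - off * s_i, 0.0)
    return amp, off, sse


def _golden_refine(r, c, seed_h, lo, hi, intensities, stats, options: FitOptions):
    """Vectorized golden-section polish of one seed per pixel."""
    a = np.array(lo, dtype=float)
    b = np.array(hi, dtype=float)
    # fixed, data-independent iteration count: the nominal bracket is two
    # coarse steps wide, so results cannot depend on pixel blocking
    span0 = 2.0 * options.coarse_step_nm
    n_iter = int(np.ceil(np.log(options.xtol_nm / span0) / np.log(_GOLDEN)))
    n_iter = min(max(n_iter, 1), options.max_iter)
    for _ in range(n_iter):
        span = b - a
        x1 = b - _GOLDEN * span
        x2 = a + _GOLDEN * span
        _, _, f1 = _sse_at(r, c, x1, intensities, stats)
        _, _, f2 = _sse_at(r, c, x2, intensities, stats)
        left = f1 <= f2
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
    h = 0.5 * (a + b)
    amp, off, sse = _sse_at(r, c, h, intensities, stats)
    return h, amp, off, sse


def _fit_block(intensities: np.ndarray, r, c, h_grid, options: FitOptions):
    """Fit a flat block of pixels; intensities shape (n_angles, n_pix)."""
    n_pix = intensities.shape[1]
    s_i = _sum0(intensities)
    s_ii = _sum0(intensities * intensities)
    stats = (s_i, s_ii)

    degenerate = np.ptp(intensities, axis=0) == 0

    amp_grid, off_grid, sse_grid = _coarse_scan(r, c, h_grid, intensities, stats)

    # local minima of the coarse profile (endpoints allowed)
    padded = np.pad(sse_grid, ((1, 1), (0, 0)), constant_values=np.inf)
    is_min = (sse_grid <= padded[:-2]) & (sse_grid <= padded[2:])
    masked = np.where(is_min, sse_grid, np.inf)
    n_seeds = min(options.n_seeds, len(h_grid))
    seed_idx = np.argsort(masked, axis=0, kind="stable")[:n_seeds]  # (n_seeds, n_pix)
    seed_valid = np.take_along_axis(masked, seed_idx, axis=0) < np.inf
    seed_valid[0, :] = True  # the global coarse minimum always seeds

    step = options.coarse_step_nm
    lo_b, hi_b = options.h_bounds_nm
    cand_h = np.empty((2 * n_seeds, n_pix))
    cand_amp = np.empty_like(cand_h)
    cand_off = np.empty_like(cand_h)
    cand_sse = np.full_like(cand_h, np.inf)
    n_starts = seed_valid.sum(axis=0)

    for k in range(n_seeds):
        idx = seed_idx[k]
        h_seed = h_grid[idx]
        # keep the raw seed as a candidate: guarantees optimum <= every seed
        cand_h[2 * k] = h_seed
        cand_amp[2 * k] = np.take_along_axis(amp_grid, idx[None, :], axis=0)[0]
        cand_off[2 * k] = np.take_along_axis(off_grid, idx[None, :], axis=0)[0]
        sse_seed = np.take_along_axis(sse_grid, idx[None, :], axis=0)[0]
        cand_sse[2 * k] = np.where(seed_valid[k], sse_seed, np.inf)

        lo = np.clip(h_seed - step, lo_b, hi_b)
        hi = np.clip(h_seed + step, lo_b, hi_b)
        h_ref, a_ref, b_ref, s_ref = _golden_refine(r, c, h_seed, lo, hi, intensities, stats, options)
        cand_h[2 * k + 1] = h_ref
        cand_amp[2 * k + 1] = a_ref
        cand_off[2 * k + 1] = b_ref
        cand_sse[2 * k + 1] = np.where(seed_valid[k], s_ref, np.inf)

    # pick minimum SSE; among near-ties (relative tol) pick the smallest H
    best_sse = cand_sse.min(axis=0)
    tie = cand_sse <= best_sse * (1.0 + options.tie_rel_tol) + np.finfo(float).tiny
    h_for_tie = np.where(tie, cand_h, np.inf)
    pick = np.argmin(h_for_tie, axis=0)

    take = lambda arr: np.take_along_axis(arr, pick[None, :], axis=0)[0]
    height = take(cand_h)
    amp = take(cand_amp)
    off = take(cand_off)
    sse = take(cand_sse)

    height = np.where(degenerate, h_grid[0], height)
    amp = np.where(degenerate, 0.0, amp)
    off = np.where(degenerate, s_i / intensities.shape[0], off)
    sse = np.where(degenerate, 0.0, sse)
    converged = ~degenerate & (amp >= 0)
    return height, amp, off, sse, converged, degenerate, n_starts


def fit_pixel(
    intensities: np.ndarray,
    grid: AngleGrid,
    config: OpticalStackConfig,
    options: FitOptions | None = None,
) -> PixelFit:
    """Fit (H, A, B) to one pixel's intensity-versus-angle curve.

    Minimizes ``sum_j (I_j - A f(theta_j, H) - B)^2`` with the seeded
    coarse-scan + golden-section scheme. An all-constant curve leaves H
    unidentifiable and returns ``converged=False`` with ``degenerate=True``.
    """
    options = options or FitOptions()
    vec = np.asarray(intensities, dtype=float)
    if vec.ndim != 1 or len(vec) != len(grid):
        raise InvalidInputError(
            f"intensity vector length {vec.shape} does not match grid length {len(grid)}"
        )
    if len(grid) < 3:
        raise InvalidInputError("need at least 3 angles to fit 3 parameters")
    if not np.all(np.isfinite(vec)):
        raise InvalidInputError("intensities must be finite")

    r, c = _phase_coefficients(config, grid)
    lo, hi = options.h_bounds_nm
    h_grid = np.arange(lo, hi + 0.5 * options.coarse_step_nm, options.coarse_step_nm)
    height, amp, off, sse, conv, degen, n_starts = _fit_block(vec[:, None], r, c, h_grid, options)
    return PixelFit(
        height_nm=float(height[0]),
        amplitude=float(amp[0]),
        offset=float(off[0]),
        sse=float(sse[0]),
        converged=bool(conv[0]),
        degenerate=bool(degen[0]),
        n_starts_used=int(n_starts[0]),
    )


def fit_stack(
    stack: AngleImageStack,
    config: OpticalStackConfig,
    options: FitOptions | None = None,
) -> HeightMap:
    """Fit every pixel of an angle stack independently.

    Per-pixel results are identical to :func:`fit_pixel`; rows are chunked
    across ``options.n_workers`` threads with no effect on any value. Failed
    or degenerate pixels are masked out, never abort the stack.
    """
    options = options or FitOptions()
    if len(stack.grid) < 3:
        raise InvalidInputError("need at least 3 angles to fit 3 parameters")
    n_angles, n_rows, n_cols = stack.intensities.shape
    flat = stack.intensities.reshape(n_angles, n_rows * n_cols)

    r, c = _phase_coefficients(config, stack.grid)
    lo, hi = options.h_bounds_nm
    h_grid = np.arange(lo, hi + 0.5 * options.coarse_step_nm, options.coarse_step_nm)

    n_pix = flat.shape[1]
    chunk = max(1, -(-n_pix // max(1, options.n_workers)))
    bounds = [(i, min(i + chunk, n_pix)) for i in range(0, n_pix, chunk)]

    def run(span):
        i0, i1 = span
        return _fit_block(flat[:, i0:i1], r, c, h_grid, options)

    if options.n_workers > 1 and len(bounds) > 1:
        with ThreadPoolExecutor(max_workers=options.n_workers) as pool:
            parts = list(pool.map(run, bounds))
    else:
        parts = [run(b) for b in bounds]

    height, amp, off, sse, conv, degen, _ = (np.concatenate(ps) for ps in zip(*parts))

    quality = conv & (amp > options.amplitude_floor)
    shape = (n_rows, n_cols)
    raw = height.reshape(shape)
    masked = np.where(quality.reshape(shape), raw, np.nan)
    return HeightMap(
        heights_nm=masked,
        amplitude=amp.reshape(shape),
        offset=off.reshape(shape),
        sse=sse.reshape(shape),
        quality_mask=quality.reshape(shape),
        heights_raw_nm=raw,
    )


def quantify_thickness(
    dye_map: HeightMap,
    reference_map: HeightMap,
    rois: list[tuple],
    size: int = 100,
) -> list[ThicknessResult]:
    """Glycocalyx thickness per subregion: mean dye height minus mean reference height.

    ``rois`` is a list of ``(roi_id, row0, col0)``; each ROI is the half-open
    square ``[row0, row0+size) x [col0, col0+size)`` and must lie inside the
    image. Only quality-masked pixels enter each channel's mean;
    ``n_pixels_used`` is the smaller of the two channels' counts.
    """
    if dye_map.shape != reference_map.shape:
        raise InvalidInputError("dye and reference maps must share a shape")
    n_rows, n_cols = dye_map.shape
    results = []
    for roi_id, r0, c0 in rois:
        r0, c0 = int(r0), int(c0)
        if r0 < 0 or c0 < 0 or r0 + size > n_rows or c0 + size > n_cols:
            raise InvalidInputError(f"ROI {roi_id!r} at ({r0},{c0}) size {size} exceeds image {dye_map.shape}")
        sl = (slice(r0, r0 + size), slice(c0, c0 + size))
        dye = dye_map.heights_nm[sl]
        ref = reference_map.heights_nm[sl]
        n_dye = int(np.sum(np.isfinite(dye)))
        n_ref = int(np.sum(np.isfinite(ref)))
        if n_dye == 0 or n_ref == 0:
            raise EmptyROIError(f"ROI {roi_id!r} has no usable pixels (dye {n_dye}, ref {n_ref})")
        mean_dye = float(np.nanmean(dye))
        mean_ref = float(np.nanmean(ref))
        results.append(
            ThicknessResult(
                roi_id=str(roi_id),
                mean_height_dye_nm=mean_dye,
                mean_height_reference_nm=mean_ref,
                thickness_nm=mean_dye - mean_ref,
                n_pixels_used=min(n_dye, n_ref),
            )
        )
    return results
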