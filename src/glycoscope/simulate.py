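"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and seed, so regeneration
is bitwise identical and every inverse operation can be tested against known
ground truth:

* height phantoms — flat fields, steps, hemispherical bleb caps (emulating
  bleb-covered cell surfaces), and dilated ridge networks (emulating
  interconnected ridge-like membrane projections);
* SAIM angle stacks — the interference forward model evaluated over a height
  field, with optional Poisson shot noise or Gaussian read noise;
* FLIM decay cubes — two-component exponential mixtures (free/bound NADH)
  folded to the laser repetition period, with multinomial photon sampling and
  an optional instrument time shift;
* isotopologue ladders — binomial 13C labeling of a metabolite's carbon
  skeleton, with optional lognormal multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import dilation, disk, skeletonize

from .exceptions import InvalidInputError
from .optics import AngleGrid, OpticalStackConfig, excitation_probability
from .phasor import DecayImage
from .reconstruct import AngleImageStack

__all__ = [
    "PhantomSpec",
    "make_height_field",
    "simulate_saim_stack",
    "simulate_decay_image",
    "simulate_isotopologues",
]

_PATTERNS = ("flat", "step", "blebs", "ridges")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a ground-truth height field.

    ``pattern`` is one of flat / step / blebs / ridges. Heights in nm;
    lateral sizes in pixels. ``bleb_density`` is the expected number of caps
    per pixel; ``ridge_scale_px`` the band-pass correlation length of the
    ridge network and ``ridge_width_px`` the dilated ridge width.
    """

    shape: tuple[int, int] = (64, 64)
    pattern: str = "flat"
    base_height_nm: float = 60.0
    step_delta_nm: float = 40.0
    bleb_radius_px: float = 6.0
    bleb_height_nm: float = 80.0
    bleb_density: float = 0.002
    ridge_scale_px: float = 8.0
    ridge_width_px: int = 2
    ridge_height_nm: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise InvalidInputError(f"unknown pattern {self.pattern!r}; choose from {_PATTERNS}")
        if self.base_height_nm < 0 or self.bleb_height_nm < 0 or self.ridge_height_nm < 0:
            raise InvalidInputError("heights must be >= 0")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise InvalidInputError("shape must be (rows, cols) with positive sizes")


def make_height_field(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth height map for a phantom spec; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    h = np.full(spec.shape, float(spec.base_height_nm))

    if spec.pattern == "flat":
        return h

    if spec.pattern == "step":
        h[:, cols // 2:] += spec.step_delta_nm
        return h

    if spec.pattern == "blebs":
        n_caps = rng.poisson(spec.bleb_density * rows * cols)
        rr, cc = np.mgrid[0:rows, 0:cols]
        radius = spec.bleb_radius_px
        for _ in range(n_caps):
            cr = rng.uniform(0, rows)
            cl = rng.uniform(0, cols)
            d2 = (rr - cr) ** 2 + (cc - cl) ** 2
            inside = d2 < radius**2
            cap = spec.bleb_height_nm * np.sqrt(np.clip(1.0 - d2 / radius**2, 0, 1))
            h = np.where(inside, np.maximum(h, spec.base_height_nm + cap), h)
        return h

    # ridges: threshold a band-pass random field, skeletonize, dilate to width
    noise = rng.standard_normal(spec.shape)
    band = ndimage.gaussian_filter(noise, spec.ridge_scale_px) - ndimage.gaussian_filter(
        noise, 2.0 * spec.ridge_scale_px
    )
    mask = band > np.quantile(band, 0.7)
    ridge = skeletonize(mask)
    if spec.ridge_width_px > 1:
        ridge = dilation(ridge, disk(spec.ridge_width_px // 2))
    h[ridge] += spec.ridge_height_nm
    return h


def simulate_saim_stack(
    height_field: np.ndarray,
    amplitude_field,
    offset_field,
    config: OpticalStackConfig,
    grid: AngleGrid,
    noise: str = "none",
    gaussian_sd: float = 0.0,
    seed: int = 0,
    channel: str = "sim",
) -> AngleImageStack:
    """Angle-scan image stack of a height field under the interference model.

    The noiseless expectation equals ``A f(theta_j, H) + B`` exactly per
    pixel; ``noise="poisson"`` draws independent shot noise per (angle,
    pixel), ``noise="gaussian"`` adds read noise of the given sd.
    Scalar amplitude/offset broadcast over the field.
    """
    h = np.asarray(height_field, dtype=float)
    if h.ndim != 2:
        raise InvalidInputError("height_field must be 2-D")
    amp = np.broadcast_to(np.asarray(amplitude_field, dtype=float), h.shape)
    off = np.broadcast_to(np.asarray(offset_field, dtype=float), h.shape)
    if noise not in ("none", "poisson", "gaussian"):
        raise InvalidInputError(f"unknown noise model {noise!r}")

    f = excitation_probability(config, grid.angles_deg.reshape(-1, 1, 1), h[None, :, :])
    expected = amp[None] * f + off[None]

    if noise == "none":
        data = expected
    elif noise == "poisson":
        if np.any(expected <= 0):
            raise InvalidInputError("Poisson noise requires positive expected counts")
        rng = np.random.default_rng(seed)
        data = rng.poisson(expected).astype(float)
    else:
        rng = np.random.default_rng(seed)
        data = np.clip(expected + rng.normal(0.0, gaussian_sd, expected.shape), 0, None)

    return AngleImageStack(grid=grid, intensities=data, channel=channel,
                           d_oxide_nm=config.d_oxide_nm)


def _folded_decay_bins(tau_ns: float, rep_period_ns: float, n_bins: int) -> np.ndarray:
    """Bin probabilities of a mono-exponential folded to the repetition period."""
    edges = np.linspace(0.0, rep_period_ns, n_bins + 1)
    cdf = -np.expm1(-edges / tau_ns)  # 1 - exp(-t/tau)
    p = np.diff(cdf)
    return p / p.sum()


def _circular_shift(p: np.ndarray, shift_bins: float) -> np.ndarray:
    """Fractional circular shift by linear interpolation; conserves mass."""
    k = int(np.floor(shift_bins))
    frac = shift_bins - k
    rolled = np.roll(p, k)
    return (1.0 - frac) * rolled + frac * np.roll(rolled, 1)


def simulate_decay_image(
    fb_field: np.ndarray,
    tau_free_ns: float,
    tau_bound_ns: float,
    photons: float,
    rep_period_ns: float,
    n_bins: int,
    instrument_shift_ns: float = 0.0,
    seed: int = 0,
    channel: str = "sim",
) -> DecayImage:
    """Two-component decay cube over a known bound-fraction field.

    Per pixel the expected decay is ``photons * [FB * decay(tau_bound) +
    (1-FB) * decay(tau_free)]`` folded to the repetition period, optionally
    circular-shifted by the instrument delay; photons are drawn multinomially
    across bins so the total per pixel is exact.
    """
    fb = np.asarray(fb_field, dtype=float)
    if fb.ndim != 2 or np.any(fb < 0) or np.any(fb > 1) or not np.all(np.isfinite(fb)):
        raise InvalidInputError("fb_field must be 2-D with values in [0, 1]")
    if tau_free_ns <= 0 or tau_bound_ns <= 0:
        raise InvalidInputError("lifetimes must be > 0")
    if photons <= 0 or n_bins < 2:
        raise InvalidInputError("photons must be > 0 and n_bins >= 2")

    bin_width = rep_period_ns / n_bins
    p_free = _folded_decay_bins(tau_free_ns, rep_period_ns, n_bins)
    p_bound = _folded_decay_bins(tau_bound_ns, rep_period_ns, n_bins)
    if instrument_shift_ns:
        shift_bins = (instrument_shift_ns / bin_width) % n_bins
        p_free = _circular_shift(p_free, shift_bins)
        p_bound = _circular_shift(p_bound, shift_bins)

    # (rows, cols, n_bins) mixture probabilities
    pvals = fb[..., None] * p_bound[None, None, :] + (1.0 - fb[..., None]) * p_free[None, None, :]
    pvals /= pvals.sum(axis=-1, keepdims=True)

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(photons), pvals)  # batched over leading axes
    return DecayImage(
        counts=np.moveaxis(counts, -1, 0),
        bin_width_ns=bin_width,
        rep_period_ns=rep_period_ns,
        channel=channel,
    )


def simulate_isotopologues(
    n_carbons: int,
    label_fraction: float,
    total_signal: float = 1.0e6,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Binomially labeled isotopologue ladder M0..Mn for one metabolite.

    Each of the ``n_carbons`` carbons is 13C independently with probability
    ``label_fraction``, so the noiseless ladder is ``total_signal *
    Binomial(n, p)`` and its fractional contribution equals p exactly.
    ``noise_cv`` applies per-isotopologue lognormal noise of that CV.
    """
    if not 0 <= label_fraction <= 1:
        raise InvalidInputError("label_fraction must lie in [0, 1]")
    if n_carbons < 1 or total_signal <= 0 or noise_cv < 0:
        raise InvalidInputError("need n_carbons >= 1, total_signal > 0, noise_cv >= 0")
    pmf = stats.binom.pmf(np.arange(n_carbons + 1), n_carbons, label_fraction)
    abundances = total_signal * pmf
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_carbons + 1)
        abundances = abundances * factors
    return abundances
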