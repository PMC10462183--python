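"""Thin-film interference optics for scanning-angle interference microscopy (SAIM).

SAIM localizes fluorophores axially above a silicon wafer carrying a thermal
silicon-oxide spacer. A circle-scanned, s-polarized (TE) excitation laser hits
the wafer at a sequence of incidence angles; the direct and mirror-reflected
fields interfere at the fluorophore height H, so the excitation probability
oscillates with angle in a way that encodes H with nanometre sensitivity.

This module implements the forward model only:

* Snell refraction angles through buffer / oxide / silicon,
* the 2x2 characteristic (transfer) matrix of the oxide film,
* the TE stack reflection coefficient ``r_TE``,
* the axial phase shift ``phi = 4 pi n_b H cos(theta_b) / lambda``,
* the excitation probability ``f = |1 + r_TE exp(i phi)|^2`` (expanded form),
* the affine pixel intensity model ``I_j = A f(theta_j, H) + B``.

Conventions: angles are given in degrees *in the buffer medium*, measured from
the wafer normal; heights and wavelengths in nm (wavelength in vacuum).
Absorbing media carry a non-negative imaginary index; complex cosines use the
branch with ``Im(n cos(theta)) >= 0`` so that waves decay into the substrate.
Only TE (s) polarization is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGeometryError, InvalidInputError

__all__ = [
    "OpticalStackConfig",
    "AngleGrid",
    "TEResponse",
    "default_config",
    "default_angle_grid",
    "refraction_angles",
    "characteristic_matrix",
    "reflection_te",
    "phase_shift",
    "excitation_probability",
    "forward_intensity",
]

# Literature index values for common SAIM excitation lines (water buffer at
# ~37 C, thermal oxide, crystalline silicon). These are configurable defaults,
# never baked into any computed result; analyses should pin their own values.
_DEFAULT_INDICES = {
    488.0: {"n_buffer": 1.337, "n_oxide": 1.463, "n_silicon": 4.367 + 0.079j},
    560.0: {"n_buffer": 1.335, "n_oxide": 1.460, "n_silicon": 4.042 + 0.032j},
    642.0: {"n_buffer": 1.332, "n_oxide": 1.457, "n_silicon": 3.846 + 0.016j},
}


def _check_index(name: str, value: complex) -> complex:
    value = complex(value)
    if not (np.isfinite(value.real) and np.isfinite(value.imag)):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    if value.real <= 0:
        raise InvalidInputError(f"{name} must have positive real part, got {value!r}")
    if value.imag < 0:
        raise InvalidInputError(
            f"{name} must have non-negative imaginary part (absorption convention), "
            f"got {value!r}"
        )
    return value


@dataclass(frozen=True)
class OpticalStackConfig:
    """Physical constants of the silicon / oxide / buffer interference stack.

    Parameters
    ----------
    wavelength_nm
        Vacuum excitation wavelength (nm).
    n_buffer
        Refractive index of the imaging medium above the chip.
    n_oxide
        Refractive index of the thermal-oxide spacer (may be complex).
    n_silicon
        Complex refractive index of the silicon substrate; the imaginary part
        encodes absorption and must be >= 0.
    d_oxide_nm
        Oxide thickness in nm; measured per chip in practice (~1900 nm for
        standard SAIM wafers).
    """

    wavelength_nm: float
    n_buffer: complex = 1.335
    n_oxide: complex = 1.460
    n_silicon: complex = 4.042 + 0.032j
    d_oxide_nm: float = 1900.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.wavelength_nm) or self.wavelength_nm <= 0:
            raise InvalidInputError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if not np.isfinite(self.d_oxide_nm) or self.d_oxide_nm < 0:
            raise InvalidInputError(f"d_oxide_nm must be >= 0, got {self.d_oxide_nm}")
        for name in ("n_buffer", "n_oxide", "n_silicon"):
            object.__setattr__(self, name, _check_index(name, getattr(self, name)))


def default_config(wavelength_nm: float = 560.0, d_oxide_nm: float = 1900.0) -> OpticalStackConfig:
    """Config with documented literature indices for a standard laser line."""
    try:
        indices = _DEFAULT_INDICES[float(wavelength_nm)]
    except KeyError:
        raise InvalidInputError(
            f"no default indices for {wavelength_nm} nm; "
            f"known lines: {sorted(_DEFAULT_INDICES)} — build OpticalStackConfig directly"
        ) from None
    return OpticalStackConfig(wavelength_nm=wavelength_nm, d_oxide_nm=d_oxide_nm, **indices)


@dataclass(frozen=True)
class AngleGrid:
    """Ordered incidence angles (degrees, in the buffer, from the wafer normal)."""

    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        if angles.ndim != 1:
            raise InvalidInputError("angles_deg must be a 1-D sequence")
        if not np.all(np.isfinite(angles)):
            raise InvalidInputError("angles must be finite")
        if np.any(angles < 0) or np.any(angles >= 90):
            raise InvalidInputError("angles must lie in [0, 90) degrees")
        if len(angles) > 1 and not np.all(np.diff(angles) > 0):
            raise InvalidInputError("angles must be strictly increasing")
        object.__setattr__(self, "angles_deg", angles)

    def __len__(self) -> int:
        return len(self.angles_deg)


def default_angle_grid(n_angles: int = 32, min_deg: float = 5.0, max_deg: float = 43.75) -> AngleGrid:
    """Evenly spaced acquisition grid, endpoints inclusive.

    The standard SAIM acquisition uses 32 angles from 5 to 43.75 degrees.
    """
    if n_angles < 2:
        raise InvalidInputError("n_angles must be >= 2")
    if not (0 <= min_deg < max_deg < 90):
        raise InvalidInputError("require 0 <= min_deg < max_deg < 90")
    return AngleGrid(np.linspace(min_deg, max_deg, n_angles))


@dataclass
class TEResponse:
    """Intermediate TE-wave quantities of the stack at one or more angles.

    All fields are complex arrays broadcast to the shape of the input angle.
    ``p0, p1, p2`` are the TE admittances ``n_Si cos(theta_Si)``,
    ``n_ox cos(theta_ox)``, ``n_b cos(theta_b)``; ``m11..m22`` the oxide
    characteristic-matrix entries; ``r_te`` the stack reflection coefficient.
    """

    theta_ox: np.ndarray | None = None
    theta_si: np.ndarray | None = None
    p0: np.ndarray | None = None
    p1: np.ndarray | None = None
    p2: np.ndarray | None = None
    m11: np.ndarray | None = None
    m12: np.ndarray | None = None
    m21: np.ndarray | None = None
    m22: np.ndarray | None = None
    r_te: np.ndarray | None = field(default=None)


def _branch_cos(sin_theta: np.ndarray, n: complex) -> np.ndarray:
    """cos(theta) from sin(theta) with the decaying-wave branch.

    Principal square root of ``1 - sin^2``, with the sign flipped where needed
    so that ``Im(n cos(theta)) >= 0`` (fields decay, not grow, into an
    absorbing medium).
    """
    cos = np.sqrt((1.0 + 0j) - sin_theta**2)
    flip = np.imag(n * cos) < 0
    return np.where(flip, -cos, cos)


def _validate_angle(theta_b_deg) -> np.ndarray:
    theta = np.asarray(theta_b_deg, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise InvalidInputError("incidence angle must be finite")
    if np.any(theta < 0) or np.any(theta >= 90):
        raise InvalidInputError("incidence angle must lie in [0, 90) degrees")
    return theta


def refraction_angles(config: OpticalStackConfig, theta_b_deg) -> TEResponse:
    """Snell refraction angles in oxide and silicon for a buffer-side angle.

    ``n_b sin(theta_b) = n_ox sin(theta_ox) = n_Si sin(theta_Si)``; the
    returned :class:`TEResponse` has ``theta_ox``/``theta_si`` and the three
    admittances populated.
    """
    theta_b = np.deg2rad(_validate_angle(theta_b_deg))
    sin_b = np.sin(theta_b) + 0j
    sin_ox = config.n_buffer * sin_b / config.n_oxide
    sin_si = config.n_buffer * sin_b / config.n_silicon
    cos_b = np.cos(theta_b) + 0j
    cos_ox = _branch_cos(sin_ox, config.n_oxide)
    cos_si = _branch_cos(sin_si, config.n_silicon)
    return TEResponse(
        theta_ox=np.arcsin(sin_ox),
        theta_si=np.arcsin(sin_si),
        p0=config.n_silicon * cos_si,
        p1=config.n_oxide * cos_ox,
        p2=config.n_buffer * cos_b,
    )


def characteristic_matrix(config: OpticalStackConfig, theta_b_deg) -> TEResponse:
    """Characteristic (transfer) matrix of the oxide film for the TE wave.

    With ``beta = k_ox d_ox cos(theta_ox)`` and ``k_ox = 2 pi n_ox / lambda``:
    ``m11 = m22 = cos(beta)``, ``m12 = -i sin(beta)/p1``, ``m21 = -i p1 sin(beta)``.
    Unimodular (det M = 1) for a lossless oxide.
    """
    resp = refraction_angles(config, theta_b_deg)
    if np.any(np.abs(resp.p1) == 0):
        raise DegenerateGeometryError("oxide admittance p1 = 0 (grazing pathological case)")
    k_ox = 2.0 * np.pi * config.n_oxide / config.wavelength_nm
    cos_ox = resp.p1 / config.n_oxide
    beta = k_ox * config.d_oxide_nm * cos_ox
    resp.m11 = resp.m22 = np.cos(beta)
    sin_beta = np.sin(beta)
    resp.m12 = -1j * sin_beta / resp.p1
    resp.m21 = -1j * resp.p1 * sin_beta
    return resp


def reflection_te(config: OpticalStackConfig, theta_b_deg) -> TEResponse:
    """TE reflection coefficient of the buffer / oxide / silicon stack.

    Standard stratified-media form with incident medium = buffer (p2) and
    substrate = silicon (p0):

    ``r = [(m11 + m12 p0) p2 - (m21 + m22 p0)] / [(m11 + m12 p0) p2 + (m21 + m22 p0)]``

    For ``d_ox = 0`` this reduces to the two-media Fresnel TE coefficient
    ``(p2 - p0)/(p2 + p0)``.
    """
    resp = characteristic_matrix(config, theta_b_deg)
    top = (resp.m11 + resp.m12 * resp.p0) * resp.p2
    bottom = resp.m21 + resp.m22 * resp.p0
    den = top + bottom
    if np.any(np.abs(den) == 0):
        raise DegenerateGeometryError("zero denominator in reflection coefficient")
    resp.r_te = (top - bottom) / den
    return resp


def phase_shift(config: OpticalStackConfig, theta_b_deg, height_nm) -> np.ndarray:
    """Axial interference phase ``phi = 4 pi n_b H cos(theta_b) / lambda`` (rad)."""
    theta_b = np.deg2rad(_validate_angle(theta_b_deg))
    height = np.asarray(height_nm, dtype=float)
    if not np.all(np.isfinite(height)) or np.any(height < 0):
        raise InvalidInputError("height_nm must be finite and >= 0")
    n_b = np.real(config.n_buffer)
    return 4.0 * np.pi * n_b * height * np.cos(theta_b) / config.wavelength_nm


def excitation_probability(config: OpticalStackConfig, theta_b_deg, height_nm) -> np.ndarray:
    """Excitation probability of a fluorophore at height H above the oxide.

    ``f = 1 + 2 Re(r) cos(phi) - 2 Im(r) sin(phi) + Re(r)^2 + Im(r)^2``,
    algebraically ``|1 + r_TE exp(i phi)|^2``.
    """
    r = reflection_te(config, theta_b_deg).r_te
    phi = phase_shift(config, theta_b_deg, height_nm)
    re_r, im_r = np.real(r), np.imag(r)
    return 1.0 + 2.0 * re_r * np.cos(phi) - 2.0 * im_r * np.sin(phi) + re_r**2 + im_r**2


def forward_intensity(
    config: OpticalStackConfig,
    grid: AngleGrid,
    height_nm: float,
    amplitude: float,
    offset: float,
) -> np.ndarray:
    """Modeled pixel intensity ``I_j = A f(theta_j, H) + B`` over the grid."""
    if len(grid) < 1:
        raise InvalidInputError("angle grid must have at least one angle")
    f = excitation_probability(config, grid.angles_deg, height_nm)
    return amplitude * f + offset
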