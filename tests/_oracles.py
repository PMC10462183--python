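"""Independent oracles used to cross-check the implementation.

These re-derive the physics from scratch (recursive Fresnel / Airy film
summation, complex-modulus excitation probability, general linear least
squares) and deliberately share no code with the package internals.
"""

import numpy as np


def airy_reflection_te(wavelength_nm, n_buffer, n_oxide, n_silicon, d_oxide_nm, theta_deg):
    """TE stack reflection by summing multiple reflections in the oxide film.

    r = (r12 + r23 e^{2 i beta}) / (1 + r12 r23 e^{2 i beta}) with the
    interface Fresnel coefficients r12 (buffer->oxide) and r23
    (oxide->silicon) and the one-pass film phase beta.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    sin_b = np.sin(theta) + 0j
    sin_ox = n_buffer * sin_b / n_oxide
    sin_si = n_buffer * sin_b / n_silicon

    def branch_cos(sin_t, n):
        cos_t = np.sqrt(1 - sin_t**2)
        return np.where(np.imag(n * cos_t) < 0, -cos_t, cos_t)

    p2 = n_buffer * (np.cos(theta) + 0j)
    p1 = n_oxide * branch_cos(sin_ox, n_oxide)
    p0 = n_silicon * branch_cos(sin_si, n_silicon)
    r12 = (p2 - p1) / (p2 + p1)
    r23 = (p1 - p0) / (p1 + p0)
    beta = 2 * np.pi * n_oxide / wavelength_nm * d_oxide_nm * (p1 / n_oxide)
    phase = np.exp(2j * beta)
    return (r12 + r23 * phase) / (1 + r12 * r23 * phase)


def fresnel_te_two_media(n_in, n_out, theta_deg):
    """Two-media Fresnel TE coefficient (no film)."""
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    sin_t = n_in * (np.sin(theta) + 0j) / n_out
    cos_t = np.sqrt(1 - sin_t**2)
    cos_t = np.where(np.imag(n_out * cos_t) < 0, -cos_t, cos_t)
    p_in = n_in * (np.cos(theta) + 0j)
    p_out = n_out * cos_t
    return (p_in - p_out) / (p_in + p_out)


def excitation_modulus(r_te, phi):
    """|1 + r e^{i phi}|^2 evaluated directly in complex arithmetic."""
    return np.abs(1.0 + r_te * np.exp(1j * phi)) ** 2


def linear_ab_lstsq(f, intensities):
    """General linear least-squares solve of I = A f + B via numpy.lstsq."""
    design = np.column_stack([f, np.ones_like(f)])
    coef, *_ = np.linalg.lstsq(design, intensities, rcond=None)
    return coef[0], coef[1]
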