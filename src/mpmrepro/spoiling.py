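"""RF-spoiling simulation and spoiling-correction coefficients.

Ideal spoiling destroys all transverse magnetization before each excitation,
giving the Ernst closed form.  Real sequences approximate this with quadratic
RF phase cycling (50 deg increment here); the residual transverse coherences
bias the steady-state signal and hence the two-point R1 estimate.  This module
simulates the imperfectly spoiled steady state with an isochromat ensemble and
derives the linear T1 correction T1_corr = a(f_T) + b(f_T) * T1_app used on
the estimation side, with coefficients a, b fitted as polynomials in the
transmit field.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import RegularGridInterpolator

DEFAULT_PHASE_INC_DEG = 50.0
DEFAULT_T2 = 0.070  # s; single representative tissue T2 for the simulation
DEFAULT_N_ISO = 256


def isochromat_signal(
    alpha, r1, tr,
    t2: float = DEFAULT_T2,
    phase_inc_deg: float = DEFAULT_PHASE_INC_DEG,
    n_iso: int = DEFAULT_N_ISO,
    n_exc: int | None = None,
    n_avg: int = 64,
):
    """Steady-state signal magnitude of an RF- and gradient-spoiled FLASH
    sequence, relative to an amplitude of 1 (so ideal spoiling would give the
    Ernst value sin(alpha) * m).

    ``alpha`` and ``r1`` broadcast against each other.  The ensemble uses
    ``n_iso`` isochromats uniformly dephased across 2*pi per TR by the spoiler
    gradient; the RF phase follows the quadratic schedule
    phi_n = phase_inc * n * (n + 1) / 2.  The returned value is the mean
    demodulated signal magnitude over the last ``n_avg`` excitations.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    r1 = np.atleast_1d(np.asarray(r1, dtype=float))
    alpha, r1 = np.broadcast_arrays(alpha, r1)
    shape = alpha.shape
    if n_exc is None:
        t1max = 1.0 / max(r1.min(), 1e-3)
        n_exc = int(min(max(5.0 * t1max / tr, 500), 4000))

    e1 = np.exp(-tr * r1)[..., None]
    e2 = np.exp(-tr / t2)
    theta = 2.0 * np.pi * (np.arange(n_iso) + 0.5) / n_iso
    dephase = e2 * np.exp(1j * theta)

    m = np.zeros(shape + (n_iso,), dtype=complex)
    mz = np.ones(shape + (n_iso,))
    ca, sa = np.cos(alpha)[..., None], np.sin(alpha)[..., None]
    cos2, sin2 = (1.0 + ca) / 2.0, (1.0 - ca) / 2.0

    inc = np.deg2rad(phase_inc_deg)
    sig_acc = np.zeros(shape)
    for n in range(n_exc):
        phi = inc * n * (n + 1) / 2.0
        eiphi = np.exp(1j * phi)
        m_rot = m * np.exp(-1j * phi)
        m_new = eiphi * (
            m_rot * cos2 + np.conj(m_rot) * sin2 + 1j * sa * mz
        )
        mz_new = mz * ca - np.imag(m_rot) * sa
        m, mz = m_new, mz_new
        if n >= n_exc - n_avg:
            sig_acc += np.abs((m * np.exp(-1j * phi)).mean(axis=-1))
        # free precession + relaxation over TR
        m = m * dephase
        mz = 1.0 + (mz - 1.0) * e1[..., 0:1]
    return (sig_acc / n_avg).reshape(shape)


@lru_cache(maxsize=8)
def _scale_interpolator(tr, t2, phase_inc_deg, n_iso):
    """Interpolator of the imperfect/ideal signal ratio over (alpha, r1)."""
    alphas = np.linspace(0.05, 0.55, 14)
    r1s = np.linspace(0.2, 2.5, 10)
    aa, rr = np.meshgrid(alphas, r1s, indexing="ij")
    iso = isochromat_signal(
        aa, rr, tr, t2=t2, phase_inc_deg=phase_inc_deg, n_iso=n_iso
    )
    e1 = np.exp(-tr * rr)
    ernst = np.sin(aa) * (1 - e1) / (1 - e1 * np.cos(aa))
    return RegularGridInterpolator(
        (alphas, r1s), iso / ernst, bounds_error=False, fill_value=None
    )


def spoiling_scale(
    alpha_local, r1, tr,
    t2: float = DEFAULT_T2,
    phase_inc_deg: float = DEFAULT_PHASE_INC_DEG,
    n_iso: int = DEFAULT_N_ISO,
):
    """Multiplicative deviation of the imperfectly spoiled signal from the
    Ernst closed form, interpolated from a precomputed (alpha, R1) table."""
    interp = _scale_interpolator(round(tr, 6), t2, phase_inc_deg, n_iso)
    alpha = np.asarray(alpha_local, dtype=float)
    r1c = np.clip(np.asarray(r1, dtype=float), 0.2, 2.5)
    pts = np.stack([alpha.ravel(), np.broadcast_to(r1c, alpha.shape).ravel()], axis=-1)
    return interp(pts).reshape(alpha.shape)


@dataclass(frozen=True)
class SpoilingCorrection:
    """T1_corr = a(f_T) + b(f_T) * T1_app with polynomial coefficients in the
    transmit field (highest order first, numpy polyval convention)."""

    poly_a: tuple[float, ...]
    poly_b: tuple[float, ...]

    def correct_t1(self, t1_app, f_t):
        a = np.polyval(self.poly_a, f_t)
        b = np.polyval(self.poly_b, f_t)
        return a + b * t1_app

    @staticmethod
    def identity() -> "SpoilingCorrection":
        return SpoilingCorrection(poly_a=(0.0,), poly_b=(1.0,))


def fit_spoiling_coefficients(
    spec_t1w, spec_pdw,
    t2: float = DEFAULT_T2,
    phase_inc_deg: float = DEFAULT_PHASE_INC_DEG,
    n_iso: int = DEFAULT_N_ISO,
    f_grid=None,
    t1_grid=None,
    poly_deg: int = 3,
) -> SpoilingCorrection:
    """Derive the spoiling-correction coefficients for a protocol pair.

    For each transmit-field value f, imperfectly spoiled steady-state signals
    of the two acquisitions are simulated over a grid of true T1, inverted
    with the two-point rational approximation at *local* flip angles (i.e.
    after transmit correction), and the linear map from apparent to true T1 is
    fitted; a(f) and b(f) are then fitted as polynomials in f.
    """
    from .mapfit import two_point_rational

    if f_grid is None:
        f_grid = np.linspace(0.7, 1.3, 7)
    if t1_grid is None:
        t1_grid = np.linspace(0.6, 2.2, 6)
    r1_grid = 1.0 / np.asarray(t1_grid)

    a_vals, b_vals = [], []
    for f in f_grid:
        s1 = isochromat_signal(
            f * spec_t1w.flip_angle, r1_grid, spec_t1w.tr,
            t2=t2, phase_inc_deg=phase_inc_deg, n_iso=n_iso,
        )
        s2 = isochromat_signal(
            f * spec_pdw.flip_angle, r1_grid, spec_pdw.tr,
            t2=t2, phase_inc_deg=phase_inc_deg, n_iso=n_iso,
        )
        _, r1_app = two_point_rational(
            s1, s2,
            f * spec_t1w.flip_angle, f * spec_pdw.flip_angle,
            spec_t1w.tr, spec_pdw.tr,
        )
        t1_app = 1.0 / r1_app
        b, a = np.polyfit(t1_app, np.asarray(t1_grid), 1)
        a_vals.append(a)
        b_vals.append(b)
    return SpoilingCorrection(
        poly_a=tuple(np.polyfit(f_grid, a_vals, poly_deg)),
        poly_b=tuple(np.polyfit(f_grid, b_vals, poly_deg)),
    )
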