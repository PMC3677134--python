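"""Estimation of quantitative maps from the three multi-echo FLASH scans.

The chain mirrors the multi-parameter mapping recipe: arithmetic echo
averaging for SNR, a two-point inversion of the rational (low-angle, short-TR)
FLASH approximation for amplitude and apparent R1, transmit-field and
RF-spoiling corrections of R1, the semi-quantitative MT saturation with its
semi-empirical B1 correction, a log-linear R2* fit over the eight PD-weighted
echoes, smooth receive-bias removal from the amplitude map and a global
white-matter PD calibration to 69 percent units.

Invalid voxels (non-positive signals, degenerate denominators) are marked NaN
and propagate; callers shrink masks accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import MT_B1_CONSTANT, EchoSeries
from .grids import Grid, SmoothFieldFitter
from .spoiling import SpoilingCorrection

log = logging.getLogger(__name__)

WM_PD_CALIBRATION_PU = 69.0


@dataclass
class MeanWeightedImage:
    """Arithmetic mean over the first echoes of one weighting."""

    weighting: str
    data: np.ndarray
    effective_te: float  # s; arithmetic mean of the averaged echoes' TEs
    tr: float
    flip_angle: float
    grid: Grid


@dataclass
class QuantMaps:
    """The estimated parameter maps of one (volunteer, site) cell."""

    r1: np.ndarray  # 1/s
    a: np.ndarray  # amplitude, arbitrary units
    pd: np.ndarray  # p.u. once calibrated
    mt: np.ndarray  # p.u.
    r2s: np.ndarray  # 1/s
    grid: Grid
    flags: dict = field(default_factory=dict)


def average_first_echoes(series: EchoSeries, n: int = 6) -> MeanWeightedImage:
    """Voxel-wise arithmetic mean of the first ``n`` echoes (shortest TEs).

    For the default protocol the six averaged echoes give an effective
    TE of 8.45 ms.
    """
    if n < 1 or n > series.data.shape[-1]:
        raise ValueError(f"cannot average {n} echoes of {series.data.shape[-1]}")
    return MeanWeightedImage(
        weighting=series.weighting,
        data=series.data[..., :n].mean(axis=-1),
        effective_te=float(np.mean(series.echo_times[:n])),
        tr=series.tr,
        flip_angle=series.flip_angle,
        grid=series.grid,
    )


def fit_r2star(series: EchoSeries, mask: np.ndarray | None = None):
    """Per-voxel ordinary least squares of ln(S) against TE.

    Returns ``(r2s, intercept)`` where r2s = −slope (1/s) and the intercept is
    the ln S(TE=0) diagnostic.  Voxels with any non-positive signal inside the
    mask are excluded (NaN) and counted in the log.
    """
    data = series.data
    if data.shape[-1] < 2:
        raise ValueError("need at least two echoes for the R2* fit")
    if mask is None:
        mask = np.ones(data.shape[:-1], dtype=bool)
    te = np.asarray(series.echo_times)
    valid = mask & np.all(data > 0, axis=-1)
    n_excl = int(mask.sum() - valid.sum())
    if n_excl:
        log.info("fit_r2star: %d voxels with non-positive signal excluded", n_excl)

    logs = np.log(data[valid])
    te_c = te - te.mean()
    slope = (logs * te_c).sum(axis=-1) / (te_c**2).sum()
    icpt = logs.mean(axis=-1) - slope * te.mean()

    r2s = np.full(data.shape[:-1], np.nan)
    intercept = np.full(data.shape[:-1], np.nan)
    r2s[valid] = -slope
    intercept[valid] = icpt
    return r2s, intercept


def two_point_rational(s1, s2, a1, a2, tr1, tr2):
    """Exact inversion of the rational FLASH approximation
    S ≈ A·α·TR·R1 / (α²/2 + TR·R1) from two acquisitions.

    Index 1 is the T1-weighted, index 2 the PD-weighted acquisition; the
    flip angles may be maps (local angles) or scalars (nominal angles).
    Degenerate voxels and non-positive estimates come back as NaN.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.all(a1 == a2) and tr1 == tr2:
        raise ValueError("the two acquisitions must differ in (alpha, TR)")
    num_r1 = s1 * a1 / tr1 - s2 * a2 / tr2
    den_r1 = 2.0 * (s2 / a2 - s1 / a1)
    num_a = s1 * s2 * (a1**2 / tr1 - a2**2 / tr2)
    den_a = a1 * a2 * num_r1
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = num_r1 / den_r1
        a = num_a / den_a
    bad = ~np.isfinite(r1) | ~np.isfinite(a) | (r1 <= 0) | (a <= 0)
    r1 = np.where(bad, np.nan, r1)
    a = np.where(bad, np.nan, a)
    return a, r1


def estimate_a_r1_apparent(
    t1w_mean: MeanWeightedImage, pdw_mean: MeanWeightedImage
):
    """Apparent amplitude and R1 maps from the two mean images, using the
    nominal flip angles (transmit correction is applied separately)."""
    if t1w_mean.grid != pdw_mean.grid:
        raise ValueError("mean images are on different grids")
    if (
        t1w_mean.flip_angle == pdw_mean.flip_angle
        and t1w_mean.tr == pdw_mean.tr
    ):
        raise ValueError("identical (alpha, TR): cannot separate A and R1")
    a, r1 = two_point_rational(
        t1w_mean.data, pdw_mean.data,
        t1w_mean.flip_angle, pdw_mean.flip_angle,
        t1w_mean.tr, pdw_mean.tr,
    )
    n_bad = int(np.isnan(r1).sum())
    if n_bad:
        log.info("estimate_a_r1_apparent: %d invalid voxels", n_bad)
    return a, r1


def correct_r1(
    r1_app: np.ndarray,
    b1: np.ndarray,
    spoiling: SpoilingCorrection | None = None,
):
    """Transmit-field and RF-spoiling correction of the apparent R1.

    Re-estimating with local flip angles α_i·f_T is algebraically identical to
    scaling the nominal-angle estimate by f_T², which is done here; the
    spoiling correction T1_corr = a(f_T) + b(f_T)·T1_app then maps the
    (transmit-corrected) apparent T1 to the true T1.  Voxels with transmit
    field outside [0.5, 1.5] are flagged invalid.
    """
    b1 = np.asarray(b1, dtype=float)
    f_ok = (b1 >= 0.5) & (b1 <= 1.5)
    r1 = np.where(f_ok, r1_app * b1**2, np.nan)
    if spoiling is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = spoiling.correct_t1(1.0 / r1, b1)
            r1 = np.where(t1 > 0, 1.0 / t1, np.nan)
    return r1


def correct_amplitude(a_app: np.ndarray, b1: np.ndarray):
    """Transmit correction of the amplitude map (the local-angle re-estimate
    equals the nominal-angle amplitude divided by f_T)."""
    return np.asarray(a_app, dtype=float) / np.asarray(b1, dtype=float)


def compute_mt_sat(
    mtw_mean: MeanWeightedImage,
    a_map: np.ndarray,
    r1_map: np.ndarray,
    b1: np.ndarray | None = None,
):
    """Semi-quantitative MT saturation (uncorrected), in percent units:

        δ = (A·α/S_MT − 1)·TR_MT·R1 − α²/2

    with the excitation angle α taken as the local angle f_T·α_MT when a B1
    map is supplied (A and R1 are then the transmit-corrected maps); without a
    B1 map the nominal angle is used and apparent inputs are consistent.
    """
    alpha = mtw_mean.flip_angle * (np.asarray(b1, float) if b1 is not None else 1.0)
    s_mt = np.asarray(mtw_mean.data, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a_map * alpha / s_mt - 1.0) * mtw_mean.tr * r1_map - alpha**2 / 2.0
    delta = np.where(s_mt > 0, delta, np.nan)
    return 100.0 * delta


def correct_mt_b1(mt_uncorr_pu: np.ndarray, b1: np.ndarray):
    """Semi-empirical B1 correction of the MT saturation:

        MT_corr = MT_uncorr · (1 − 0.4) / (1 − 0.4 · RF_local)

    RF_local is the measured relative local flip angle.  Voxels at or beyond
    the formula's pole (RF_local ≥ 2.5) are flagged invalid.
    """
    b1 = np.asarray(b1, dtype=float)
    out = mt_uncorr_pu * (1.0 - MT_B1_CONSTANT) / (1.0 - MT_B1_CONSTANT * b1)
    return np.where(b1 < 1.0 / MT_B1_CONSTANT, out, np.nan)


def estimate_receive_bias(
    a_map: np.ndarray,
    brain_mask: np.ndarray,
    grid: Grid,
    cutoff_mm: float = 60.0,
    n_classes: int = 5,
    tol: float = 1e-4,
    max_iter: int = 50,
    priors: dict[str, np.ndarray] | None = None,
    ridge: float = 0.5,
):
    """Estimate a smooth multiplicative receive-bias field from the amplitude
    map so that A / b is receive-flat.

    Generative model in the log domain: log A = mu_k + log b + noise, with a
    small number of tissue-intensity classes and a band-limited smooth field
    log b.  EM alternates soft classification of bias-corrected
    log-amplitudes with a least-squares smooth fit of the residual given the
    class means, until the field changes by less than ``tol`` or ``max_iter``
    iterations.

    When spatial prior probability maps are given (``priors``, a dict with
    csf/gm/wm volumes, as in generative unified segmentation) they anchor the
    classification — this is the configuration the pipeline uses.  Without
    priors the mixing weights are global and the field is initialized with a
    single-class pre-fit (the bias dominates tissue contrast at 200-300% coil
    profiles).  The field is normalized to mean 1 over the mask.  Returns
    ``(field, converged)``; non-convergence returns the last iterate with a
    warning.
    """
    if not np.any(brain_mask):
        raise ValueError("brain mask is empty")
    mask = brain_mask & np.isfinite(a_map) & (a_map > 0)
    x = np.log(a_map[mask])
    fitter = SmoothFieldFitter(grid, mask, cutoff_mm, ridge=ridge)

    if priors is not None:
        pri = np.stack(
            [np.clip(priors[k][mask], 1e-4, None) for k in sorted(priors)],
            axis=1,
        )
        pri /= pri.sum(axis=1, keepdims=True)
        n_classes = pri.shape[1]
        coef = np.zeros(fitter.n_basis)
        log_b = np.zeros(x.shape)
        w = pri.sum(axis=0)
        mu = (pri * x[:, None]).sum(axis=0) / w
        sd = np.sqrt((pri * (x[:, None] - mu) ** 2).sum(axis=0) / w)
    else:
        pri = np.full((x.size, n_classes), 1.0 / n_classes)
        coef, log_b = fitter.fit_masked(x - x.mean())
        resid0 = x - log_b
        mu = np.quantile(resid0, np.linspace(0.08, 0.92, n_classes))
        sd = np.full(n_classes, max(resid0.std() / n_classes, 1e-6))

    sd_floor = 1e-4 * max(abs(x).mean(), 1e-30)
    converged = False
    for _ in range(max_iter):
        r = x - log_b
        logp = (
            -0.5 * ((r[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            + np.log(pri)
        )
        logp -= logp.max(axis=1, keepdims=True)
        resp = np.exp(logp)
        resp /= resp.sum(axis=1, keepdims=True)
        w = resp.sum(axis=0)
        if priors is None:
            pri = np.broadcast_to(w / w.sum(), resp.shape)
        mu = (resp * r[:, None]).sum(axis=0) / w
        sd = np.maximum(
            np.sqrt((resp * (r[:, None] - mu[None, :]) ** 2).sum(axis=0) / w),
            sd_floor,
        )
        coef, new_log_b = fitter.fit_masked(x - resp @ mu)
        change = np.max(np.abs(new_log_b - log_b))
        log_b = new_log_b
        if change < tol:
            converged = True
            break
    if not converged:
        log.warning("estimate_receive_bias did not converge in %d iterations", max_iter)
    b = np.exp(fitter.evaluate(coef))
    b /= b[mask].mean()
    return b, converged


def calibrate_pd(
    a_corrected: np.ndarray, wm_mask: np.ndarray, target_pu: float = WM_PD_CALIBRATION_PU
):
    """Global scaling of the receive-corrected amplitude so that the mean over
    the white-matter calibration mask is exactly ``target_pu`` (69 p.u.).

    No TE = 0 extrapolation is performed: the calibrated map retains the R2*
    weighting of the effective echo time and is therefore an *effective*
    proton density (PD*).
    """
    if not np.any(wm_mask):
        raise ValueError("white-matter calibration mask is empty")
    ref = np.nanmean(a_corrected[wm_mask])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("calibration mask mean is not positive")
    return a_corrected * (target_pu / ref)
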