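"""Forward simulation of the three multi-echo FLASH acquisitions.

Signal model: RF-spoiled steady state of the event cycle {MT partial
saturation of the longitudinal magnetization by a factor (1 − δ) → excitation
by the local flip angle → T1 relaxation over TR}, read out at several gradient
echoes with mono-exponential R2* decay:

    m  = (1 − δ) (1 − E1) / (1 − (1 − δ) E1 cos α),   E1 = exp(−TR·R1)
    S  = A · sin α · m · exp(−TE·R2*)

With δ = 0 this is the Ernst equation.  The transmit field scales the local
flip angle (α_local = f_T·α) and, for the MT-weighted scan, the applied
saturation follows δ_app = δ_true·(1 − 0.4·f_T)/0.6 — the inverse of the
semi-empirical B1 correction applied on the estimation side — with a
quadratic-in-B1 alternative available for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, apply_rigid
from .phantom import Phantom, SiteRealization

MT_B1_CONSTANT = 0.4  # semi-empirical constant of the MT B1 correction


@dataclass(frozen=True)
class AcquisitionSpec:
    """One multi-echo FLASH protocol (SI units: s, rad)."""

    weighting: str  # "T1w" | "PDw" | "MTw"
    tr: float
    flip_angle: float
    echo_times: tuple[float, ...]
    mt_pulse: bool = False
    spoiling: str = "ideal"  # "ideal" | "simulated"

    def __post_init__(self):
        if self.weighting not in ("T1w", "PDw", "MTw"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        te = np.asarray(self.echo_times)
        if len(te) < 1 or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.spoiling not in ("ideal", "simulated"):
            raise ValueError("spoiling must be 'ideal' or 'simulated'")


def _equidistant(first_ms: float, last_ms: float, n: int) -> tuple[float, ...]:
    return tuple(np.linspace(first_ms, last_ms, n) * 1e-3)


# The multi-centre protocol: TR/α = 18.7 ms/20° (T1w) and 23.7 ms/6°
# (PDw, MTw); 6 equidistant echoes 2.2–14.7 ms for T1w/MTw, 8 echoes
# 2.2–19.7 ms for PDw.  The first six echo times coincide across scans.
T1W_SPEC = AcquisitionSpec("T1w", 18.7e-3, np.deg2rad(20.0), _equidistant(2.2, 14.7, 6))
PDW_SPEC = AcquisitionSpec("PDw", 23.7e-3, np.deg2rad(6.0), _equidistant(2.2, 19.7, 8))
MTW_SPEC = AcquisitionSpec(
    "MTw", 23.7e-3, np.deg2rad(6.0), _equidistant(2.2, 14.7, 6), mt_pulse=True
)
DEFAULT_PROTOCOL = {"T1w": T1W_SPEC, "PDw": PDW_SPEC, "MTw": MTW_SPEC}


@dataclass
class EchoSeries:
    """4-D multi-echo stack (x, y, z, echo) for one weighting."""

    weighting: str
    data: np.ndarray
    echo_times: tuple[float, ...]
    tr: float
    flip_angle: float
    grid: Grid
    site_id: int = 0
    volunteer_id: int = 0

    def __post_init__(self):
        if self.data.shape[-1] != len(self.echo_times):
            raise ValueError("echo count does not match echo_times")


def steady_state_signal(amplitude, r1, r2s, delta_app, alpha_local, tr, te):
    """Closed-form spoiled steady-state FLASH signal (broadcasts over arrays).

    ``delta_app`` is the applied MT saturation as a fraction (not p.u.).
    """
    r1 = np.asarray(r1, dtype=float)
    delta_app = np.asarray(delta_app, dtype=float)
    alpha_local = np.asarray(alpha_local, dtype=float)
    if np.any(r1 < 0) or np.any(np.asarray(r2s) < 0):
        raise ValueError("relaxation rates must be non-negative")
    if np.any(delta_app < 0) or np.any(delta_app >= 1):
        raise ValueError("MT saturation fraction must lie in [0, 1)")
    if np.any(alpha_local <= 0) or np.any(alpha_local >= np.pi / 2):
        raise ValueError("local flip angle must lie in (0, pi/2)")
    e1 = np.exp(-tr * r1)
    m = (1.0 - delta_app) * (1.0 - e1) / (1.0 - (1.0 - delta_app) * e1 * np.cos(alpha_local))
    return amplitude * np.sin(alpha_local) * m * np.exp(-np.asarray(te) * r2s)


def mt_forward_saturation(mt_true_pu, f_t, law: str = "inverse-correction"):
    """Applied MT saturation fraction as a function of the transmit field.

    ``inverse-correction`` mirrors the published estimation-side correction
    exactly; ``quadratic`` scales the pulse saturation with B1 power.
    """
    frac = np.asarray(mt_true_pu, dtype=float) / 100.0
    if law == "inverse-correction":
        return frac * (1.0 - MT_B1_CONSTANT * f_t) / (1.0 - MT_B1_CONSTANT)
    if law == "quadratic":
        return frac * f_t**2
    raise ValueError(f"unknown MT forward law {law!r}")


def add_noise(volume, noise_sd, model="gaussian", seed=0):
    """Additive Gaussian or Rician (magnitude of complex Gaussian) noise."""
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if noise_sd == 0:
        return np.asarray(volume).copy()
    rng = np.random.default_rng(seed)
    volume = np.asarray(volume, dtype=float)
    if model == "gaussian":
        return volume + noise_sd * rng.standard_normal(volume.shape)
    if model == "rician":
        re = volume + noise_sd * rng.standard_normal(volume.shape)
        im = noise_sd * rng.standard_normal(volume.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def _noise_free_base(
    phantom: Phantom, site: SiteRealization, spec: AcquisitionSpec,
    mt_law: str = "inverse-correction",
):
    """TE-independent part of the signal on the reference grid: everything
    except the exp(−TE·R2*) decay, including the receive field."""
    alpha_local = site.f_t * spec.flip_angle
    delta = (
        mt_forward_saturation(phantom.truth["mt"], site.f_t, mt_law)
        if spec.mt_pulse
        else 0.0
    )
    base = steady_state_signal(
        phantom.truth["pd"], phantom.truth["r1"], 0.0, delta, alpha_local,
        spec.tr, 0.0,
    )
    if spec.spoiling == "simulated":
        from .spoiling import spoiling_scale

        base = base * spoiling_scale(
            alpha_local, phantom.truth["r1"], spec.tr
        )
    base = base * site.f_r
    base[~phantom.brain_mask] = 0.0
    return base


def simulate_echo_series(
    phantom: Phantom,
    site: SiteRealization,
    spec: AcquisitionSpec,
    seed: int = 0,
    mt_law: str = "inverse-correction",
) -> EchoSeries:
    """Simulate one multi-echo FLASH scan at one site.

    The noise-free signal is computed on the reference grid, moved by the
    site's rigid pose (trilinear, simulating acquisition at the displaced
    position), and noise is added per echo.  Deterministic given ``seed``.
    """
    if site.grid != phantom.grid:
        raise ValueError("phantom and site are on different grids")
    if site.noise_sd is None:
        raise ValueError(
            "site noise SD unset; call calibrate_noise_sd or set SiteSpec.noise_sd"
        )
    base = _noise_free_base(phantom, site, spec, mt_law)
    r2s = phantom.truth["r2s"]
    echoes = []
    for i, te in enumerate(spec.echo_times):
        vol = base * np.exp(-te * r2s)
        vol = apply_rigid(vol, phantom.grid, site.pose, order=1, cval=0.0)
        vol = add_noise(
            vol, site.noise_sd, model=site.noise_model,
            seed=np.random.SeedSequence([seed, i]),
        )
        echoes.append(vol)
    return EchoSeries(
        weighting=spec.weighting,
        data=np.stack(echoes, axis=-1),
        echo_times=spec.echo_times,
        tr=spec.tr,
        flip_angle=spec.flip_angle,
        grid=phantom.grid,
        site_id=site.site_id,
        volunteer_id=phantom.volunteer_id,
    )


def measured_b1_series(site: SiteRealization) -> np.ndarray:
    """The site's measured B1 map as acquired (moved by the head pose)."""
    return apply_rigid(site.b1_measured, site.grid, site.pose, order=1, cval=1.0)


def calibrate_noise_sd(
    phantom: Phantom,
    site: SiteRealization,
    spec: AcquisitionSpec | None = None,
    target_snr: float = 50.0,
) -> float:
    """Noise SD giving the target SNR for the mean WM signal of the first
    PDw echo (the protocol's highest-SNR anchor point)."""
    from .forward import PDW_SPEC  # default anchor

    spec = spec or PDW_SPEC
    base = _noise_free_base(phantom, site, spec)
    sig = base * np.exp(-spec.echo_times[0] * phantom.truth["r2s"])
    wm = phantom.tissue_mask("wm")
    if target_snr <= 0:
        return 0.0
    return float(sig[wm].mean() / target_snr)
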