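"""Digital brain phantom and per-site scanner realizations.

The phantom is a parametric ellipsoid-shell head: a CSF envelope, a cortical
grey-matter ribbon, a white-matter core with CSF ventricles, bilateral caudate
blobs and a corpus-callosum bridge crossing the midline.  Each tissue carries
ground-truth R1 (1/s), PD (p.u.), MT saturation (p.u.) and R2* (1/s) with
Gaussian within-tissue variation.  A site realization adds the scanner-side
nuisances of a multi-centre study: a smooth RF transmit field (local/nominal
flip-angle ratio), a measured-B1 map with a stated relative error, a smooth
receive-sensitivity field, a rigid head pose, and a thermal-noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import Grid, RigidTransform, bandlimited_field, scaled_exp_field

log = logging.getLogger(__name__)

LABELS = {
    "background": 0,
    "csf": 1,
    "gm": 2,
    "wm": 3,
    "caudate": 4,
    "corpus-callosum": 5,
}
PARAM_NAMES = ("r1", "pd", "mt", "r2s")


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth means and within-tissue SDs for one tissue class.

    Rates in 1/s, PD and MT in percent units (MT = 0.794 p.u. means a
    saturation fraction of 0.00794 per repetition).
    """

    label: str
    r1: float
    pd: float
    mt: float
    r2s: float
    r1_sd: float = 0.0
    pd_sd: float = 0.0
    mt_sd: float = 0.0
    r2s_sd: float = 0.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown tissue label {self.label!r}")
        if self.label != "background":
            for name in PARAM_NAMES:
                if getattr(self, name) <= 0 and not (
                    name == "mt" and self.mt >= 0
                ):
                    raise ValueError(
                        f"{self.label}: parameter {name} must be positive"
                    )


# Group-mean tissue values for the four reported ROI tissues; within-tissue SDs
# are the across-volunteer SDs of ROI means scaled by sqrt(5) (they are SDs of
# means of five volunteers).  CSF values are literature-typical at 3T: long T1
# (R1 ~ 0.25 1/s), near-full water PD, negligible MT saturation and a low R2*.
_SQ5 = np.sqrt(5.0)
DEFAULT_TISSUES = (
    TissueParams("csf", 0.25, 100.0, 0.02, 3.0, 0.005, 1.0, 0.005, 0.3),
    TissueParams(
        "gm", 0.609, 84.44, 0.794, 15.2,
        0.008 * _SQ5, 1.87 * _SQ5, 0.014 * _SQ5, 0.4 * _SQ5,
    ),
    TissueParams(
        "wm", 1.036, 68.35, 1.764, 21.0,
        0.036 * _SQ5, 0.06 * _SQ5, 0.066 * _SQ5, 0.8 * _SQ5,
    ),
    TissueParams(
        "caudate", 0.683, 82.67, 0.836, 18.2,
        0.022 * _SQ5, 1.64 * _SQ5, 0.027 * _SQ5, 1.2 * _SQ5,
    ),
    TissueParams(
        "corpus-callosum", 1.158, 64.65, 1.978, 25.0,
        0.050 * _SQ5, 0.86 * _SQ5, 0.085 * _SQ5, 0.5 * _SQ5,
    ),
)


@dataclass
class Phantom:
    """Label volume plus one ground-truth volume per parameter."""

    grid: Grid
    labels: np.ndarray  # integer label volume
    truth: dict[str, np.ndarray]  # r1, pd, mt, r2s
    volunteer_id: int = 0
    seed: int = 0

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


# Base geometry in mm (semi-axes / centres), jittered per volunteer.
_GEOM = {
    "head": (48.0, 60.0, 45.0),
    "gm_outer": (44.0, 56.0, 41.0),
    "wm_outer": (34.0, 46.0, 31.0),
    "ventricle": dict(center=(0.0, -5.0, 0.0), semi=(8.0, 18.0, 8.0)),
    "caudate": dict(center=(16.0, 6.0, 2.0), semi=(7.0, 10.0, 7.0)),
    "cc": dict(center=(0.0, 28.0, 2.0), semi=(14.0, 6.0, 7.0)),
}


def _inside(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def generate_phantom(
    dims: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 2.5,
    tissue_table: tuple[TissueParams, ...] = DEFAULT_TISSUES,
    seed: int = 0,
    volunteer_id: int = 0,
    geometry_jitter: float = 0.03,
) -> Phantom:
    """Build a volunteer phantom; deterministic given ``seed``.

    ``geometry_jitter`` is the relative SD of per-volunteer ellipsoid scaling
    (anatomical variability across volunteers).
    """
    if min(dims) < 32:
        raise ValueError("grid must be at least 32^3")
    table = {t.label: t for t in tissue_table}
    missing = set(LABELS) - {"background"} - set(table)
    if missing:
        raise ValueError(f"tissue table is missing labels: {sorted(missing)}")

    grid = Grid(tuple(dims), float(voxel_size))
    rng = np.random.default_rng(np.random.SeedSequence([seed, volunteer_id]))

    jit = 1.0 + geometry_jitter * np.clip(rng.standard_normal(3), -2, 2)
    shift = 2.0 * rng.uniform(-1, 1, size=3)
    coords = grid.coords_mm()
    coords = tuple(c - s for c, s in zip(coords, shift))

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[_inside(coords, (0, 0, 0), np.asarray(_GEOM["head"]) * jit)] = LABELS["csf"]
    labels[_inside(coords, (0, 0, 0), np.asarray(_GEOM["gm_outer"]) * jit)] = LABELS["gm"]
    labels[_inside(coords, (0, 0, 0), np.asarray(_GEOM["wm_outer"]) * jit)] = LABELS["wm"]
    v = _GEOM["ventricle"]
    labels[_inside(coords, v["center"], np.asarray(v["semi"]) * jit)] = LABELS["csf"]
    c = _GEOM["caudate"]
    for side in (+1, -1):
        ctr = (side * c["center"][0], c["center"][1], c["center"][2])
        labels[_inside(coords, ctr, np.asarray(c["semi"]) * jit)] = LABELS["caudate"]
    cc = _GEOM["cc"]
    labels[_inside(coords, cc["center"], np.asarray(cc["semi"]) * jit)] = LABELS["corpus-callosum"]

    truth: dict[str, np.ndarray] = {}
    for pname in PARAM_NAMES:
        vol = np.zeros(grid.shape)
        for tname, lab in LABELS.items():
            if tname == "background":
                continue
            t = table[tname]
            mean = getattr(t, pname)
            sd = getattr(t, f"{pname}_sd")
            m = labels == lab
            n = int(m.sum())
            noise = np.clip(rng.standard_normal(n), -3.0, 3.0) * sd
            vol[m] = np.maximum(mean + noise, 1e-6)
        truth[pname] = vol
    return Phantom(grid, labels, truth, volunteer_id=volunteer_id, seed=seed)


def tissue_priors(
    phantom: Phantom, fwhm_mm: float = 4.0, merge: bool = True
) -> dict[str, np.ndarray]:
    """Spatial prior probability maps from the phantom geometry, blurred with
    a Gaussian of the given FWHM.  With ``merge`` (the default) the caudate
    counts as GM and the corpus callosum as WM, giving the csf/gm/wm classes
    of the tissue classifier; ``merge=False`` keeps all five tissues as
    separate intensity classes (used by the receive-bias estimator)."""
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / phantom.grid.voxel_size
    if merge:
        groups = {
            "csf": [LABELS["csf"]],
            "gm": [LABELS["gm"], LABELS["caudate"]],
            "wm": [LABELS["wm"], LABELS["corpus-callosum"]],
        }
    else:
        groups = {
            name: [lab] for name, lab in LABELS.items() if name != "background"
        }
    priors = {
        k: ndimage.gaussian_filter(
            np.isin(phantom.labels, labs).astype(float), sigma
        )
        for k, labs in groups.items()
    }
    total = sum(priors.values())
    for k in priors:
        priors[k] = np.where(total > 1.0, priors[k] / np.maximum(total, 1e-12), priors[k])
    return priors


@dataclass(frozen=True)
class SiteSpec:
    """Ranges from which one site realization is drawn.

    Transmit-field amplitude: max |f_T − 1| within the head, drawn uniformly
    from ``ft_amp_range`` (the 20–30% regime of body-coil transmission at 3T).
    Receive field max/min ratio within the head from ``fr_ratio_range``
    (the 200–300% variation of a 32-channel head coil).  Pose magnitudes in mm
    and degrees; B1 mapping error as relative SD; noise SD either explicit
    (signal units) or calibrated downstream from ``target_snr``.
    """

    ft_amp_range: tuple[float, float] = (0.20, 0.30)
    fr_ratio_range: tuple[float, float] = (2.0, 3.0)
    translation_mm_range: tuple[float, float] = (10.0, 20.0)
    rotation_deg_range: tuple[float, float] = (3.0, 5.0)
    b1_error_sd: float = 0.03
    field_cutoff_mm: float = 120.0
    noise_sd: float | None = None
    target_snr: float = 50.0
    noise_model: str = "rician"

    def __post_init__(self):
        if not 0 <= self.ft_amp_range[0] <= self.ft_amp_range[1] <= 0.3:
            raise ValueError("ft_amp_range must lie within [0, 0.3]")
        if not 1.0 <= self.fr_ratio_range[0] <= self.fr_ratio_range[1] <= 3.0:
            raise ValueError("fr_ratio_range must lie within [1, 3]")
        if self.translation_mm_range[1] > 20.0:
            raise ValueError("|translation| must be <= 20 mm")
        if self.rotation_deg_range[1] > 5.0:
            raise ValueError("|rotation| must be <= 5 deg")
        if self.b1_error_sd < 0 or self.field_cutoff_mm <= 0:
            raise ValueError("invalid field parameters")


NULL_SITE_SPEC = SiteSpec(
    ft_amp_range=(0.0, 0.0),
    fr_ratio_range=(1.0, 1.0),
    translation_mm_range=(0.0, 0.0),
    rotation_deg_range=(0.0, 0.0),
    b1_error_sd=0.0,
    noise_sd=0.0,
)


@dataclass
class SiteRealization:
    """One scanner/session: smooth RF fields, measured B1, pose and noise."""

    site_id: int
    grid: Grid
    f_t: np.ndarray  # true transmit field (local/nominal flip-angle ratio)
    b1_measured: np.ndarray  # f_t * (1 + error field)
    f_r: np.ndarray  # receive sensitivity field, arbitrary units
    pose: RigidTransform
    noise_sd: float | None
    noise_model: str
    seed: int = 0

    def with_noise_sd(self, sd: float) -> "SiteRealization":
        return replace(self, noise_sd=sd)


def generate_site(
    phantom: Phantom,
    site_spec: SiteSpec = SiteSpec(),
    seed: int = 0,
    site_id: int = 0,
) -> SiteRealization:
    """Draw one site realization; deterministic given ``seed``."""
    grid = phantom.grid
    rng = np.random.default_rng(np.random.SeedSequence([seed, site_id, 7]))
    brain = phantom.brain_mask

    ft_amp = rng.uniform(*site_spec.ft_amp_range)
    fr_ratio = rng.uniform(*site_spec.fr_ratio_range)

    g_t = bandlimited_field(grid, site_spec.field_cutoff_mm, rng)
    f_t = scaled_exp_field(g_t, brain, 1.0 - ft_amp, 1.0 + ft_amp)

    g_r = bandlimited_field(grid, site_spec.field_cutoff_mm, rng)
    f_r = scaled_exp_field(g_r, brain, 1.0, fr_ratio)

    if site_spec.b1_error_sd > 0:
        err = bandlimited_field(grid, site_spec.field_cutoff_mm, rng)
        err_b = err[brain]
        err = (err - err_b.mean()) / err_b.std() * site_spec.b1_error_sd
    else:
        err = np.zeros(grid.shape)
    b1_measured = f_t * (1.0 + err)

    tmag = rng.uniform(*site_spec.translation_mm_range)
    tdir = rng.standard_normal(3)
    tdir /= max(np.linalg.norm(tdir), 1e-12)
    rmag = rng.uniform(*site_spec.rotation_deg_range)
    rdir = rng.standard_normal(3)
    rdir /= max(np.linalg.norm(rdir), 1e-12)
    pose = RigidTransform(tuple(rmag * rdir), tuple(tmag * tdir))

    return SiteRealization(
        site_id=site_id,
        grid=grid,
        f_t=f_t,
        b1_measured=b1_measured,
        f_r=f_r,
        pose=pose,
        noise_sd=site_spec.noise_sd,
        noise_model=site_spec.noise_model,
        seed=seed,
    )


@dataclass
class CohortCell:
    volunteer_id: int
    site_id: int
    phantom_seed: int
    site_seed: int
    noise_seed: int


@dataclass
class CohortManifest:
    """Pairing of volunteer phantoms with per-site realizations."""

    n_volunteers: int
    n_sites: int
    cells: list[CohortCell] = field(default_factory=list)


def make_cohort(
    n_volunteers: int = 5, n_sites: int = 3, seeds: list[int] | None = None
) -> CohortManifest:
    """Build the cohort manifest (default: the five-volunteer, three-site
    design).  ``seeds`` supplies one base seed per volunteer; site and noise
    seeds are derived so that anatomy is site-invariant while fields, pose and
    noise differ per (volunteer, site) cell."""
    if n_volunteers < 1:
        raise ValueError("need at least one volunteer")
    if n_sites < 1:
        raise ValueError("need at least one site")
    if seeds is None:
        seeds = list(range(1, n_volunteers + 1))
    if len(seeds) != n_volunteers:
        raise ValueError("need one seed per volunteer")
    if len(set(seeds)) != len(seeds):
        log.warning("duplicate volunteer seeds: %s", seeds)
    cells = [
        CohortCell(
            volunteer_id=v,
            site_id=s,
            phantom_seed=seeds[v],
            site_seed=1000 * (seeds[v] % 2**18) + 10 * s,
            noise_seed=1000 * (seeds[v] % 2**18) + 10 * s + 1,
        )
        for v in range(n_volunteers)
        for s in range(n_sites)
    ]
    return CohortManifest(n_volunteers, n_sites, cells)
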