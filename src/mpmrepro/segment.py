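"""Analysis-side spatial operations: resampling, tissue classification, ROIs.

The tissue classifier is a prior-guided three-class Gaussian mixture with a
co-estimated smooth multiplicative bias field, in the generative spirit of
unified segmentation.  This level of modelling is sufficient here because the
reproducibility statistics only need consistent tissue posteriors and the
spatial priors come from the known phantom geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid, RigidTransform, SmoothFieldFitter, apply_rigid
from .phantom import LABELS

log = logging.getLogger(__name__)

CLASS_NAMES = ("csf", "gm", "wm")


@dataclass
class TissueProbMaps:
    """CSF/GM/WM posterior probability volumes in [0, 1]; the remainder up to
    1 is background."""

    csf: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    source: str  # "MT" | "T1w"
    converged: bool = True

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def total(self) -> np.ndarray:
        return self.csf + self.gm + self.wm


@dataclass
class ROISet:
    """Masks used by the reproducibility statistics."""

    brain: np.ndarray  # sum of tissue probabilities > 0.90
    gm: np.ndarray  # GM probability > 0.99
    wm: np.ndarray  # WM probability > 0.99
    caudate: np.ndarray  # eroded ground-truth label (conservative ROI)
    corpus_callosum: np.ndarray
    gm_mask: np.ndarray  # GM probability > 0.90

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name.replace("-", "_"))


def resample_rigid(
    volume: np.ndarray,
    transform: RigidTransform,
    grid: Grid,
    order: int = 4,
) -> np.ndarray:
    """Resample ``volume`` moved by ``transform`` onto the same grid using
    B-spline interpolation of the given order (4 by default, as on the
    analysis side).  Out-of-field and NaN-contaminated voxels come back NaN.
    """
    if transform.is_identity:
        return volume.copy()
    finite = np.isfinite(volume)
    filled = np.where(finite, volume, 0.0)
    out = apply_rigid(filled, grid, transform, order=order, cval=0.0)
    support = apply_rigid(np.ones_like(filled), grid, transform, order=1, cval=0.0)
    validity = apply_rigid(finite.astype(float), grid, transform, order=1, cval=0.0)
    out[(support < 0.999) | (validity < 0.999)] = np.nan
    return out


def segment_tissue(
    image: np.ndarray,
    priors: dict[str, np.ndarray],
    grid: Grid,
    source: str = "MT",
    bias_cutoff_mm: float = 60.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    prior_floor: float = 1e-4,
    ridge: float = 0.5,
) -> TissueProbMaps:
    """Prior-guided 3-class GMM with a co-estimated multiplicative smooth bias
    field.  Returns posterior probabilities; non-convergence after
    ``max_iter`` EM iterations returns the last iterate with a warning.
    """
    prior_sum = sum(priors[k] for k in CLASS_NAMES)
    mask = (prior_sum > 0.05) & np.isfinite(image)
    if not np.any(mask):
        raise ValueError("empty analysis mask (no prior support)")
    x = image[mask].astype(float)
    pri = np.stack(
        [np.clip(priors[k][mask], prior_floor, None) for k in CLASS_NAMES], axis=1
    )
    pri /= pri.sum(axis=1, keepdims=True)

    # prior-weighted initialization
    mu = np.array([(pri[:, k] * x).sum() / pri[:, k].sum() for k in range(3)])
    scale = max(abs(x).mean(), 1e-30)
    sd_floor = 1e-6 * scale
    sd = np.full(3, max(x.std() / 3.0, sd_floor))

    fitter = SmoothFieldFitter(grid, mask, bias_cutoff_mm, ridge=ridge)
    b = np.ones(x.shape)
    resp = pri.copy()
    converged = False
    for _ in range(max_iter):
        # E-step
        logp = -0.5 * ((x[:, None] - b[:, None] * mu[None, :]) / sd[None, :]) ** 2
        logp -= np.log(sd[None, :])
        logp += np.log(pri)
        logp -= logp.max(axis=1, keepdims=True)
        new_resp = np.exp(logp)
        new_resp /= new_resp.sum(axis=1, keepdims=True)
        change = np.abs(new_resp - resp).mean()
        resp = new_resp
        # M-step
        for k in range(3):
            w = resp[:, k]
            denom = (w * b**2).sum()
            if denom > 0:
                mu[k] = (w * b * x).sum() / denom
            sd[k] = max(
                np.sqrt((w * (x - b * mu[k]) ** 2).sum() / max(w.sum(), 1e-12)),
                sd_floor,
            )
        # bias update: smooth fit of log(x / reconstruction)
        recon = resp @ mu
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(recon > sd_floor, x / recon, 1.0)
        ratio = np.clip(ratio, 0.2, 5.0)
        smooth = fitter.fit(np.log(ratio) + np.log(b))
        b = np.exp(smooth[mask])
        b /= b.mean()
        if change < tol:
            converged = True
            break
    if not converged:
        log.warning("segment_tissue (%s): no convergence in %d iterations", source, max_iter)

    out = {}
    post_scale = np.clip(prior_sum, 0.0, 1.0)
    for k, name in enumerate(CLASS_NAMES):
        vol = np.zeros(image.shape)
        vol[mask] = resp[:, k]
        out[name] = vol * post_scale
    return TissueProbMaps(source=source, converged=converged, **out)


def make_rois(
    prob: TissueProbMaps,
    phantom_labels: np.ndarray,
    gm_threshold: float = 0.99,
    wm_threshold: float = 0.99,
    brain_threshold: float = 0.90,
    gm_mask_threshold: float = 0.90,
) -> ROISet:
    """Threshold posteriors into analysis masks and carve the caudate /
    corpus-callosum ROIs from the ground-truth labels, eroded by one voxel to
    keep clear of partial-volume boundaries."""
    brain = prob.total > brain_threshold
    rois = {
        "brain": brain,
        "gm": (prob.gm > gm_threshold) & brain,
        "wm": (prob.wm > wm_threshold) & brain,
        "gm_mask": (prob.gm > gm_mask_threshold) & brain,
        "caudate": ndimage.binary_erosion(phantom_labels == LABELS["caudate"]) & brain,
        "corpus_callosum": ndimage.binary_erosion(
            phantom_labels == LABELS["corpus-callosum"]
        )
        & brain,
    }
    for name in ("gm", "wm", "caudate", "corpus_callosum", "brain"):
        if not np.any(rois[name]):
            raise ValueError(f"ROI {name!r} is empty")
    return ROISet(**rois)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    s = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / s if s else 1.0
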