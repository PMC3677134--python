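"""End-to-end experiment: simulate → estimate → analyze.

One *cell* is a (volunteer, site) pair: three simulated multi-echo FLASH
series plus the site's measured B1 map.  Estimation runs in site (scanner)
space; the analysis resamples the resulting maps back to the volunteer's
reference grid with 4th-order B-splines (the known inverse of the simulated
pose), segments the registered MT map and mean T1w image per site, calibrates
PD* on the MT-derived white-matter mask and computes the reproducibility
statistics across sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forward, mapfit, repro, segment
from .forward import DEFAULT_PROTOCOL, EchoSeries
from .phantom import (
    CohortManifest,
    Phantom,
    SiteRealization,
    SiteSpec,
    generate_phantom,
    generate_site,
    make_cohort,
    tissue_priors,
)
from .spoiling import SpoilingCorrection, fit_spoiling_coefficients

log = logging.getLogger(__name__)

PARAM_ORDER = ("R1", "PD*", "MT", "R2*", "T1w")
ROI_ORDER = ("gm", "caudate", "wm", "corpus-callosum")
BIAS_ROIS = {"PD*": ("gm",)}  # WM PD* is calibrated, so its bias is excluded


@dataclass
class SimulatedCell:
    volunteer_id: int
    site_id: int
    phantom: Phantom
    site: SiteRealization
    echoes: dict[str, EchoSeries]
    b1_map: np.ndarray  # measured B1 in site space


@dataclass
class CellEstimates:
    """Site-space estimates for one cell (PD not yet calibrated)."""

    volunteer_id: int
    site_id: int
    site: SiteRealization
    maps: dict[str, np.ndarray]  # R1, PD_uncal, MT, R2*, A, T1w
    flags: dict = field(default_factory=dict)

    def as_quant_maps(self) -> mapfit.QuantMaps:
        return mapfit.QuantMaps(
            r1=self.maps["R1"],
            a=self.maps["A"],
            pd=self.maps["PD_uncal"],
            mt=self.maps["MT"],
            r2s=self.maps["R2*"],
            grid=self.site.grid,
            flags=dict(self.flags),
        )


def simulate_cell(
    phantom: Phantom,
    site: SiteRealization,
    protocol: dict | None = None,
    seed: int = 0,
    mt_law: str = "inverse-correction",
    target_snr: float = 50.0,
) -> SimulatedCell:
    protocol = protocol or DEFAULT_PROTOCOL
    if site.noise_sd is None:
        site = site.with_noise_sd(
            forward.calibrate_noise_sd(
                phantom, site, protocol["PDw"], target_snr=target_snr
            )
        )
    echoes = {
        w: forward.simulate_echo_series(
            phantom, site, spec, seed=seed * 10 + i, mt_law=mt_law
        )
        for i, (w, spec) in enumerate(protocol.items())
    }
    return SimulatedCell(
        volunteer_id=phantom.volunteer_id,
        site_id=site.site_id,
        phantom=phantom,
        site=site,
        echoes=echoes,
        b1_map=forward.measured_b1_series(site),
    )


def _brain_mask_from_signal(pdw_mean: np.ndarray) -> np.ndarray:
    """Rough head mask from signal intensity (background sits at the noise
    floor, far below the dimmest brain tissue)."""
    thr = 0.25 * np.percentile(pdw_mean, 99)
    return pdw_mean > thr


# Physical plausibility bounds; estimates outside are marked invalid (NaN).
# Background voxels (pure noise) routinely produce astronomically large
# amplitude/R1 values from near-degenerate denominators.
_MAP_BOUNDS = {
    "R1": (1e-3, 10.0),  # 1/s
    "A": (1e-3, 1e4),
    "MT": (-10.0, 30.0),  # p.u.
    "R2*": (-100.0, 500.0),  # 1/s
}


def _mark_invalid(vol: np.ndarray, name: str) -> np.ndarray:
    lo, hi = _MAP_BOUNDS[name]
    out = np.where((vol >= lo) & (vol <= hi), vol, np.nan)
    n = int(np.isnan(out).sum() - np.isnan(vol).sum())
    if n:
        log.info("map %s: %d voxels outside [%g, %g] marked invalid", name, n, lo, hi)
    return out


def estimate_cell(
    cell: SimulatedCell,
    n_avg_echoes: int = 6,
    b1_correction: bool = True,
    spoiling: SpoilingCorrection | None = None,
    receive_correction: bool = True,
) -> CellEstimates:
    """Run the map-estimation chain for one cell, in site space."""
    t1w_mean = mapfit.average_first_echoes(cell.echoes["T1w"], n_avg_echoes)
    pdw_mean = mapfit.average_first_echoes(cell.echoes["PDw"], n_avg_echoes)
    mtw_mean = mapfit.average_first_echoes(cell.echoes["MTw"], n_avg_echoes)

    r2s, _ = mapfit.fit_r2star(cell.echoes["PDw"])
    a_app, r1_app = mapfit.estimate_a_r1_apparent(t1w_mean, pdw_mean)

    if b1_correction:
        b1 = cell.b1_map
        r1 = mapfit.correct_r1(r1_app, b1, spoiling)
        a = mapfit.correct_amplitude(a_app, b1)
        mt_unc = mapfit.compute_mt_sat(mtw_mean, a, r1, b1=b1)
        mt = mapfit.correct_mt_b1(mt_unc, b1)
    else:
        r1, a = r1_app, a_app
        mt = mapfit.compute_mt_sat(mtw_mean, a, r1)
    r1 = _mark_invalid(r1, "R1")
    a = _mark_invalid(a, "A")
    mt = _mark_invalid(mt, "MT")
    r2s = _mark_invalid(r2s, "R2*")

    flags = {
        "b1_corrected": b1_correction,
        "spoiling_corrected": spoiling is not None,
        "receive_corrected": receive_correction,
        "calibrated": False,
    }
    pd_uncal = a
    if receive_correction:
        brain = _brain_mask_from_signal(pdw_mean.data)
        # spatial priors moved to scanner space by the (known) head pose
        from .grids import apply_rigid

        priors = {
            k: apply_rigid(v, cell.phantom.grid, cell.site.pose, order=1)
            for k, v in tissue_priors(cell.phantom, merge=False).items()
        }
        bias, converged = mapfit.estimate_receive_bias(
            a, brain, cell.site.grid, priors=priors
        )
        # the basis extrapolation is meaningless far outside the head
        pd_uncal = _mark_invalid(a / np.clip(bias, 0.05, 20.0), "A")
        flags["receive_bias_converged"] = converged

    return CellEstimates(
        volunteer_id=cell.volunteer_id,
        site_id=cell.site_id,
        site=cell.site,
        maps={
            "R1": r1,
            "PD_uncal": pd_uncal,
            "MT": mt,
            "R2*": r2s,
            "A": a,
            "T1w": t1w_mean.data,
        },
        flags=flags,
    )


@dataclass
class VolunteerAnalysis:
    """Reference-space products of one volunteer across sites."""

    volunteer_id: int
    maps: dict[int, dict[str, np.ndarray]]  # site -> parameter -> volume
    probs_mt: dict[int, segment.TissueProbMaps]
    probs_t1w: dict[int, segment.TissueProbMaps]
    rois: segment.ROISet
    wm_calib_masks: dict[int, np.ndarray]


def analyze_volunteer(
    phantom: Phantom,
    estimates: list[CellEstimates],
    calibrate: bool = True,
) -> VolunteerAnalysis:
    """Resample one volunteer's site estimates to the reference grid, segment,
    build ROIs and calibrate PD*."""
    grid = phantom.grid
    priors = tissue_priors(phantom)

    maps: dict[int, dict[str, np.ndarray]] = {}
    probs_mt, probs_t1w, wm_masks = {}, {}, {}
    for est in sorted(estimates, key=lambda e: e.site_id):
        undo = est.site.pose.inverse()
        ref = {
            name: segment.resample_rigid(est.maps[name], undo, grid, order=4)
            for name in ("R1", "PD_uncal", "MT", "R2*", "T1w")
        }
        pmt = segment.segment_tissue(ref["MT"], priors, grid, source="MT")
        pt1 = segment.segment_tissue(ref["T1w"], priors, grid, source="T1w")
        wm_mask = pmt.wm > 0.99
        if calibrate:
            ref["PD*"] = mapfit.calibrate_pd(ref["PD_uncal"], wm_mask)
        else:
            ref["PD*"] = ref["PD_uncal"]
        maps[est.site_id] = ref
        probs_mt[est.site_id] = pmt
        probs_t1w[est.site_id] = pt1
        wm_masks[est.site_id] = wm_mask

    mean_prob = segment.TissueProbMaps(
        csf=np.mean([p.csf for p in probs_mt.values()], axis=0),
        gm=np.mean([p.gm for p in probs_mt.values()], axis=0),
        wm=np.mean([p.wm for p in probs_mt.values()], axis=0),
        source="MT",
    )
    rois = segment.make_rois(mean_prob, phantom.labels)
    return VolunteerAnalysis(
        volunteer_id=phantom.volunteer_id,
        maps=maps,
        probs_mt=probs_mt,
        probs_t1w=probs_t1w,
        rois=rois,
        wm_calib_masks=wm_masks,
    )


def _cell_rows(va: VolunteerAnalysis) -> list[dict]:
    rows = []
    for site_id, ref in va.maps.items():
        for param in PARAM_ORDER:
            for roi in ROI_ORDER:
                vals = ref[param][va.rois[roi]]
                rows.append(
                    dict(
                        volunteer=va.volunteer_id,
                        site=site_id,
                        parameter=param,
                        roi=roi,
                        value=float(np.nanmean(vals)),
                    )
                )
    return rows


def analyze_cohort(
    volunteers: list[VolunteerAnalysis], run_tests: bool = True
) -> repro.ReproReport:
    """Compute all reproducibility statistics across sites and volunteers."""
    n_sites = {len(va.maps) for va in volunteers}
    if n_sites != {max(n_sites)} or max(n_sites) < 2:
        raise ValueError(
            "inter-site statistics need the same >= 2 sites for every volunteer"
        )

    cells = pd.DataFrame([r for va in volunteers for r in _cell_rows(va)])

    inter = (
        cells.groupby(["volunteer", "parameter", "roi"])["value"]
        .apply(lambda v: repro.inter_site_cov(v.to_numpy()))
        .rename("cov_percent")
        .reset_index()
    )

    intra_rows = []
    for va in volunteers:
        for param in PARAM_ORDER:
            for roi in repro.INTRA_SITE_ROIS:
                per_site = [
                    repro.intra_site_cov(ref[param], va.rois[roi], roi)
                    for ref in va.maps.values()
                ]
                intra_rows.append(
                    dict(
                        volunteer=va.volunteer_id,
                        parameter=param,
                        roi=roi,
                        cov_percent=float(np.mean(per_site)),
                    )
                )
    intra = pd.DataFrame(intra_rows)

    bias_rows = []
    for param in PARAM_ORDER:
        rois = BIAS_ROIS.get(param, ("gm", "wm"))
        per_roi = [
            repro.inter_site_bias(
                cells[(cells.parameter == param) & (cells.roi == roi)]
            )
            for roi in rois
        ]
        per_site = pd.concat(per_roi, axis=1).mean(axis=1)
        bias_rows += [
            dict(site=int(s), parameter=param, bias_percent=float(b))
            for s, b in per_site.items()
        ]
    bias = pd.DataFrame(bias_rows)

    gm_rows = []
    for va in volunteers:
        for source, probs in (("MT", va.probs_mt), ("T1w", va.probs_t1w)):
            gm_maps = [p.gm for p in probs.values()]
            # GM mask: probability > 0.90 consistently across sites, from the
            # corresponding map type (conservative against partial volume)
            gm_mask = np.logical_and.reduce([g > 0.90 for g in gm_maps])
            gm_rows.append(
                dict(
                    volunteer=va.volunteer_id,
                    source=source,
                    cov_percent=repro.gm_prob_cov(gm_maps, gm_mask),
                )
            )
    gm_prob = pd.DataFrame(gm_rows)

    tests: dict = {}
    if run_tests and cells.volunteer.nunique() >= 2:
        for param in ("R1", "PD*", "MT", "R2*"):
            sub = inter[inter.parameter.isin([param, "T1w"])].rename(
                columns={"volunteer": "subject"}
            )
            sub = sub.assign(
                type=np.where(sub.parameter == param, "map", "T1w")
            )
            res = repro.rm_anova(
                sub[["subject", "roi", "type", "cov_percent"]],
                depvar="cov_percent",
            )
            by_vol = sub.groupby(["subject", "type"])["cov_percent"].mean().unstack()
            t, p = repro.paired_t(by_vol["T1w"], by_vol["map"], "greater")
            res.update(t_posthoc=t, p_posthoc=p)
            tests[f"inter_site_cov_{param}_vs_T1w"] = res

        wide = gm_prob.pivot(index="volunteer", columns="source", values="cov_percent")
        t, p = repro.paired_t(wide["T1w"], wide["MT"], "greater")
        tests["gm_prob_cov_MT_vs_T1w"] = dict(
            t=t,
            p=p,
            mean_MT=float(wide["MT"].mean()),
            ci_MT=repro.t_confidence_interval(wide["MT"]),
            mean_T1w=float(wide["T1w"].mean()),
            ci_T1w=repro.t_confidence_interval(wide["T1w"]),
        )

    return repro.ReproReport(
        cells=cells,
        inter_site=inter,
        intra_site=intra,
        bias=bias,
        gm_prob=gm_prob,
        tests=tests,
    )


def run_experiment(
    seed: int = 1,
    n_volunteers: int = 5,
    n_sites: int = 3,
    dims: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 2.5,
    site_spec: SiteSpec | None = None,
    protocol: dict | None = None,
    mt_law: str = "inverse-correction",
    b1_correction: bool = True,
    spoiling_correction: str | SpoilingCorrection | None = None,
    run_tests: bool = True,
) -> tuple[repro.ReproReport, list[VolunteerAnalysis]]:
    """Simulate and analyze a full multi-site cohort.

    Deterministic given ``seed``; the phantom anatomy is site-invariant per
    volunteer while fields, pose and noise vary per (volunteer, site) cell.
    """
    protocol = protocol or DEFAULT_PROTOCOL
    site_spec = site_spec or SiteSpec()
    manifest: CohortManifest = make_cohort(
        n_volunteers, n_sites,
        seeds=[seed % 2**20 * 100 + v for v in range(n_volunteers)],
    )
    spoil = None
    if spoiling_correction == "auto":
        spoil = fit_spoiling_coefficients(protocol["T1w"], protocol["PDw"])
    elif isinstance(spoiling_correction, SpoilingCorrection):
        spoil = spoiling_correction

    phantoms = {
        v: generate_phantom(
            dims, voxel_size,
            seed=manifest.cells[v * n_sites].phantom_seed,
            volunteer_id=v,
        )
        for v in range(n_volunteers)
    }
    volunteers = []
    for v in range(n_volunteers):
        ests = []
        for c in manifest.cells:
            if c.volunteer_id != v:
                continue
            site = generate_site(
                phantoms[v], site_spec, seed=c.site_seed, site_id=c.site_id
            )
            cell = simulate_cell(
                phantoms[v], site, protocol, seed=c.noise_seed,
                mt_law=mt_law, target_snr=site_spec.target_snr,
            )
            ests.append(
                estimate_cell(cell, b1_correction=b1_correction, spoiling=spoil)
            )
        volunteers.append(analyze_volunteer(phantoms[v], ests))
        log.info("analyzed volunteer %d", v)

    report = analyze_cohort(volunteers, run_tests=run_tests)
    return report, volunteers
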