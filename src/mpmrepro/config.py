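"""YAML experiment configuration.

Every protocol constant lives here with its standard value as the default
(TRs, flip angles, echo times, the 69 p.u. white-matter PD calibration, the
90%/99% probability thresholds, the 0.4 MT-correction constant), so that any
deviation is explicit in the config file.  Configs state times in ms and
angles in degrees; conversion to SI happens once, at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forward import DEFAULT_PROTOCOL, AcquisitionSpec
from .phantom import DEFAULT_TISSUES, SiteSpec, TissueParams


@dataclass
class ExperimentConfig:
    dims: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.5
    n_volunteers: int = 5
    n_sites: int = 3
    tissues: tuple[TissueParams, ...] = DEFAULT_TISSUES
    site_spec: SiteSpec = field(default_factory=SiteSpec)
    protocol: dict[str, AcquisitionSpec] = field(
        default_factory=lambda: dict(DEFAULT_PROTOCOL)
    )
    mt_law: str = "inverse-correction"
    b1_correction: bool = True
    spoiling_correction: str | None = None  # None | "auto"
    n_avg_echoes: int = 6
    wm_calibration_pu: float = 69.0

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "voxel_size_mm": self.voxel_size_mm,
            "n_volunteers": self.n_volunteers,
            "n_sites": self.n_sites,
            "mt_law": self.mt_law,
            "b1_correction": self.b1_correction,
            "spoiling_correction": self.spoiling_correction,
            "n_avg_echoes": self.n_avg_echoes,
            "wm_calibration_pu": self.wm_calibration_pu,
            "site_spec": vars(self.site_spec).copy(),
            "protocol": {
                w: {
                    "tr_ms": s.tr * 1e3,
                    "flip_deg": float(np.rad2deg(s.flip_angle)),
                    "te_ms": [t * 1e3 for t in s.echo_times],
                    "mt_pulse": s.mt_pulse,
                    "spoiling": s.spoiling,
                }
                for w, s in self.protocol.items()
            },
            "tissues": [vars(t).copy() for t in self.tissues],
        }


def _parse_protocol(raw: dict) -> dict[str, AcquisitionSpec]:
    protocol = dict(DEFAULT_PROTOCOL)  # unspecified weightings keep defaults
    for w, p in raw.items():
        base = DEFAULT_PROTOCOL[w]
        protocol[w] = AcquisitionSpec(
            weighting=w,
            tr=p.get("tr_ms", base.tr * 1e3) * 1e-3,
            flip_angle=np.deg2rad(
                p.get("flip_deg", np.rad2deg(base.flip_angle))
            ),
            echo_times=tuple(
                t * 1e-3 for t in p.get("te_ms", [t * 1e3 for t in base.echo_times])
            ),
            mt_pulse=p.get("mt_pulse", base.mt_pulse),
            spoiling=p.get("spoiling", base.spoiling),
        )
    return protocol


def config_from_dict(raw: dict) -> ExperimentConfig:
    cfg = ExperimentConfig()
    known = {
        "dims", "voxel_size_mm", "n_volunteers", "n_sites", "mt_law",
        "b1_correction", "spoiling_correction", "n_avg_echoes",
        "wm_calibration_pu", "site_spec", "protocol", "tissues",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    simple = {
        k: raw[k]
        for k in (
            "voxel_size_mm", "n_volunteers", "n_sites", "mt_law",
            "b1_correction", "spoiling_correction", "n_avg_echoes",
            "wm_calibration_pu",
        )
        if k in raw
    }
    for k, v in simple.items():
        setattr(cfg, k, v)
    if "dims" in raw:
        cfg.dims = tuple(raw["dims"])
    if "site_spec" in raw:
        d = dict(raw["site_spec"])
        for k in ("ft_amp_range", "fr_ratio_range", "translation_mm_range", "rotation_deg_range"):
            if k in d:
                d[k] = tuple(d[k])
        cfg.site_spec = SiteSpec(**d)
    if "protocol" in raw:
        cfg.protocol = _parse_protocol(raw["protocol"])
    if "tissues" in raw:
        cfg.tissues = tuple(TissueParams(**t) for t in raw["tissues"])
    return cfg


def load_config(path: str | Path | None) -> ExperimentConfig:
    if path is None:
        return ExperimentConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)
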