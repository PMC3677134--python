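# mpmrepro

Quantitative multi-parameter mapping (MPM) at 3T estimates four tissue
parameters — the longitudinal relaxation rate R1 = 1/T1, the effective proton
density PD\*, the magnetization transfer saturation MT and the effective
transverse relaxation rate R2\* = 1/T2\* — from three multi-echo FLASH scans
plus a transmit-field (B1) map.  Because these are physical quantities rather
than scanner-flavoured intensities, maps acquired on different scanners should
agree, which is what makes MPM attractive for multi-centre neuroimaging.

`mpmrepro` is for people who want to study that claim quantitatively without
scanner time: it implements the full estimation chain, the multi-site
reproducibility statistics used to validate it, and — since raw multi-site
scans are not publicly available — the forward problem: a digital brain
phantom and a scanner/session model (smooth RF transmit and receive fields,
B1-map error, head repositioning, thermal noise) emulating five volunteers
scanned at three sites.

## The model in brief

Each scan is a spoiled gradient echo in steady state,

    S(TE) = A sin α · (1−δ)(1−E1) / (1 − (1−δ) E1 cos α) · e^(−TE·R2*),
    E1 = exp(−TR·R1),

with amplitude A ∝ proton density × receive sensitivity, local flip angle
α = f_T·α_nom, and saturation δ > 0 only in the MT-weighted scan
(TR/α = 18.7 ms/20° for T1w, 23.7 ms/6° for PDw and MTw; echoes 2.2–14.7 ms,
eight echoes to 19.7 ms for PDw).  The chain estimates:

* **R2\***: log-linear fit over the eight PDw echoes;
* **A, R1**: two-point inversion of the rational approximation
  S ≈ A α TR·R1/(α²/2 + TR·R1) from the T1w/PDw echo averages, then transmit
  correction (R1 ← R1·f_T², quadratic in B1) and optional RF-spoiling
  correction with coefficients derived from an isochromat simulation;
* **MT**: δ = (A α/S_MT − 1)·TR·R1 − α²/2 at the local angle, then the
  semi-empirical B1 correction MT ← MT·0.6/(1 − 0.4 f_T);
* **PD\***: receive-bias removal by a generative smooth-field/tissue-class
  model, then global calibration of mean white-matter PD to 69 p.u.

The analysis registers all maps to a per-volunteer reference (known rigid
transforms, 4th-order B-splines), segments the MT map and the mean T1w image
into CSF/GM/WM, and computes inter-site and intra-site coefficients of
variation, per-site bias, GM-probability reproducibility, repeated-measures
ANOVAs and paired t-tests.  `docs/methods.md` documents every model choice.

## Worked example

```python
from mpmrepro.pipeline import run_experiment

# two volunteers, three sites, 48^3 grid - a 40 s smoke experiment
report, volunteers = run_experiment(seed=42, n_volunteers=2, n_sites=3,
                                    dims=(48, 48, 48), voxel_size=160/48)
print(report.inter_site_summary().round(2).to_string(index=False))
```

prints (excerpt)

```
parameter             roi  mean   std
       MT              wm  0.49  0.06
      PD*              gm  1.73  0.13
       R1              gm  0.11  0.06
      R2*              wm  0.23  0.01
      T1w              gm  6.04  1.50
      T1w              wm 11.54  6.99
```

— the quantitative maps vary by well under 2% across simulated scanners while
the conventional T1w intensity varies by 6–12%, the contrast the method is
designed to produce.  Recovery of the configured ground truth by the full
chain, same run:

```
  R1 gm: estimated 0.603 (ground truth 0.609)
  MT wm: estimated 1.798 (ground truth 1.764)
 R2* wm: estimated 21.039 (ground truth 21.0)
 PD* wm: estimated 68.992 (ground truth 69.0)
```

The small positive MT offset (~+2%) is the documented first-order bias of the
semi-quantitative MT formula, not noise (see `docs/methods.md`).

A command-line interface wraps the same pipeline for file-based runs:

```bash
mpmrepro simulate --config my.yaml --seed 1 --out run/   # NIfTI echo series
mpmrepro estimate --seed 1 --out run/                     # parameter maps
mpmrepro analyze  --seed 1 --out run/                     # TSV/JSON tables
mpmrepro report   --seed 1 --out run/                     # console summary
```

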