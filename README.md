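# blebkit

Quantification of T-cell blebbing and motility from two-channel time-lapse
microscopy.

Cytotoxic T lymphocytes normally crawl through tissue with an actin-rich
lamellipodium. When branched-actin nucleation by the Arp2/3 complex is
impaired, the cortex weakens and cells switch to *blebbing* migration:
transient balloon-like membrane protrusions, initially devoid of cortical
actin, inflate at the leading edge and retract as actin reassembles. blebkit
implements the full measurement pipeline around this phenotype:

- **Track motility** — per-track mean speed (path length / duration, in
  μm/min), confinement ratio (net displacement / path length), mean squared
  displacement `MSD(τ)` averaged over all overlapping frame pairs and then
  over tracks, diffusion coefficient `D = slope / (2d)` from a through-origin
  linear fit of the short-lag MSD, straightness z-score against an isotropic
  step-shuffling null, and planar distance from an injection site
  `d = √((xᵢ−x₀)² + (yᵢ−y₀)²) · pixel size`.
- **Bleb morphometry** — cell segmentation (Otsu, largest component), aspect
  ratio from the second-moment-equivalent ellipse, detection of actin-void
  peripheral protrusions, greedy nearest-centroid linking, per-bleb area
  fraction / major-axis diameter, and expansion/retraction durations from the
  area-versus-time profile.
- **Actin-recruitment delay** — per-channel mean ROI intensity normalized to
  [0, 1], delay = difference of interpolated 0.5-crossings (positive when
  actin follows membrane).
- **Assay formulas** — cortical tension by the law of Laplace
  `T_c = R_c R_p / (2 (R_c − R_p)) · Δp` (μm, Pa → pN/μm), micropipette
  adhesion frequency, specific cytotoxic index
  `100 · (experimental − spontaneous) / (maximum − spontaneous)`, and homing
  indices.
- **Synthetic data** — ground-truthed generators for Brownian and
  persistent-random-walk track ensembles, blebbing-cell movies (membrane +
  actin channels, programmed bleb kinetics and actin lag), aspiration tables
  and killing-assay tables, so every stage is testable without microscopy
  data.

## Worked example

`examples/` contains one short script per capability. For instance,
recovering motility parameters from simulated ensembles
(`python examples/01_track_motility.py`):

```
control: 220 tracks, D = 26.8 um^2/min (generating 26.7), mean confinement ratio 0.15
Arp3-KD: 55 tracks, D = 10.7 um^2/min (generating 10.4), mean confinement ratio 0.14
straight track: S = 1.00, z = 8.5
```

The two ensembles are simulated at the control and knockdown presets
(diffusion coefficients 26.7 and 10.4 μm²/min; 220 and 55 tracks of 45
frames every 20 s), the 5 μm track-length filter is applied, and the MSD
regression recovers the generating coefficients to within a few percent. And
bleb morphometry on the default synthetic fixture
(`python examples/02_bleb_morphometry.py`):

```
blebs per frame at steady state: 5.0 (programmed 5)
bleb area fraction: 1.90% of cell area (programmed ~2%)
bleb diameter: 3.06 um (programmed 3.0)
5 bleb tracks, 55 linked regions
bleb 0: expansion 15 s, retraction 30 s (programmed 19/32)
```

Five ~3 μm blebs, each about 2% of whole-cell area, are detected at the
leading edge in every steady-state frame; the linked tracks recover the
programmed 19 s expansion and 32 s retraction to within one 5 s frame
interval (the detector first sees a bleb one frame after its birth, hence
the one-frame bias).

A thin `blebkit` CLI exposes the same stages
(`blebkit simulate movie --out DIR`, `blebkit blebs --movie m.tif --meta
m.json --out DIR`, `blebkit tension --in asp.csv --out t.csv`, ...).

## Layout

```
src/blebkit/
  simulate/        track, movie and assay-table generators with ground truth
  motility.py      track statistics, MSD, diffusion fit, straightness z-score
  morphometry.py   segmentation, bleb detection/linking/kinetics, shape features
  recruitment.py   ROI traces and actin-delay estimation
  assays.py        Laplace tension, adhesion frequency, cytotoxic/homing indices
  io.py            TIFF+JSON movies, track CSVs
  pipeline.py      configured end-to-end runs with provenance
  cli.py           thin command-line interface
docs/methods.md    models, parameters, numerical choices, limitations
examples/          one narrative script per capability
```
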