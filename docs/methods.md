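# Methods

This note documents the models behind blebkit, the defaults and why they were
chosen, the numerical conventions, and what the synthetic fixtures do and do
not establish about real microscopy data.

## Track motility

A track is a time-ordered sequence of 2D/3D positions (μm) with strictly
increasing timestamps (s). Statistics:

- **Mean speed** = path length / duration, reported in μm/min. For uniform
  sampling this equals the mean of instantaneous speeds; tracking software
  reports a "mean speed" without a formula, so the path-based definition is
  fixed here.
- **Confinement ratio** = net displacement / path length ∈ [0, 1]; defined as
  0 for a zero-length path.
- **Track filter**: tracks with path length < 5 μm are excluded before
  population statistics, removing essentially stationary (blebbing-in-place)
  cells.
- **MSD**: per track, the squared displacement is averaged over *all*
  overlapping frame pairs at each integer lag; the population curve is the
  unweighted mean of per-track MSDs at each lag, excluding tracks too short
  to reach it. Unweighted averaging (rather than pair-count weighting)
  matches "average the MSD of all tracks" semantics and keeps long tracks
  from dominating.
- **Diffusion coefficient**: least-squares line *through the origin* on lags
  up to 25% of the maximum observed lag; `D = slope / (2d)` converted to
  μm²/min, with d = 3 for collagen/in-vivo data and d = 2 available for
  planar assays. Short-lag fitting is standard practice because long-lag MSD
  values average few pairs and are strongly correlated; both the lag
  fraction and d are exposed. Negative slopes are clamped to zero with a
  flag.
- **Straightness z-score**: S = net displacement / path length compared
  against a null of the same step lengths with directions redrawn uniformly
  (circle in 2D, sphere in 3D); z = (S − μ_null)/σ_null, seeded. The exact
  published recipe for this score is not restated in the source literature,
  so the step-length-preserving isotropic null is this package's documented
  construction.
- **Injection-site distance** is planar by definition: z is ignored even
  when present.

## Synthetic tracks

Brownian mode draws per-axis Gaussian steps with variance 2·D·Δt. PRW mode
moves each cell at a per-track constant speed drawn from a Gaussian truncated
at zero, with heading evolving as d ← normalize(α·d + √(1−α²)·η),
α = exp(−Δt/τ_p), i.e. exponential decorrelation with persistence time τ_p
(default 60 s, a typical T-cell value; the track model itself is a package
choice since only summary statistics are reported upstream). Presets encode
the two study conditions: control (220 tracks, D = 26.7 μm²/min, speed
5 ± 2.3 μm/min) and knockdown (55 tracks, D = 10.4 μm²/min, speed
2.3 ± 1.4 μm/min), 45 frames at Δt = 20 s (~15 min of imaging). Truncation
at zero inflates the realized mean speed by <2% at these parameters, well
inside the 10% recovery tolerance.

## Synthetic blebbing-cell movies

Movies are rendered in 2D (a single plane per timestamp) with per-plane
timestamps advancing by frame_interval / z_steps_per_frame, mirroring how
fast intra-stack kinetics are analyzed after maximum-intensity projection;
the same analysis code path therefore runs on desk-scale fixtures. Geometry
and kinetics defaults are the reported bleb morphology: five blebs of 3 μm
diameter at the leading edge (±60° of the heading; the heading of the
stationary fixture cell defaults to +x), 19 s expansion, 10 s plateau, 32 s
retraction, 1 s actin lag. `cell_radius_um = 9.8` is derived so one fully
expanded bleb is ~2% of whole-cell (body + blebs) area.

Intensity model (the source reports none, so these are package choices):

- membrane channel: uniform fill of the cell body disk plus each bleb disk
  (blebs sit at distance R_cell + 0.8·r from the center, so ~20% of the bleb
  disk overlaps the body);
- actin channel: a 2-pixel cortical rim on the body circle at full
  intensity, plus a uniform fill inside each bleb at 40% of rim intensity
  whose footprint is the bleb's membrane footprint *delayed by the actin
  lag*. Two consequences: (i) a mature bleb stays darker than the cortical
  rim, so the actin-void detector finds blebs in every phase of their life
  cycle (their interior never reaches rim intensity), and (ii) the mean
  actin intensity inside a bleb ROI is an exact time-shift of the membrane
  intensity, which is what a threshold-crossing delay estimator measures.
- Bleb area ramps *linearly in area* (radius ∝ √t) during expansion and
  retraction. This keeps the ROI-mean intensity traces piecewise-linear in
  time, so the delay estimator's linear interpolation is near-exact, and it
  corresponds to constant volume flux into/out of the bleb.
- Blebs are placed evenly (with seeded jitter) on the leading-edge arc; a
  configuration whose blebs cannot fit without overlap raises an explicit
  placement error. All blebs are born at t = 0 by default, giving a clean
  steady-state window (all blebs at plateau) recorded in the ground truth.
- Optional Gaussian noise (sd as a fraction of foreground intensity) is a
  stand-in; real camera noise statistics are unreported upstream.

Ground truth carries per-frame cell and per-bleb masks, programmed birth and
death times, per-frame radius and centroid, the actin lag, and the echoed
configuration.

## Bleb detection

Per frame, the cell is the largest Otsu-foreground component of the membrane
channel, holes filled. Bleb candidates are *geometric protrusions*: the cell
mask minus its morphological opening (disk radius `opening_radius_um`,
default 2.5 μm — larger than the expected bleb radius so bleb bumps are
removed from the outline, much smaller than the cell radius so the body is
preserved). Candidates must touch the cell boundary and have area between
`min_area_um2` (0.5) and `max_area_fraction` (0.25) of the cell. A candidate
qualifies as a bleb when its *mean* actin intensity is below the
`actin_void_quantile` (default 0.5) quantile of the cortical-rim actin
distribution (rim = body pixels within `rim_width_px` of the body boundary).

The region-level actin test is deliberately not a per-pixel threshold:
comparing individual pixels against the rim's own median makes the rim
porous under noise (half its pixels fall below their median by
construction), letting bleb components merge with the dark cell interior;
region means average the noise away and keep precision/recall high at 5%
noise. The `leading_edge` flag is set when the centroid direction from the
cell centroid lies within ±60° of the heading (cone half-angle
configurable); for moving cells the heading should be supplied from the
centroid displacement over the previous ~3 frames.

Linking is greedy nearest-centroid, one-to-one per consecutive frame pair,
with default gate 2 μm; no split/merge handling. Kinetics from a linked
track's area profile: expansion = first frame → first maximal-area frame,
retraction = last maximal-area frame → last frame; plateau frames belong to
neither, so expansion + plateau + retraction equals the observed lifetime
exactly. Because a bleb has zero area at its birth instant, the first
*detected* frame is typically one frame late, biasing recovered expansion
short by about one frame interval; recovered durations are guaranteed only
to within one frame interval of truth.

Coordinates are 0-based row-major pixel indices; physical positions use
pixel centers, (index + 0.5)·pixel size.

## Actin-recruitment delay

Mean intensity of each channel inside a polygon ROI per plane (a pixel
belongs to the ROI when its center is inside the polygon), normalized
min→0/max→1 over the observation window — for bleb ROIs the window should be
the bleb's lifetime, since pre-birth background would distort the
normalization. The crossing time per channel is the first time the
normalized trace reaches the threshold (default 0.5), linearly interpolated
between samples; delay = actin crossing − membrane crossing. Normalization
makes the estimate invariant to per-channel gain and offset; interpolation
keeps the quantization error below half the sampling interval. The upstream
detection criterion behind the ~1 s literature value is unspecified;
threshold crossing is this package's documented operationalization, with the
threshold configurable.

## Assay formulas

- Cortical tension: T_c = R_c·R_p / (2·(R_c − R_p)) · Δp, radii in μm and
  pressure in Pa giving pN/μm (Pa·μm ≡ pN/μm). Requires R_c > R_p; a
  validity flag marks measurements whose aspirated tongue length deviates
  from R_p by more than 10% (the hemispherical-cap regime of the Laplace
  relation). Homogeneous of degree 1 in Δp.
- Adhesion frequency: adhesion events / touches per cell pair (typically 10
  touches); cohort summary is median, quartiles and extrema.
- Specific cytotoxic index: 100·(experimental − spontaneous)/(maximum −
  spontaneous). Values outside [0, 100] — possible with noisy percentages —
  are flagged, not clamped, so assay problems stay visible.
- Homing index: % labeled cells in tissue / % in the injected input; a
  second ratio normalizes to day-6 blood instead.

The synthetic assay generators invert these formulas around drawn ground
truths (tension range 50–400 pN/μm, pipette radii 1.5–3 μm, cell radius
1.5–3× pipette radius; killing-assay spontaneous death anchored at 4.51%),
so estimator round trips are exact to floating point.

## Problem sizes and determinism

Default analysis problem sizes — 220/55 tracks × 45 frames, a 128×128×14
movie fixture, a 192×192×40 delay fixture at 0.15 μm pixels (finer pixels
keep the pixel-count staircase of a 3 μm bleb small relative to the 0.65 s
sampling) — were chosen so that each stage completes in seconds while
leaving the estimators' statistical errors well inside their tolerances.
Every generator and the straightness null are driven by explicit seeds;
identical configuration and seed give bit-identical outputs, and pipeline
outputs embed a provenance block (hash of analysis parameters, seed,
version).

## Limitations

The fixtures validate the estimators' correctness on data whose generating
process is known; they do not establish performance on real microscopy.
Specifically not modeled: optics (PSF, z-attenuation), photobleaching,
non-Gaussian camera noise, cell translocation during blebbing, overlapping
or merging blebs (merged regions are counted once), filopodia, and 3D
volumetric rendering. The straightness null and the delay detection
criterion are documented substitutes for upstream procedures that were not
fully specified. Track statistics assume (near-)uniform sampling and raise
otherwise.
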