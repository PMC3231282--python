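# Methods

This note records the models implemented in `burrowtrack`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
do and do not establish about real recordings.

## Tank, grid and position quantization

The tank is a 150 × 70 cm footprint (30 cm deep) in continuous centimetre
coordinates, origin at a corner. The antenna grid has 42 positions at the
cell midpoints of the uniform 7 × 6 partition (spacing ≈ 21.43 × 11.67 cm),
numbered row-major 1–42, one controller per row. The physical system reads
37 of them: which five grid positions are unconnected is a wiring detail of
the built instrument that is not recoverable from its description, so the
default deactivates the highest-numbered 2 positions of controller C2 and 3
of C3 (ids 13, 14, 19, 20, 21), which reproduces the documented per-controller
counts (7, 5, 4, 7, 7, 7); any other wiring can be expressed in the YAML
layout config. The same applies to the four burrows: their exact placement
is configurable, and the default puts each entrance on a grid-cell midpoint
with the tunnel running parallel to the x axis, so that entrance and
interior points fall on distinct active antennas.

Two position-assignment modes exist:

* **Full-coverage Voronoi** (default): a tag is always localized to the
  nearest active antenna center. This is the idealization under which a
  displacement series is defined at every tick.
* **Range-limited**: no detection when the tag is farther than the field
  radius (3.0 cm, half the 6.0 cm tracking diameter of the chosen tag) from
  every center — the physical dead zones of the antenna fields. Gaps in the
  log are bridged by a single center-to-center distance and flagged.

A property worth knowing when interpreting either mode: full-coverage
quantization is *not* guaranteed to under-estimate travelled distance. For
motion slow relative to the cell size, each boundary crossing is scored at
the full inter-center distance, which behaves like an L1 metric and can
slightly over-count (up to ~4/π for isotropic small steps), while fast or
dwelling motion is under-counted. In the range-limited mode the reader
strictly loses distance (dead zones plus within-field motion), which is the
regime in which the video-above-RFID ordering of total activity holds in
every simulated replicate; the ordering tests therefore use that mode,
while the end-to-end runner keeps the Voronoi default for analysis
continuity.

## Behavioural simulator

Each animal is a two-state continuous-time Markov chain discretized at the
simulation step (1 s by default, deliberately finer than the 5-s reader
cadence so that quantization is genuinely downstream):

* sheltered → emerged at rate r_e(t) = r_light · L(t) + r_dark · (1 − L(t)),
  where L(t) ∈ [0, 1] is the photoperiod's light fraction (lights on
  07:00–19:00 with a 30-min linear ramp at each transition; a square-wave
  mode exists);
* emerged → sheltered at the constant retreat rate.

Sheltered animals rest at their burrow's interior point (the horizontal
projection of the 25 cm, 20°-inclined tunnel end). Emerged motion is a
correlated random walk: wrapped-normal turning angles with standard
deviation 1/√κ (κ = `turning_concentration`, default 4; κ = 0 gives uniform
turning), truncated-normal step speeds (mean 2 cm/s, sd 0.8 cm/s by
default), reflection at the walls. `activity_scale` multiplies step lengths
so that path length scales linearly at fixed seed (exactly so away from
walls; reflections clip a small fraction).

No published emergence/retreat rates or walking speeds exist for this
setting, so the presets are illustrative: they are chosen to produce the
qualitative pattern the instrument was built to measure — strong nocturnal
emergence (dark rate 2 /h vs 0.05 /h in light, retreat 1 /h gives roughly
two-thirds of the day sheltered and >80 % of path length in darkness) and
inter-individual differences (the default trio varies emergence rate and
speed). A dominance option multiplies a designated subordinate's emergence
rates by a factor in (0, 1], a minimal stand-in for the activity
suppression seen when several animals share a tank. There is no collision,
aggression or hydrodynamic model.

Per-animal random streams are spawned from the master seed by animal index,
so group runs reproduce the corresponding individual runs exactly.

## RFID reader model

All controllers are idealized as sweeping simultaneously every 5-s tick;
intra-sweep latency of the real serial polling is microseconds-to-
milliseconds, far below the 10-min analysis bins, and is not modelled.
Anti-collision is assumed perfect (several animals may be logged on one
antenna in one tick). Displacement between consecutive detections is the
distance between antenna centers; occupancy is the percentage of an
animal's detections per antenna; burrow occupancy converts maximal runs of
ticks on burrow-interior antennas into (enter, exit) intervals, discarding
runs shorter than 2 ticks as pass-throughs (configurable). Interval ends
are placed at the end of the last tick, so an n-tick stay spans n × 5 s and
recovered sheltered time agrees with ground truth to within one cadence per
transition — provided the emerged walk stays off the interior antenna's
cell, which a wandering animal near its burrow need not do; on free
simulations the recovered total is accordingly biased slightly upward.

## Video imaging chain

Frames are 8-bit grey, 1280 × 1024 by default, calibrated by a uniform
scale mapping the 150 cm tank side to the frame width (no lens distortion).
The detection pipeline is: absolute difference against an empty-tank
background → foreground strictly above the grey threshold (10 at night, 20
by day — read as "keep pixels brighter than the threshold in the
difference image"; the alternative reading, deleting bright pixels, would
delete the tags) → 8-connected components → area filter 100–400 px → shape
matching. No morphological cleanup is applied.

Shape matching scans each template through rotations in 2° steps and scores
alignment-at-centroids overlap as intersection-over-union (the original
procedure names no score; IoU is the standard choice). Template rotations
are bilinear, leaving fractional edge pixels, and the score generalizes to
sum(min)/sum(max): with hard-rotated small masks, neighbouring 2° rotations
are often pixel-identical, which makes the argmax degenerate; the soft
variant discriminates to ≤ 2° in noise-free closed loop. Ties break to the
lower rotation, then to template order (circle, triangle, outlined
triangle). The circle reports rotation 0. A detection requires score ≥ 0.5
(configurable). Equilateral triangles are 120°-symmetric, so rotation
accuracy is meaningful modulo 120°.

The synthetic renderer draws template masks at calibrated positions over a
uniform background (day grey 90, night 35, tag grey 230) with optional
Gaussian pixel noise. It emulates geometry, day/night contrast and sensor
noise only — not water-surface reflection, moult debris, bubbles, turbidity
or uneven illumination. Closed-loop tests (render → detect) therefore
establish the correctness of the pipeline's logic, not its robustness on
real footage.

## Rhythm statistics

Displacement values (stamped at interval ends) are summed into clock-aligned
10-min bins; a value landing exactly on a boundary belongs to the preceding
bin; trailing partial bins are dropped; empty bins are 0.

The chi-square periodogram scans candidate periods of p bins from 20 h to
27 h at one-bin (10-min) resolution. For each p the series x_1…x_N is
folded into columns h = 1…p with K_h entries and means M_h (unequal K_h —
partial last cycles — are handled by the general formula):

    Q_p = Σ_h K_h (M_h − M̄)² / σ̂²,   σ̂² = Σ_i (x_i − M̄)² / N,

compared against χ²(1 − α, p − 1) with α = 0.05 per candidate period — the
per-peak significance line customary in this analysis; no multiplicity
correction is applied across the scan, which is a documented limitation
(the null-calibration test verifies the per-period rate, not a family-wise
one). The peak is the significant Q-maximizing period; %V = 100 ·
Σ K_h (M_h − M̄)² / Σ (x_i − M̄)² there. Q is invariant to adding a
constant and to positive rescaling. Zero-variance input is a data error.
The commercial chronobiology package this mirrors scans a 5-min grid
(hence published peaks like 1,430/1,435 min); the 10-min grid here follows
the binning resolution.

Waveform analysis folds onto exactly 144 bins aligned to clock time, means
across days (SEM = sd/√days; 0 where only one day covers a bin), MESOR =
mean of the 144 means (identically, to ~1e-16), phases = maximal runs
strictly above the MESOR, merged across midnight, onset/offset at run
boundaries. A constant series yields a flat profile and no phases.

## Problem sizes and determinism

Default experiments simulate 3 animals × 7 days at 1-s steps; tests use
shorter spans (hours to one day) and the statistical suites use 100–200
replicates of 7-day binned series, which the vectorized periodogram handles
in well under a second each. Every stochastic stage draws from
`numpy.random.default_rng` seeded from a single master seed, so all outputs
are bit-reproducible per seed.

## Known limitations

* Behavioural parameters are illustrative presets, not fitted to animals;
  conclusions from simulations are about the measurement chain, not about
  lobster biology.
* The full-coverage Voronoi mode can slightly over-count slow motion (see
  above); use the range-limited mode when the strict under-count semantics
  of finite antenna fields matter.
* Occupancy and burrow-occupancy attribute all detections to the single
  answering antenna; overlapping-field effects at cell borders are not
  modelled.
* The video model omits every optical artefact of real tanks; its accuracy
  figures are upper bounds.
* No cosinor, Lomb–Scargle or wavelet alternatives; the periodogram's
  α is per candidate period.
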