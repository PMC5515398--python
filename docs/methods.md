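# Methods

`virtualrig` is a software twin of a low-cost Raspberry-Pi/Arduino
behavioural-neurogenetics rig: a camera with a binning/frame-rate trade-off,
an LED ring and Peltier plate for opto- and thermogenetic stimulation, and
the image-analysis procedures used on the resulting recordings. Because no
recordings from such rigs are distributed with the package, every analysis is
validated against synthetic scenes whose ground truth the generator records
exactly. This note describes the models, the defaults and why they are what
they are, and what the synthetic validation does and does not establish.

## Conventions

Pixel coordinates are 0-based, row-major, origin top-left. Rectangles are
half-open `[x0, x1) × [y0, y1)`. 8-bit stacks hold values in [0, 255]; the
signed time-differential output is float. Stacks are written as multi-page
TIFF with a JSON sidecar for frame rate, pixel size, start time and channel
names (TIFF tags for these are dialect-ridden; a sidecar is unambiguous).
TIFF is the lossless primary format; AVI import exists but is excluded from
bit-exact guarantees. Greyscale conversion defaults to the unweighted RGB
mean rounded half-up (BT.601 luminance behind a flag); spatial binning and
temporal downsampling are block means (decimation behind a flag) — averaging
improves SNR and reproduces the ~100 ms frame spacing of the downsampled
calcium analysis. The rounding/averaging rule of the real camera's GPU
binning is not documented anywhere we know of; block-mean is the stand-in.

## Camera and noise model

The virtual sensor mirrors the acquisition conventions of the hardware:
2592 × 1944 RGB at 15 Hz, ×2 binning (1296 × 972) at 42 Hz, ×4 at 90 Hz,
~1 µm effective pixel size at peak zoom. Scenes are rendered directly at the
binned output geometry for speed; a slow render-then-bin path exists and is
used to cross-validate the binning transform. Bayer mosaicing is not
simulated — analyses operate on demosaiced output only.

Noise: analytic intensity `I ∈ [0, 1]` → Poisson photon counts with mean
`photon_scale · I` → Gaussian read noise (`read_noise_sd` grey levels) →
8-bit quantisation. `photon_scale=None` disables noise for noise-free
oracles. The flat-field mean and variance follow the Poisson + read-noise
prediction; a test checks both.

## Scenes and their ground truth

* **Beads** — isolated integrated-2D-Gaussian spots (s.d. `sigma_um`,
  default 5.4 µm, the rig's measured optical PSF width at full zoom),
  placed by rejection sampling at ≥ 6 σ separation. At the defaults
  (`photon_scale=800`, peak intensity 0.5) the peak photon SNR is √400 = 20.
* **Crawling larva** — a vertical body band whose green-channel intensity
  carries a travelling raised-cosine calcium wave: baseline 0.25, amplitude
  0.5, period 1.5 s, speed 4000 µm/s (≈ one body length per second for a
  4 mm animal), wave width 800 µm. Waves start at the tail and run
  head-ward; the body drifts head-ward by 150 µm per wave period. The first
  wave starts at 0.5 s so the running-average differential has a wave-free
  warm-up. The scene is rendered at 10.5 Hz and 20 µm pixels — the effective
  rate and scale of the real analysis after ×4 temporal and ×2 spatial
  downsampling of a 42 Hz low-zoom recording. No quantitative GCaMP
  amplitudes are published for this preparation; the fluorescence levels are
  free parameters of the generator, documented here and in the config.
* **Proboscis extension (PER)** — a fixed fly; each red-LED stimulus (the
  default protocol is 1 s on / 2 s off × 5, compiled by the protocol engine)
  adds a uniform 10-grey-level illumination artefact to the whole frame and,
  100 ms later, brightens a known tip ROI for the stimulus duration. The
  artefact forces the analysis to do background-over-time subtraction; an
  artefact-only control (extension disabled) must come out flat.
* **Tethered fish** — two fin ROIs burst (3 Hz-modulated brightness, 0.8 s)
  from 100 ms after each stimulus whose duration is ≥ 0.5 s — the shortest
  reliably effective stimulus on the physical rig, with ~150 ms stimuli
  ineffective. The threshold is modelled as sharp because only those two
  operating points are characterised; the transition shape is unknown. The
  model is ROI-level brightness, not fin kinematics, because the analysis it
  feeds is ROI mean brightness — the minimal sufficient structure.
* **Arena flies** — dark blobs on a light floor doing reflecting,
  direction-persistent random walks with pairwise repulsion below 60% of the
  minimum separation. Truth is the per-frame centroid per identity.

All generators are deterministic given (config, seed), and every truth
payload is validated against its stack (events inside the time span,
coordinates inside the frame).

## Calcium analysis

Background subtraction offers three estimators: static minimum projection
(default; the underspecified "background subtraction" of the calcium
workflow), per-pixel temporal median, and `frame_background` — the spatial
median of each frame, i.e. the background level *over time*, which is the
only one of the three that removes a frame-wide time-varying artefact and is
what the PER chain uses.

The running-average time-differential subtracts from each frame the mean of
the `k = 4` preceding frames (signed float output, first `k` frames dropped,
`t0` shifted by `k`/rate). The implementation fixes its summation order so it
is bit-identical to the naive double-loop oracle, and its frame-sum obeys a
telescoping closed form — both are tested.

The kymograph is the short-axis mean per frame (position axis = image rows;
rotating the body axis vertical is the caller's responsibility — there is no
automatic body-axis registration). Wave detection thresholds the positive
differential at `min_prominence = 0.3` of the map maximum and keeps
8-connected components spanning ≥ `min_extent = 0.5` of the position axis
(rejecting noise blobs and the short body-edge ridges produced by crawling
drift); speed is the least-squares slope of the intensity-weighted ridge
centroids. The original analysis identified waves by eye; these defaults are
this package's operationalisation and recover 5/5 waves with < 4% speed
error across seeds on the default scene.

## PSF estimation

Candidate spots: local maxima above median background + 5 MAD-derived noise
s.d.; spots with saturated pixels, neighbours within 6 widths, or windows
crossing the border are rejected. Each spot is fitted with an integrated 2-D
isotropic Gaussian (amplitude, centre, σ, offset) by least squares on a
±4 σ window. The summary is the **median** per-bead σ × pixel size — the
aggregation behind the single reported width is not documented, and the
median is robust to the occasional spurious detection. Recovery bias is
< 5% over σ ∈ {2, 4, 8} px at photon SNR ≥ 20, and < 1% in the noiseless
limit (tested).

## Behavioural quantification

Event detection: baseline = trace median; threshold = baseline + 3 × MAD-
derived σ (or absolute); runs above threshold are merged across gaps
< 100 ms and kept if ≥ 100 ms. These are config values, not constants.

Larval length replaces a manual head-to-tail measurement with an automated
one: Otsu threshold → largest component → skeleton → longest geodesic path.
The raw 8-connected path over-counts curved digital lines by several
percent, so the reconstructed path is smoothed (7-sample moving average)
before summing segment lengths, and the distance-transform radii at the two
endpoints are added back (the skeleton stops about one local radius short of
each end). A straight rod and a semicircular arc fixture are both recovered
within 5% — the arc is the case an ellipse major axis or chord would get
badly wrong. Contraction metrics take the nearest samples at t = −1, +0.5
and +5 s around the flash; contraction = 1 − len(0.5)/len(−1), recovery =
len(5)/len(−1).

Fin-bout verdicts: a stimulus scores a bout when event detection fires on
either fin trace within 1 s of onset (the recordings show prompt responses;
no window is documented, 1 s is this package's choice); latency is first
event onset minus stimulus onset.

The tracker is deliberately minimal: per-frame Otsu + connected components,
greedy nearest-neighbour linking under `max_jump_px` (15 px default, set
well below the scene's minimum inter-fly separation), new tracks for
unmatched detections, termination after 2 missed frames. Greedy rather than
Hungarian assignment: at the separations the generator guarantees the two
coincide, and greedy is simpler to verify. Recall/precision are 1.0 with
zero identity switches at ≥ 4-blob-diameter separation (tested).

## Thermoelectric loop

The plant is a two-node lumped model (surface plate, fan-cooled heat sink)
with antisymmetric pumped/conducted flows between the nodes — energy is
conserved up to the ambient couplings, asserted per step. Cooling is derated
by `eta_asym = 0.7` (thermoelectric cooling is less efficient than heating).
The published characterisation of the physical loop is performance, not
physics, so the default constants are a calibration chosen once to
reproduce that performance at 19 °C ambient and then frozen:

| parameter | value | note |
|---|---|---|
| C_surf | 12 J/°C | ~16 cm² × 3 mm aluminium plate |
| C_sink | 200 J/°C | finned sink + fan mass |
| k_surf_sink | 0.5 W/°C | conduction through the module |
| k_surf_amb | 0.3 W/°C | free convection off the plate |
| k_sink_amb_fan | 2.0 W/°C | forced convection |
| Q_max | 28 W | peak pumped heat |

Closed form, these give full-drive steady offsets of +32.0 / −22.4 °C from
ambient (≥ ±20 °C), and the closed loop ramps 15 ↔ 35 °C at ≈ 1.9 °C/s
(10–90%) while holding with s.d. ≈ 0.26 °C — inside the < 1 °C figure.

The control law of the physical firmware is not published; the default is
bang-bang with ±0.25 °C hysteresis (robust, no tuning — the observed stable
holds are achievable by it), with a clamped PI controller available for
comparison. The thermistor is a 10 kΩ NTC (β = 3950 K, typical catalogue
values — the actual part values are hardware BOM details) in a 10 kΩ divider
read by a 10-bit ADC; Gaussian sensor noise (0.1 °C s.d.) is added before
quantisation. Near 25 °C one ADC code is ≈ 0.1 °C. Integration runs at
10 ms explicit Euler (stability bound ≈ 30 s for the default constants, so
the step is conservative by three orders of magnitude; the open-loop
trajectory changes < 0.05 °C under step halving), the controller at 10 Hz,
logging at 2 Hz as the firmware streams it.

Loop statistics: epochs are maximal runs of constant setpoint; hold s.d. is
taken after settling (first entry into setpoint ± hysteresis, plus 10 s);
ramp rate is 0.8 × |step| over the time between the 10% and 90% level
crossings, per transition; overshoot is the excursion beyond the setpoint in
the step direction (for the first epoch, which has no transition, the
excursion beyond the setpoint after first reaching the band).

Note the closed bang-bang loop is a relay oscillator: its switching phase is
not robust to integration-step refinement, so step-convergence is asserted
on the open-loop plant, and closed-loop quality is asserted through the
hold/ramp/overshoot statistics.

## Protocol engine

Protocols compile to integer-microsecond event logs (on event, off event per
repeat, steps sequential) with exact integer arithmetic — the total span
equals Σ repeats × (on + off) by construction, property-tested over random
protocols. Execution dispatches on a virtual clock to registered channel
handlers; there is no floating-point time anywhere in the scheduler, and no
wall-clock dependence. The ASCII serial grammar (`RING r g b`,
`PELT SET <0.1 °C units>`, `SERVO id pos`, `LOG ON|OFF`) is a documented
stand-in, not a wire-compatible clone; Peltier setpoints travel as ×10
fixed-point integers to avoid float-parsing ambiguity. The 8×8 LED matrix
channel exists in the grammar but renders only an on/off intensity; spatial
stimulation patterns are out of scope.

## Problem sizes

Synthetic validation runs at reduced geometry chosen to keep every scene
comfortably analysable while preserving the governing ratios (PSF width in
pixels, wave period × frame rate, blob separation ÷ jump limit): bead fields
on a 512 × 512 crop, larva at 160 × 256 / 10.5 Hz, PER and fish at 128 × 96
/ 42 Hz, arena at 256 × 256 / 15 Hz. The full-sensor geometry itself is
exercised where it is the point (the 2592 × 1944 → 1296 × 972 binning
check). The thermo reference run is the full 20-minute switching schedule.

## What passing tests do and do not show

The synthetic scenes share the analysis chain's *model family* (Gaussian
spots, raised-cosine waves, uniform artefacts, sharp bout thresholds), so
recovery tests demonstrate correctness of the implementations and
identifiability of the parameters — not robustness to everything real
recordings add: motion of the larval body axis (no registration is
attempted), occlusions and touching animals in the arena, graded bout
probabilities near threshold, non-uniform illumination artefacts, or optics
(filters, spectra) which are not modelled at all. ΔF/F normalisation,
16-bit pipelines, h264 encoding and live capture are likewise out of scope.
Absolute fluorescence scales are arbitrary units throughout.
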