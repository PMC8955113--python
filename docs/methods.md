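# Methods

`thermofall` implements two analyses over low-resolution thermal sensor
streams from the homes of older adults: (1) a privacy-preserving
*activity score* — how much of each hour a person was moving in a room —
and (2) *fall detection* from short windows of thermal video. Both work
on data so coarse (a 32×24 thermopile array at ~16 fps, and stacks of
8-pixel thermopile line sensors at ~5 fps) that individuals are not
identifiable, which is the point of the sensing modality.

## Sensor model and capture formats

The 2D unit of capture is one 24×32 temperature matrix (°C) with a
timestamp; the 1D unit is a 1×33 array — timestamp plus 4 line sensors ×
8 pixels. Captures are stored as plain text (frames: a `# <ISO-8601>`
header plus 24 rows of 32 values; 1D: 33-column CSV).

A capture hour is **valid** only if it was recorded without
interruption: at least `frame_rate × 3600` records, i.e. 57,600 records
per hour for the 2D sensor and 18,000 for the 1D sensor at their nominal
rates. Invalid hours are *missing*, never zero — an interrupted capture
says nothing about activity. The thresholds scale with `frame_rate`, and
the test suite and examples exploit this to run "hours" at reduced
rates; all defaults are the nominal hardware rates.

### Trailing-zero codec

Measurements are serialized as fixed-point decimals with 7 fractional
digits. The sensors resolve 0.01 °C, so the last five characters of
every measurement field are zeros by construction — pure storage and
transport overhead. The codec elides exactly those five characters per
field and restores them on decompression; timestamps are untouched, and
a field that does not end in five zeros (which the serializer never
produces, but a corrupted stream might) passes through verbatim with a
flag rather than being corrupted. The round trip is lossless by
construction and property-tested. Measured whole-file rates are ~42%
(1D CSV) and ~45% (2D frames); the exact rate depends on the
serialization dialect (timestamp format, separators, field widths), so
it is reported by `compress_file` rather than asserted as a constant.
The 7-digit width is a deliberate choice: it is the narrowest width for
which the five-zero premise holds at the sensors' resolution, and with
it the elision saves ≥40% of a capture file.

## Activity scoring

Principle: compare each pixel against a **reference (background)
temperature**; a pixel whose excess over the reference exceeds a
threshold `delta_t` (default 1.5 °C) is active; a frame is active if at
least `min_active_pixels` pixels are (default 2 for 2D, 1 for 1D — the
1D bins are 4-pixel averages, so a person rarely lights two bins).
Only *positive* exceedance counts: people are warmer than the ambient
background in this setting.

The background itself drifts on a timescale of tens of minutes, so the
reference is a per-pixel **weighted moving average** (WMA) with linearly
increasing weights toward the present — a cheap, robust low-pass filter
that is slow against human movement but fast against diurnal drift.
Defaults: a 600-sample window fed one sample per second (`update_every`
= 16 frames at 16 fps), i.e. a 10-minute memory. Two refinements, both
optional: background samples are *decimated* (above), and *masked* —
pixels currently flagged active contribute their previous reference
value instead of their observation, so a stationary person does not melt
into the background. The plain WMA is available by turning
`masked_update` off.

The **hourly score** is `100 × active frames / total frames` of a valid
hour. Monthly aggregation averages each hour-of-day over the days of the
month per room and reports the population standard deviation; missing
hours are excluded from both moments. On simulated streams the score
recovers a scripted 10% occupancy within ±2 points.

Two choices here are assumptions, made explicit: the score is a
*frame* fraction (not a pixel fraction or an event count), and the WMA
runs *per pixel* (not on a frame aggregate).

## Fall detection

Per 24-frame window (1.5 s at 16 fps, hop 8):

1. **Binarize** each frame at a fixed 28 °C threshold — between ambient
   and the apparent temperature of skin/clothing. Otsu's
   between-class-variance criterion is available (`mode="otsu"`) and
   performs equivalently on two-level frames, but the fixed rule is
   cheaper and is the default. Otsu on a constant (person-free) frame is
   degenerate; it returns an empty mask with a warning.
2. **Clean** the mask: one 3×3 morphological closing (with out-of-grid
   pixels as background), then removal of 8-connected components smaller
   than 3 px.
3. **Thin** with the Zhang–Suen two-subiteration parallel rules until a
   full pass deletes nothing. The implementation is vectorized and is
   property-tested against an independent brute-force application of the
   published per-pixel conditions. One documented property of these
   rules: isolated 2×2 squares are erased entirely; components larger
   than that are preserved one-to-one. **Prune** spurs — endpoint-to-
   branch-point paths strictly shorter than `max_spur_px` (default 3,
   removing spurs of ≤2 px) — re-thinning after each pass to
   convergence; pruning never deletes an isolated segment, so component
   counts are preserved and the operation is idempotent.
4. **Graph**: skeleton pixels are subsampled into nodes — endpoints and
   branch points always, plus every 2nd pixel along each path — with
   edges between consecutive retained pixels, so graph components mirror
   skeleton components. The per-frame graphs of a window are combined
   into one **spatiotemporal graph**: a node-disjoint union plus one
   temporal edge from each node to its nearest node (Euclidean, ties
   toward smaller row then column) in the next frame. Coordinates are
   stored on nodes for inspection but are *never* used as features.
5. **Embed** with Graph2Vec: each graph's Weisfeiler–Lehman subtree
   label multiset (depth 2) is a "document", and PV-DBOW with negative
   sampling learns one k-dimensional vector per graph (k = 30, selected
   by grid search — `grid_search_k` reproduces the selection). The
   embedding is trained without labels on all graphs; unseen graphs are
   embedded in inference mode against the frozen label matrix.
6. **Classify** with a random forest (200 trees, fall = positive class).

### Structural node labels

The initial WL label is a quantized *degree profile*. For spatiotemporal
graphs it separates three structurally distinct edge roles at a node:
intra-frame degree (local skeleton morphology, capped at 4), backward
temporal degree (how many nodes of the previous frame chose this node as
nearest neighbor — this concentrates precisely when the body moves fast,
which is the kinematic signature of a fall as opposed to a controlled
sit/lie/stoop, capped at 8), and forward temporal degree (capped at 2).
Plain graphs without frame annotations fall back to a total-degree
bucket. A single total-degree bucket was evaluated and discards most of
the motion signal: almost every node in a spatiotemporal graph has
total degree ≥3. All variants are invariant to node relabeling and to
translating the skeleton, which is what makes the representation
position- and size-robust.

### PV-DBOW trainer

No embedding library is used: the trainer is ~60 lines of numpy.
Documents are (graph, WL-label) occurrence pairs; per epoch the pairs
are shuffled and processed in mini-batches of 8192 with 5 negative
samples per positive from the unigram^0.75 distribution, a linearly
decaying learning rate (start 0.05), and scatter-updates *averaged* per
row — summing over duplicate indices in a batch makes the step size
proportional to label frequency and diverges; averaging bounds every
row's step by the learning rate. 400 epochs; labels rarer than
`min_count=2` corpus-wide are dropped (they are document identifiers,
not shared structure). Training is deterministic under a fixed seed and
single-threaded BLAS.

### Evaluation protocol

Stratified 5-fold cross-validation of the forest on the (label-free,
transductively trained) embeddings, pooling confusion counts over folds;
precision, sensitivity and specificity are reported as percentages with
fall as the positive class. A permutation control — the same protocol on
shuffled labels — sits at chance (50 ± 10%), confirming the unsupervised
embedding cannot leak labels. Whether the original protocol was CV or a
held-out split is not recoverable; stratified 5-fold CV is the recorded
assumption.

### Alerts

A window classified as a fall yields an alert record with the protocol's
five fields — recipient/response status, event start, event end,
notification time, reviewer comment — appended to an NDJSON log, with
`start ≤ end ≤ notification` enforced.

## Synthetic scenes

No real recordings are distributable, so a simulator generates streams
with the statistical structure the pipeline assumes:

* **Background**: a stationary Ornstein–Uhlenbeck process (τ = 1200 s,
  σ = 0.5 °C) shared by all pixels — the simplest process with the
  "drifts gradually over tens of minutes" property — plus i.i.d.
  Gaussian pixel noise (σ = 0.3 °C) around a 21 °C mean.
* **Body**: a rotated ellipse (aspect ~0.35) at `max(background, body)`
  temperature, body 31 °C varied ±2 °C per subject; always above
  background + threshold by construction. Row indices increase downward
  and the floor is the bottom rows.
* **Scripts**: walking (reflective path with gait bob), sitting
  (trunk shortens over ~2 s), lying down (slow pivot to horizontal,
  3–5 s), picking an object off the floor (1.8 s stoop, hold,
  straighten), and falling (ballistic pivot about the feet,
  0.7–1.1 s, quadratic ease-in). The non-fall kinds are exactly the
  confounders that cause false alarms in deployment. The kinematic
  separation between a fall and a deliberate lie-down is speed, not
  final pose — both end horizontal on the floor.
* **Dataset**: 120 fall and 120 non-fall 24-frame windows from 10
  subjects (subject-specific size, temperature, walking speed), windows
  jittered around the scripted event, non-falls cycling through the four
  confounders. Deterministic under a seed.

What the simulator does **not** model: multi-person scenes, pets,
furniture occlusion, sensor dropouts, emissivity variation, hot
appliances, or realistic thermal texture within the body. Passing the
synthetic validation therefore shows the pipeline separates the *modeled*
kinematics (fast falls vs. slow controlled transitions, with pose and
position variation) at the sensor's resolution and noise level — not
that it would reach the same numbers in real homes.

## Numerical and problem-size choices

* Thinning/pruning act on 24×32 boolean arrays; all neighbor operations
  treat out-of-grid as background.
* Nearest-neighbor temporal linking breaks ties deterministically
  (smaller row, then column); all randomness flows from one seed per
  run.
* Occupancy-recovery and pipeline tests simulate "hours" at reduced
  frame rates (0.2–0.5 fps) with validity thresholds scaled
  accordingly; the classification study runs at the full 240-window,
  24-frame size.
* Random forests run single-threaded (`n_jobs=1`) for reproducibility.

## Known limitations

* The Zhang–Suen rules erase isolated 2×2 components; harmless here
  because cleanup removes sub-3-px components first, but a property to
  know about.
* Graph2Vec embeddings are transductive by design; inference-mode
  embedding of unseen graphs (frozen label vectors) is implemented for
  deployment but is slightly weaker than refitting.
* The compression rate of the codec is dialect-dependent; only the
  lossless round trip and the ≥40% bound on the package's own formats
  are guaranteed.
* Hourly scores assume a single occupant (the study's inclusion
  criterion); a second heat source inflates scores.
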