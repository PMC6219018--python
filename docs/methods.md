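# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind somnapose, in the spirit of a model-description appendix.

## Sensing model and conventions

Two arrays observe a supine-or-side-lying subject in bed: a 16×10
pressure array (readings in kg/cm², full scale 10) under the upper body
and an 8×8 thermal array (°C) imaging the lower body from above. One
global grid convention is used everywhere: row 0 is the head end, column
0 is the **subject's right** as seen from above, coordinates are 0-based
row-major. "Left/right" in every feature and label name refers to the
subject's side. Time is an abstract sample index; no sampling rate is
assumed, so the moving-average window is specified in samples.

## Pre-processing

Each cell is smoothed with an N-point moving average (default N = 10).
For t < N−1 the mean is taken over the t+1 available samples: the filter
is total from the first frame, at the cost of less smoothing during
warm-up. Thresholding is strict (`value > τ`); a value exactly at the
threshold is not a sensed point. The pressure threshold is absolute
(default 0.5 kg/cm², configurable). The thermal threshold is
ambient-relative — per-frame median + 2 °C — because the room baseline
drifts while the skin-ambient contrast does not; the median is a robust
ambient estimate as long as warm cells cover less than half the array
(true for legs on an 8×8 grid). Both streams are smoothed identically;
smoothing can be bypassed by setting `maf_window: 1`.

## Middle-axis localisation

Occupied projection indexes (zero-count indexes are excluded) become 2-D
points (position, count) and are clustered by fuzzy c-means with c = 3,
m = 2, per-point Euclidean distance over the (position, count) pair.
The published description of this distance sums over all points inside
one norm, which would make the objective independent of k's pairing; the
per-point form used here is the standard one that makes the objective,
distance and membership equations mutually consistent.

Implementation choices where the method description is silent:

* **Initialisation** — deterministic: c centres evenly spaced over the
  occupied index range, count coordinates taken from the nearest
  occupied point. Reproducible without a seed.
* **Stopping** — |ΔA| < ε with ε = 10⁻⁵, at most 200 iterations. The
  objective is evaluated after each membership/centre update pair, which
  makes the recorded objective trace provably non-increasing; this is
  asserted in tests on every run.
* **Singularities** — a point coincident with a centre receives
  membership 1 there (split evenly over coincident centres).
* **Middle cluster** — the median centre position of the three clusters.
  With only two occupied indexes c drops to 2 and the cluster carrying
  the larger membership-weighted count is taken as foreground (tie: the
  lower centre position); with one occupied index that index is the
  axis.
* **Ties** in maximal membership break to the lower index.
* **Mirror canonicalisation** — the lexicographically larger of the
  count vector and its reverse is clustered and the axis mapped back.
  Both orientations of a map therefore pass through one identical
  floating-point computation, making the mirror-equivariance property
  (axis a → cols−1−a) exact. Exactly palindromic projections are the
  one exception — there the lower-index tie rule wins — but they have
  effectively zero probability on noisy data.

A property of the 2-D clustering worth knowing: the middle axis is the
*max-membership* index of the middle cluster, not the projection peak.
A strict single-column count peak is an outlier in the count dimension
and can lose membership to its flanks; the axis is reliably recovered
where the projection has a small plateau around the body midline, which
is what real chest/hip contact patches produce and what the synthetic
templates emulate.

## Features and classification

The trunk middle point cuts the pressure map into four quadrants with
strict inequalities; cells on either axis belong to no quadrant (the
partition into four quadrants + on-axis cells is conserved, and this is
tested). Leg cells on the middle axis form L_MAC, so L_L + L_R + L_MAC
is exactly the thermal sensed-point total. Feature arithmetic is exact
integer arithmetic.

The classifier is a fixed decision tree whose tests are distance-weighted
k-NN votes: k = 5 and weight 1/d² (standard distance-weighted k-NN
defaults; both configurable). A zero-distance neighbour decides
outright. Distance-rank ties and score ties break to the lower exemplar
index, making the vote deterministic. Features enter the vote raw
(unscaled), matching how the two feature spaces are defined; an optional
mirror-symmetrised model (`mirror_symmetrized`) interleaves every trunk
exemplar with its mirror image, which makes label assignment exactly
equivariant under left-right mirroring of the input (up to exact
cross-class score ties, which have measure zero).

No training recordings exist for this sensor pair, so the default
reference model is built from the synthetic generator: 50 recordings per
posture at seed 20240 under default jitter, weight classes cycled. Any
labelled dataset can replace it via `build_reference_model`.

## Synthetic recordings

The generator stands in for human recordings; its defaults define the
simulated study conditions.

**Templates.** Upper-body contact is a sum of generalised-Gaussian
patches `amp·exp(−|d/s|^p/2)`: chest and hip slabs (row centres 3.5 and
12.5, symmetric about the waist row 8), a flat abdomen bridge over rows
7–9, and for lateral postures a spine-ridge plateau at the trunk column
with the shoulder/knee bulge on the facing side and a light trailing-arm
strip behind. Flat tops (p = 6) are used where an axis must be
recovered, for the plateau reason above. Prone differs from supine by
broader, lower-reaching hips (chest–hip balance negative); lateral
postures are column-mirrored pairs. Lower-body heat is ambient 24 °C
plus 9 °C on leg cells: two parallel lines (supine/prone), one straight
line on the axis (log), or a hip-column/knee-bridge/folded-shin hook
(fetus, where the designed middle axis is the knee column). Right-side
templates are exact mirrors of left-side ones.

**Weight classes.** Peak contact pressure 1.2 / 2.0 / 2.8 kg/cm² and
footprint width scale 0.9 / 1.0 / 1.1 for light (≈40 kg), medium
(≈60 kg), heavy (≈80 kg). Temperatures do not scale with weight.

**Jitter and noise.** Per recording: integer translation uniform in
±1 cell per axis (independently for the two arrays) and rotation uniform
in ±5° about the body centre, rendered by nearest-cell resampling —
sub-cell rendering is not warranted on 16×10 and 8×8 grids. Per frame:
additive Gaussian noise (0.2 kg/cm² pressure, 0.5 °C thermal) and
"ghost" activations (rate 0.005 per cell-frame) that jump a cell to a
clearly-over-threshold value for one sample. The ±5° range and the
ghost rate were fixed by requiring the stated properties of the
conditions to hold — the moving average must reject transient
activations (a ghost must appear in ≥3 of 10 frames to survive, which at
rate 0.005 is negligible), and axis localisation must tolerate the
orientation spread; beyond ±5–7° the projection of a rotated trunk
smears enough that the middle axis is genuinely ambiguous at this grid
resolution. Ground truth (label, spine column, waist row, leg axis,
contact masks) is recorded per recording, with translations applied to
the designed axes.

**What the generator does not emulate:** mattress force diffusion and
sensor cross-talk, limb-position variety within a posture class,
body-shape variation beyond the three weight classes, temporal posture
transitions, and thermal blur from sensor height. Passing tests
therefore demonstrate the pipeline's correctness and its robustness to
placement jitter and sensor noise under these conditions — not clinical
performance on real subjects.

## Deployment geometry

For a square lattice of disk sensors (radius r, pitch p = coverage
width / columns): spatial resolution = sensors / coverage area; sensing
gap = p − 2r; and the detection threshold max(A_u) is the area of the
largest circle centred in a sensing cell touching the four corner disks,
`π (p·√2/2 − r)²`, strictly increasing in p and decreasing in r. The
reference 7×7 lattice over 0.875 m × 0.875 m has p = 0.125 m; its disk
radius is not usually quoted directly and is recovered from the quoted
0.1 m gap as r = (p − gap)/2 = 0.0125 m. The widely circulated figure of
180.83 cm² for this layout reproduces exactly with π rounded to 3.14;
exact π gives 180.93 cm², and a Monte-Carlo placement oracle confirms
the closed form within 1%. The `pi_value` parameter exposes both
readings. The infrared array has no sensing gap (contiguous pixels) and
its ≈25 cm² detection threshold is an empirical constant from
shank/finger detectability experiments, stored as a constant rather than
computed.

## Evaluation

The evaluation report contains the six-label confusion matrix (plus an
`unresolved` column for partial runs), per-posture and per-weight-class
accuracies in percent, the pooled overall accuracy, and an average
accuracy defined as the **unweighted mean of the per-weight-class
accuracies** — the convention under which the published per-group values
90, 85.83 and 88.33 average to 88.05.

## Problem sizes

The test suite and the acceptance script use 600-recording evaluations
(100 per posture, 12 frames each), 300-recording axis-localisation
trials, and 3×10⁵-sample Monte-Carlo geometry checks; together they run
in well under a minute on one CPU, and the sizes give binomial standard
errors of about 1 percentage point on the reported rates.

## Known limitations

* Middle-axis recovery assumes a unimodal body footprint per projection;
  gross artefacts (a second person, large objects) violate the
  three-cluster model.
* Supine and prone are separated only by the chest–hip balance; bedding
  that equalises chest and hip contact would merge them.
* The leg stage assumes legs are the dominant warm region of the thermal
  view; uncovered arms or hot-water bottles are confounders.
* The default reference model is synthetic; deployment on real hardware
  requires recalibrating thresholds and exemplars on labelled recordings.
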