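# somnapose

Sleeping-posture recognition from two cheap bed-mounted sensor arrays: a
16×10 force-sensing-resistor (FSR) bedsheet under the upper body and an
8×8 infrared thermal array (Grid-EYE class) imaging the lower body from
above. The package recognises six postures — supine, prone, left/right
log (side-lying, straight legs) and left/right fetus (side-lying, curled
legs) — and is aimed at long-term, unobtrusive monitoring settings
(pressure-ulcer prevention, sleep studies) where camera-based or
high-density pressure-mat systems are too expensive or too invasive.

Because no public dataset pairs these two arrays, the package includes a
synthetic-recording generator that emulates the study conditions (six
postures, three body-weight classes of roughly 40/60/80 kg, position and
orientation jitter, sensor noise) with per-recording ground truth, plus
deployment-geometry analytics for comparing sensor layouts.

## Method

For each stream, every cell is smoothed with an N-point moving average
(default N = 10),

```
MAF_t = (x_t + x_{t-1} + … + x_{t-N+1}) / N ,
```

then binarised into *sensed points*: a cell is 1 iff its smoothed value
strictly exceeds the detection threshold (absolute 0.5 kg/cm² for
pressure; per-frame median + 2 °C for the thermal stream).

The binary map is projected into per-column and per-row sensed-point
counts. Each occupied index i becomes a 2-D point x_i = (position,
count), clustered by fuzzy c-means (c = 3) minimising

```
A = Σ_i Σ_k u_ik^m ‖x_i − c_k‖²,   Σ_k u_ik = 1,  m = 2,
```

with memberships `u_ik = 1 / Σ_l (d_ik/d_il)^(2/(m−1))`. The two outer
clusters are background; the index with maximal membership in the middle
(foreground) cluster is the **middle axis**. The trunk's horizontal axis
(spine column) and vertical axis (waist row) cross at the **middle
point**, which cuts the pressure map into right/left chest and hip
quadrants (C_R, C_L, H_R, H_L); the thermal map splits into right-leg,
left-leg and on-axis counts (L_R, L_L, L_MAC). Four symmetry features
follow:

```
T_D-RL = (C_R + H_R) − (C_L + H_L)     trunk right–left balance
T_D-CH = (C_R + C_L) − (H_R + H_L)     trunk chest–hip balance
L_D-RL = |L_R − L_L|                   leg asymmetry
L_MAC  = on-axis leg sensed points     leg straightness
```

A two-stage decision tree classifies them: a distance-weighted k-NN
(k = 5, weight 1/d²) on (T_D-RL, T_D-CH) selects supine / prone / left
lateral / right lateral; lateral results descend to a second k-NN on
(L_D-RL, L_MAC) separating log from fetus. A default exemplar model
built from the synthetic generator ships with the package; any labelled
recordings can replace it via `build_reference_model`.

## Worked example

```
$ somnapose simulate --out demo --n-per-class 1 --seed 3
$ somnapose classify demo/rec0002_supine_pressure.csv demo/rec0002_supine_thermal.csv
{"label": "supine", "trunk": "supine", "legs": "fetus", "partial": false,
 "trunk_scores": {"supine": 1.0}, "leg_scores": {"fetus": 1.0},
 "features": {"T_D_RL": 2, "T_D_CH": -2, "L_D_RL": 0, "L_MAC": 2}}
```

The trunk features sit at (2, −2), essentially the origin of the trunk
symmetry space, so the first stage returns *supine* and the tree stops
there (the leg-stage score is reported but unused for supine/prone).
`somnapose evaluate demo/manifest.json` scores a labelled dataset and
prints per-posture and per-weight-class accuracies, the six-label
confusion matrix, and the average accuracy (the unweighted mean over the
weight classes). Passing only one frame file yields a partial,
`"partial": true` result from the available stage alone.

Deployment geometry:

```
$ somnapose geometry
                     pressure lattice  infrared array
sensors              49                64
resolution (/m^2)    64                64
sensing gap          0.100 m           N/A
detection threshold  180.93 cm^2       25.00 cm^2
(smaller detection threshold is better)
```

Both layouts provide 64 sensing points/m², but a sparse 7×7 disk-sensor
lattice (pitch 0.125 m, sensor radius 0.0125 m) leaves a 0.1 m sensing
gap, so a body part of up to `π·(pitch·√2/2 − r)² ≈ 181 cm²` can evade
every sensor, while the contiguous-pixel infrared array's empirically
measured detection threshold is about 25 cm² — the rationale for sensing
the leg region thermally instead of with pressure sensors.

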