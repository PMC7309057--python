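# Methods

`broilervision` implements a machine-vision workflow for estimating the
floor distribution of broiler chickens in a top-view pen image: how many
birds are in the drinking zone, the feeding zone, and the rest/exercise
zone at a moment in time. Floor distribution is a welfare indicator —
lame or heat-stressed birds cluster near feeders and drinkers — and the
workflow automates a count that is otherwise done by manual inspection.

## Detection model

A pen frame is an 8-bit RGB image of light birds on darker litter. The
detection front end is threshold-based rather than learned:

1. **Non-target removal.** Pixels outside the pen's overall detection
   rectangle are blanked and excluded from all statistics.
2. **Channel-pair feature.** Each pixel maps to the quantised pair of
   its green and blue channel values (G, B). The green/blue pair
   separates white plumage from brown litter well and is cheap; the
   classical variant pairing one channel with its 3x3 neighbourhood
   mean is available as `mode="value_vs_neighborhood"`.
3. **Two-dimensional Otsu.** Over the L x L joint histogram the method
   searches the threshold pair (t1, t2) maximising the between-class
   scatter `P_fg * ||mu_fg - mu||^2 + P_bg * ||mu_bg - mu||^2`, where
   the foreground class is the quadrant `{f1 > t1 and f2 > t2}` and the
   background class is its complement. The search is vectorised with
   2-D suffix sums (O(L^2)); ties break toward the smallest (t1, t2).
   A brute-force search over all pairs serves as the test oracle.
   Foreground polarity is auto-selected: of the two classes, the one
   whose mean feature lies farther from the median pen feature becomes
   foreground (white birds on dark litter or the inverse both work).
4. **Morphological cleanup.** Erosion with a disc structuring element
   (radius 1 by default; radius 1 is the 4-neighbourhood cross) cuts
   thin bridges, then connected components smaller than `min_area`
   pixels are dropped. The default `min_area` is 30 px at 1440x1080
   and scales with image area. Regions are 8-connected components in
   deterministic (ymin, xmin) order.

K-means (Lloyd's, with an emptied cluster re-seeded from the farthest
pixel) and fuzzy c-means (fuzzifier m = 2, maximum-membership
defuzzification, zero-distance pixels get full membership) operate on
per-pixel RGB vectors as comparison baselines; both are seeded and
deterministic, and both use the same foreground-polarity rule. Their
initial centres are drawn from distinct pixel colours, because duplicate
initial centres stall the alternating updates on flat backgrounds. A
timing harness reports wall-clock per method; timings are informational
only and never asserted, since they measure the host machine.

## Counting model

Birds touch and merge into blobs, so region count != bird count. The
counting model is area-based:

* **Reference area.** For each rearing day d, the mean pixel area `s`
  of manually (here: synthetically) selected single-bird profiles.
  Per-day recalibration removes growth bias: birds roughly triple
  their silhouette between day 18 and day 35.
* **Normalisation.** A region of area `s_i` becomes
  `s_bar_i = s_i / s` (dimensionless; ~k for k merged birds).
* **BP network.** A 1-input feedforward regression network (one hidden
  layer of 10 sigmoid units by default, linear output) maps `s_bar_i`
  to a bird count, rounded half-away-from-zero and clamped to >= 1 for
  any region that survived the area filter. The plain rounding rule
  `round(s_i / s)` is the fallback and the test oracle. The network
  earns its keep on merged blobs: two touching birds cover less than
  twice a single silhouette, and the network absorbs that bias where
  plain rounding cannot.

Training splits the (normalised area, count) pairs 0.70 / 0.15 / 0.15
into train / validation / test by a seeded shuffle and minimises the
squared error with a damped Gauss-Newton (Levenberg-Marquardt) loop,
written out in numpy so that training is bit-reproducible under a fixed
seed (iterative optimisers behind compiled wrappers were observed to
differ across processes at the last-ulp level, which cascades).
Early stopping monitors the validation error with patience 20; at most
500 iterations; the best-validation weights are restored. Five seeded
restarts are run and the restart with the lowest validation error wins —
small sigmoid networks occasionally stall in a smooth local optimum
(fitting the identity instead of a staircase), and best-of-k restarts
is the standard remedy. Models serialise to JSON (architecture,
weights, input scale, training metadata).

Fit quality is reported as R = 1 - SS_res / SS_tot (the
coefficient-of-determination form; an ordinary Pearson correlation is
exposed separately as `pearson_r`), MSE, and a *relative* MAE,
`(1/n) * sum |y_i - yhat_i| / y_i` — the relative form is deliberate
and is undefined when any true count is zero.

## Zones and the occupancy rule

The floor is divided into three virtual zones (all in pixel
coordinates, origin top-left): a drinking rectangle centred on the
nipple-drinker water line whose width is one body length of a
three-week-old broiler; a feeding disc centred on the tube feeder with
radius = feeder radius + one body length; rest/exercise is everything
else inside the pen. The geometry is static across days (it is
calibrated to the three-week body length) and validation rejects
overlapping or out-of-pen zones.

A *single-bird* region is assigned to a zone only when strictly more
than 50% of its pixels fall inside that zone; a tie goes to rest.
Fractions are exact pixel counts, not bounding-box approximations.

For a *multi-bird* region the strict body-majority rule has no natural
reading — the merged blob is not one body. Assigning the whole count to
the blob's majority zone was implemented first and measured: whenever a
touching pair straddles a zone boundary with its two birds on opposite
sides, the all-to-one rule mis-attributes one bird with certainty, and
with about one touching pair per 19-bird frame this alone caps per-zone
frame exactness near 95%. Multi-bird regions therefore apportion their
count over zones proportionally to the region's zone pixel fractions
(largest-remainder rounding; remainder ties resolve conservatively to
rest, then drinking, then feeding), which is the consistent estimator
of how many of the merged birds stand in each zone. Ground-truth
labels always use the per-bird strict rule.

Per-frame counts are summed into `(D_num, F_num, rest, total)` with
`rest = total - D_num - F_num`; a counting overshoot (negative rest) is
clamped to zero and flagged rather than silently accepted.

## Evaluation

Detection over an evaluation set is tallied per zone: true count
`T_truenum`, detected count `T_num`, missed detections `T_miss` broken
down by cause (crowding / occlusion / others), and false detections
`T_false`. The reported rates are
`R_accuracy = T_num / T_truenum`, `R_miss = T_miss / T_truenum`,
`R_false = T_false / T_truenum`, rounded half-away-from-zero to 4
decimals (raw ratios retained). The bookkeeping identity
`T_num = T_truenum - T_miss + T_false` is enforced on every synthetic
run. On synthetic scenes, miss causes are derived from ground truth:
misses are attributed first to birds more than half hidden by an
occluder, then to birds flagged as crowded, then to "others".

## Synthetic scenes

The generator renders what the camera sees at desk scale and carries
exact ground truth, so every stage is testable without field imagery.

* **Canvas** 480 x 360 by default (same 4:3 aspect as the 1440 x 1080
  capture, 1/9 the pixels, chosen to keep a 200-frame evaluation fast);
  pen, drinking and feeding zones laid out proportionally, calibration
  body length 30 px at this scale.
* **Birds** are filled ellipses with axis ratio 1.6 and area drawn
  around a per-day mean growing linearly from 300 px (d18) to 900 px
  (d35) with 6% relative spread — broilers of one age are fairly
  uniform. Default flock 19 (21 stocked minus two sampled for health
  checks). Bird colour (235, 230, 222), litter (120, 96, 70), additive
  Gaussian pixel noise sd 8 on the 8-bit scale.
* **Crowding** places a configurable fraction of birds in touching
  clusters of 2-3, each newcomer attached to a cluster member at
  just-touching distance along its boundary (support-radius contact
  with a slight overlap), so merged blobs look like real huddles
  rather than stacked silhouettes.
* **Occluders** (water line, feeder chain) are thick polylines drawn
  over the birds; each bird records its occluded fraction.
* **Wing spread** inflates a bird's area by 1.8 with a configurable
  probability (off by default — it is a failure-mode knob, like
  occluders and crowding).
* Same seed, same config: bit-identical image and ground truth.

Training pairs for the counting network are unions of 1-4 rasterised
ellipses built with the same touching rule plus a 2% area jitter for
segmentation boundary noise.

What the generator does *not* emulate: plumage texture, shadows,
lighting flicker, dust, posture. Passing synthetic tests therefore
demonstrates the correctness and internal consistency of the pipeline
under its stated noise model, not field performance on commercial-house
imagery.

## Numerical choices and degenerate inputs

* All counts round half-away-from-zero (2.5 -> 3), documented to avoid
  banker's-rounding surprises at .5 boundaries.
* 2-D Otsu of a single-bin histogram returns that bin with objective 0
  and a degenerate flag; an empty histogram is an error.
* Quantisation maps an 8-bit value v to bin `v * levels // 256`.
* `fit_metrics` refuses zero variance in y (R undefined) and any
  `y_i = 0` (relative MAE undefined); `detection_metrics` refuses
  `T_truenum = 0`.
* Bird placement uses rejection sampling bounded at 1000 retries per
  bird; failure raises a placement error rather than looping.

## Problem sizes

The test suite and worked examples run at desk scale: 480 x 360 scenes,
50 noiseless scenes for pixel-exactness, 200 noisy frames for the
end-to-end distribution check, 1000 training pairs for the counting
network, and 200 random histograms (<= 16 levels) for the Otsu oracle
check. These sizes make the full suite run in well under a minute per
module while leaving the statistical conclusions stable.

## Known limitations

* The zone-apportionment rule for merged regions assumes the birds of a
  blob distribute like its pixels; a blob of many birds concentrated on
  one side of a boundary can still be mis-split.
* A bird more than half hidden by equipment is unrecoverable by design
  (the remnant is filtered or miscounted); multiple cameras, not
  software, are the fix.
* Per-day reference areas assume the day is known per frame.
* The published feeding-row accuracy and false rates are internally
  inconsistent with their own tallies (785/823 = 0.9538 vs printed
  0.9544; 3/823 = 0.0036 vs printed 0.0037); the package computes the
  formula values and the evaluation report documents the raw ratios
  alongside the rounded ones.
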