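# Methods

This note documents the models, conventions, and numerical choices behind
`copalign`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Coordinate frames and conventions

All positions are millimetres, forces Newtons, moments N·mm, pressures kPa.
The global frame has Z up with the walking surface at Z = 0. The per-frame
shoe frame is built from the HEEL, MT1 and MT5 markers: Y is the unit
vector from the heel toward the MT1/MT5 midpoint (anterio-posterior, AP),
Z the unit normal of the marker plane, X = Y x Z (medio-lateral, ML), and
the origin is the heel marker with its Z coordinate forced to zero — COP is
planar data, so the shoe frame is anchored to the ground plane. All AP/ML
error reporting uses these axes. Degenerate marker geometry (collinear or
coincident markers, relative tolerance 1e-8) flags the frame invalid rather
than interpolating; occluded frames are likewise flagged, never filled.

Shoe-frame COP is the inverse pose applied to the global COP with the Z
component dropped. This projection is exact while the shoe sole lies in the
ground plane; when marker noise or genuine foot tilt rotates the marker
plane, the projection introduces sub-0.01 mm apparent displacement per
degree-scale tilt — a real property of the construction, shared by any
planar treatment of COP, and visible in the round-trip tests.

## Signal conditioning and gating

Force-platform streams are low-pass filtered with a 2nd-order Butterworth
at 15 Hz cut-off applied forward and backward (zero phase lag, squared
magnitude response), then decimated from 960 Hz to 60 Hz by sample picking
— the 15 Hz filter already provides the anti-alias attenuation. Streams
that arrive at 60 Hz are taken as conditioned. Frames with vertical force
below 20 N count as off-ground; exactly 20 N is contact. Off-ground frames
are excluded from every fit and every metric. Platform COP comes from the
standard moment balance about the plate origin, resolved on the walking
surface.

Streams are aligned by sample index from a shared trigger sample recorded
in each file header, emulating hardware TTL synchronization; no
resampling-based alignment is attempted, and a trial whose streams disagree
on trial id or trigger is rejected at read time.

## The RIGID estimator

Insole-frame COP and shoe-frame COP at jointly valid frames form
corresponding planar point clouds. The estimator minimizes
`sum_i ||R(theta) p_i + d - q_i||^2` via SVD of the centered 2x2
cross-covariance, with the determinant sign corrected so only proper
rotations are returned. The fit is deliberately restricted to the plane:
both clouds are planar, so the out-of-plane components of a general 3-D
rigid fit are unidentifiable; on planar data the restricted solution
coincides with the general one. Frames are equally weighted (no
force-magnitude weighting). At least 3 jointly valid pairs and nonzero
source spread are required. The brute-force oracle in the test suite
(exhaustive 0.01-degree rotation grid with closed-form translation)
confirms the SVD solution attains the global optimum.

## Feature sets and the network mapping

Sensor pressures are converted to forces (pressure x area) and divided by
half the participant's body *weight* (0.5 m g, g = 9.81 m/s^2), making
force features dimensionless; the normalizer is stated in some sources as
half the body mass, but dividing a force by a mass would leave units
dangling, and weight normalization is the standard convention. A sensor is
active when its pressure is strictly positive; active ratios divide by the
subset size (99 globally, the region size regionally).

The eight insole regions are lateral/medial heel, two midfoot areas, three
forefoot areas (medial/central/lateral thirds) and the toes. The cited
regional scheme publishes no boundary numbers, so the default partition
cuts at 30% (heel/midfoot), 60% (midfoot/forefoot) and 85%
(forefoot/toes) of insole length, splitting heel and midfoot at the insole
midline. The partition lives in an editable `sensor,region` table so exact
boundaries can be substituted without code changes.

PCA for MFNN1 is mean-centered without variance scaling (all inputs share
units after normalization), fitted on the training fold only and frozen;
the retained dimension is the smallest k whose cumulative explained
variance exceeds 0.90. It is fitted per participant-foot per training
fold, consistent with every mapping being estimated separately per foot.

The network has one sigmoid hidden layer and a linear 2-output layer
(targets are unbounded mm coordinates). Inputs and targets are
standardized with training-fold statistics; constant columns pass through
with unit scale. Training uses scikit-learn's MLPRegressor with L-BFGS,
L2 penalty `alpha = 1e-4` and `max_iter = 300`; L-BFGS is deterministic
given the seed and converges reliably on these small dense problems, and
the L2 penalty provides the capacity control that iteration-level early
stopping would otherwise supply (solver, iteration budget and penalty are
exposed as keyword configuration). Hidden sizes 3–20 are evaluated on a
seeded 80/20 split of the training fold; the mapper with the lowest
validation RMS error (ties to the smallest size) is returned as trained on
the 80% slice. Sizes whose parameter count exceeds the available rows are
skipped; training requires at least max(50, parameter count) rows.

## Evaluation protocol

Two-fold cross-validation at the participant level: fold 1 trains on
replication 1 of LL_GROUND and LL_KNUCKLE and tests on replication 2 of all
four tasks; fold 2 swaps replications. Per test trial and axis the report
lists RMSE, peak absolute error and r^2 over contact-gated, jointly valid
frames (gate first, then compute). r^2 is the squared Pearson correlation,
in [0, 1] and blind to sign; `1 - SS_res/SS_tot` is available as an option
but not the default. Zero-variance series report r^2 as missing. Summaries
are means with 95% t-interval half-widths per (task, method, axis); no
transformation is applied to the metrics. Every fold records the exact
(trial id, frame) sets used for training and testing, and
`CrossValidationResult.train_test_disjoint()` audits their disjointness.

## The synthetic generator

The generator emulates one foot of a manual-material-handling trial:

* **Motion**: a smooth planar shoe pose — yaw about the heel plus in-plane
  translation (sway for symmetric lifts, large yaw excursions for the
  asymmetric lift, fore-aft sweep for push/pull) — and a smooth insole COP
  path with task-specific amplitudes and rates, with per-trial random
  phases. Poses are planar by design: a planar pose keeps the shoe plane
  in the walking surface, which makes the generated platform COP, marker
  streams and insole pressures *exactly* mutually consistent, so that with
  zero noise and zero deformation the rigid fit must recover the true
  transform to machine precision. This exactness is the generator's core
  contract and the anchor for every downstream tolerance.
* **Load**: a vertical-force profile around half body weight (default
  body mass 76.1 kg) with a raised-cosine ramp at each trial end, so every
  trial crosses the 20 N contact gate in both directions. Pressures form
  an isotropic squared-exponential bump (width 25 mm) centred on the COP
  path, truncated at a 0.5 kPa device floor and rescaled so the summed
  sensor force equals the platform's vertical force exactly. A small
  oscillating shear (3% of vertical) exercises the full moment balance.
* **Deformation** (`bending`, default): the apparent COP shifts by
  `delta x (anterior - posterior load share)` along AP and
  `0.5 delta x (medial - lateral load share)` along ML, computed from the
  eight-region partition. It vanishes for balanced loading and scales
  linearly in `delta`. The ML term reflects that turning and rolling foot
  movements deform a pliant insole medio-laterally as well as in flexion;
  an `ap_only` model tag is available. The displacement acts on the
  insole-to-shoe mapping, not on the markers: the insole deforms under
  load while the marker-defined shoe frame stays rigid.
* **Noise defaults**: 0.3 mm marker noise, 1.0 mm platform-COP noise and
  2 kPa pressure noise with a noise-floor threshold at 2 sigma — levels
  typical of optical capture, platform COP accuracy, and capacitive
  insoles. The platform stream is emitted at 60 Hz (already conditioned)
  by default; `plate_rate_hz = 960` emits raw-rate data through the
  filter-and-decimate path.

What the generator does **not** emulate: foot tilt and heel rise (poses are
planar), hysteresis and creep of capacitive sensors, spatially correlated
pressure noise, marker soft-tissue artefact, subject-specific foot shapes,
or between-participant variability. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and the
*mechanism* by which regional-loading features beat a rigid transform under
insole deformation — not the error magnitudes to expect on human data.

## Problem sizes

Default trials are 8 s at 60 Hz (480 frames, ~400 of them in contact); the
cross-validated comparison uses one participant-foot, two replications of
four tasks, and ten seeded replicates, which keeps the full comparison
under a minute on one CPU while leaving the per-fold training set (~800
frames) comfortably above the largest network's parameter count.

## Known limitations

* The rigid fit is planar by construction; recordings with substantial
  out-of-plane marker motion violate the planarity assumption upstream of
  the fit, not inside it.
* The `MFNN1` pipeline requires carrying the training-fold PCA model
  alongside the mapper; the CLI serializes both.
* r^2 as squared correlation rewards any linear association, including an
  inverted one; use the `ss` variant when calibration matters.
* C3D marker files are not read; marker data arrive as delimited text.
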