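# axokin

Suction-feeding kinematics and ontogenetic scaling for the axolotl
(*Ambystoma mexicanum*) — a tested pipeline from 2-D landmark trajectories
of feeding bouts to the 25 standard kinematic variables, through allometric
scaling against geometric-similarity predictions, to the mixed-model
stage/size ANCOVA workflow.  A forward simulator of feeding bouts with
closed-form ground truth stands in for high-speed video, so every stage of
the pipeline is validated by parameter recovery.

## The problem

Axolotls are paedomorphic: adults keep the larval body plan (external
gills, tail fin, suction feeding) and differ from larvae mainly in size.
That makes an ontogenetic series of larvae, juveniles and adults a natural
experiment for separating the effects of **size** from those of
**developmental stage** on prey-capture movements.  The raw data are
lateral-view pose-tracking tables (DeepLabCut-style CSV: three header rows,
then x, y, likelihood per frame) for seven head landmarks — eye (`e`),
upper- and lower-jaw tips (`uj`, `lj`), mouth corner / jaw joint (`am`),
anterior and posterior hyoid points (`hd1`, `hd2`), shoulder (`sh`) —
filmed at 1000 frames/s and calibrated with a 0.5 cm checkerboard.

The pipeline:

1. **Kinematics** — smooth each coordinate with a cubic smoothing spline at
   80 effective degrees of freedom (the trace of the smoother matrix, as in
   R's `smooth.spline`), compute gape distance `d(uj, lj)`, jaw and head
   angles by the law of cosines, hyoid depression as the distance of each
   hyoid point to the jaw joint minus its pre-bout baseline, and speeds and
   accelerations by repeated first differences.  Event detection
   (mouth-opening onset, peak gape, closure, hyoid depression and return)
   uses threshold crossings of each excursion, and 25 variables per bout
   are extracted (MG, TMG, MGA, DG, MSGO, MAGO, ..., PCD).
2. **Scaling** — per-individual peak performance (largest gape, fastest
   opening; shortest time for timing/duration variables) is regressed on
   snout–vent length (SVL) on log10–log10 axes.  Under Hill's
   geometric-similarity model, lengths scale as L¹, angles and speeds
   as L⁰, durations as L¹ and accelerations as L⁻¹; a variable is
   classified *positive* / *negative* allometry when the predicted exponent
   falls below / above the slope's 95% CI, isometry otherwise.
3. **Stage statistics** — linear mixed models `log10(y) ~ log10(SVL) *
   stage + (1 | individual)` with Satterthwaite type-II F tests: a size
   ANOVA across stages, an interaction screen that splits the 25 variables
   by the significance of the size-by-stage term, additive ANCOVAs for the
   no-interaction set, pairwise-stage ANCOVAs (larva–adult,
   juvenile–adult, larva–juvenile, immature–adult) for the rest, and
   Tukey-adjusted estimated-marginal-mean contrasts.

## Worked example

Run the numbered analysis scripts from the repository root:

```bash
python analysis/01_simulate_cohort.py     # 25 animals, 103 bouts -> results/cohort/
python analysis/02_extract_kinematics.py  # -> results/kinematics.csv
python analysis/03_scaling_allometry.py   # -> results/scaling_table.csv
python analysis/04_stage_ancova.py        # -> results/ancova/
```

The first script simulates the study-shaped cohort (16 larvae, 4
juveniles, 5 adults; adults three times larger on average, larvae and
juveniles overlapping in size) and exports it in the pose-tracker CSV
dialect.  The second runs every bout through the full extraction pipeline
and reports recovery against the simulator's expected measurements, e.g.:

```
extracted 103 bouts -> results/kinematics.csv
  MG    worst deviation from expected: 1.61 %
  TMG   worst deviation from expected: 4.00 frames
```

(at the default 0.3-pixel tracking noise; with noise off the worst timing
deviation is 2 frames).  The scaling script prints the classified table —
with this synthetic cohort the maximum gape scales isometrically
(slope 0.94, CI 0.80–1.09, prediction 1) while speeds and accelerations
show positive allometry — and the ANCOVA script reproduces the inference
cascade:

```
size ANOVA: F=30.14, p=5e-07
  L-J: t=-0.33, adjusted p=1
  L-A: t=-7.64, adjusted p=3.75e-07
size significant (no-interaction set): ['MG', 'MSGO', 'Mhd1', 'Mhd2', ...]
```

i.e. stages differ in size except larvae vs juveniles, and size (not
stage) drives most magnitude variables — the structure the method is
designed to resolve.  The same workflow runs from a shell via the `axokin`
CLI (`simulate`, `extract`, `scale`, `ancova` subcommands).

The stage-specific slope shifts (adult speed and acceleration slopes
three- to seven-fold steeper than immature ones) are exercised through the
record-tier simulator (`axokin.synthetic_data.sample_records`), whose
per-variable laws impose them directly; see the interaction-screen tests.

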