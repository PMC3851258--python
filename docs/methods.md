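# Methods

## Data model and preprocessing

A plate experiment is a set of wells, each measured at T time points
(default 18 at 10-minute spacing) under every treatment.  Wells carry
one of three roles: *promoter* (a promoter–reporter fusion strain whose
fluorescence tracks promoter activity), *promoterless* (reporter
plasmid without a promoter; measures cellular autofluorescence) and
*empty* (no cells; instrument noise only).  Treatments are labelled
with numeric concentrations; exactly one has concentration 0 and is the
control.

The correction pipeline runs in a fixed order:

1. **OD normalization** divides each non-empty well by its pre-treatment
   optical density, converting fluorescence to per-cell activity.
2. **Smoothing** applies a centered moving average (window 3, odd).  The
   window shrinks at the series ends so the output keeps T points; this
   keeps time-point-one alignment (step 4) well defined.  The
   alternative — dropping to T−2 points — loses the first time point
   the alignment step needs.
3. **Background subtraction** pools all promoterless wells over all
   treatments into a single mean per time point and subtracts it from
   every promoter and empty well.  Pooling assumes autofluorescence is
   treatment-independent over the assay's 3 hours.  The pooled sample
   standard deviation of the processed promoterless values (one scalar)
   becomes the noise floor scale.
4. **Baseline alignment**: per gene, the first-time-point values of all
   treatments are averaged; each treatment's whole series is shifted so
   its first value equals that mean.  Shifting *all* points (not only
   the later ones) is equivalent at t ≥ 2 and additionally makes the
   first-time-point values exactly equal — a testable invariant.
5. **Noise floor** zeroes every value strictly below `2 × sd`
   (multiplier configurable).  The comparison is on the signed value —
   negatives left by background subtraction are zeroed — and ties at
   the threshold are kept; the step is idempotent.

Replicate promoter wells of the same gene are carried individually
through steps 1–4 (each well divided by its own OD, aligned across
treatments) and averaged into one gene row before the noise floor.
Activity scoring (below) still sees the individual wells.

## DE detection

**Type I (activity within a treatment).**  Each promoter well's series
is scored by a marginal log-likelihood ratio: a zero-mean Gaussian
process over the mean-centered series with kernel
`amplitude · RBF(lengthscale) + white noise`, hyperparameters optimized
by L-BFGS (optionally with restarts), against a null of constant mean
plus iid noise with both parameters at their MLE.  The lengthscale is
bounded below by twice the sampling interval: promoter-activity
kinetics are slower than the 10-minute sampling, so the smooth
component is not allowed to chase point-to-point noise.  Centering
makes the score invariant to additive shifts; an exactly constant
series scores 0.  On pure white noise the score averages well under 1
nat (the dynamic model has two extra hyperparameters), while smooth
signals at 5× the noise sd score an order of magnitude higher.

Empty wells run through the same preprocessing and the same scorer;
within each treatment their maximum score is the detection cutoff.  A
gene is active if, in at least one treatment, its score (maximum over
replicate wells) strictly exceeds that treatment's cutoff; ties are
excluded as a conservative choice.

**Type II (between treatments).**  Per gene, a least-squares linear
trend is fitted to the control and to each treated series; the gene
qualifies if the fitted values differ by ≥ 1.5-fold (either direction)
at one or more time points for at least one treated concentration.
Fitted rather than raw values damp single-point outliers; fitted values
are clipped at zero and a pseudocount (default `2 × promoterless sd`)
stabilizes ratios near the noise floor.

The DE panel is the union of the two screens.

## Network reconstruction

Per treatment, the N-gene panel follows a latent linear dynamical
system

    x_{t+1} = A x_t + w_t,   w_t ~ N(0, Q)
    y_t     = C x_t + v_t,   v_t ~ N(0, diag(R))

with hidden dimension k < min(N, T).  Gene rows are mean-centered
before fitting, so the dynamics describe fluctuations about resting
levels and the connectivity readout is not biased by baseline
expression.  EM uses the Kalman filter and Rauch–Tung–Striebel smoother
(with the lag-one covariance recursion) for the E-step and the standard
closed-form M-step; the log-likelihood is non-decreasing to numerical
tolerance.  Covariances are symmetrized each step, the filter uses the
Joseph form, and Q/R carry small relative floors (1e-9 / 1e-10 of the
data scale) for positive definiteness.

k is chosen as the smallest number of principal components explaining
90% of the control panel's variance, and the same k is used for all
treatments so the four networks are directly comparable.

**Connectivity.**  The fitted model induces a one-step gene-level map
`D = C A C⁺` (Moore–Penrose pseudoinverse).  Entry (i, j) is reported
as the signed confidence of the directed edge gene_i → gene_j; the
row/column orientation of the pair is a labelling convention, applied
identically in the simulator's ground truth, with no effect on any
derived quantity.  Self-edges (diagonal) are retained.  All N² entries
are ranked by absolute value (ties broken lexicographically by gene
pair for determinism) and the top 4N edges form the network, following
the empirical rule that curated interaction networks rarely exceed four
edges per node.

**Ensemble confidence.**  With T = 18 a single EM fit's connectivity is
estimation-noise dominated, and differential comparisons between
independently fitted networks would largely measure that noise.  The
pipeline therefore (a) draws one set of starting parameters from the
PCA of the pooled, per-treatment-centered data and reuses it — plus the
same jittered variants — for every treatment, and (b) averages D over
an ensemble of short EM runs (defaults: 5 starts × 10 iterations).
Sharing the start set correlates the estimation errors of the four
networks so they cancel in the control-versus-treatment comparison;
averaging over starts shrinks couplings that are unstable across
restarts, which is also the classical reading of "confidence" in
restart-based network reconstruction.  Longer EM runs (the library
default for a standalone fit is 100 iterations with best-of-restarts)
raise each network's likelihood but decorrelate the errors and were
observed to degrade differential-edge recovery; the short-run ensemble
is a deliberate bias–variance trade.

## Differential networks and pathway scoring

An edge's identity is its ordered (source, target) pair.  Sign is
ignored for presence by default — a stimulatory→inhibitive flip is not
a differential edge — matching a definition of gained/lost purely by
presence; `sign_sensitive=True` counts flips as one lost plus one
gained.  Gained = treatment \ control; lost = control \ treatment.
Because both networks are cut to exactly 4N edges, |lost| = |gained|,
and summaries report this changed-position count as a percentage of the
4N selected edges.

Per gene g and treatment, with incident edges counted once for
self-edges:

    pct_change(g) = (n_gained + n_lost) / (n_control + n_treatment)

The denominator counts g's incident edges in both networks (edges
present in both count twice), the only reading under which complete
turnover gives exactly 1.0; a gene disconnected in both networks scores
0.  Genes with ≥ 4 differential edges in at least one treatment are
retained for pathway analysis.

A pathway's perturbation degree at a concentration is the arithmetic
mean of `pct_change` over its retained member genes (genes may belong
to several pathways).  A pathway is concentration-responsive when its
high-concentration degree strictly exceeds both the mid and the low
degrees — ties fail.  The toxicity threshold is the largest tested
concentration c such that every responsive pathway has degree ≤ ε at
all tested concentrations up to c; ε defaults to 0 (degrees on noisy
data are rarely exactly zero, so ε is configurable), the result is
"below lowest tested" when the lowest dose is already perturbed, and
the highest tested concentration when no pathway responds.

## Synthetic data

The generator emulates the plate design end to end with known truth:

- **Network.**  A directed, signed network over the active genes at
  density 0.1; weights are uniform ±[0.3, 0.6].  Per exposure
  concentration a fraction of edges (defaults 0.1 / 0.2 / 0.4 for
  10 / 100 / 1000 mg/L, non-decreasing by construction) is rewired —
  removed and replaced by random new pairs; these are the true
  lost/gained edges.
- **Dynamics.**  First-order vector autoregression under the
  treatment's weight matrix (spectral radius rescaled to 0.95), driven
  by unit-sd innovations, on top of a resting activity baseline of 8
  units; 80% of genes are active, the rest are flat.  The innovation
  sequence is drawn once and shared across treatments — a paired
  design, as when one master culture per strain is split across the
  treatment plates — so treatments differ through the network, not
  through independent stochastic histories.  Measurement noise
  (sd 0.1, i.e. a tenth of the signal scale) is independent per
  treatment.
- **Plate layer.**  Per-well OD uniform on [0.3, 0.9]; a shared
  autofluorescence background (level 2.0) with a slow random walk
  (sd 0.05); promoter wells read `od · (activity + background) + noise`,
  promoterless wells `od · background + noise`, empty wells tiny
  instrument noise (sd 0.01); defaults include 4 promoterless and 6
  empty wells.

What the generator does *not* emulate: growth during the assay (OD is a
single pre-treatment scalar), GFP maturation kinetics, plate-position
effects, and treatment-dependent autofluorescence.  Passing tests on
this generator therefore show that the pipeline recovers
network-rewiring signal under its own structural assumptions
(first-order linear dynamics, shared background, paired cultures); they
do not certify performance on data violating them.

## Numerical and design choices

- All randomness flows from one master seed through named per-stage
  `SeedSequence` streams; reruns are byte-identical.
- End-to-end recovery is assessed against the 3-point-smoothed
  noise-free trajectory: smoothing is a deterministic pipeline step,
  and autoregressive trajectories are rough at the sampling interval,
  so no smoothing method can match the unsmoothed signal exactly.
- Degenerate inputs: constant series score 0 in the GP screen;
  rank-deficient C falls back to a tolerance pseudoinverse;
  `max_iter=0` returns the EM initialization with a one-point
  likelihood trace; a request for more than N² top edges returns all
  edges.
- Desk-scale defaults keep the full pipeline around 1.5 s per simulated
  30-gene experiment; the test suite's simulation studies use 8–20
  seeds per property at that scale.

## Limitations

- With 18 time points the connectivity estimate is strongly
  regularized; edge-level precision is well above chance but far from
  certain, and individual differential edges should be read as
  hypotheses, not calls.
- The concentration-response criterion and threshold rule are
  deliberately simple (strict inequalities over three doses, no
  replication model); with replicated designs a regression-based
  point-of-departure would be preferable and is out of scope here.
- No statistical significance is attached to differential edges or
  pathway degrees; the design has no replicates to estimate their
  sampling variability from.
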