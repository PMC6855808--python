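# Methods

This note documents the models implemented in `lipidmod`, the assumptions
behind them, the defaults of the synthetic-data generators, and the
numerical choices that matter when reproducing results.

## Binomial equal-site model of native-MS lipid binding

Native MS of the intact pentamer resolves the apo channel and the series of
lipid-bound species separated by one lipid mass (~750 Da). With peak
heights `I_n` for the n-bound species at one lipid concentration, the
average number of bound lipids is the intensity-weighted mean
`sum(n I_n) / sum(I_n)`. The binding model assumes N independent,
equivalent sites with dissociation constant K: per-site occupancy at free
lipid concentration [A] is `p = [A]/([A] + K)` and the mole fraction of the
q-bound species is the binomial `C(N, q) p^q (1-p)^(N-q)`, with mean `N p`.

Assumptions and caveats:

* Equivalent, independent sites is a deliberate oversimplification; it is
  adequate for the peak-height histograms and for *relative* affinity
  comparisons across lipid species or channel variants, which is how the
  results should be read.
* Peak heights are treated as proportional to species abundance (no
  response-factor correction); upstream deconvolution is trusted, with
  an optional restriction to charge states <= 26+ because higher charge
  states strip bound lipid electrostatically.
* The free concentration is approximated by the total lipid concentration
  (protein at 1 uM binds a few uM of lipid at most).

Fitting: both observed and predicted histograms are expressed as
per-concentration mole fractions and compared jointly across the series
with equal weight per concentration. Exactly one parameter is free —
either K (continuous, with N fixed) or N (integer grid 1..64, with K
fixed), mirroring the two scientific questions (affinity comparison across
lipids at fixed stoichiometry; site loss in mutants at fixed affinity).
The K search brackets the optimum on a coarse logarithmic grid before
refining, because the sum of squared residuals is flat for K far below the
measured concentration range and a bare 1-D minimiser can stall there. An
approximate standard error for K is derived from the curvature of the SSR
profile at the optimum.

## Hill model of thermal stabilization and the coupling to binding

The stabilizing effect of a lipid is the pentamer peak height after
heating with lipid divided by the heated no-lipid control, so the baseline
is exactly 1 and is held fixed. The effect versus concentration is fitted
as `E(c) = 1 + (E_max - 1) c^n / (c^n + EC50^n)` with EC50, n and E_max
free. E_max is floated rather than fixed because the assay saturates
within the measured range and the data determine it.

Because binding (native MS) and stability were measured under identical
conditions, concentration can be eliminated between the two curves to
express the *fractional* effect (fraction of the maximal stabilization
above baseline) as a function of the average number of bound lipids.
Binding does not saturate over the measurable range (<= 36 uM), so the
binding curve must be extrapolated: the default continues it linearly
through the origin and the last measured point. A saturating binomial
curve with N = 32 can never reach 32 bound lipids at finite concentration,
so linear continuation is the only extrapolation under which the "effect
of a full annulus" question is well-posed; queries beyond the measured
range under `extrapolation="model"` therefore raise rather than
extrapolate silently. With the measured anchor of 2.9 bound at 12 uM,
32 bound lipids map to ~132 uM and ~83% of the maximal effect.

## Boundary-lipid enrichment and polar density maps

A lipid is a boundary (annular) lipid in a frame when the minimum distance
between any of its beads and any transmembrane-domain (TMD) protein bead
is <= 6 Å, inclusive, under minimum-image periodic boundary conditions in
x,y (and z only when the box is flagged fully periodic). All lipid beads
are tested, not only headgroups. Enrichment of species i is

    B_i = < (b_i / b_tot) / x_i > - 1

averaged over frames, where x_i is the species' mole fraction over the
*full* lipid census of the same frame. B > 0 means enrichment; the
opposite sign convention appears in one place in the source literature and
was rejected as inconsistent with p's use elsewhere. Frames with no
boundary lipids at all are excluded from the average with a warning rather
than counted as zero. By construction `sum_i x_i B_i = 0` in every frame,
which the tests assert exactly.

Leaflets are assigned per frame by phosphate-bead z relative to the
instantaneous median phosphate z. Polar density maps bin phosphate beads
of one species and leaflet by radius (4 Å bins to 40 Å) and angle (pi/15)
around the TMD centre of mass projected onto the membrane plane; values
are per-bin area densities averaged over the frame window (default: the
last half of the frames supplied). Integrating density over bin areas
recovers the mean in-range bead count per frame exactly.

## Stopped-flow flux kinetics

Each quench trace is fitted to a stretched exponential
`F(t) = F_inf + (F0 - F_inf) exp(-(t/tau)^beta)` with tau > 0 and beta in
(0, 1]; beta > 1 (compressed exponential) is unphysical for heterogeneous
liposome populations and is excluded by the bound. The influx rate is the
instantaneous relaxation rate evaluated at 2 ms,
`k = (beta/tau)(t/tau)^(beta-1)`; 2 ms is the conventional evaluation
point and is exposed as a flag.

Two guards replace visual trace inspection:

* No-flux gate. A trace is flagged (rate 0) when the head-minus-tail mean
  difference is indistinguishable from the sampling error of the
  first-difference noise estimate (3 SE by default), or when the fitted
  curve explains less quench over the recorded window than 3x the noise.
  Without this gate, near-flat noise traces pass a naive amplitude check
  (the range of n noise samples is ~5 sigma) and their stretched fits
  extrapolate to absurd rates at 2 ms.
* Outlier screen. Within each delay, repeats whose rate deviates from the
  median by > 3 scaled MADs, or whose fit RMSE exceeds 3x the median
  RMSE, are rejected (never with fewer than 3 repeats). Thresholds are
  configurable; the rule is a deterministic surrogate for the visual
  screening used in practice.

Kept repeats are averaged per delay (mean, SD with ddof = 1) and the rate
versus agonist-exposure delay course is decomposed into
`K(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2)` with signed amplitudes; the
rise-then-decay shape requires one negative amplitude. Components are
ordered tau1 < tau2 and interpreted as activation and desensitization by
that ordering, not by amplitude sign. The fit is unweighted by default
(weighting by the per-delay SDs is available but with 8 repeats the SD
estimates are noisy enough that weighting occasionally overweights lucky
points and destabilises the fit). A monotone course with no resolvable
second component (including fitted time constants within 5% of each
other) falls back to a single exponential with a flag. Initial guesses are
multi-started over combinations of the time-to-peak and a tail
log-slope estimate.

## Patch-clamp kinetics

Activation is the single-exponential time constant of the 10-90% rise
window before the peak; an instantaneous rise is reported as the sample
interval with a warning. Desensitization is fitted from the peak sample
onward with both a single and a double exponential decaying to a free
plateau (currents do not decay to zero), and the model is selected by
small-sample-corrected AIC *plus* identifiability guards: the double
model is only accepted when its time constants differ by at least 2x and
both amplitudes share a sign and carry at least 5% of the total. Bare
AICc alone prefers the double model in ~14% of single-exponential traces
with realistic noise, because at large n a chi-square-distributed SSR
improvement beats the 2-parameter penalty too often. Double fits are
summarised by the amplitude-weighted time constant
`(A1 tau1 + A2 tau2)/(A1 + A2)`; pooled summaries mix weighted taus of
double fits with taus of single fits. The extent of desensitization is
the current 20 s after agonist onset (onset, not peak) normalised to the
peak. Dose-response curves are Hill fits with n fixed at 2; a fit whose
largest tested concentration is below 2x the fitted EC50 carries a
wide-confidence flag.

Group statistics follow the two study designs: one-way ANOVA with Tukey
HSD adjusted pairwise p-values for many-group panels, and per-group
t-tests against a reference with Bonferroni adjustment for
reference-versus-variants panels. A simulated three-group null keeps the
Tukey family-wise error at the nominal 5%.

## Synthetic-data generators

The generators produce every input class with known ground truth; their
defaults are the study conditions wherever those are stated.

* **Peak sets**: exact binomial mole fractions (default N = 32,
  K = 120.4 uM — the K implied by 2.9 bound at 12 uM with 32 sites)
  scaled and multiplied by log-normal noise (sigma = 0.05); the histogram
  is truncated at the last species above 1e-4 mole fraction.
  Concentrations default to 2-36 uM, the measurable range.
* **Stability curves**: Hill evaluation (EC50 52 uM, n 1.7, E_max 6 — an
  ~85% pentamer loss in the control implies a maximal protection ratio
  near 6) plus additive Gaussian noise floored at 0.
* **Membrane frames**: a ring of TMD beads (radius 22 Å, repeated at the
  two leaflet planes and the midplane) in a 300 x 300 Å box with 3000
  one-bead lipids split across two leaflets — the box/lipid count of the
  source simulations. With uniform placement this geometry yields
  ~32 boundary lipids per frame, matching the measured annulus
  (31.6 +/- 2.5). Inside the 6 Å boundary shell species are drawn with
  probability proportional to `w_i x_i`, giving the closed-form expected
  enrichment `B_i = w_i / sum_j w_j x_j - 1`. The generator is 2-D per
  leaflet because the enrichment metric and the density maps depend only
  on in-plane positions and leaflet labels; it does not emulate lipid
  diffusion, correlated frames, membrane undulations or protein
  asymmetry, so passing tests validate the estimators, not force-field
  behaviour.
* **Quench traces**: an irreversible resting -> open -> desensitized
  scheme with open probability
  `O(t) = a/(a-d) (exp(-d t) - exp(-a t))` (confluent limit at a = d)
  sets the target rate `k = k_leak + k_max O(t)`; the stretched-exponential
  time constant is obtained by *inverting* the 2 ms rate equation, so the
  pipeline's recovery of (1/a, 1/d) is a genuine inverse problem rather
  than a tautology. Defaults: k_max 30 1/s, k_leak 0 (rates are treated
  as control-subtracted; the course model has no constant term), beta
  0.7, 24 log-spaced delays over 10 ms - 25 s, 8 repeats, 5% amplitude
  noise, 400 log-spaced samples over 2 ms - 1 s (stopped-flow instruments
  record multi-decade kinetics on a logarithmic timebase; sparser linear
  sampling leaves the early decay unconstrained and inflates rate errors
  several-fold).
* **Current traces**: exponential activation multiplying a normalised
  double-exponential desensitization envelope with a free plateau, at
  1 kHz for 21 s. Defaults reproduce the wild-type scale (activation
  134 ms; weighted tau 1.95 s from equal amplitudes at 0.5 s and 3.4 s;
  plateau 0.10). Note that with activation only ~4x faster than the fast
  desensitization component, the observed peak is attenuated below the
  driving amplitude; recovery tests therefore compare against the
  generating model evaluated exactly, not against the envelope
  parameters naively.

Every generator is a pure function of its arguments including the seed,
and returns its ground truth alongside the data.

## Problem sizes used in the acceptance computations

The acceptance script evaluates the binding-stability coupling once
(closed-form, instantaneous), the flux condition contrast over 50 seeded
replicate experiments (2 conditions x 24 delays x 8 repeats each), and the
null enrichment over 50 frames of 3000 lipids. The desensitization-tau
ratio of the two lipid conditions recovers at 22.7 +/- 1.0 against a
generating ratio of 21.9. The null-enrichment mean carries a Monte-Carlo
SE of ~0.07 (per-frame B of a 10% species among ~32 boundary lipids has
SD ~0.5), so individual seeds scatter accordingly; the test suite checks
both the absolute band and the 3-SE consistency interval.

## Known limitations

* The equal-affinity binomial model cannot represent site heterogeneity;
  K is an effective, not microscopic, constant.
* The linear binding extrapolation is a reconstruction constrained only
  by the coupling endpoint; other monotone extrapolations would shift the
  effect-per-bound-lipid curve.
* Boundary classification treats all protein beads supplied as TMD unless
  a z-range is given; callers reading real coarse-grained frames should
  restrict the selection.
* Rates below the no-flux detection floor (quench indistinguishable from
  noise over the 1 s window) are reported as 0; this is correct for the
  course decomposition but means very slow fluxes are censored.
* Stretched-exponential fits of partially decayed traces (tau >> 1 s)
  underestimate the rate by up to ~30%; these points sit at <= 7% of the
  peak rate and perturb the course fit only marginally.
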