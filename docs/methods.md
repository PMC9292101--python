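# Methods

This note documents the models, the synthetic generators, the numerical
choices, and the limits of what the test suite can show.

## Speech synchrony

Synchrony between a heard syllable stream and concurrent whispered
production is measured on the two amplitude envelopes. Both are resampled
to 100 Hz by polyphase rational resampling (antialiased, no phase
distortion), band-passed 3.5–5.5 Hz — a band centered on the 4.5 syll/s
presentation rate — with a 4th-order Butterworth applied forward–backward
so filtering adds no group delay, and converted to instantaneous phase via
the Hilbert analytic signal. The phase-locking value of a window of T
samples is `(1/T)|Σ exp(i Δθ(t))|`; windows are 5 s long and overlap by
2 s, which we read as a 3-s hop (5 − 2). Some authors read "2 s overlap"
as a 2-s hop, so the hop is a parameter (`hop_s`) and the default is
recorded in every output. Trailing partial windows are discarded: the
formula fixes T per window and partial windows would change the
estimator's variance. One value per block is the mean over complete
windows.

The stimulus-side envelope can be computed by a cochlear-style front end:
64 ERB-spaced gammatone channels between 100 and 4000 Hz, per-channel
magnitude (analytic-signal) envelopes, averaged across channels. Channel
count, frequency range, and the mean-vs-sum summary are parameters
reported in output metadata, since cochlear front ends vary across labs.
The production-side envelope is taken directly (absolute Hilbert envelope
of the whisper waveform, or the synthetic envelope itself).

## High/low synchronizer classification

Participants are split by clustering a PLV pool (either the sample itself
or a larger normative pool) into two groups by squared-Euclidean two-means
and thresholding at the midpoint of the two centers; ties label "low"
(conservative, documented choice). In one dimension the optimal
two-cluster solution is a split of the sorted values, so the classifier
computes the exact optimum by scanning all n−1 split points with prefix
sums rather than running Lloyd iterations; this is deterministic and
reproducible by construction, and the test suite verifies it against a
brute-force scan and against multi-restart k-means.

## Synthetic speaker: a coupled phase oscillator

Whispered production during the synchronization test is modeled as a
phase oscillator forced by the stimulus phase:

    dθ = [ω + κ sin(θ_stim − θ)] dt + σ dW

integrated by Euler–Maruyama at dt = 10 ms (matching the 100 Hz analysis
rate; the phase dynamics are smooth at this scale). The produced envelope
is (1 + cos θ)/2. For κ large the oscillator phase-locks and the PLV
approaches 1; for κ = 0 with matched ω and σ = 0 the phase difference is
constant and the PLV is also 1 — so *detuning and noise*, not just weak
coupling, are what make a low synchronizer. Since no generative account
of low synchronizers is established, all three knobs (κ, ω, σ) are
exposed; the cohort defaults are:

| group | κ (rad/s) | natural rate (Hz) | σ (rad/√s) |
|------|-----------|-------------------|-------------|
| high | 8         | 4.5               | 0.7         |
| low  | 0         | 4.2               | 0.7         |

chosen so the cohort PLV distribution is clearly bimodal (highs near 1,
lows around 0.2), as observed empirically. Real cohorts have more overlap
between the modes; passing label-recovery tests on these defaults
therefore shows the classifier works on a separable population, not that
every real participant near the threshold would be labeled correctly.

## Behavioral model

Trial-level 2AFC correctness follows a binomial logit mixed model.
Condition (PL/AS) and Group (high/low) are coded sum-to-zero at ±0.5, so
the condition coefficient is the PL−AS logit difference averaged over
groups, the group coefficient the high−low difference, and the
interaction the difference of within-group condition effects; with this
coding, dropping single terms gives Type-3 likelihood-ratio tests. Each
participant contributes a Gaussian random intercept.

The generative defaults plant the qualitative pattern seen in this
paradigm — an articulatory-suppression cost carried by the high group —
with cell probabilities near 0.82/0.65 (high PL/AS) and 0.63/0.62 (low
PL/AS): intercept 0.78, condition 0.475, group 0.525, interaction 0.85
(logits), random-intercept SD 0.5, cohort 23 high + 32 low, 16 trials per
condition (two 8-trial blocks). These values were fixed once from the
published effect pattern and are not tuned per test.

### Fitting

The marginal likelihood integrates the random intercept per participant.
Trials are first aggregated to binomial counts per participant × cell, so
likelihood evaluations are cheap. The default integral approximation is
Laplace — the mode of each participant's integrand is found by vectorized
Newton steps, and the curvature term completes the approximation —
matching the convention of the standard mixed-model stacks. Adaptive
Gauss–Hermite quadrature (any node count; 25 by default) centered and
scaled at the same modes is available both as a fitting method and as the
accuracy oracle in tests. The outer optimization is quasi-Newton
(L-BFGS-B) over coefficients and log random-effect SD; because the
aggregated objective costs microseconds, numerical gradients are used
rather than analytic ones. Convergence uses the optimizer's tight default
tolerances (ftol 1e-12). A fitted SD below 1e-3 (or at the lower bound)
is reported as 0 with a `singular` flag; a design cell with all-correct
(or all-wrong) responses raises a separation warning. The fixed-effect
covariance is the inverse observed information (central-difference
Hessian), which feeds the marginal-mean contrasts (delta method, Wald
z and CIs on the response scale via the inverse logit).

Measured on data of this shape, the Laplace and AGQ-25 log-likelihoods
agree to ~0.002 per participant, and the two methods' fixed effects agree
to about two decimals — adequate for the χ² tests, whose null calibration
is verified directly (rejection rate at α = 0.05 within [0.03, 0.07] over
500 null replicates).

Additional random-intercept factors (language, block order) are available
behind `extra_random=`; they use a joint dense-Newton Laplace over all
levels. Model comparison against the participant-only base model uses AIC
computed on identically aggregated cells so likelihood constants cancel;
with a zero-variance added factor the penalty is at most 2, reproducing
the keep-the-simple-model selection. Wilcoxon tests against chance use
the exact null for n ≤ 25 without ties and the tie/continuity-corrected
normal approximation otherwise.

## Synthetic BOLD and group ICA

Each subject's 4-D volume is baseline (100) plus planted networks —
Gaussian blobs with unit peak — times their condition time courses, plus
white Gaussian noise (SD 0.5 by default, ~0.5% of baseline). Condition
time courses are boxcars of the two-run block schedule (per run: 1 min
rest, 2 min PL learning, self-paced test, 1 min rest, 2 min AS learning,
test, 2 min speech-motor control; TR 1.5 s) convolved with the canonical
double-gamma HRF (response peak 6 s, undershoot 16 s, ratio 6, unit
peak). The default two networks mirror the empirical dissociation: an
"auditory" network active during listening in both groups, and a
"frontoparietal" network active only in high synchronizers, with
per-subject amplitude jitter (SD 0.25). Head motion is emulated as six
small AR(1) nuisance series (not added to the data by default). The
generator does not model drift, physiological noise, motion artifacts, or
spatial autocorrelation beyond the smooth planted maps — so ICA recovery
results on this data bound what the algorithm does under white noise, not
under realistic fMRI artifact structure.

Group ICA follows the standard recipe: per-voxel intensity normalization
to percent of the voxel's temporal mean (the common convention; recorded
in metadata), subject-level temporal PCA (default 40 dimensions,
configurable), temporal concatenation, group PCA to the component count,
and extended infomax unmixing (natural-gradient updates in shuffled
blocks, sub/super-Gaussian switching by source kurtosis sign,
learning-rate annealing on oscillation, convergence at relative weight
change < 1e-6 or 512 epochs; the seed controls initialization). Component
sign is fixed so each map's absolute peak is positive, and components are
ordered by explained variance. Subject time courses and maps come from
dual regression (spatial then temporal regression) rather than the
dewhitening-based back-reconstruction of the reference MATLAB toolbox —
equivalent at this scale and a simpler contract; the time-course stage is
verified against a direct least-squares oracle. In tests, components are
matched to planted maps by Hungarian assignment on absolute spatial
correlation with sign flipping, resolving ICA's inherent order/sign
ambiguity.

Artifact screening replaces visual inspection with two rules (thresholds
configurable): discard a component if more than half of its absolute map
mass lies in the one-voxel rim of the volume, or if its time course
correlates with any motion regressor above |r| = 0.6 in any subject.
These rules capture the spirit of edge/vessel/motion rejection but are
not a validated formalization of human raters.

Engagement betas regress each component time course on HRF-convolved
boxcars for rest, PL, AS, speech-motor and the test phase (nuisance),
six motion regressors and an intercept; contrasts are PL − rest and
AS − mean(rest, speech-motor). Because the self-paced test phases break
exact collinearity of the condition set, the design is full rank; an
explicit check rejects constant columns. The 2-SD outlier rule is applied
per component × contrast across subjects (the grouping is not fixed by
convention, so it is a documented choice here). Group maps are one-sample
t maps over subject maps, thresholded one-sided at voxel p < 0.001,
labeled with 26-connectivity, pruned at a 50-voxel extent; an optional
sign-flip permutation null of maximum cluster size (1000 permutations)
gives cluster-level family-wise correction in place of random-field
theory.

## XOR interplay

"Above baseline activity" is not a standardized rule, so the binarization
baseline is a parameter: default is the mean of the same time course
during rest blocks; global mean and literal zero (for z-scored series)
are selectable, and the rule used is carried on the output. The analysis
window defaults to the PL learning blocks (the benefit analysis concerns
PL) and is configurable. The XOR score of two binarized series is the
fraction of TRs at which exactly one is active; the occupancy-normalized
variant (raw score divided by the fraction of TRs with at least one
network active) is emitted alongside because "normalized XOR" appears in
figure axes without a definition; the raw score is primary. The learning
benefit is percent correct in PL minus percent correct in AS; the
interplay statistic is the Spearman correlation of XOR with benefit among
high synchronizers (it is not meaningful in lows, whose frontoparietal
engagement is absent).

## Pipeline and problem sizes

`run_full_pipeline` chains the stages with per-stage seeds derived from
one master seed by fixed offsets, caches each stage's JSON summary when
an output directory is given (reruns skip completed stages byte-
identically), and evaluates the qualitative replication pattern: a
significant Condition × Group interaction, a PL−AS effect significant in
highs but not lows, and an FDR-significant between-group frontoparietal
difference in PL − rest engagement.

Default cohort sizes follow the study design (55 behavioral participants:
23 high/32 low; 41 imaging: 19 high/22 low). The default grid is 20³
voxels; the end-to-end replication runs and the acceptance script use a
12×12×10 grid with 6 ICA components, a desk-scale choice that preserves
the design structure (two planted networks, full two-run block schedule)
while keeping a 20-seed replication study to a few minutes. Monte-Carlo
checks in the test suite use 5–500 replicates depending on the cost of
one replicate; the replicate counts are stated in each test.

## Known limitations

- The oscillator is a one-dimensional phase model; it produces no
  amplitude structure, pauses, or articulatory variability.
- The behavioral generator has no learning dynamics (no trial-order or
  block-order effects) and a single random-intercept source.
- The BOLD generator's noise is white; ICA recovery under colored noise,
  motion, or spatially overlapping networks is untested.
- Artifact screening thresholds are heuristics, not calibrated to human
  raters.
- Bayes-factor analyses of the null results are out of scope.
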