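# syncsl

Analysis pipeline for studying how **speech auditory–motor synchrony**
shapes **statistical word-form learning**, with synthetic generators that
plant a known ground truth under every stage.

## The scientific problem

Listeners can segment recurring trisyllabic pseudo-words out of a
continuous, pause-free syllable stream using only transitional
probabilities. Concurrently whispering a syllable (articulatory
suppression, AS) interferes with this learning relative to passive
listening (PL) — but not for everyone. People split into **high** and
**low synchronizers**: when asked to whisper along with an isochronous
4.5 syll/s stream, some spontaneously phase-lock their produced syllables
to the heard ones and others do not. The package implements the full
analysis chain for this paradigm:

1. **Stimuli** (`syncsl.stimgen`) — pseudo-languages of 4 trisyllabic words
   over 12 unique CV syllables (111 ms phonemes, 222 ms syllables),
   2-minute learning streams with equal, non-adjacent word repetitions at
   exactly 4.5 syll/s, the 12 part-word foils, 8-trial 2AFC test sets, and
   the random syllable stream for the synchronization test.
2. **Synchrony** (`syncsl.sync`) — envelopes are resampled to 100 Hz,
   band-passed 3.5–5.5 Hz and Hilbert-transformed; synchrony is the
   phase-locking value

   `PLV = (1/T) |Σ_t exp(i(θ₁(t) − θ₂(t)))|`

   over 5-s windows with 2-s overlap, averaged per block. Participants are
   classified high/low by 1-D two-means on a PLV pool; the threshold is the
   midpoint of the cluster centers.
3. **Behavior** (`syncsl.behavior`) — a binomial logit mixed model of 2AFC
   correctness with Condition × Group fixed effects (sum-to-zero coding)
   and participant random intercepts, fitted by a Laplace-approximated
   marginal likelihood (adaptive Gauss–Hermite available as an accuracy
   oracle); Type-3 likelihood-ratio tests, estimated marginal means and
   contrasts, Wilcoxon tests against chance, and Benjamini–Hochberg FDR.
4. **Networks** (`syncsl.networks`) — group spatial ICA of block-design
   BOLD (percent-signal normalization, two-stage PCA, extended infomax,
   dual regression), rule-based artifact screening, network-engagement
   betas from an HRF-convolved condition GLM with motion and test-phase
   nuisance (contrasts PL − rest and AS − mean(rest, speech-motor), 2-SD
   outlier exclusion), nonparametric group statistics, and one-sample-t
   group maps thresholded at voxel p < .001 with a 50-voxel extent rule.
5. **Interplay** (`syncsl.interplay`) — network time courses are binarized
   against their rest-block mean and combined with a per-TR XOR (1 when
   exactly one network is active); the time-averaged XOR is correlated
   (Spearman) with each high synchronizer's learning benefit (PL% − AS%).
6. **Generators** (`syncsl.synthdata`) — a coupled phase oscillator
   `dθ = [ω + κ sin(θ_stim − θ)]dt + σ dW` that emulates whispered
   production (coupling and detuning control synchronizer type), the
   generative twin of the behavioral mixed model, and planted-network
   block-design BOLD with a canonical double-gamma HRF.
7. **Pipeline** (`syncsl.pipeline`) — a seeded, resumable end-to-end run
   with a machine-readable report, plus the `syncsl` command-line
   interface.

## Worked example

```python
import numpy as np
from syncsl import synthdata, sync, behavior as bh

# a 40-participant synchronization cohort: 20 strongly coupled speakers,
# 20 detuned uncoupled ones
plvs, truth = synthdata.simulate_cohort_plvs(n_high=20, n_low=20, seed=3)
cls = sync.classify_synchronizers(plvs)
print(round(cls.threshold, 3), np.mean([a == b for a, b in zip(cls.labels, truth)]))

# behavioral cohort at the planted effect pattern, mixed-model analysis
data, _ = synthdata.simulate_behavior(synthdata.BehaviorGenParams(seed=1))
for t in bh.type3_lr_tests(data):
    print(f"{t.term:12s} chi2={t.chi2:5.1f}  p={t.p:.2g}")
for c in bh.marginal_contrasts(bh.fit_binomial_glmm(data)):
    print(f"{c.contrast:14s} z={c.zratio:5.2f}  p={c.p:.2g}")
```

prints

```
0.601 1.0
condition    chi2= 17.6  p=2.8e-05
group        chi2= 11.3  p=0.00079
interaction  chi2= 16.2  p=5.6e-05
PL-AS | high   z= 5.09  p=3.6e-07
PL-AS | low    z= 0.13  p=0.89
high-low | PL  z= 4.97  p=6.8e-07
high-low | AS  z= 0.66  p=0.51
```

The classifier separates the bimodal PLV distribution at 0.601 and labels
every participant correctly. The mixed model recovers the planted pattern:
learning drops under articulatory suppression (Condition), high
synchronizers outperform lows (Group), and the suppression cost is carried
by the high group (interaction; PL−AS significant only in the highs, group
difference only under passive listening).

```bash
syncsl run --seed 1 --out runs/demo      # full synthetic replication
syncsl plv --stim s.wav --prod p.wav     # PLV between two recordings
```

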