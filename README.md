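# neuroauth

Multi-task person authentication from EEG and eye-blink signals.

## The problem

EEG is attractive as a biometric because brain activity is hard to steal or
forge, but single-modality EEG systems are not accurate or stable enough
for practical use. `neuroauth` implements a two-modality authentication
pipeline for researchers studying EEG biometrics:

1. **Visual-evoked EEG.** A rapid serial visual presentation (RSVP) stream
   of face images — one *self-face* (the enrolled user's own face) per nine
   *non-self* faces, 300 ms per image — evokes a subject-specific
   event-related potential (an N250-like deflection whose latency,
   amplitude and scalp topography differ across individuals). Sixteen
   electrodes are recorded at 2400 Hz.
2. **Eye blinks.** The electrooculogram at Fp1 contains biphasic blink
   waveforms (positive lobe > 100 μV, negative undershoot < −50 μV) whose
   morphology is also subject-specific.

Since no public recordings exist for this paradigm, the package ships a
first-class synthetic-data generator (`neuroauth.synthgen`) that emulates
both signals with controllable subject effects, so the entire pipeline is
testable end to end.

## The method

**ERP features.** After a 40 Hz Chebyshev low-pass, 2400→600 Hz averaging
downsampler and −200..1000 ms epoching with baseline correction, each
electrode *i* and post-stimulus sample *n* is scored by the point-biserial
discriminability

    P_i(n) = √(N₁N₂)/(N₁+N₂) · (M_i^SF(n) − M_i^NSF(n)) / S(n),

the Pearson correlation between single-trial voltage and the self/non-self
label (N₁, N₂ class trial counts; S(n) pooled SD). Per channel the 200
points with largest |P| are kept; channels are ranked by the mean square of
their selected P values and the top 5 retained. Self-face epochs (adjacent
trials averaged pairwise) are reduced to a 5×20 matrix of 20 window means
(10 samples per window) and embedded in a sparse 20×20 map.

**Blink features.** Band-passed (1–40 Hz) Fp1 traces are segmented by
threshold detection plus zero-crossing scans, normalized to [−1, 1], and
summarized by 20 morphological features: peak amplitudes and pulse areas
(Ap, An, Ep, En), peak positions and pulse durations (Pp, Pn, Dp, Dn),
onset/offset slopes and dispersions (S1–S6), and first/second-derivative
extremes and zero-crossing counts (D1–D6).

**Scoring and fusion.** A small CNN (conv 6@5×5 → maxpool 2 → conv 12@3×3
→ maxpool 2 → 108-unit flatten → 2 outputs) scores ERP maps; a 20-5-5-5-2
back-propagation network scores blink vectors. The minority (user) class is
balanced with SMOTE. The two match scores s = (s₁, s₂) are fused by a
power-series function

    S_f = λ₀ + Σ_{m=1..M} Σ_{n=1..N} λ_{m,n} s_n^m,

with λ fitted by least squares against 0/1 class targets; login accepts
when S_f ≥ 0.5. Closed-set, open-set (unseen imposters, FAR only) and
permanence (repeat session with parameter drift, FRR only) protocols report
ACC/FAR/FRR and ROC curves.

## Worked example

```python
import neuroauth as na

cohort = na.CohortSpec.small(seed=0)       # 5 users, scaled-down sessions
results, models = na.run_closed_set(cohort)
print(na.closed_set_table(results).round(2))
```

```
       acc_eeg  acc_fused  far_eeg  far_fused  frr_eeg  frr_fused  auc_eeg  auc_fused
user
user0    100.0      100.0      0.0        0.0      0.0        0.0      1.0        1.0
...
mean     100.0      100.0      0.0        0.0      0.0        0.0      1.0        1.0
```

Under the scaled strong-effect conditions (5–9 μV subject-specific
deflections over 2 μV pink noise) every enrolled user separates perfectly
from their imposters. The open-set protocol scores previously unseen
imposters against the frozen models:

```python
print(na.rate_table(na.run_open_set(cohort, models), "far").round(2))
```

```
       far_eeg  far_fused
user
user0     0.00       0.00
user1     4.17       0.00
user2     4.17       4.17
...
mean      1.67       0.83
```

A mean fused false-accept rate below the EEG-only rate shows the blink
modality tightening the decision. The same flow is available from the
shell: `neuroauth simulate`, `neuroauth train`, `neuroauth authenticate`,
`neuroauth evaluate closed --out DIR`.

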