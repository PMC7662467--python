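# Methods

`apneakit` scores overnight recordings for sleep-disordered breathing from
four sensor streams: two triaxial accelerometers (thorax and abdomen,
50 Hz), pulse-oximetry SpO2 (1 Hz) and a single-lead ECG (500 Hz, or a
precomputed R-peak list). The output is a per-step label sequence over the
classes NOR (normal breathing), OSA (obstructive apnea), CSA (central
apnea) and HYP (hypopnea), a 30-s sleep-wake hypnogram, the list of scored
events, the apnea-hypopnea index (AHI, events per hour of sleep) and its
severity grade. This note records the model, the parameter choices and
their rationale, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Signal model and processing chain

Respiratory effort at either placement is modelled as a single
amplitude- and frequency-modulated oscillation A(t)·sin(φ(t)) with
instantaneous frequency φ'(t)/2π in the adult breathing band
(0.2-0.3 Hz), riding on sensor noise and posture-dependent projection:
only one accelerometer axis carries the breathing excursion at a time, and
the axis changes when the sleeper turns.

1. **Axis selection.** Each 30-s segment (10-s hop) of the three axes is
   scored by its count of breathing peaks; the axis whose count is closest
   to the physiological 6-9 peaks/30 s band wins the segment, and the
   output axis at each step is the modal winner of the five most recent
   segments, with ties broken by larger RMS. Peaks are counted after a 1-s
   moving average with a prominence floor of 0.25 segment SD and a 2-s
   minimum separation; the smoothing is what makes the count stable at
   10 dB SNR. Axis selection runs on the raw axes; the 6th-order 0.8-Hz
   zero-phase Butterworth low-pass is applied to the selected output
   (zero-phase so that peak timing is undistorted).
2. **Instantaneous amplitude (synchrosqueezing).** The amplitude ratio
   features need Ã(t), an envelope estimate that ignores DC shifts and
   broadband posture artifacts. We use a continuous-wavelet
   synchrosqueezing transform: an analytic Morlet-type wavelet
   (centre μ = 6, bandwidth σ = 2.3, with the standard admissibility
   correction so ψ̂(0⁺) = 0), a log-spaced grid of 32 voices/octave over
   0.05-2 Hz, reassignment of each coefficient to the frequency given by
   its own phase derivative, a maximum-energy ridge through the squeezed
   energy with a quadratic log-frequency jump penalty (λ = 4, Viterbi),
   and amplitude recovery by summing the squeezed transform over ±2 bins
   around the ridge. The normalisation constant is computed per ridge
   frequency from the wavelet itself, which also corrects scale-grid
   truncation at the band edges. σ = 2.3 trades frequency resolution for
   a ≈2-s time resolution so that apneic amplitude steps settle within
   5 s; the pure-tone error of the whole chain is below 1 %. Signals are
   decimated to 10 Hz internally (the band ends at 2 Hz) and the envelope
   is interpolated back. Edges are reflect-padded 15 s.
3. **Features** (one frame per 0.5 s, nine values): amplitude ratios
   AR = Q95(Ã over the current 10-s window) / Q95(Ã over the previous
   60 s) for thorax and abdomen (Q95 with linear interpolation between
   order statistics; the denominator is floored at 10⁻⁸ of the night
   median so long silences cannot divide by zero); frequency ratios
   FR = log10 of cardiac-band (0.8-1.5 Hz) over respiratory-band
   (0.1-0.8 Hz) energy of the rectangular-windowed 10-s segment,
   trapezoid-integrated on the FFT grid and clipped to ±6 — computed on
   the *unfiltered* axis-selected signal, because the 0.8-Hz low-pass
   would destroy the cardiac band that makes central apneas visible; and
   five SpO2 features from the median/SD-normalised whole-night trace:
   the value at the frame time plus min/max/mean/variance of the first
   difference over a 20-s segment delayed 20 s, matching the ≈19 s
   physiological lag between an event and its desaturation. Frames are
   emitted where every window exists: 60 s warm-up, 40 s look-ahead.
4. **Event classifier.** A single-layer LSTM (9 inputs, 80 cells, softmax
   over 4 classes; σ/tanh gates, linear logits) reads 20-s windows
   (40 frames) and is trained with Adam (lr 10⁻³), cross-entropy plus an
   L2 penalty β = 0.05, and global-norm gradient clipping at 5. The L2
   term is implemented as β·mean(w²) per weight matrix (biases excluded);
   at these parameter counts a raw sum of squares would dominate the
   loss. Training windows slide 5 frames apart and take the majority
   ground-truth label over their span. At inference one softmax row is
   emitted per 0.5-s step; the pipeline assigns each step the window
   *centred* on it, which removes the half-window lag a
   window-ending-at-step convention would introduce against
   window-majority training labels (both alignments are exposed).
5. **Desaturation detection.** First difference of the 1-Hz SpO2 trace,
   convolved with a 20-sample all-ones kernel (the accumulated drop over
   the trailing 20 s); samples at or beyond 3 % are marked and the mark
   series is shifted 20 s earlier. The implementation is exactly
   equivalent to the brute-force loop (tested on 1,000 random traces).
6. **Fusion.** Steps whose argmax is NOR under an active desaturation
   mark become HYP — but per desaturation *run*: a run that already
   overlaps abnormal argmax labels belongs to a detected event and does
   not spawn an extra HYP span. The rescue exists to catch hypopneas the
   classifier missed; applied per step it double-counts every detected
   event whose desaturation outlasts it. Abnormal labels inside wake
   epochs are reset to NOR.
7. **Sleep-wake.** Instantaneous heart rate IHR = 60/RR (bpm, at each
   R peak from the second on, held to 1 Hz) and the 20-s-delayed SpO2
   form a 2×300 input (5-min context centred on each 30-s epoch,
   median-subtracted per window). The CNN has five blocks of two
   convolutions (10 filters, kernel 8, strides 1 and 2 — each block
   halves its input), two 20-node dense layers, dropout 0.5 on the last
   convolution and both dense layers, L2 β = 0.3, Adam lr 10⁻³, batch
   100. Batches are drawn half-sleep/half-wake because wake epochs are
   rare (~10 %) and an unbalanced sampler collapses to the all-sleep
   baseline. An epoch is wake when the wake output ≥ the sleep output.
   R peaks come from a Pan-Tompkins-style detector (5-15 Hz band-pass,
   derivative, squaring, 150-ms integration, adaptive threshold, 0.25-s
   refractory, peak refinement on the band-passed signal).
8. **Events and AHI.** Maximal same-kind label runs; abnormal runs
   separated by under 2 s of NOR merge (argmax flicker would otherwise
   split events); runs shorter than the 10-s scoring minimum are dropped.
   AHI = (#OSA + #CSA + #HYP) / hours of sleep from the hypnogram;
   severity uses the standard cutoffs <5 normal, 5-15 mild, 15-30
   moderate, ≥30 severe, boundaries to the upper bin.

## Synthetic nights

The simulator generates fully labelled recordings with the statistical
structure the pipeline assumes. Defaults (one "night" = 30 min for
desk-scale runs): event rates OSA 8 / CSA 5 / HYP 7 per hour of sleep
(a moderate-to-severe screening population), event durations
N(20.2, 3.4²) s truncated at 10, desaturation delays N(19.3, 9.6²) s
truncated at 5, desaturation depths uniform in 3.5-8 % (the lower edge is
kept clear of 3.0 so that 1-Hz sampling plus baseline drift cannot blur a
scripted desaturation below the detection threshold), breathing frequency
drifting in 0.2-0.3 Hz, posture changes at 2/h re-drawing the
respiration-bearing axis, one wake bout of 2-5 min per half hour with
faster and more variable heart rate, white sensor noise with SD 0.05 of
the breathing amplitude, and a 1.1-Hz cardiogenic ripple at 3 % of
baseline during central apneas (inside the FR numerator band).

Event rendering: OSA raises both effort envelopes to 1.4× baseline
(crescendo effort against the occlusion) while driving thorax and abdomen
to antiphase, so the airflow-equivalent sum collapses by over 90 %; CSA
reduces both envelopes to 3 % of baseline and adds the cardiogenic
ripple; HYP reduces envelopes to 70 %. Desaturations are linear 10-s
declines with exponential recovery (τ = 15 s) on a 96.5 % baseline with
slow drift. ECG is an impulse-train of QRS-like templates from a
state-dependent AR(1) RR process (sleep mean 1.0 s, wake 0.75 s with
higher variance). Events are placed only in sleep, at least 70 s apart,
so scripted truth is unambiguous: the truth AHI equals the AHI recomputed
from truth events and hypnogram exactly.

What the simulator does **not** emulate: realistic ECG morphology and
artifact, oximeter quantisation and probe dropouts (the reader handles
dropouts, the generator does not script them), REM/NREM structure beyond
binary sleep-wake, apnea clustering/periodicity, obesity-hypoventilation
baselines, or inter-subject variability of effort waveforms beyond
amplitude/frequency drift. Passing the synthetic end-to-end test
therefore shows the chain is self-consistent and learnable under the
stated physiology — not that clinical performance matches any cohort.

## Training-set construction

Windows are balanced before LSTM training: every abnormal window is kept,
as is every NOR window whose centre lies within 60 s of a scored event —
these hard negatives see the delayed desaturation with a normal amplitude
ratio, and discarding them makes the classifier hallucinate hypopneas at
event boundaries — while far-from-event NOR windows are subsampled to the
mean abnormal class count. The train/test split is by night (the last
third of nights, at least one, is held out); no window crosses the split.

## Desk-scale problem sizes

The end-to-end experiment used by the acceptance tests and
`scripts/acceptance.py` trains on six simulated 30-min nights (four
train, two held out; ≈1,900 event windows), 50 epochs of 30 Adam batches
of 64 for the LSTM and 600 balanced batches for the CNN — sizes chosen so
a full run completes in minutes on one CPU while every quantity is still
measured, not assumed. Published clinical-cohort benchmarks require the
cohort recordings and are not reproduced.

## Known limitations

* The desaturation-rescue rule cannot distinguish a missed hypopnea from
  a desaturation caused by an adjacent detected apnea when the classifier
  missed *both*; run-level suppression then favours the detected kind.
* The amplitude estimate near recording edges (first/last ~15 s) relies
  on reflect padding and is biased for events that touch the boundary.
* The EDF codec writes/reads plain 16-bit EDF with one-second records and
  integer samples-per-second; EDF+ annotations and discontinuous records
  are out of scope.
* Sleep-wake staging is binary; arousal scoring and REM detection are not
  attempted.
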