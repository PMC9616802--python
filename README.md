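# thetawm — fronto-medial theta and working-memory content in synthetic EEG

`thetawm` re-implements, as a tested and reusable Python pipeline, the
complete sensor-space EEG analysis of a working-memory study design:
spectral power contrasts with cluster-based permutation inference,
cross-validated category decoding (per-timepoint LDA, temporal
generalization, channel searchlight), seed-based theta coherence with
trial-count matching, and a per-trial theta peak-frequency statistic with
1/f control via IRASA. Because the analyses are validated end-to-end on
synthetic EEG with known ground truth, every stage ships with a generator
that injects the effect it is meant to detect.

It is written for cognitive-neuroscience researchers and methods developers
who want (a) a transparent, scriptable version of this analysis stack
outside MATLAB, and (b) a harness for checking that each inferential step
recovers known, injected effects at realistic signal-to-noise ratios.

## The science in brief

Working memory (WM) is thought to rely on an executive system — indexed by
fronto-medial theta oscillations (FMT, 4–8 Hz) — coordinating stimulus
content maintained in posterior cortex. The pipeline tests four signatures
of that architecture on epoched EEG (trials × channels × time):

1. **FMT power.** Delay-period power (2–10 Hz, 0.5 Hz steps; sliding
   Hanning taper, 2–5 cycles per frequency, 50 ms steps) contrasted between
   a high-engagement task (1-back) and a control (delayed match-to-sample)
   with a cluster-based permutation test: per-bin paired *t*, clusters of
   adjacent suprathreshold channel × frequency bins, max-sum null over 500
   condition flips, clusters spanning < 3 channels discarded.
2. **Content decoding.** Two-class LDA (object vs scene) on channel
   voltages at every time point after resampling to 200 Hz, 100 ms sliding
   average, baseline correction to the preceding 200 ms and exemplar
   pair-averaging; stratified 5-fold × 5-repeat cross-validation; group
   significance against chance (50 %) by sign-flip temporal clustering; a
   channel searchlight (centre + neighbours, mean degree ≈ 5.7) localises
   the informative sensors.
3. **Fronto-posterior coupling.** Magnitude-squared coherence between the
   Fz seed and every channel, |⟨S_xy⟩|² / (⟨S_xx⟩⟨S_yy⟩) over trials,
   from the same tapered decomposition; the larger condition is subsampled
   (10 draws) to match trial counts before the paired cluster contrast.
4. **Theta slowing.** Per trial, the frequency of the most prominent
   spectral peak (4–8 Hz, 0.2 Hz zero-padded grid, height above the higher
   flanking base) on the frontal-cluster channel mean; condition means per
   participant; paired *t* for the load effect, repeated on IRASA
   oscillatory residuals and on smoothed spectra (2–5 grid elements), plus
   a load × frequency repeated-measures ANOVA with Holm-corrected
   follow-ups.

The synthetic generator (`thetawm.synth`) produces sessions with 1/f
background noise (PSD ∝ 1/f^χ), load-dependent frontal theta oscillators
(per-trial frequency ~ truncated Normal), posterior category patterns, and
band-limited Fz–posterior coupling — each logged in a ground-truth
manifest so recovery can be scored exactly.

## Worked example

The numbered scripts under `analysis/` run each stage on a synthetic
cohort and write their tables to `results/`. The theta-slowing analysis
(28 participants × 40 trials per load, oscillator means 5.85 Hz at low and
5.77 Hz at high load on a 1/f background):

```bash
$ python analysis/06_theta_slowing.py
recovered grand-mean peaks: 1-back 5.831 Hz, 2-back 5.759 Hz (true 5.85 / 5.77)
paired slowing test: t(27) = 5.09, p = 2.4e-05, d = 0.96
IRASA residual: 5.838 vs 5.764 Hz, p = 3.2e-05
smoothing 2 elements: t = 4.79, p = 5.3e-05
smoothing 3 elements: t = 4.75, p = 5.9e-05
smoothing 4 elements: t = 4.67, p = 7.4e-05
smoothing 5 elements: t = 4.09, p = 0.00035
```

The per-trial peak procedure recovers both preset oscillator frequencies to
within ~0.02 Hz, and the 0.08 Hz load difference is detected by the paired
test (and survives 1/f removal and every smoothing window). The other
scripts behave analogously: `03_power_contrast.py` recovers the injected
frontal theta channels as a significant positive cluster,
`04_decoding.py` finds a cluster-significant decoding window matching the
injected pattern window with the searchlight peaking at an injected
channel, and `05_coherence.py` recovers the coupled posterior channel set
and its overlap with the decodable channels.

## Layout

```
src/thetawm/      library: synth, preprocessing, spectral, stats,
                  decoding, connectivity, behavior, pipeline, containers
analysis/         numbered narrative drivers (simulate → behavior → power
                  → decoding → coherence → slowing)
tests/            pytest suite incl. end-to-end acceptance checks
scripts/          acceptance.py (see above)
docs/methods.md   models, parameters, numerical choices, limitations
```
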