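# Methods

## Scope and model

`ratsleep` classifies 10-s epochs of one-EEG + one-EMG rat
polysomnography into five vigilance stages (W, NREM1, NREM2, TS, REM)
with a fixed, interpretable rule set: spectral features on 2-s segments,
per-recording normalization, eight ratio indexes, and a two-part decision
tree with seven testing points. The stage definitions are the standard
rodent ones: wake = low-amplitude theta plus high-frequency activity with
large EMG; NREM1 = spindles and/or slow waves over less than half the
epoch with reduced EMG; NREM2 = slow waves (0.5–5 Hz) over more than half
the epoch with low EMG; TS = regular theta intermixed with 1–3-s
high-amplitude spindles; REM = regular theta with absent EMG tone. The
tree is shipped with fixed constants and is never re-trained; the
distribution-distance and threshold utilities in `calibration` report the
statistics a designer would use to re-derive node features and cuts, but
re-learning the tree structure is out of scope, as are group-level
inferential statistics on staging output.

## Feature extraction

* **Segmentation.** Epochs of 10 s, five non-overlapping 2-s segments
  each; the trailing partial epoch is discarded. The analyzable duration
  is the minimum of the two channel durations (which must agree to within
  one epoch).
* **Periodogram.** Plain rectangular-window FFT per 2-s segment,
  one-sided, DC and Nyquist unhalved, no demeaning — bin powers sum to
  the segment's mean square, and the DC bin is the EEG_lo band that the
  movement-artifact rules need. A 2-s segment puts the bins on a 0.5-Hz
  grid at any sampling rate.
* **Bands.** Half-open [lo, hi) on that grid: EEG_lo [0, 0.5) (the DC
  bin), δ [0.5, 5), θ [6, 9), α [10.5, 15), β [22, 30), γ [35, 45),
  total [0, 30). The inter-band gaps are excluded by design.
* **Band power (dB).** Mean over the band's bins of
  `10·log10(power + 1e-12 µV²)`; the floor keeps silent segments finite
  at −120 dB. The mean-of-dB convention makes a band feature sensitive to
  how much of the band is filled, not only to total energy — a
  consequence that shapes both the synthetic generator (below) and the
  interpretation of the features.
* **Power ratios.** Raw band power over raw total [0, 30) power (0 when
  the total is 0); these are physical fractions in [0, 1].
* **EMG energy.** The whole EMG channel is band-passed 10–100 Hz with a
  4th-order zero-phase (forward–backward) Butterworth — zero phase so
  segment windows stay aligned — then each 2-s window contributes its
  mean absolute amplitude. EEG and EMG are never resampled; segment k of
  both channels covers the same [2k, 2k+2) s.

## Normalization

Per recording and per feature, the mean of the 10 % smallest values
(decile size ⌈0.1·n⌉, at least 1) maps to 0 and the mean of the 10 %
largest to 1, with clipping to [0, 1]; a constant feature maps to 0.5.
This is computed once over all 2-s segments of the recording, matching
the offline per-subject scope, and bounds can be exported/imported as CSV
to re-score reproducibly or to calibrate a streaming session.

Two consequences matter in practice. First, clipping makes roughly the
bottom 5 % of every feature exactly 0, so index denominators are floored
at ε = 1e-6 (denominators only, never numerators). Second, the scaling is
distributional: it assumes the recording samples all stages, as a
24-h session does. On short recordings missing a stage entirely (e.g. no
REM), the extreme deciles anchor on the wrong stages and accuracy
degrades — this is a property of per-recording calibration, not of the
tree; use stored bounds from a representative session in that case.

## Indexes and decision tree

Indexes are computed per segment from the normalized features and
averaged over the five segments of the epoch (part 1 of the tree uses
epoch means; part 2 counts per-segment comparisons, which is why
per-segment computation is the single code path). `Index_1` is
definitionally `Index_W` and is stored as an alias. ΣEEG excludes EEG_lo,
exactly as the index definitions state.

The tree evaluates, in order: (1) artifact —
`Index_A/(Index_N+Index_R+Index_A) > 0.9` scores the epoch wake and sets
an artifact flag (the flag is kept in the hypnogram rather than
discarded); then the condition W/N/R by argmax of the three epoch-mean
indexes, exact ties resolved W > N > R (wake is the conservative default
for ambiguous epochs); then per condition: W → (2) low-band ratio > 0.5
in ≥ 1 segment ⇒ W, (3) `Index_1 > Index_2` in all 5 segments ⇒ W else
NREM1; N → (4) low-band ratio > 0.5 in ≥ 2 segments ⇒ W,
(5) `Index_3 > Index_4` in ≥ 3 segments ⇒ TS, (6) δ-ratio > 0.5 in ≥ 3
segments ⇒ NREM2 else NREM1; R → (7) α-ratio > 0.3 in ≥ 1 segment ⇒ TS
else REM. All comparisons are strict, so values exactly at a threshold
fall to the else branch. Every constant is exposed in `TreeConfig`.

The band-power-ratio tests (points 2, 4, 6, 7) intentionally use the
*raw* ratios: the δ-ratio cut at 0.5 is the literal "slow waves occupy
more than half the epoch" criterion and the fixed constants only make
sense on the physical [0, 1] scale, whereas per-recording normalization
would turn them into relative ranks. The index comparisons use
normalized features throughout.

## Agreement statistics

Rows of a confusion matrix are the reference (expert-consensus) labels,
columns the automatic labels. Overall agreement is 100·trace/total;
Cohen's κ uses the margin-product chance term; per-stage SE/SP/PPV/NPV
are one-vs-rest percentages. `stage_metrics` takes an explicit
`reference_axis` because the published validation tables for this scorer
compute SE/SP with the automatic *column* totals as the condition (their
wake SE is the wake diagonal over the wake column total, and the
row-based value appears as their PPV); `"columns"` reproduces those
tables, `"rows"` is the conventional default. Zero-denominator statistics
are NaN, never 0 or 100. Per-subject summaries use the sample (n−1)
standard deviation. κ bands follow Landis & Koch, with gap values (e.g.
0.205) assigned by their 2-dp rounding; display rounding is
half-away-from-zero. Consensus filtering keeps only epochs both experts
labeled identically. Collapsing NREM1/NREM2/TS to NREM can only merge
disagreements, so three-stage agreement is never below five-stage.

The published 20-rat / 168,656-epoch validation tables ship as CSVs in
`ratsleep.data`. The three-stage matrix is the exact collapse of the
five-stage one; one printed cell (REM row, NREM column) is inconsistent
with its own margins in the original and is stored as the
margin-consistent value (390).

## Synthetic generator

The generator exists to make every stage of the pipeline testable with
known ground truth; it emulates the five stage *signatures*, not real rat
EEG. Stage sequences come from a per-epoch Markov chain wired
W↔NREM1↔NREM2→TS→REM→W with self-transition 0.8, giving bout structure
with a stationary mix of all five stages. Signals are synthesized per
epoch, deterministically from a seed.

Design choices, and why:

* **Harmonic band activities.** Slow-wave, theta and spindle activity are
  random-phase Gaussian harmonic series on the 0.5-Hz analysis grid,
  rescaled to a target rms. Filling the band is essential under the
  mean-of-dB feature (a lone sinusoid occupies one bin and is diluted
  ~10–20× by the band's floor bins); staying *on the grid* is equally
  essential, because the rectangular window smears off-grid or
  filtered-noise components well above the noise floor of neighboring
  bands (a realistic 85-µV-rms slow-wave band raises the theta feature by
  >20 dB through leakage alone, which corrupts the REM/TS signature).
  Duty cycles and spindle bursts are segment-aligned (bursts last one 2-s
  segment, within the 1–3-s range described for rat spindles) for the
  same reason.
* **Default recipes** (rms amplitudes, µV): wake = 5 theta + 15 broadband
  background, EMG 80; NREM1 = 42 delta over 40 % of the epoch + two 28
  spindle bursts, EMG 25; NREM2 = 85 delta over 80 %, EMG 15; TS = 28
  theta + three 42 spindle bursts, EMG 10; REM = 28 theta on a 7-µV
  background, EMG 3. The EMG ladder is strictly ordered W > N1 > N2 >
  TS > R; NREM2's slow waves are twice NREM1's in amplitude and duty;
  wake's background is the largest (movement plus high-frequency
  activity) while its theta stays low-amplitude; REM's background sits
  slightly above the NREM floor, reflecting its desynchronized,
  wake-like EEG. Both NREM stages carry faint (1.5 µV rms) slow-wave and
  spindle-band backgrounds: sleeping cortex is never spectrally flat, and
  without them the normalized δ/α of NREM segments clip to exactly 0 and
  the ε-floored `Index_W`/`Index_R` denominators explode in the wrong
  stages. All amplitudes are free parameters of the recipes and are
  tunable per stage.
* **Noise model.** Backgrounds are Gaussian and white; real EEG has a 1/f
  spectrum, within-stage nonstationarity, electrode drift and line
  interference, none of which are modeled. Passing the recovery tests
  therefore demonstrates the internal consistency of the
  feature→index→tree chain under the stage definitions — not performance
  on real recordings, which only a validation against expert-scored data
  can establish.

On 600-epoch default recordings the scorer recovers 95–98 % of five-stage
labels and 96–99 % of three-stage labels across seeds, and accuracy
degrades monotonically as the background noise is scaled ×2 and ×4
(`scale_noise`). These numbers are recomputed by
`scripts/acceptance.py` and the test suite, at the 600/300-epoch problem
sizes used there.

## Numerical choices and degenerate inputs

* dB floor 1e-12 µV² (−120 dB); index-denominator floor ε = 1e-6 applied
  after normalization, denominators only.
* Degenerate normalization bounds (constant feature) map to 0.5, keeping
  downstream denominators defined without biasing any stage.
* Distribution distance is defined as 0 for identical point masses
  (its ratio is 0/0 there) and whenever the spread term exceeds the mean
  gap; it is symmetric and lies in [0, 1].
* The threshold formula uses sample (n−1) standard deviations; a
  single-value decile contributes sd 0.
* Decile size is ⌈0.1·n⌉ with a minimum of 1, so tiny series fall back to
  plain min/max.
* EDF I/O quantizes to 16 bits over ±1000 µV (EEG) / ±500 µV (EMG),
  spanning typical rat amplitudes with headroom; CSV signal files are
  exact decimal text with rates in a YAML sidecar. Reading never
  resamples. EDF cannot represent ragged channels, so unequal durations
  are zero-padded to whole records on write and validated (≤ one epoch
  mismatch) on read.
* Undefined statistics propagate as NaN markers, never as 0 or 100.

## Known limitations

* The scorer expects recordings whose stage mix populates both tails of
  every feature; per-recording normalization is unreliable on short or
  single-stage recordings (see Normalization).
* Epoch and segment lengths other than 10 s / 2 s are supported by the
  segmentation API but the tree's segment-count constants (≥1/≥2/≥3 of 5)
  assume five segments per epoch.
* One EEG lead is used; multi-lead montages must be reduced to a single
  configured channel at read time.
* No online/real-time scoring loop, no wavelet/entropy features, and no
  re-learning of the tree from labeled data.
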