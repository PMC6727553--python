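# ratsleep

Rule-based five-stage sleep scoring for rat EEG/EMG polysomnography.

Sleep studies in rat models — pain, psychiatric and neurological disease —
need every 10-s epoch of a day-long recording labeled as wake, NREM1
(light NREM), NREM2 (deep NREM), transition sleep (TS) or REM. Scoring by
eye takes an expert hours per recording; most automatic scorers stop at
the coarse wake/NREM/REM split and miss the NREM1↔NREM2 shifts that carry
the interesting pathology. `ratsleep` implements a transparent,
threshold-based scorer for the fine five-stage analysis that needs only
one EEG channel (nominally 200 Hz) and one EMG channel (nominally
500 Hz), plus the agreement statistics used to validate such scorers and
a seedable synthetic polysomnography generator so the whole pipeline can
be exercised without animal data.

## Method

Each 10-s epoch is split into five 2-s segments. Per segment, ten
features are computed: six mean band powers in dB on the 0.5-Hz FFT grid
— EEG_lo [0, 0.5), δ [0.5, 5), θ [6, 9), α [10.5, 15), β [22, 30),
γ [35, 45) Hz — three band-power ratios (EEG_lo, δ, α over total
[0, 30) Hz power), and the mean absolute amplitude of the 10–100 Hz
band-passed EMG. Features are normalized per recording by extreme-decile
scaling (mean of the 10 % smallest values ↦ 0, mean of the 10 % largest
↦ 1, clipped), which removes between-animal amplitude differences. From
the normalized features, stage indexes are formed per segment and
averaged per epoch:

    Index_W = EMG·γ/δ            Index_N = δ·α/γ²
    Index_R = θ³/(δ·α·EMG)       Index_A = ((2·EEG_lo)+β)·γ/ΣEEG
    Index_1 = Index_W            Index_2 = α·δ/θ
    Index_3 = θ·γ/δ              Index_4 = δ/θ      (ΣEEG = δ+θ+α+β+γ)

A two-part decision tree with seven testing points assigns the stage:
part 1 flags artifact epochs (Index_A/(Index_N+Index_R+Index_A) > 0.9,
scored wake) and otherwise picks the condition W/N/R by the largest
epoch-mean index; part 2 refines each condition using per-segment counts
— low-band ratio > 0.5 (≥ 1 segment under W, ≥ 2 under N) rescues
movement-corrupted wake, Index_1 > Index_2 in all five segments confirms
wake vs NREM1, Index_3 > Index_4 in ≥ 3 segments marks TS, δ-ratio > 0.5
in ≥ 3 segments marks NREM2 (slow waves over more than half the epoch),
and α-ratio > 0.3 in ≥ 1 segment separates TS from REM. Merging
NREM1/NREM2/TS yields the three-stage view. Agreement against expert
consensus is quantified by confusion matrices, per-stage SE/SP/PPV/NPV,
overall agreement and Cohen's κ with Landis–Koch interpretation.

## Worked example

Simulate a 600-epoch (100 min) recording with known ground truth, score
it, and evaluate the agreement:

```sh
$ ratsleep simulate --epochs 600 --seed 7 --out-signals sim600.edf --out-truth truth600.csv
simulated 600 epochs (W=101, N1=142, N2=206, TS=88, R=63)
$ ratsleep score --eeg sim600.edf --out auto600.csv
scored 600 epochs (W=96, N1=139, N2=203, TS=92, R=70; artifacts=0)
$ ratsleep evaluate --ref truth600.csv --test auto600.csv
     W   N1   N2  TS   R
W   96    0    0   0   5
N1   0  139    0   3   0
N2   0    0  203   1   2
TS   0    0    0  88   0
R    0    0    0   0  63
           se      sp     ppv     npv
stage
W       95.05  100.00  100.00   99.01
N1      97.89  100.00  100.00   99.35
N2      98.54  100.00  100.00   99.24
TS     100.00   99.22   95.65  100.00
R      100.00   98.70   90.00  100.00
overall agreement: 98.17%
kappa: 0.98 (excellent)
```

The confusion matrix has the ground truth on rows and the automatic
staging on columns; 98.17 % of epochs match, and κ = 0.98 means the
agreement is far beyond chance ("excellent" on the Landis–Koch scale).
The few mistakes sit on the physiologically adjacent boundaries
(W↔R, N1↔TS, N2↔R). The same workflow applies to real data: pass your
EDF (or CSV + sidecar YAML) recording to `ratsleep score`, and one or
two expert hypnograms to `ratsleep evaluate` (`--ref2` restricts
evaluation to expert-consensus epochs; `--collapse3` evaluates the
three-stage view).

The library mirrors the CLI: `ratsleep.score_recording` returns the
hypnogram plus a per-epoch decision trace, `ratsleep.synthetic` exposes
the generator, and `ratsleep.metrics` the agreement statistics.

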