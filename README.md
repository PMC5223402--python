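# iinfb — a closed-loop mu-rhythm neurofeedback engine

`iinfb` is a testable re-implementation of a real-time EEG neurofeedback
system for *imagined imitation* (simultaneous action observation + motor
imagery of a right-handed movement). It is aimed at BCI/neurofeedback
researchers who want to study, stress-test or extend the control logic of
such a system — difficulty titration, artifact gating, sham yoking —
without human subjects: a seeded virtual-subject simulator generates
EEG/EOG/EMG streams whose effect sizes are exactly controllable, and the
entire closed loop runs end to end on them.

## The computation at its core

Sensorimotor activity is quantified as event-related
(de)synchronization of the mu rhythm (7.5–14.5 Hz) at C3/CP3 (left,
contralateral) and C4/CP4 (right, ipsilateral). Every 500 ms tick the
engine estimates band power P(ch) with a rectangular-window FFT
periodogram (2-Hz bins; in-band centers 8, 10, 12, 14 Hz), smooths each
channel's power over the most recent 6 ticks (3 s), and computes the
feedback score

```
score = rw · log2(P(C4)/B(C4) + P(CP4)/B(CP4))
      − lw · log2(P(C3)/B(C3) + P(CP3)/B(CP3))
```

where B(ch) is the mean tick power over a fixed 15-s rest baseline and
(lw, rw) come from a 17-row difficulty table (levels −1…15): lw = 1
always, rw = 0 up to level 4, then +0.1 per level to 1.0 at level 14–15.
Contralateral ERD (left power down) raises the score; at higher levels
ipsilateral ERS (right power up) is rewarded too. Note the printed
sum-of-ratios form gives a rest-state expectation of rw − lw (i.e. −1
when rw = 0), not 0; the engine keeps this exactly as designed.

Each tick the score is compared with the level's thresholds: above the
upper threshold the 1–6 *video score* (color saturation of the feedback
video) rises by one, below the lower threshold it falls, and any change
freezes the score for 2 s. If either forearm EMG channel's rectified
500-ms mean exceeds its baseline mean by more than 2 SD, the video score
resets to 1. After each 50-s trial the video scores of the final 20 s
are averaged: mean > 4 promotes one difficulty level, mean < 2 demotes
(dropping below level 1 only after three consecutive trials there). A
sham participant is *yoked* to a real one: the recorded video-score and
level streams are replayed verbatim, and the sham's own EMG never
alters them.

A session is: 15-s baseline, then 3 blocks × 10 trials (50 s + 10 s
rest), then a transfer block of 10 × 20-s motor-imagery trials with
randomized 8–12-s rests. The offline pipeline re-preprocesses the raw
recording (0.5-Hz zero-phase high-pass, 60-Hz notch, DC correction,
EOG-triggered PCA), epochs by markers, drops feedback-task ticks with
excessive EMG, and exports per-tick log2 ERD/S values against
task-specific 4-s baselines as a tidy table ready for external
statistical modeling.

## Worked example

```python
from iinfb import SubjectProfile, simulate_closed_loop_session
from iinfb.offline import analyze_session, summarize_group_session

# a subject with 60% contralateral ERD that deepens 5% per rewarded trial
prof = SubjectProfile(contra_ratio_task=0.4, responsiveness=0.05, seed=7)
rec, log = simulate_closed_loop_session(prof)
print("final difficulty level:", log.final_level)
print(log.trials.head(4).to_string(index=False))

table, rejected = analyze_session(rec)
print("EMG-rejected fraction: %.3f" % rejected)
print(summarize_group_session(table).to_string(index=False))
```

prints

```
final difficulty level: 2
 block  trial  level_before  level_after  mean_video_score
     1      1             1            2             6.000
     1      2             2            1             1.000
     1      3             1            1             3.975
     1      4             1            2             4.750
EMG-rejected fraction: 0.014
group  session task hemisphere      mean       sd    n
  nfb        1   mi       left -2.164388 0.314337  400
  nfb        1   mi      right -0.039647 0.153852  400
  nfb        1  nfb       left -1.692362 0.378173 2957
  nfb        1  nfb      right  0.002309 0.143257 2957
```

The subject oscillates between levels 1 and 2 — at level 2 the score
thresholds ([−2, 2]) sit above what a 60% ERD can reach, so promotion
alternates with demotion, exactly the titration dynamic the threshold
table encodes. The offline summary recovers the programmed asymmetry:
strong negative log2 ERD/S on the left (the ERD deepened over the
session via `responsiveness`), none on the right.

The same functionality is exposed as a CLI:

```sh
iinfb simulate --seed 7 --out sess --format edf
iinfb run --mode sham --yoke sess.log.csv --seed 99 --out sham.csv
iinfb analyze sess.edf --out erds.csv
iinfb report erds.csv
```

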