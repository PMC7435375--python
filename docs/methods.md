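# Methods

This note records the model, the defaults and the judgement calls behind
`drowsemeter`, in enough detail that a maintainer can retune it or
disagree with it precisely.

## Data model

A stream is one row per video frame: a strictly increasing timestamp `t`
(seconds from stream start), optional continuous measurements (left/right
eyelid gap in image units, mouth aspect ratio `mar`), and/or binary state
flags (`left_closed`, `right_closed`, `mouth_open`). Frame indices are
never stored — real capture drops frames, so indices are derived from `t`
and the nominal frame rate. A validator enforces monotone timestamps and
non-negative measurements and warns when the median frame interval
deviates more than 20 % from the nominal rate. Rows with *no*
measurement at all are legal and flagged with a warning: they represent
frames where no face was detected, and all downstream stages treat them as
missing (calibration skips them; classification maps them to the
least-drowsy state so a dropped face never raises an alarm by itself).

## Landmark geometry

The eyelid gap is the mean of the two vertical upper-lid/lower-lid
landmark distances of an eye, not an area: the tracked markers (38/42,
39/41; 44/48, 45/47) define two vertical pairs per eye, which determine
distances, and the 20 % closed-eye ratio is dimensionally indifferent to
that choice. Averaging the two pairs rather than picking one is a choice;
it halves landmark jitter at the cost of slightly blurring partial
closures. An area variant (polygon over all six eye landmarks) would need
its own calibration references and is intentionally out of scope.

`mar` uses the inner-lip height markers (62/68, 63/67, 64/66, averaged)
over the inner corner distance (61–65), making it robust to lip thickness
and invariant under uniform scaling, hence camera distance.

Face detection and landmark localization are *backends*: any callable
`image -> (68, 2) array or None`. The built-in names ("haar", "hog")
lazily import OpenCV/dlib and their pretrained models; the package never
trains detectors. Only the largest detected face is processed
(single-driver assumption). Optional frame down-scaling before detection
is exposed (`rescale`) with coordinates mapped back to the original
resolution; it defaults to off.

## Calibration

Parameters, with defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `calibration_duration_s` | 60 s | setup window length |
| `top_fraction` | 0.05 | fraction of largest values averaged |
| `eye_closed_ratio` | 0.2 | closed-eye threshold as a fraction of the open reference |
| `mar_open_threshold` | 0.7 | absolute open-mouth mar threshold (strict >) |
| `eye_combine` | `all` | how per-eye flags merge into "eyes closed" |

The top-k count is `ceil(top_fraction × N)` with N the number of usable
frames; the estimator is an order statistic plus a mean, hence
permutation-invariant and deterministic, and scales linearly with the
measurement gain (so camera distance cancels out of classification).
Averaging only the top 5 % deliberately overestimates the typical open
gap — the frames with the widest opening — which is the intent: the
reference should represent fully open eyes, not the average over blinks.

"Eyes closed" requires **both** eyes below threshold by default: winks and
single-eye landmark glitches are the dominant false-closure mode, and a
genuine closure almost always affects both eyes. `any` is available in
the profile for setups where one eye is frequently occluded.

The mouth threshold defaults to the fixed 0.7 aspect ratio; a relative
mode (`mar_mode: relative`, threshold = `mar_open_ratio ×` calibrated
open-mouth reference) exists for drivers whose resting mar sits unusually
high or low, but is off by default because the absolute ratio is the only
committed constant in the underlying method.

## Indicators

Window geometry: length 60 s, stride 1 s, both configurable. The window
ending at emission time `t` contains the frames whose coverage interval
(frame start to start + one frame period) ends in `(t − 60, t]`; with
stride = window the windows partition time exactly. The first emission is
at `t = 60 s` — the definitions presuppose a full window, so there is no
partial-window warm-up output.

Durations are run-length × nominal frame period ("frames" mode), matching
fixed-fps frame-count arithmetic; a "timestamps" mode measures runs by
timestamp differences for irregular streams. In frames mode the interval
means are computed from integer frame totals (`total_frames × period /
count`), which makes the results independent of summation order and
exactly reproducible against a reference implementation.

Conventions on degenerate windows: intervals straddling a window edge are
clipped to their in-window part (every window is self-contained, and
ECD ≤ window length becomes provable); ECD = 0 when there is no closed
interval and AOT = 0 when there is no yawn (the defining ratios are 0/0
there, and "no events" must map to the least-drowsy value). A yawn is a
mouth-open run strictly longer than `yawn_min_s = 3 s`, contributing its
duration *minus* those 3 s. ECD uses **all** closed intervals, blinks
included; no minimum-duration floor is applied, because the blink-rate
sensitivity this introduces is exactly what combining PERCLOS with ECD in
the inference stage is meant to absorb.

## Fuzzy inference

Inputs are clamped to their universes, fuzzified through trapezoidal
Low/Medium/High terms, combined with `min` (AND and implication),
aggregated with `max`, and defuzzified by minimum-of-maximum over
singleton outputs (0, 0.5, 1 on a normalized drowsiness scale — only the
ordering matters for the label). Min-of-max with singletons means: among
the output terms attaining the maximal aggregated degree, the smallest
singleton wins; ties therefore resolve toward the *less* severe level,
which is the conservative direction for an alarm device and is exercised
explicitly in the tests.

Default membership breakpoints (tunable defaults, not measured
constants — the YAML config is the contract):

| variable | universe | Low | Medium | High | crossovers |
| --- | --- | --- | --- | --- | --- |
| PERCLOS | [0, 1] | (0, 0, .10, .20) | (.10, .20, .25, .35) | (.25, .35, 1, 1) | 0.15, 0.30 |
| ECD (s) | [0, 60] | (0, 0, 0.5, 1.5) | (0.5, 1.5, 3, 5) | (3, 5, 60, 60) | 1, 4 |
| AOT (s) | [0, 60] | (0, 0, 1, 3) | (1, 3, 5, 7) | (5, 7, 60, 60) | 2, 6 |

The PERCLOS crossovers bracket the 0.15–0.4 range of drowsiness
thresholds reported across the PERCLOS literature; the ECD and AOT
crossovers were chosen so that ordinary blinking (~0.2 s closures) and
short mouth openings sit deep in Low while multi-second closures and
genuine yawns reach Medium/High.

The 27-rule table is anchored by five semantic constraints — all-Low is
Normal; a single eye indicator at High yields Drowsy; two eye indicators
at Medium yield Drowsy; AOT High plus any other indicator at Medium
yields Drowsy; AOT High alone stays Normal — and completed by taking the
smallest output consistent with those anchors and with monotonicity
(raising any antecedent never lowers the conclusion). Under that
completion, Severe requires both eye indicators High, or one High and the
other Medium with AOT High. Totality, monotonicity and singleton ordering
are validated whenever a config is loaded, and the shipped YAML marks
anchored vs completed rows. Inference is stateless per second (no
hysteresis); an optional debounce exists in the alarm hook
(`alarm_events`), off by default.

## Simulator

Each regime is three independent renewal processes: blinks (exponential
durations), sustained closures and yawns (gamma durations, shape
configurable — higher shape = narrower spread). Within a process, the gap
from the end of one event to the start of the next is exponential with
mean `60/rate − mean_duration` (floored at a 0.2 s refractory time), so a
single process's long-run closed fraction is exactly
`rate × mean_duration / 60`; independent processes combine as a union,
`1 − Π(1 − f_i)`, which is what `expected_perclos` returns. Every process
starts each segment in its stationary state (equilibrium residual via
length-biased sampling), so the closed fraction holds from the first
frame rather than ramping up over one inter-event gap. A single seeded
PCG64 generator drives all draws in a fixed order, making runs exactly
reproducible.

Regime presets (presets of this package, chosen once so that each
regime's renewal-theory means land inside the intended fuzzy terms):

| regime | blinks | sustained closures | yawns | implied PERCLOS / ECD |
| --- | --- | --- | --- | --- |
| Normal | 15/min × 0.2 s | — | — | 0.05 / 0.2 s (Low/Low) |
| Drowsy | 1/min × 0.3 s | 6/min × 2.7 s (shape 6) | 0.5/min × 6 s | 0.27 / ~2.4 s (Medium/Medium) |
| Severe | — | 1.5/min × 38 s (shape 8) | 1/min × 10 s | 0.95 / ~tens of s (High/High) |

The Drowsy preset drops most reflex blinks deliberately: ECD is a mean
over *all* closed intervals, so a drowsy regime whose interval population
is dominated by 0.2 s blinks would sit in ECD-Low no matter how long its
sustained closures are. Slow, long closures with rare blinks are both the
more faithful picture of drowsy oculomotor behaviour and the
configuration whose window statistics are stable. The Severe preset is a
near-continuous closure (~95 % closed, ~2 s re-openings), i.e. sustained
microsleeps.

`render_continuous` turns binary tracks into continuous signals: open
frames at the profile's open reference, closed frames at 10 % of it
(within the 5–15 % a closed eyelid leaves), mouth at 1.0 / 0.3 around the
0.7 threshold, plus optional Gaussian noise scaled by the reference. With
zero noise, classification with the generating profile recovers the
binary track exactly — the property the round-trip tests pin down.

What the simulator does *not* model: landmark jitter correlated over
time, occlusion, illumination changes, head pose, or physiological sleep
dynamics. Passing tests on simulated streams validate the
indicator/fuzzy/evaluation chain, not the vision frontend.

## Evaluation protocol

Ground truth is a per-second label track with segment ids. Each segment's
prediction is the majority vote of the per-second output states within
its span `(start, end]`, with ties broken toward the more severe label —
the fail-safe direction, since over-alarming is cheaper than missing a
drowsy driver. The summary is a 3×3 confusion matrix (rows truth) with
per-class and total accuracy.

The packaged end-to-end experiment uses 200 one-minute segments in
100/60/40 (Normal/Drowsy/Severe) proportions, arranged as four drive-like
sessions that each progress Normal (25 min) → Drowsy (15 min) → Severe
(10 min), emulating alertness degrading over a drive. With a one-minute
window, the first segment after each regime change is scored against a
window still dominated by the previous regime; those boundary segments
are the expected error mode (typically the first Drowsy and the first
Normal segment of a session), and the observed total accuracy of the
default configuration sits around 95 % with Severe segments recovered in
full. Problem sizes throughout (30-minute stationary runs for the
expectation check, 200 segments ≈ 3.3 h of stream for the end-to-end
experiment) were chosen as the smallest that make the statistical checks
sharp.

## Known limitations

* The eyelid-gap measure is in image units; large head-pose changes alter
  it and are not compensated (no head-pose estimation).
* Calibration is one-shot at startup; no rolling recalibration for
  lighting or posture drift.
* ECD's sensitivity to the interval *count* makes the system slow to
  recognize a Drowsy→Severe transition when the preceding minute contained
  many short closures; with the default 60 s window the output lags a
  regime change by up to ~30 s.
* The FIS breakpoints are defaults to be tuned per deployment; nothing in
  the package fits them to data.
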