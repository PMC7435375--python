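# drowsemeter

Fuzzy driver-drowsiness estimation from facial-state time series.

Camera-based drowsiness monitors watch a driver's eyes and mouth and raise
an alarm before a microsleep does damage. `drowsemeter` implements the
processing chain of such a monitor as a reusable, testable Python library:
everything between per-frame facial measurements and the per-second
drowsiness verdict, including a synthetic-data generator so the whole chain
can be exercised without a camera or dataset.

## The method

Per frame, the eye state is reduced to a binary *closed* flag and the mouth
to a binary *open* flag:

* an eye is **closed** when its eyelid gap (mean vertical distance between
  the upper/lower-lid landmark pairs of the 68-point iBUG convention —
  pairs 38/42 + 39/41 for the right eye, 44/48 + 45/47 for the left) falls
  below 20 % of that driver's *open-eye reference*;
* the mouth is **open** when its aspect ratio `mar = Height/Width`
  (inner-lip landmarks 62–64 / 66–68 over corners 61/65) exceeds 0.7.

The open-eye (and open-mouth) references are personal: during a one-minute
setup the system records the eyelid gaps and mar of the driver — 1800
values per signal at 30 fps — and averages the largest 5 % of each.

Over a sliding one-minute window, re-evaluated each second, three
complementary indicators are computed from the binary tracks:

* **PERCLOS** `= (1/n) Σ frame[j]` — fraction of window frames with the
  eyes closed;
* **ECD** `= (1/p) Σ Duration[j]` — mean duration of the eyes-closed
  intervals in the window (0 if none);
* **AOT** `= (1/N_y) Σ t_j` — mean yawn duration, a yawn being a
  mouth-open run longer than 3 s, counted only past those first 3 s
  (0 if none).

A Mamdani fuzzy inference system maps `(PERCLOS, ECD, AOT)` to one of
three drowsiness levels — **Normal**, **Drowsy**, **Severe** — using
Low/Medium/High trapezoidal terms per input, a monotone 27-rule table,
`min` for AND/implication, `max` for aggregation, and minimum-of-maximum
defuzzification over singleton outputs. The rule table lets the eye
indicators carry the signal and uses yawning only as corroboration (AOT
High alone stays Normal, so conversation or singing cannot trigger an
alarm).

## Worked example

Simulate a 5-minute drive that degrades from alert to severe drowsiness,
calibrate on it, and run the chain (all via the `drowsemeter` CLI; each
stage is also a library call):

```bash
$ python -c "import yaml; yaml.safe_dump([['Normal',120.],['Drowsy',120.],['Severe',60.]], open('plan.yaml','w'))"
$ drowsemeter simulate --plan plan.yaml --seed 7 --continuous --noise-sd 0.03 \
      --out stream.csv --truth truth.csv
9000 frames written to stream.csv
$ drowsemeter calibrate --input stream.csv --out profile.yaml
profile written to profile.yaml (refs L=10.56 R=10.62)
$ drowsemeter binarize --input stream.csv --profile profile.yaml --out binary.csv
$ drowsemeter indicators --input binary.csv --out indicators.csv
241 indicator samples written to indicators.csv
$ drowsemeter infer --indicators indicators.csv --out levels.csv
$ drowsemeter evaluate --levels levels.csv --truth truth.csv
truth \ pred   Normal   Drowsy   Severe
      Normal        1        0        0
      Drowsy        0        1        0
      Severe        0        0        1
total accuracy 100.0% (Normal=100.0% Drowsy=100.0% Severe=100.0%)
```

`stream.csv` holds the noisy per-frame eyelid gaps and mar; `profile.yaml`
the calibrated open-eye references (the true open gap was 10, recovered as
~10.6 from the top-5 % average of noisy values); `levels.csv` one row per
second from t = 60 s (the first full window) with the label, the three
aggregated membership degrees, and the indicator values, e.g.

```
t,label,state,crisp,deg_low,deg_medium,deg_high,perclos,ecd,aot
60,Low,Normal,0,1,0,0,0.0444,0.2051,0
```

The per-second states track the script with the expected ~half-window lag
at each transition: Normal until t = 161, Drowsy until t = 253, Severe
afterwards. The confusion matrix scores one majority-vote label per
scripted segment (ties toward the severer label).

## Layout

| module | role |
| --- | --- |
| `drowsemeter.stream` | per-frame facial-state data model, CSV/JSONL I/O |
| `drowsemeter.landmarks` | 68-point geometry (eyelid gap, mar), pluggable detectors |
| `drowsemeter.calibration` | one-minute personalized thresholds, frame classifier |
| `drowsemeter.indicators` | sliding-window PERCLOS / ECD / AOT |
| `drowsemeter.fuzzy` | Mamdani FIS, config validation and YAML I/O |
| `drowsemeter.simulate` | renewal-process blink/closure/yawn generator |
| `drowsemeter.evaluate` | segment majority vote, confusion summary |
| `drowsemeter.pipeline` / `drowsemeter.cli` | end-to-end chain and CLI |

See `docs/methods.md` for the modelling choices, defaults and limitations.
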