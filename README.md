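# limbwear

Free-living analytics for upper-limb prosthesis use from two body-worn
sensors: a tri-axial accelerometer mounted at the **prosthetic wrist** and an
activity monitor worn on the **thigh**.

Clinicians and rehabilitation researchers fitting upper-limb prostheses
rarely know what happens after the clinic visit: how many hours a day the
prosthesis is actually worn, whether it is put on to go out into the
community, and how activity is distributed around donning and doffing.
`limbwear` turns the two raw sensor streams into exactly those outcomes:

1. **Activity-count emulation** (`limbwear.counts`) — the raw wrist signal
   (50 Hz, ±16 g) is converted into legacy "activity counts":
   per axis, resample to 30 Hz → band-pass (0.29–1.66 Hz movement band) →
   decimate to 10 Hz → clip at ±2.13 g → rectify → 0.068 g dead-band →
   quantize at 0.0164 g → accumulate into 60-s epochs, then combine into a
   resultant vector magnitude `vm = √(cx² + cy² + cz²)`.
2. **Wear detection** (`limbwear.wear`) — a run-length non-wear rule on `vm`:
   an epoch is *doffed* when it lies in a window ≥ 60 min long of `vm ≤ 0`
   epochs, allowing up to 2 non-adjacent artefactual epochs with `vm ≤ 100`.
   Since the sensor sits on the prosthesis, sensor non-wear is prosthesis
   non-wear.  Worn↔doffed transitions are the **don/doff events**, and wear
   hours are summarised per midnight-to-midnight day.
3. **Behaviour analysis** (`limbwear.behaviour`) — the thigh monitor's
   per-minute activity table (seconds of sedentary / upright / stepping /
   cycling / primary lying / secondary lying / seated transport / non-wear,
   plus steps) yields dominant epoch labels, continuous stepping bouts,
   sleep periods, and **transition events**: stepping continuously for
   more than 60 s (or more than 25 s in a straight line when heading data
   exist) — behaviour unlikely inside a home.  The first transition after
   the morning sleep marks leaving home, the last before the evening sleep
   marks returning; intermediate transitions toggle home↔away.  Days with
   more than 20 h of monitor data count as valid.
4. **Stream fusion** (`limbwear.fusion`) — both streams are aligned on one
   clock and stepping is counted in the 30-min windows before and after
   every don and doff event, then averaged per cohort group and phase.
5. **Synthetic cohorts** (`limbwear.synthetic_data`) — a seeded generator
   produces truth schedules (sleep, excursions bounded by transition walks,
   wear intervals with don-at-departure structure) and renders both sensor
   streams from them, so the entire pipeline is testable against known
   ground truth without any recorded data.

## Worked example

```python
import limbwear as lw

cfg = lw.CohortConfig(n_participants=2, n_days=2, seed=3)
truth = lw.simulate_truth(cfg)[0]       # an experienced prosthesis user
wrist = lw.render_wrist(truth, cfg)     # 50 Hz RawTriaxialRecording
thigh = lw.render_thigh(truth, cfg)     # per-minute BehaviourEpochTable

res = lw.run_participant(wrist, thigh)
print(res.daily_wear[["date", "worn_hours", "observed_hours"]])
print([(e.kind, str(e.time)) for e in res.events[:4]])
print([(str(d.date.date()), round(d.away_hours, 2), d.valid) for d in res.participation])
```

prints

```
        date  worn_hours  observed_hours
0 2025-03-03   10.533333            24.0
1 2025-03-04   10.000000            24.0
[('don', '2025-03-03 06:49:00'), ('doff', '2025-03-03 07:44:00'), ('don', '2025-03-03 08:58:00'), ('doff', '2025-03-03 12:12:00')]
[('2025-03-03', 4.88, True), ('2025-03-04', nan, True)]
```

— the participant wore the prosthesis ~10 h on each fully observed day
across several wear blocks (first don 06:49), and spent 4.9 h away from home
on the first day.  The second day reports `nan` away hours because the
recording ends at midnight, so no complete evening sleep period exists to
anchor the returning-home rule — the day is excluded rather than guessed.

A CLI mirrors the stages: `limbwear simulate`, `limbwear ingest`,
`limbwear counts`, `limbwear wear`, `limbwear homeaway`, `limbwear fuse`
(`limbwear --help` for options).

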