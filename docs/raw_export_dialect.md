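# Raw-export JSON dialect

One directory per participant, containing five JSON files. All timestamps on
disk are **local clock time** (`YYYY-MM-DDTHH:MM:SS`); the participant's fixed
UTC offset is recorded in `meta.json` as `tz_offset_minutes`. Files are
written with sorted keys and compact separators, so serialization is
byte-deterministic.

```
<participant_id>/
  meta.json
  heart_rate.json
  steps.json
  sleep.json
  summaries.json
```

## meta.json

```json
{
  "participant_id": "wc-ao-000",
  "group": "acute-orthopedic",
  "device_profile": "inspire2",
  "tz_offset_minutes": 0,
  "sync_events": ["2024-03-06T20:00:00", "..."],
  "clip_mode_days": ["2024-03-09"],
  "acceptability": {
    "comfort": 8.5, "burden": 1.0, "sleep_disturbance": null,
    "adverse_reaction": false, "adverse_text": null
  }
}
```

`acceptability` may be `null`. `clip_mode_days` lists local calendar days on
which the device was carried in clip mode (heart rate and sleep suppressed).

## heart_rate.json / steps.json

A map from local calendar day to an intraday array at 1-minute steps. Only
minutes carrying a sample appear; a worn sedentary minute appears in
`steps.json` with `"value": 0`, while an unworn minute appears in neither
file. Absent-vs-zero is semantically load-bearing for wear inference.

```json
{"2024-03-04": [{"time": "09:41:00", "value": 72}, {"time": "09:42:00", "value": 74}]}
```

## sleep.json

An array of sleep logs. `levels` is a run-length encoding of 30-second stage
records; `seconds` is always a positive multiple of 30 and the runs tile
`[startTime, endTime)` exactly. Levels are `wake | light | deep | rem`.

```json
[
  {
    "startTime": "2024-03-04T23:12:00",
    "endTime": "2024-03-05T07:20:00",
    "levels": [
      {"dateTime": "2024-03-04T23:12:00", "level": "light", "seconds": 1800}
    ]
  }
]
```

## summaries.json

Device-side daily summaries, one per calendar day of the stream. These
survive on-device storage truncation even when the minute-level data for a
day has been discarded.

```json
[
  {"date": "2024-03-04", "totalSteps": 7790, "meanHeartRate": 84.8,
   "wornMinutes": 764, "sleepMinutes": 112}
]
```

## Parser guarantees

- malformed intraday entries and out-of-range values are dropped, with a
  logged count;
- duplicated timestamps are deduplicated keeping the **last** occurrence,
  with a logged count;
- out-of-order entries are sorted;
- overlapping sleep logs raise an error;
- a file that is not valid JSON raises an error naming the file and offset.
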