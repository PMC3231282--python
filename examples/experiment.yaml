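# Seven-day, three-animal experiment mirroring the default laboratory setup.
duration_days: 7.0
cadence_seconds: 5.0
lights_on: "07:00"
lights_off: "19:00"
video: ideal
seed: 1
out_dir: results/experiment
animals:
  - {uid: circle, home_burrow: 0, emergence_rate_dark: 2.0, speed_mean: 2.0}
  - {uid: triangle, home_burrow: 1, emergence_rate_dark: 1.5, speed_mean: 2.5}
  - {uid: triangle_outline, home_burrow: 2, emergence_rate_dark: 2.5, speed_mean: 1.6}
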