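# imupose

Low-cost multi-IMU motion capture and operation-posture recognition,
end to end and fully synthetic:

* **synth** — scripted posture sessions (seven operation-posture classes
  defined by torso/hip/knee bend-angle ranges) and a forward sensor model
  that turns skeletal motion into noisy six-tracker IMU streams
  (accelerometer noise 300 µg/√Hz, gyroscope 0.007 °/s/√Hz at 100 Hz).
* **signal** — per-channel scalar Kalman smoothing, strapdown integration
  (quaternion dead reckoning plus trapezoid velocity/displacement), and
  heading-only drift compensation.
* **skeleton** — anthropometric joint hierarchy from subject stature,
  two-pose (upright + skiing) mounting calibration, forward kinematics,
  posture-angle extraction, a rule-based posture labeler, and BVH export.
* **dataset** — 36 features per frame (six tracked joints × cumulative
  XYZ displacement + yaw/pitch/roll), label-pure sliding windows
  (length 50, stride 5), seeded 4:1 train/test split.
* **classify** — a NumPy BiLSTM recognizer (64 hidden units per direction,
  dropout 0.5, Adam at 0.001, 10 epochs, batch 32, L2 1e-4) with a
  unidirectional LSTM baseline and a 5-repeat evaluation suite
  (accuracy, per-class precision/recall/F-score, summed confusion matrix).
  No deep-learning framework is required: forward and
  backpropagation-through-time are implemented directly on BLAS.

The trackers are worn on the chest, waist, and above both knees and ankles,
with the sensor Y axis pointing to the ground and Z forward; the world frame
is fixed to the upright calibration pose (Y down, Z forward, X right).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` trains the full-protocol recognizer (5 BiLSTM
repeats + 5 LSTM baseline repeats on ~15k windows) and takes ~10 minutes on
one CPU; the rest of the suite runs in well under a minute.

## CLI

```bash
# full pipeline with the default session protocol
imupose run-all --out out/ --baseline

# or stage by stage
imupose synth --seed 20240686 --out session/
imupose process --in session/ --out states/
imupose dataset --states states/ --labels session/labels.csv --out ds.h5
imupose classify --dataset ds.h5 --out model/ --repeats 5
```

Every stage is seeded; `run-all` stamps artifacts with a config hash and
writes `eval_report.json`, `confusion.csv`, and a BVH motion excerpt.
A YAML config (see `imupose run-all --config`) can override any pipeline
value, including a custom session script (`script_tasks`).

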