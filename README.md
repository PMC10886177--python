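# ergoskel

Repair of missing and misidentified skeletons in 2D pose sequences, with
REBA (Rapid Entire Body Assessment) ergonomic risk scoring. Built for
caregiving-task footage processed by OpenPose-style pose estimators, where
overlapping bodies produce dropped keypoints and limbs latched onto the
wrong person.

The pipeline over BODY_25 (25-keypoint) skeleton sequences:

1. **Discriminate** — classify every frame as *complete*, *missing*, or
   *misidentified*. Misidentification is detected through the temporal
   kinematic chain: the Gram matrix of the bone-vector matrix carries
   squared bone lengths on its diagonal and is invariant to rigid motion,
   so relative changes in squared bone length against the last trusted
   frame are a pose-independent corruption signal. Per-frame action-label
   weights add a second evidence channel (a frame whose label disagrees
   with the >60%-dominant label of its ±10-frame window is heterogeneous).
2. **Compensate** — fill missing keypoints by linear interpolation between
   the nearest complete anchor frames within a ±10-frame traversal span.
3. **Correct** — rewrite misidentified frames to the dominant action label
   and re-synthesize the implicated keypoints from same-labelled anchor
   frames; then Kalman-smooth every keypoint trajectory (constant-state
   scalar filter per coordinate).
4. **Score** — eight joint angles per frame (trunk, neck, per-side legs,
   upper and lower arms; the wrist is held constant) fed through the
   published REBA tables (A/B/C, load, coupling, activity) to a 1–15 score
   and risk level.
5. **Evaluate** — per-joint angle MAE, REBA accuracy, and per-joint
   missing / overall misidentification rates.

A synthetic-data module generates ground-truth 25-keypoint motion at 50 Hz
with constant bone lengths (forward kinematics over joint-angle scripts),
plus seeded injection of missing-keypoint bursts and bone-length-violating
misidentification events with the truth retained — so the whole pipeline is
testable without any external data. Action weights can come from the
bundled deterministic mock classifier, an external `actions.json`, or a
miniature spatial-temporal graph-convolutional classifier (pure numpy,
trainable on a CPU in seconds).

## CLI

```sh
# generate a corrupted synthetic fixture (+ truth/actions/labels sidecars)
ergoskel simulate --out poses.json --frames 1000 --seed 0

# full pipeline: discriminate -> compensate -> correct -> score
ergoskel run --in poses.json --weights poses_actions.json --out-dir out/

# or stage by stage
ergoskel discriminate --in poses.json --weights poses_actions.json --out reports.csv
ergoskel compensate --in poses.json --out poses_fixed.json --max-span 10
ergoskel correct --in poses_fixed.json --weights poses_actions.json --out poses_final.json
ergoskel score --in poses_final.json --out scores.csv
ergoskel evaluate --scores scores.csv --truth truth_scores.csv --out eval.csv
```

Pose files use the OpenPose BODY_25 JSON dialect (a `people` array with a
flat 75-value `pose_keypoints_2d` list per frame). Configuration (all
thresholds, spans, Kalman parameters, REBA modifiers, seed) is a TOML or
JSON file passed via `--config`; every run echoes it into a
`run_manifest.json` for provenance.

Manual REBA modifiers (load, coupling, activity, twist/abduction flags)
live in the `[reba]` config section — they cannot be inferred from a 2D
skeleton.

## Library

```python
from ergoskel import synthetic, run_pipeline, PipelineConfig

fx = synthetic.default_fixture(seed=0, n_frames=1000)
result = run_pipeline(fx["corrupted"], fx["weights"], PipelineConfig())
print(result.summary)
result.scores.head()   # per-frame angles, per-joint scores, final REBA, risk
```

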