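# faceval

Validation toolkit for 3D face models: given a reference face scan and a
test reconstruction (triangulated meshes in mm plus named anatomical
landmarks), `faceval` rigidly registers the pair in two steps (4-landmark
seeding, then best-fit point-to-surface ICP), builds the tragion-based
anatomical coordinate frame, computes signed surface-deviation fields and
region-wise RMSE, decomposes per-landmark errors along the anatomical
axes, evaluates 12 standard soft-tissue linear/angular measurements, and
provides the accompanying agreement statistics (paired t, two-way
absolute-agreement average-measures ICC, Bland–Altman with CIs, and exact
noncentral-t sample-size calculation for paired designs).

Because real patient scans are rarely shareable, the package ships a
first-class synthetic data module: smooth face-like height-field meshes
with all landmarks placed at analytically defined surface points, plus a
deformation generator (Gaussian radial-basis bumps, rigid misalignment,
sensor noise) whose ground-truth displacement field lets every pipeline
stage be checked against exact expected values.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks
(registration recovery on 20 synthetic faces, RMSE vs analytic ground
truth, exhaustive geometry oracles, statistics oracles, measurement
invariance); the rest are per-module unit and property tests.

## CLI

```sh
faceval simulate   --out-dir D --seed 1                 # synthetic pair + truth.csv
faceval register   --test t.obj --ref r.obj --test-lms t.json --ref-lms r.json --out transform.json
faceval deviate    --test t.obj --ref r.obj --lms-ref r.json --region facial \
                   --colormap map.ply --report report.json
faceval measure    --lms lms.json --out measurements.json
faceval reposition --front-lms front.json --lateral-lms lateral.json --out angles.json
faceval agreement  --ratings ratings.csv --out agree.json   # CSV: subject,rater,measurement,value
faceval samplesize --delta 0.42 --sd 0.68 --alpha 0.05 --power 0.80
faceval run        --config run.json                     # full pipeline
```

A pipeline config (`faceval run`) looks like:

```json
{
  "out_dir": "out",
  "seed": 1,
  "synthetic": {
    "face": {"resolution": 81},
    "deformation": {"kind": "study_like", "noise_sd": 0.05}
  },
  "regions": ["facial", "perioral"]
}
```

or replaces `"synthetic"` with the four real-input paths `test_mesh`,
`reference_mesh`, `test_landmarks`, `reference_landmarks`. The run writes
`transform.json`, `report.json` (region RMSE, landmark deviations, the 12
measurements for both models and their paired differences), `colormap.ply`
and a log; identical configs reproduce every artifact byte-identically.

## File formats

- Meshes: Wavefront OBJ (`v`/`f` records, 1-based indices, polygons
  fan-triangulated; coordinates written with 17 significant digits so
  round-trips are lossless).
- Color maps: ASCII PLY 1.0 with 8-bit vertex RGB.
- Landmarks: JSON `{"units": "mm", "landmarks": {"Prn": [x, y, z], ...}}`
  with names from a controlled vocabulary (see
  `faceval.LANDMARK_VOCABULARY`).

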