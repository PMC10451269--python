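# engagekit

Facial engagement measurement for robot-assisted autism therapy
sessions.

During robot-assisted therapy, a therapist scores each task of a
session on a behaviour sheet while a camera records the child's face.
`engagekit` implements the automated counterpart and the comparison
between the two raters:

* per-frame face detection and 68-point landmark extraction
  (iBUG-300W ordering), with a pluggable detector backend;
* a binary engagement model on Russell's circumplex of affect —
  a frame is engaged iff its valence v and arousal a satisfy
  v > 0 and a > 0;
* a convolutional frame classifier (conv 32·3×3 → ReLU → pool,
  conv 32·3×3 → ReLU → pool, conv 64·3×3 → ReLU → pool, flatten,
  2-way head) over rasterized, similarity-normalized landmarks;
* session metrics: per task
  `EPM = 100 · engaged frames / total frames` (model) and
  `EPT = 100 · sheet points / 24` (therapist, 8 items × 0–3 scale);
  per child the unweighted task mean rounded half-up;
* rater agreement: inclusive 50% binarization of both percentages and
  Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` with the conventional
  interpretation bands;
* a synthetic session generator (schematic faces with exact landmark,
  box and engagement ground truth) so the entire pipeline is testable
  without any recordings or model downloads.

See `docs/methods.md` for the model, the generator and every numerical
convention.

## Worked example

```bash
# 1. a labelled synthetic session: 3 tasks, 10 fps, zero landmark noise
engagekit simulate --out sess --seed 3

# 2. train the frame classifier on 2,000 synthetic frames, 5 epochs
engagekit train --out model.npz --seed 1

# 3. run the full pipeline on the session
engagekit analyze --session sess --model model.npz --out report.json
```

The train step reports `checkpoint model.npz: epoch 5 loss 0.0048
val_acc 1.000`, and `report.json` then contains (alongside the config
hash, seed and version):

```json
{
  "child_id": "C1",
  "task_metrics": [
    {"task_id": "task_1", "n_frames_total": 190, "n_frames_engaged": 86,
     "n_frames_no_face": 0, "epm_percent": 45.26, "policy": "count_not_engaged"},
    {"task_id": "task_2", "n_frames_total": 80, "n_frames_engaged": 17,
     "n_frames_no_face": 0, "epm_percent": 21.25, "policy": "count_not_engaged"},
    {"task_id": "task_3", "n_frames_total": 190, "n_frames_engaged": 87,
     "n_frames_no_face": 0, "epm_percent": 45.79, "policy": "count_not_engaged"}
  ],
  "overall_epm_percent": 37
}
```

`epm_percent` is the share of that task's frames classified engaged;
`overall_epm_percent` is the child's session value (task mean, rounded
half-up) that gets binarized at 50% for the agreement analysis.
`engagekit agree --report report.json … --assessment sess/assessment.csv …`
(one pair per child) then emits the kappa, the observed/expected
agreement and the interpretation band.

The packaged five-child published results table can be re-derived with

```bash
engagekit reproduce-table3
```

which recomputes each child's overall engagement from the per-task
percentages (84, 14, 41, 15, 9 — the 14 is a documented off-by-one of
the printed source, reconstructed as 13), binarizes model and therapist
values and reports κ = 1.0, band "almost_perfect".

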