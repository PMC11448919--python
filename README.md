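# dropsight

Analysis toolkit for micrographs of protein-crystallization drops.

Robotic imagers at macromolecular crystallography facilities photograph
thousands of sitting-drop vapour-diffusion experiments on a schedule,
producing far more images than scientists can inspect. Instance-segmentation
detectors can locate the drop and every crystal in such a micrograph, but a
detector alone is not a pipeline: its training data must be curated from
noisy LIMS scores and disagreeing expert labels, its masks must be turned
into actionable beamline coordinates, and its quality must be measured with
standard detection metrics. `dropsight` implements that non-neural machinery,
end to end, with a synthetic scene generator so everything is testable
without real images or trained weights:

- **`dropsight.synthetic`** — synthetic drop scenes (elliptical drop, convex
  polygonal crystals, noise) with exact ground-truth masks, LIMS-style
  inspection tables, simulated multi-expert label panels with tunable
  confusion matrices, and a mock detector with known corruption rates.
- **`dropsight.annotations`** — citizen-science (Zooniverse-dialect) CSV and
  COCO JSON conversion, polygon rasterization under an exact pixel-centre
  rule, tight bounding boxes, and micrograph preprocessing (integer
  downscale, then CLAHE with a 12×12 tile grid).
- **`dropsight.curation`** — dataset-construction rules: the ten-score →
  four-class outcome mapping (Clear / Precipitate / Other / Crystals),
  one-image-per-subwell de-duplication (second scored inspection), 80/20
  train/validation splits, inverse-frequency balancing weights, loss-ranked
  relabel flagging, balanced test-pool sampling, and unanimous/majority
  expert-consensus label sets.
- **`dropsight.targeting`** — detection post-processing: probability
  filtering (default ≥ 0.6), crystal centre-of-mass targets for data
  collection, and the compound-dispensing point for fragment soaking.
- **`dropsight.evaluation`** — precision/recall/F1 reports and COCO-style
  mAP (IoU sweep 0.50:0.05:0.95, size bins at 32² and 96² pixels, 101-point
  interpolated AP) for boxes and masks, plus the detection-to-classification
  collapse ("Crystals" iff ≥ 1 crystal detected).
- **`dropsight.pipeline` / `dropsight.cli`** — deterministic, manifest-logged
  orchestration and the `dropsight` command
  (`simulate`, `curate`, `target`, `evaluate classify|detect`,
  `convert zooniverse-to-coco`).

## The dispense-point algorithm

When soaking fragment libraries into grown crystals, a compound solution in
DMSO is acoustically dispensed into the drop. A high local DMSO concentration
damages crystals, so the dispense point should be far from every crystal and
from the drop edge. Given the detector's drop mask `D` and crystal masks
`C_1 … C_k`:

1. form the residual region `M = D \ (C_1 ∪ … ∪ C_k)`;
2. compute the exact Euclidean distance transform
   `EDT(M)(p) = min { ‖p − q‖ : q ∉ M }`, with pixels outside the image frame
   counting as background;
3. dispense at `argmax EDT(M)`, breaking ties by smallest row, then column.

The distance value at the chosen pixel is reported as the *clearance*. The
crystal data-collection targets are the mask centroids
`(x̄ + ½, ȳ + ½)` in pixel-centre coordinates.

Detection quality uses IoU `= |A ∩ B| / |A ∪ B|`, greedy score-ordered
matching at an IoU threshold, and classification quality uses
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`.

## Worked example

```python
from dropsight import SceneSpec, generate_scene, mock_predictor, make_targets
from dropsight.evaluation import mean_ap
from dropsight.synthetic import scene_annotations

spec = SceneSpec(crystal_count_range=(3, 3), seed=5)
scene = generate_scene(spec)
print(f"outcome score: {scene.outcome_score}")

detections = mock_predictor(scene, score_law=0.9, seed=0)
crystals, dispense = make_targets(detections, min_probability=0.6)
for t in crystals:
    print(f"crystal target: x={t.x:.2f}, y={t.y:.2f}, inside_mask={t.inside_mask}")
print(f"dispense point: x={dispense.x}, y={dispense.y}, clearance={dispense.clearance:.2f} px")

gt = {"scene": scene_annotations(scene, "scene")}
result = mean_ap(gt, {"scene": mock_predictor(scene, score_law=1.0, seed=0)}, geometry="mask")
print(f"mAP (mask, 0.50:0.05:0.95): {result.map_all:.3f}")
```

prints

```
outcome score: 9
crystal target: x=162.02, y=167.51, inside_mask=True
crystal target: x=59.50, y=129.50, inside_mask=True
crystal target: x=131.05, y=174.74, inside_mask=True
dispense point: x=185, y=102, clearance=65.52 px
mAP (mask, 0.50:0.05:0.95): 1.000
```

The scene holds three crystals, so its ten-point outcome score (9, "3D
Crystals") maps to the Crystals class. Each crystal yields a continuous
centroid target; the dispense point sits 65.5 px clear of every crystal and
of the drop edge. A detector that reproduces the ground truth exactly scores
mAP 1.0.

The same flows are available from the shell:

```bash
dropsight simulate --out bundle --n-scenes 5 --seed 1
dropsight curate --inspections bundle/inspections.csv \
    --panel bundle/expert_panel.csv --out curated
dropsight evaluate detect --ground-truth bundle/ground_truth.coco.json \
    --detections my_detections.json --out ap_table.csv
```

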