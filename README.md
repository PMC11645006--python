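# plantstress3d

Plant stress detection from a single top-view RGB image.

The pipeline has three steps:

1. **Plant recognition** — a CNN classifies 32×32 RGB sections as plant /
   no-plant and is swept over the image as a stride-1 sliding window,
   painting each window's label onto its central pixel.
2. **Leaf detection** — the image is partitioned into SLIC superpixels
   (defaults 999 / 9 iterations / smoothing 5) and a superpixel is kept as a
   leaf region only when *every* one of its pixels carries the plant label.
3. **3D stress analysis** — a patch CNN regresses the mean 8-bit depth code
   under each window from the RGB alone; codes convert to meters via
   `Z = k·z/255`, leaf pixels are back-projected through a pinhole camera
   into metric point clouds, and each leaf's moment centroid feeds a
   15–128–64–32–64–128–2 DNN that scores the plant stressed / unstressed.

Because the study's datasets are not public, the package ships a seeded
synthetic scene generator (`plantstress3d.synthetic`) that emulates their
structure: eight irrigation groups (A–H), paired RGB + 8-bit depth PNGs,
plant masks, leaf instance maps, and camera-to-leaf distances of 65–74 cm
(unstressed) vs 75–80 cm (stressed).

The neural networks are implemented in pure NumPy (no GPU frameworks
required): convolution, batch norm, max pooling, dense layers, Adam, and
seeded deterministic training. A reduced 3-block encoder trains on one CPU
core in seconds; the full VGG16-style encoder (13 conv / 13 batch-norm /
5 max-pool) is available via `variant="vgg16"`.

## CLI

```bash
# synthetic dataset: 8 groups x N scenes, paired rgb_/depth_/mask_/leaves_ PNGs + manifest.csv
plantstress3d generate --out data/ --n-per-group 5 --seed 0 --width 96 --height 96

# train the three models
plantstress3d train-seg    --dataset data/ --out seg.npz    --seed 0
plantstress3d train-depth  --dataset data/ --out depth.npz  --seed 1
plantstress3d train-stress --dataset data/ --out stress.npz --seed 2 --config config.yaml

# individual stages
plantstress3d segment     --image img.png --model seg.npz --out mask.png
plantstress3d leaves      --image img.png --model seg.npz --out regions.json
plantstress3d depth       --image img.png --model depth.npz --out depth.png
plantstress3d reconstruct --image img.png --seg-model seg.npz --depth-model depth.npz --ply cloud.ply

# full pipeline & evaluation
plantstress3d run --image img.png --seg-model seg.npz --depth-model depth.npz \
    --stress-model stress.npz --config config.yaml --report report.json
plantstress3d evaluate --predictions preds.csv
plantstress3d sweep-superpixels --dataset data/ --seg-model seg.npz \
    --depth-model depth.npz --stress-model stress.npz --counts 800,900,999,1100,1200
```

`config.yaml` holds the `PipelineConfig` schema (strides, SLIC parameters,
camera intrinsics `focal_length` / `principal_point` / `max_depth` /
`image_size`, feature mode, checkpoint paths).

## Evaluation utilities

`plantstress3d.evaluation` implements confusion-count metrics (recall,
precision, F-score, accuracy, specificity, Jaccard), trapezoidal ROC AUC,
the Polygon Area Metric (hexagon vertex order SE, SP, JI, AC, F1, AUC;
normalizer 3√3/2 ≈ 2.59807), seeded five-fold cross-validation,
method-comparison deltas, and the drying-curve moisture ratio
`(Mt−Me)/(Mo−Me)`.

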