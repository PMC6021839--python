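# touchsplit

Separate two touching objects in a low-contrast binary blob (e.g. two
animals merged into one connected component by motion/foreground
extraction from an overhead depth camera).

The package implements a hybrid strategy:

1. **Box path** (`bb_eval`) — candidate detector bounding boxes from any
   external detector are scored against the blob (size condition, boundary
   condition, a confidence value, and a coverage condition for the second
   box). One or two *useful* boxes induce a straight cut from their
   geometry; the result is accepted only if the cut is short
   (`seg_length_th`, default 20) and the halves are balanced
   (`seg_size_th`, default 1.5).
2. **Shape path** (`shape_sep`) — used whenever the box path declines.
   A *hole* seeds the cut: an enclosed background region if present,
   otherwise one manufactured by repeated morphological erosion (default
   8 iterations) or, as a last resort, from the medial-axis skeleton.
   A *guideline* spans each hole's farthest point pair; up to two
   *concave points* are located on the outline via convex-hull defect
   time series (depth series `L`, position series `G`); guideline and
   concave points are joined into the boundary line.

Supporting modules: `maskgeom` (contours, rasterization, cutting),
`preprocess` (depth interpolation, background differencing, the
touching-blob size gate, default threshold 500), `pipeline` (routing,
pixel-ID accuracy metric, batch driver), `synthdata` (synthetic
touching-ellipse fixtures with ground truth and simulated detector
boxes), `cli`.

## CLI

```sh
# hybrid separation: PNG mask (0/255) + JSON box list -> label PNG {0,1,2}
touchsplit separate --mask blob.png --bbs boxes.json --out labels.png --report report.json

# shape-analysis only (no boxes)
touchsplit shape --mask blob.png --out labels.png

# pixel-ID accuracy of a prediction against ground truth
touchsplit eval --pred labels.png --truth truth.png

# write a synthetic fixture suite (mask/truth/boxes/spec per fixture)
touchsplit synth --n 200 --seed 0 --out fixtures/

# run a synthetic suite end-to-end and summarize
touchsplit batch --n 200 --seed 0 --mode hybrid --out summary.json
```

Box JSON accepts `{"top","left","bottom","right","probability"}` or
`{"x","y","w","h","probability"}` (x/y = left/top corner, inclusive
bounds). Every threshold is exposed as a CLI flag and via `--config`
(flat `key = value` file; unknown keys rejected; CLI flag > file >
default). Exit codes: 0 success, 1 file/argument errors, 2 unseparable.

Note: the default `probability_th` is 1.0 (detector objectness is
compared with `>=`); when feeding boxes whose probabilities are genuine
scores below 1, lower it, e.g. `--probability-th 0.8`.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the box scoring, partition conservation, gate fidelity,
hole-branch coverage, concave-point geometry, the accuracy analog on the
200-fixture synthetic suite, and byte-level determinism).

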