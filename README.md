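# retinakey

Joint keypoint detection and matching for fundus (retinal) image
registration.

Registration of retinal photographs — aligning a moving image to a fixed one
so the same anatomical point lands at the same coordinate — underpins
longitudinal follow-up of eye disease. The stable landmarks of a retina are
its vessel **bifurcations** (degree-≥3 points of the vascular tree) and
**crossings** (artery/vein overlaps). `retinakey` implements a single
encoder–decoder network that simultaneously

* classifies every pixel as keypoint/background (a probability map over all
  branching and crossing points), and
* attaches a D-dimensional embedding to every pixel, so keypoints are matched
  across the image pair by Euclidean distance between their embeddings,

with a **spatially-varying adaptive pyramid context aggregation** bottleneck:
the deepest feature map `X ∈ R^{H×W×C}` predicts its own depth-wise kernel
`S' = Q'ᵀK' ∈ R^{s²×C}` from learned key/query projections (every pair of
pixel locations interacts through the product over all H·W positions), and
the normalised kernel drives three dilated depth-wise convolution branches
(rates 1, 3, 5) whose sigmoid gates sum to a fused weight `R ∈ (0,3)^{H×W×C}`
that re-weights `X` element-wise. Training combines cross-entropy + Dice
losses on the probability map with a metric-learning loss on the embeddings —
pair-wise (contrastive), triplet, or the structured triplet ranking loss

    L = 1/(2|P|) Σ_{(i,j)∈P} [ d(f_i,f_j) + log( Σ_{neg p of i} e^{m−d(f_i,f_p)}
                                               + Σ_{neg l of j} e^{m−d(f_j,f_l)} ) ]₊

which pushes each matched pair together and both of its anchors away from
*all* their negatives at once. Registration quality is scored by the
fundus-benchmark convention: mean control-point error per pair, success
fraction as a threshold sweeps 0→25 px, and the normalised area under that
curve (AUC).

Clinical datasets for this task are private, so the package ships a
first-class synthetic generator: random vessel trees rendered as dark strokes
on a textured bright disc, with exact ground-truth keypoints (tree nodes of
degree ≥ 3; analytic inter-tree intersections), known warps, photometric
perturbation and two image-quality presets. The neural network and its
gradients run on a compact NumPy reverse-mode autodiff engine included in the
package (`retinakey.autodiff`), validated end-to-end by finite differences.

## Worked example

```python
from retinakey import (ModelConfig, TrainConfig, generate_dataset,
                       register_pair, train)
from retinakey.evaluation import evaluate_model

data = generate_dataset(25, canvas_size=64, seed=0)   # synthetic pairs
cfg = TrainConfig(iterations=300, seed=0,
                  model=ModelConfig(num_levels=2, base_channels=8,
                                    embedding_dim=32, context_mode="sapca"))
model, log = train(cfg, data[:20])
print(f"loss {log['total'].iloc[:10].mean():.2f} -> "
      f"{log['total'].iloc[-10:].mean():.2f}")

curve, errors = evaluate_model(model, data[20:], transform_model="similarity",
                               robust=True)
print(f"held-out registration AUC = {curve.auc:.3f}")
```

Output from this exact run:

```
loss 3.36 -> 0.74
held-out registration AUC = 0.978
```

The loss line shows the total training objective (cross-entropy + Dice +
structured matching loss) dropping by ~78% over 300 SGD iterations; the AUC
line says that, sweeping the success threshold from 0 to 25 px, the trained
model registers the five held-out pairs with a normalised area under the
success curve of 0.978 (1.0 would mean zero error on every pair; the same
untrained network scores ≈ 0.1).

The same pipeline is scriptable from the shell:

```sh
retinakey synth --n-pairs 10 --size 64 --quality high --seed 0 --out-dir data/
retinakey train --dataset-dir data/ --out model.ckpt --iterations 300 \
                --num-levels 2 --base-channels 8 --embedding-dim 32
retinakey register --fixed data/pair_0000/fixed.png \
                   --moving data/pair_0000/moving.png \
                   --checkpoint model.ckpt --out-dir out/
retinakey evaluate --pred-dir preds/ --gt-dir data/ --t-max 25 --out report.csv
retinakey benchmark --out-dir bench/        # ablation table over variants
```

An sklearn-style facade (`KeypointRegistrationEstimator` with
`fit`/`predict`/`score`, `get_params`/`set_params`/`clone`) wraps the same
pipeline for composition with scikit-learn tooling.

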