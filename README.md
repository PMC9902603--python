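# chromotype

Neural-network scoring of sister chromatid cohesion (SCC) morphology from
cropped metaphase-chromosome images.

Cohesion assays classify each chromosome in a metaphase spread into three
shapes: **type A** (sisters tightly cohered), **type B** (arms separated,
centromere joined), **type C** (sisters fully separated).  Counting these
by eye for 50–100 chromosomes per sample is slow and observer-dependent —
inter-observer concordance on the same images can range from ~51% to ~77%.
`chromotype` is for chromosome biologists who want that scoring done by a
fixed, reproducible model: it detects cohesion defects (e.g. in knockouts
of cohesion regulators such as CTF18) as shifts of the A/B/C distribution
between genotypes.

## What's inside

* **Classifier** — a frozen convolutional feature extractor Φ (three
  compact families: plain stack, fire-module style, residual style; seeded
  fixed weights, optional plug-in pretrained weights) with a trainable
  3-way affine head. For an image *x* the class scores are

  $$s = W\,\mathrm{std}\big(\mathrm{GAP}\,\Phi(x)\big) + b,\qquad
  \hat{y} = \arg\max_c s_c ,$$

  where GAP is global average pooling, averaged over the eight square
  symmetries of the crop (orientation is nuisance), and only $(W, b)$ are
  trained (softmax cross-entropy, SGD with momentum, validation-based
  epoch selection).
* **Preprocessing** — white-out of extraneous objects to (255,255,255),
  resize to 224×224, contrast/brightness $dst = \alpha\,src + \beta$
  (α=3.0, β=80.0), gamma $y=(x/255)^{\gamma}\times 255$ (γ=3.0), and
  per-channel standardization to mean 64 / SD 16.
* **Evaluation protocol** — cell-level test split, pool rebalancing with
  extra rare-type images, repeated validation/training selection
  (3 selections × 10 training cycles = 30 trials in the reference design),
  concordance rate, confusion matrix, per-type distributions.
* **Grad-CAM** — $\mathrm{map}=\mathrm{ReLU}\big(\sum_k \alpha_k A_k\big)$
  with $\alpha_k$ the spatial mean of $\partial s_c/\partial A_k$, for any
  convolutional layer.
* **Genotype contrast** — per-type percentage-point deltas between two
  samples plus a supplementary χ² independence test.
* **Synthetic data** — a seeded renderer of Giemsa-style single-chromosome
  images whose arm opening and centromere gap realize the three classes,
  with ground-truth geometry stored per image.  The whole pipeline runs
  and is tested without any downloads.

## Worked example

Train a head on balanced synthetic wild-type-like images, then compare a
wild-type sample against a cohesion-defective one (type B/C enriched, as
in a CTF18 knockout):

```python
import numpy as np
from chromotype import (SynthConfig, generate_dataset, generate_genotype_pair,
                        train_head, predict_batch, contrast_genotypes)

cfg = SynthConfig()
train = generate_dataset({"A": 60, "B": 60, "C": 60}, cfg, seed=1)
val   = generate_dataset({"A": 40, "B": 40, "C": 40}, cfg, seed=2)
model = train_head("small_scratch", train, val, seed=0)

wt, ko = generate_genotype_pair((0.637, 0.305, 0.058),   # wild-type mix
                                (0.265, 0.522, 0.213),   # cohesion-defective mix
                                300, cfg, seed=3)
c = contrast_genotypes(predict_batch(model, wt), predict_batch(model, ko),
                       names=("WT", "CTF18-KO"))
print(np.round(c.distributions["WT"], 1))        # [65.  29.7  5.3]
print(np.round(c.distributions["CTF18-KO"], 1))  # [32.  44.7 23.3]
print(np.round(c.deltas, 1))                     # [-33.  15.  18.]
print(f"chi2={c.test_statistic:.1f} p={c.p_value:.2e}")  # chi2=76.7 p=2.25e-17
```

The predicted distributions track the generating mixes (WT truly
63.7/30.5/5.8; KO truly 26.5/52.2/21.3): type A drops by ~33 percentage
points while types B and C rise by ~15 and ~18 — the signature of a
cohesion defect.  The χ² line says the shift is far beyond sampling noise.
During training the model reported a best validation concordance of 94.2%.

The same stages are scriptable from a shell (`chromotype synth | preprocess
| train | evaluate | gradcam | compare`), and `examples/` contains one
short narrative script per capability.

## Layout

```
src/chromotype/   synthetic.py  preprocess.py  nn.py  backbones.py
                  classify.py   protocol.py    saliency.py  genotype.py
                  manifest.py   cli.py
tests/            unit + property + end-to-end acceptance tests
examples/         one narrative script per capability
docs/methods.md   model, parameters, design decisions, limitations
```
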