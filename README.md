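# fcaeffnet

Lightweight convolutional classifiers for leaf-disease images in cluttered
field conditions, built around a **fully-convolution-based coordinate
attention** (FCA) block. The package reimplements, as a tested library and
CLI, an EfficientNet-B0 derivative in which

* the squeeze-excitation gate of every inverted-residual (MBConv) block is
  replaced by coordinate attention whose two directional global average
  pools are themselves replaced by *learnable full-extent depthwise
  convolutions* with kernels (1, W) and (H, 1);
* an **adaptive fusion** (AF) stem merges a max-pooled, 1×1-projected copy
  of the raw input into a shallow node as `w1·y_m + w2·y_f` with two
  unconstrained learnable scalars;
* batch normalisation and the SiLU/Swish activation are swapped for
  per-sample layer normalisation (statistics over all of C×H×W) and the
  exact-CDF GELU;
* the three deepest repeated stages are trimmed from (3, 3, 4) to (2, 3, 2)
  blocks, giving a 3.4M-parameter model.

Everything runs on a compact NumPy reverse-mode autograd engine that ships
inside the package (convolutions, normalisations, Adam, stochastic depth,
Grad-CAM); there is no deep-learning-framework dependency.

## The model in brief

An MBConv block computes `x̂ = DWConv_{k×k}(Conv_{1×1}(x))` (each conv
followed by normalisation and the model activation), gates it with
attention, projects back with a 1×1 conv, and adds the input through a
stochastic-depth residual when shapes allow. FCA gating forms

```
zʰ = DWConv_{1×W}(x̂)         # (C, H, 1)   directional summaries
zʷ = DWConv_{H×1}(x̂)         # (C, 1, W)
f  = δ(Conv₁ₓ₁([zʰ ; zʷ]))    # channel reduction to max(C/16, 8)
gʰ = σ(Conv₁ₓ₁(fʰ)),  gʷ = σ(Conv₁ₓ₁(fʷ))
y(i, j) = x̂(i, j) · gʰ(i) · gʷ(j)
```

so each pixel is modulated by a learned row gate and column gate — position
is retained, unlike a squeeze-excitation scalar per channel. Because the
directional kernels span the full spatial extent, a built model is bound to
its input resolution.

## Worked example

```python
>>> from fcaeffnet import baseline_b0, final_spec, build_model, count_params, count_macs
>>> for name, spec in [("baseline SE/BN/Swish", baseline_b0(num_classes=6)),
...                    ("final FCA/LN/GELU (2,3,2)", final_spec())]:
...     m = build_model(spec)
...     print(f"{name}: {count_params(m)/1e6:.2f}M params, {count_macs(m)/1e6:.2f}M MACs")
baseline SE/BN/Swish: 4.02M params, 398.02M MACs
final FCA/LN/GELU (2,3,2): 3.38M params, 350.76M MACs
```

The baseline totals match the published 4.02M / 398.03M figures; the final
trimmed model carries 0.63M fewer parameters than the baseline. Metric
derivation works straight from confusion matrices:

```python
>>> import numpy as np
>>> from fcaeffnet import ConfusionMatrix, compute_metrics
>>> cm = np.diag([43, 59, 69, 53, 55, 42])   # published corn test set
>>> cm[1, 2] = cm[1, 5] = cm[3, 5] = cm[5, 0] = 1
>>> r = compute_metrics(ConfusionMatrix(cm))
>>> print(f"accuracy {r.accuracy:.4f}, macro P/R/F1 "
...       f"{r.macro_precision:.4f}/{r.macro_recall:.4f}/{r.macro_f1:.4f}")
accuracy 0.9877, macro P/R/F1 0.9863/0.9876/0.9868
```

Accuracy 0.9877 is 321 of 325 test images correct; the macro numbers are
unweighted means over the six disease classes.

End to end on images, the scikit-learn-style estimator wraps generation,
training and prediction (here on the bundled synthetic leaf renderer):

```python
from fcaeffnet import SynthSpec, generate_arrays
from fcaeffnet.estimator import FCAEfficientNetClassifier

images, labels, classes = generate_arrays(SynthSpec(n_per_class=40, seed=1))
clf = FCAEfficientNetClassifier(input_resolution=64, epochs=20,
                                batch_size=8, random_state=1)
clf.fit(images[::2], labels[::2])
print("held-out accuracy:", clf.score(images[1::2], labels[1::2]))
```

The CLI mirrors the library: `fcaeff summary`, `fcaeff search-space`,
`fcaeff synth`, `fcaeff split`, `fcaeff train`, `fcaeff evaluate` (metrics,
confusion matrix, Grad-CAM heatmaps) and `fcaeff robustness`
(brightness/contrast perturbation at factors 0.5/0.67/1.5/2).

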