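"""End-to-end benchmark protocol on the synthetic leaf-disease set.

The published headline accuracy was measured on a restricted field corpus
after 200 GPU epochs; neither the data nor that budget is reproducible at
desk scale.  The stand-in protocol defined here exercises the identical
pipeline end to end — render the six-class synthetic set, split it 8:1:1
per class, build the final trimmed coordinate-attention model at 64 px,
train for 20 epochs with the published optimiser settings (Adam, 1e-3 base
rate, linear warmup then 0.99 exponential decay), select the
best-validation checkpoint and score the held-out test subset.  Everything
derives from one seed, so a run is exactly repeatable.

Problem sizes (80 images per class, 64 px, 20 epochs, batch 8, the easy
end of the clutter dial) were chosen so the protocol completes in minutes
on one CPU core while the generated classes stay learnable within the
short schedule; the online augmentations are deliberately not applied here
— at this sample size they starve the schedule — and are exercised by
their own tests and by the full training recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import FCAEfficientNet, build_model, final_spec
from .datapipe import split_dataset
from .evaluation import ConfusionMatrix, MetricsReport, compute_metrics
from .synth import SynthSpec, generate_arrays
from .training import TrainConfig, TrainHistory, evaluate_loss_acc, train


@dataclass
class BenchmarkResult:
    history: TrainHistory
    best_val_accuracy: float
    best_epoch: int
    test_accuracy: float
    test_report: MetricsReport
    model: FCAEfficientNet
    n_train: int
    n_valid: int
    n_test: int


#: clutter level of the *easy* protocol.  The generator's realistic default
#: (0.25) lets foreground clutter occlude lesions, which a 20-epoch schedule
#: on ~200 images cannot absorb; the benchmark is defined on the easy end of
#: the dial, leaving the default untouched everywhere else.
EASY_CLUTTER = 0.1


def synthetic_benchmark(seed: int, n_per_class: int = 80, resolution: int = 64,
                        epochs: int = 20, clutter: float = EASY_CLUTTER,
                        log=None) -> BenchmarkResult:
    """Run the full synthetic-set protocol from one seed."""
    spec = SynthSpec(n_per_class=n_per_class, resolution=resolution,
                     seed=seed, background_clutter=clutter)
    images, labels, classes = generate_arrays(spec)
    ids = np.arange(len(labels))
    items = {c: ids[labels == i].tolist() for i, c in enumerate(classes)}
    _, assignment = split_dataset(items, seed=seed)
    subsets = {name: np.array([i for i in ids if assignment[i] == name])
               for name in ("train", "valid", "test")}

    model = build_model(final_spec(num_classes=6, input_resolution=resolution),
                        seed=seed)
    cfg = TrainConfig(epochs=max(epochs, 21), warmup_epochs=2, batch_size=8,
                      seed=seed)
    history, best = train(model,
                          (images[subsets["train"]], labels[subsets["train"]]),
                          (images[subsets["valid"]], labels[subsets["valid"]]),
                          cfg, epochs=epochs, log=log)
    model.load_state_dict(best["state"])
    from .datapipe import to_model_input
    x_test = to_model_input(images[subsets["test"]])
    y_test = labels[subsets["test"]]
    _, test_acc = evaluate_loss_acc(model, x_test, y_test)
    preds = model.predict_logits(x_test).argmax(axis=1)
    report = compute_metrics(ConfusionMatrix.from_predictions(y_test, preds, 6))
    return BenchmarkResult(history=history,
                           best_val_accuracy=best["val_acc"],
                           best_epoch=best["epoch"],
                           test_accuracy=test_acc,
                           test_report=report,
                           model=model,
                           n_train=len(subsets["train"]),
                           n_valid=len(subsets["valid"]),
                           n_test=len(subsets["test"]))
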