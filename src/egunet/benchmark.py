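"""End-to-end desk-scale benchmark: train the default small model on the
phantom task and score it on the held-out split.

This is the package's "does the whole pipeline work" experiment: 64x64
four-class phantoms (400/50/50 split), the default small architecture, and
the standard training recipe. It is used by the test suite and the
reproduction script; everything is deterministic in ``seed``.
"""

from __future__ import annotations

import numpy as np

from .estimator import GatedUNetSegmenter
from .metrics import dsc
from .synthetic import SyntheticSpec, make_dataset

__all__ = ["toy_segmentation_benchmark"]


def toy_segmentation_benchmark(seed: int = 1234, epochs: int = 12,
                               spec: SyntheticSpec | None = None) -> dict:
    """Train the default small segmenter and evaluate on the test split.

    Returns per-class and mean foreground DSC on the held-out cases, the
    training history, and the sizes used.
    """
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    data = make_dataset(spec)
    est = GatedUNetSegmenter(num_classes=spec.num_classes, epochs=epochs, seed=seed)
    est.fit(data["train"]["images"], data["train"]["labels"],
            data["val"]["images"], data["val"]["labels"])
    pred = est.predict(data["test"]["images"])
    gt = data["test"]["labels"]
    per_class = {k: dsc(pred == k, gt == k) for k in range(spec.num_classes)}
    fg = float(np.mean([per_class[k] for k in range(1, spec.num_classes)]))
    return {
        "test_foreground_dsc": fg,
        "per_class_dsc": per_class,
        "best_val_dsc": est.history_.get("best_val_dsc", float("nan")),
        "history": est.history_,
        "n_train": spec.n_train,
        "n_test": spec.n_test,
        "epochs": epochs,
        "seed": seed,
    }
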