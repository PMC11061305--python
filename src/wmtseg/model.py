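"""High-level modelling surface: build, fit, inspect, predict.

``SegmentationModel`` wraps an architecture config; ``fit`` runs the
optimization loop and returns a ``SegmentationResults`` carrying the trained
parameters, the per-epoch loss history, and evaluation helpers, in the
spirit of statistical modelling packages where a model object's ``fit``
hands back a results object.

Example
-------
>>> from wmtseg.model import SegmentationModel
>>> from wmtseg.synthetic import PhantomSpec, generate
>>> data = generate(PhantomSpec(mode="organ", side=32, n_images=4, seed=3))
>>> sm = SegmentationModel(variant="wmt", input_side=32, base_channels=8,
...                        depth=2, seed=1)
>>> res = sm.fit(data, epochs=50, schedule="constant")
>>> print(res.summary())                     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .network import (
    SegmentationOutput,
    VariantConfig,
    build_variant,
    load_checkpoint,
    save_checkpoint,
)
from .training import TrainConfig, train

__all__ = ["SegmentationModel", "SegmentationResults"]


class SegmentationModel:
    """A segmentation architecture bound to its configuration."""

    def __init__(self, **variant_kwargs):
        self.config = VariantConfig(**variant_kwargs)
        self._net = build_variant(self.config)

    @classmethod
    def from_config(cls, cfg: VariantConfig) -> "SegmentationModel":
        return cls(**cfg.to_dict())

    @classmethod
    def from_checkpoint(cls, path) -> "SegmentationResults":
        net = load_checkpoint(path)
        model = cls.__new__(cls)
        model.config = net.cfg
        model._net = net
        return SegmentationResults(model=model, history=[], lr=[],
                                   train_config=None)

    @property
    def net(self):
        return self._net

    def n_parameters(self) -> int:
        return self._net.n_parameters()

    def fit(self, dataset, train_config: TrainConfig | None = None,
            log_path=None, progress: bool = False,
            **train_kwargs) -> "SegmentationResults":
        """Train on (image, mask) pairs; returns the results object."""
        if train_config is None:
            train_config = TrainConfig(**train_kwargs)
        elif train_kwargs:
            raise TypeError("pass either train_config or keyword overrides")
        out = train(self._net, dataset, train_config, log_path=log_path,
                    progress=progress)
        return SegmentationResults(model=self, history=out["history"],
                                   lr=out["lr"], train_config=train_config)


@dataclass
class SegmentationResults:
    """Trained parameters plus training diagnostics and evaluation."""

    model: SegmentationModel
    history: list[float]
    lr: list[float]
    train_config: TrainConfig | None
    _eval_cache: dict = field(default_factory=dict, repr=False)

    @property
    def final_loss(self) -> float | None:
        return self.history[-1] if self.history else None

    def predict(self, image) -> SegmentationOutput:
        """Probability map + logits for one image or a batch."""
        return self.model.net(np.asarray(image, dtype=np.float64))

    def predict_mask(self, image, threshold: float = 0.5) -> np.ndarray:
        out = self.predict(image)
        mask = out.mask(threshold)
        return mask[0, 0] if np.asarray(image).ndim == 2 else mask

    def evaluate(self, dataset, threshold: float = 0.5,
                 aggregate: str = "macro") -> dict:
        """F1 / IoU / accuracy report over (image, mask) pairs."""
        dataset = list(dataset)
        if not dataset:
            raise ValueError("cannot evaluate an empty dataset")
        preds, truths = [], []
        for img, mask in dataset:
            preds.append(self.predict_mask(np.asarray(img, dtype=np.float64),
                                           threshold))
            truths.append(np.asarray(mask))
        return _metrics.evaluate_masks(preds, truths, aggregate=aggregate)

    def save(self, path) -> None:
        save_checkpoint(path, self.model.net)

    def summary(self, dataset=None) -> str:
        """Text summary in the style of a model-results table."""
        cfg = self.model.config
        lines = [
            "Segmentation model results",
            "=" * 46,
            f"variant:            {cfg.variant}",
            f"input side:         {cfg.input_side}",
            f"depth / base chans: {cfg.depth} / {cfg.base_channels}",
            f"parameters:         {self.model.n_parameters()}",
        ]
        if self.history:
            lines += [
                f"epochs trained:     {len(self.history)}",
                f"initial loss:       {self.history[0]:.5f}",
                f"final loss:         {self.history[-1]:.5f}",
            ]
        if dataset is not None:
            agg = self.evaluate(dataset)["aggregate"]
            lines += [
                f"F1:                 {agg['f1']:.4f}",
                f"IoU:                {agg['iou']:.4f}",
                f"accuracy:           {agg['accuracy']:.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)
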