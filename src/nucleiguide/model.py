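"""Model/Results surface for nuclei-guided tumour grading.

:class:`NucleiGuidedGradingModel` is built from a dataset (image tiles,
binary nuclei masks, 1-based grade labels) plus a :class:`ModelConfig`;
``fit()`` performs the stratified train/test split, optimises the network
and returns a :class:`GradingResults` object carrying the fitted
parameters, the loss history, held-out evaluation, a ``summary()`` table
and Grad-CAM explanations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import explain as _explain
from .masks import apply_mask, baseline_segment, load_mask
from .network import ModelConfig, forward, init_params, predict
from .synthetic import SynthConfig, generate_sample, load_image, load_manifest
from .training import (
    EvalReport,
    TrainConfig,
    evaluate_predictions,
    split_dataset,
    train,
)

__all__ = ["NucleiGuidedGradingModel", "GradingResults"]


def _to_nchw(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) channel-last [0,1] floats -> (N, 3, H, W)."""
    return np.ascontiguousarray(np.asarray(images, dtype=float).transpose(0, 3, 1, 2))


class NucleiGuidedGradingModel:
    """Two-branch attention network fitted to a graded tile collection.

    Parameters
    ----------
    images : (N, H, W, 3) array in [0, 1]
        H&E-like RGB tiles.
    masks : (N, H, W) binary array
        Nuclei segmentation masks paired with the tiles.
    grades : (N,) int array
        1-based grade labels.
    config : ModelConfig, optional
        Network architecture; defaults to the desk-scale backbone.
    """

    def __init__(self, images, masks, grades, config: ModelConfig | None = None):
        images = np.asarray(images, dtype=float)
        masks = np.asarray(masks)
        grades = np.asarray(grades, dtype=int)
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(f"images must be (N,H,W,3), got {images.shape}")
        if masks.shape != images.shape[:3]:
            raise ValueError(
                f"masks {masks.shape} do not pair with images {images.shape[:3]}"
            )
        if grades.shape != (images.shape[0],):
            raise ValueError("one grade per image required")
        self.config = config or ModelConfig(input_size=images.shape[1])
        if images.shape[1] != self.config.input_size or images.shape[1] != images.shape[2]:
            raise ValueError(
                f"expected square {self.config.input_size} px tiles, "
                f"got {images.shape[1]}x{images.shape[2]}"
            )
        self.images = images
        self.masks = masks
        self.grades = grades
        # guide-branch input: image restricted to nuclei
        nuclei = np.stack([apply_mask(im, mk) for im, mk in zip(images, masks)])
        self.x_main = _to_nchw(images)
        self.x_nuclei = _to_nchw(nuclei)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_manifest(
        cls,
        manifest_path,
        config: ModelConfig | None = None,
        mask_provider: str = "manifest",
        min_area: int = 20,
    ) -> "NucleiGuidedGradingModel":
        """Build from a CSV manifest (image_path, mask_path, grade).

        ``mask_provider``: ``"manifest"`` loads the ground-truth mask PNGs;
        ``"baseline"`` segments each image with the classical Otsu pipeline.
        """
        records = load_manifest(manifest_path)
        images = np.stack([load_image(r["image_path"]) for r in records])
        if mask_provider == "manifest":
            masks = np.stack([load_mask(r["mask_path"]) for r in records])
        elif mask_provider == "baseline":
            masks = np.stack([baseline_segment(im, min_area=min_area) for im in images])
        else:
            raise ValueError(f"unknown mask provider {mask_provider!r}")
        grades = np.array([r["grade"] for r in records])
        return cls(images, masks, grades, config)

    @classmethod
    def from_synthetic(
        cls, synth_config: SynthConfig, config: ModelConfig | None = None
    ) -> "NucleiGuidedGradingModel":
        """Generate a balanced synthetic dataset in memory and wrap it."""
        images, masks, grades = [], [], []
        for grade in sorted(synth_config.grade_rules):
            for i in range(synth_config.n_per_grade):
                s = generate_sample(synth_config, grade, i)
                images.append(s.image)
                masks.append(s.mask)
                grades.append(s.grade)
        return cls(np.stack(images), np.stack(masks), np.array(grades), config)

    # -- fitting ----------------------------------------------------------
    def fit(
        self, train_config: TrainConfig | None = None, init_seed: int | None = None
    ) -> "GradingResults":
        """Split, train and return a results object.

        The stratified 80/20 (by default) split and all training
        randomness derive from ``train_config.seed``.
        """
        tc = train_config or TrainConfig.desk()
        train_idx, test_idx = split_dataset(self.grades, tc.split_fraction, tc.seed)
        params = init_params(self.config, seed=tc.seed if init_seed is None else init_seed)
        xn = None if self.config.variant == "image_only" else self.x_nuclei
        history = train(
            params,
            self.x_main[train_idx],
            None if xn is None else xn[train_idx],
            self.grades[train_idx],
            self.config,
            tc,
        )
        return GradingResults(self, params, tc, history, train_idx, test_idx)


@dataclasses.dataclass
class GradingResults:
    """Fitted network plus everything needed to judge and explain it."""

    model: NucleiGuidedGradingModel
    params: dict
    train_config: TrainConfig
    loss_history: list[float]
    train_indices: np.ndarray
    test_indices: np.ndarray

    # -- prediction -------------------------------------------------------
    def _inputs(self, idx):
        xn = None if self.model.config.variant == "image_only" else self.model.x_nuclei[idx]
        return self.model.x_main[idx], xn

    def predict(self, idx=None):
        """Per-image :class:`GradingPrediction` list (default: test part)."""
        idx = self.test_indices if idx is None else np.atleast_1d(idx)
        xm, xn = self._inputs(idx)
        return predict(self.params, xm, xn, self.model.config)

    def predict_proba(self, idx=None) -> np.ndarray:
        idx = self.test_indices if idx is None else np.atleast_1d(idx)
        xm, xn = self._inputs(idx)
        logits, _ = forward(self.params, xm, xn, self.model.config)
        return logits.softmax(axis=-1).data

    # -- evaluation -------------------------------------------------------
    def evaluate(self, part: str = "test") -> EvalReport:
        """Confusion matrix, OvR accuracy/sensitivity/specificity and AUC."""
        idx = {"test": self.test_indices, "train": self.train_indices}[part]
        probs = self.predict_proba(idx)
        return evaluate_predictions(self.model.grades[idx], probs)

    def grad_cam(self, index: int, target_class=None, stage=None) -> _explain.Heatmap:
        """Grad-CAM heatmap for dataset item ``index`` (absolute index)."""
        xm, xn = self._inputs(np.atleast_1d(index))
        return _explain.grad_cam(
            self.params, self.model.config, xm[0],
            None if xn is None else xn[0],
            target_class=target_class, stage=stage,
        )

    # -- persistence ------------------------------------------------------
    def save(self, prefix) -> None:
        """Write ``{prefix}.npz`` (arrays) and ``{prefix}.json`` (configs)."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        arrays = {f"param__{k}": p.data for k, p in self.params.items()}
        np.savez(
            prefix.with_suffix(".npz"),
            train_indices=self.train_indices,
            test_indices=self.test_indices,
            loss_history=np.array(self.loss_history),
            **arrays,
        )
        meta = {
            "model_config": dataclasses.asdict(self.model.config),
            "train_config": dataclasses.asdict(self.train_config),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix, model: NucleiGuidedGradingModel) -> "GradingResults":
        """Rebuild results saved by :meth:`save` against ``model``'s data."""
        import json
        from pathlib import Path

        from .autodiff import Tensor

        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        tc = TrainConfig(**meta["train_config"])
        with np.load(prefix.with_suffix(".npz")) as z:
            params = {
                k[len("param__"):]: Tensor(z[k], requires_grad=True)
                for k in z.files
                if k.startswith("param__")
            }
            return cls(
                model=model,
                params=params,
                train_config=tc,
                loss_history=list(z["loss_history"]),
                train_indices=z["train_indices"],
                test_indices=z["test_indices"],
            )

    def summary(self) -> str:
        """Human-readable fit summary with held-out metrics."""
        cfg = self.model.config
        rep = self.evaluate("test")
        n_par = sum(int(np.prod(p.data.shape)) for p in self.params.values())
        lines = [
            "Nuclei-Guided Grading Network Results",
            "=" * 46,
            f"variant:           {cfg.variant}",
            f"stages / fusion L: {cfg.n_stages} / {cfg.fusion_depth}",
            f"channels:          {cfg.channels_per_stage}",
            f"parameters:        {n_par}",
            f"train / test n:    {len(self.train_indices)} / {len(self.test_indices)}",
            f"epochs:            {self.train_config.epochs}"
            f"  (final loss {self.loss_history[-1]:.4f})"
            if self.loss_history
            else f"epochs:            {self.train_config.epochs}",
            "-" * 46,
            f"test accuracy:     {rep.accuracy:.3f}",
            f"macro sensitivity: {rep.macro_sensitivity:.3f}",
            f"macro specificity: {rep.macro_specificity:.3f}",
            f"mean OvR AUC:      {rep.mean_auc:.3f}",
            "confusion (rows true, cols predicted):",
            str(rep.confusion),
        ]
        return "\n".join(lines)
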