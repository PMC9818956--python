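"""Model/Results facade over the two-stage registration pipeline.

:class:`DeformableRegistration` is built from data (training pairs, plus
optional annotated fine-tuning and test pairs) and a network
configuration; :meth:`DeformableRegistration.fit` runs the unsupervised
stage and returns a :class:`DeformableRegistrationResults` carrying the
trained parameters, the loss trace and evaluation helpers.
``results.fine_tune()`` transfers the weights into the semi-supervised
network and continues with the landmark-augmented loss, returning a new
results object, so both stages stay inspectable.
"""

from __future__ import annotations

import numpy as np

from .evaluate import TREReport, evaluate_method
from .nn import NetworkConfig, RegistrationModel, build_network, predict_field
from .train import (
    TrainConfig,
    fine_tune_validated,
    register_pair,
    train_unsupervised,
    transfer_weights,
)
from .warp import warp_points_dense

__all__ = ["DeformableRegistration", "DeformableRegistrationResults"]


class DeformableRegistration:
    """Deformable double-view registration model.

    Parameters
    ----------
    train_pairs : sequence
        Unlabeled (fixed, moving) records — preprocessed, pre-registered.
    config : NetworkConfig, optional
        Network architecture; defaults to the desk-scale profile.
    finetune_pairs, test_pairs : sequence, optional
        Annotated records (with landmarks) for stage 2 and evaluation.
    """

    def __init__(self, train_pairs, config: NetworkConfig | None = None,
                 finetune_pairs=None, test_pairs=None):
        self.train_pairs = list(train_pairs)
        self.config = config or NetworkConfig.desk_scale()
        self.finetune_pairs = list(finetune_pairs) if finetune_pairs is not None else []
        self.test_pairs = list(test_pairs) if test_pairs is not None else []

    def fit(self, train_config: TrainConfig | None = None, seed: int = 0,
            start: RegistrationModel | None = None) -> "DeformableRegistrationResults":
        """Run the unsupervised stage; returns a results object."""
        cfg = train_config or TrainConfig(seed=seed)
        model = start if start is not None else build_network(self.config, seed=seed)
        model, trace = train_unsupervised(model, self.train_pairs, cfg)
        return DeformableRegistrationResults(self, model, cfg, trace, stage="unsupervised")


class DeformableRegistrationResults:
    """Trained registration network plus its training history."""

    def __init__(self, model: DeformableRegistration, reg_model: RegistrationModel,
                 train_config: TrainConfig, loss_history: list[float], stage: str):
        self.model = model
        self.reg_model = reg_model
        self.train_config = train_config
        self.loss_history = list(loss_history)
        self.stage = stage

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.reg_model.theta

    def fine_tune(self, annotated=None, train_config: TrainConfig | None = None
                  ) -> "DeformableRegistrationResults":
        """Transfer weights and fine-tune on annotated pairs (stage 2).

        Uses validated early stopping with an evidence gate (see
        :func:`penreg.train.fine_tune_validated`): the returned model
        keeps the warm-start weights unless held-out-validated
        improvement is significant.
        """
        annotated = annotated if annotated is not None else self.model.finetune_pairs
        cfg = train_config or TrainConfig(
            learning_rate=1e-4, seed=self.train_config.seed,
            lambda_=self.train_config.lambda_, mu=self.train_config.mu,
            similarity=self.train_config.similarity,
        )
        target = transfer_weights(self.reg_model, self.reg_model.config)
        target, trace, info = fine_tune_validated(target, annotated, cfg)
        res = DeformableRegistrationResults(self.model, target, cfg, trace, stage="fine_tuned")
        res.finetune_info = info
        return res

    def register(self, fixed, moving):
        """(field, warped moving image) for one pair."""
        return register_pair(self.reg_model, fixed, moving)

    def map_landmarks(self, fixed, moving, moving_points) -> np.ndarray:
        """Carry moving-image landmarks into the fixed frame."""
        field = predict_field(self.reg_model, fixed, moving)
        return warp_points_dense(moving_points, field, max_iter=60, strict=False)

    def evaluate(self, test_set=None, convention: str = "euclidean") -> TREReport:
        """TRE report of this model on an annotated test set."""
        test_set = test_set if test_set is not None else self.model.test_pairs
        return evaluate_method(self.map_landmarks, test_set, convention=convention)

    def summary(self, test_set=None) -> str:
        cfg = self.reg_model.config
        lines = [
            "Deformable registration network",
            f"  stage          : {self.stage}",
            f"  levels/filters : {cfg.levels} / {cfg.filters_per_level}",
            f"  input size     : {cfg.input_size}",
            f"  similarity     : {self.train_config.similarity}"
            f"  (lambda={self.train_config.lambda_}, mu={self.train_config.mu})",
            f"  epochs         : {self.train_config.epochs}"
            f"  (lr {self.train_config.learning_rate:g}, batch {self.train_config.batch_size})",
            f"  loss           : first {self.loss_history[0]:.5f}"
            f" -> last {self.loss_history[-1]:.5f}",
        ]
        eval_set = test_set if test_set is not None else self.model.test_pairs
        if eval_set:
            lines.append("  " + self.evaluate(eval_set).summary())
        return "\n".join(lines)
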