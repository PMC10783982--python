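"""End-to-end experiment driver on the synthetic texture task.

Wires the whole pipeline together: generate seeded source/target
datasets, boost every image to a 4-channel stack (natural + bilateral +
residual + high grey-level zone-emphasis map), pretrain the small CNN on
the source task, fine-tune on the target task with the early blocks
frozen, and tabulate batch metrics on a held-out test split.

The *source* task uses the same class structure but 1.6x longer
correlation lengths than the target task, so transfer is exercised
across a genuine (if mild) domain shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boosting import default_learners
from .evaluate import batch_evaluate_predictions
from .network import (
    NetworkModel,
    TrainConfig,
    build_model,
    predict_labels,
    prepare_inputs,
    pretrain,
    transfer_and_finetune,
)
from .synthetic import TextureParams, default_class_params, gen_dataset

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "source_task_params"]

SOURCE_CORRELATION_SCALE = 1.6


def source_task_params(target: dict[str, TextureParams]) -> dict[str, TextureParams]:
    """Pretraining task: same classes, coarser texture scale."""
    return {
        name: TextureParams(
            fill_fraction=p.fill_fraction,
            correlation_length=p.correlation_length * SOURCE_CORRELATION_SCALE,
            bone_level=p.bone_level,
            marrow_level=p.marrow_level,
            noise_sigma=p.noise_sigma,
            size=p.size,
            max_intensity=p.max_intensity,
        )
        for name, p in target.items()
    }


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one end-to-end run.

    Defaults follow the evaluation protocol: 100 images per class for
    training (200 total for two classes), 50 per class held out, batches
    of 20 at evaluation, and a 4-channel boosted input.
    """

    n_classes: int = 2
    n_train_per_class: int = 100
    n_test_per_class: int = 50
    n_source_per_class: int = 50
    seed: int = 0
    freeze_upto: int = 2
    pretrain_epochs: int = 8
    finetune_epochs: int = 10
    batch_size: int = 20
    positive_class: str = "osteoporotic"
    learner_names: tuple[str, ...] = ("bilateral", "residual", "hgze_map")


@dataclass(frozen=True)
class ExperimentResult:
    model: NetworkModel
    test_accuracy: float
    metrics_table: pd.DataFrame
    pretrain_log: list = field(repr=False, default_factory=list)
    finetune_log: list = field(repr=False, default_factory=list)


def run_experiment(config: ExperimentConfig = ExperimentConfig()) -> ExperimentResult:
    """Run generate -> boost -> pretrain -> fine-tune -> evaluate."""
    rootseed = int(config.seed)
    target = default_class_params(config.n_classes)
    source = source_task_params(target)
    learners = default_learners({"learners": list(config.learner_names)})

    src = gen_dataset(source, config.n_source_per_class, seed=rootseed + 101)
    trn = gen_dataset(target, config.n_train_per_class, seed=rootseed + 202)
    tst = gen_dataset(target, config.n_test_per_class, seed=rootseed + 303)

    Xs, ys, classes = prepare_inputs(src, learners)
    Xt, yt, _ = prepare_inputs(trn, learners, classes=classes)
    Xe, _, _ = prepare_inputs(tst, learners, classes=classes)

    model = build_model(Xt.shape[1:], classes, seed=rootseed)
    model, pre_log = pretrain(
        model, (Xs, ys), TrainConfig(epochs=config.pretrain_epochs, seed=rootseed + 7)
    )
    model, fin_log = transfer_and_finetune(
        model,
        (Xt, yt),
        TrainConfig(
            epochs=config.finetune_epochs, seed=rootseed + 8, freeze_upto=config.freeze_upto
        ),
    )

    # interleave classes in the evaluation order so every batch of 20 mixes
    # positives and negatives (all-one-class batches have undefined ratios)
    order = np.random.default_rng(rootseed + 9).permutation(len(tst))
    preds = predict_labels(model, Xe[order])
    truth = [tst.labels[i] for i in order]
    accuracy = float(np.mean([p == t for p, t in zip(preds, truth)]))
    table = batch_evaluate_predictions(
        preds, truth, config.positive_class, batch_size=config.batch_size
    )
    return ExperimentResult(
        model=model,
        test_accuracy=accuracy,
        metrics_table=table,
        pretrain_log=pre_log,
        finetune_log=fin_log,
    )
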