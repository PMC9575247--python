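"""End-to-end orchestration: SMOTE -> split -> standardize -> train -> evaluate.

By default SMOTE is applied to the whole dataset before splitting, which
matches the published pipeline order; ``leakage_safe=True`` instead
oversamples only the training partition so no synthetic sample can carry
test-set information.  The standardizer is fitted on the training
partition and reapplied everywhere (``paper_literal_standardize=True``
fits it on the full post-SMOTE matrix instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcgn_model import TrainedDCGN
from .evaluation import EvaluationReport, evaluate
from .io_config import DCGNConfig, ExpressionDataset
from .preprocessing import (
    SmoteParams,
    apply_standardizer,
    fit_standardizer,
    smote_oversample,
    split_dataset,
)
from .training import TrainState, train_dcgn


@dataclass
class PipelineResult:
    model: TrainedDCGN
    state: TrainState
    report: EvaluationReport
    test: ExpressionDataset


def run_pipeline(
    data: ExpressionDataset,
    config: DCGNConfig,
    *,
    leakage_safe: bool = False,
    paper_literal_standardize: bool = False,
    stratified: bool = True,
    verbose: bool = False,
) -> PipelineResult:
    """Balance, split, standardize, train and score one dataset."""
    config.n_classes = data.n_classes
    smote = SmoteParams(
        threshold=config.smote_threshold, k=config.smote_k, seed=config.seed
    )

    if leakage_safe:
        train, val, test = split_dataset(
            data, config.split_fractions, seed=config.seed, stratified=stratified
        )
        train = smote_oversample(train, smote)
        full = train
    else:
        full = smote_oversample(data, smote)
        train, val, test = split_dataset(
            full, config.split_fractions, seed=config.seed, stratified=stratified
        )

    std = fit_standardizer(full if paper_literal_standardize else train)
    train_s = apply_standardizer(train, std)
    val_s = apply_standardizer(val, std)

    trained, state = train_dcgn(train_s, val_s, config, verbose=verbose)
    trained.standardizer = std
    report = evaluate(trained, test)
    return PipelineResult(model=trained, state=state, report=report, test=test)
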