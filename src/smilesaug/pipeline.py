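"""End-to-end runs: clean -> augment -> encode -> train -> evaluate.

A :class:`RunConfig` captures every stage's settings so a run is
reproducible from the config plus its seed alone; the config is echoed
into the artifact directory next to the outputs it produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate
from .augment import AugmentConfig, augment_dataset, records_to_frame
from .errors import SmilesAugError
from .model import (
    EncodedDataset,
    ModelConfig,
    TrainConfig,
    save_model,
    train_cv,
)
from .preprocess import CleaningRules, clean_dataset, molecules_to_frame, read_dataset
from .vectorize import encode, fit_encoding

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    input_csv: str
    smiles_column: str
    label_columns: list[str]
    output_dir: str
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    extra_pad: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            input_csv=payload["input_csv"],
            smiles_column=payload.get("smiles_column", "smiles"),
            label_columns=list(payload["label_columns"]),
            output_dir=payload.get("output_dir", "run_artifacts"),
            augment=AugmentConfig(**payload.get("augment", {})),
            model=ModelConfig(**payload.get("model", {})),
            train=TrainConfig(**payload.get("train", {})),
            extra_pad=int(payload.get("extra_pad", 5)),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _timed(stage: str, started: float) -> None:
    logger.info("%s finished in %.2f s", stage, time.time() - started)


def run_pipeline(config: RunConfig) -> evaluate.EvalReport:
    """Execute the full pipeline, writing all artifacts to ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(json.dumps(config.to_dict(), indent=2))

    t = time.time()
    records = read_dataset(config.input_csv, config.smiles_column, config.label_columns)
    molecules, report = clean_dataset(records, CleaningRules())
    if not molecules:
        raise SmilesAugError("cleaning removed every record")
    molecules_to_frame(molecules).to_csv(outdir / "cleaned.csv", index=False)
    (outdir / "cleaning_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    logger.info("cleaning: %d -> %d molecules", report.n_input, report.n_output)
    _timed("clean", t)

    t = time.time()
    augmented = augment_dataset(molecules, config.augment)
    records_to_frame(augmented).to_csv(outdir / "augmented.csv", index=False)
    (outdir / "augment_config.json").write_text(
        json.dumps(dataclasses.asdict(config.augment), indent=2)
    )
    logger.info("augmentation: %d molecules -> %d records", len(molecules), len(augmented))
    _timed("augment", t)

    t = time.time()
    spec = fit_encoding([r.smiles for r in augmented], config.extra_pad)
    (outdir / "encoding.json").write_text(spec.to_json())
    samples = [
        encode(r.smiles, spec, r.parent_id, r.variant_index, r.labels)
        for r in augmented
    ]
    dataset = EncodedDataset.from_samples(samples)
    _timed("encode", t)

    t = time.time()
    runs = train_cv(dataset, config.model, config.train, encoding_spec=spec)
    for run in runs:
        fold_dir = outdir / f"fold_{run.fold_index}"
        save_model(run.model, fold_dir)
        pd.DataFrame(
            {
                "parent_id": run.test_parent_ids,
                "y_true": run.test_targets.ravel(),
                "y_pred": run.test_scores.ravel(),
            }
        ).to_csv(fold_dir / "test_predictions.csv", index=False)
    _timed("train", t)

    fold_results = [
        evaluate.FoldResult(run.fold_index, run.metrics, run.n_test_molecules)
        for run in runs
    ]
    report = evaluate.summarize(
        fold_results, config_fingerprint=evaluate.fingerprint(config.to_dict())
    )
    (outdir / "eval_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
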