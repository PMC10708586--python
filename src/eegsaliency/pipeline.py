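"""End-to-end orchestration: classify, extract features, train the saliency
GAN, then transfer its weights and fine-tune to reconstruct the stimulus.

``run_full_experiment`` executes the whole flow on synthetic data —
generation, stratified cross-validation of the classifier, feature
extraction, adversarial saliency training, per-class SSIM/CC evaluation,
weight transfer and fine-tuning against the original digit images — and
returns a JSON-serialisable report.  Every stage is seeded from the
experiment seed, so two runs with the same configuration agree exactly.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .classifier import (
    ClassifierSpec,
    TrainConfig,
    crossvalidate,
    extract_features,
    predict_labels,
    train_classifier,
)
from .gan import (
    GanPair,
    GanTrainConfig,
    GeneratorSpec,
    build_gan,
    evaluate_against_targets,
    map_to_image,
    train_adversarial,
    train_gan,
)
from .metrics import classification_metrics, confusion_matrix, evaluate_saliency_per_class
from .synthetic import SynthConfig, generate_paired_dataset


class TransferError(ValueError):
    """Source and destination network architectures do not match."""


def _transfer_sequential(src: nn.Sequential, dst: nn.Sequential, tag: str):
    src_state = src.state_dict()
    dst_state = dst.state_dict()
    bad = sorted(
        set(src_state) ^ set(dst_state)
    ) + [
        k for k in src_state
        if k in dst_state and src_state[k].shape != dst_state[k].shape
    ]
    if bad:
        raise TransferError(f"{tag}: mismatched layers/parameters: {bad}")
    dst.load_state_dict(src_state)


def transfer_weights(source: GanPair, destination: GanPair) -> GanPair:
    """Copy all generator and discriminator weights exactly.

    Requires identical architectures; a mismatch raises
    :class:`TransferError` naming the offending parameters.  After the
    copy, destination forward passes equal the source's bit for bit.
    """
    _transfer_sequential(source.generator, destination.generator, "generator")
    _transfer_sequential(source.discriminator, destination.discriminator,
                         "discriminator")
    return destination


def clone_pair(pair: GanPair, seed: int | None = None) -> GanPair:
    """A freshly built pair with the same specs (untrained weights)."""
    fresh = build_gan(copy.deepcopy(pair.gen_spec),
                      copy.deepcopy(pair.disc_spec),
                      seed=pair.seed if seed is None else seed)
    return fresh


@dataclass
class TransferConfig:
    """Fine-tuning schedule: lr = base lr x ``lr_factor``, all layers trainable."""

    lr_factor: float = 0.1
    iterations: int = 100


def finetune_for_original_images(pair: GanPair, features, images,
                                 gan_config: GanTrainConfig | None = None,
                                 transfer_config: TransferConfig | None = None):
    """Fine-tune a transferred pair to reproduce the stimulus images.

    ``images`` are unit-range arrays (or StimulusImage objects) at the
    generator's output side.  Both networks are tuned with the reduced
    learning rate; the history tracks g/d losses plus per-iteration SSIM
    and CC against the targets.  Returns (pair, history).
    """
    gan_config = gan_config or GanTrainConfig()
    transfer_config = transfer_config or TransferConfig()
    targets = np.stack([
        img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
        for img in images
    ])
    if targets.shape[1] != pair.gen_spec.output_side:
        raise ValueError(
            f"image side {targets.shape[1]} != generator output "
            f"{pair.gen_spec.output_side}"
        )
    cfg = replace(gan_config, iterations=transfer_config.iterations,
                  track_metrics=True)
    history = train_adversarial(pair, np.asarray(features, dtype=float),
                                targets, cfg,
                                lr_factor=transfer_config.lr_factor)
    return pair, history


@dataclass
class ExperimentConfig:
    """Configuration of the full synthetic-data experiment."""

    seed: int = 42
    profile: str = "desk"
    synth: SynthConfig | None = None
    classifier_config: TrainConfig | None = None
    classifier_spec: ClassifierSpec | None = None
    gan_config: GanTrainConfig | None = None
    transfer_config: TransferConfig | None = None
    cv_folds: int = 3
    test_fraction: float = 0.25

    def __post_init__(self):
        if self.profile not in ("desk", "paper"):
            raise ValueError("profile must be 'desk' or 'paper'")
        if self.synth is None:
            # desk world: 3 clearly separable classes, 12 trials each,
            # 63-pixel images matching the desk generator side
            self.synth = SynthConfig(
                n_per_class=12, n_classes=3, seed=self.seed,
                noise_sd=0.3, image_size=63 if self.profile == "desk" else 299,
            )
        if self.classifier_spec is None:
            self.classifier_spec = (
                ClassifierSpec.desk(n_classes=self.synth.n_classes)
                if self.profile == "desk"
                else ClassifierSpec(n_classes=self.synth.n_classes)
            )
        if self.classifier_config is None:
            self.classifier_config = TrainConfig(iterations=300, seed=self.seed)
        if self.gan_config is None:
            self.gan_config = GanTrainConfig(iterations=150, seed=self.seed)
        if self.transfer_config is None:
            self.transfer_config = TransferConfig(iterations=80)
        side = 299 if self.profile == "paper" else 63
        if self.synth.image_size != side:
            raise ValueError(
                f"profile {self.profile!r} uses image side {side}, synth "
                f"config has {self.synth.image_size}"
            )


def run_full_experiment(config: ExperimentConfig | None = None,
                        out_dir=None) -> dict:
    """Execute the six-stage pipeline; returns (and optionally writes) a report."""
    config = config or ExperimentConfig()
    report: dict = {"seed": config.seed, "profile": config.profile}
    t0 = time.time()

    def _stage(name):
        report.setdefault("stages", []).append(name)

    try:
        # 1. synthetic data ------------------------------------------------
        _stage("synthetic_data")
        from .eeg_io import prepare

        records, images, maps, manifest = generate_paired_dataset(config.synth)
        records = prepare(records)
        report["synthetic_data"] = {
            "manifest": {str(k): v for k, v in manifest.counts.items()},
            "total": manifest.total,
        }

        # 2. classifier cross-validation and final fit ---------------------
        _stage("classifier")
        folds, summary, (cv_true, cv_pred) = crossvalidate(
            records, k=config.cv_folds, config=config.classifier_config,
            spec=config.classifier_spec,
        )
        rng = np.random.default_rng(config.seed)
        n = len(records)
        perm = rng.permutation(n)
        n_test = max(1, int(round(config.test_fraction * n)))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        model, history = train_classifier(
            train, config=config.classifier_config,
            spec=config.classifier_spec, test_records=test,
        )
        test_pred = predict_labels(model, test)
        test_true = [r.label for r in test]
        cm = confusion_matrix(test_true, test_pred, model.class_labels)
        test_metrics = classification_metrics(cm)
        report["classifier"] = {
            "cv_accuracy_mean": float(folds["accuracy"].mean()),
            "cv_accuracy_sd": float(folds["accuracy"].std()),
            "cv_kappa_mean": float(folds["kappa"].mean()),
            "held_out_accuracy": test_metrics["accuracy"],
            "confusion_matrix": cm.counts.tolist(),
            "predictions": [[str(t), str(p)] for t, p in zip(test_true, test_pred)],
            "final_train_loss": float(history["loss"].iloc[-1]),
        }

        # 3. feature extraction --------------------------------------------
        _stage("features")
        features = extract_features(model, records)
        report["features"] = {
            "length": int(features.shape[1]),
            "n_vectors": int(features.shape[0]),
        }

        # 4. saliency GAN training -----------------------------------------
        _stage("saliency_gan")
        gen_spec = (GeneratorSpec.desk(input_dim=features.shape[1])
                    if config.profile == "desk"
                    else GeneratorSpec(input_dim=features.shape[1]))
        pair, gan_history = train_gan(features, maps, gen_spec=gen_spec,
                                      config=config.gan_config)
        report["saliency_gan"] = {
            "iterations": int(len(gan_history)),
            "final_d_loss": float(gan_history["d_loss"].iloc[-1]),
            "final_g_loss": float(gan_history["g_loss"].iloc[-1]),
        }

        # 5. per-class saliency evaluation ---------------------------------
        _stage("saliency_eval")
        generated = np.clip(pair.generator.forward(features)[:, 0], 0.0, None)
        target_imgs = np.stack([map_to_image(m) for m in maps])
        labels = [r.label for r in records]
        table = evaluate_saliency_per_class(
            list(generated), list(target_imgs), labels
        )
        report["saliency_eval"] = {
            "table": table.to_dict(orient="records"),
            "average_ssim": float(table[table["category"] == "Average"]["SSIM"].iloc[0]),
            "average_cc": float(table[table["category"] == "Average"]["CC"].iloc[0]),
        }

        # 6. transfer + fine-tune on original images -----------------------
        _stage("transfer")
        fresh = clone_pair(pair, seed=config.seed + 1000)
        transfer_weights(pair, fresh)
        image_targets = np.stack([img.pixels for img in images])
        ssim0, cc0 = evaluate_against_targets(fresh, features, image_targets)
        tuned, ft_history = finetune_for_original_images(
            fresh, features, image_targets, gan_config=config.gan_config,
            transfer_config=config.transfer_config,
        )
        ssim1, cc1 = evaluate_against_targets(tuned, features, image_targets)
        report["transfer"] = {
            "ssim_before_finetune": ssim0,
            "cc_before_finetune": cc0,
            "ssim_after_finetune": ssim1,
            "cc_after_finetune": cc1,
            "history_columns": list(ft_history.columns),
        }
        report["runtime_seconds"] = round(time.time() - t0, 2)
    except Exception as exc:
        stage = report.get("stages", ["setup"])[-1]
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
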