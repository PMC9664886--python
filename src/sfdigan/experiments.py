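"""Experiment harnesses: dataset -> training -> NMAE reports.

Four designs are reproduced at configurable scale:

* ``rect`` — the 'complex rectangular' run: four flat models in equal parts,
  random 70/30 split, train, per-image NMAE scatter over the validation set.
* ``cylinder`` — the lumen run: plain and polyp-bearing cylinders in the
  200:120 ratio, 80/20 split, with a naive uniform-frequency SSOP baseline
  evaluated on the same validation images for comparison.
* ``sf_sweep`` — robustness of a trained model to +/-10% illumination
  spatial frequency: fresh validation sets rendered at 0.9 fx and 1.1 fx.
* ``factor_grid`` — the four factor-range rows (final factor alone; plus
  swept absorption strength; plus swept scattering strength; all three),
  each trained and evaluated separately.

Defaults mirror the full-scale study (50 frames per flat model, 200 + 120
cylinder frames, 200 epochs at 256 px); tests and quick runs pass reduced
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .config import Calibration, DEFAULT_CALIBRATION
from .dataset import generate_samples, manifest_from_samples, split_dataset
from .gan import (DiscriminatorSpec, GeneratorSpec, TrainConfig, predict, train)
from .metrics import NMAEReport, nmae, report_from_per_image
from .optics import build_inversion_lut
from .render import CameraParams, render_ground_truth, render_sfdi
from .scenes import (ConfigError, cylinder_dataset_scenes, cylinder_model,
                     flat_dataset_scenes, rect_tumour_model)
from .ssop import ssop_predict

__all__ = ["ExperimentConfig", "run_experiment", "evaluate_model", "evaluate_ssop",
           "FACTOR_GRID_ROWS"]

# the four factor-range rows: (label, factor_ranges) with swept ranges 0.05-0.95
FACTOR_GRID_ROWS = [
    ("final", {}),
    ("final+abs", {"absorption": (0.05, 0.95)}),
    ("final+sct", {"scattering": (0.05, 0.95)}),
    ("final+abs+sct", {"absorption": (0.05, 0.95), "scattering": (0.05, 0.95)}),
]


@dataclass
class ExperimentConfig:
    resolution: int = 256
    frames_per_model: int = 50     # flat dataset: 4 models x this
    n_plain: int = 200             # cylinder dataset composition
    n_polyp: int = 120
    epochs: int = 200
    batch_size: int = 4
    base_channels: int = 16
    disc_channels: int = 16
    lambda_l1: float = 60.0
    lr: float = 1e-4
    final_activation: str = "tanh"
    seed: int = 0
    train_fraction_flat: float = 0.7
    train_fraction_cyl: float = 0.8
    n_sweep_images: int = 50
    calib: Calibration = dc_field(default_factory=lambda: DEFAULT_CALIBRATION)
    camera: CameraParams = dc_field(default_factory=CameraParams)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, lr=self.lr, lambda_l1=self.lambda_l1,
            batch_size=self.batch_size, seed=self.seed,
            generator=GeneratorSpec(size=self.resolution,
                                    base_channels=self.base_channels,
                                    final_activation=self.final_activation),
            discriminator=DiscriminatorSpec(size=self.resolution,
                                            base_channels=self.disc_channels))


def evaluate_model(generator, samples, label: str = "") -> NMAEReport:
    """Per-image NMAE of the generator's R (absorption) and G (scattering)."""
    rows = []
    for s in samples:
        pred = predict(generator, s.input_half)
        truth = s.truth_half
        rows.append((s.sample_id,
                     nmae(pred[..., 0], truth[..., 0]),
                     nmae(pred[..., 1], truth[..., 1])))
    return report_from_per_image(rows, label=label)


def evaluate_ssop(samples, fx: float, calib: Calibration, label: str = "ssop",
                  lut=None) -> NMAEReport:
    """SSOP baseline NMAE on paired samples, on the 8-bit encoded scale.

    The recovered (mu_a, mu_s') maps are re-encoded with the ground-truth
    colour mapping so that prediction and reference share one scale.
    """
    from .render import encode_channel, properties_to_colour

    if lut is None:
        lut = build_inversion_lut(fx, calib)
    rows = []
    for s in samples:
        mu_a, mu_s, _ = ssop_predict(s.input_half, fx, lut, calib)
        r, g = properties_to_colour(mu_a, mu_s, calib)
        pred_r = encode_channel(np.clip(r, 0.05, 0.95))
        pred_g = encode_channel(np.clip(g, 0.05, 0.95))
        truth = s.truth_half
        rows.append((s.sample_id,
                     nmae(pred_r, truth[..., 0]),
                     nmae(pred_g, truth[..., 1])))
    return report_from_per_image(rows, label=label)


def _split_samples(samples, fraction: float, seed: int):
    manifest = split_dataset(manifest_from_samples(samples), fraction, seed)
    labels = manifest.records["split"].to_numpy()
    train_s = [s for s, lab in zip(samples, labels) if lab == "train"]
    val_s = [s for s, lab in zip(samples, labels) if lab == "val"]
    return train_s, val_s, manifest


def _train_flat(config: ExperimentConfig, factor_ranges=None):
    scenes = flat_dataset_scenes(config.frames_per_model, config.seed, factor_ranges)
    samples = generate_samples(scenes, config.calib, config.resolution)
    tr, va, manifest = _split_samples(samples, config.train_fraction_flat,
                                      config.seed + 100)
    gen, history = train(tr, va, config.train_config())
    return gen, history, tr, va, manifest


def _train_cylinder(config: ExperimentConfig, factor_ranges=None):
    scenes = cylinder_dataset_scenes(config.n_plain, config.n_polyp, config.seed,
                                     factor_ranges)
    samples = generate_samples(scenes, config.calib, config.resolution,
                               camera=config.camera)
    tr, va, manifest = _split_samples(samples, config.train_fraction_cyl,
                                      config.seed + 100)
    gen, history = train(tr, va, config.train_config())
    return gen, history, tr, va, manifest


def run_experiment(kind: str, config: ExperimentConfig, generator=None) -> dict:
    """Run one experiment design; returns reports keyed by set label."""
    calib = config.calib
    if kind == "rect":
        gen, history, _, va, manifest = _train_flat(config)
        report = evaluate_model(gen, va, label="rect")
        return {"report": report, "history": history, "generator": gen,
                "manifest": manifest, "val_samples": va}
    if kind == "cylinder":
        gen, history, _, va, manifest = _train_cylinder(config)
        report = evaluate_model(gen, va, label="cylinder")
        ssop_report = evaluate_ssop(va, calib.fx, calib, label="cylinder_ssop")
        return {"report": report, "ssop_report": ssop_report, "history": history,
                "generator": gen, "manifest": manifest, "val_samples": va}
    if kind == "sf_sweep":
        if generator is None:
            generator = run_experiment("rect", config)["generator"]
        reports = {}
        for rel in (0.9, 1.1):
            fx = rel * calib.fx
            scenes = rect_tumour_model(config.n_sweep_images, config.seed + 50)
            for s in scenes:
                s.illumination["fx"] = fx
            samples = generate_samples(scenes, calib, config.resolution)
            reports[f"fx={fx:.3f}"] = evaluate_model(generator, samples,
                                                     label=f"sf{rel:+.0%}")
        return {"reports": reports, "generator": generator}
    if kind == "factor_grid":
        rows = {}
        for k, (label, ranges) in enumerate(FACTOR_GRID_ROWS):
            cfg = replace(config, seed=config.seed + k)
            gen, _, _, va, _ = _train_flat(cfg, factor_ranges=ranges)
            rows[label] = evaluate_model(gen, va, label=label)
        return {"reports": rows}
    raise ConfigError(f"unknown experiment kind {kind!r}")
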