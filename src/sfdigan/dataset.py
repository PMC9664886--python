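"""Pairing, serialisation and splitting of training datasets.

The unit of training data is a 512x256 (W x H) 8-bit RGB PNG: the left
256x256 half is the quantised fringe-illuminated input, the right half the
pure-colour ground truth.  A dataset directory holds ``images/NNNN.png``, a
flat CSV manifest (one row per sample: id, file, frame, model tag, scene
hash, split label) and a JSON header with seeds and counts, so provenance is
inspectable without custom tooling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .render import GroundTruthMap, SfdiImage
from .scenes import scene_to_dict

__all__ = [
    "PairingError",
    "FormatError",
    "PairedSample",
    "DatasetManifest",
    "pair_sample",
    "unpair_sample",
    "split_dataset",
    "write_dataset",
    "read_dataset",
    "generate_samples",
]


class PairingError(ValueError):
    """Input and ground-truth halves are incompatible."""


class FormatError(ValueError):
    """An on-disk sample violates the dataset layout."""


@dataclass
class PairedSample:
    """Concatenated (input | ground truth) 8-bit sample."""

    pixels: np.ndarray  # H x 2W x 3 uint8
    sample_id: str
    frame_index: int = 0
    model_tag: str = ""
    scene_hash: str = ""

    @property
    def input_half(self) -> np.ndarray:
        return self.pixels[:, : self.pixels.shape[1] // 2]

    @property
    def truth_half(self) -> np.ndarray:
        return self.pixels[:, self.pixels.shape[1] // 2:]


@dataclass
class DatasetManifest:
    """Sample records plus split bookkeeping."""

    records: pd.DataFrame  # columns: sample_id, file, frame_index, model_tag, scene_hash, split
    meta: dict = dc_field(default_factory=dict)

    @property
    def counts(self) -> dict:
        return self.records["split"].value_counts().to_dict()


def _hash_scene(scene) -> str:
    try:
        payload = json.dumps(scene_to_dict(scene), sort_keys=True, default=float)
    except Exception:
        payload = repr(scene)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def pair_sample(sfdi: SfdiImage, truth: GroundTruthMap, sample_id: str = "",
                frame_index: int | None = None, scene=None) -> PairedSample:
    """Concatenate input (left) and ground truth (right) into one sample."""
    left = sfdi.quantise()
    right = truth.pixels
    if left.shape != right.shape:
        raise PairingError(f"halves disagree in shape: {left.shape} vs {right.shape}")
    if left.shape[0] != left.shape[1]:
        raise PairingError(f"halves must be square, got {left.shape[:2]}")
    if frame_index is None:
        frame_index = int(sfdi.meta.get("frame_index", 0))
    return PairedSample(
        pixels=np.concatenate([left, right], axis=1),
        sample_id=sample_id or f"{frame_index:04d}",
        frame_index=frame_index,
        model_tag=sfdi.meta.get("model_tag", ""),
        scene_hash=_hash_scene(scene) if scene is not None else "",
    )


def unpair_sample(sample: PairedSample):
    """Exact inverse of pairing: (input uint8, truth uint8)."""
    return sample.input_half.copy(), sample.truth_half.copy()


def generate_samples(scenes, calib, resolution: int = 256, camera=None,
                     noise: dict | None = None) -> list:
    """Render and pair one sample per scene."""
    from .render import render_pair

    samples = []
    for i, scene in enumerate(scenes):
        img, truth = render_pair(scene, calib, resolution, camera=camera, noise=noise)
        samples.append(pair_sample(img, truth, sample_id=f"{i:04d}", scene=scene))
    return samples


def split_dataset(manifest: DatasetManifest, train_fraction: float,
                  seed: int) -> DatasetManifest:
    """Seeded random train/validation split, recorded in the manifest."""
    n = len(manifest.records)
    if n == 0:
        raise FormatError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise FormatError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    split = np.full(n, "val", dtype=object)
    split[order[:n_train]] = "train"
    records = manifest.records.copy()
    records["split"] = split
    meta = dict(manifest.meta)
    meta.update({"split_seed": int(seed), "train_fraction": float(train_fraction),
                 "n_train": int(n_train), "n_val": int(n - n_train)})
    return DatasetManifest(records, meta)


def manifest_from_samples(samples, meta: dict | None = None) -> DatasetManifest:
    records = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "file": [f"images/{s.sample_id}.png" for s in samples],
        "frame_index": [s.frame_index for s in samples],
        "model_tag": [s.model_tag for s in samples],
        "scene_hash": [s.scene_hash for s in samples],
        "split": ["unsplit"] * len(samples),
    })
    return DatasetManifest(records, meta or {})


def write_dataset(samples, directory, meta: dict | None = None,
                  manifest: DatasetManifest | None = None) -> DatasetManifest:
    """Write PNGs + manifest.csv + meta.json; returns the manifest."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = manifest_from_samples(samples, meta)
    for sample in samples:
        Image.fromarray(sample.pixels).save(directory / "images" / f"{sample.sample_id}.png")
    manifest.records.to_csv(directory / "manifest.csv", index=False)
    (directory / "meta.json").write_text(json.dumps(manifest.meta, indent=1))
    return manifest


def read_dataset(directory):
    """Load samples and the manifest back; validates the pair layout."""
    directory = Path(directory)
    records = pd.read_csv(directory / "manifest.csv", keep_default_na=False,
                          dtype={"sample_id": str, "model_tag": str,
                                 "scene_hash": str, "split": str})
    meta_path = directory / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    samples = []
    for row in records.itertuples():
        path = directory / row.file
        pixels = np.asarray(Image.open(path))
        if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.shape[1] != 2 * pixels.shape[0]:
            raise FormatError(f"{path} is not an HxWx3 pair with W = 2H "
                              f"(got {pixels.shape})")
        samples.append(PairedSample(pixels=pixels, sample_id=row.sample_id,
                                    frame_index=int(row.frame_index),
                                    model_tag=row.model_tag,
                                    scene_hash=row.scene_hash))
    return samples, DatasetManifest(records, meta)
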