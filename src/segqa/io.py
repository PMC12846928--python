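"""NIfTI readers/writers and the study run-configuration.

Image volumes are stored as floating-point NIfTI, label masks as unsigned
8-bit NIfTI with labels restricted to 0..3.  Pixel spacing travels in the
NIfTI header zooms; a file without spacing information falls back to unit
spacing with a warning.  The run configuration is one plain-text YAML file
covering every stage of the study; CLI flags override it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .model import ModelConfig, TrainConfig
from .phantom import N_CLASSES

log = logging.getLogger("segqa")


def write_volume(volume: np.ndarray, spacing, path) -> None:
    """Write a (S, H, W) or (H, W) array as NIfTI with the given spacing."""
    vol = np.asarray(volume)
    if np.issubdtype(vol.dtype, np.integer) or vol.dtype == bool:
        data = vol.astype(np.uint8)
    else:
        data = vol.astype(np.float64)
    img = nib.Nifti1Image(data, affine=np.diag(list(spacing) + [1.0] * (4 - len(spacing))))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_volume(path, is_mask: bool = False) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI volume; returns (array, spacing).

    Mask files are validated: values must be integers in 0..3.  Missing
    spacing information falls back to unit spacing with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[: data.ndim]
    if len(zooms) < data.ndim or any(z <= 0 for z in zooms):
        warnings.warn(f"{path}: no usable spacing in header, assuming unit spacing")
        zooms = (1.0,) * data.ndim
    if is_mask:
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(data == np.round(data)):
                raise ValueError(f"{path}: mask file contains non-integer labels")
            data = data.astype(np.int64)
        if data.min() < 0 or data.max() >= N_CLASSES:
            raise ValueError(
                f"{path}: mask labels outside 0..{N_CLASSES - 1} "
                f"(found {int(data.min())}..{int(data.max())})"
            )
        data = data.astype(np.uint8)
    return data, tuple(float(z) for z in zooms)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one end-to-end study run needs, from one YAML file."""

    out_dir: str = "results/run"
    seed: int = 0
    image_size: int = 64
    n_train_scans: int = 10
    n_test_scans: int = 10
    n_ood_scans: int = 10
    slices_per_scan: int = 8
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)  # slice, row, col
    ood_shift: float = 1.0  # scales the OOD intensity/shape shift (1 = default)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    T: int = 50
    thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.30, 0.361, 0.01), 2))
    flag_threshold: float = 0.30
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if len(self.thresholds) == 0:
            raise ValueError("threshold list must be non-empty")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if min(self.n_train_scans, self.n_test_scans, self.n_ood_scans) < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.slices_per_scan < 1:
            raise ValueError("slices_per_scan must be >= 1")
        div = 2 ** (self.model.levels - 1)
        if self.image_size % div:
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^(levels-1) = {div}"
            )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def config_from_yaml(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    kwargs = dict(raw)
    if "model" in kwargs:
        m = dict(kwargs["model"])
        if "dropout_init_range" in m:
            m["dropout_init_range"] = tuple(m["dropout_init_range"])
        kwargs["model"] = ModelConfig(**m)
    if "train" in kwargs:
        kwargs["train"] = TrainConfig(**kwargs["train"])
    for key in ("thresholds", "spacing"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_to_plain(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
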