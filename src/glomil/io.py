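"""Readers, writers and run configuration.

Conventions used everywhere in the package (enforced by tests):
0-based indices, row-major arrays, volume axis order (row, col, slice) =
(H, W, D), half-open rectangles.  Volumes and masks are stored as NIfTI
(``.nii``/``.nii.gz``) or multi-page TIFF (``.tif``/``.tiff``); manifests
and patch locations as CSV; metric summaries as JSON.  All writers are
atomic (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = ["Volume", "RunConfig", "read_volume", "write_volume", "read_mask",
           "write_mask", "read_manifest", "write_manifest", "load_config",
           "dump_config"]

_NIFTI_EXTS = (".nii", ".nii.gz")
_TIFF_EXTS = (".tif", ".tiff")


@dataclasses.dataclass
class Volume:
    """A 3D grayscale stack with (H, W, D) axis order, values in [0, 1]."""

    values: np.ndarray
    id: str = ""
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D (H, W, D), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")


def _atomic_write(path: Path, write_fn) -> None:
    # temp name keeps the target's full suffix so format-by-extension
    # writers (nibabel, tifffile) behave identically on the temp file
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp.",
                               suffix="." + path.name)
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def _normalize_dtype(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        peak = arr.max()
        arr = arr.astype(np.float32) / (peak if peak > 0 else 1)
    elif np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    else:
        raise TypeError(f"unsupported volume dtype {arr.dtype}")
    return arr


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI or multi-page TIFF stack as a (H, W, D) Volume.

    Integer-typed files are rescaled to [0, 1] by their per-volume max;
    a single-page 2D file becomes a volume with D = 1.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
    elif path.suffix.lower() in _TIFF_EXTS:
        arr = tifffile.imread(str(path))
        if arr.ndim == 3:  # pages-first -> (H, W, D)
            arr = np.moveaxis(arr, 0, -1)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 2D or 3D stack, got {arr.shape}")
    if arr.shape[2] == 0:
        raise ValueError(f"{path.name}: volume has zero slices")
    return Volume(values=_normalize_dtype(arr), id=path.name.split(".")[0])


def write_volume(path: str | Path, values: np.ndarray) -> None:
    """Write a (H, W, D) array as NIfTI or multi-page TIFF (by extension)."""
    path = Path(path)
    values = np.asarray(values)
    if _is_nifti(path):
        img = nib.Nifti1Image(values.astype(np.float32), affine=np.eye(4))
        _atomic_write(path, lambda tmp: nib.save(img, tmp))
        return
    if path.suffix.lower() in _TIFF_EXTS:
        pages = np.moveaxis(values.astype(np.float32), -1, 0)
        _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, pages, photometric="minisblack"))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def write_mask(path: str | Path, masks: np.ndarray) -> None:
    """Write a (H, W, D, 2) binary mask stack (classes as a 4th axis)."""
    path = Path(path)
    masks = np.asarray(masks, dtype=np.uint8)
    if _is_nifti(path):
        img = nib.Nifti1Image(masks, affine=np.eye(4))
        _atomic_write(path, lambda tmp: nib.save(img, tmp))
        return
    if path.suffix.lower() in _TIFF_EXTS:
        # store as (D*2, H, W) pages: class-major blocks
        pages = np.concatenate([np.moveaxis(masks[..., c], -1, 0) for c in range(2)])
        _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, pages, photometric="minisblack"))
        return
    raise ValueError(f"unsupported mask format: {path.name}")


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if _is_nifti(path):
        arr = np.asarray(nib.load(str(path)).dataobj)
        if arr.ndim != 4 or arr.shape[3] != 2:
            raise ValueError(f"{path.name}: expected (H, W, D, 2) mask")
        return arr.astype(np.uint8)
    if path.suffix.lower() in _TIFF_EXTS:
        pages = tifffile.imread(str(path))
        depth = pages.shape[0] // 2
        out = np.stack([np.moveaxis(pages[c * depth:(c + 1) * depth], 0, -1)
                        for c in range(2)], axis=-1)
        return out.astype(np.uint8)
    raise ValueError(f"unsupported mask format: {path.name}")


# -- manifests --------------------------------------------------------------------

MANIFEST_COLUMNS = ["id", "volume_path", "mask_path", "y_b", "y_m", "D",
                    "group_id", "split"]


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    _atomic_write(Path(path),
                  lambda tmp: manifest[MANIFEST_COLUMNS].to_csv(tmp, index=False))


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = manifest[~manifest["y_b"].isin([0, 1]) | ~manifest["y_m"].isin([0, 1])]
    if len(bad):
        raise ValueError("manifest labels must be in {0, 1}")
    if not manifest["split"].isin(["train", "val", "test"]).all():
        raise ValueError("manifest split must be train/val/test")
    return manifest


# -- run configuration -------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """All tunables of the pipeline with their documented defaults.

    ``t`` is the pooling percentage *per slice* (the pooled count is
    t/100 of one slice's saliency cells, independent of slice count);
    ``omega`` the constant initialization of the 1x1 segmentation layer;
    ``zeta`` the half-width (slices) of retrieval suppression/sampling;
    ``beta`` the saliency L1 weight.  Defaults: K=8 patches of 256x256,
    zeta=10; t, omega, learning_rate and beta default to the midpoints of
    their published search ranges (t ~ U(10.97, 274.25), log10(omega) ~
    U(-3, -2), log10(lr) ~ U(-5.5, -4.5), log10(beta) ~ U(-6.54, -4.54)).
    """

    t: float = 142.61
    omega: float = 10 ** -2.5
    backbone_width: int = 16
    backbone_downsample: int = 16
    saliency_nonlinearity: str = "relu_tanh"   # "sigmoid" available for A/B runs
    K: int = 8
    zeta: int = 10
    patch_size: int = 256
    patch_width: int = 16
    feature_dim: int = 512        # S
    attention_dim: int = 128      # L
    learning_rate: float = 10 ** -5.0
    beta: float = 10 ** -5.54
    epochs: int = 40
    early_stop_patience: int = 15
    batch_size: int = 4           # gradient-accumulation group
    seed: int = 0
    tta_count: int = 10
    max_shift: int = 100
    max_rescale: float = 0.1

    def validate(self) -> "RunConfig":
        errors = []
        if self.t <= 0:
            errors.append("t must be > 0")
        if self.omega <= 0:
            errors.append("omega must be > 0")
        if self.K < 1:
            errors.append("K must be >= 1")
        if self.zeta < 0:
            errors.append("zeta must be >= 0")
        if self.patch_size < 1:
            errors.append("patch_size must be >= 1")
        if self.beta < 0:
            errors.append("beta must be >= 0")
        if self.tta_count < 1:
            errors.append("tta_count must be >= 1")
        if self.max_shift < 0:
            errors.append("max_shift must be >= 0")
        if self.backbone_width % 8:
            errors.append("backbone_width must be a multiple of 8")
        if self.saliency_nonlinearity not in ("relu_tanh", "sigmoid"):
            errors.append("saliency_nonlinearity must be relu_tanh or sigmoid")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return self


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected, defaults filled in."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**raw).validate()


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    if path is not None:
        _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(text))
    return text
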