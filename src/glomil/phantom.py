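"""Synthetic tomosynthesis-like phantoms with tiny class-conditional lesions.

Emulates the statistical structure of a reconstructed slice stack: every
inserted structure keeps its full in-plane footprint on every slice but
its contrast decays exponentially with distance from its focus slice, so
the same object is visible from many slices with varying sharpness.
Lesions occupy a tiny fraction of the volume — the small-object regime
the classifier targets.  Benign lesions are discs; malignant lesions are
spiculated star polygons: the simplest shape pair a small patch encoder
can separate.

Every sample carries voxel-level ground-truth masks which are used only
for evaluating weakly-supervised localization, never for training.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

__all__ = ["PhantomSpec", "LesionRecord", "PhantomSample",
           "generate_phantom", "generate_dataset"]

CLASS_NAMES = ("benign", "malignant")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Generator configuration; defaults define the desk-scale study conditions."""

    height: int = 64
    width: int = 64
    slice_count_range: tuple[int, int] = (4, 8)
    background_level: float = 0.35
    background_texture_scale: float = 8.0
    background_noise_sd: float = 0.03
    #: probability of inserting 0/1/2 lesions of each class, independently per class
    lesions_per_class_distribution: tuple[float, float, float] = (0.5, 0.4, 0.1)
    lesion_radius_range: tuple[float, float] = (2.5, 4.5)
    focus_spread: float = 1.5
    lesion_contrast_range: tuple[float, float] = (0.25, 0.5)
    #: minimum gap (pixels) between lesion bounding circles
    min_lesion_gap: float = 3.0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom height and width must be >= 64")
        lo, hi = self.slice_count_range
        if not (2 <= lo <= hi <= 96):
            raise ValueError("slice_count_range must lie within [2, 96]")
        if self.lesion_radius_range[1] > min(self.height, self.width) / 8:
            raise ValueError("max lesion radius exceeds min(height, width)/8")
        if self.focus_spread < 1:
            raise ValueError("focus_spread must be >= 1 slice")
        if self.lesion_contrast_range[0] <= 0:
            raise ValueError("lesion contrast must be positive")
        p = np.asarray(self.lesions_per_class_distribution, dtype=float)
        if p.shape != (3,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("lesions_per_class_distribution must be a probability "
                             "vector over {0, 1, 2}")


@dataclasses.dataclass(frozen=True)
class LesionRecord:
    class_index: int          # 0 = benign, 1 = malignant
    center: tuple[int, int]   # (row, col)
    radius: float
    focus_slice: int
    contrast: float


@dataclasses.dataclass
class PhantomSample:
    volume: np.ndarray            # (H, W, D) float32 in [0, 1]
    labels: tuple[int, int]       # (y_benign, y_malignant)
    masks: np.ndarray             # (H, W, D, 2) uint8
    lesions: list[LesionRecord]
    spec: PhantomSpec
    seed: int | None = None


def _lesion_footprint(class_index: int, center: tuple[int, int], radius: float,
                      shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Binary in-plane footprint: disc (benign) or spiculated star (malignant)."""
    mask = np.zeros(shape, dtype=bool)
    if class_index == 0:
        rr, cc = draw_disk(center, radius, shape=shape)
        mask[rr, cc] = True
    else:
        n_spikes = int(rng.integers(6, 11))
        phase = rng.uniform(0, 2 * np.pi)
        angles = phase + np.arange(2 * n_spikes) * np.pi / n_spikes
        radii = np.where(np.arange(2 * n_spikes) % 2 == 0, radius, 0.45 * radius)
        rows = center[0] + radii * np.sin(angles)
        cols = center[1] + radii * np.cos(angles)
        rr, cc = draw_polygon(rows, cols, shape=shape)
        mask[rr, cc] = True
    return mask


def _sample_lesions(spec: PhantomSpec, depth: int, rng: np.random.Generator,
                    force_counts: tuple[int, int] | None) -> list[LesionRecord]:
    counts = []
    for c in range(2):
        if force_counts is not None:
            counts.append(int(force_counts[c]))
        else:
            counts.append(int(rng.choice(3, p=spec.lesions_per_class_distribution)))
    records: list[LesionRecord] = []
    margin = int(np.ceil(spec.lesion_radius_range[1])) + 2
    for c in range(2):
        for _ in range(counts[c]):
            radius = rng.uniform(*spec.lesion_radius_range)
            placed = False
            for _trial in range(100):
                row = int(rng.integers(margin, spec.height - margin))
                col = int(rng.integers(margin, spec.width - margin))
                ok = all(
                    np.hypot(row - r.center[0], col - r.center[1])
                    > radius + r.radius + spec.min_lesion_gap
                    for r in records
                )
                if ok:
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place a non-overlapping lesion after 100 trials; "
                    f"spec too crowded: {spec}"
                )
            records.append(LesionRecord(
                class_index=c,
                center=(row, col),
                radius=radius,
                focus_slice=int(rng.integers(0, depth)),
                contrast=float(rng.uniform(*spec.lesion_contrast_range)),
            ))
    return records


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator, *,
                     force_counts: tuple[int, int] | None = None) -> PhantomSample:
    """Generate one phantom volume with labels and voxel ground-truth masks.

    The background is smoothed Gaussian noise at ``background_texture_scale``
    plus i.i.d. pixel noise, drawn independently per slice.  Each lesion's
    footprint is stamped on *every* slice with contrast scaled by
    ``exp(-|d - d_focus| / focus_spread)``; the ground-truth mask covers
    the slices where that factor is at least 1/2 (the slices the lesion
    "spans"), with an identical in-plane footprint on each of them.
    """
    h, w = spec.height, spec.width
    d_lo, d_hi = spec.slice_count_range
    depth = int(rng.integers(d_lo, d_hi + 1))

    texture = rng.normal(0.0, 1.0, size=(h, w, depth))
    for d in range(depth):
        texture[:, :, d] = gaussian_filter(texture[:, :, d],
                                           spec.background_texture_scale)
    sd = texture.std()
    texture = texture / (sd if sd > 0 else 1.0) * 0.05
    volume = spec.background_level + texture
    volume += rng.normal(0.0, spec.background_noise_sd, size=(h, w, depth))

    lesions = _sample_lesions(spec, depth, rng, force_counts)
    masks = np.zeros((h, w, depth, 2), dtype=np.uint8)
    span = spec.focus_spread * np.log(2.0)  # contrast >= 1/2 within this distance
    for rec in lesions:
        footprint = _lesion_footprint(rec.class_index, rec.center, rec.radius,
                                      (h, w), rng)
        decay = np.exp(-np.abs(np.arange(depth) - rec.focus_slice)
                       / spec.focus_spread)
        volume[footprint] += rec.contrast * decay[np.newaxis, :]
        in_span = np.abs(np.arange(depth) - rec.focus_slice) <= span
        masks[:, :, in_span, rec.class_index] |= footprint[:, :, np.newaxis]

    np.clip(volume, 0.0, 1.0, out=volume)
    labels = tuple(int(masks[:, :, :, c].any()) for c in range(2))
    return PhantomSample(volume=volume.astype(np.float32), labels=labels,
                         masks=masks, lesions=lesions, spec=spec)


def _sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed: truncated SHA-256 of (master, index)."""
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def generate_samples(n: int, spec: PhantomSpec, seed: int, *,
                     views_per_group: int = 1) -> list[PhantomSample]:
    """Generate ``n`` phantoms in memory with per-sample derived seeds.

    Samples in the same group (consecutive blocks of ``views_per_group``)
    share their lesion counts per class — and hence their labels — the way
    two views of the same subject would, but lesion placement, size and
    background are drawn independently per view.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples: list[PhantomSample] = []
    group_counts: dict[int, tuple[int, int]] = {}
    for i in range(n):
        gid = i // views_per_group
        sub = _sample_seed(seed, i)
        rng = np.random.default_rng(sub)
        if views_per_group > 1:
            if gid not in group_counts:
                grng = np.random.default_rng(_sample_seed(seed, 10**9 + gid))
                group_counts[gid] = tuple(
                    int(grng.choice(3, p=spec.lesions_per_class_distribution))
                    for _ in range(2)
                )
            sample = generate_phantom(spec, rng, force_counts=group_counts[gid])
        else:
            sample = generate_phantom(spec, rng)
        sample.seed = sub
        samples.append(sample)
    return samples


def generate_dataset(n: int, spec: PhantomSpec, seed: int, out_dir: str | Path, *,
                     views_per_group: int = 1,
                     split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                     overwrite: bool = False, fmt: str = "nifti") -> pd.DataFrame:
    """Write ``n`` phantoms plus masks and a CSV manifest to ``out_dir``.

    The manifest has one row per volume: id, volume_path, mask_path, y_b,
    y_m, D, group_id, split.  Splits are assigned contiguously by group so
    no group straddles a split.  Regenerating with the same seed yields a
    byte-identical manifest.
    """
    from . import io as gio  # deferred: io imports nothing from here

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    samples = generate_samples(n, spec, seed, views_per_group=views_per_group)
    n_groups = (n + views_per_group - 1) // views_per_group
    n_train = int(round(split_fractions[0] * n_groups))
    n_val = int(round(split_fractions[1] * n_groups))

    rows = []
    for i, s in enumerate(samples):
        gid = i // views_per_group
        split = ("train" if gid < n_train
                 else "val" if gid < n_train + n_val else "test")
        sid = f"phantom_{i:05d}"
        ext = ".nii.gz" if fmt == "nifti" else ".tiff"
        vol_path = out_dir / f"{sid}{ext}"
        mask_path = out_dir / f"{sid}_mask{ext}"
        gio.write_volume(vol_path, s.volume)
        gio.write_mask(mask_path, s.masks)
        rows.append({
            "id": sid,
            "volume_path": vol_path.name,
            "mask_path": mask_path.name,
            "y_b": s.labels[0],
            "y_m": s.labels[1],
            "D": s.volume.shape[2],
            "group_id": gid,
            "split": split,
        })
    manifest = pd.DataFrame(rows)
    gio.write_manifest(out_dir / "manifest.csv", manifest)
    return manifest
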