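"""Greedy ROI retrieval from the 3D saliency map.

``retrieve_roi_from_3d_image`` selects K fixed-size 2D patches from a
stack guided by its saliency map: per-class maps are min-max normalized
and summed into a criterion map A*, then K times the single-slice
rectangle maximizing the summed criterion is picked, mapped back to
image coordinates, and the selected footprint is zeroed across the
+-zeta neighboring slices so near-duplicate appearances of the same
structure on adjacent slices are not picked again.  During training the
selected slice is additionally resampled uniformly from the same +-zeta
window as a depth-jitter augmentation.

Two implementations are provided: the optimized one (per-slice summed
column tables) used by the model, and ``naive_retrieve_roi``, a literal
sliding-window transcription kept as an executable reference — the two
must agree exactly, which the test suite asserts on random instances.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PatchLocation", "RetrievalConfig", "minmax_normalize",
           "combine_class_maps", "retrieve_roi_from_3d_image",
           "naive_retrieve_roi", "extract_patch"]


@dataclasses.dataclass(frozen=True)
class PatchLocation:
    """(slice, top, left) of a half-open size[0] x size[1] crop, 0-based."""

    slice: int
    top: int
    left: int
    size: tuple[int, int] = (256, 256)


@dataclasses.dataclass(frozen=True)
class RetrievalConfig:
    K: int = 8
    zeta: int = 10
    patch_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")


def minmax_normalize(plane: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant plane maps to all zeros."""
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("cannot normalize an empty plane")
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def combine_class_maps(saliency: np.ndarray) -> np.ndarray:
    """Criterion map A* = sum over classes of min-max normalized planes."""
    if saliency.ndim != 4 or saliency.shape[3] != 2:
        raise ValueError(f"saliency must be (h, w, D, 2), got {saliency.shape}")
    return sum(minmax_normalize(saliency[..., c]) for c in range(2))


def _grid_rect_size(patch_size: tuple[int, int], grid: tuple[int, int],
                    image: tuple[int, int]) -> tuple[int, int]:
    h, w = grid
    H, W = image
    rh = max(1, int(round(patch_size[0] * h / H)))
    rw = max(1, int(round(patch_size[1] * w / W)))
    if rh > h or rw > w:
        raise ValueError(
            f"patch footprint {rh}x{rw} exceeds the {h}x{w} saliency grid")
    return rh, rw


def _grid_to_image(gt: int, gl: int, grid: tuple[int, int],
                   image_shape: tuple[int, int, int],
                   patch_size: tuple[int, int]) -> tuple[int, int]:
    H, W, _ = image_shape
    h, w = grid
    top = int(round(gt * H / h))
    left = int(round(gl * W / w))
    # shift inward so the full crop fits
    top = min(max(top, 0), H - patch_size[0])
    left = min(max(left, 0), W - patch_size[1])
    return top, left


# two candidate rectangles can have *exactly* equal criteria in real
# arithmetic (e.g. when suppression zeroes every cell they differ in);
# summation order then perturbs the computed sums by ~1e-15, so ties are
# detected with a small absolute slack and broken lexicographically
_TIE_TOL = 1e-9


def _argmax_lex(crit: np.ndarray) -> tuple[int, int, int]:
    """First near-maximum of a (D, nh, nw) criterion in (slice, top, left)
    order; candidates within _TIE_TOL of the max count as tied."""
    best = crit.max()
    idx = int(np.argmax(crit.ravel() >= best - _TIE_TOL))
    return tuple(int(v) for v in np.unravel_index(idx, crit.shape))


def retrieve_roi_from_3d_image(saliency: np.ndarray,
                               config: RetrievalConfig,
                               image_shape: tuple[int, int, int],
                               training: bool = False,
                               rng: np.random.Generator | None = None,
                               ) -> list[PatchLocation]:
    """Greedy selection of K patch locations from an (h, w, D, 2) saliency map.

    Ties on the criterion break to the lexicographically smallest
    (slice, top, left).  In inference mode the result is a pure function
    of its inputs; in training mode (and D > 1) each selected slice is
    replaced by a uniform draw from [d - zeta, d + zeta] clipped to the
    stack, and ``rng`` must be provided.
    """
    H, W, D = image_shape
    h, w = saliency.shape[:2]
    if saliency.shape[2] != D:
        raise ValueError(f"saliency depth {saliency.shape[2]} != image depth {D}")
    if training and D > 1 and rng is None:
        raise ValueError("training-mode retrieval requires an rng")
    rh, rw = _grid_rect_size(config.patch_size, (h, w), (H, W))
    astar = combine_class_maps(saliency)

    locations: list[PatchLocation] = []
    for _ in range(config.K):
        # criterion for every single-slice rectangle via per-slice cumsums
        cs = astar.cumsum(axis=0).cumsum(axis=1)
        cs = np.pad(cs, ((1, 0), (1, 0), (0, 0)))
        win = (cs[rh:, rw:] - cs[:-rh, rw:] - cs[rh:, :-rw] + cs[:-rh, :-rw])
        crit = np.moveaxis(win, -1, 0)  # (D, nh, nw): lexicographic argmax order
        d, gt, gl = _argmax_lex(crit)
        top, left = _grid_to_image(gt, gl, (h, w), image_shape, config.patch_size)
        out_slice = d
        if training and D > 1:
            lo, hi = max(0, d - config.zeta), min(D - 1, d + config.zeta)
            out_slice = int(rng.integers(lo, hi + 1))
        locations.append(PatchLocation(out_slice, top, left,
                                       tuple(config.patch_size)))
        lo, hi = max(0, d - config.zeta), min(D, d + config.zeta + 1)
        astar[gt:gt + rh, gl:gl + rw, lo:hi] = 0.0
    return locations


def naive_retrieve_roi(saliency: np.ndarray, config: RetrievalConfig,
                       image_shape: tuple[int, int, int], training: bool = False,
                       rng: np.random.Generator | None = None,
                       ) -> list[PatchLocation]:
    """Literal transcription of the greedy pseudocode (explicit loops).

    Reference implementation: evaluates the rectangle criterion by direct
    summation over every candidate position.  Must agree exactly with
    :func:`retrieve_roi_from_3d_image`.
    """
    H, W, D = image_shape
    h, w = saliency.shape[:2]
    rh, rw = _grid_rect_size(config.patch_size, (h, w), (H, W))
    astar = combine_class_maps(saliency)

    locations: list[PatchLocation] = []
    for _ in range(config.K):
        sums = {}
        best = -np.inf
        for d in range(D):
            for gt in range(h - rh + 1):
                for gl in range(w - rw + 1):
                    s = astar[gt:gt + rh, gl:gl + rw, d].sum()
                    sums[(d, gt, gl)] = s
                    best = max(best, s)
        # first candidate within the tie tolerance, in (slice, top, left) order
        best_pos = next(pos for pos, s in sums.items() if s >= best - _TIE_TOL)
        d, gt, gl = best_pos
        top, left = _grid_to_image(gt, gl, (h, w), image_shape, config.patch_size)
        out_slice = d
        if training and D > 1:
            lo, hi = max(0, d - config.zeta), min(D - 1, d + config.zeta)
            out_slice = int(rng.integers(lo, hi + 1))
        locations.append(PatchLocation(out_slice, top, left,
                                       tuple(config.patch_size)))
        lo, hi = max(0, d - config.zeta), min(D, d + config.zeta + 1)
        astar[gt:gt + rh, gl:gl + rw, lo:hi] = 0.0
    return locations


def extract_patch(volume: np.ndarray, loc: PatchLocation) -> np.ndarray:
    """Copy the single-slice crop at ``loc`` from a (H, W, D) volume."""
    H, W, D = volume.shape
    ph, pw = loc.size
    if not (0 <= loc.slice < D and 0 <= loc.top <= H - ph
            and 0 <= loc.left <= W - pw):
        raise ValueError(f"patch {loc} does not fit inside volume {volume.shape}")
    return volume[loc.top:loc.top + ph, loc.left:loc.left + pw, loc.slice].copy()


def locations_to_frame(volume_id: str, locations: list[PatchLocation]):
    """Patch locations as a DataFrame (volume id, rank, slice, top, left)."""
    import pandas as pd

    return pd.DataFrame([
        {"volume_id": volume_id, "rank": k, "slice": loc.slice,
         "top": loc.top, "left": loc.left,
         "height": loc.size[0], "width": loc.size[1]}
        for k, loc in enumerate(locations)
    ])
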