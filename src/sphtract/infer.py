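"""Tri-planar inference: per-view 2D prediction, probability fusion, thresholding.

A trained 2D network is applied slice-by-slice along each of the three
anatomical planes of a cubic fODF volume, giving three full 3D probability
maps.  These are fused by voxel-wise averaging and thresholded (strictly
above 0.5 by default) into the final binary tract mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sphtract.data import VIEWS


@dataclass(frozen=True)
class ProbabilityVolume:
    """3D map of tract-membership probabilities in [0, 1]."""

    values: np.ndarray  # (X, Y, Z) or (X, Y, Z, C)
    provenance: str = "fused"  # "axis0" | "axis1" | "axis2" | "fused"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim not in (3, 4):
            raise ValueError("values must be a 3D (or 3D+channel) array")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def predict_view(model, volume: np.ndarray, view: int,
                 batch_size: int = 16) -> ProbabilityVolume:
    """Predict every slice along ``view`` and restack into a 3D map.

    ``model`` is any callable mapping (B, H, W, Cin) -> (B, H, W, Cout)
    probabilities; slices are taken along the given axis and the outputs are
    stacked back in the original orientation.  Single-channel outputs are
    squeezed to a plain 3D map.
    """
    if view not in VIEWS:
        raise ValueError("view must be 0, 1 or 2")
    vol = np.asarray(volume)
    if vol.ndim != 4:
        raise ValueError("expected a 4D (X, Y, Z, channels) volume")
    n = vol.shape[view]
    slabs = []
    for start in range(0, n, batch_size):
        idx = range(start, min(start + batch_size, n))
        batch = np.stack([np.take(vol, i, axis=view) for i in idx])
        out = np.asarray(model(batch), dtype=np.float32)
        if out.shape[:3] != batch.shape[:3]:
            raise ValueError(
                f"model output spatial shape {out.shape[:3]} does not match "
                f"input {batch.shape[:3]}"
            )
        slabs.append(out)
    probs = np.concatenate(slabs, axis=0)  # (n, H, W, C)
    probs = np.moveaxis(probs, 0, view)
    if probs.shape[-1] == 1:
        probs = probs[..., 0]
    return ProbabilityVolume(np.clip(probs, 0.0, 1.0), provenance=f"axis{view}")


def fuse_views(maps: list[ProbabilityVolume] | tuple[ProbabilityVolume, ...]) -> ProbabilityVolume:
    """Voxel-wise arithmetic mean of per-view probability maps.

    Commutative in argument order; the fused value lies between the
    voxel-wise min and max of the inputs.
    """
    if not maps:
        raise ValueError("need at least one probability map")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"probability maps have mismatched grids: {shapes}")
    fused = np.mean([m.values.astype(np.float64) for m in maps], axis=0)
    return ProbabilityVolume(fused.astype(np.float32), provenance="fused")


def threshold_mask(pmap: ProbabilityVolume, tau: float = 0.5) -> np.ndarray:
    """Binary mask: voxel positive iff probability strictly exceeds ``tau``.

    The strict inequality makes the tie at exactly 0.5 negative, so behaviour
    is bit-stable (e.g. fused views (1.0, 0.0, 0.5) average to 0.5 -> negative).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    return (pmap.values > tau).astype(np.uint8)


def segment_volume(model, volume: np.ndarray, tau: float = 0.5,
                   views: tuple[int, ...] = VIEWS,
                   return_views: bool = False):
    """Full pipeline: per-view prediction, fusion, thresholding.

    Returns ``(mask, fused)`` or ``(mask, fused, per_view_maps)``.
    """
    per_view = [predict_view(model, volume, v) for v in views]
    fused = fuse_views(per_view)
    mask = threshold_mask(fused, tau)
    if return_views:
        return mask, fused, per_view
    return mask, fused
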