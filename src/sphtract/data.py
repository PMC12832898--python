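"""Deterministic preprocessing: central crop, normalization, tri-plane slicing,
subject-wise splits.

The segmentation network is 2D: a single in-plane slice of the 4D fODF volume
(H x W x 45 coefficients) is one training example, and slices are taken along
all three anatomical planes of a cubic grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VIEWS = (0, 1, 2)  # slicing axes: axis0 / axis1 / axis2


@dataclass(frozen=True)
class SliceRecord:
    """One 2D training example: an fODF slice and its aligned label."""

    subject: str
    view: int  # slicing axis in {0, 1, 2}
    index: int  # slice position along that axis
    image: np.ndarray  # (H, W, n_coeffs)
    label: np.ndarray  # (H, W) binary or (H, W, C) multi-label

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError("view must be 0, 1 or 2")
        if self.image.shape[0] != self.image.shape[1]:
            raise ValueError("slices must be square in-plane")
        if self.label.shape[:2] != self.image.shape[:2]:
            raise ValueError("label must align voxel-for-voxel with image")


@dataclass(frozen=True)
class SplitPlan:
    """Pairwise-disjoint train / validation / test subject lists."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("splits must be pairwise disjoint")


def central_crop(volume: np.ndarray, target: tuple[int, int, int] = (144, 144, 144)) -> np.ndarray:
    """Centrally crop the three spatial axes to ``target``; channels untouched.

    The window on each axis starts at floor((dim - target)/2) with half-open
    extent ``target`` — for a 145 x 174 x 145 grid cropped to 144^3 the
    offsets are (0, 15, 0), leaving any odd leftover voxel on the high side.
    """
    vol = np.asarray(volume)
    if vol.ndim not in (3, 4):
        raise ValueError("expected a 3D or 4D array")
    spatial = vol.shape[:3]
    for dim, tgt in zip(spatial, target):
        if dim < tgt:
            raise ValueError(
                f"cannot crop spatial shape {spatial} to {tuple(target)}: "
                f"dimension {dim} < {tgt}"
            )
    slices = tuple(
        slice((dim - tgt) // 2, (dim - tgt) // 2 + tgt)
        for dim, tgt in zip(spatial, target)
    )
    return vol[slices]


def normalize_fodf(volume: np.ndarray) -> np.ndarray:
    """Scale all SH channels by the mean j=0 coefficient over foreground voxels.

    Foreground = voxels with a positive j=0 coefficient.  The result is
    invariant to global positive rescaling of the input, which removes
    arbitrary intensity scaling between fODF reconstructions.
    """
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim != 4:
        raise ValueError("expected a 4D (X, Y, Z, n_coeffs) volume")
    c0 = vol[..., 0]
    fg = c0 > 0
    if not np.any(fg):
        raise ValueError("cannot normalize: no foreground voxel with positive j=0 coefficient")
    return vol / np.float32(c0[fg].mean())


def extract_slices(
    fodf: np.ndarray,
    label: np.ndarray,
    subject: str = "subject",
    views: tuple[int, ...] = VIEWS,
) -> list[SliceRecord]:
    """All 2D slices of a cubic volume along the requested axes.

    ``label`` may be (S, S, S) binary for single-class training or
    (S, S, S, C) for multi-label.  Stacking the records of any single view in
    index order reproduces the volume exactly.
    """
    vol = np.asarray(fodf)
    lab = np.asarray(label)
    if vol.ndim != 4:
        raise ValueError("fodf must be 4D (X, Y, Z, n_coeffs)")
    if lab.shape[:3] != vol.shape[:3]:
        raise ValueError("label grid must match the fODF grid")
    S = vol.shape[0]
    views = tuple(views)
    if any(v not in VIEWS for v in views) or not views:
        raise ValueError("views must be a non-empty subset of (0, 1, 2)")
    if (vol.shape[1] != S or vol.shape[2] != S) and len(views) > 1:
        raise ValueError("multiple views require a cubic spatial grid")
    records = []
    for v in views:
        for i in range(vol.shape[v]):
            records.append(
                SliceRecord(
                    subject=subject,
                    view=v,
                    index=i,
                    image=np.take(vol, i, axis=v),
                    label=np.take(lab, i, axis=v),
                )
            )
    return records


def stack_view(records: list[SliceRecord], view: int) -> np.ndarray:
    """Reassemble the 3D (or 4D) volume from one view's slice records."""
    recs = sorted((r for r in records if r.view == view), key=lambda r: r.index)
    if not recs:
        raise ValueError(f"no records for view {view}")
    return np.stack([r.image for r in recs], axis=view)


def make_splits(
    subjects: list[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    explicit: tuple[list[str], list[str], list[str]] | None = None,
) -> SplitPlan:
    """Disjoint, exhaustive subject-wise train/validation/test split.

    Explicit lists pass through unchanged (validated for disjointness);
    otherwise subjects are shuffled with ``seed`` and partitioned by
    ``fractions`` (train size rounded to nearest, validation to floor of its
    share of the remainder).  105 subjects at (0.6, 0.2, 0.2) give the
    63/21/21 fold sizes used for hyperparameter selection and testing.
    """
    if explicit is not None:
        tr, va, te = explicit
        return SplitPlan(tuple(tr), tuple(va), tuple(te))
    subjects = list(subjects)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_val = max(1, min(n_val, n - n_train - 1))
    return SplitPlan(
        tuple(order[:n_train]),
        tuple(order[n_train: n_train + n_val]),
        tuple(order[n_train + n_val:]),
    )
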