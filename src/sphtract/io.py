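"""NIfTI and sidecar I/O.

Conventions: 4D fODF volumes store the SH coefficient axis as the 4th
dimension in the package's flat ordering; masks are uint8 {0, 1};
probabilities float32.  Affines are propagated untouched from input to
output — volumes are assumed already consistently oriented, as after
standard preprocessing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a NIfTI file."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_nifti(path: str | Path, data: np.ndarray,
               affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def save_mask(path: str | Path, mask: np.ndarray,
              affine: np.ndarray | None = None) -> None:
    save_nifti(path, np.asarray(mask).astype(np.uint8), affine)


def save_probability(path: str | Path, probs: np.ndarray,
                     affine: np.ndarray | None = None) -> None:
    save_nifti(path, np.asarray(probs).astype(np.float32), affine)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
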