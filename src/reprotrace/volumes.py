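"""Overlap metrics and difference maps for label volumes.

Tissue classifications and subcortical segmentations are integer label
maps on a voxel grid (0 = background).  Two runs of the same segmentation
tool are compared with:

- the Dice similarity index ``2|A∩B|/(|A|+|B|)`` per label, and a
  generalized (label-summed) global Dice for the whole map;
- a binarized difference mask (1 where the labels disagree), whose sum
  across subjects localizes where disagreements concentrate;
- file checksums, as a cheap first screen before any metric is computed.

Inputs must already live on a common grid: comparison is voxel-for-voxel
and never resamples.
"""

from __future__ import annotations

import gzip
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "DiceReport",
    "ChecksumResult",
    "dice",
    "per_label_dice",
    "binarized_diff",
    "diff_sum",
    "checksum_compare",
    "load_label_volume",
    "save_volume",
]


@dataclass
class LabelVolume:
    """A 3D integer label map with voxel geometry.

    ``affine`` (grid-to-world) is carried through I/O but never computed
    on; all comparisons are in voxel space.
    """

    grid: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            as_int = self.grid.astype(np.int64)
            if not np.array_equal(as_int, self.grid):
                raise ValueError("label grid must contain integers")
            self.grid = as_int
        if self.grid.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.grid)
        return u[u != 0]


def _as_grid(x) -> np.ndarray:
    if isinstance(x, LabelVolume):
        return x.grid
    return np.asarray(x)


def dice(
    a: np.ndarray,
    b: np.ndarray,
    empty: str = "one",
) -> float:
    """Dice similarity index between two binary masks.

    Parameters
    ----------
    a, b
        Boolean / 0-1 arrays of identical shape.
    empty
        Convention when both masks are empty: ``"one"`` (default) returns
        1.0 — perfect agreement on absence — with a warning; ``"nan"``
        returns NaN; ``"strict"`` raises.
    """
    a = _as_grid(a).astype(bool)
    b = _as_grid(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_a = int(a.sum())
    size_b = int(b.sum())
    if size_a == 0 and size_b == 0:
        if empty == "strict":
            raise ValueError("Dice undefined: both masks are empty")
        if empty == "nan":
            return float("nan")
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    overlap = int(np.logical_and(a, b).sum())
    return 2.0 * overlap / (size_a + size_b)


@dataclass
class DiceReport:
    """Per-label and generalized global Dice for a pair of label volumes.

    ``per_label`` maps each evaluated label to its Dice; labels requested
    but absent from both volumes are listed in ``absent`` rather than
    scored 0.
    """

    per_label: Dict[int, float] = field(default_factory=dict)
    global_dice: float = float("nan")
    absent: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_label": {int(k): float(v) for k, v in self.per_label.items()},
            "global_dice": float(self.global_dice),
            "absent": [int(l) for l in self.absent],
        }


def per_label_dice(
    a: Union[LabelVolume, np.ndarray],
    b: Union[LabelVolume, np.ndarray],
    labels: Optional[Sequence[int]] = None,
    empty: str = "one",
) -> DiceReport:
    """Dice per label plus generalized global Dice.

    The global value is the label-summed (generalized) Dice
    ``2·Σ_l |A_l ∩ B_l| / Σ_l (|A_l| + |B_l|)`` over nonzero labels,
    which equals 1 iff the two volumes agree on every nonzero voxel.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    if ga.shape != gb.shape:
        raise ValueError(f"volume shapes differ: {ga.shape} vs {gb.shape}")
    if labels is None:
        labels = sorted(set(np.unique(ga)) | set(np.unique(gb)) - {0})
        labels = [int(l) for l in labels if l != 0]
    report = DiceReport()
    inter_sum = 0
    size_sum = 0
    for label in labels:
        ma = ga == label
        mb = gb == label
        na, nb = int(ma.sum()), int(mb.sum())
        if na == 0 and nb == 0:
            report.absent.append(int(label))
            continue
        k = int(np.logical_and(ma, mb).sum())
        report.per_label[int(label)] = 2.0 * k / (na + nb)
        inter_sum += k
        size_sum += na + nb
    if size_sum > 0:
        report.global_dice = 2.0 * inter_sum / size_sum
    elif empty != "strict":
        report.global_dice = 1.0
    else:
        raise ValueError("global Dice undefined: no nonzero labels in either volume")
    return report


def binarized_diff(
    a: Union[LabelVolume, np.ndarray],
    b: Union[LabelVolume, np.ndarray],
) -> np.ndarray:
    """Binary mask of voxels where the two label maps disagree."""
    ga, gb = _as_grid(a), _as_grid(b)
    if ga.shape != gb.shape:
        raise ValueError(f"volume shapes differ: {ga.shape} vs {gb.shape}")
    return (ga != gb).astype(np.uint8)


def diff_sum(masks: Iterable[np.ndarray]) -> np.ndarray:
    """Voxelwise sum of binary difference masks across subjects.

    All masks must share one grid (inputs are assumed pre-aligned to a
    common template).  The result at each voxel counts in how many
    subjects the two runs disagreed there; its maximum is the number of
    masks.
    """
    total: Optional[np.ndarray] = None
    for mask in masks:
        m = _as_grid(mask)
        if total is None:
            total = np.zeros(m.shape, dtype=np.int64)
        elif m.shape != total.shape:
            raise ValueError(f"mask shapes differ: {m.shape} vs {total.shape}")
        total += m.astype(bool)
    if total is None:
        raise ValueError("diff_sum requires at least one mask")
    return total


@dataclass(frozen=True)
class ChecksumResult:
    equal: bool
    digest_a: str
    digest_b: str


def _sha256_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_payload(path: Union[str, Path]) -> str:
    """Hash only the voxel data block of a NIfTI file.

    Ignores header fields (description strings, timestamps) so that two
    files with identical voxel payloads compare equal.  Raw on-disk bytes
    from the data offset onward are hashed, after transparent gunzip.
    """
    path = Path(path)
    img = nib.load(str(path))
    offset = int(getattr(img.dataobj, "offset", None) or img.header.get_data_offset())
    opener = gzip.open if path.suffix == ".gz" else open
    h = hashlib.sha256()
    with opener(path, "rb") as f:
        f.seek(offset)
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def checksum_compare(
    path_a: Union[str, Path],
    path_b: Union[str, Path],
    payload: bool = False,
) -> ChecksumResult:
    """SHA-256 comparison of two files.

    ``payload=True`` hashes only the voxel data block of NIfTI files,
    ignoring header differences.  Default hashes raw file bytes — the
    cheap first screen run before any overlap metric.
    """
    digest = _sha256_payload if payload else _sha256_file
    da, db = digest(path_a), digest(path_b)
    return ChecksumResult(equal=(da == db), digest_a=da, digest_b=db)


def load_label_volume(path: Union[str, Path]) -> LabelVolume:
    """Read a NIfTI label map (rounds floating storage to nearest integer)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int64)
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(grid=data, voxel_size=tuple(float(z) for z in zooms),
                       affine=np.asarray(img.affine))


def save_volume(
    data: Union[LabelVolume, np.ndarray],
    path: Union[str, Path],
    affine: Optional[np.ndarray] = None,
) -> None:
    """Write an array or LabelVolume as NIfTI-1."""
    if isinstance(data, LabelVolume):
        affine = data.affine if affine is None else affine
        data = data.grid
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    img = nib.Nifti1Image(arr, affine)
    nib.save(img, str(path))
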