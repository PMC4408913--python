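"""Residual rigid-transform metrics and stage-wise difference attribution.

fMRI motion correction estimates one rigid transform (rotation +
translation, 6 degrees of freedom) per timepoint.  When two runs of the
same correction disagree, the disagreement at each timepoint is the
residual transform ``T1 ∘ T2⁻¹`` — identity iff the runs agree — which
is summarized by the norm of its translation vector (mm) and the
absolute rotation angle (degrees).

Divergence between two runs of a multi-stage pre-processing chain is
attributed stage by stage with the mean absolute difference (MAD) of the
intermediate images, normalized by the MAD after the final stage, so the
profile reads as "fraction of the total difference present after each
step".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "RigidTransform",
    "ResidualMetrics",
    "SeriesResiduals",
    "StageMADProfile",
    "load_flirt_matrix",
    "save_flirt_matrix",
    "load_matrix_series",
    "residual",
    "rotation_angle",
    "translation_norm",
    "series_residuals",
    "mean_abs_diff",
    "stage_mad_profile",
]

#: Orthonormality / determinant tolerance for accepting a matrix as rigid.
RIGID_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A 4×4 homogeneous rigid transform acting on column vectors.

    Validation enforces rigidity: last row (0,0,0,1), RᵀR = I and
    det R = +1 within ``RIGID_TOL``.  Non-rigid matrices are rejected
    rather than re-orthogonalized — silent repair would mask exactly the
    differences this toolkit exists to measure.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got shape {m.shape}")
        object.__setattr__(self, "matrix", m)
        last = m[3]
        if not np.allclose(last, [0.0, 0.0, 0.0, 1.0], atol=RIGID_TOL):
            raise ValueError(f"last row must be (0,0,0,1), got {last}")
        r = m[:3, :3]
        ortho_err = float(np.abs(r.T @ r - np.eye(3)).max())
        if ortho_err > RIGID_TOL:
            raise ValueError(
                f"rotation block not orthonormal: max |R'R - I| = {ortho_err:.3e}"
            )
        det = float(np.linalg.det(r))
        if abs(det - 1.0) > RIGID_TOL:
            raise ValueError(f"rotation block has det {det:.9f}, expected +1")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @classmethod
    def from_parts(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    def inverse(self) -> "RigidTransform":
        # analytic rigid inverse (Rᵀ, -Rᵀt): exact up to rounding, never
        # amplifies error the way a general 4x4 inversion can
        r = self.rotation
        t = self.translation
        return RigidTransform.from_parts(r.T, -r.T @ t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))


def load_flirt_matrix(source: Union[str, Path]) -> RigidTransform:
    """Read a FLIRT-style ASCII 4×4 matrix (4 lines × 4 numbers).

    ``source`` may be a path or the matrix text itself.  Non-rigid
    matrices raise with the violated invariant and its magnitude.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    rows = [line.split() for line in text.strip().splitlines() if line.strip()]
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise ValueError(
            f"expected 4 lines of 4 numbers, got {[len(r) for r in rows]} tokens"
        )
    try:
        m = np.array([[float(x) for x in row] for row in rows])
    except ValueError as exc:
        raise ValueError(f"non-numeric token in matrix: {exc}") from exc
    return RigidTransform(m)


def save_flirt_matrix(t: RigidTransform, path: Union[str, Path]) -> None:
    """Write FLIRT-style ASCII with 17 significant digits (exact float64 round trip)."""
    lines = ["  ".join(f"{x:.17g}" for x in row) for row in t.matrix]
    Path(path).write_text("\n".join(lines) + "\n")


_MAT_INDEX_RE = re.compile(r"(\d+)")


def load_matrix_series(directory: Union[str, Path], pattern: str = "MAT_*") -> List[RigidTransform]:
    """Load a directory of per-timepoint matrices ordered by zero-padded index."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern!r} in {directory}")
    return [load_flirt_matrix(p) for p in paths]


def residual(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Residual transform ``T1 ∘ T2⁻¹`` remaining after undoing run 2's
    estimate by run 1's; identity iff the two runs agree."""
    return t1.compose(t2.inverse())


def rotation_angle(t: RigidTransform) -> float:
    """Absolute rotation angle in degrees: arccos((trace R − 1)/2).

    The arccos argument is clamped to [−1, 1] to absorb rounding of
    traces marginally outside [−1, 3].
    """
    c = (float(np.trace(t.rotation)) - 1.0) / 2.0
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def translation_norm(t: RigidTransform) -> float:
    """Euclidean norm of the translation vector, in mm."""
    return float(np.linalg.norm(t.translation))


@dataclass(frozen=True)
class ResidualMetrics:
    """Summary of one residual transform."""

    translation_norm: float  # mm
    rotation_angle: float    # degrees, in [0, 180]


@dataclass
class SeriesResiduals:
    """Per-timepoint residual metrics plus the across-series maxima."""

    per_timepoint: List[ResidualMetrics]
    max_translation_norm: float
    max_rotation_angle: float
    argmax_translation: int
    argmax_rotation: int


def series_residuals(
    series1: Sequence[RigidTransform],
    series2: Sequence[RigidTransform],
) -> SeriesResiduals:
    """Residual metrics at every timepoint of two motion-estimate series.

    The maxima over timepoints are the usual one-line summary of how far
    apart two motion-correction runs are.
    """
    if len(series1) != len(series2):
        raise ValueError(
            f"series lengths differ: {len(series1)} vs {len(series2)}"
        )
    if not series1:
        raise ValueError("empty transform series")
    metrics = []
    for t1, t2 in zip(series1, series2):
        res = residual(t1, t2)
        metrics.append(
            ResidualMetrics(
                translation_norm=translation_norm(res),
                rotation_angle=rotation_angle(res),
            )
        )
    trans = [m.translation_norm for m in metrics]
    rots = [m.rotation_angle for m in metrics]
    it = int(np.argmax(trans))
    ir = int(np.argmax(rots))
    return SeriesResiduals(
        per_timepoint=metrics,
        max_translation_norm=trans[it],
        max_rotation_angle=rots[ir],
        argmax_translation=it,
        argmax_rotation=ir,
    )


def mean_abs_diff(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask: Optional[np.ndarray] = None,
    per_volume: bool = False,
):
    """Mean absolute difference between two images.

    For 4D inputs the default pools voxels and timepoints jointly;
    ``per_volume=True`` returns one MAD per timepoint instead.  An
    optional 3D mask restricts the average to in-mask voxels (broadcast
    over timepoints for 4D).
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        if m.ndim not in (a.ndim, a.ndim - 1) or m.shape != a.shape[: m.ndim]:
            raise ValueError(
                f"mask shape {m.shape} incompatible with image shape {a.shape}"
            )
        if not m.any():
            raise ValueError("mask selects no voxels")
        diff = diff[m]  # (nvox,) for matching ndim, (nvox, T) for 3D mask on 4D
    elif a.ndim == 4:
        diff = diff.reshape(-1, a.shape[-1])
    if per_volume and a.ndim == 4:
        if diff.ndim != 2:
            raise ValueError("per-volume MAD needs a spatial (3D) mask for 4D images")
        return diff.mean(axis=0)
    return float(diff.mean())


@dataclass
class StageMADProfile:
    """Ordered per-stage MAD values, raw and normalized by a reference stage.

    The reference is conventionally the final pre-processing step, so the
    normalized profile reads as the fraction of the end-to-end difference
    already present after each stage (reference = exactly 1.0).
    """

    stages: List[Tuple[str, float, float]]  # (name, raw_mad, normalized_mad)
    reference: str

    @property
    def names(self) -> List[str]:
        return [s[0] for s in self.stages]

    @property
    def raw(self) -> List[float]:
        return [s[1] for s in self.stages]

    @property
    def normalized(self) -> List[float]:
        return [s[2] for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "stages": [
                {"name": n, "raw_mad": r, "normalized_mad": z}
                for n, r, z in self.stages
            ],
        }


def stage_mad_profile(
    stage_pairs: Sequence[Tuple[str, np.ndarray, np.ndarray]],
    reference: str,
    mask: Optional[np.ndarray] = None,
) -> StageMADProfile:
    """MAD after each pre-processing stage, normalized by the reference stage.

    Raises if the reference stage is absent or its raw MAD is zero (no
    difference to attribute).
    """
    names = [name for name, _, _ in stage_pairs]
    if reference not in names:
        raise ValueError(f"reference stage {reference!r} not among {names}")
    raw = {name: mean_abs_diff(a, b, mask=mask) for name, a, b in stage_pairs}
    ref_mad = raw[reference]
    if ref_mad == 0.0:
        raise ValueError(
            f"reference stage {reference!r} has zero MAD: no difference to attribute"
        )
    stages = [(name, raw[name], raw[name] / ref_mad) for name in names]
    # guard against rounding in the division: the reference is 1.0 by definition
    stages = [
        (n, r, 1.0 if n == reference else z) for n, r, z in stages
    ]
    return StageMADProfile(stages=stages, reference=reference)
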