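"""Spatial ICA component matching and thresholded-overlap agreement.

Independent component analysis of fMRI produces a set of spatial maps
whose order (and sign) is arbitrary between runs.  To compare two runs,
each component of set A is matched to the maximally correlated component
of set B; agreement of a matched pair is then quantified by Dice overlap
of the thresholded positive parts and of the thresholded negative parts
separately.  Matching is per component (many-to-one allowed) and hence
asymmetric, so both A→B and B→A directions are reported.

A sign-flipped but otherwise identical component illustrates why the
positive/negative split matters: its positive part moves to the other
sign, the positive-vs-positive supports become disjoint and the Dice
drops to 0 even though the underlying source is the same.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

from reprotrace.volumes import dice

__all__ = [
    "ComponentSet",
    "ComponentMatch",
    "SetComparison",
    "HistogramSummary",
    "spatial_correlation",
    "match_components",
    "thresholded_dice",
    "compare_sets",
    "histogram_summary",
    "load_component_set",
]


@dataclass
class ComponentSet:
    """A set of spatial statistic maps on a common grid.

    ``threshold`` is the statistic cutoff used when binarizing positive
    and negative parts; 0 means any nonzero activation counts (callers
    with mixture-model-thresholded maps pass those in directly, callers
    with raw z-maps pass a z cutoff such as 2.3).
    """

    maps: List[np.ndarray]
    mask: Optional[np.ndarray] = None
    threshold: float = 0.0

    def __post_init__(self):
        self.maps = [np.asarray(m, dtype=np.float64) for m in self.maps]
        if not self.maps:
            raise ValueError("component set must contain at least one map")
        shape = self.maps[0].shape
        if any(m.shape != shape for m in self.maps):
            raise ValueError("all maps in a set must share one grid")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != shape:
                raise ValueError("mask grid does not match map grid")

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def shape(self):
        return self.maps[0].shape


def spatial_correlation(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Sample linear (Pearson) correlation over in-mask voxels."""
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        if m.shape != a.shape:
            raise ValueError("mask shape does not match maps")
        a, b = a[m], b[m]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero variance map: correlation undefined")
    r = float(np.dot(da, db) / (na * nb))
    return min(1.0, max(-1.0, r))


def thresholded_dice(
    map_a: np.ndarray,
    map_b: np.ndarray,
    threshold: float = 0.0,
) -> Tuple[float, float]:
    """Dice of the binarized positive parts and of the negative parts.

    ``dice_pos`` compares ``A > +threshold`` with ``B > +threshold``;
    ``dice_neg`` compares ``A < −threshold`` with ``B < −threshold``.
    An empty part on one side against a nonempty part on the other gives
    0; both parts empty gives 1 (agreement on absence).
    """
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    out = []
    for pa, pb in (((a > threshold), (b > threshold)),
                   ((a < -threshold), (b < -threshold))):
        if not pa.any() and not pb.any():
            out.append(1.0)
        elif not pa.any() or not pb.any():
            out.append(0.0)
        else:
            out.append(dice(pa, pb))
    return out[0], out[1]


@dataclass(frozen=True)
class ComponentMatch:
    """One A-component matched to its best-correlated B-component."""

    index_a: int
    index_b: int
    correlation: float
    dice_pos: float
    dice_neg: float


def match_components(
    a: ComponentSet,
    b: ComponentSet,
    signed: bool = True,
    threshold: Optional[float] = None,
) -> List[ComponentMatch]:
    """Match every component of A to the maximally correlated one in B.

    ``signed=True`` (default) maximizes the signed correlation r, so a
    sign-flipped copy of a component is *not* its own best match —
    reproducing the Dice ≈ 0 mode such inversions produce in practice.
    ``signed=False`` maximizes |r| instead.  Matching is per component;
    several A-components may share one B-component (no bipartite
    constraint).
    """
    if a.shape != b.shape:
        raise ValueError("component sets live on different grids")
    thr = a.threshold if threshold is None else threshold
    mask = a.mask if a.mask is not None else b.mask
    matches = []
    for i, map_a in enumerate(a.maps):
        rs = np.array([spatial_correlation(map_a, mb, mask=mask) for mb in b.maps])
        j = int(np.argmax(np.abs(rs) if not signed else rs))
        dpos, dneg = thresholded_dice(map_a, b.maps[j], threshold=thr)
        matches.append(
            ComponentMatch(index_a=i, index_b=j, correlation=float(rs[j]),
                           dice_pos=dpos, dice_neg=dneg)
        )
    return matches


@dataclass(frozen=True)
class HistogramSummary:
    """Fixed-bin histogram summary: min, mean, sd, and mode-bin center.

    Bins are ``[k·w, (k+1)·w)``; for data confined to [0, 1] the final
    bin is closed ``[1−w, 1]`` so a Dice of exactly 1 is countable.
    Mode ties break toward the lowest bin; sd uses the n−1 denominator.
    """

    min: float
    mean: float
    sd: float
    mode: float
    bin_width: float
    n: int


def histogram_summary(values: Sequence[float], bin_width: float = 0.1) -> HistogramSummary:
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("histogram_summary requires at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # round guard: 0.7/0.1 = 6.999...9 in binary; values meant to sit on a
    # bin edge must land in the upper bin
    idx = np.floor(np.round(v / bin_width, 9)).astype(np.int64)
    if v.min() >= 0.0 and v.max() <= 1.0:
        # unit-interval data (Dice, correlations mapped to [0,1]): close
        # the top bin so 1.0 lands in [1-w, 1]
        top = int(np.ceil(1.0 / bin_width)) - 1
        idx = np.minimum(idx, top)
    lo = int(idx.min())
    counts = np.bincount(idx - lo)
    mode_bin = lo + int(np.argmax(counts))  # argmax -> lowest bin on ties
    return HistogramSummary(
        min=float(v.min()),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        mode=float((mode_bin + 0.5) * bin_width),
        bin_width=float(bin_width),
        n=int(v.size),
    )


@dataclass
class SetComparison:
    """Both-direction match tables plus pooled Dice histogram summaries."""

    matches_ab: List[ComponentMatch]
    matches_ba: List[ComponentMatch]
    n_a: int
    n_b: int
    dimensions_equal: bool
    hist_pos: HistogramSummary
    hist_neg: HistogramSummary

    def dimension_report(self) -> str:
        verdict = "equal" if self.dimensions_equal else "differ"
        return f"{self.n_a} vs {self.n_b} components, {verdict}"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (direction, m.index_a, m.index_b, m.correlation, m.dice_pos, m.dice_neg)
            for direction, matches in (("A->B", self.matches_ab), ("B->A", self.matches_ba))
            for m in matches
        ]
        return pd.DataFrame(
            rows,
            columns=["direction", "index_a", "index_b",
                     "correlation", "dice_pos", "dice_neg"],
        )


def compare_sets(
    a: ComponentSet,
    b: ComponentSet,
    threshold: Optional[float] = None,
    signed: bool = True,
    bin_width: float = 0.1,
) -> SetComparison:
    """Full two-direction comparison of two component sets.

    Because per-component matching is not symmetric, matches are computed
    A→B and B→A and the Dice values of both directions are pooled into
    the histogram summaries (positive and negative parts separately).
    Also reports whether the two runs detected the same number of
    components — automatic model-order selection can itself diverge
    between platforms.
    """
    ab = match_components(a, b, signed=signed, threshold=threshold)
    ba = match_components(b, a, signed=signed, threshold=threshold)
    pos = [m.dice_pos for m in ab] + [m.dice_pos for m in ba]
    neg = [m.dice_neg for m in ab] + [m.dice_neg for m in ba]
    return SetComparison(
        matches_ab=ab,
        matches_ba=ba,
        n_a=len(a),
        n_b=len(b),
        dimensions_equal=(len(a) == len(b)),
        hist_pos=histogram_summary(pos, bin_width=bin_width),
        hist_neg=histogram_summary(neg, bin_width=bin_width),
    )


def load_component_set(
    source: Union[str, Path, Sequence[Union[str, Path]]],
    mask: Optional[Union[str, Path]] = None,
    threshold: float = 0.0,
) -> ComponentSet:
    """Load components from a 4D NIfTI (one component per volume) or a
    list/directory of 3D NIfTI maps."""
    maps: List[np.ndarray] = []
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        source = sorted(Path(source).glob("*.nii*"))
    if isinstance(source, (str, Path)):
        data = np.asanyarray(nib.load(str(source)).dataobj).astype(np.float64)
        if data.ndim == 3:
            maps = [data]
        elif data.ndim == 4:
            maps = [data[..., k] for k in range(data.shape[-1])]
        else:
            raise ValueError(f"expected 3D or 4D image, got {data.ndim}D")
    else:
        maps = [np.asanyarray(nib.load(str(p)).dataobj).astype(np.float64)
                for p in source]
    mask_arr = None
    if mask is not None:
        mask_arr = np.asanyarray(nib.load(str(mask)).dataobj).astype(bool)
    return ComponentSet(maps=maps, mask=mask_arr, threshold=threshold)
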