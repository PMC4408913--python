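"""Vertex-wise cortical-thickness difference statistics.

Given per-subject cortical thickness sampled at corresponding vertices
under two processing conditions (two clusters, or two builds of the same
source), the per-subject difference score d = A − B is computed at every
vertex and summarized with the mean and standard deviation of |d| and a
one-sample t-statistic on d (an intercept-only linear model: is the mean
difference zero?).  Thresholding the t-map at an uncorrected two-sided
alpha localizes vertices where the two conditions systematically
disagree.

Vertex data are plain delimited-text matrices (subjects × vertices); no
surface geometry is used because no geometric operation (smoothing,
random-field correction) is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThicknessMatrix",
    "VertexStats",
    "load_thickness",
    "difference_scores",
    "vertex_ttest",
    "threshold_tmap",
]


@dataclass
class ThicknessMatrix:
    """Subjects × vertices cortical thickness in mm."""

    values: np.ndarray
    subject_ids: Optional[List[str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(
                f"expected a 2D subjects x vertices array, got shape {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("thickness values must be finite")
        if (self.values < 0).any():
            raise ValueError("thickness values must be non-negative")
        if self.subject_ids is not None:
            self.subject_ids = [str(s) for s in self.subject_ids]
            if len(self.subject_ids) != self.values.shape[0]:
                raise ValueError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]


def load_thickness(
    path: Union[str, Path],
    sep: Optional[str] = None,
    header: bool = False,
    id_column: bool = False,
) -> ThicknessMatrix:
    """Read a delimited-text thickness matrix (rows = subjects).

    ``sep=None`` sniffs tab vs comma from the first line.  ``header``
    skips one header row; ``id_column`` takes the first column as
    subject identifiers.
    """
    path = Path(path)
    if sep is None:
        first = path.open().readline()
        sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, header=0 if header else None)
    ids = None
    if id_column:
        ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    return ThicknessMatrix(values=df.to_numpy(dtype=np.float64), subject_ids=ids)


def difference_scores(
    cond_a: ThicknessMatrix,
    cond_b: ThicknessMatrix,
) -> np.ndarray:
    """Per-subject, per-vertex difference scores A − B.

    Requires matching shapes and, when both carry subject ids, matching
    subject order — the difference is within-subject by design.
    """
    if cond_a.values.shape != cond_b.values.shape:
        raise ValueError(
            f"condition shapes differ: {cond_a.values.shape} vs {cond_b.values.shape}"
        )
    if (
        cond_a.subject_ids is not None
        and cond_b.subject_ids is not None
        and cond_a.subject_ids != cond_b.subject_ids
    ):
        raise ValueError("subject id order differs between conditions")
    return cond_a.values - cond_b.values


@dataclass
class VertexStats:
    """Per-vertex summaries of the subject-wise difference scores.

    ``t`` is NaN and ``defined`` False at zero-variance vertices (all
    subjects show the identical difference there, typically 0), keeping
    downstream summaries finite.
    """

    mean_abs_diff: np.ndarray  # mm
    sd_abs_diff: np.ndarray    # mm
    t: np.ndarray
    defined: np.ndarray        # bool
    df: int
    mean_diff: np.ndarray      # signed, mm

    @property
    def n_vertices(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": np.arange(self.n_vertices),
                "mean_abs_diff": self.mean_abs_diff,
                "sd_abs_diff": self.sd_abs_diff,
                "t": self.t,
                "defined": self.defined,
            }
        )


def vertex_ttest(d: np.ndarray) -> VertexStats:
    """One-sample t-test of the difference scores at every vertex.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with the n−1 denominator in sd and
    df = n − 1; equivalent to fitting the intercept-only model Y = 1 to
    the difference scores and testing the intercept.  Also reports the
    mean and sd of |d| per vertex (the magnitude maps).
    """
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2:
        raise ValueError(f"expected subjects x vertices array, got shape {d.shape}")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a t-test")
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    defined = sd_d > 0.0
    t = np.full(d.shape[1], np.nan)
    t[defined] = mean_d[defined] / (sd_d[defined] / np.sqrt(n))
    abs_d = np.abs(d)
    return VertexStats(
        mean_abs_diff=abs_d.mean(axis=0),
        sd_abs_diff=abs_d.std(axis=0, ddof=1),
        t=t,
        defined=defined,
        df=n - 1,
        mean_diff=mean_d,
    )


def threshold_tmap(vstats: VertexStats, alpha: float) -> np.ndarray:
    """Boolean vertex mask of two-sided p < alpha (uncorrected).

    Undefined (zero-variance) vertices are never selected.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha >= 1.0:
        return vstats.defined.copy()
    p = np.full(vstats.t.shape, np.nan)
    d = vstats.defined
    p[d] = 2.0 * stats.t.sf(np.abs(vstats.t[d]), vstats.df)
    return (p < alpha) & d
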