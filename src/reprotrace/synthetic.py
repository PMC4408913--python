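"""Seeded generators of paired inputs with known ground truth.

Real audits compare outputs of full neuroimaging pipelines; those data
are large and site-bound.  Every comparison operation in this package is
instead exercised on synthetic pairs whose differences are *planted* —
trace logs with injected difference classes at known positions, label
volumes constructed to hit exact per-label Dice targets, motion series
with a known residual transform, component sets related by a known
permutation and sign flips, image pairs with prescribed per-stage mean
absolute differences, and thickness matrices with a planted regional
effect.  Each generator returns a :class:`GroundTruth` sufficient to
verify that the paired comparison module recovers the plant exactly (or
within a stated tolerance).

All generators are deterministic: the same seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from reprotrace.ica import ComponentSet
from reprotrace.motion import RigidTransform
from reprotrace.surface import ThicknessMatrix
from reprotrace.volumes import LabelVolume

__all__ = [
    "GroundTruth",
    "InjectionSpec",
    "gen_trace_pair",
    "gen_label_volume_pair",
    "gen_rigid_pair",
    "gen_rigid_series_pair",
    "gen_component_sets",
    "gen_stage_series",
    "gen_thickness_pair",
]

#: Functions used in generated traces — the libm calls that dominate real
#: pipeline traces (exp/log from tissue classification, trig and
#: floor/ceil from mesh fitting and motion correction).
DEFAULT_VOCABULARY = ("expf", "logf", "cosf", "sinf", "ceilf", "floorf")

#: Classes that can be injected into a trace pair.
_INJECTABLE = ("type1", "type2", "type3", "mismatch")


@dataclass
class GroundTruth:
    """What a generator planted, sufficient for an exact recovery test."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"generator": self.generator, "seed": self.seed,
                "params": _jsonable(self.params)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# trace pairs


@dataclass
class InjectionSpec:
    """Which difference classes to plant, where (or how often).

    Each class takes either an explicit list of 0-based positions or a
    rate in [0, 1] (count = round(rate x n_calls), positions drawn
    without replacement).  At most one injection per position.
    """

    type1: Union[Sequence[int], float] = 0.0
    type2: Union[Sequence[int], float] = 0.0
    type3: Union[Sequence[int], float] = 0.0
    mismatch: Union[Sequence[int], float] = 0.0
    vocabulary: Tuple[str, ...] = DEFAULT_VOCABULARY

    def resolve(self, n_calls: int, rng: np.random.Generator) -> Dict[str, List[int]]:
        """Fix concrete injection positions for a trace of ``n_calls`` lines."""
        explicit: Dict[str, List[int]] = {}
        rates: Dict[str, float] = {}
        for cls in _INJECTABLE:
            v = getattr(self, cls)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if not 0.0 <= float(v) <= 1.0:
                    raise ValueError(f"{cls} rate must be in [0,1], got {v}")
                rates[cls] = float(v)
            else:
                positions = sorted(int(p) for p in v)
                if positions and (positions[0] < 0 or positions[-1] >= n_calls):
                    raise ValueError(f"{cls} positions outside trace of {n_calls}")
                explicit[cls] = positions
        taken = [p for ps in explicit.values() for p in ps]
        if len(set(taken)) != len(taken):
            raise ValueError("at most one injection per position")
        free = np.setdiff1d(np.arange(n_calls), np.array(taken, dtype=int))
        n_needed = {cls: int(round(r * n_calls)) for cls, r in rates.items()}
        if sum(n_needed.values()) > free.size:
            raise ValueError(
                f"injection spec needs {sum(n_needed.values())} free positions, "
                f"only {free.size} available"
            )
        drawn = rng.choice(free, size=sum(n_needed.values()), replace=False)
        out = dict(explicit)
        start = 0
        for cls in _INJECTABLE:
            if cls in n_needed:
                k = n_needed[cls]
                out[cls] = sorted(int(p) for p in drawn[start:start + k])
                start += k
            else:
                out.setdefault(cls, [])
        return out


def _perturb_last_digit(token: str) -> str:
    """Change the final printed digit by one (9 steps down, else up)."""
    last = token[-1]
    if not last.isdigit():
        raise ValueError(f"token {token!r} does not end in a digit")
    new = str(int(last) - 1) if last == "9" else str(int(last) + 1)
    return token[:-1] + new


_ARG_RANGES = {
    "expf": (0.0, 5.0),
    "logf": (0.1, 10.0),
    "cosf": (0.0, 6.28),
    "sinf": (0.0, 6.28),
    "ceilf": (0.0, 100.0),
    "floorf": (0.0, 100.0),
}

_FUNCS = {
    "expf": math.exp,
    "logf": math.log,
    "cosf": math.cos,
    "sinf": math.sin,
    "ceilf": lambda x: float(math.ceil(x)),
    "floorf": lambda x: float(math.floor(x)),
}


def _base_line(func: str, arg: float) -> str:
    return f"{func}({arg:.6f}) = {_FUNCS[func](arg):.6f}"


def gen_trace_pair(
    n_calls: int,
    spec: Optional[InjectionSpec] = None,
    seed: int = 0,
) -> Tuple[str, str, GroundTruth]:
    """Generate a pair of trace logs with planted per-line differences.

    Non-injected lines are byte-identical between the two logs.  Planted
    constructions match the class definitions exactly:

    - type-1: ``floorf``/``ceilf`` called on different arguments with the
      same integral result;
    - type-2: argument and result both perturbed in the last printed digit;
    - type-3: identical argument, result perturbed in the last printed
      digit (so string and bit-level comparison agree on the difference);
    - mismatch: the function name replaced, tokens kept.

    Returns (trace A text, trace B text, ground truth with the planted
    class at each injected position).
    """
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    spec = spec or InjectionSpec()
    rng = np.random.default_rng(seed)
    positions = spec.resolve(n_calls, rng)
    planted = {}  # position -> class
    for cls, ps in positions.items():
        for p in ps:
            planted[p] = cls

    vocab = list(spec.vocabulary)
    lines_a: List[str] = []
    lines_b: List[str] = []
    for i in range(n_calls):
        cls = planted.get(i)
        if cls == "type1":
            # non-injective construction: same floor/ceil, different args
            rounders = [f for f in vocab if f in ("floorf", "ceilf")] or ["floorf"]
            func = rounders[int(rng.integers(len(rounders)))]
            k = int(rng.integers(0, 99))
            u = float(rng.uniform(0.05, 0.45))
            xa, xb = k + u, k + u + 0.3
            line_a = _base_line(func, xa)
            line_b = _base_line(func, xb)
        else:
            func = vocab[int(rng.integers(len(vocab)))]
            lo, hi = _ARG_RANGES.get(func, (0.0, 1.0))
            x = float(rng.uniform(lo, hi))
            line_a = _base_line(func, x)
            if cls is None:
                line_b = line_a
            elif cls == "type3":
                head, ret = line_a.rsplit(" = ", 1)
                line_b = f"{head} = {_perturb_last_digit(ret)}"
            elif cls == "type2":
                arg_tok = f"{x:.6f}"
                ret_tok = f"{_FUNCS[func](x):.6f}"
                line_b = (f"{func}({_perturb_last_digit(arg_tok)}) = "
                          f"{_perturb_last_digit(ret_tok)}")
            elif cls == "mismatch":
                others = [f for f in vocab if f != func]
                other = others[int(rng.integers(len(others)))]
                line_b = line_a.replace(f"{func}(", f"{other}(", 1)
            else:  # pragma: no cover
                raise AssertionError(cls)
        lines_a.append(line_a)
        lines_b.append(line_b)

    truth = GroundTruth(
        generator="gen_trace_pair",
        seed=seed,
        params={
            "n_calls": n_calls,
            "positions": positions,
            "counts": {cls: len(ps) for cls, ps in positions.items()},
            "first_difference": (min(planted) if planted else None),
        },
    )
    return "\n".join(lines_a) + "\n", "\n".join(lines_b) + "\n", truth


# ---------------------------------------------------------------------------
# label volume pairs


def gen_label_volume_pair(
    shape: Tuple[int, int, int],
    label_sizes: Dict[int, int],
    target_dice: Dict[int, float],
    seed: int = 0,
) -> Tuple[LabelVolume, LabelVolume, GroundTruth]:
    """Construct two label volumes with exact per-label Dice.

    For each label, both volumes get an equal-size block of ``s`` voxels
    with overlap ``k = d·s`` (which must be integral — otherwise the
    nearest realizable Dice is suggested), so the measured Dice is
    exactly ``2k/(2s) = d``.  Labels are spatially disjoint within each
    volume; voxel order is shuffled per seed so blocks land at scattered
    locations.
    """
    shape = tuple(int(x) for x in shape)
    n_vox = int(np.prod(shape))
    overlaps: Dict[int, int] = {}
    for label, s in label_sizes.items():
        if label not in target_dice:
            raise ValueError(f"no target Dice for label {label}")
        d = target_dice[label]
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"Dice target for label {label} must be in [0,1]")
        k = d * s
        if abs(k - round(k)) > 1e-9:
            nearest = round(k) / s
            raise ValueError(
                f"Dice {d} not realizable with size {s} (overlap d*s = {k} "
                f"not integral); nearest realizable value is {nearest}"
            )
        overlaps[label] = int(round(k))

    # each label consumes 2s - k voxels laid out as [A only | shared | B only]
    needed = sum(2 * s - overlaps[l] for l, s in label_sizes.items())
    if needed > n_vox:
        raise ValueError(f"labels need {needed} voxels, grid has {n_vox}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_vox)
    flat_a = np.zeros(n_vox, dtype=np.int32)
    flat_b = np.zeros(n_vox, dtype=np.int32)
    cursor = 0
    for label in sorted(label_sizes):
        s = label_sizes[label]
        k = overlaps[label]
        block = order[cursor: cursor + 2 * s - k]
        cursor += 2 * s - k
        flat_a[block[:s]] = label            # first s voxels
        flat_b[block[s - k:]] = label        # last s voxels; k shared
    a = LabelVolume(grid=flat_a.reshape(shape))
    b = LabelVolume(grid=flat_b.reshape(shape))
    truth = GroundTruth(
        generator="gen_label_volume_pair",
        seed=seed,
        params={
            "shape": shape,
            "label_sizes": dict(label_sizes),
            "target_dice": dict(target_dice),
            "overlap_voxels": overlaps,
        },
    )
    return a, b, truth


# ---------------------------------------------------------------------------
# rigid transform pairs


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    ux, uy, uz = axis / n
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    kmat = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)


def _random_rigid(rng: np.random.Generator, t_scale: float = 20.0) -> RigidTransform:
    axis = rng.normal(size=3)
    angle = float(rng.uniform(-30.0, 30.0))
    r = _rotation_about(axis, angle)
    t = rng.uniform(-t_scale, t_scale, size=3)
    return RigidTransform.from_parts(r, t)


def gen_rigid_pair(
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    angle_deg: float = 0.0,
    translation_mm: Union[float, Sequence[float]] = 0.0,
    seed: int = 0,
) -> Tuple[RigidTransform, RigidTransform, GroundTruth]:
    """Two motion estimates whose residual is a known rigid transform G.

    G rotates by ``angle_deg`` about ``axis`` and translates by
    ``translation_mm`` (a 3-vector, or a scalar norm assigned a random
    direction).  With a random rigid T1 and ``T2 = G⁻¹ ∘ T1``, the
    residual ``T1 ∘ T2⁻¹`` equals G exactly, so the residual metrics
    must recover (angle_deg, ‖translation‖).
    """
    if abs(angle_deg) > 180.0:
        raise ValueError("|angle_deg| must be <= 180")
    rng = np.random.default_rng(seed)
    if np.isscalar(translation_mm):
        norm = float(translation_mm)
        if norm == 0.0:
            t = np.zeros(3)
        else:
            direction = rng.normal(size=3)
            t = direction / np.linalg.norm(direction) * norm
    else:
        t = np.asarray(translation_mm, dtype=np.float64)
    g = RigidTransform.from_parts(_rotation_about(np.asarray(axis, float), angle_deg), t)
    t1 = _random_rigid(rng)
    t2 = g.inverse().compose(t1)
    truth = GroundTruth(
        generator="gen_rigid_pair",
        seed=seed,
        params={
            "angle_deg": abs(float(angle_deg)),
            "translation_norm": float(np.linalg.norm(t)),
            "residual_matrix": g.matrix,
        },
    )
    return t1, t2, truth


def gen_rigid_series_pair(
    n_timepoints: int,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    angle_deg: float = 0.0,
    translation_mm: Union[float, Sequence[float]] = 0.0,
    seed: int = 0,
) -> Tuple[List[RigidTransform], List[RigidTransform], GroundTruth]:
    """Per-timepoint motion series with the planted residual at the last
    timepoint and identity residuals elsewhere (so the planted values are
    the series maxima)."""
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    series1, series2 = [], []
    for t in range(n_timepoints - 1):
        shared = _random_rigid(rng)
        series1.append(shared)
        series2.append(shared)
    t1, t2, inner = gen_rigid_pair(axis=axis, angle_deg=angle_deg,
                                   translation_mm=translation_mm,
                                   seed=int(rng.integers(2 ** 31)))
    series1.append(t1)
    series2.append(t2)
    truth = GroundTruth(
        generator="gen_rigid_series_pair",
        seed=seed,
        params={**inner.params, "n_timepoints": n_timepoints,
                "planted_timepoint": n_timepoints - 1},
    )
    return series1, series2, truth


# ---------------------------------------------------------------------------
# ICA component sets


def _blob_centers(n: int, shape: Tuple[int, int, int], margin: int) -> np.ndarray:
    """Lay up to n centers on a regular lattice with the given margin."""
    per_axis = max(1, math.ceil(n ** (1.0 / 3.0)))
    while per_axis ** 3 < n:
        per_axis += 1
    centers = []
    axes = []
    for dim in shape:
        usable = dim - 2 * margin
        if usable <= 0 or (per_axis > 1 and usable / (per_axis - 1) < 1):
            raise ValueError(f"grid {shape} too small for {n} disjoint components")
        axes.append(
            np.linspace(margin, dim - 1 - margin, per_axis)
        )
    for ix in axes[0]:
        for iy in axes[1]:
            for iz in axes[2]:
                centers.append((ix, iy, iz))
    centers = np.array(centers[:n])
    if len(centers) < n:
        raise ValueError(f"grid {shape} too small for {n} disjoint components")
    return centers


def gen_component_sets(
    n_components: int,
    shape: Tuple[int, int, int] = (30, 30, 30),
    permutation: Optional[Sequence[int]] = None,
    sign_flips: Sequence[int] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    blob_sigma: float = 2.5,
) -> Tuple[ComponentSet, ComponentSet, GroundTruth]:
    """Two ICA-like component sets related by a known permutation.

    Set A holds ``n_components`` spatially disjoint truncated-Gaussian
    blobs of unit amplitude.  Set B contains the same blobs reordered by
    ``permutation`` (B[j] is a copy of A[permutation[j]]), with the
    listed A-indices sign-flipped, plus iid Gaussian voxel noise of
    standard deviation ``noise_sd``.  For ``noise_sd`` below half the
    component amplitude, correlation matching recovers the permutation
    exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    shape = tuple(int(x) for x in shape)
    if permutation is None:
        permutation = list(range(n_components))
    permutation = [int(p) for p in permutation]
    if sorted(permutation) != list(range(n_components)):
        raise ValueError("permutation must reorder range(n_components)")
    sign_flips = sorted(set(int(i) for i in sign_flips))
    if sign_flips and (sign_flips[0] < 0 or sign_flips[-1] >= n_components):
        raise ValueError("sign flip indices out of range")

    # blob support radius keeps neighbours disjoint on the lattice
    margin = max(3, int(round(2 * blob_sigma)))
    centers = _blob_centers(n_components, shape, margin)
    if len(centers) >= 2:
        from scipy.spatial.distance import pdist
        radius = min(float(pdist(centers).min()) / 2.0 - 0.5, 2.0 * blob_sigma)
    else:
        radius = 2.0 * blob_sigma
    if radius < 1.0:
        raise ValueError(f"grid {shape} too small for {n_components} disjoint blobs")

    grid = np.stack(np.meshgrid(*[np.arange(d) for d in shape], indexing="ij"), axis=-1)
    maps_a = []
    for c in centers:
        dist2 = ((grid - c) ** 2).sum(axis=-1)
        blob = np.exp(-dist2 / (2.0 * blob_sigma ** 2))
        blob[dist2 > radius ** 2] = 0.0  # truncate: blobs strictly disjoint
        maps_a.append(blob)

    rng = np.random.default_rng(seed)
    maps_b = []
    for j in range(n_components):
        src = permutation[j]
        m = maps_a[src].copy()
        if src in sign_flips:
            m = -m
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=shape)
        maps_b.append(m)

    truth = GroundTruth(
        generator="gen_component_sets",
        seed=seed,
        params={
            "n_components": n_components,
            "shape": shape,
            "permutation": permutation,
            "sign_flips": sign_flips,
            "noise_sd": noise_sd,
            "blob_sigma": blob_sigma,
        },
    )
    return (ComponentSet(maps=maps_a), ComponentSet(maps=maps_b), truth)


# ---------------------------------------------------------------------------
# stage MAD series


def gen_stage_series(
    shape: Tuple[int, ...],
    n_timepoints: int,
    stage_mads: Sequence[Tuple[str, float]],
    seed: int = 0,
) -> Tuple[List[Tuple[str, np.ndarray, np.ndarray]], GroundTruth]:
    """Per-stage image pairs with prescribed mean absolute differences.

    For each stage, B = A + a signed perturbation field of constant
    magnitude equal to the target MAD (random ±1 signs), so the measured
    MAD equals the request to machine precision.  The final stage's MAD
    must be positive — it is the normalization reference.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    stage_mads = [(str(n), float(m)) for n, m in stage_mads]
    if any(m < 0 for _, m in stage_mads):
        raise ValueError("stage MADs must be >= 0")
    if not stage_mads or stage_mads[-1][1] == 0.0:
        raise ValueError("final stage MAD must be > 0 (normalization reference)")
    rng = np.random.default_rng(seed)
    full_shape = tuple(shape) + ((n_timepoints,) if n_timepoints > 1 else ())
    pairs = []
    for name, target in stage_mads:
        a = rng.uniform(100.0, 1000.0, size=full_shape)
        signs = rng.choice([-1.0, 1.0], size=full_shape)
        b = a + signs * target
        pairs.append((name, a, b))
    truth = GroundTruth(
        generator="gen_stage_series",
        seed=seed,
        params={
            "shape": tuple(shape),
            "n_timepoints": n_timepoints,
            "stage_mads": {n: m for n, m in stage_mads},
            "reference": stage_mads[-1][0],
            "normalized": {n: m / stage_mads[-1][1] for n, m in stage_mads},
        },
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# thickness matrices


def gen_thickness_pair(
    n_subjects: int,
    n_vertices: int,
    effect_region: Sequence[int] = (),
    effect_mm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_mm: float = 2.5,
) -> Tuple[ThicknessMatrix, ThicknessMatrix, GroundTruth]:
    """Paired thickness matrices with a planted regional effect.

    Both conditions share the same per-subject baseline (mean ``base_mm``
    with between-subject and between-vertex variation).  Condition B adds
    ``effect_mm`` at the vertices of ``effect_region`` plus iid Gaussian
    noise of sd ``noise_sd`` at every entry, so the A−B difference scores
    have sd ``noise_sd`` and mean ``−effect_mm`` inside the region.  With
    ``effect_mm = 0`` the t-map is null-calibrated by construction.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    region = sorted(set(int(v) for v in effect_region))
    if region and (region[0] < 0 or region[-1] >= n_vertices):
        raise ValueError("effect region outside vertex range")
    if effect_mm != 0.0 and not region:
        raise ValueError("nonzero effect requires a nonempty region")
    rng = np.random.default_rng(seed)
    subject_offset = rng.normal(0.0, 0.25, size=(n_subjects, 1))
    vertex_profile = rng.normal(0.0, 0.3, size=(1, n_vertices))
    base = base_mm + subject_offset + vertex_profile
    base = np.clip(base, 0.5, None)  # thickness stays physical
    a = base.copy()
    b = base.copy()
    if region:
        b[:, region] += effect_mm
    if noise_sd > 0:
        b = b + rng.normal(0.0, noise_sd, size=b.shape)
    b = np.clip(b, 0.0, None)
    ids = [f"sub-{i:03d}" for i in range(n_subjects)]
    truth = GroundTruth(
        generator="gen_thickness_pair",
        seed=seed,
        params={
            "n_subjects": n_subjects,
            "n_vertices": n_vertices,
            "effect_region": region,
            "effect_mm": effect_mm,
            "noise_sd": noise_sd,
            "base_mm": base_mm,
        },
    )
    return (
        ThicknessMatrix(values=a, subject_ids=ids),
        ThicknessMatrix(values=b, subject_ids=list(ids)),
        truth,
    )
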