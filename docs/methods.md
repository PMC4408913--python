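# Methods

## Problem

Two executions of a deterministic neuroimaging pipeline on different
operating systems (or different builds of the same source) can disagree
because implementations of the dynamically linked math library change
between system versions. A one-ULP shift in `expf`/`cosf`/`sinf` output is
amplified by thresholding, loop bounds computed from `floorf`/`ceilf`, and
iterative optimization, until segmentations, motion estimates, ICA
decompositions and thickness maps visibly differ. This package provides the
measurement layer of such an audit: it never runs the pipelines themselves,
it compares their outputs and intermediate artifacts.

## Models and procedures

### Float forensics

A binary32 value is handled as its 32-bit pattern with sign (1), exponent
(8) and mantissa (23) fields. Little-endian byte dumps (`"24 58 95 40"`)
are reversed into the big-endian pattern (`0x40955824`). ULP distance maps
each non-NaN pattern to a monotone rank over the ordered floats
(sign-magnitude folded so negatives rank negatively; +0 and −0 share rank
0; infinities sit adjacent to the largest finite magnitudes) and takes the
absolute rank difference; NaN raises. The Hamming count is the popcount of
the XOR of patterns. The two scales differ on purpose: a one-ULP step can
flip up to 24 bits (carry propagation), and +0/−0 are zero ULPs but one
bit apart. `format_30dec` prints the exact decimal expansion of the binary
value truncated to 30 fractional digits (every binary float has a finite
exact expansion; 200 digits of working precision cover subnormals).

### Trace classification

Traces are one call per line, `func(args…) = ret`, with an optional
`[pid N]` prefix for traced child processes. Classification of a paired
line is decided in fixed order: different function names → mismatch (the
argument comparison would be meaningless); equal args and equal return →
identical; equal args, different return → type-3; different args, equal
return → type-1; otherwise type-2. Token equality is exact-string after
whitespace trimming, because the tracer's formatting is fixed within one
run; a numeric mode compares tokens as float64 bit patterns for logs whose
formatting differs. Unequal trace lengths do not abort: each unpaired
trailing line counts as a mismatch, so diverged control flow lengthens the
mismatch series. Diffing is streaming (iterators, constant memory per
line) with cumulative per-(function, class) checkpoints every 10⁴ lines by
default, sized for logs of tens of millions of calls. Interleaved
multi-process logs can be compared in raw file order or split per pid and
compared independently; the per-pid mode renumbers indices within each
stream, since the serialization order of children is tracer-dependent.

### Volume overlap

Dice of two binary masks is `2|A∩B|/(|A|+|B|)`. For label maps, Dice is
computed per label on the `== label` masks; the global value is the
generalized (label-summed) Dice `2·Σ_l |A_l∩B_l| / Σ_l(|A_l|+|B_l|)` over
nonzero labels, which equals 1 iff the maps agree on every nonzero voxel.
Both-empty masks score 1.0 with a warning by default (agreement on
absence); a strict mode errors, and labels absent from both volumes are
reported as absent rather than scored. Comparison is voxel-for-voxel on a
shared grid — alignment/resampling is the caller's responsibility, keeping
the core deterministic. Checksum screening hashes raw file bytes with
SHA-256; a payload mode hashes only the NIfTI voxel data block (bytes from
the data offset onward, after transparent gunzip) so header-only edits
compare equal.

### Motion residuals and stage attribution

Rigid transforms are 4×4 homogeneous matrices acting on column vectors,
validated to orthonormality and det +1 within 1e-6; looser matrices are
rejected, not re-orthogonalized — silent repair would hide exactly the
differences being audited. The residual of two estimates is `T₁∘T₂⁻¹`
(right-to-left composition), with the inverse computed analytically as
(Rᵀ, −Rᵀt). The rotation angle is `arccos((tr R − 1)/2)` with the argument
clamped to [−1, 1] against rounding; the translation norm is Euclidean.
Per-timepoint metrics are summarized by their maxima. Stage attribution
computes the mean absolute difference (MAD) of each intermediate image
pair — 4D images pool voxels and timepoints by default, per-volume
available — and normalizes by the final stage's MAD, so the profile reads
as the fraction of the end-to-end difference present after each step; a
zero reference MAD errors (nothing to attribute).

### ICA matching

Each component of one set is matched to the maximally correlated component
of the other (Pearson over in-mask voxels). Default matching maximizes
*signed* r: a sign-flipped duplicate then matches elsewhere (weakly) and
its positive-vs-positive Dice is 0, which is the mechanism behind the
Dice-0 mode seen when runs invert components; absolute-value matching is
available to deliberately re-pair inversions. No one-to-one constraint is
imposed — matching is per component and therefore asymmetric, so both
directions are computed and pooled. Agreement per matched pair is Dice of
the `> +threshold` parts and of the `< −threshold` parts separately
(threshold 0 by default; callers with mixture-model-thresholded maps pass
them directly). Histogram summaries use fixed width-0.1 bins `[k/10,
(k+1)/10)` with the final bin closed at 1.0 so perfect Dice is countable;
mode ties break toward the lowest bin; σ uses n−1.

### Surface statistics

Difference scores `d = A − B` per subject and vertex feed a one-sample
t-test: `t = d̄/(s_d/√n)`, df = n−1 — the intercept-only linear model.
Zero-variance vertices are flagged undefined (NaN t) rather than ±∞ so
summaries stay finite. Thresholding is two-sided and uncorrected;
family-wise correction over the surface requires geometry (random-field
theory) and is out of scope, as is any resampling between surfaces.

## Synthetic data: what it emulates and what it does not

The generators produce the *structure* of real audit inputs with planted,
exactly recoverable differences; they do not produce anatomy.

- `gen_trace_pair`: lines drawn from the libm vocabulary that dominates
  real pipeline traces (expf, logf, cosf, sinf, ceilf, floorf), arguments
  uniform on per-function ranges, returns computed and printed at 6
  decimals. Type-3/-2 injections perturb the last printed digit (so string
  and numeric comparison agree), type-1 uses floor/ceil non-injectivity,
  mismatch swaps the function name. Defaults used in the recovery suite:
  10⁴ lines, 1% rate per class.
- `gen_label_volume_pair`: equal-size label blocks (s voxels each side)
  with overlap k = d·s placed at seed-shuffled flat positions, so any
  rational Dice with integral d·s is hit *exactly*; non-realizable targets
  error with the nearest realizable value. Recovery grid: 64³, s = 1000,
  d ∈ {0, 0.59, 0.8, 0.9, 1.0} — spanning disjoint to identical around the
  worst overlaps reported for subcortical segmentations.
- `gen_rigid_pair` / `gen_rigid_series_pair`: T₂ = G⁻¹∘T₁ for a random
  rigid T₁ and a prescribed residual G, so `residual(T₁,T₂) = G` to
  rounding; the series variant plants G at the last timepoint. The
  recovery test uses 0.096° and 10⁻⁵ mm — the scale at which two
  motion-correction runs are reported to agree — with 1e-9 relative
  tolerance (float64 leaves ~1e-11).
- `gen_component_sets`: unit-amplitude truncated-Gaussian blobs
  (σ = 2.5 voxels) on a lattice, strictly disjoint; set B is a permuted,
  optionally sign-flipped, noise-added copy. With 20 components on a 30³
  grid and noise sd 0.3 (less than half the amplitude), signed-correlation
  matching recovers the permutation exactly.
- `gen_stage_series`: B = A ± target (random signs), so each stage's MAD
  equals its target to machine precision.
- `gen_thickness_pair`: baseline 2.5 mm with between-subject (sd 0.25 mm)
  and between-vertex (sd 0.3 mm) variation shared by both conditions;
  condition B adds the effect in the region plus iid noise, so
  sd(A−B) = noise_sd and, with zero effect, the t-map is null-calibrated
  by construction. Calibration is checked at n = 20 subjects and 10⁴
  vertices (±3 binomial standard errors at α ∈ {0.05, 0.01}); effect
  recovery at n = 50, σ = 0.1 mm, effect 0.5 mm.

What passing these tests shows: the comparison machinery is exact where
exactness is constructible and statistically calibrated where it is not.
What it does not show: behavior on real anatomy — spatially correlated
noise, partial-volume boundaries, registration error, non-Gaussian
thickness distributions — none of which the generators model.

## Numerical choices

- Rigidity tolerance 1e-6; arccos clamping; analytic rigid inverse.
- Dice both-empty convention 1.0 (warn) / NaN / error, configurable.
- Histogram bin index uses a 1e-9 rounding guard so values intended to sit
  on a bin edge (0.7/0.1 = 6.999…) land in the upper bin.
- FLIRT-matrix text I/O at 17 significant digits: float64 round-trips
  bit-identically.
- Correlations are clipped to [−1, 1] after the dot-product formula.
- Seeds: every generator takes one integer seed driving a
  `numpy.random.default_rng`; ground-truth objects record it.

## Known limitations

- No resampling, registration, surface geometry or random-field
  correction; inputs must be pre-aligned and vertex-corresponded.
- Trace grammar is one canonical dialect (tracer output formats vary);
  non-matching lines are skipped (lenient) or fatal (strict).
- The suite runner covers checksum/Dice/trace/MAD blocks; the remaining
  comparisons are library- and subcommand-level.
- Per-pid comparison assumes pids correspond across runs, which holds for
  deterministic fork orders only.
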