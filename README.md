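# reprotrace

Audit toolkit for numerical reproducibility of neuroimaging pipelines.

Running the same pipeline (tissue classification, motion correction, ICA,
cortical-thickness extraction) on two operating systems or two builds can
produce different results, because the dynamically linked math library
(`libm`) changes between system versions: a single-precision `expf`, `cosf`
or `sinf` result moving by one unit in the last place (ULP) is enough to
seed divergence that grows through conditionals, loop bounds and iterative
fits. `reprotrace` quantifies and localizes such differences between two
executions. It is written for pipeline developers and imaging researchers
who need to answer: *are these two runs the same, and if not, where and how
much do they differ?*

## What it measures

| Stage | Question | Metric |
|---|---|---|
| `floats` | How far apart are two printed float results? | ULP distance and flipped-bit count of binary32 encodings |
| `traces` | Where do two executions first diverge? | Per-line classification of paired library-call logs: type-1 (args differ, result equal), type-2 (both differ), type-3 (args equal, result differs — implementation change), mismatch (different functions — control flow diverged) |
| `volumes` | How similar are two label maps? | Per-label Dice `2\|A∩B\|/(\|A\|+\|B\|)`, generalized global Dice, binarized difference maps summed across subjects, SHA-256 screening |
| `motion` | How far apart are two motion-correction runs? | Residual rigid transform `T₁∘T₂⁻¹` per timepoint: translation norm (mm) and rotation angle `θ = arccos((tr R − 1)/2)` (deg); stage-wise mean-absolute-difference profile normalized by the final stage |
| `ica` | Do two ICA runs find the same sources? | Per-component matching by maximal spatial correlation, Dice of thresholded positive/negative parts, both directions, histogram summaries (min/μ/σ/mode) |
| `surface` | Do two conditions disagree on cortical thickness? | Vertex-wise one-sample t on the difference scores `d = A − B` (`t = d̄/(s_d/√n)`, df = n−1), mean/sd of \|d\|, uncorrected two-sided thresholding |
| `synthetic` | — | Seeded generators producing paired inputs with planted, exactly recoverable ground truth for every stage |

## Worked example

The canonical one-ULP cases — the expf/cosf/sinf single-precision results
whose little-endian encodings changed between glibc 2.5 and glibc 2.18:

```bash
$ reprotrace glibc-examples
func   hex A        hex B         ULP bits
expf   24 58 95 40  25 58 95 40     1    1
cosf   d8 b3 5d 3f  d7 b3 5d 3f     1    4
sinf   9a 0c 2d 3d  99 0c 2d 3d     1    2
```

Each pair is one ULP apart — adjacent representable floats — while the
number of flipped *bits* varies (a one-ULP step across a hex-digit borrow
flips several bits at once). That distinction is why the toolkit reports
both. A single pair:

```bash
$ reprotrace float-diff --hex-le "24 58 95 40" --hex-le2 "25 58 95 40"
{
  "value_a": 4.667009353637695,
  "value_b": 4.6670098304748535,
  "pattern_a": "0x40955824",
  "pattern_b": "0x40955825",
  "ulp": 1,
  "bits": 1
}
```

And an end-to-end synthetic audit of a trace pair with planted differences:

```bash
$ reprotrace simulate trace --seed 7 --out demo/ --n 10000
$ reprotrace trace-diff demo/trace_a.log demo/trace_b.log
{
  "n_lines": 10000,
  "n_identical": 9600,
  "first_difference": {"index": 31, "diff_class": "type1"},
  "class_totals": {"mismatch": 100, "type1": 100, "type2": 100, "type3": 100},
  ...
}
```

The recovered counts and positions equal the generator's ground truth
(written to `demo/ground_truth.json`) exactly. Exit codes: 0 = compared
and identical, 1 = compared and differing, 2 = usage/input error, so shell
pipelines can branch on reproducibility.

Other subcommands: `dice`, `diff-sum`, `checksum`, `motion-residuals`,
`stage-mad`, `ica-match`, `surf-ttest`, `run-suite` (checksum screening
first, metrics only for non-identical pairs).

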