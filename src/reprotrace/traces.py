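"""Library-call trace parsing and pairwise difference classification.

Two executions of the same deterministic program on two platforms should
perform the same sequence of math-library calls with the same arguments
and results.  Tracing those calls (one line per call) and comparing the
logs line by line localizes where, and in which function, the two
executions start to diverge.  Per-line differences fall in four classes:

- **type-1** — same function, different arguments, identical result
  (typical of non-injective functions such as ``floorf``/``ceilf``);
- **type-2** — same function, different arguments, different result
  (usually cascading consequences of earlier differences);
- **type-3** — same function, identical arguments, different result
  (the smoking gun: the library implementation itself differs);
- **mismatch** — different functions called at the same position
  (control flow has diverged).

Trace logs may reach tens of millions of lines, so parsing and diffing
are streaming: one line at a time, constant memory per line, with
periodic cumulative checkpoints for plotting difference curves.
"""

from __future__ import annotations

import enum
import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CallRecord",
    "DiffClass",
    "DiffRecord",
    "TraceDiffResult",
    "parse_trace",
    "classify_pair",
    "diff_traces",
    "split_by_pid",
    "diff_traces_per_pid",
    "summarize_functions",
]

#: Reserved return token for calls recorded without a return value.
VOID_RETURN = "<void>"

# "[pid 1234] expf(1.540630) = 4.667011"  (pid prefix optional)
_LINE_RE = re.compile(
    r"^\s*(?:\[pid\s+(?P<pid>\d+)\]\s*)?"
    r"(?P<func>[A-Za-z_][A-Za-z0-9_.]*)"
    r"\((?P<args>[^)]*)\)"
    r"\s*=\s*"
    r"(?P<ret>\S+)\s*$"
)


class DiffClass(enum.Enum):
    """Classification of one compared pair of trace lines."""

    IDENTICAL = "identical"
    TYPE1 = "type1"
    TYPE2 = "type2"
    TYPE3 = "type3"
    MISMATCH = "mismatch"

    def __str__(self) -> str:  # compact TSV rendering
        return self.value


@dataclass(frozen=True)
class CallRecord:
    """One parsed library call at a trace position.

    Argument and return tokens are kept as the decimal strings printed by
    the tracer: within one run the formatting is fixed, so exact string
    equality is the faithful comparison.
    """

    index: int
    func: str
    args: Tuple[str, ...]
    ret: str
    pid: Optional[int] = None
    raw: str = ""

    def __post_init__(self):
        if self.index < 0:
            raise ValueError("index must be >= 0")
        if not self.func:
            raise ValueError("func must be non-empty")


class TraceParseError(ValueError):
    """A trace line did not match the expected grammar (strict mode)."""


def _parse_line(line: str, index: int) -> Optional[CallRecord]:
    m = _LINE_RE.match(line)
    if m is None:
        return None
    args_str = m.group("args").strip()
    args = tuple(a.strip() for a in args_str.split(",")) if args_str else ()
    pid = m.group("pid")
    return CallRecord(
        index=index,
        func=m.group("func"),
        args=args,
        ret=m.group("ret"),
        pid=int(pid) if pid is not None else None,
        raw=line.rstrip("\r\n"),
    )


def parse_trace(stream: Union[str, Iterable[str]], strict: bool = False) -> Iterator[CallRecord]:
    """Parse a trace log into a stream of :class:`CallRecord`.

    Parameters
    ----------
    stream
        A text string, an open text file, or any iterable of lines.
        Comment lines (starting with ``#``) and blank lines are skipped
        and never consume an index.
    strict
        If true, a malformed line raises :class:`TraceParseError` naming
        the line number; otherwise it is skipped with a logged warning
        and does not consume an index.

    Yields
    ------
    CallRecord with consecutive 0-based indices in file order.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    index = 0
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rec = _parse_line(line, index)
        if rec is None:
            if strict:
                raise TraceParseError(
                    f"line {lineno}: cannot parse trace line: {stripped!r}"
                )
            logger.warning("skipping unparseable trace line %d: %r", lineno, stripped)
            continue
        yield rec
        index += 1


def _tokens_equal(xs: Sequence[str], ys: Sequence[str], numeric: bool) -> bool:
    if not numeric:
        return tuple(t.strip() for t in xs) == tuple(t.strip() for t in ys)
    if len(xs) != len(ys):
        return False
    for x, y in zip(xs, ys):
        try:
            fx, fy = float(x), float(y)
        except ValueError:
            if x.strip() != y.strip():
                return False
            continue
        # bit-pattern equality: distinguishes +0/-0, treats NaN != NaN
        if np.float64(fx).tobytes() != np.float64(fy).tobytes():
            return False
    return True


def classify_pair(a: CallRecord, b: CallRecord, numeric: bool = False) -> DiffClass:
    """Classify a pair of trace lines occupying the same index.

    A mismatch (different function names) is decided first — comparing
    arguments of different functions is meaningless.  Token comparison is
    exact-string after whitespace trimming by default; ``numeric=True``
    parses tokens to binary floating point and compares bit patterns.
    """
    if a.func != b.func:
        return DiffClass.MISMATCH
    args_eq = _tokens_equal(a.args, b.args, numeric)
    ret_eq = _tokens_equal((a.ret,), (b.ret,), numeric)
    if args_eq and ret_eq:
        return DiffClass.IDENTICAL
    if args_eq:  # same inputs, different output: implementation difference
        return DiffClass.TYPE3
    if ret_eq:
        return DiffClass.TYPE1
    return DiffClass.TYPE2


@dataclass(frozen=True)
class DiffRecord:
    """One non-identical compared position."""

    index: int
    func_a: Optional[str]
    func_b: Optional[str]
    diff_class: DiffClass


@dataclass
class TraceDiffResult:
    """Outcome of a line-by-line comparison of two traces.

    ``records`` holds only the non-identical positions (traces with tens
    of millions of identical lines stay cheap).  ``cumulative`` maps
    ``(function, DiffClass)`` to a list of ``(index, running_count)``
    checkpoints, suitable for plotting cumulative difference curves.
    """

    n_lines: int = 0
    n_identical: int = 0
    records: List[DiffRecord] = field(default_factory=list)
    totals: Counter = field(default_factory=Counter)        # (func, DiffClass) -> n
    class_totals: Counter = field(default_factory=Counter)  # DiffClass -> n
    first_difference: Optional[Tuple[int, DiffClass]] = None
    cumulative: Dict[Tuple[str, DiffClass], List[Tuple[int, int]]] = field(
        default_factory=dict
    )
    checkpoint: int = 10_000

    def to_records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.index, r.func_a, r.func_b, str(r.diff_class)) for r in self.records],
            columns=["index", "func_a", "func_b", "diff_class"],
        )

    def to_cumulative_frame(self) -> pd.DataFrame:
        rows = [
            (idx, func, str(cls), count)
            for (func, cls), series in sorted(
                self.cumulative.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
            for idx, count in series
        ]
        return pd.DataFrame(rows, columns=["index", "function", "diff_class", "count"])

    def summary_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "n_identical": self.n_identical,
            "first_difference": (
                None
                if self.first_difference is None
                else {"index": self.first_difference[0],
                      "diff_class": str(self.first_difference[1])}
            ),
            "class_totals": {str(c): n for c, n in sorted(
                self.class_totals.items(), key=lambda kv: kv[0].value)},
            "function_totals": {
                f"{func}:{cls}": n
                for (func, cls), n in sorted(
                    self.totals.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
            },
        }


def diff_traces(
    a: Iterable[CallRecord],
    b: Iterable[CallRecord],
    numeric: bool = False,
    checkpoint: int = 10_000,
) -> TraceDiffResult:
    """Compare two parsed traces line by line.

    Both traces must come from the same tracer dialect.  If the traces
    have different lengths, every unpaired trailing line counts as a
    MISMATCH (divergent control flow lengthens the mismatch series
    instead of aborting the comparison).  Raises on two empty traces.
    """
    result = TraceDiffResult(checkpoint=checkpoint)
    running: Counter = Counter()  # (func, DiffClass) -> count

    def _record(index: int, func_a, func_b, cls: DiffClass) -> None:
        result.records.append(DiffRecord(index, func_a, func_b, cls))
        func = func_a if func_a is not None else func_b
        result.totals[(func, cls)] += 1
        result.class_totals[cls] += 1
        running[(func, cls)] += 1
        if result.first_difference is None:
            result.first_difference = (index, cls)

    n = 0
    for ra, rb in zip_longest(a, b):
        idx = n
        if ra is None or rb is None:
            _record(idx, ra.func if ra else None, rb.func if rb else None,
                    DiffClass.MISMATCH)
        else:
            cls = classify_pair(ra, rb, numeric=numeric)
            if cls is DiffClass.IDENTICAL:
                result.n_identical += 1
            else:
                _record(idx, ra.func, rb.func, cls)
        n += 1
        if checkpoint and n % checkpoint == 0:
            for key, count in running.items():
                result.cumulative.setdefault(key, []).append((idx, count))
    if n == 0:
        raise ValueError("cannot diff empty traces")
    result.n_lines = n
    # closing checkpoint so the series always ends at the totals
    if not checkpoint or n % checkpoint != 0:
        for key, count in running.items():
            result.cumulative.setdefault(key, []).append((n - 1, count))
    return result


def split_by_pid(records: Iterable[CallRecord]) -> Dict[Optional[int], List[CallRecord]]:
    """Split an interleaved multi-process trace into per-pid streams.

    Indices are renumbered consecutively within each stream so that the
    per-pid streams can be compared independently.
    """
    streams: Dict[Optional[int], List[CallRecord]] = {}
    for rec in records:
        stream = streams.setdefault(rec.pid, [])
        stream.append(
            CallRecord(index=len(stream), func=rec.func, args=rec.args,
                       ret=rec.ret, pid=rec.pid, raw=rec.raw)
        )
    return streams


def diff_traces_per_pid(
    a: Iterable[CallRecord],
    b: Iterable[CallRecord],
    numeric: bool = False,
    checkpoint: int = 10_000,
) -> Dict[Optional[int], TraceDiffResult]:
    """Compare traces pid-by-pid; a pid missing on one side diffs against empty."""
    sa, sb = split_by_pid(a), split_by_pid(b)
    out = {}
    for pid in sorted(set(sa) | set(sb), key=lambda p: (p is None, p)):
        out[pid] = diff_traces(sa.get(pid, []), sb.get(pid, []),
                               numeric=numeric, checkpoint=checkpoint)
    return out


def summarize_functions(result: TraceDiffResult) -> pd.DataFrame:
    """Per-(function, class) counts of non-identical lines.

    Functions with zero differences are omitted; counts partition all
    non-identical compared lines.
    """
    rows = [
        (func, str(cls), count)
        for (func, cls), count in sorted(
            result.totals.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        )
        if count > 0
    ]
    return pd.DataFrame(rows, columns=["function", "diff_class", "count"])
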