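"""IEEE-754 single-precision forensics.

Library-call traces and debug printouts of numerical pipelines frequently
expose single-precision results as raw little-endian byte dumps.  This
module decodes such dumps, decomposes the binary32 bit pattern into its
sign / exponent / mantissa fields, and quantifies the difference between
two values on the two scales that matter for a reproducibility audit:

- **ULP distance** — how many representable floats lie between the two
  values (0 = identical, 1 = adjacent).  This is the honest measure of
  "how different" two libm results are.
- **Hamming bits** — how many bits of the two 32-bit patterns differ.
  A one-ULP step can flip several bits at once (e.g. a borrow across a
  hex digit), so "one bit flipped" phrasing in debug output usually means
  one ULP, not one bit; reporting both makes that distinction explicit.
"""

from __future__ import annotations

import math
import re
import struct
from dataclasses import dataclass
from decimal import Decimal, ROUND_DOWN, localcontext
from typing import List

__all__ = [
    "Float32Bits",
    "BitDiff",
    "hex_le_to_bits",
    "bits_from_pattern",
    "ulp_distance",
    "hamming_bits",
    "bit_diff",
    "format_30dec",
    "glibc_examples",
]

_HEX_BYTES_RE = re.compile(r"^[0-9a-fA-F]{8}$")


@dataclass(frozen=True)
class Float32Bits:
    """A binary32 value together with its raw bit pattern and fields.

    Attributes
    ----------
    pattern : int
        The 32-bit unsigned pattern (big-endian integer reading).
    sign, exponent, mantissa : int
        The 1-, 8- and 23-bit IEEE-754 fields.
    value : float
        The decoded real value (held in a Python double; every binary32
        value is exactly representable in binary64, including subnormals).
    """

    pattern: int
    sign: int
    exponent: int
    mantissa: int
    value: float

    def hex_le(self) -> str:
        """Little-endian byte encoding as ``"aa bb cc dd"``."""
        b = struct.pack("<I", self.pattern)
        return " ".join(f"{byte:02x}" for byte in b)

    @property
    def is_nan(self) -> bool:
        return self.exponent == 0xFF and self.mantissa != 0

    @property
    def is_inf(self) -> bool:
        return self.exponent == 0xFF and self.mantissa == 0


def bits_from_pattern(pattern: int) -> Float32Bits:
    """Build a :class:`Float32Bits` from a 32-bit unsigned integer pattern."""
    if not 0 <= pattern <= 0xFFFFFFFF:
        raise ValueError(f"pattern {pattern!r} is not a 32-bit unsigned integer")
    sign = (pattern >> 31) & 0x1
    exponent = (pattern >> 23) & 0xFF
    mantissa = pattern & 0x7FFFFF
    (value,) = struct.unpack("<f", struct.pack("<I", pattern))
    return Float32Bits(pattern=pattern, sign=sign, exponent=exponent,
                       mantissa=mantissa, value=value)


def hex_le_to_bits(hex_bytes: str) -> Float32Bits:
    """Decode a little-endian hex byte dump of a binary32 value.

    Accepts ``"24 58 95 40"`` and ``"24589540"`` (case-insensitive).  The
    four bytes are in memory order on a little-endian machine, so they are
    reversed to obtain the integer bit pattern: ``"24 58 95 40"`` decodes
    to pattern ``0x40955824``.
    """
    compact = re.sub(r"\s+", "", hex_bytes)
    if not _HEX_BYTES_RE.match(compact):
        raise ValueError(
            f"expected exactly 4 hex bytes (8 hex digits), got {hex_bytes!r}"
        )
    raw = bytes.fromhex(compact)
    (pattern,) = struct.unpack("<I", raw)
    return bits_from_pattern(pattern)


def _rank(bits: Float32Bits) -> int:
    """Map a non-NaN pattern to a monotone integer over the ordered floats.

    Sign-magnitude patterns are folded so that consecutive ranks are
    adjacent representable values; +0 and -0 share rank 0.  Infinities
    participate (adjacent to the largest finite magnitude).
    """
    if bits.is_nan:
        raise ValueError("ULP distance is undefined for NaN")
    magnitude = bits.pattern & 0x7FFFFFFF
    return -magnitude if bits.sign else magnitude


def _coerce(x) -> Float32Bits:
    if isinstance(x, Float32Bits):
        return x
    if isinstance(x, int):
        return bits_from_pattern(x)
    if isinstance(x, str):
        return hex_le_to_bits(x)
    raise TypeError(f"cannot interpret {x!r} as a binary32 pattern")


def ulp_distance(a, b) -> int:
    """Number of representable binary32 values separating ``a`` and ``b``.

    Accepts :class:`Float32Bits`, integer patterns or little-endian hex
    strings.  0 iff the values are equal (+0 and -0 count as equal);
    1 iff adjacent.  NaN inputs raise ``ValueError``.
    """
    return abs(_rank(_coerce(a)) - _rank(_coerce(b)))


def hamming_bits(a, b) -> int:
    """Population count of the XOR of the two 32-bit patterns."""
    return ((_coerce(a).pattern) ^ (_coerce(b).pattern)).bit_count()


@dataclass(frozen=True)
class BitDiff:
    """ULP distance and flipped-bit count between two binary32 values."""

    ulp_distance: int
    hamming_bits: int


def bit_diff(a, b) -> BitDiff:
    return BitDiff(ulp_distance=ulp_distance(a, b), hamming_bits=hamming_bits(a, b))


def format_30dec(v: float) -> str:
    """Exact fixed-point rendering with 30 fractional digits.

    Every finite binary float has a finite exact decimal expansion; this
    prints it truncated (toward zero) and zero-padded to exactly 30
    fractional digits, which is enough to display the complete expansion
    of any normal binary32 value.
    """
    if isinstance(v, Float32Bits):
        v = v.value
    v = float(v)
    if not math.isfinite(v):
        raise ValueError(f"cannot format non-finite value {v!r}")
    with localcontext() as ctx:
        ctx.prec = 200  # binary32 subnormals need ~150 significant digits
        d = Decimal(v).quantize(Decimal(1).scaleb(-30), rounding=ROUND_DOWN)
    return f"{d:f}"


# The expf/cosf/sinf single-precision results whose encodings changed
# between glibc 2.5 and glibc 2.18 — canonical cases where a libm update
# moved a correctly-printed result by exactly one ULP.
_GLIBC_CASES = [
    ("expf", "24 58 95 40", "25 58 95 40"),
    ("cosf", "d8 b3 5d 3f", "d7 b3 5d 3f"),
    ("sinf", "9a 0c 2d 3d", "99 0c 2d 3d"),
]


def glibc_examples() -> List[dict]:
    """Decode the three documented glibc 2.5-vs-2.18 libm result pairs.

    Returns one row per function (expf, cosf, sinf) with the decoded
    values, the ULP distance (1 for each) and the flipped-bit count —
    which differs between cases, showing that one ULP is not one bit.
    """
    rows = []
    for func, hex_a, hex_b in _GLIBC_CASES:
        a = hex_le_to_bits(hex_a)
        b = hex_le_to_bits(hex_b)
        rows.append({
            "function": func,
            "hex_le_a": hex_a,
            "hex_le_b": hex_b,
            "pattern_a": f"0x{a.pattern:08x}",
            "pattern_b": f"0x{b.pattern:08x}",
            "value_a": a.value,
            "value_b": b.value,
            "ulp_distance": ulp_distance(a, b),
            "hamming_bits": hamming_bits(a, b),
        })
    return rows
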