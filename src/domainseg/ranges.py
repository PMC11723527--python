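"""Residue range strings.

Domain boundaries are reported ECOD-style: comma-separated 1-based inclusive
intervals, optionally prefixed with a chain id, e.g. ``"A:1-100,A:150-200"``
or ``"12-57"``. Internally a domain is just a set of residue numbers
(1..L, author numbering after renumbering), possibly discontinuous.
"""

from __future__ import annotations

import re

_RANGE_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?(?P<start>\d+)(?:-(?P<end>\d+))?$")


def parse_range_string(text: str) -> set[int]:
    """Parse ``"A:1-100,A:150-200"`` into a residue-number set.

    Chain prefixes are accepted and ignored (single-chain convention).
    """
    residues: set[int] = set()
    for token in text.strip().split(","):
        token = token.strip()
        if not token:
            continue
        m = _RANGE_RE.match(token)
        if m is None:
            raise ValueError(f"malformed range token {token!r} in {text!r}")
        start = int(m.group("start"))
        end = int(m.group("end")) if m.group("end") else start
        if end < start:
            raise ValueError(f"inverted range {token!r}")
        residues.update(range(start, end + 1))
    return residues


def parse_range_intervals(text: str) -> list[tuple[int, int]]:
    """Parse a range string into sorted, non-overlapping inclusive intervals."""
    intervals: list[tuple[int, int]] = []
    for token in text.strip().split(","):
        token = token.strip()
        if not token:
            continue
        m = _RANGE_RE.match(token)
        if m is None:
            raise ValueError(f"malformed range token {token!r} in {text!r}")
        start = int(m.group("start"))
        intervals.append((start, int(m.group("end")) if m.group("end") else start))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping intervals in {text!r}")
        if e1 < s1 or e2 < s2:
            raise ValueError(f"inverted interval in {text!r}")
    return intervals


def format_range_string(residues: set[int] | frozenset[int], chain: str | None = None) -> str:
    """Format a residue set as sorted inclusive intervals, e.g. ``"1-100,150-200"``."""
    if not residues:
        return ""
    prefix = f"{chain}:" if chain else ""
    out: list[str] = []
    ordered = sorted(residues)
    start = prev = ordered[0]
    for r in ordered[1:]:
        if r == prev + 1:
            prev = r
            continue
        out.append(_fmt(prefix, start, prev))
        start = prev = r
    out.append(_fmt(prefix, start, prev))
    return ",".join(out)


def _fmt(prefix: str, start: int, end: int) -> str:
    return f"{prefix}{start}" if start == end else f"{prefix}{start}-{end}"
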