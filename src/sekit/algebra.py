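"""Pairwise algebra over piecewise-constant pileup tracks.

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping
``(start, end, value)`` segments with strictly positive values; zero
coverage is represented by absence. Seven operators combine two tracks:

====== ===========================================================
token  semantics (a = left operand, b = right operand)
====== ===========================================================
AND    a's pileup where both tracks have signal
OR     a's pileup where a has signal, b's pileup elsewhere on b
NOT    a's pileup where b has no signal
XOR    each side's own pileup on its exclusive support
``+``  pointwise sum
``-``  pointwise a - b, negative pileups clamped to zero
SYM    pointwise absolute difference (both clamped subtractions)
====== ===========================================================

The Boolean operators (AND/OR/NOT/XOR) never alter pileup heights, only
where signal survives; on overlaps the *left* operand's height is kept,
which makes the left fold of :func:`combine` treat the accumulated track
as the reference signal. The arithmetic operators (+/-/SYM) change
heights, and any negative result is clamped to zero and dropped from the
track.

An expression ``Sig1 Op12 Sig2 Op23 Sig3`` is evaluated strictly left to
right: ``(Sig1 Op12 Sig2) Op23 Sig3``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

from .errors import InputError, UsageError
from .intervals import GenomicInterval, Peak, Read

Segment = tuple[int, int, float]

_TOKEN_ALIASES = {
    "+": "+",
    "ADD": "+",
    "-": "-",
    "SUB": "-",
    "−": "-",  # unicode minus
    "AND": "AND",
    "OR": "OR",
    "NOT": "NOT",
    "XOR": "XOR",
    "SYM": "SYM",
}

OPERATORS = ("AND", "OR", "NOT", "XOR", "+", "-", "SYM")


def normalize_operator(token: str) -> str:
    """Resolve a (case-insensitive) operator token to its canonical form."""
    op = _TOKEN_ALIASES.get(token.upper().strip())
    if op is None:
        raise UsageError(f"unknown operator token {token!r}; expected one of {OPERATORS}")
    return op


def _coalesce(segments: Iterable[Segment]) -> list[Segment]:
    """Drop zero-valued segments and merge adjacent equal-valued ones."""
    out: list[Segment] = []
    for start, end, value in segments:
        if value <= 0 or end <= start:
            continue
        if out and out[-1][1] == start and out[-1][2] == value:
            out[-1] = (out[-1][0], end, value)
        else:
            out.append((start, end, value))
    return out


def _sweep(a: list[Segment], b: list[Segment], fn: Callable[[float, float], float]) -> list[Segment]:
    """Evaluate ``fn(value_a, value_b)`` over every elementary segment.

    Two-pointer sweep over the union of breakpoints; absent coverage
    contributes value 0. Output is coalesced and zero-free.
    """
    bounds = sorted({x for s, e, _ in a for x in (s, e)} | {x for s, e, _ in b for x in (s, e)})
    out: list[Segment] = []
    ia = ib = 0
    for lo, hi in zip(bounds, bounds[1:]):
        while ia < len(a) and a[ia][1] <= lo:
            ia += 1
        while ib < len(b) and b[ib][1] <= lo:
            ib += 1
        va = a[ia][2] if ia < len(a) and a[ia][0] <= lo else 0.0
        vb = b[ib][2] if ib < len(b) and b[ib][0] <= lo else 0.0
        out.append((lo, hi, fn(va, vb)))
    return _coalesce(out)


_PAIRWISE: dict[str, Callable[[float, float], float]] = {
    "AND": lambda va, vb: va if (va > 0 and vb > 0) else 0.0,
    "OR": lambda va, vb: va if va > 0 else vb,
    "NOT": lambda va, vb: va if vb == 0 else 0.0,
    "XOR": lambda va, vb: va if vb == 0 else (vb if va == 0 else 0.0),
    "+": lambda va, vb: va + vb,
    "-": lambda va, vb: max(va - vb, 0.0),
    "SYM": lambda va, vb: abs(va - vb),
}


class SignalTrack:
    """A genome-wide piecewise-constant non-negative pileup."""

    def __init__(self, segments: Iterable[tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[Segment]] = {}
        for chrom, start, end, value in segments:
            if value < 0:
                raise InputError(f"negative pileup {value} on {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._segs: dict[str, list[Segment]] = {}
        for chrom in sorted(per_chrom):
            segs = sorted(per_chrom[chrom])
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise InputError(f"overlapping segments on {chrom} at {s2} < {e1}")
            segs = _coalesce(segs)
            if segs:
                self._segs[chrom] = segs

    # -- construction -------------------------------------------------

    @classmethod
    def from_reads(cls, reads: Iterable[Read]) -> "SignalTrack":
        """Coverage track: value at a base = number of reads covering it."""
        events: dict[str, list[tuple[int, int]]] = {}
        for read in reads:
            iv = read.interval
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
        segments = []
        for chrom in sorted(events):
            evs = sorted(events[chrom])
            depth = 0
            prev = None
            for pos, delta in evs:
                if prev is not None and pos > prev and depth > 0:
                    segments.append((chrom, prev, pos, float(depth)))
                depth += delta
                prev = pos
        return cls(segments)

    @classmethod
    def from_peaks(cls, peaks: Iterable[Peak]) -> "SignalTrack":
        """Track where each peak contributes its pileup; overlaps add."""
        events: dict[str, list[tuple[int, float]]] = {}
        for peak in peaks:
            iv = peak.interval
            events.setdefault(iv.chrom, []).append((iv.start, +peak.pileup))
            events[iv.chrom].append((iv.end, -peak.pileup))
        segments = []
        for chrom in sorted(events):
            evs = sorted(events[chrom])
            height = 0.0
            prev = None
            for pos, delta in evs:
                if prev is not None and pos > prev and height > 0:
                    segments.append((chrom, prev, pos, height))
                height += delta
                prev = pos
        return cls(segments)

    @classmethod
    def from_bedgraph_rows(cls, rows: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        return cls(rows)

    # -- inspection ---------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._segs)

    def segments(self, chrom: str) -> list[Segment]:
        return list(self._segs.get(chrom, []))

    def to_rows(self) -> list[tuple[str, int, int, float]]:
        return [(c, s, e, v) for c in self._segs for s, e, v in self._segs[c]]

    def is_empty(self) -> bool:
        return not self._segs

    def support(self) -> list[GenomicInterval]:
        """Maximal merged intervals where pileup > 0."""
        out = []
        for chrom, segs in self._segs.items():
            cur_s, cur_e = segs[0][0], segs[0][1]
            for s, e, _ in segs[1:]:
                if s == cur_e:
                    cur_e = e
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append(GenomicInterval(chrom, cur_s, cur_e))
        return out

    def area(self, region: GenomicInterval | None = None) -> float:
        """Integral of the pileup, optionally restricted to ``region``."""
        total = 0.0
        if region is None:
            for segs in self._segs.values():
                total += sum((e - s) * v for s, e, v in segs)
            return total
        for s, e, v in self._segs.get(region.chrom, []):
            total += max(0, min(e, region.end) - max(s, region.start)) * v
        return total

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SignalTrack) and self._segs == other._segs

    def __repr__(self) -> str:
        n = sum(len(v) for v in self._segs.values())
        return f"SignalTrack({len(self._segs)} chroms, {n} segments)"


def overlap_regions(a: SignalTrack, b: SignalTrack) -> list[GenomicInterval]:
    """Intersection of the two supports as maximal intervals."""
    return apply_pairwise("AND", a, b).support()


def apply_pairwise(op: str, a: SignalTrack, b: SignalTrack) -> SignalTrack:
    """Apply one operator to two tracks; see the module table for semantics."""
    fn = _PAIRWISE[normalize_operator(op)]
    rows = []
    for chrom in sorted(set(a.chroms) | set(b.chroms)):
        for s, e, v in _sweep(a.segments(chrom), b.segments(chrom), fn):
            rows.append((chrom, s, e, v))
    return SignalTrack(rows)


def combine(signals: Sequence[SignalTrack], operators: Sequence[str]) -> SignalTrack:
    """Strict left fold: ``((Sig1 Op1 Sig2) Op2 Sig3) ...``."""
    if not signals:
        raise UsageError("expression needs at least one signal")
    if len(operators) != len(signals) - 1:
        raise UsageError(
            f"expression arity mismatch: {len(signals)} signals need "
            f"{len(signals) - 1} operators, got {len(operators)}"
        )
    acc = signals[0]
    for op, sig in zip(operators, signals[1:]):
        acc = apply_pairwise(op, acc, sig)
    return acc
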