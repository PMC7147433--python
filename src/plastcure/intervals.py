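"""Circular-interval arithmetic on a genome of length L.

A plastome is a circle; every interval here is a (start, length) pair taken
modulo L.  Intervals never cover the whole circle (length < L) except where
explicitly allowed, and ``length == 0`` denotes an empty arc.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CircularInterval:
    """Arc ``[start, start+length)`` on a circle of circumference ``L``."""

    start: int
    length: int
    L: int

    def __post_init__(self) -> None:
        if not (0 < self.L):
            raise ValueError("circle length must be positive")
        if not (0 <= self.length <= self.L):
            raise ValueError("interval length outside [0, L]")
        object.__setattr__(self, "start", self.start % self.L)

    @property
    def end(self) -> int:
        """Exclusive end position, reduced mod L."""
        return (self.start + self.length) % self.L

    @property
    def wraps(self) -> bool:
        return self.start + self.length > self.L

    def contains(self, pos: int) -> bool:
        off = (pos - self.start) % self.L
        return off < self.length

    def shift(self, r: int) -> "CircularInterval":
        return CircularInterval((self.start + r) % self.L, self.length, self.L)

    def reflect(self) -> "CircularInterval":
        """Image under the strand flip p -> L-1-p (interval reversed in place)."""
        if self.length == 0:
            return CircularInterval((-self.start) % self.L, 0, self.L)
        new_start = (self.L - self.end) % self.L
        return CircularInterval(new_start, self.length, self.L)

    def overlaps(self, other: "CircularInterval") -> bool:
        if self.length == 0 or other.length == 0:
            return False
        return (
            self.contains(other.start)
            or other.contains(self.start)
        )

    def linear_parts(self) -> list[tuple[int, int]]:
        """Split into 1 or 2 linear [start, end) pieces within [0, L)."""
        if self.length == 0:
            return []
        if self.wraps:
            return [(self.start, self.L), (0, self.start + self.length - self.L)]
        return [(self.start, self.start + self.length)]

    def slice(self, seq: str) -> str:
        """Extract the arc's bases from a linear string of length L."""
        if len(seq) != self.L:
            raise ValueError("sequence length does not match circle length")
        return "".join(seq[a:b] for a, b in self.linear_parts())


def circular_gap(a: CircularInterval, b: CircularInterval) -> CircularInterval:
    """The arc running forward from the end of ``a`` to the start of ``b``."""
    if a.L != b.L:
        raise ValueError("intervals on different circles")
    L = a.L
    length = (b.start - a.end) % L
    return CircularInterval(a.end, length, L)


def circular_distance(p: int, q: int, L: int) -> int:
    """Shortest-way distance between two positions on the circle."""
    d = (p - q) % L
    return min(d, L - d)


def circular_hull(a: CircularInterval, b: CircularInterval) -> CircularInterval:
    """Smallest interval containing two overlapping-or-nearby arcs.

    Chooses the hull that spans from one arc to the other the short way
    around; the caller must ensure the pair genuinely belongs to one repeat
    copy (hull length is capped at L).
    """
    if a.L != b.L:
        raise ValueError("intervals on different circles")
    if a.length == 0:
        return b
    if b.length == 0:
        return a
    L = a.L
    len_from_a = max(a.length, ((b.start - a.start) % L) + b.length)
    len_from_b = max(b.length, ((a.start - b.start) % L) + a.length)
    if len_from_a <= len_from_b:
        return CircularInterval(a.start, min(len_from_a, L), L)
    return CircularInterval(b.start, min(len_from_b, L), L)
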