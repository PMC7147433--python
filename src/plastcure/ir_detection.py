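"""Inverted-repeat detection on circular draft plastomes.

The detector tiles the circle with non-overlapping windows, looks up each
window's reverse complement at every circular offset, and exploits the
anti-diagonal geometry of an inverted repeat: if position ``p`` in one copy
pairs with position ``c - 1 - p`` (mod L) in the other, every matched
window pair ``(i, j)`` satisfies ``i + j + w == c`` exactly.  Matches are
therefore clustered by this pairing constant, fragmented clusters (gapped
palindromes) are merged span-wise from their outermost extremes, and the
final boundaries are refined base-by-base so the two copies end exactly
where their reverse-complement agreement ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .intervals import CircularInterval, circular_gap, circular_hull
from .model import (
    CurationFailure,
    DetectionError,
    Plastome,
    REASON_AMBIGUOUS,
    REASON_NO_IR,
    REASON_TOO_SHORT,
    REASON_UNRESOLVED,
)

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)
_IUPAC = frozenset(IUPAC_COMPLEMENT)
_UNAMBIGUOUS = frozenset("ACGT")

# boundary refinement: a mismatch run of up to _MAX_SKIP_RUN bases may be
# stepped over, but only when followed by _MIN_CONTINUATION exact matches —
# a chance continuation of that length in single-copy sequence has
# probability (1/4)^12 ~ 6e-8, so clean boundaries stay base-exact.
_MAX_SKIP_RUN = 50
_MIN_CONTINUATION = 12


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (involution)."""
    bad = set(seq) - _IUPAC
    if bad:
        pos = next(i for i, ch in enumerate(seq) if ch in bad)
        raise ValueError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the sliding-window detector.

    window_size: tiling window in bp; smaller windows survive denser
        mismatches at the cost of specificity.
    ir_discrepancy_tolerance: allowed implied length difference between the
        two copies (in bp) before fragments are declared irreconcilable.
    min_ir_length: shortest repeat reported as an IR; defaults to one window.
    max_ambiguous_fraction: windows with a higher fraction of non-ACGT
        characters are excluded from the match index.
    """

    window_size: int = 1000
    ir_discrepancy_tolerance: int = 500
    min_ir_length: int | None = None
    max_ambiguous_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.window_size < 10:
            raise ValueError("window_size must be >= 10")
        if self.min_ir_length is None:
            object.__setattr__(self, "min_ir_length", self.window_size)
        if self.min_ir_length < self.window_size:
            raise ValueError("min_ir_length must be >= window_size")
        if not (0.0 <= self.max_ambiguous_fraction <= 1.0):
            raise ValueError("max_ambiguous_fraction must lie in [0, 1]")
        if self.ir_discrepancy_tolerance < 0:
            raise ValueError("ir_discrepancy_tolerance must be >= 0")


@dataclass(frozen=True)
class Window:
    index: int
    start: int            # circular start position
    text: str
    excluded: bool        # too many ambiguity codes


@dataclass
class WindowMatchIndex:
    """Forward windows matched against reverse-complement w-mers anywhere.

    ``matches`` holds ``(i, j)`` pairs: the full window starting at circular
    position ``i`` equals the reverse complement of the w-mer starting at
    circular position ``j``.  ``j`` is *not* restricted to the tiling grid —
    a repeat's second copy is almost never grid-aligned with the first.
    """

    w: int
    L: int
    windows: list[Window]
    matches: list[tuple[int, int]]
    revcomp_lookup: dict[str, list[int]]


@dataclass
class RepeatPair:
    """The two copies of a detected inverted repeat on the input circle."""

    copy_a: CircularInterval
    copy_b: CircularInterval
    pairing_constant: int  # c: base p in copy_a pairs with (c - 1 - p) mod L
    mismatches: int = 0
    repaired: bool = False
    n_candidate_pairs_considered: int = 1

    @property
    def length(self) -> int:
        return self.copy_a.length


def tile_windows(
    seq: str, w: int, max_ambiguous_fraction: float = 0.1
) -> list[Window]:
    """Non-overlapping w-windows over the circle; the last window wraps.

    Starts are 0, w, 2w, ...; when L is not a multiple of w the final
    window begins at (m-1)*w and wraps across the origin, so up to w-1
    bases near the origin are covered twice.
    """
    L = len(seq)
    if L < 2 * w:
        raise DetectionError(
            REASON_TOO_SHORT, f"sequence of {L} bp shorter than two windows of {w} bp"
        )
    m = math.ceil(L / w)
    doubled = seq + seq[: w - 1]
    windows = []
    for t in range(m):
        start = t * w
        text = doubled[start : start + w]
        n_ambig = sum(1 for ch in text if ch not in _UNAMBIGUOUS)
        windows.append(
            Window(t, start, text, excluded=n_ambig / w > max_ambiguous_fraction)
        )
    return windows


def _circular_occurrences(doubled: str, pattern: str, L: int) -> list[int]:
    """All circular start positions (< L) of ``pattern`` in the sequence."""
    out = []
    pos = doubled.find(pattern)
    while 0 <= pos < L:
        out.append(pos)
        pos = doubled.find(pattern, pos + 1)
    return out


def build_match_index(seq: str, cfg: DetectionConfig) -> WindowMatchIndex:
    """Pair every clean tiled window with all reverse-complement sites."""
    w = cfg.window_size
    L = len(seq)
    windows = tile_windows(seq, w, cfg.max_ambiguous_fraction)
    if all(win.excluded for win in windows):
        raise DetectionError(
            REASON_AMBIGUOUS, "every window exceeds the ambiguity limit"
        )
    doubled = seq + seq[: w - 1]
    matches: list[tuple[int, int]] = []
    lookup: dict[str, list[int]] = {}
    for win in windows:
        if win.excluded:
            continue
        target = reverse_complement(win.text)
        hits = _circular_occurrences(doubled, target, L)
        site = CircularInterval(win.start, w, L)
        kept = [j for j in hits if not site.overlaps(CircularInterval(j, w, L))]
        if kept:
            lookup[win.text] = kept
            matches.extend((win.start, j) for j in kept)
    matches.sort()
    return WindowMatchIndex(w=w, L=L, windows=windows, matches=matches, revcomp_lookup=lookup)


def _phi(interval: CircularInterval, c: int) -> CircularInterval:
    """Image of an interval under the pairing reflection p -> c - 1 - p."""
    L = interval.L
    return CircularInterval((c - interval.start - interval.length) % L, interval.length, L)


def _runs_to_pairs(index: WindowMatchIndex) -> list[RepeatPair]:
    """Maximal anti-diagonal runs of matched windows -> raw candidate pairs."""
    w, L = index.w, index.L
    m = len(index.windows)
    by_c: dict[int, list[int]] = {}
    for i, j in index.matches:
        by_c.setdefault((i + j + w) % L, []).append(i)
    pairs: list[RepeatPair] = []
    start_to_t = {win.start: win.index for win in index.windows}
    for c, starts in sorted(by_c.items()):
        ts = sorted({start_to_t[s] for s in starts})
        # split into circularly consecutive runs of window indices
        runs: list[list[int]] = []
        cur = [ts[0]]
        for t in ts[1:]:
            if t == cur[-1] + 1:
                cur.append(t)
            else:
                runs.append(cur)
                cur = [t]
        runs.append(cur)
        # wrap-around: last run may continue into the first
        if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == m - 1:
            runs[0] = runs.pop() + runs[0]
        for run in runs:
            first = index.windows[run[0]].start
            last = index.windows[run[-1]].start
            length = ((last - first) % L) + w
            if length > L // 2:
                continue  # copies would overlap; not a valid repeat copy
            a = CircularInterval(first, length, L)
            pairs.append(RepeatPair(copy_a=a, copy_b=_phi(a, c), pairing_constant=c))
    return pairs


def _try_merge(p: RepeatPair, q: RepeatPair, c: int) -> RepeatPair | None:
    """Merge two same-constant fragments if their hulls stay disjoint."""
    best = None
    for qa in (q.copy_a, q.copy_b):
        a = circular_hull(p.copy_a, qa)
        if a.length > p.copy_a.L // 2:
            continue
        b = _phi(a, c)
        if a.overlaps(b):
            continue
        if best is None or a.length < best.copy_a.length:
            best = RepeatPair(copy_a=a, copy_b=b, pairing_constant=c)
    return best


def locate_repeat_extremes(
    index: WindowMatchIndex, cfg: DetectionConfig
) -> list[RepeatPair]:
    """Cluster matched windows into candidate repeat pairs.

    Runs sharing a pairing constant whose evidence overlaps (the mirror
    image of the same physical repeat seen from the other copy's windows)
    are unified; fragments separated by mismatched windows remain distinct
    candidates for the repair step.  Candidates are sorted longest first.
    """
    raw = _runs_to_pairs(index)
    by_c: dict[int, list[RepeatPair]] = {}
    for p in raw:
        by_c.setdefault(p.pairing_constant, []).append(p)
    candidates: list[RepeatPair] = []
    for c, group in sorted(by_c.items()):
        group = sorted(group, key=lambda p: (-p.copy_a.length, p.copy_a.start))
        merged: list[RepeatPair] = []
        for p in group:
            placed = False
            for k, q in enumerate(merged):
                if (
                    q.copy_a.overlaps(p.copy_a)
                    or q.copy_a.overlaps(p.copy_b)
                    or q.copy_b.overlaps(p.copy_a)
                    or q.copy_b.overlaps(p.copy_b)
                ):
                    u = _try_merge(q, p, c)
                    if u is not None:
                        merged[k] = u
                        placed = True
                        break
            if not placed:
                merged.append(p)
        candidates.extend(merged)
    candidates.sort(key=lambda p: (-p.copy_a.length, p.copy_a.start))
    # canonical orientation: copy_a is the copy with the smaller circular start
    oriented = []
    for p in candidates:
        if p.copy_b.start < p.copy_a.start:
            p = replace(p, copy_a=p.copy_b, copy_b=p.copy_a)
        oriented.append(p)
    return oriented


def _c_distance(c1: int, c2: int, L: int) -> int:
    d = (c1 - c2) % L
    return min(d, L - d)


def repair_gapped_pair(
    candidates: list[RepeatPair], seq: str, cfg: DetectionConfig
) -> RepeatPair:
    """Merge fragmented candidates of the dominant repeat by their extremes.

    Fragments whose pairing constants differ by more than the discrepancy
    tolerance imply copies of different lengths (an indel-style
    misassembly); if such an irreconcilable fragment overlaps the dominant
    repeat's territory the record is failed rather than guessed at.
    """
    if not candidates:
        raise DetectionError(REASON_NO_IR, "no matched window runs")
    L = len(seq)
    primary = candidates[0]
    c = primary.pairing_constant
    merged = primary
    n_fragments = 1
    others: list[RepeatPair] = []
    for p in candidates[1:]:
        if _c_distance(p.pairing_constant, c, L) <= cfg.ir_discrepancy_tolerance:
            u = _try_merge(merged, p, c)
            if u is not None:
                merged = u
                n_fragments += 1
                continue
        others.append(p)
    # irreconcilable fragment overlapping the chosen repeat's territory
    for p in others:
        if p.copy_a.length < cfg.min_ir_length:
            continue
        if (
            merged.copy_a.overlaps(p.copy_a)
            or merged.copy_a.overlaps(p.copy_b)
            or merged.copy_b.overlaps(p.copy_a)
            or merged.copy_b.overlaps(p.copy_b)
        ):
            raise DetectionError(
                REASON_UNRESOLVED,
                "candidate repeat pairs overlap but cannot be reconciled "
                f"(pairing constants differ by more than {cfg.ir_discrepancy_tolerance} bp)",
            )
    return replace(
        merged,
        repaired=n_fragments > 1,
        n_candidate_pairs_considered=1 + len(others),
    )


def _bases_pair(seq: str, p: int, q: int) -> bool:
    a, b = seq[p], seq[q]
    return a in _UNAMBIGUOUS and b in _UNAMBIGUOUS and IUPAC_COMPLEMENT[a] == b


def refine_boundaries(pair: RepeatPair, seq: str) -> RepeatPair:
    """Extend/trim repeat boundaries to base precision.

    The outer edges move outward while the two copies keep pairing;
    isolated interior mismatch runs are stepped over only when followed by
    a long exact continuation, so boundaries remain exact in the presence
    of scattered substitutions near the repeat ends yet never overshoot on
    clean sequence.  The two copies stay equal length by construction.
    """
    L = len(seq)
    c = pair.pairing_constant
    start_a, length = pair.copy_a.start, pair.copy_a.length

    def pairs_at(p: int) -> bool:
        return _bases_pair(seq, p % L, (c - 1 - p) % L)

    # trim inward while the current outermost bases do not pair
    while length > 0 and not pairs_at(start_a):
        start_a += 1
        length -= 1
    while length > 0 and not pairs_at(start_a + length - 1):
        length -= 1
    if length == 0:
        raise DetectionError(REASON_NO_IR, "candidate dissolved during refinement")

    def max_steps(gap: int) -> int:
        # each outward step consumes 2 bp of the single-copy arc on that side
        return max(gap, 0) // 2

    def extend(side: int) -> int:
        """Confirmed outward extension on one side (side=-1 left, +1 right)."""
        a = CircularInterval(start_a, length, L)
        b = _phi(a, c)
        if side < 0:
            gap = circular_gap(b, a).length
            probe0 = start_a - 1
            step = -1
        else:
            gap = circular_gap(a, b).length
            probe0 = start_a + length
            step = 1
        cap = max_steps(gap)
        ext = 0
        while ext < cap:
            p = probe0 + step * ext
            if pairs_at(p):
                ext += 1
                continue
            # mismatch run of g bases, then a long exact continuation?
            advanced = False
            for g in range(1, _MAX_SKIP_RUN + 1):
                if ext + g + _MIN_CONTINUATION > cap:
                    break
                run_ok = all(
                    pairs_at(probe0 + step * (ext + g + k)) for k in range(_MIN_CONTINUATION)
                )
                mid_is_gap = not pairs_at(probe0 + step * (ext + g - 1))
                if mid_is_gap and run_ok:
                    ext += g + _MIN_CONTINUATION
                    advanced = True
                    break
                if not mid_is_gap:
                    break
            if not advanced:
                break
        # retract to the outermost position that actually pairs
        while ext > 0 and not pairs_at(probe0 + step * (ext - 1)):
            ext -= 1
        return ext

    left = extend(-1)
    start_a -= left
    length += left
    right = extend(+1)
    length += right

    a = CircularInterval(start_a % L, length, L)
    b = _phi(a, c)
    mismatches = sum(
        0 if _bases_pair(seq, (a.start + k) % L, (c - 1 - (a.start + k)) % L) else 1
        for k in range(length)
    )
    out = replace(pair, copy_a=a, copy_b=b, mismatches=mismatches)
    if out.copy_b.start < out.copy_a.start:
        out = replace(out, copy_a=out.copy_b, copy_b=out.copy_a)
    return out


def detect_inverted_repeats(
    plastome: Plastome | str, cfg: DetectionConfig | None = None
) -> RepeatPair | CurationFailure:
    """Full detection: tile, index, locate, repair, refine.

    Works for any linearization of the circle, including cuts that split a
    repeat copy across the sequence origin, and for either strand.
    """
    if cfg is None:
        cfg = DetectionConfig()
    if isinstance(plastome, str):
        plastome = Plastome(id="<anonymous>", sequence=plastome)
    seq = plastome.sequence
    try:
        index = build_match_index(seq, cfg)
        candidates = locate_repeat_extremes(index, cfg)
        pair = repair_gapped_pair(candidates, seq, cfg)
        pair = refine_boundaries(pair, seq)
        if pair.length < cfg.min_ir_length:
            raise DetectionError(
                REASON_TOO_SHORT,
                f"longest repeat ({pair.length} bp) below minimum {cfg.min_ir_length} bp",
            )
        return pair
    except DetectionError as err:
        return err.to_failure(plastome.id)


# re-exported for users of this module's failure type
__all__ = [
    "CurationFailure",
    "DetectionConfig",
    "IUPAC_COMPLEMENT",
    "RepeatPair",
    "Window",
    "WindowMatchIndex",
    "build_match_index",
    "detect_inverted_repeats",
    "locate_repeat_extremes",
    "repair_gapped_pair",
    "refine_boundaries",
    "reverse_complement",
    "tile_windows",
]
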