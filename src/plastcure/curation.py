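"""Canonical reordering of a plastome once its inverted repeats are known.

Given the detected repeat pair, the circle decomposes into four arcs:
LSC (the longer single-copy arc), one IR copy, SSC, and the other copy.
The curated output is the linearization LSC-IRb-SSC-IRa beginning at the
first LSC base, where IRb is by definition the copy following the LSC.
Because the circle already carries that structure, curation is always a
pure rotation of the input, or of its reverse complement — never a
re-shuffling — so base content is conserved exactly and annotations can
be lifted through a bijective coordinate map.

Which strand to emit is chosen deterministically: of the two whole-
molecule candidates (forward reading and reverse-complement reading, each
rotated to its own LSC start) the lexicographically smaller sequence wins.
This makes every rotation and either strand of the same molecule converge
to one byte-identical curated string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import CircularInterval, circular_gap
from .ir_detection import (
    DetectionConfig,
    RepeatPair,
    detect_inverted_repeats,
    reverse_complement,
)
from .model import (
    CurationFailure,
    DetectionError,
    FeatureAnnotation,
    Plastome,
    REASON_UNRESOLVED,
    SummaryRow,
)


@dataclass
class RegionPartition:
    """The four structural arcs on the *input* circle.

    ``irb`` is the IR copy that immediately follows the LSC when the
    molecule is read in the sense selected for output; ``input_strand_flipped``
    records whether that sense is the reverse complement of the input.
    """

    lsc: CircularInterval
    irb: CircularInterval
    ssc: CircularInterval
    ira: CircularInterval
    input_strand_flipped: bool = False

    @property
    def L(self) -> int:
        return self.lsc.L

    def region_lengths(self) -> tuple[int, int, int, int]:
        return (self.lsc.length, self.irb.length, self.ssc.length, self.ira.length)

    def reflected(self) -> "RegionPartition":
        """The same arcs read from the reverse-complement strand.

        Intervals stay in input coordinates (the arcs themselves are
        strand-independent); only the IRb/IRa labels swap, because the copy
        that follows the LSC reverses with the reading sense.
        """
        return RegionPartition(
            lsc=self.lsc,
            irb=self.ira,
            ssc=self.ssc,
            ira=self.irb,
            input_strand_flipped=not self.input_strand_flipped,
        )


@dataclass(frozen=True)
class CoordinateTransform:
    """Bijection from input circular positions to output linear positions.

    Forward sense:  out = (p - anchor) mod L.
    Flipped sense:  out = (anchor - p) mod L with base complementation
    (anchor is then the *last* input position of the output's first base's
    arc, i.e. out position 0 maps back to input position ``anchor``).
    """

    L: int
    flipped: bool
    anchor: int

    @property
    def rotation_offset(self) -> int:
        return self.anchor

    def map_position(self, p: int) -> int:
        if self.flipped:
            return (self.anchor - p) % self.L
        return (p - self.anchor) % self.L

    def map_linear_interval(self, u: int, v: int) -> list[tuple[int, int]]:
        """Image of input piece [u, v) as 1-2 output pieces in reading order.

        Reading order follows ascending *input* position; under a flipped
        transform that is descending output position, so callers must
        reverse piece order themselves when re-assembling minus-sense
        features (see :func:`liftover_annotations`).
        """
        if not (0 <= u < v <= self.L):
            raise ValueError(f"piece ({u}, {v}) outside [0, {self.L}]")
        length = v - u
        if self.flipped:
            x = (self.anchor - v + 1) % self.L
        else:
            x = (u - self.anchor) % self.L
        if x + length <= self.L:
            return [(x, x + length)]
        return [(x, self.L), (0, x + length - self.L)]

    def apply(self, seq: str) -> str:
        if len(seq) != self.L:
            raise ValueError("sequence length does not match transform")
        if self.flipped:
            rc = reverse_complement(seq)
            cut = (self.L - 1 - self.anchor) % self.L
            return rc[cut:] + rc[:cut]
        return seq[self.anchor :] + seq[: self.anchor]


@dataclass
class CurationResult:
    """A curated record: canonical sequence, coordinate map, lifted features."""

    id: str
    status: str
    partition: RegionPartition
    transform: CoordinateTransform
    curated_sequence: str
    lifted_features: list[FeatureAnnotation] = field(default_factory=list)
    summary: SummaryRow | None = None
    alternative: "CurationResult | None" = None  # other-strand candidate

    def output_regions(self) -> dict[str, tuple[int, int]]:
        """0-based half-open region intervals on the curated sequence."""
        l_lsc, l_irb, l_ssc, l_ira = self.partition.region_lengths()
        a = l_lsc
        b = a + l_irb
        c = b + l_ssc
        d = c + l_ira
        return {"LSC": (0, a), "IRb": (a, b), "SSC": (b, c), "IRa": (c, d)}

    def region_sequence(self, name: str) -> str:
        a, b = self.output_regions()[name]
        return self.curated_sequence[a:b]


def partition_regions(plastome: Plastome, pair: RepeatPair) -> RegionPartition:
    """Label the two single-copy arcs between the repeat copies.

    The longer arc is the LSC; ties and zero-length arcs are biologically
    aberrant and fail rather than guess.
    """
    arc_ab = circular_gap(pair.copy_a, pair.copy_b)  # a.end -> b.start
    arc_ba = circular_gap(pair.copy_b, pair.copy_a)  # b.end -> a.start
    if arc_ab.length == 0 or arc_ba.length == 0:
        raise DetectionError(
            REASON_UNRESOLVED, "degenerate structure: repeat copies are adjacent"
        )
    if arc_ab.length == arc_ba.length:
        raise DetectionError(
            REASON_UNRESOLVED,
            f"ambiguous LSC/SSC: both single-copy arcs are {arc_ab.length} bp",
        )
    if arc_ba.length > arc_ab.length:
        # ... LSC(arc_ba) -> copy_a -> SSC(arc_ab) -> copy_b ...
        return RegionPartition(lsc=arc_ba, irb=pair.copy_a, ssc=arc_ab, ira=pair.copy_b)
    return RegionPartition(lsc=arc_ab, irb=pair.copy_b, ssc=arc_ba, ira=pair.copy_a)


def _candidate(plastome: Plastome, partition: RegionPartition) -> CurationResult:
    """Build one strand candidate (no lex selection, no liftover yet)."""
    L = plastome.length
    if partition.input_strand_flipped:
        # out position 0 reads the complement of the last LSC input base
        transform = CoordinateTransform(L=L, flipped=True, anchor=(partition.lsc.end - 1) % L)
    else:
        transform = CoordinateTransform(L=L, flipped=False, anchor=partition.lsc.start)
    curated = transform.apply(plastome.sequence)
    return CurationResult(
        id=plastome.id,
        status="curated",
        partition=partition,
        transform=transform,
        curated_sequence=curated,
    )


def reorder_plastome(plastome: Plastome, partition: RegionPartition) -> CurationResult:
    """Emit the canonical LSC-IRb-SSC-IRa linearization.

    Both strand candidates are constructed; the lexicographically smaller
    curated string is returned (ties keep the forward sense), with the
    rejected candidate attached for batch orientation harmonization.
    """
    if partition.input_strand_flipped:
        partition = partition.reflected()  # normalize: arcs described on input strand
    fwd = _candidate(plastome, partition)
    rev = _candidate(plastome, partition.reflected())
    if rev.curated_sequence < fwd.curated_sequence:
        chosen, other = rev, fwd
    else:
        chosen, other = fwd, rev
    chosen.alternative = other
    return chosen


def liftover_annotations(
    plastome: Plastome, transform: CoordinateTransform
) -> list[FeatureAnnotation]:
    """Map every feature into the curated frame, preserving its sequence.

    Pieces are split at the output origin and merged when they become
    adjacent; a flipped transform flips strands and reverses piece order so
    that extraction from the curated sequence reproduces the input feature
    sequence exactly.
    """
    lifted: list[FeatureAnnotation] = []
    for feat in plastome.features:
        pieces: list[tuple[int, int]] = []
        source = feat.sub_intervals if not transform.flipped else list(reversed(feat.sub_intervals))
        for u, v in source:
            pieces.extend(transform.map_linear_interval(u, v))
        # merge pieces that are adjacent in the output reading order
        merged: list[tuple[int, int]] = []
        for x, y in pieces:
            if merged and merged[-1][1] == x:
                merged[-1] = (merged[-1][0], y)
            else:
                merged.append((x, y))
        strand = feat.strand
        if transform.flipped:
            strand = "-" if strand == "+" else "+"
        lifted.append(
            FeatureAnnotation(
                feature_type=feat.feature_type,
                start=min(x for x, _ in merged),
                end=max(y for _, y in merged),
                strand=strand,
                sub_intervals=merged,
                attributes=dict(feat.attributes),
            )
        )
    lifted.sort(key=lambda f: (f.start, f.end, f.feature_type))
    return lifted


def _summary_row(result: CurationResult, window_size: int, mismatches: int) -> SummaryRow:
    regions = result.output_regions()

    def one_based(name: str) -> tuple[int, int, int]:
        a, b = regions[name]
        return (a + 1, b, b - a)

    return SummaryRow(
        id=result.id,
        status="curated",
        window_size_used=window_size,
        lsc=one_based("LSC"),
        irb=one_based("IRb"),
        ssc=one_based("SSC"),
        ira=one_based("IRa"),
        ir_mismatches=mismatches,
        notes="strand flipped" if result.transform.flipped else "",
    )


def curate_plastome(
    plastome: Plastome, cfg: DetectionConfig | None = None
) -> CurationResult | CurationFailure:
    """Detect the IRs and rewrite one plastome in canonical order."""
    if cfg is None:
        cfg = DetectionConfig()
    detected = detect_inverted_repeats(plastome, cfg)
    if isinstance(detected, CurationFailure):
        return detected
    try:
        partition = partition_regions(plastome, detected)
    except DetectionError as err:
        return err.to_failure(plastome.id)
    result = reorder_plastome(plastome, partition)
    result.lifted_features = liftover_annotations(plastome, result.transform)
    result.summary = _summary_row(result, cfg.window_size, detected.mismatches)
    result.summary.notes = (result.summary.notes + " repaired" if detected.repaired else result.summary.notes).strip()
    if result.alternative is not None:
        result.alternative.lifted_features = liftover_annotations(
            plastome, result.alternative.transform
        )
        result.alternative.summary = _summary_row(
            result.alternative, cfg.window_size, detected.mismatches
        )
    return result


def _kmers(seq: str, k: int = 15) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def harmonize_orientation(results: list[CurationResult]) -> list[CurationResult]:
    """Choose per-record strand so all LSCs read in the batch reference sense.

    The first curated record fixes the reference; every other record keeps
    its canonical form or swaps to its other-strand candidate, whichever
    LSC shares more 15-mers with the reference LSC.  Stranded (non-
    canonicalized) k-mers are used on purpose: collapsing a k-mer with its
    reverse complement would erase exactly the orientation signal sought.
    """
    if not results:
        return results
    ref_kmers = _kmers(results[0].region_sequence("LSC"))
    out = [results[0]]
    for res in results[1:]:
        if res.alternative is None:
            out.append(res)
            continue
        score_self = len(ref_kmers & _kmers(res.region_sequence("LSC")))
        score_alt = len(ref_kmers & _kmers(res.alternative.region_sequence("LSC")))
        if score_alt > score_self:
            alt = res.alternative
            alt.alternative = res
            out.append(alt)
        else:
            out.append(res)
    return out
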