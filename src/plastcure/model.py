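"""Core domain records shared across the package.

A draft plastome arrives as a single circular DNA sequence, optionally
annotated (GenBank input).  Curation either succeeds — producing a
canonically ordered sequence — or fails with a machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# closed vocabulary for the failure report
REASON_NO_IR = "no_ir_found"
REASON_UNRESOLVED = "multiple_candidate_pairs_unresolved"
REASON_TOO_SHORT = "ir_length_below_minimum"
REASON_PARSE = "parse_error"
REASON_AMBIGUOUS = "ambiguous_bases_exceed_limit"

FAILURE_REASONS = frozenset(
    {REASON_NO_IR, REASON_UNRESOLVED, REASON_TOO_SHORT, REASON_PARSE, REASON_AMBIGUOUS}
)


@dataclass
class FeatureAnnotation:
    """One annotated feature with 0-based half-open sub-intervals.

    ``sub_intervals`` are listed in the feature's reading order along the
    plus strand of the stored sequence; a minus-strand feature's sequence is
    the reverse complement of the concatenated sub-interval strings.
    Locations that wrap the sequence origin are held as two sub-intervals
    rather than modular coordinates.
    """

    feature_type: str
    start: int
    end: int
    strand: str  # '+' or '-'
    is_compound: bool = False
    sub_intervals: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.sub_intervals:
            self.sub_intervals = [(self.start, self.end)]
        for a, b in self.sub_intervals:
            if not (0 <= a < b):
                raise ValueError(f"malformed sub-interval ({a}, {b})")
        self.is_compound = len(self.sub_intervals) > 1

    def extract(self, seq: str) -> str:
        """Feature sequence under the stored reading-order convention."""
        s = "".join(seq[a:b] for a, b in self.sub_intervals)
        if self.strand == "-":
            from .ir_detection import reverse_complement

            s = reverse_complement(s)
        return s

    @property
    def span_length(self) -> int:
        return sum(b - a for a, b in self.sub_intervals)


@dataclass
class Plastome:
    """A single circular plastome sequence plus provenance and annotations."""

    id: str
    sequence: str
    source_format: str = "fasta"
    features: list[FeatureAnnotation] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CurationFailure:
    """A record that could not be curated, with a closed-set reason code."""

    id: str
    reason_code: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason_code not in FAILURE_REASONS:
            raise ValueError(f"unknown reason code {self.reason_code!r}")


class DetectionError(Exception):
    """Internal signal carrying a failure reason through the pipeline."""

    def __init__(self, reason_code: str, detail: str = ""):
        super().__init__(f"{reason_code}: {detail}")
        self.reason_code = reason_code
        self.detail = detail

    def to_failure(self, seq_id: str) -> CurationFailure:
        return CurationFailure(seq_id, self.reason_code, self.detail)


@dataclass
class SummaryRow:
    """Per-record line of the batch summary table (1-based output coordinates)."""

    id: str
    status: str  # 'curated' | 'failed'
    window_size_used: int
    lsc: tuple[int, int, int] | None = None  # (start, end, length)
    irb: tuple[int, int, int] | None = None
    ssc: tuple[int, int, int] | None = None
    ira: tuple[int, int, int] | None = None
    ir_mismatches: int = 0
    notes: str = ""
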