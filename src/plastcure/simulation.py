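"""Synthetic plastomes with known ground truth, and the mutation-robustness
experiment.

The generator emits a circle LSC + IRb + SSC + IRa (IRa the exact reverse
complement of IRb), arbitrarily linearized at one of nine cut positions and
optionally strand-flipped, with two certificates enforced at build time:
no spurious inverted-repeat seed exists anywhere off the planted pairing,
and the bases flanking the repeat boundaries do not extend the palindrome —
so the planted boundaries are the unique base-exact answer.

The robustness experiment plants random substitutions inside one IR copy
at a series of divergence levels and scores how often detection still
recovers the true boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import CircularInterval, circular_distance
from .ir_detection import (
    DetectionConfig,
    IUPAC_COMPLEMENT,
    RepeatPair,
    detect_inverted_repeats,
    reverse_complement,
)
from .model import CurationFailure, Plastome

# NC_000932-like region sizes (A. thaliana chloroplast, 154,478 bp)
ARABIDOPSIS_SCALE = {"lsc_len": 84170, "ir_len": 26264, "ssc_len": 17780}

# desk-scale default: one order of magnitude below typical plastome regions
DEFAULT_SCALE = {"lsc_len": 8500, "ir_len": 2500, "ssc_len": 1800}

_CERT_WORD = 40  # spurious-repeat certificate word size (bp)
_MAX_RESAMPLE = 10

_BASES = np.array(list("ACGT"))


def default_variation_levels(n: int = 11) -> list[float]:
    """Geometric ladder of IR divergence levels from 0.01% to 5.31%."""
    return [float(x) for x in np.geomspace(1e-4, 5.31e-2, n)]


@dataclass
class SyntheticTruth:
    """A generated plastome plus its ground-truth structure (emitted coords)."""

    plastome: Plastome
    lsc: CircularInterval
    ssc: CircularInterval
    ir1: CircularInterval
    ir2: CircularInterval
    cut_class: int
    flipped: bool
    seed: int
    planted_mismatches: int = 0

    @property
    def ir_length(self) -> int:
        return self.ir1.length


@dataclass
class SimulationConfig:
    """Conditions of the mutation-robustness experiment."""

    variation_levels: list[float] = field(default_factory=default_variation_levels)
    replicates_per_level: int = 1000
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    boundary_tolerance_bp: int = 0

    def __post_init__(self) -> None:
        lv = self.variation_levels
        if any(not (0.0 < x < 1.0) for x in lv) or any(
            b <= a for a, b in zip(lv, lv[1:])
        ):
            raise ValueError("variation levels must be strictly increasing in (0, 1)")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")


@dataclass
class LevelResult:
    level: float
    n_alterations: int
    n_replicates: int
    n_correct: int
    n_incorrect: int
    n_failed: int  # subset of n_incorrect where no repeat was returned at all
    recovery_rate: float
    mean_boundary_error_bp: float | None


@dataclass
class SimulationReport:
    levels: list[LevelResult]
    config: SimulationConfig

    def to_tsv(self) -> str:
        header = (
            "level\tn_alterations\tn_replicates\tn_correct\tn_incorrect\t"
            "n_failed\trecovery_rate\tmean_boundary_error_bp"
        )
        rows = [header]
        for r in self.levels:
            err = "" if r.mean_boundary_error_bp is None else f"{r.mean_boundary_error_bp:.1f}"
            rows.append(
                f"{r.level:.6g}\t{r.n_alterations}\t{r.n_replicates}\t{r.n_correct}\t"
                f"{r.n_incorrect}\t{r.n_failed}\t{r.recovery_rate:.4f}\t{err}"
            )
        return "\n".join(rows) + "\n"


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _certify_no_spurious(seq: str, c0: int, k: int = _CERT_WORD) -> bool:
    """True iff every inverted k-mer match lies on the planted pairing."""
    L = len(seq)
    doubled = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for p in range(L):
        index.setdefault(doubled[p : p + k], []).append(p)
    for p in range(L):
        word = doubled[p : p + k]
        target = reverse_complement(word)
        for q in index.get(target, ()):
            if q != (c0 - k - p) % L:
                return False
    return True


_CUT_FRACTIONS = {
    # class -> offset into the canonical circle where the linearization cuts
    1: lambda lsc, ir, ssc: 0,                       # conventional LSC start
    2: lambda lsc, ir, ssc: lsc // 3,                # inside LSC
    3: lambda lsc, ir, ssc: (2 * lsc) // 3,          # inside LSC
    4: lambda lsc, ir, ssc: lsc,                     # IRb start
    5: lambda lsc, ir, ssc: lsc + ir // 2,           # inside IRb (IR split)
    6: lambda lsc, ir, ssc: lsc + ir,                # SSC start
    7: lambda lsc, ir, ssc: lsc + ir + ssc // 2,     # inside SSC
    8: lambda lsc, ir, ssc: lsc + ir + ssc,          # IRa start
    9: lambda lsc, ir, ssc: lsc + ir + ssc + ir // 2,  # inside IRa (IR split)
}

CUT_CLASSES = tuple(sorted(_CUT_FRACTIONS))


def generate_synthetic_plastome(
    lsc_len: int = DEFAULT_SCALE["lsc_len"],
    ir_len: int = DEFAULT_SCALE["ir_len"],
    ssc_len: int = DEFAULT_SCALE["ssc_len"],
    seed: int = 0,
    cut_class: int | str = 1,
    flip: bool | str = False,
    gc: float = 0.37,
) -> SyntheticTruth:
    """Build a certified synthetic plastome in a chosen linearization.

    The emitted record is the canonical circle rotated so the cut of the
    requested class becomes position 0, then optionally reverse-
    complemented; the returned truth intervals live on the emitted
    coordinates.
    """
    if not (lsc_len > ssc_len > 0 and ir_len > 0):
        raise ValueError("sizes must satisfy lsc_len > ssc_len > 0 and ir_len > 0")
    rng = np.random.default_rng(seed)
    if cut_class == "random":
        cut_class = int(rng.integers(1, 10))
    if cut_class not in _CUT_FRACTIONS:
        raise ValueError(f"cut_class must be 1-9, got {cut_class!r}")
    if flip == "random":
        flip = bool(rng.integers(0, 2))

    L = lsc_len + 2 * ir_len + ssc_len
    c0 = 2 * lsc_len + 2 * ir_len + ssc_len  # planted pairing constant (canonical)
    comp = IUPAC_COMPLEMENT
    seq = None
    for _ in range(_MAX_RESAMPLE):
        lsc = _random_bases(rng, lsc_len, gc)
        irb = _random_bases(rng, ir_len, gc)
        ssc = _random_bases(rng, ssc_len, gc)
        s = list(lsc + irb + ssc + reverse_complement(irb))
        # flank certificates: the palindrome must stop exactly at the
        # planted boundaries (positions derived from p <-> c0-1-p pairing)
        while s[lsc_len - 1] == comp[s[0]]:
            s[lsc_len - 1] = str(rng.choice(_BASES))
        while s[lsc_len + ir_len] == comp[s[lsc_len + ir_len + ssc_len - 1]]:
            s[lsc_len + ir_len] = str(rng.choice(_BASES))
        cand = "".join(s)
        if _certify_no_spurious(cand, c0 % L):
            seq = cand
            break
    if seq is None:
        raise RuntimeError("could not generate a certified sequence; sizes too small?")

    return _emit(seq, lsc_len, ir_len, ssc_len, int(cut_class), bool(flip), seed)


def _emit(
    canonical: str,
    lsc_len: int,
    ir_len: int,
    ssc_len: int,
    cut_class: int,
    flip: bool,
    seed: int,
) -> SyntheticTruth:
    """Linearize a canonical-order circle at the requested cut, maybe flipped."""
    L = len(canonical)
    r = _CUT_FRACTIONS[cut_class](lsc_len, ir_len, ssc_len) % L
    emitted = canonical[r:] + canonical[:r]
    intervals = {
        "lsc": CircularInterval(0, lsc_len, L).shift(-r),
        "ir1": CircularInterval(lsc_len, ir_len, L).shift(-r),
        "ssc": CircularInterval(lsc_len + ir_len, ssc_len, L).shift(-r),
        "ir2": CircularInterval(lsc_len + ir_len + ssc_len, ir_len, L).shift(-r),
    }
    if flip:
        emitted = reverse_complement(emitted)
        intervals = {k: v.reflect() for k, v in intervals.items()}
    name = f"synth-s{seed}-c{cut_class}" + ("-flip" if flip else "")
    return SyntheticTruth(
        plastome=Plastome(id=name, sequence=emitted, source_format="fasta"),
        lsc=intervals["lsc"],
        ssc=intervals["ssc"],
        ir1=intervals["ir1"],
        ir2=intervals["ir2"],
        cut_class=cut_class,
        flipped=flip,
        seed=seed,
    )


def relinearize(
    truth: SyntheticTruth, cut_class: int, flip: bool = False
) -> SyntheticTruth:
    """Re-emit a conventionally linearized molecule under another cut/strand.

    The input must be in the conventional linearization (cut class 1,
    unflipped); all certificates carry over since the molecule is unchanged.
    """
    if truth.cut_class != 1 or truth.flipped:
        raise ValueError("relinearize requires a cut-class-1, unflipped truth")
    return _emit(
        truth.plastome.sequence,
        truth.lsc.length,
        truth.ir_length,
        truth.ssc.length,
        int(cut_class),
        bool(flip),
        truth.seed,
    )


def inject_ir_substitutions(
    truth: SyntheticTruth, level: float, seed: int
) -> tuple[Plastome, list[tuple[int, str, str]]]:
    """Plant ``round(level * ir_length)`` substitutions inside one IR copy.

    Changes touch only the first copy, so the number of planted changes
    equals the number of mismatching positions between the two copies.
    """
    if not (0.0 <= level < 1.0):
        raise ValueError("level must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    k = round(level * truth.ir_length)
    seq = list(truth.plastome.sequence)
    L = len(seq)
    changes: list[tuple[int, str, str]] = []
    if k > 0:
        offsets = rng.choice(truth.ir_length, size=k, replace=False)
        for off in sorted(int(o) for o in offsets):
            pos = (truth.ir1.start + off) % L
            old = seq[pos]
            options = [b for b in "ACGT" if b != old]
            new = options[int(rng.integers(0, len(options)))]
            seq[pos] = new
            changes.append((pos, old, new))
    mutated = Plastome(
        id=truth.plastome.id + f"-mut{len(changes)}",
        sequence="".join(seq),
        source_format="fasta",
    )
    return mutated, changes


@dataclass(frozen=True)
class RecoveryScore:
    outcome: str  # 'correct' | 'incorrect' | 'failed'
    boundary_error_bp: int | None

    @property
    def correct(self) -> bool:
        return self.outcome == "correct"


def score_recovery(
    detected: RepeatPair | CurationFailure,
    truth: SyntheticTruth,
    boundary_tolerance_bp: int = 0,
) -> RecoveryScore:
    """Compare detected repeat copies with the planted truth on the circle."""
    if isinstance(detected, CurationFailure):
        return RecoveryScore("failed", None)
    L = truth.plastome.length

    def pair_error(a: CircularInterval, t: CircularInterval) -> int:
        return max(
            circular_distance(a.start, t.start, L),
            circular_distance(a.end, t.end, L),
        )

    err = min(
        max(pair_error(detected.copy_a, truth.ir1), pair_error(detected.copy_b, truth.ir2)),
        max(pair_error(detected.copy_a, truth.ir2), pair_error(detected.copy_b, truth.ir1)),
    )
    if err <= boundary_tolerance_bp:
        return RecoveryScore("correct", err)
    return RecoveryScore("incorrect", err)


def _replicate_seed(master: int, level_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(level_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_mutation_experiment(
    substrate: SyntheticTruth, cfg: SimulationConfig
) -> SimulationReport:
    """Replicated detection on progressively noisier copies of one substrate."""
    out: list[LevelResult] = []
    for li, level in enumerate(cfg.variation_levels):
        n_correct = n_incorrect = n_failed = 0
        errors: list[int] = []
        for rep in range(cfg.replicates_per_level):
            mutated, changes = inject_ir_substitutions(
                substrate, level, _replicate_seed(cfg.seed, li, rep)
            )
            detected = detect_inverted_repeats(mutated, cfg.detection)
            score = score_recovery(detected, substrate, cfg.boundary_tolerance_bp)
            if score.correct:
                n_correct += 1
            else:
                n_incorrect += 1
                if score.outcome == "failed":
                    n_failed += 1
                else:
                    errors.append(score.boundary_error_bp)
        out.append(
            LevelResult(
                level=level,
                n_alterations=round(level * substrate.ir_length),
                n_replicates=cfg.replicates_per_level,
                n_correct=n_correct,
                n_incorrect=n_incorrect,
                n_failed=n_failed,
                recovery_rate=n_correct / cfg.replicates_per_level,
                mean_boundary_error_bp=(sum(errors) / len(errors)) if errors else None,
            )
        )
    return SimulationReport(levels=out, config=cfg)


def make_annotated_record(
    sequence: str, rec_id: str, seed: int, n_features: int = 22
):
    """A GenBank-style SeqRecord with deterministic random annotations.

    Emulates the annotation shapes that exercise liftover: plus and minus
    strand features, two compound (multi-exon) locations, and one feature
    wrapping the sequence origin.  Gene names are unique so lifted features
    can be matched back to their sources.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    L = len(sequence)
    rec = SeqRecord(
        Seq(sequence),
        id=rec_id,
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    features = []
    a = int(rng.integers(80, 300))
    b = int(rng.integers(80, 300))
    features.append(
        SeqFeature(
            CompoundLocation([SimpleLocation(L - a, L, 1), SimpleLocation(0, b, 1)]),
            type="gene",
            qualifiers={"gene": ["wrap0"]},
        )
    )
    for k, strand in enumerate((1, -1)):
        s = int(rng.integers(0, L - 4000))
        exon1 = SimpleLocation(s, s + int(rng.integers(150, 400)), strand)
        e2 = int(exon1.end) + int(rng.integers(100, 500))
        exon2 = SimpleLocation(e2, e2 + int(rng.integers(150, 400)), strand)
        parts = [exon1, exon2] if strand == 1 else [exon2, exon1]
        features.append(
            SeqFeature(CompoundLocation(parts), type="CDS", qualifiers={"gene": [f"join{k}"]})
        )
    while len(features) < n_features:
        s = int(rng.integers(0, L - 2000))
        length = int(rng.integers(120, 1500))
        strand = int(rng.choice([1, -1]))
        ftype = str(rng.choice(["gene", "CDS", "tRNA", "rRNA"]))
        features.append(
            SeqFeature(
                SimpleLocation(s, s + length, strand),
                type=ftype,
                qualifiers={"gene": [f"g{len(features)}"]},
            )
        )
    rec.features = features
    return rec


def emit_fixture(truth: SyntheticTruth, out_prefix: str) -> tuple[str, str]:
    """Write the synthetic record as FASTA plus a truth sidecar TSV."""
    from pathlib import Path

    fasta = Path(f"{out_prefix}.fasta")
    seq = truth.plastome.sequence
    wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
    fasta.write_text(f">{truth.plastome.id}\n{wrapped}\n")
    rows = ["id\tregion\tstart\tend\tstrand\tcut_class\tflipped\tseed"]
    for name, iv in (
        ("LSC", truth.lsc),
        ("IR1", truth.ir1),
        ("SSC", truth.ssc),
        ("IR2", truth.ir2),
    ):
        rows.append(
            f"{truth.plastome.id}\t{name}\t{iv.start}\t{iv.end}\t+\t"
            f"{truth.cut_class}\t{truth.flipped}\t{truth.seed}"
        )
    tsv = Path(f"{out_prefix}_truth.tsv")
    tsv.write_text("\n".join(rows) + "\n")
    return str(fasta), str(tsv)
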