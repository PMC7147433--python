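"""Reading draft plastomes and writing the curated output artifacts.

Input is a folder with one sequence per file, FASTA or GenBank.  Output
artifacts are: the batch summary TSV, curated sequences (multi-FASTA or
per-record GFF3 with embedded FASTA), the failure report TSV, optional
per-region multi-FASTAs, and the orientation-harmonized set.  All writes
go to a temporary file first and are renamed into place.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path

from Bio import SeqIO

from .curation import CurationResult
from .model import (
    CurationFailure,
    FeatureAnnotation,
    Plastome,
    REASON_PARSE,
)

log = logging.getLogger(__name__)

FASTA_EXTENSIONS = {".fa", ".fasta", ".fna"}
GENBANK_EXTENSIONS = {".gb", ".gbk", ".genbank", ".gbff"}
REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")

_LINE_WIDTH = 70

# feature types carried through curation; 'source' spans the whole record
# and is regenerated as region lines instead
_SKIPPED_FEATURE_TYPES = {"source"}


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + _LINE_WIDTH] for i in range(0, len(seq), _LINE_WIDTH))


def _atomic_write(path: Path, content: str) -> Path:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(content)
    os.replace(tmp, path)
    return path


def _feature_from_seqfeature(feat, record) -> FeatureAnnotation | None:
    if feat.type in _SKIPPED_FEATURE_TYPES:
        return None
    strand = "-" if feat.location.strand == -1 else "+"
    parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
    if any(a >= b for a, b in parts):
        return None  # zero-width or malformed location
    wanted = {"gene", "product", "locus_tag", "note"}
    attributes = {
        k: v[0] for k, v in feat.qualifiers.items() if k in wanted and v
    }
    fa = FeatureAnnotation(
        feature_type=feat.type,
        start=min(a for a, _ in parts),
        end=max(b for _, b in parts),
        strand=strand,
        sub_intervals=parts,
        attributes=attributes,
    )
    # normalize part order to this package's reading-order convention:
    # extraction must reproduce what the GenBank location itself encodes
    reference = str(feat.extract(record.seq)).upper()
    if fa.extract(str(record.seq).upper()) != reference:
        flipped = FeatureAnnotation(
            feature_type=fa.feature_type,
            start=fa.start,
            end=fa.end,
            strand=strand,
            sub_intervals=list(reversed(parts)),
            attributes=attributes,
        )
        if flipped.extract(str(record.seq).upper()) == reference:
            fa = flipped
        else:
            log.warning(
                "%s: feature %s location not representable; kept best effort",
                record.id,
                feat.type,
            )
    return fa


def _read_one_file(path: Path, fmt: str) -> Plastome:
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) == 0:
        raise ValueError("no sequence records found")
    if len(records) > 1:
        raise ValueError(f"{len(records)} records in file; exactly one expected")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    features: list[FeatureAnnotation] = []
    if fmt == "genbank":
        for feat in rec.features:
            fa = _feature_from_seqfeature(feat, rec)
            if fa is not None:
                features.append(fa)
    return Plastome(
        id=rec.id or path.stem,
        sequence=seq,
        source_format=fmt,
        features=features,
        source_path=str(path),
    )


def read_plastome_folder(
    path: str | os.PathLike, fmt: str = "auto"
) -> tuple[list[Plastome], list[CurationFailure]]:
    """Read every recognized single-sequence file, lexicographic order.

    Returns the successfully parsed plastomes plus one failure entry per
    unreadable or multi-record file; an input folder with no recognized
    files at all is an error.
    """
    if fmt not in {"fasta", "genbank", "auto"}:
        raise ValueError(f"unknown input format {fmt!r}")
    folder = Path(path)
    if not folder.is_dir():
        raise ValueError(f"input folder {folder} does not exist")
    candidates = sorted(
        p
        for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in (FASTA_EXTENSIONS | GENBANK_EXTENSIONS)
    )
    if fmt == "fasta":
        candidates = [p for p in candidates if p.suffix.lower() in FASTA_EXTENSIONS]
    elif fmt == "genbank":
        candidates = [p for p in candidates if p.suffix.lower() in GENBANK_EXTENSIONS]
    if not candidates:
        raise ValueError(f"no input sequences found in {folder}")
    plastomes: list[Plastome] = []
    failures: list[CurationFailure] = []
    for p in candidates:
        file_fmt = "fasta" if p.suffix.lower() in FASTA_EXTENSIONS else "genbank"
        try:
            plastomes.append(_read_one_file(p, file_fmt))
        except Exception as exc:  # per-file isolation: one bad file never aborts
            failures.append(CurationFailure(p.name, REASON_PARSE, str(exc)))
    return plastomes, failures


def _curated_record(result: CurationResult, no_irs_mode: int) -> str:
    seq = result.curated_sequence
    if no_irs_mode == 1:
        a, b = result.output_regions()["IRa"]
        seq = seq[:a]  # IRa is always the final region
    return f">{result.id}\n{_wrap(seq)}\n"


def write_curated_fasta(
    results: list[CurationResult],
    out_prefix: str,
    no_irs_mode: int = 1,
    suffix: str = "_curated.fasta",
) -> Path:
    """Multi-FASTA of curated sequences; mode 1 omits the trailing IRa."""
    if no_irs_mode not in (1, 2):
        raise ValueError("no_irs_mode must be 1 or 2")
    if not results:
        log.warning("no curated records; writing empty %s%s", out_prefix, suffix)
    body = "".join(_curated_record(r, no_irs_mode) for r in results)
    return _atomic_write(Path(f"{out_prefix}{suffix}"), body)


def _gff3_escape(value: str) -> str:
    return re.sub(r"[;=&,\t\n]", lambda m: "%%%02X" % ord(m.group()), value)


def _feature_lines(result: CurationResult) -> list[str]:
    lines = []
    L = len(result.curated_sequence)
    for n, feat in enumerate(result.lifted_features, start=1):
        attrs = [f"ID={_gff3_escape(result.id)}.f{n}"]
        if "gene" in feat.attributes:
            attrs.append(f"Name={_gff3_escape(feat.attributes['gene'])}")
        for key in ("gene", "product", "locus_tag", "note"):
            if key in feat.attributes:
                attrs.append(f"{key}={_gff3_escape(feat.attributes[key])}")
        attr_col = ";".join(attrs)
        # phase is tracked through the feature's reading order for CDS
        reading = feat.sub_intervals if feat.strand == "+" else list(reversed(feat.sub_intervals))
        cum = 0
        phases = {}
        for a, b in reading:
            phases[(a, b)] = (3 - cum % 3) % 3
            cum += b - a
        for a, b in sorted(feat.sub_intervals):
            if not (0 <= a < b <= L):
                raise RuntimeError(
                    f"{result.id}: lifted feature outside [1, {L}] — liftover defect"
                )
            phase = str(phases[(a, b)]) if feat.feature_type == "CDS" else "."
            lines.append(
                "\t".join(
                    [
                        result.id,
                        "plastcure",
                        feat.feature_type,
                        str(a + 1),
                        str(b),
                        ".",
                        feat.strand,
                        phase,
                        attr_col,
                    ]
                )
            )
    return lines


def write_gff3(result: CurationResult, out_prefix: str) -> Path:
    """GFF3 v3 for one curated record, curated FASTA appended."""
    L = len(result.curated_sequence)
    lines = ["##gff-version 3", f"##sequence-region {result.id} 1 {L}"]
    for name, (a, b) in result.output_regions().items():
        lines.append(
            "\t".join(
                [
                    result.id,
                    "plastcure",
                    "region",
                    str(a + 1),
                    str(b),
                    ".",
                    "+",
                    ".",
                    f"ID={_gff3_escape(result.id)}.{name};Name={name}",
                ]
            )
        )
    lines.extend(_feature_lines(result))
    lines.append("##FASTA")
    lines.append(f">{result.id}")
    lines.append(_wrap(result.curated_sequence))
    safe_id = re.sub(r"[^A-Za-z0-9._-]", "_", result.id)
    return _atomic_write(Path(f"{out_prefix}_{safe_id}.gff3"), "\n".join(lines) + "\n")


def write_region_files(
    results: list[CurationResult] | CurationResult,
    out_prefix: str,
    which: tuple[str, ...] | set[str] = REGION_NAMES,
) -> list[Path]:
    """One multi-FASTA per requested region across the batch.

    The IRa file holds the IRa exactly as it appears in the curated
    sequence, i.e. the reverse complement of the IRb file's content.
    """
    if isinstance(results, CurationResult):
        results = [results]
    unknown = set(which) - set(REGION_NAMES)
    if unknown:
        raise ValueError(f"unknown region name(s): {sorted(unknown)}")
    paths = []
    for name in (n for n in REGION_NAMES if n in set(which)):
        body = "".join(
            f">{r.id}\n{_wrap(r.region_sequence(name))}\n" for r in results
        )
        paths.append(_atomic_write(Path(f"{out_prefix}_{name}.fasta"), body))
    return paths


def write_failure_report(
    failures: list[CurationFailure], out_prefix: str
) -> Path:
    """TSV of per-record failures; header-only when the batch was clean."""
    lines = ["id\treason_code\tdetail"]
    lines.extend(f"{f.id}\t{f.reason_code}\t{f.detail}" for f in failures)
    return _atomic_write(Path(f"{out_prefix}_failures.tsv"), "\n".join(lines) + "\n")


def write_summary(results: list[CurationResult], out_prefix: str) -> Path:
    """Batch summary: region coordinates (1-based inclusive) and IR stats."""
    header = ["id", "status", "window_size"]
    for region in ("lsc", "irb", "ssc", "ira"):
        header += [f"{region}_start", f"{region}_end", f"{region}_length"]
    header += ["ir_mismatches", "notes"]
    lines = ["\t".join(header)]
    for r in results:
        s = r.summary
        row = [s.id, s.status, str(s.window_size_used)]
        for region in (s.lsc, s.irb, s.ssc, s.ira):
            row += [str(x) for x in region]
        row += [str(s.ir_mismatches), s.notes]
        lines.append("\t".join(row))
    return _atomic_write(Path(f"{out_prefix}_summary.tsv"), "\n".join(lines) + "\n")
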