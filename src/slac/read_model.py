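"""Per-read data model for single-read tRNA-seq analysis.

A sequencing read of a tRNA is short enough to represent one molecule, so a
single alignment record simultaneously reports the misincorporation
("mutation") signature at every modified position it covers, the 3' terminus
(CCA = aminoacylated, CC = deacylated after periodate treatment), and any 3'
truncation.  This module defines :class:`SingleReadRecord` / :class:`ReadSet`
and the readers/writers that move them between SAM/BAM, the tab-delimited
single-read table, and the mature-tRNA FASTA reference.

Coordinates are 1-based inclusive positions on the mature tRNA transcript
(including the 3' CCA).  Canonical (Sprinzl) numbering, when needed for
labelling, is an annotation layer on top and never enters computation.
"""

from __future__ import annotations

import enum
import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "EndCall",
    "SingleReadRecord",
    "ReadSet",
    "SlacDataError",
    "TableFormatError",
    "load_reference",
    "infer_end_call",
    "read_single_read_table",
    "write_single_read_table",
    "read_alignments",
]


class SlacDataError(ValueError):
    """Invalid input data (bad reference, malformed table, contig mismatch)."""


class TableFormatError(SlacDataError):
    """Malformed row in a single-read table; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EndCall(str, enum.Enum):
    """Classification of a read's 3' terminus relative to the reference 3' end.

    CCA / CC are only assigned when the read reaches the reference 3' region
    with matching terminal bases; a mismatch or deletion inside the terminal
    CCA/CC itself yields OTHER (the charging state cannot be trusted), and a
    read ending before the 3' region is UNREACHED.
    """

    CCA = "CCA"
    CC = "CC"
    OTHER = "OTHER"
    UNREACHED = "UNREACHED"


@dataclass(slots=True)
class SingleReadRecord:
    """One sequenced tRNA molecule.

    ``mismatch_positions`` holds the 1-based transcript positions where the
    read base differs from the reference.  Insertions are ignored; positions
    deleted in the read are listed in ``deletions`` and count as *not covered*
    rather than mismatched.
    """

    read_id: str
    transcript_id: str
    align_start: int
    align_end: int
    mismatch_positions: frozenset[int]
    end_call: EndCall
    deletions: frozenset[int] = frozenset()

    def covers(self, position: int) -> bool:
        return (
            self.align_start <= position <= self.align_end
            and position not in self.deletions
        )

    def validate(self) -> None:
        if self.align_start > self.align_end:
            raise SlacDataError(
                f"read {self.read_id}: align_start {self.align_start} > "
                f"align_end {self.align_end}"
            )
        for p in self.mismatch_positions:
            if not self.align_start <= p <= self.align_end:
                raise SlacDataError(
                    f"read {self.read_id}: mismatch position {p} outside "
                    f"aligned span [{self.align_start}, {self.align_end}]"
                )


@dataclass
class ReadSet:
    """A sample's worth of single-read records plus the tRNA reference."""

    sample_id: str
    records: list[SingleReadRecord]
    reference: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SingleReadRecord]:
        return iter(self.records)

    def transcripts(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.transcript_id, None)
        return list(seen)

    def records_for(self, transcript_id: str) -> list[SingleReadRecord]:
        return [r for r in self.records if r.transcript_id == transcript_id]

    def validate(self) -> None:
        for r in self.records:
            r.validate()
            if self.reference:
                if r.transcript_id not in self.reference:
                    raise SlacDataError(
                        f"read {r.read_id}: transcript {r.transcript_id!r} "
                        "absent from reference"
                    )
                ref_len = len(self.reference[r.transcript_id])
                if r.align_end > ref_len:
                    raise SlacDataError(
                        f"read {r.read_id}: align_end {r.align_end} exceeds "
                        f"reference length {ref_len}"
                    )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def load_reference(fasta_path: str | Path) -> dict[str, str]:
    """Load mature tRNA sequences (DNA alphabet) from FASTA.

    Every transcript must end in the post-transcriptionally added 3' CCA;
    sequences lacking it are rejected because charging calls and the
    coordinate frame depend on it.
    """
    from Bio import SeqIO

    reference: dict[str, str] = {}
    with _open_text(fasta_path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq.endswith("CCA"):
                raise SlacDataError(
                    f"reference transcript {rec.id!r} does not end in CCA; "
                    "mature tRNA references must include the 3' CCA"
                )
            reference[rec.id] = seq
    if not reference:
        raise SlacDataError(f"no sequences found in {fasta_path}")
    return reference


def infer_end_call(
    align_end: int,
    mismatch_positions: Iterable[int],
    deletions: Iterable[int],
    ref_len: int,
) -> EndCall:
    """Classify a read 3' terminus against a reference of length ``ref_len``.

    CCA requires the read to end exactly at the reference 3' A with the
    terminal CCA intact; CC requires ending one base short with the terminal
    CC intact.  Any mismatch/deletion within those terminal bases disqualifies
    the call (OTHER); reads ending before position ``ref_len - 1`` are
    UNREACHED.
    """
    if align_end < ref_len - 1:
        return EndCall.UNREACHED
    if align_end == ref_len:
        tail = {ref_len - 2, ref_len - 1, ref_len}
        ok = EndCall.CCA
    elif align_end == ref_len - 1:
        tail = {ref_len - 2, ref_len - 1}
        ok = EndCall.CC
    else:  # pragma: no cover - guarded by ReadSet.validate
        raise SlacDataError(f"align_end {align_end} beyond reference length {ref_len}")
    disrupted = tail & (set(mismatch_positions) | set(deletions))
    return EndCall.OTHER if disrupted else ok


_TABLE_COLUMNS = ("read_id", "transcript", "start", "end", "mismatches", "end_call")
_TABLE_COLUMNS_FULL = _TABLE_COLUMNS + ("deletions",)


def _parse_positions(token: str, line_number: int, what: str) -> frozenset[int]:
    token = token.strip()
    if not token:
        return frozenset()
    out = []
    for part in token.split(","):
        try:
            out.append(int(part))
        except ValueError:
            raise TableFormatError(
                f"non-integer {what} position {part!r}", line_number
            ) from None
    return frozenset(out)


def read_single_read_table(
    path: str | Path,
    reference: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> ReadSet:
    """Parse a tab-delimited single-read table into a :class:`ReadSet`.

    Expected header columns: read_id, transcript, start, end, mismatches
    (comma-joined 1-based positions, empty allowed), end_call, and optionally
    deletions.  Lines starting with '#' are comments.  Malformed rows raise
    :class:`TableFormatError` with the offending line number.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".tsv")
    records: list[SingleReadRecord] = []
    with _open_text(path) as handle:
        header: list[str] | None = None
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if tuple(header[: len(_TABLE_COLUMNS)]) != _TABLE_COLUMNS:
                    raise TableFormatError(
                        f"unexpected header {header!r}; expected columns "
                        f"{list(_TABLE_COLUMNS)} (+ optional 'deletions')",
                        line_number,
                    )
                continue
            if len(fields) < len(_TABLE_COLUMNS):
                raise TableFormatError(
                    f"expected at least {len(_TABLE_COLUMNS)} fields, got "
                    f"{len(fields)}",
                    line_number,
                )
            read_id, transcript, start_s, end_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TableFormatError(
                    f"non-integer alignment span ({start_s!r}, {end_s!r})",
                    line_number,
                ) from None
            if end < start:
                raise TableFormatError(
                    f"align_end {end} < align_start {start}", line_number
                )
            mismatches = _parse_positions(fields[4], line_number, "mismatch")
            try:
                end_call = EndCall(fields[5].strip())
            except ValueError:
                raise TableFormatError(
                    f"unknown end_call token {fields[5]!r}", line_number
                ) from None
            deletions = (
                _parse_positions(fields[6], line_number, "deletion")
                if len(fields) > 6
                else frozenset()
            )
            rec = SingleReadRecord(
                read_id=read_id,
                transcript_id=transcript,
                align_start=start,
                align_end=end,
                mismatch_positions=mismatches,
                end_call=end_call,
                deletions=deletions,
            )
            for p in mismatches:
                if not start <= p <= end:
                    raise TableFormatError(
                        f"mismatch position {p} outside span [{start}, {end}]",
                        line_number,
                    )
            records.append(rec)
    readset = ReadSet(sample_id=sample_id, records=records, reference=dict(reference or {}))
    if reference:
        readset.validate()
    return readset


def write_single_read_table(readset: ReadSet, path: str | Path) -> None:
    """Write the canonical single-read table (round-trip safe).

    Mismatch/deletion positions are emitted sorted ascending so that
    parse -> write is byte-identical on canonically formatted input.
    """
    with _open_text(path, "wt") as out:
        out.write("\t".join(_TABLE_COLUMNS_FULL) + "\n")
        for r in readset.records:
            out.write(
                "\t".join(
                    (
                        r.read_id,
                        r.transcript_id,
                        str(r.align_start),
                        str(r.align_end),
                        ",".join(str(p) for p in sorted(r.mismatch_positions)),
                        r.end_call.value,
                        ",".join(str(p) for p in sorted(r.deletions)),
                    )
                )
                + "\n"
            )


def read_alignments(
    alignment_path: str | Path,
    reference_fasta: str | Path,
    sample_id: str | None = None,
) -> ReadSet:
    """Build a :class:`ReadSet` from a SAM/BAM of reads aligned to mature tRNAs.

    Only primary alignments are used (the upstream pipeline resolves
    multi-mapping); unmapped, secondary and supplementary records are skipped
    and counted in the log.  Mismatches come from a reference-aware walk of
    the aligned pairs, so an MD tag is not required.  Deletions are recorded
    separately; inserted bases are ignored.  Ambiguous read bases (N) are not
    counted as mismatches.
    """
    import pysam

    alignment_path = Path(alignment_path)
    reference = load_reference(reference_fasta)
    if sample_id is None:
        sample_id = alignment_path.stem
    mode = "rb" if alignment_path.suffix == ".bam" else "r"
    records: list[SingleReadRecord] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_skipped += 1
                continue
            contig = aln.reference_name
            if contig not in reference:
                raise SlacDataError(
                    f"alignment contig {contig!r} not present in reference FASTA"
                )
            ref_seq = reference[contig]
            qseq = aln.query_sequence or ""
            mismatches: list[int] = []
            deletions: list[int] = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=False):
                if rpos is None:
                    continue  # insertion in read
                pos1 = rpos + 1
                if qpos is None:
                    deletions.append(pos1)
                    continue
                base = qseq[qpos].upper()
                if base != "N" and base != ref_seq[rpos]:
                    mismatches.append(pos1)
            align_start = aln.reference_start + 1
            align_end = aln.reference_end  # 0-based exclusive == 1-based inclusive
            if align_end > len(ref_seq):
                raise SlacDataError(
                    f"read {aln.query_name}: alignment end {align_end} exceeds "
                    f"reference length {len(ref_seq)} for {contig!r}"
                )
            records.append(
                SingleReadRecord(
                    read_id=aln.query_name,
                    transcript_id=contig,
                    align_start=align_start,
                    align_end=align_end,
                    mismatch_positions=frozenset(mismatches),
                    end_call=infer_end_call(
                        align_end, mismatches, deletions, len(ref_seq)
                    ),
                    deletions=frozenset(deletions),
                )
            )
    if n_skipped:
        log.info(
            "skipped %d unmapped/secondary/supplementary alignments in %s",
            n_skipped,
            alignment_path,
        )
    return ReadSet(sample_id=sample_id, records=records, reference=reference)
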