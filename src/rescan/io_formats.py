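"""Text-format readers and writers used throughout the pipeline.

Covers FASTA, FASTQ in both common Phred encodings (offset 33 "Sanger" and
offset 64 "Illumina 1.3-1.7"), the samtools multi-sample text mpileup dialect,
and simple tabular outputs (BED fragment intervals, TSV reports).

Conventions
-----------
* Sequences are normalized to uppercase over the alphabet ``{A, C, G, T, N}``.
* Pileup files and all user-facing reports are 1-based (matching the mpileup
  standard); everything internal is 0-based half-open.  The conversion happens
  exactly once, at this boundary.
* ``N`` basecalls are dropped when a pileup is parsed: the caller's basecall
  set is ``A/C/G/T/*`` plus attached indels, and an ``N`` carries no allele
  information.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SeqRecord",
    "ReadRecord",
    "Basecall",
    "PileupColumn",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_pileup",
    "write_pileup",
    "write_bed",
    "write_tsv",
]

SEQ_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over ``{A, C, G, T, N}``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities.

    ``quals`` is stored as :class:`bytes` (one Phred score per base, already on
    the Sanger scale regardless of the file encoding it came from); indexing
    yields plain integers.  ``library`` is filled in by demultiplexing and is
    ``None`` for unassigned reads.
    """

    id: str
    seq: str
    quals: bytes
    library: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.quals, (list, tuple)):
            self.quals = bytes(self.quals)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.seq)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 93):
            raise ValueError(f"read {self.id!r}: Phred score out of range")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Basecall:
    """One basecall in a pileup column.

    ``base`` is one of ``A/C/G/T/*`` ('*' marks a deleted base).  An indel
    string such as ``+AT`` or ``-G`` is attached to the basecall that precedes
    it in the pileup, mirroring the mpileup dialect.  ``map_qual`` is ``None``
    when the file carries no mapping-quality column; such calls are treated as
    passing any mapping-quality gate (filtering assumed pre-applied upstream).
    """

    base: str
    qual: int
    map_qual: Optional[int] = None
    indel: Optional[str] = None


@dataclass
class PileupColumn:
    """Per-position, per-library basecalls (1-based position)."""

    contig: str
    pos: int
    ref_base: str
    per_library: List[List[Basecall]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> List[SeqRecord]:
    """Read a FASTA file into an ordered list of normalized records.

    Lowercase input is accepted and uppercased.  Malformed headers or empty
    sequences raise :class:`FormatError` naming the offending line.
    """
    records: List[SeqRecord] = []
    name: Optional[str] = None
    name_line = 0
    chunks: List[str] = []

    def _flush(line_no: int) -> None:
        nonlocal name, chunks
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(
                f"{path}: record {name!r} starting at line {name_line} has an "
                "empty sequence"
            )
        try:
            records.append(SeqRecord(name, seq))
        except ValueError as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
        name, chunks = None, []

    with open(path) as handle:
        line_no = 0
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].split()
                if not header:
                    raise FormatError(f"{path}: line {line_no}: empty FASTA header")
                name = header[0]
                name_line = line_no
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: line {line_no}: sequence data before any header"
                    )
                chunks.append(line)
        _flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

_FASTQ_FORMAT = {33: "fastq-sanger", 64: "fastq-illumina"}


def read_fastq(path: Union[str, Path], encoding_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream a 4-line-record FASTQ file as :class:`ReadRecord` objects.

    Qualities are decoded as ``ord(char) - encoding_offset``; offset-64 input
    yields the same integer scores as the equivalent offset-33 file.
    """
    if encoding_offset not in _FASTQ_FORMAT:
        raise ValueError(f"encoding_offset must be 33 or 64, got {encoding_offset}")
    try:
        for rec in SeqIO.parse(str(path), _FASTQ_FORMAT[encoding_offset]):
            yield ReadRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                quals=bytes(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython signals malformed records this way
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: Union[str, Path]) -> None:
    """Write reads as Sanger-scale (Phred+33) FASTQ."""
    with open(path, "w") as handle:
        for read in reads:
            qual_str = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual_str}\n")


# ---------------------------------------------------------------------------
# samtools text mpileup (multi-sample)
# ---------------------------------------------------------------------------

def _parse_bases(bases: str, ref_base: str, where: str) -> List[dict]:
    """Expand an mpileup base string into a list of raw call dicts."""
    calls: List[dict] = []
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":  # read-start marker: next char is the encoded map qual
            if i + 1 >= n:
                raise FormatError(f"{where}: dangling '^' marker")
            i += 2
        elif c == "$":  # read-end marker
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"{where}: indel marker without length")
            length = int(bases[i + 1 : j])
            if j + length > n:
                raise FormatError(f"{where}: truncated indel sequence")
            if not calls:
                raise FormatError(f"{where}: indel with no preceding basecall")
            calls[-1]["indel"] = c + bases[j : j + length].upper()
            i = j + length
        elif c in ".,":
            calls.append({"base": ref_base})
            i += 1
        elif c.upper() in "ACGTN*":
            calls.append({"base": c.upper()})
            i += 1
        else:
            raise FormatError(f"{where}: unexpected pileup character {c!r}")
    return calls


def read_pileup(
    path: Union[str, Path], n_libraries: int
) -> Iterator[PileupColumn]:
    """Stream a multi-sample text pileup.

    Each line must carry ``contig pos ref`` followed by one triplet per library
    (coverage, base string, base-quality string) and optionally a fourth
    mapping-quality column per library.  Read start (``^`` + map-qual char) and
    end (``$``) markers are consumed; ``.``/``,`` expand to the reference base;
    indel strings attach to the preceding basecall; ``N`` calls are dropped
    after the coverage check.
    """
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            where = f"{path}: line {line_no}"
            per_lib = len(fields) - 3
            if per_lib == 3 * n_libraries:
                has_mapq = False
            elif per_lib == 4 * n_libraries:
                has_mapq = True
            else:
                raise FormatError(
                    f"{where}: expected {3 * n_libraries} or {4 * n_libraries} "
                    f"sample fields for {n_libraries} libraries, found {per_lib}"
                )
            contig, pos_str, ref_base = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_str)
            except ValueError as exc:
                raise FormatError(f"{where}: non-integer position {pos_str!r}") from exc
            if pos < 1:
                raise FormatError(f"{where}: position must be >= 1")

            step = 4 if has_mapq else 3
            per_library: List[List[Basecall]] = []
            for lib in range(n_libraries):
                base_idx = 3 + lib * step
                try:
                    coverage = int(fields[base_idx])
                except ValueError as exc:
                    raise FormatError(
                        f"{where}: non-integer coverage for library {lib}"
                    ) from exc
                bases = fields[base_idx + 1] if coverage else ""
                quals = fields[base_idx + 2] if coverage else ""
                mapqs = fields[base_idx + 3] if (has_mapq and coverage) else ""
                raw_calls = _parse_bases(bases, ref_base, where)
                if len(raw_calls) != coverage:
                    raise FormatError(
                        f"{where}: library {lib} declares coverage {coverage} "
                        f"but {len(raw_calls)} basecalls were parsed"
                    )
                if len(quals) != coverage:
                    raise FormatError(
                        f"{where}: library {lib} has {len(quals)} quality "
                        f"characters for coverage {coverage}"
                    )
                if has_mapq and len(mapqs) != coverage:
                    raise FormatError(
                        f"{where}: library {lib} has {len(mapqs)} map-qual "
                        f"characters for coverage {coverage}"
                    )
                calls = []
                for k, rc in enumerate(raw_calls):
                    if rc["base"] == "N":
                        continue
                    calls.append(
                        Basecall(
                            base=rc["base"],
                            qual=ord(quals[k]) - 33,
                            map_qual=(ord(mapqs[k]) - 33) if has_mapq else None,
                            indel=rc.get("indel"),
                        )
                    )
                per_library.append(calls)
            yield PileupColumn(contig, pos, ref_base, per_library)


def write_pileup(
    columns: Iterable[PileupColumn],
    path: Union[str, Path],
    with_mapq: bool = False,
) -> None:
    """Write columns in the multi-sample text pileup dialect."""
    with open(path, "w") as handle:
        for col in columns:
            fields = [col.contig, str(col.pos), col.ref_base]
            for calls in col.per_library:
                bases = []
                quals = []
                mapqs = []
                for call in calls:
                    bases.append("." if call.base == col.ref_base else call.base)
                    if call.indel:
                        bases.append(
                            f"{call.indel[0]}{len(call.indel) - 1}{call.indel[1:]}"
                        )
                    quals.append(chr(call.qual + 33))
                    mapqs.append(chr((call.map_qual or 0) + 33))
                fields.append(str(len(calls)))
                fields.append("".join(bases) or "*")
                fields.append("".join(quals) or "*")
                if with_mapq:
                    fields.append("".join(mapqs) or "*")
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: Union[str, Path]) -> None:
    """Write (contig, start, end[, name...]) tuples as BED (0-based half-open)."""
    with open(path, "w") as handle:
        for row in intervals:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(
    rows: Iterable[Sequence],
    path: Union[str, Path],
    header: Optional[Sequence[str]] = None,
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        if header:
            writer.writerow(header)
        writer.writerows(rows)
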