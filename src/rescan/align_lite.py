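"""Desk-scale read placement with at most one mismatch.

The production path for large genomes is an external aligner plus pileup
ingestion through :mod:`rescan.io_formats`; this module covers the k-mer
pseudo-reference and small (test-scale) genomes.  Reads are placed by their
first ``prefix_len`` bases (default 65) on both strands with a guaranteed-
complete pigeonhole search: the query prefix is split into two halves, and
any placement with <= 1 mismatch must match one half exactly, so exact-match
lookups over target substrings of the two half lengths enumerate every
candidate.  Only unique best placements are emitted; ties across targets,
offsets or strands are reported as ``multi`` and dropped before pileup.

Unique placements carry a constant mapping quality of 37 so that the
downstream map-qual >= 20 gate behaves as it would on a BWA alignment
filtered at the same threshold; ambiguous placements never reach the pileup.
The aligner is substitution-only: a <= 1-mismatch model has no gaps, so
indel pileup symbols can only arrive via externally ingested pileups.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from .io_formats import Basecall, PileupColumn, ReadRecord, SeqRecord, revcomp

__all__ = [
    "Placement",
    "PrefixIndex",
    "build_index",
    "align_read",
    "build_pileup",
    "scan_place",
    "DEFAULT_MAP_QUAL",
]

DEFAULT_MAP_QUAL = 37


@dataclass(frozen=True)
class Placement:
    """A unique read placement on a target sequence."""

    read_id: str
    target: str
    offset: int  # 0-based start of the aligned prefix on the target
    strand: str  # '+' or '-'
    mismatches: int
    length: int  # number of aligned bases (the read prefix length)
    unique: bool = True


class PrefixIndex:
    """Exact-match half-seed index over a set of target sequences."""

    def __init__(self, targets: Sequence[SeqRecord], prefix_len: int = 65):
        if not targets:
            raise ValueError("cannot index an empty target list")
        ids = [t.id for t in targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids")
        short = [t.id for t in targets if len(t.seq) < prefix_len]
        if short:
            raise ValueError(
                f"targets shorter than the {prefix_len}-base seed span: {short[:3]}"
            )
        self.prefix_len = prefix_len
        self.left_len = (prefix_len + 1) // 2
        self.right_len = prefix_len - self.left_len
        self.targets: Dict[str, str] = {t.id: t.seq for t in targets}
        self._left: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        self._right: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for t in targets:
            seq = t.seq
            for off in range(len(seq) - self.left_len + 1):
                self._left[seq[off : off + self.left_len]].append((t.id, off))
            for off in range(len(seq) - self.right_len + 1):
                self._right[seq[off : off + self.right_len]].append((t.id, off))
        self._left.default_factory = None
        self._right.default_factory = None

    def candidates(self, query: str) -> Iterator[Tuple[str, int]]:
        """Candidate (target, offset) placements for one oriented query."""
        P, L = self.prefix_len, self.left_len
        for tid, off in self._left.get(query[:L], ()):
            yield tid, off
        for tid, off in self._right.get(query[L:P], ()):
            yield tid, off - L


def build_index(targets: Sequence[SeqRecord], prefix_len: int = 65) -> PrefixIndex:
    """Build the pigeonhole index guaranteeing <= 1-mismatch completeness."""
    return PrefixIndex(targets, prefix_len)


def _mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def align_read(
    read: ReadRecord,
    index: PrefixIndex,
    prefix_len: Optional[int] = None,
    max_mm: int = 1,
) -> Tuple[Optional[Placement], Optional[str]]:
    """Place a read's leading prefix on both strands, unique best hit only.

    Returns ``(placement, None)`` or ``(None, reason)`` with reason in
    ``{"too_short", "no_hit", "multi"}``.  Completeness: every placement with
    at most one mismatch is found (pigeonhole over the two query halves);
    ``max_mm`` above 1 is not supported by this search.
    """
    P = index.prefix_len if prefix_len is None else prefix_len
    if P != index.prefix_len:
        raise ValueError("prefix_len must match the index seed span")
    if max_mm not in (0, 1):
        raise ValueError("only max_mm of 0 or 1 is supported")
    if len(read.seq) < P:
        return None, "too_short"
    fwd = read.seq[:P]
    rev = revcomp(fwd)
    hits: Dict[Tuple[str, int, str], int] = {}
    for query, strand in ((fwd, "+"), (rev, "-")):
        for tid, off in index.candidates(query):
            if off < 0:
                continue
            key = (tid, off, strand)
            if key in hits:
                continue
            tseq = index.targets[tid]
            if off + P > len(tseq):
                continue
            mm = _mismatches(query, tseq[off : off + P], max_mm)
            if mm <= max_mm:
                hits[key] = mm
    if not hits:
        return None, "no_hit"
    best = min(hits.values())
    best_keys = [k for k, mm in hits.items() if mm == best]
    if len(best_keys) > 1:
        return None, "multi"
    tid, off, strand = best_keys[0]
    return (
        Placement(
            read_id=read.id,
            target=tid,
            offset=off,
            strand=strand,
            mismatches=best,
            length=P,
        ),
        None,
    )


def build_pileup(
    placements_per_library: Mapping[str, Sequence[Tuple[Placement, ReadRecord]]],
    targets: Mapping[str, str],
    map_qual: int = DEFAULT_MAP_QUAL,
) -> Iterator[PileupColumn]:
    """Stream multi-library pileup columns from unique placements.

    Columns are emitted target by target (in ``targets`` order) for every
    position covered in at least one library; positions are 1-based in the
    emitted columns.  Reverse-strand reads contribute complemented bases at
    the correct target coordinates with their original per-base qualities.
    """
    libraries = list(placements_per_library)
    by_target: Dict[str, List[Tuple[int, Placement, ReadRecord]]] = defaultdict(list)
    for lib_idx, lib in enumerate(libraries):
        for placement, read in placements_per_library[lib]:
            by_target[placement.target].append((lib_idx, placement, read))

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for tid, tseq in targets.items():
        stack = by_target.get(tid)
        if not stack:
            continue
        tlen = len(tseq)
        columns: List[Optional[List[List[Basecall]]]] = [None] * tlen
        for lib_idx, pl, read in stack:
            P = pl.length
            if pl.offset < 0 or pl.offset + P > tlen:
                raise RuntimeError(
                    f"placement of {pl.read_id} runs off target {tid}"
                )
            seq = read.seq
            quals = read.quals
            if pl.strand == "+":
                for i in range(P):
                    pos = pl.offset + i
                    col = columns[pos]
                    if col is None:
                        col = columns[pos] = [[] for _ in libraries]
                    col[lib_idx].append(
                        Basecall(base=seq[i], qual=quals[i], map_qual=map_qual)
                    )
            else:
                for j in range(P):
                    pos = pl.offset + j
                    col = columns[pos]
                    if col is None:
                        col = columns[pos] = [[] for _ in libraries]
                    i = P - 1 - j
                    col[lib_idx].append(
                        Basecall(base=comp[seq[i]], qual=quals[i], map_qual=map_qual)
                    )
        for pos in range(tlen):
            col = columns[pos]
            if col is not None:
                yield PileupColumn(
                    contig=tid, pos=pos + 1, ref_base=tseq[pos], per_library=col
                )


def scan_place(
    query: str,
    targets: Iterable[SeqRecord],
    max_mm: int = 1,
) -> Tuple[Optional[Placement], Optional[str]]:
    """Place one sequence on arbitrary-size targets without a prebuilt index.

    Same guarantees and tie rules as :func:`align_read` (pigeonhole halves
    located with string search per contig); intended for occasional queries
    such as mapping candidate-bearing k-mers back onto a genome.
    """
    if max_mm not in (0, 1):
        raise ValueError("only max_mm of 0 or 1 is supported")
    P = len(query)
    L = (P + 1) // 2
    rev = revcomp(query)
    hits: Dict[Tuple[str, int, str], int] = {}
    for rec in targets:
        seq = rec.seq
        for oriented, strand in ((query, "+"), (rev, "-")):
            for half, shift in ((oriented[:L], 0), (oriented[L:], L)):
                start = seq.find(half)
                while start != -1:
                    off = start - shift
                    if 0 <= off and off + P <= len(seq):
                        key = (rec.id, off, strand)
                        if key not in hits:
                            mm = _mismatches(oriented, seq[off : off + P], max_mm)
                            if mm <= max_mm:
                                hits[key] = mm
                    start = seq.find(half, start + 1)
    if not hits:
        return None, "no_hit"
    best = min(hits.values())
    best_keys = [k for k, mm in hits.items() if mm == best]
    if len(best_keys) > 1:
        return None, "multi"
    tid, off, strand = best_keys[0]
    return (
        Placement(
            read_id="", target=tid, offset=off, strand=strand,
            mismatches=best, length=P,
        ),
        None,
    )
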