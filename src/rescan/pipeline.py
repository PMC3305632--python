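"""End-to-end orchestration of the mutation-discovery workflow.

Two paths share the downstream caller:

* **de novo** (:func:`run_denovo`) - build a k-mer pseudo-reference from the
  control library's read starts, align every library's reads back to it and
  call mutations on the resulting multi-library pileup; no genome required.
* **referenced** (:func:`run_referenced`) - align reads directly to a genome
  (desk-scale contigs; production data would arrive as an externally
  produced pileup via :func:`rescan.io_formats.read_pileup`) and call on
  that pileup.  This path also supports read-start typing
  (:func:`run_type1`).

Both consume per-library read lists as produced by
:func:`prepare_libraries`, which runs demultiplexing and read filtering over
a pooled lane.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .align_lite import PrefixIndex, align_read, build_index, build_pileup
from .demux import BarcodeSpec, FilterConfig, UNASSIGNED, demultiplex, trim_and_filter
from .insilico_digest import Enzyme
from .io_formats import ReadRecord, SeqRecord
from .kmer_reference import (
    KmerSet,
    count_across_samples,
    extract_kmers,
    hamming1_prune,
    repeat_filter,
)
from .mutation_caller import CallResult, CallerConfig, call_pileup
from .type1_typing import (
    ReferenceFrames,
    StartClassification,
    Type1Call,
    call_type1,
    classify_start,
    summarize_type1,
)

__all__ = [
    "prepare_libraries",
    "DenovoResult",
    "ReferencedResult",
    "Type1Result",
    "run_denovo",
    "run_referenced",
    "run_type1",
]


def prepare_libraries(
    pooled_reads: Sequence[ReadRecord],
    barcode_table: Sequence[BarcodeSpec],
    filter_cfg: Optional[FilterConfig] = None,
) -> Tuple[Dict[str, List[ReadRecord]], Counter]:
    """Demultiplex a pooled lane and apply read filters per library.

    Returns the per-library read lists (unassigned reads excluded) and a
    tally of demux/filter outcomes (``assigned``, ``unassigned``,
    ``too_short``, ``low_quality``).
    """
    if filter_cfg is None:
        filter_cfg = FilterConfig()
    bins = demultiplex(pooled_reads, barcode_table)
    tally: Counter = Counter()
    tally["unassigned"] = len(bins.pop(UNASSIGNED, []))
    out: Dict[str, List[ReadRecord]] = {}
    for lib, reads in bins.items():
        kept: List[ReadRecord] = []
        for read in reads:
            filtered, reason = trim_and_filter(read, filter_cfg)
            if filtered is None:
                tally[reason] += 1
            else:
                kept.append(filtered)
        tally["assigned"] += len(kept)
        out[lib] = kept
    return out, tally


def _align_libraries(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    index: PrefixIndex,
) -> Tuple[Dict[str, List[Tuple]], Dict[str, Counter]]:
    placements: Dict[str, List[Tuple]] = {}
    tallies: Dict[str, Counter] = {}
    for lib, reads in reads_by_library.items():
        placed = []
        tally: Counter = Counter()
        for read in reads:
            placement, reason = align_read(read, index)
            if placement is None:
                tally[reason] += 1
            else:
                tally["placed"] += 1
                placed.append((placement, read))
        placements[lib] = placed
        tallies[lib] = tally
    return placements, tallies


@dataclass
class DenovoResult:
    libraries: List[str]
    kmer_set: KmerSet
    kmer_seqs: Dict[str, str]  # target id -> k-mer sequence (survivors)
    align_tallies: Dict[str, Counter]
    call: CallResult

    @property
    def complexity(self) -> int:
        """Total bases of surviving pseudo-reference sequence."""
        return len(self.kmer_seqs) * self.kmer_set.k


def run_denovo(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    control: str,
    k: int = 70,
    prefix_len: int = 65,
    caller_cfg: Optional[CallerConfig] = None,
    collect_coverage: bool = False,
) -> DenovoResult:
    """Reference-free discovery: pseudo-reference, alignment and calling.

    ``reads_by_library`` must contain the control; library order is
    preserved throughout (pileup columns, caller accounting).
    """
    if control not in reads_by_library:
        raise ValueError(f"control library {control!r} not in input")
    if prefix_len > k:
        raise ValueError("prefix_len cannot exceed k")
    libraries = list(reads_by_library)
    kset = extract_kmers(reads_by_library[control], k=k)
    if not kset.entries:
        raise ValueError("control library yielded no k-mers")
    count_across_samples(kset, reads_by_library)
    repeat_filter(kset)
    hamming1_prune(kset)
    targets = [
        SeqRecord(f"kmer_{i:06d}", km)
        for i, km in enumerate(sorted(kset.surviving()), start=1)
    ]
    if not targets:
        raise ValueError("no k-mer survived curation")
    kmer_seqs = {t.id: t.seq for t in targets}
    index = build_index(targets, prefix_len=prefix_len)
    placements, tallies = _align_libraries(reads_by_library, index)
    cfg = caller_cfg or CallerConfig(
        n_libraries=len(libraries), control_index=libraries.index(control)
    )
    columns = build_pileup(placements, kmer_seqs)
    call = call_pileup(
        columns,
        cfg,
        libraries,
        collect_coverage=collect_coverage,
        target_lengths={tid: len(seq) for tid, seq in kmer_seqs.items()},
    )
    return DenovoResult(
        libraries=libraries,
        kmer_set=kset,
        kmer_seqs=kmer_seqs,
        align_tallies=tallies,
        call=call,
    )


@dataclass
class ReferencedResult:
    libraries: List[str]
    align_tallies: Dict[str, Counter]
    call: CallResult
    placements: Optional[Dict[str, List[Tuple]]] = None


def run_referenced(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    genome: Sequence[SeqRecord],
    control: str,
    prefix_len: int = 65,
    caller_cfg: Optional[CallerConfig] = None,
    collect_coverage: bool = False,
    keep_placements: bool = False,
) -> ReferencedResult:
    """Genome-referenced discovery on desk-scale contigs."""
    if control not in reads_by_library:
        raise ValueError(f"control library {control!r} not in input")
    libraries = list(reads_by_library)
    index = build_index(list(genome), prefix_len=prefix_len)
    placements, tallies = _align_libraries(reads_by_library, index)
    cfg = caller_cfg or CallerConfig(
        n_libraries=len(libraries), control_index=libraries.index(control)
    )
    targets = {rec.id: rec.seq for rec in genome}
    call = call_pileup(
        build_pileup(placements, targets),
        cfg,
        libraries,
        collect_coverage=collect_coverage,
        target_lengths={tid: len(seq) for tid, seq in targets.items()},
    )
    return ReferencedResult(
        libraries=libraries,
        align_tallies=tallies,
        call=call,
        placements=placements if keep_placements else None,
    )


@dataclass
class Type1Result:
    classifications: List[StartClassification]
    summary: Dict[str, float]
    calls: List[Type1Call]


def run_type1(
    reads: Sequence[ReadRecord],
    genome: Sequence[SeqRecord],
    enzyme: Enzyme,
    prefix_len: int = 65,
    min_reads: int = 1,
    index: Optional[PrefixIndex] = None,
) -> Type1Result:
    """Read-start typing of one library against a genome."""
    if index is None:
        index = build_index(list(genome), prefix_len=prefix_len)
    frames = ReferenceFrames(genome)
    classifications: List[StartClassification] = []
    for read in reads:
        placement, _ = align_read(read, index)
        if placement is None:
            continue
        classifications.append(classify_start(placement, read, frames, enzyme))
    return Type1Result(
        classifications=classifications,
        summary=summarize_type1(classifications),
        calls=call_type1(classifications, enzyme, min_reads=min_reads),
    )
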