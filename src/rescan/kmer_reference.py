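"""Reference-free pseudo-reference built from control-library read starts.

Because every read of a restriction-phased library begins at a cut site, the
leading k bases of the control individual's reads enumerate a reduced,
position-anchored representation of the genome without requiring an assembly.
The set is curated in two passes before use as an alignment reference:

1. **Repeat filtering** - k-mers with higher-than-expected pooled coverage
   are flagged as likely multi-copy sequence.  "Expected" is modeled as
   Poisson: entries whose pooled count exceeds the upper 1 - 1e-4 quantile of
   ``Poisson(lambda)`` are flagged, where ``lambda`` is estimated robustly
   from the count histogram (single-occurrence sequencing-error k-mers form a
   spike at 1; the estimate averages counts above the first valley of the
   histogram so the error spike cannot drag it down).  A fixed cutoff can be
   supplied instead.
2. **Hamming-1 pruning** - for every pair of surviving k-mers at Hamming
   distance exactly 1 (sequencing errors and allelic near-duplicates), the
   minority member is flagged.  Pair discovery is near-linear via pigeonhole
   half-split indexing: two k-mers at distance 1 share at least one exact
   half, so grouping on each half finds every pair without all-pairs
   comparison.

Flags are advisory until :func:`export_reference`, which writes only
unflagged entries.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from math import ceil
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from scipy.stats import poisson

from .io_formats import ReadRecord, SeqRecord, write_fasta

__all__ = [
    "KmerEntry",
    "KmerSet",
    "extract_kmers",
    "count_across_samples",
    "repeat_filter",
    "hamming1_prune",
    "export_reference",
]


@dataclass
class KmerEntry:
    count_control: int = 0
    counts_per_sample: Optional[List[int]] = None
    flags: set = field(default_factory=set)

    def pooled(self) -> int:
        """Total evidence for this k-mer across every counted library."""
        if self.counts_per_sample is not None:
            return sum(self.counts_per_sample)
        return self.count_control


@dataclass
class KmerSet:
    """Counted leading k-mers from the control library with curation flags."""

    k: int
    entries: Dict[str, KmerEntry]
    sample_names: Optional[List[str]] = None
    n_short_skipped: int = 0

    def surviving(self) -> List[str]:
        return [km for km, e in self.entries.items() if not e.flags]


def extract_kmers(reads: Iterable[ReadRecord], k: int = 70) -> KmerSet:
    """One leading k-mer per read of length >= k; duplicates accumulate."""
    if k <= 0:
        raise ValueError("k must be positive")
    entries: Dict[str, KmerEntry] = {}
    skipped = 0
    for read in reads:
        if len(read.seq) < k:
            skipped += 1
            continue
        km = read.seq[:k]
        entry = entries.get(km)
        if entry is None:
            entries[km] = KmerEntry(count_control=1)
        else:
            entry.count_control += 1
    return KmerSet(k=k, entries=entries, n_short_skipped=skipped)


def count_across_samples(
    kmer_set: KmerSet, all_libraries: Mapping[str, Iterable[ReadRecord]]
) -> KmerSet:
    """Fill per-sample counts by exact leading-k-mer lookup.

    The set is closed: k-mers present in treated libraries but absent from
    the control-defined set add no entries.  ``all_libraries`` should include
    the control so pooled counts reflect every library once.
    """
    names = list(all_libraries)
    k = kmer_set.k
    counts = {km: [0] * len(names) for km in kmer_set.entries}
    for idx, name in enumerate(names):
        for read in all_libraries[name]:
            if len(read.seq) < k:
                continue
            row = counts.get(read.seq[:k])
            if row is not None:
                row[idx] += 1
    for km, entry in kmer_set.entries.items():
        entry.counts_per_sample = counts[km]
    kmer_set.sample_names = names
    return kmer_set


def _robust_poisson_lambda(counts: List[int]) -> float:
    """Mean coverage of the single-copy component of a k-mer count histogram.

    Sequencing-error k-mers pile up at very low counts; true single-copy
    k-mers cluster around the per-site depth.  The estimate finds the first
    valley of the histogram and averages the counts above it.  If the
    histogram is unimodal (no error spike) the plain mean is returned.
    """
    hist = Counter(counts)
    cmax = max(hist)
    dense = [hist.get(c, 0) for c in range(cmax + 1)]
    valley = None
    for c in range(1, cmax):
        if dense[c] <= dense[c - 1] and dense[c] < dense[c + 1]:
            valley = c
            break
    if valley is None:
        return sum(counts) / len(counts)
    upper = [c for c in counts if c > valley]
    if not upper:
        return sum(counts) / len(counts)
    return sum(upper) / len(upper)


def repeat_filter(
    kmer_set: KmerSet,
    mode: str = "poisson",
    max_cov: Optional[int] = None,
    tail_prob: float = 1e-4,
    per_sample: bool = False,
) -> KmerSet:
    """Flag k-mers whose coverage exceeds the single-copy expectation.

    ``mode="poisson"`` (default) flags entries with pooled count above the
    ``1 - tail_prob`` quantile of a Poisson fit to the single-copy component;
    ``mode="fixed"`` uses the user cutoff ``max_cov``.  With ``per_sample``
    the rule is applied to each library's counts separately (an entry is
    flagged if any library exceeds its own cutoff).
    """
    if not kmer_set.entries:
        raise ValueError("cannot repeat-filter an empty k-mer set")
    if mode not in ("poisson", "fixed"):
        raise ValueError(f"unknown repeat filter mode {mode!r}")
    if mode == "fixed":
        if max_cov is None:
            raise ValueError("fixed mode requires max_cov")
        for entry in kmer_set.entries.values():
            if entry.pooled() > max_cov:
                entry.flags.add("repeat")
        return kmer_set

    if per_sample:
        if kmer_set.sample_names is None:
            raise ValueError("per-sample filtering requires per-sample counts")
        n = len(kmer_set.sample_names)
        for j in range(n):
            col = [e.counts_per_sample[j] for e in kmer_set.entries.values()]
            lam = _robust_poisson_lambda(col)
            cutoff = int(poisson.ppf(1.0 - tail_prob, lam))
            for entry in kmer_set.entries.values():
                if entry.counts_per_sample[j] > cutoff:
                    entry.flags.add("repeat")
        return kmer_set

    pooled = [e.pooled() for e in kmer_set.entries.values()]
    lam = _robust_poisson_lambda(pooled)
    cutoff = int(poisson.ppf(1.0 - tail_prob, lam))
    for entry in kmer_set.entries.values():
        if entry.pooled() > cutoff:
            entry.flags.add("repeat")
    return kmer_set


def _half_split(k: int) -> int:
    # the left half takes the ceiling when k is odd
    return ceil(k / 2)


def hamming1_pairs(kmers: List[str], k: int) -> List[Tuple[str, str]]:
    """All unordered pairs at Hamming distance exactly 1.

    Pigeonhole: two equal-length strings at distance 1 agree exactly on one
    of their halves, so exact-match grouping over the left ``ceil(k/2)``-mers
    and right halves discovers every pair without an all-pairs scan.
    """
    h = _half_split(k)
    pairs = set()
    for half_of in (lambda s: s[:h], lambda s: s[h:]):
        groups: Dict[str, List[str]] = defaultdict(list)
        for km in kmers:
            groups[half_of(km)].append(km)
        for members in groups.values():
            if len(members) < 2:
                continue
            for i in range(len(members)):
                a = members[i]
                for j in range(i + 1, len(members)):
                    b = members[j]
                    d = 0
                    for x, y in zip(a, b):
                        if x != y:
                            d += 1
                            if d > 1:
                                break
                    if d == 1:
                        pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


def hamming1_prune(kmer_set: KmerSet) -> KmerSet:
    """Flag the minority member of every surviving Hamming-1 pair.

    Operates on entries not already flagged as repeats.  Minority is decided
    on pooled counts frozen before any flagging (a single deterministic pass:
    chains A-B-C are not re-evaluated after a member is flagged), with count
    ties broken by keeping the lexicographically smaller k-mer.  The result
    is therefore independent of input order.
    """
    unflagged = [km for km, e in kmer_set.entries.items() if not e.flags]
    counts = {km: kmer_set.entries[km].pooled() for km in unflagged}
    for a, b in hamming1_pairs(unflagged, kmer_set.k):
        if (counts[a], b) < (counts[b], a):
            loser = a
        else:
            loser = b
        kmer_set.entries[loser].flags.add("hamming_minority")
    return kmer_set


def export_reference(kmer_set: KmerSet, path) -> Tuple[int, int]:
    """Write surviving k-mers as FASTA; returns (record count, total bases).

    Record ids encode an ordinal and the control count
    (``kmer_000001|count=12``); the total exported base count is the
    "complexity" of the pseudo-reference.
    """
    survivors = kmer_set.surviving()
    records = [
        SeqRecord(f"kmer_{i:06d}|count={kmer_set.entries[km].count_control}", km)
        for i, km in enumerate(survivors, start=1)
    ]
    write_fasta(records, path)
    return len(records), len(records) * kmer_set.k
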