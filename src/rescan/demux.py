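"""Barcode demultiplexing and read-level quality filtering.

Multiplexed restriction-phased libraries carry an inline barcode at the very
start of read 1, immediately followed by the regenerated restriction-site
overhang and then genomic sequence.  Demultiplexing assigns a read to a
library if and only if its prefix exactly matches one barcode (no mismatch
rescue: barcodes are validated to be unique and prefix-free, so exact
matching keeps assignment unambiguous).  The barcode is always removed; the
overhang is *kept* by default because it is genomic sequence that aligns to
the restriction site.

Filtering is deliberately strict: after 3' adapter trimming a read is
rejected if it is shorter than ``min_len`` or if *any* remaining base is
below ``min_base_qual``.  A windowed 3'-trimming rescue can be enabled via
``FilterConfig.trim_low_qual_tail`` but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .io_formats import ReadRecord

__all__ = [
    "BarcodeSpec",
    "FilterConfig",
    "BarcodeTableError",
    "validate_barcode_table",
    "demultiplex",
    "trim_and_filter",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


class BarcodeTableError(ValueError):
    """The barcode table is internally inconsistent."""


@dataclass(frozen=True)
class BarcodeSpec:
    """One library's inline barcode and expected post-barcode overhang."""

    library: str
    barcode: str
    overhang: str = ""

    def __post_init__(self) -> None:
        if not (1 <= len(self.barcode) <= 8):
            raise ValueError(f"{self.library}: barcode length must be 1-8 bases")
        if set(self.barcode.upper()) - set("ACGT"):
            raise ValueError(f"{self.library}: barcode must be A/C/G/T only")
        object.__setattr__(self, "barcode", self.barcode.upper())
        object.__setattr__(self, "overhang", self.overhang.upper())


@dataclass
class FilterConfig:
    """Read-level filter thresholds.

    ``min_len`` and ``min_base_qual`` default to the strict settings used for
    induced-mutation discovery: reads shorter than 25 bases or containing any
    base below Phred 20 are discarded outright.
    """

    min_len: int = 25
    min_base_qual: int = 20
    adapter_seq: Optional[str] = None
    min_adapter_match: int = 5
    trim_low_qual_tail: bool = False

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0 <= self.min_base_qual <= 60:
            raise ValueError("min_base_qual must be in [0, 60]")


def validate_barcode_table(table: Iterable[BarcodeSpec]) -> List[BarcodeSpec]:
    specs = list(table)
    seen: Dict[str, str] = {}
    for spec in specs:
        if spec.barcode in seen:
            raise BarcodeTableError(
                f"barcode {spec.barcode} assigned to both "
                f"{seen[spec.barcode]!r} and {spec.library!r}"
            )
        seen[spec.barcode] = spec.library
    libraries = [s.library for s in specs]
    if len(set(libraries)) != len(libraries):
        raise BarcodeTableError("library names must be unique")
    # prefix-freeness guarantees a read can match at most one barcode
    codes = sorted(seen)
    for a, b in zip(codes, codes[1:]):
        if b.startswith(a):
            raise BarcodeTableError(f"barcode {a} is a prefix of {b}")
    return specs


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_table: Iterable[BarcodeSpec],
    strip_overhang: bool = False,
) -> Dict[str, List[ReadRecord]]:
    """Split reads by exact barcode prefix match.

    Returns a mapping from library name to its reads plus an
    ``"unassigned"`` bin.  The barcode (and the overhang, when
    ``strip_overhang`` is set) is removed from sequence and qualities
    symmetrically, and each assigned read's ``library`` field is set.
    """
    specs = validate_barcode_table(barcode_table)
    by_barcode = {s.barcode: s for s in specs}
    lengths = sorted({len(b) for b in by_barcode}, reverse=True)
    out: Dict[str, List[ReadRecord]] = {s.library: [] for s in specs}
    out[UNASSIGNED] = []
    for read in reads:
        spec = None
        for L in lengths:
            spec = by_barcode.get(read.seq[:L])
            if spec is not None:
                break
        if spec is None:
            out[UNASSIGNED].append(read)
            continue
        cut = len(spec.barcode)
        if strip_overhang:
            cut += len(spec.overhang)
        out[spec.library].append(
            ReadRecord(
                id=read.id,
                seq=read.seq[cut:],
                quals=read.quals[cut:],
                library=spec.library,
            )
        )
    return out


def _trim_adapter(seq: str, adapter: str, min_match: int) -> int:
    """Return the trim point: length of seq after removing a 3' adapter hit.

    The longest read suffix equal to an adapter prefix of at least
    ``min_match`` bases is removed (read-through into the adapter); a full
    internal adapter occurrence also trims everything from its start.
    """
    full = seq.find(adapter)
    if full != -1:
        return full
    n = len(seq)
    earliest = n
    for i in range(max(0, n - len(adapter)), n - min_match + 1):
        if adapter.startswith(seq[i:]):
            earliest = i
            break
    return earliest


def trim_and_filter(
    read: ReadRecord, cfg: FilterConfig
) -> Tuple[Optional[ReadRecord], Optional[str]]:
    """Apply 3' adapter trimming then the length and quality gates.

    Returns ``(read, None)`` for a kept read (possibly trimmed) or
    ``(None, reason)`` with reason in ``{"too_short", "low_quality"}``.
    """
    seq, quals = read.seq, read.quals
    if cfg.adapter_seq:
        cut = _trim_adapter(seq, cfg.adapter_seq.upper(), cfg.min_adapter_match)
        if cut < len(seq):
            seq, quals = seq[:cut], quals[:cut]
    if cfg.trim_low_qual_tail:
        end = len(quals)
        while end > 0 and quals[end - 1] < cfg.min_base_qual:
            end -= 1
        seq, quals = seq[:end], quals[:end]
    if len(seq) < cfg.min_len:
        return None, "too_short"
    if quals and min(quals) < cfg.min_base_qual:
        return None, "low_quality"
    if seq is read.seq:
        return read, None
    return ReadRecord(read.id, seq, quals, read.library), None
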