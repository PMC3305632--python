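"""In silico restriction digestion and restriction-site arithmetic.

A restriction-phased sequencing library initiates every read at an enzyme cut
site, so fragment structure fully determines which parts of a genome the
library can interrogate.  This module enumerates exact recognition sites,
computes the fragment tiling produced by a complete digest, applies size
selection, and enumerates *proto sites* - windows at Hamming distance 1 from
the recognition site.  A read that starts at a proto site implies either
relaxed-specificity ("star") cutting or a sample polymorphism that completed
the site; that inference lives in :mod:`rescan.type1_typing`.

Only exact, palindromic recognition sequences are supported (the common
4- and 6-cutters used for reduced-representation libraries are all
reverse-complement palindromes, which keeps the cut arithmetic single-strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .io_formats import SeqRecord, revcomp

__all__ = [
    "Enzyme",
    "Fragment",
    "ProtoSite",
    "MSEI",
    "NLAIII",
    "SPHI",
    "ENZYMES",
    "find_sites",
    "digest",
    "size_histogram",
    "size_select",
    "enumerate_proto_sites",
    "hamming",
]


def hamming(a: str, b: str, limit: Optional[int] = None) -> int:
    """Hamming distance between equal-length strings, optionally capped.

    With ``limit`` set, counting stops once the distance exceeds it (the exact
    value above ``limit`` is not meaningful; only ``<= limit`` comparisons are).
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    if a == b:
        return 0
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: exact recognition site plus top-strand cut offset.

    ``cut_offset`` is the index within ``site`` where the top strand is cut:
    MseI (T^TAA) has offset 1, NlaIII (CATG^) offset 4, SphI (GCATG^C)
    offset 5.  Sites must be reverse-complement palindromes.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.site) < 2:
            raise ValueError(f"{self.name}: recognition site must be >= 2 bases")
        if set(self.site) - set("ACGT"):
            raise ValueError(
                f"{self.name}: degenerate-base sites are not supported"
            )
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside the site")
        if revcomp(self.site) != self.site:
            raise ValueError(
                f"{self.name}: site {self.site} is not a reverse-complement "
                "palindrome; non-palindromic enzymes are not supported"
            )

    @property
    def site_len(self) -> int:
        return len(self.site)

    @property
    def read_start_within_site(self) -> int:
        """Offset within the site at which a phased read's sequence begins.

        After adapter ligation the read covers the regenerated overhang, so
        it starts at the 5'-most cut of the double-stranded break:
        ``min(cut_offset, len(site) - cut_offset)``.  For a 5'-overhang cutter
        (MseI, T^TAA) this is 1 and the read begins with ``TAA``; for a
        3'-overhang cutter (NlaIII, CATG^) it is 0 and the read begins with
        the full ``CATG``.
        """
        return min(self.cut_offset, len(self.site) - self.cut_offset)

    @property
    def sequenced_overhang(self) -> str:
        """Fixed genomic bases at the start of every phased read."""
        return self.site[self.read_start_within_site :]


MSEI = Enzyme("MseI", "TTAA", 1)
NLAIII = Enzyme("NlaIII", "CATG", 4)
SPHI = Enzyme("SphI", "GCATGC", 5)

ENZYMES: Dict[str, Enzyme] = {e.name: e for e in (MSEI, NLAIII, SPHI)}


@dataclass(frozen=True)
class Fragment:
    """One fragment of a complete digest, 0-based half-open.

    ``left_site_pos``/``right_site_pos`` give the recognition-site start
    coordinates of the bounding cuts, or ``None`` at a contig terminus
    (terminal ends are not phased and emit no reads).
    """

    contig: str
    start: int
    end: int
    left_site_pos: Optional[int]
    right_site_pos: Optional[int]

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProtoSite:
    """A window at Hamming distance exactly 1 from a recognition site."""

    contig: str
    pos: int  # 0-based start of the window
    window: str
    diff_index: int  # position within the window that differs from the site


def find_sites(seq: str, enzyme: Enzyme) -> List[int]:
    """All 0-based start positions of the recognition site, overlaps included."""
    positions: List[int] = []
    start = seq.find(enzyme.site)
    while start != -1:
        positions.append(start)
        start = seq.find(enzyme.site, start + 1)
    return positions


def digest(
    genome: Union[SeqRecord, Sequence[SeqRecord]], enzyme: Enzyme
) -> List[Fragment]:
    """Complete in silico digest: per contig, fragments tile without gaps.

    Cuts are placed at ``site_pos + cut_offset``.  Overlapping site
    occurrences that would imply a zero-length fragment are collapsed (a real
    digest cannot cut twice at the same phosphodiester bond).
    """
    contigs = [genome] if isinstance(genome, SeqRecord) else list(genome)
    fragments: List[Fragment] = []
    for rec in contigs:
        sites = find_sites(rec.seq, enzyme)
        cuts: List[int] = []
        cut_sites: List[int] = []
        for s in sites:
            c = s + enzyme.cut_offset
            if 0 < c < len(rec.seq) and (not cuts or c > cuts[-1]):
                cuts.append(c)
                cut_sites.append(s)
        bounds = [0] + cuts + [len(rec.seq)]
        left_sites = [None] + cut_sites
        right_sites = cut_sites + [None]
        for i in range(len(bounds) - 1):
            fragments.append(
                Fragment(
                    contig=rec.id,
                    start=bounds[i],
                    end=bounds[i + 1],
                    left_site_pos=left_sites[i],
                    right_site_pos=right_sites[i],
                )
            )
    return fragments


def size_histogram(fragments: Iterable[Fragment], bin_width: int) -> Dict[int, int]:
    """Fragment-length histogram keyed by bin start (e.g. 25 -> [25, 50))."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    hist: Dict[int, int] = {}
    for frag in fragments:
        b = (len(frag) // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return hist


def size_select(
    fragments: Iterable[Fragment], min_len: int, max_len: int
) -> List[Fragment]:
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [f for f in fragments if min_len <= len(f) <= max_len]


def enumerate_proto_sites(seq: str, enzyme: Enzyme) -> List[ProtoSite]:
    """All windows at Hamming distance exactly 1 from the recognition site.

    Windows equal to the site are excluded by construction.  Uses the site's
    occurrence structure only implicitly: every window is tested directly.
    """
    site = enzyme.site
    L = len(site)
    protos: List[ProtoSite] = []
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        diff = -1
        count = 0
        for i in range(L):
            if window[i] != site[i]:
                count += 1
                if count > 1:
                    break
                diff = i
        if count == 1:
            protos.append(ProtoSite("", pos, window, diff))
    return protos
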