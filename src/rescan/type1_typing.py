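"""Type I SNP discovery from read start positions.

In a restriction-phased library the mere *position* at which a read starts is
informative: a read initiating where the reference has no recognition site
implies that the sample carries a site the reference lacks.  When the
reference window under the observed cut is at Hamming distance 1 from the
site (a *proto site*), two explanations compete: relaxed-specificity "star"
cutting of the near-cognate reference sequence, or a genuine sample SNP that
completed the site.  The two are distinguished by the read's own base at the
divergent position whenever that position is inside the read: matching the
site confirms a SNP; matching the reference proto base indicates star
cutting.

SNP inference from a confirmed proto site is only unequivocal when exactly
one single-base substitution in the local context can explain a new cut
there.  Because alternative site-creating substitutions in overlapping
windows shift the cut by at most one site length - less than the positional
resolution of low-coverage read-start evidence - every site-creating
substitution whose window overlaps the proto window is treated as a
candidate; a unique candidate yields an inferred call, several yield
``ambiguous`` (the classic case being a TTTAG context, where two different
substitutions each create a TTAA site over the observed cut region).

Calls are reported reference -> sample (``ref_base > alt_base``), on the
forward genome strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .align_lite import Placement
from .insilico_digest import Enzyme, ProtoSite, hamming
from .io_formats import ReadRecord, SeqRecord, revcomp

__all__ = [
    "StartClassification",
    "Type1Call",
    "ReferenceFrames",
    "classify_start",
    "infer_type1",
    "star_rate",
    "summarize_type1",
    "call_type1",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ReferenceFrames:
    """Forward and reverse-complement views of a reference genome.

    Read-start geometry is simplest in the frame of the read itself; for a
    reverse-strand placement that frame is the reverse complement of the
    contig, which this class caches.
    """

    def __init__(self, genome: Iterable[SeqRecord]):
        self.fwd: Dict[str, str] = {rec.id: rec.seq for rec in genome}
        self._rc: Dict[str, str] = {}

    def rc(self, contig: str) -> str:
        seq = self._rc.get(contig)
        if seq is None:
            seq = self._rc[contig] = revcomp(self.fwd[contig])
        return seq

    def length(self, contig: str) -> int:
        return len(self.fwd[contig])


@dataclass(frozen=True)
class StartClassification:
    """Where a read's start falls relative to the reference site landscape.

    ``category`` is ``full_site``, ``proto_site`` or ``off_site``.  For proto
    starts, ``evidence`` records what the read shows at the divergent
    position: ``confirming`` (read completes the site -> sample SNP),
    ``star`` (read matches the reference proto base -> star cutting) or
    ``indeterminate`` (divergent base not within the read, or an unrelated
    third base).  ``divergent_in_read`` separates those two indeterminate
    situations: when the divergent position precedes the read start the read
    is silent about star cutting but its start position still argues for a
    sample site.  ``context`` and the frame bookkeeping fields feed SNP
    inference; frame coordinates follow the read's orientation.
    """

    read_id: str
    category: str
    contig: str
    strand: str
    proto: Optional[ProtoSite] = None
    evidence: Optional[str] = None
    divergent_in_read: bool = False
    context: Optional[str] = None
    window_pos_in_context: Optional[int] = None
    context_frame_start: Optional[int] = None
    contig_length: Optional[int] = None
    genome_divergent_pos: Optional[int] = None


@dataclass(frozen=True)
class Type1Call:
    """A SNP inferred (or not) from a confirmed proto site.

    ``pos`` is the 0-based forward-strand genome coordinate of the divergent
    base; ``alt_base`` is the sample base that completes the enzyme site.
    ``status`` is ``inferred`` or ``ambiguous`` (ref/alt absent when
    ambiguous).
    """

    contig: str
    pos: int
    ref_base: Optional[str]
    alt_base: Optional[str]
    n_reads: int
    status: str


def classify_start(
    placement: Placement,
    read: ReadRecord,
    frames: ReferenceFrames,
    enzyme: Enzyme,
) -> StartClassification:
    """Classify one placed read's start as full-site, proto-site or off-site.

    The expected recognition window is reconstructed from the cut geometry:
    in the read's frame the window begins ``read_start_within_site`` bases
    before the read start.  Hamming distance of the reference window to the
    site gives the category (0 full, 1 proto, >= 2 off); a window truncated
    by the contig edge is off-site.
    """
    L = enzyme.site_len
    rso = enzyme.read_start_within_site
    contig = placement.target
    N = frames.length(contig)
    if placement.strand == "+":
        frame = frames.fwd[contig]
        s = placement.offset
    else:
        frame = frames.rc(contig)
        s = N - (placement.offset + placement.length)
    wstart = s - rso
    if wstart < 0 or wstart + L > N:
        return StartClassification(
            read_id=read.id, category="off_site", contig=contig,
            strand=placement.strand,
        )
    window = frame[wstart : wstart + L]
    d = hamming(window, enzyme.site, limit=1)
    if d == 0:
        return StartClassification(
            read_id=read.id, category="full_site", contig=contig,
            strand=placement.strand,
        )
    if d > 1:
        return StartClassification(
            read_id=read.id, category="off_site", contig=contig,
            strand=placement.strand,
        )
    diff = next(i for i in range(L) if window[i] != enzyme.site[i])
    q = wstart + diff
    rel = q - s
    in_read = 0 <= rel < len(read.seq)
    if in_read:
        observed = read.seq[rel]
        if observed == enzyme.site[diff]:
            evidence = "confirming"
        elif observed == window[diff]:
            evidence = "star"
        else:
            evidence = "indeterminate"
    else:
        evidence = "indeterminate"
    cstart = max(0, wstart - (L - 1))
    cend = min(N, wstart + L + (L - 1))
    gpos = q if placement.strand == "+" else N - 1 - q
    return StartClassification(
        read_id=read.id,
        category="proto_site",
        contig=contig,
        strand=placement.strand,
        proto=ProtoSite(contig, wstart, window, diff),
        evidence=evidence,
        divergent_in_read=in_read,
        context=frame[cstart:cend],
        window_pos_in_context=wstart - cstart,
        context_frame_start=cstart,
        contig_length=N,
        genome_divergent_pos=gpos,
    )


def infer_type1(
    context: str, window_pos: int, enzyme: Enzyme
) -> Tuple[str, List[Tuple[int, str, str]]]:
    """Enumerate site-creating substitutions explaining a proto-site cut.

    ``context`` must contain the proto window at ``window_pos`` with up to
    ``len(site) - 1`` flanking bases on each side.  Every single-base
    substitution that turns a window overlapping the proto window into a
    recognition site is a candidate ``(context_pos, ref_base, alt_base)``.
    Exactly one candidate -> ``("inferred", [cand])``; several ->
    ``("ambiguous", cands)``.  Zero candidates is impossible for a genuine
    proto window and raises ``RuntimeError``.
    """
    site = enzyme.site
    L = enzyme.site_len
    lo = max(0, window_pos - (L - 1))
    hi = min(len(context) - L, window_pos + L - 1)
    cands: Set[Tuple[int, str, str]] = set()
    for p in range(lo, hi + 1):
        w = context[p : p + L]
        diff = -1
        count = 0
        for i in range(L):
            if w[i] != site[i]:
                count += 1
                if count > 1:
                    break
                diff = i
        if count == 1:
            cands.add((p + diff, w[diff], site[diff]))
    if not cands:
        raise RuntimeError(
            "no site-creating substitution found for a proto window; "
            "classification and inference disagree"
        )
    ordered = sorted(cands)
    return ("inferred" if len(ordered) == 1 else "ambiguous"), ordered


def star_rate(
    classifications: Iterable[StartClassification],
) -> Optional[Tuple[float, int, int]]:
    """Fraction of determinate proto-site reads explained by star cutting.

    Returns ``(rate, n_star, n_confirming)`` with
    ``rate = star / (star + confirming)``; indeterminate reads are excluded.
    ``None`` when no determinate proto read exists.
    """
    n_star = n_conf = 0
    for c in classifications:
        if c.category != "proto_site":
            continue
        if c.evidence == "star":
            n_star += 1
        elif c.evidence == "confirming":
            n_conf += 1
    total = n_star + n_conf
    if total == 0:
        return None
    return n_star / total, n_star, n_conf


def summarize_type1(
    classifications: Iterable[StartClassification],
) -> Dict[str, float]:
    """Read-start tally: total, full-site, off-site, proto and proto percent."""
    counts = {"full_site": 0, "proto_site": 0, "off_site": 0}
    for c in classifications:
        counts[c.category] += 1
    total = sum(counts.values())
    return {
        "total": total,
        "full_site": counts["full_site"],
        "off_site": counts["off_site"],
        "proto": counts["proto_site"],
        "percent": (100.0 * counts["proto_site"] / total) if total else 0.0,
    }


def call_type1(
    classifications: Iterable[StartClassification],
    enzyme: Enzyme,
    min_reads: int = 1,
) -> List[Type1Call]:
    """Aggregate site-consistent proto reads into per-position Type I calls.

    Two kinds of proto reads support a call: those with confirming evidence,
    and those whose divergent position lies before the read start - for
    these the start position itself is the evidence, as no read base can
    speak to the divergent site position.  In-read star or third-base reads
    are excluded.  Reads are grouped by the divergent reference position;
    groups of at least ``min_reads`` (sites are trustworthy from as little
    as one or two phased reads) are run through :func:`infer_type1`.
    Positions and bases are reported on the forward genome strand.
    """
    groups: Dict[Tuple[str, int], List[StartClassification]] = defaultdict(list)
    for c in classifications:
        if c.category != "proto_site":
            continue
        if c.evidence == "confirming" or not c.divergent_in_read:
            groups[(c.contig, c.genome_divergent_pos)].append(c)
    calls: List[Type1Call] = []
    for (contig, gpos), members in sorted(groups.items()):
        if len(members) < min_reads:
            continue
        rep = members[0]
        status, cands = infer_type1(
            rep.context, rep.window_pos_in_context, enzyme
        )
        if status == "inferred":
            ctx_pos, ref, alt = cands[0]
            frame_pos = rep.context_frame_start + ctx_pos
            if rep.strand == "+":
                pos, ref_g, alt_g = frame_pos, ref, alt
            else:
                pos = rep.contig_length - 1 - frame_pos
                ref_g, alt_g = _COMP[ref], _COMP[alt]
            calls.append(
                Type1Call(contig, pos, ref_g, alt_g, len(members), "inferred")
            )
        else:
            calls.append(
                Type1Call(contig, gpos, None, None, len(members), "ambiguous")
            )
    return calls
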