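"""Multi-library pileup mutation caller for rare induced variants.

The caller compares one control and several mutagenized individuals sequenced
as restriction-phased libraries.  Natural polymorphisms are shared between
individuals; an induced mutation is private to one treated individual, which
is the discriminating signal.  The calling cascade per position is:

1. **Gating** (:func:`gate_column`): drop basecalls below the base-quality or
   mapping-quality thresholds; discard positions whose pooled post-gating
   coverage exceeds ``max_total_cov`` (repeat shadow) or that are not covered
   in every library.
2. **Classification** (:func:`classify_position`): a single pooled allele is
   homozygous (``hom_ref``/``hom_snp`` against the reference base - for a
   pseudo-reference run the k-mer base plays the reference role); with more
   than one allele, a minor allele seen in more than one library is called
   heterozygous when it carries more than ``het_minor_frac`` of the calls and
   homozygous-by-majority otherwise; a minor allele confined to a single
   library is routed to candidate detection.
3. **Candidate detection** (:func:`detect_candidate`): the non-wild-type base
   must be private to one library; at least ``min_hom_calls`` identical calls
   with no other call in that library make a homozygous candidate, at least
   ``min_het_calls`` mutant calls alongside other calls a heterozygous one.
   With three or more alleles, least-frequent singletons are dropped one at a
   time (two or more singletons: position ignored); if every allele is seen
   at least twice the position is ambiguous and removed.

Wild type at a candidate position is defined as the majority allele across
the *other* libraries, not the reference base - the only coherent choice for
a reference-free run, applied uniformly.  Indel-attached and deleted ('*')
calls count toward the coverage gates but never form substitution alleles.

Mutation density is candidates per megabase of *assayed* sequence, where a
position is assayed for a library if it survived the gates and could have
revealed a mutation there; heterozygous detection is additionally corrected
for binomial allele sampling at low coverage (:func:`het_detection_prob`).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from functools import lru_cache
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binomtest, fisher_exact

from .align_lite import scan_place
from .io_formats import PileupColumn, SeqRecord

__all__ = [
    "CallerConfig",
    "GatedColumn",
    "PositionCall",
    "MutationCandidate",
    "SpectrumTable",
    "RateEstimate",
    "CallResult",
    "gate_column",
    "classify_position",
    "detect_candidate",
    "evaluate_position",
    "call_pileup",
    "build_spectrum",
    "spectrum_test",
    "het_detection_prob",
    "mutation_density",
    "compare_mutation_sets",
    "CHANGE_CLASSES",
    "change_class",
]

SUBSTITUTION_BASES = frozenset("ACGT")

#: strand-collapsed substitution classes
CHANGE_CLASSES = ("GC>AT", "AT>GC", "GC>TA", "GC>CG", "AT>CG", "AT>TA")

_CLASS_OF = {
    ("G", "A"): "GC>AT", ("C", "T"): "GC>AT",
    ("A", "G"): "AT>GC", ("T", "C"): "AT>GC",
    ("G", "T"): "GC>TA", ("C", "A"): "GC>TA",
    ("G", "C"): "GC>CG", ("C", "G"): "GC>CG",
    ("A", "C"): "AT>CG", ("T", "G"): "AT>CG",
    ("A", "T"): "AT>TA", ("T", "A"): "AT>TA",
}


def change_class(wt: str, mut: str) -> str:
    """Strand-collapsed class of a substitution (G>A and C>T both GC>AT)."""
    if wt == mut:
        raise ValueError("wild-type and mutant base are identical")
    return _CLASS_OF[(wt, mut)]


@dataclass(frozen=True)
class CallerConfig:
    min_base_qual: int = 20
    min_map_qual: int = 20
    max_total_cov: int = 200
    het_minor_frac: float = 0.10
    het_minor_frac_inclusive: bool = True  # fraction == threshold counts as het
    min_hom_calls: int = 2
    min_het_calls: int = 5
    adjust_cov_below: int = 15
    n_libraries: int = 4
    control_index: int = 0

    def __post_init__(self) -> None:
        if min(
            self.min_base_qual, self.min_map_qual, self.max_total_cov,
            self.min_hom_calls, self.min_het_calls, self.adjust_cov_below,
            self.n_libraries,
        ) < 0:
            raise ValueError("caller thresholds must be non-negative")
        if not 0 <= self.control_index < self.n_libraries:
            raise ValueError("control_index out of range")


@dataclass
class GatedColumn:
    """A pileup column after quality gating.

    ``bases_per_library`` holds the surviving substitution basecalls (A/C/G/T
    only); ``cov_per_library`` the surviving coverage including '*' and
    indel-anchored calls, which gate but never vote.
    """

    contig: str
    pos: int
    ref_base: str
    bases_per_library: List[List[str]]
    cov_per_library: List[int]

    @property
    def pooled_cov(self) -> int:
        return sum(self.cov_per_library)


@dataclass(frozen=True)
class PositionCall:
    contig: str
    pos: int
    classification: Optional[str]  # hom_ref/hom_snp/het/hom_by_minor_rule/ambiguous
    routed_to_candidate: bool = False
    discarded_reason: Optional[str] = None


@dataclass(frozen=True)
class MutationCandidate:
    contig: str
    pos: int  # 1-based, as in the pileup
    wt_base: str
    mut_base: str
    zygosity: str  # 'hom' or 'het'
    library: str
    support: int


@dataclass
class SpectrumTable:
    """Candidate counts per strand-collapsed class, library and zygosity."""

    counts: Dict[Tuple[str, str], Counter] = field(default_factory=dict)

    def add(self, cand: MutationCandidate) -> None:
        key = (cand.library, cand.zygosity)
        self.counts.setdefault(key, Counter())[
            change_class(cand.wt_base, cand.mut_base)
        ] += 1

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def by_class(
        self, library: Optional[str] = None, zygosity: Optional[str] = None
    ) -> Counter:
        out: Counter = Counter()
        for (lib, zyg), counter in self.counts.items():
            if library is not None and lib != library:
                continue
            if zygosity is not None and zyg != zygosity:
                continue
            out.update(counter)
        return out


@dataclass(frozen=True)
class RateEstimate:
    library: str
    zygosity: str
    n_mutations: int
    assayed_bases_raw: float
    assayed_bases_adjusted: float
    density_per_mb_raw: Optional[float]
    density_per_mb_adjusted: Optional[float]


# ---------------------------------------------------------------------------
# gating and per-position rules
# ---------------------------------------------------------------------------

def gate_column(
    col: PileupColumn, cfg: CallerConfig
) -> Tuple[Optional[GatedColumn], Optional[str]]:
    """Apply the quality and coverage gates to one pileup column.

    Returns ``(gated, None)`` or ``(None, reason)`` with reason in
    ``{"over_covered", "not_all_covered"}``.
    """
    if len(col.per_library) != cfg.n_libraries:
        raise ValueError(
            f"column has {len(col.per_library)} libraries, config expects "
            f"{cfg.n_libraries}"
        )
    bases: List[List[str]] = []
    covs: List[int] = []
    for calls in col.per_library:
        kept_bases: List[str] = []
        cov = 0
        for call in calls:
            if call.qual < cfg.min_base_qual:
                continue
            if call.map_qual is not None and call.map_qual < cfg.min_map_qual:
                continue
            cov += 1
            if call.base in SUBSTITUTION_BASES and call.indel is None:
                kept_bases.append(call.base)
        bases.append(kept_bases)
        covs.append(cov)
    if sum(covs) > cfg.max_total_cov:
        return None, "over_covered"
    if any(c == 0 for c in covs):
        return None, "not_all_covered"
    return GatedColumn(col.contig, col.pos, col.ref_base, bases, covs), None


def _allele_counts(gated: GatedColumn) -> Tuple[Counter, Dict[str, set]]:
    pooled: Counter = Counter()
    libs_with: Dict[str, set] = defaultdict(set)
    for idx, calls in enumerate(gated.bases_per_library):
        for b in calls:
            pooled[b] += 1
            libs_with[b].add(idx)
    return pooled, libs_with


def _minor_allele(pooled: Counter, libs_with: Mapping[str, set]) -> str:
    """Deterministic least-frequent allele: fewest calls, then fewest
    libraries, then lexicographic order."""
    return min(pooled, key=lambda b: (pooled[b], len(libs_with[b]), b))


def classify_position(
    gated: GatedColumn, ref_base: str, cfg: CallerConfig
) -> PositionCall:
    """Zygosity classification of a gated position.

    All calls identical -> ``hom_ref``/``hom_snp`` against ``ref_base`` (the
    k-mer base in a pseudo-reference run).  Otherwise the least frequent
    allele decides: present in more than one library it makes the position
    ``het`` (minor fraction above the 10% threshold, inclusive) or
    ``hom_by_minor_rule``; confined to a single library the position is
    routed to :func:`detect_candidate`.
    """
    pooled, libs_with = _allele_counts(gated)
    if not pooled:
        return PositionCall(gated.contig, gated.pos, None,
                            discarded_reason="no_substitution_calls")
    if len(pooled) == 1:
        allele = next(iter(pooled))
        cls = "hom_ref" if allele == ref_base else "hom_snp"
        return PositionCall(gated.contig, gated.pos, cls)
    minor = _minor_allele(pooled, libs_with)
    if len(libs_with[minor]) > 1:
        frac = pooled[minor] / sum(pooled.values())
        if frac > cfg.het_minor_frac or (
            cfg.het_minor_frac_inclusive and frac == cfg.het_minor_frac
        ):
            cls = "het"
        else:
            cls = "hom_by_minor_rule"
        return PositionCall(gated.contig, gated.pos, cls)
    return PositionCall(gated.contig, gated.pos, None, routed_to_candidate=True)


def detect_candidate(
    gated: GatedColumn,
    cfg: CallerConfig,
    libraries: Optional[Sequence[str]] = None,
) -> Tuple[Optional[MutationCandidate], Optional[str]]:
    """Apply the private-mutation rules to a multi-allele gated position.

    Returns ``(candidate, None)`` or ``(None, reason)``; reasons include
    ``ignored_singletons`` (>= 2 least-frequent alleles seen once),
    ``ambiguous`` (>= 3 alleles all seen at least twice, removed from
    analysis), ``minor_in_multiple_libraries`` and ``insufficient_support``.
    """
    lib_names = (
        list(libraries)
        if libraries is not None
        else [str(i) for i in range(cfg.n_libraries)]
    )
    pooled, libs_with = _allele_counts(gated)
    # Peel least-frequent singletons one at a time; two or more at once means
    # the position is ignored for mutation detection.
    while len(pooled) > 2:
        singles = [b for b in pooled if pooled[b] == 1]
        if len(singles) >= 2:
            return None, "ignored_singletons"
        if len(singles) == 1:
            del pooled[singles[0]]
            del libs_with[singles[0]]
            continue
        return None, "ambiguous"
    if len(pooled) < 2:
        return None, "single_allele"
    minor = _minor_allele(pooled, libs_with)
    if len(libs_with[minor]) > 1:
        return None, "minor_in_multiple_libraries"
    focal = next(iter(libs_with[minor]))
    # wild type: the majority allele across the other libraries
    others: Counter = Counter()
    for idx, calls in enumerate(gated.bases_per_library):
        if idx != focal:
            others.update(b for b in calls if b != minor)
    if not others:
        return None, "no_wild_type_evidence"
    wt = max(others, key=lambda b: (others[b], b))
    focal_calls = gated.bases_per_library[focal]
    n_mut = sum(1 for b in focal_calls if b == minor)
    focal_other = sum(1 for b in focal_calls if b != minor)
    if n_mut >= cfg.min_hom_calls and focal_other == 0:
        zygosity = "hom"
    elif n_mut >= cfg.min_het_calls:
        zygosity = "het"
    else:
        return None, "insufficient_support"
    return (
        MutationCandidate(
            contig=gated.contig,
            pos=gated.pos,
            wt_base=wt,
            mut_base=minor,
            zygosity=zygosity,
            library=lib_names[focal],
            support=n_mut,
        ),
        None,
    )


def evaluate_position(
    gated: GatedColumn,
    cfg: CallerConfig,
    libraries: Optional[Sequence[str]] = None,
) -> Tuple[PositionCall, Optional[MutationCandidate], Optional[str]]:
    """Classification plus candidate detection for one gated position."""
    call = classify_position(gated, gated.ref_base, cfg)
    if not call.routed_to_candidate:
        return call, None, None
    cand, reason = detect_candidate(gated, cfg, libraries)
    if reason == "ambiguous":
        call = replace(call, classification="ambiguous", routed_to_candidate=False)
    return call, cand, reason


# ---------------------------------------------------------------------------
# binomial detectability and rates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def het_detection_prob(coverage: int, min_calls: int = 5) -> float:
    """P(X >= min_calls) for X ~ Binomial(coverage, 1/2), by direct summation.

    The chance that a heterozygous site sequenced to ``coverage`` yields
    enough mutant-allele calls to pass the heterozygous support threshold;
    e.g. 0.62 at coverage 10 with the default threshold of 5.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if min_calls > coverage:
        return 0.0
    total = sum(comb(coverage, k) for k in range(min_calls, coverage + 1))
    return total / 2 ** coverage


def mutation_density(
    library: str,
    zygosity: str,
    n_mutations: int,
    assayed_raw: float,
    assayed_adjusted: float,
) -> RateEstimate:
    """Mutations per megabase over raw and detectability-adjusted denominators."""
    return RateEstimate(
        library=library,
        zygosity=zygosity,
        n_mutations=n_mutations,
        assayed_bases_raw=assayed_raw,
        assayed_bases_adjusted=assayed_adjusted,
        density_per_mb_raw=(n_mutations / (assayed_raw / 1e6))
        if assayed_raw > 0
        else None,
        density_per_mb_adjusted=(n_mutations / (assayed_adjusted / 1e6))
        if assayed_adjusted > 0
        else None,
    )


# ---------------------------------------------------------------------------
# spectrum statistics
# ---------------------------------------------------------------------------

def build_spectrum(candidates: Iterable[MutationCandidate]) -> SpectrumTable:
    table = SpectrumTable()
    for cand in candidates:
        table.add(cand)
    return table


def spectrum_test(
    gc_at_count: int,
    other_count: int,
    p0: float = 0.59,
    method: str = "binomial",
) -> Tuple[Optional[float], Optional[float]]:
    """Two-sided test of the observed GC>AT fraction against ``p0``.

    ``p0`` defaults to the GC>AT fraction expected from sequencing error
    alone, so rejection indicates a mutagen-shaped spectrum.  The default is
    an exact binomial test; ``method="fisher"`` builds a 2x2 table against
    ``p0``-expected counts at the same total (rounded) for fidelity to a
    contingency-table formulation.  Returns ``(p_value, observed_fraction)``,
    or ``(None, None)`` when there are no counts.
    """
    if gc_at_count < 0 or other_count < 0:
        raise ValueError("counts must be non-negative")
    total = gc_at_count + other_count
    if total == 0:
        return None, None
    frac = gc_at_count / total
    if method == "binomial":
        p = binomtest(gc_at_count, total, p0, alternative="two-sided").pvalue
    elif method == "fisher":
        exp_gc = round(total * p0)
        _, p = fisher_exact(
            [[gc_at_count, other_count], [exp_gc, total - exp_gc]],
            alternative="two-sided",
        )
    else:
        raise ValueError(f"unknown spectrum test method {method!r}")
    return float(p), frac


# ---------------------------------------------------------------------------
# streaming driver with assayed-base accounting
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    """Everything the caller accumulates over a pileup stream."""

    libraries: List[str]
    candidates: List[MutationCandidate] = field(default_factory=list)
    classification_tally: Counter = field(default_factory=Counter)
    discard_tally: Counter = field(default_factory=Counter)
    n_columns: int = 0
    n_gated: int = 0
    assayed_hom: Dict[str, int] = field(default_factory=dict)
    assayed_het_raw: Dict[str, int] = field(default_factory=dict)
    assayed_het_adjusted: Dict[str, float] = field(default_factory=dict)
    coverage_by_target: Optional[Dict[str, np.ndarray]] = None

    def rates(self) -> List[RateEstimate]:
        per_lib_zyg: Counter = Counter()
        for cand in self.candidates:
            per_lib_zyg[(cand.library, cand.zygosity)] += 1
        out = []
        for lib in self.libraries:
            out.append(
                mutation_density(
                    lib, "hom", per_lib_zyg[(lib, "hom")],
                    self.assayed_hom.get(lib, 0), self.assayed_hom.get(lib, 0),
                )
            )
            out.append(
                mutation_density(
                    lib, "het", per_lib_zyg[(lib, "het")],
                    self.assayed_het_raw.get(lib, 0),
                    self.assayed_het_adjusted.get(lib, 0.0),
                )
            )
        return out


def call_pileup(
    columns: Iterable[PileupColumn],
    cfg: CallerConfig,
    libraries: Sequence[str],
    collect_coverage: bool = False,
    target_lengths: Optional[Mapping[str, int]] = None,
) -> CallResult:
    """Run the gate/classify/detect cascade over a pileup stream.

    Also performs assayed-base accounting: for each library, positions
    assayed for homozygous scoring (all libraries covered, focal coverage >=
    ``min_hom_calls``, pooled coverage within the cap) are counted, and
    positions assayed for heterozygous scoring accumulate both a raw count
    and a detectability weight - :func:`het_detection_prob` of the focal
    coverage when it is below ``adjust_cov_below``, 1 otherwise.

    With ``collect_coverage`` the per-target per-library post-gating coverage
    is retained (``coverage_by_target[target][lib_idx, pos0]``), which
    supports downstream truth-based audits; ``target_lengths`` sizes those
    arrays (defaults to the maximum observed position).
    """
    result = CallResult(libraries=list(libraries))
    for lib in libraries:
        result.assayed_hom[lib] = 0
        result.assayed_het_raw[lib] = 0
        result.assayed_het_adjusted[lib] = 0.0
    if collect_coverage:
        result.coverage_by_target = {}
    min_het = cfg.min_het_calls
    adjust_below = cfg.adjust_cov_below
    for col in columns:
        result.n_columns += 1
        gated, reason = gate_column(col, cfg)
        if gated is None:
            result.discard_tally[reason] += 1
            continue
        result.n_gated += 1
        if collect_coverage:
            arr = result.coverage_by_target.get(col.contig)
            if arr is None:
                size = (
                    target_lengths[col.contig]
                    if target_lengths is not None
                    else col.pos
                )
                arr = result.coverage_by_target[col.contig] = np.zeros(
                    (len(libraries), max(size, col.pos)), dtype=np.uint16
                )
            elif col.pos > arr.shape[1]:
                grown = np.zeros((len(libraries), col.pos), dtype=np.uint16)
                grown[:, : arr.shape[1]] = arr
                arr = result.coverage_by_target[col.contig] = grown
            arr[:, col.pos - 1] = gated.cov_per_library
        for idx, lib in enumerate(libraries):
            cov = gated.cov_per_library[idx]
            if cov >= cfg.min_hom_calls:
                result.assayed_hom[lib] += 1
            result.assayed_het_raw[lib] += 1
            result.assayed_het_adjusted[lib] += (
                1.0 if cov >= adjust_below else het_detection_prob(cov, min_het)
            )
        call, cand, _ = evaluate_position(gated, cfg, libraries)
        if call.classification is not None:
            result.classification_tally[call.classification] += 1
        if cand is not None:
            result.candidates.append(cand)
    return result


# ---------------------------------------------------------------------------
# referenced vs de novo comparison
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    shared: Counter
    referenced_only: Counter
    denovo_only: Counter
    n_unmappable_kmers: int

    def totals(self) -> Dict[str, int]:
        return {
            "shared": sum(self.shared.values()),
            "referenced_only": sum(self.referenced_only.values()),
            "denovo_only": sum(self.denovo_only.values()),
        }


def compare_mutation_sets(
    denovo_candidates: Sequence[MutationCandidate],
    kmer_seqs: Mapping[str, str],
    genome: Sequence[SeqRecord],
    referenced_candidates: Sequence[MutationCandidate],
) -> OverlapReport:
    """Project pseudo-reference candidates onto the genome and compare sets.

    Each de novo candidate's k-mer is placed on the genome (<= 1 mismatch,
    unique placements only; unmappable k-mers are counted, not fatal) and the
    candidate offset translated to a forward-strand genome coordinate.
    Candidates are then compared position-wise per strand-collapsed change
    class against the genome-referenced candidate set.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    denovo_positions: Dict[Tuple[str, int], str] = {}
    unmappable = 0
    placement_cache: Dict[str, Tuple] = {}
    for cand in denovo_candidates:
        kseq = kmer_seqs.get(cand.contig)
        if kseq is None:
            unmappable += 1
            continue
        if cand.contig not in placement_cache:
            placement_cache[cand.contig] = scan_place(kseq, genome, max_mm=1)
        placement, _ = placement_cache[cand.contig]
        if placement is None:
            unmappable += 1
            continue
        off0 = cand.pos - 1  # candidate position is 1-based within the k-mer
        if placement.strand == "+":
            gpos = placement.offset + off0
            wt, mut = cand.wt_base, cand.mut_base
        else:
            gpos = placement.offset + placement.length - 1 - off0
            wt, mut = comp[cand.wt_base], comp[cand.mut_base]
        denovo_positions[(placement.target, gpos)] = change_class(wt, mut)
    referenced_positions = {
        (cand.contig, cand.pos - 1): change_class(cand.wt_base, cand.mut_base)
        for cand in referenced_candidates
    }
    shared: Counter = Counter()
    ref_only: Counter = Counter()
    dn_only: Counter = Counter()
    for key, cls in referenced_positions.items():
        if key in denovo_positions:
            shared[cls] += 1
        else:
            ref_only[cls] += 1
    for key, cls in denovo_positions.items():
        if key not in referenced_positions:
            dn_only[cls] += 1
    return OverlapReport(shared, ref_only, dn_only, unmappable)
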