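"""Generative model of a restriction-phased mutagenesis experiment.

The simulator produces the exact artifact stack the analysis consumes - a
random genome, per-individual mutagenized diploid haplotypes, and barcoded
phased reads - together with the ground truth needed to audit every
downstream stage.  Its defaults mirror the experimental condition the method
was developed on: an *NlaIII* digest of a 44% GC genome, SPRI size selection,
85 genomic bases sequenced per read behind a 5-base inline barcode, one
untreated control and three individuals treated with escalating mutagen
doses whose mutations are almost exclusively GC > AT transitions.

Read geometry follows the library chemistry.  A fragment bounded by cuts at
sites ``ls`` and ``rs`` yields, after overhang fill-in, a molecule spanning
``[ls + r, rs + L - r)`` where ``L`` is the site length and ``r`` the
read-start offset within the site (``Enzyme.read_start_within_site``).
Forward reads start at the molecule's left end, reverse reads at its right
end; both truncate at the far end of the molecule.  Contig-terminal fragment
ends carry no cut site, hence no adapter and no reads.  Read counts per
fragment end are Poisson with mean ``per_end_depth / 2`` per haplotype, and
substitution errors are injected per base at ``error_rate`` before the
barcode is prepended.  All randomness flows from a single
:class:`numpy.random.Generator`, so a seed fully determines the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .insilico_digest import Enzyme, Fragment, NLAIII, digest, size_select
from .io_formats import ReadRecord, SeqRecord, revcomp

__all__ = [
    "SimConfig",
    "Mutation",
    "SimResult",
    "CLASS_CHANGES",
    "DEFAULT_SPECTRUM",
    "simulate_genome",
    "mutagenize",
    "simulate_reads",
    "simulate_experiment",
]

#: forward-strand substitutions realizing each strand-collapsed class
CLASS_CHANGES: Dict[str, Dict[str, str]] = {
    "GC>AT": {"G": "A", "C": "T"},
    "AT>GC": {"A": "G", "T": "C"},
    "GC>TA": {"G": "T", "C": "A"},
    "GC>CG": {"G": "C", "C": "G"},
    "AT>CG": {"A": "C", "T": "G"},
    "AT>TA": {"A": "T", "T": "A"},
}

#: azide-type spectrum: G:C to A:T transitions only
DEFAULT_SPECTRUM: Dict[str, float] = {"GC>AT": 1.0}


def _default_libraries() -> Dict[str, Tuple[str, float]]:
    # library -> (inline barcode, total mutation density per Mb of haploid
    # genome); doses escalate across the treated series
    return {
        "control": ("ATCAC", 0.0),
        "T1": ("CTCTC", 2.0),
        "T2": ("CGAAT", 7.0),
        "T3": ("GAGCA", 12.0),
    }


@dataclass
class SimConfig:
    """Experiment-level parameters; defaults are the reference condition."""

    genome_len: int = 1_000_000
    n_contigs: int = 1
    gc_frac: float = 0.44
    enzyme: Enzyme = field(default_factory=lambda: NLAIII)
    size_window: Tuple[int, int] = (100, 250)
    read_len: int = 85  # genomic bases per read, behind the barcode
    per_end_depth: float = 12.0
    error_rate: float = 1e-3
    base_qual: int = 40
    het_frac: float = 2.0 / 3.0
    spectrum: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    libraries: Dict[str, Tuple[str, float]] = field(
        default_factory=_default_libraries
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_len < 1 or self.n_contigs < 1:
            raise ValueError("genome_len and n_contigs must be positive")
        if not 0.0 < self.gc_frac < 1.0:
            raise ValueError("gc_frac must be strictly between 0 and 1")
        if self.size_window[0] > self.size_window[1]:
            raise ValueError("size window must be (min, max)")
        if self.read_len < 1 or self.per_end_depth < 0:
            raise ValueError("read_len must be >= 1 and depth >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.het_frac <= 1.0:
            raise ValueError("het_frac must be in [0, 1]")
        unknown = set(self.spectrum) - set(CLASS_CHANGES)
        if unknown:
            raise ValueError(f"unknown spectrum classes: {sorted(unknown)}")
        if sum(self.spectrum.values()) <= 0:
            raise ValueError("spectrum weights must sum to > 0")
        barcodes = [bc for bc, _ in self.libraries.values()]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("library barcodes must be unique")


@dataclass(frozen=True)
class Mutation:
    """One induced change, on the forward strand of the founder genome."""

    library: str
    contig: str
    pos: int  # 0-based
    wt_base: str
    mut_base: str
    zygosity: str  # 'hom' or 'het'


@dataclass
class SimResult:
    config: SimConfig
    genome: List[SeqRecord]
    mutations: List[Mutation]
    reads: List[ReadRecord]  # pooled, shuffled, barcode still attached
    barcodes: Dict[str, str]  # library -> barcode

    def mutations_by_library(self) -> Dict[str, List[Mutation]]:
        out: Dict[str, List[Mutation]] = {lib: [] for lib in self.barcodes}
        for m in self.mutations:
            out[m.library].append(m)
        return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(
    length: int,
    gc: float,
    rng: np.random.Generator,
    n_contigs: int = 1,
    name: str = "chr",
) -> List[SeqRecord]:
    """Random i.i.d. genome with the given GC content, split into contigs."""
    if length < n_contigs:
        raise ValueError("genome_length must be >= n_contigs")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = [length // n_contigs] * n_contigs
    per[-1] += length - sum(per)
    records = []
    for i, n in enumerate(per, start=1):
        idx = rng.choice(4, size=n, p=probs)
        seq = _BASES[idx].tobytes().decode("ascii")
        records.append(SeqRecord(f"{name}{i}", seq))
    return records


def _draw_sites(
    genome: Sequence[SeqRecord],
    density_per_mb: float,
    spectrum: Mapping[str, float],
    het_frac: float,
    rng: np.random.Generator,
    library: str,
) -> List[Mutation]:
    classes = sorted(spectrum)
    weights = np.array([spectrum[c] for c in classes], dtype=float)
    weights /= weights.sum()
    muts: List[Mutation] = []
    for rec in genome:
        n = rng.poisson(density_per_mb * len(rec.seq) / 1e6)
        if n == 0:
            continue
        arr = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        pos_of = {b: np.flatnonzero(arr == ord(b)) for b in "ACGT"}
        taken: set = set()
        for _ in range(n):
            pos = None
            for _attempt in range(100):
                cls = classes[rng.choice(len(classes), p=weights)]
                wt_to_mut = CLASS_CHANGES[cls]
                # no base eligible for the drawn class: resample the class
                eligible = np.concatenate([pos_of[b] for b in sorted(wt_to_mut)])
                if eligible.size == 0:
                    continue
                pos = int(eligible[rng.integers(eligible.size)])
                if pos not in taken:
                    break
                pos = None
            if pos is None:
                continue
            taken.add(pos)
            wt = rec.seq[pos]
            zyg = "het" if rng.random() < het_frac else "hom"
            muts.append(Mutation(library, rec.id, pos, wt, wt_to_mut[wt], zyg))
    return muts


def mutagenize(
    genome: Sequence[SeqRecord],
    density_per_mb: float,
    spectrum: Mapping[str, float],
    het_frac: float,
    rng: np.random.Generator,
    library: str = "",
) -> Tuple[List[SeqRecord], List[SeqRecord], List[Mutation]]:
    """Diploid mutagenesis of a founder genome.

    The number of induced sites per contig is Poisson with mean
    ``density_per_mb * contig_length / 1e6``; each site draws its change
    class from ``spectrum`` and its position uniformly over bases eligible
    for that class.  Heterozygous changes (probability ``het_frac``) land on
    one random haplotype, homozygous ones on both.  Returns the two
    haplotype genomes and the truth list.
    """
    muts = _draw_sites(genome, density_per_mb, spectrum, het_frac, rng, library)
    hap_seqs = {
        h: {rec.id: bytearray(rec.seq, "ascii") for rec in genome} for h in (0, 1)
    }
    for m in muts:
        targets = (0, 1) if m.zygosity == "hom" else (int(rng.integers(2)),)
        for h in targets:
            hap_seqs[h][m.contig][m.pos] = ord(m.mut_base)
    haplotypes = tuple(
        [SeqRecord(rec.id, hap_seqs[h][rec.id].decode("ascii")) for rec in genome]
        for h in (0, 1)
    )
    return haplotypes[0], haplotypes[1], muts


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=n_err, replace=False)
    for pos in positions:
        others = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = others[rng.integers(3)]
    return arr.decode("ascii")


def simulate_reads(
    haplotypes: Sequence[Sequence[SeqRecord]],
    cfg: SimConfig,
    barcode: str,
    rng: np.random.Generator,
    library: str,
) -> List[ReadRecord]:
    """Phased reads from the size-selected digest of each haplotype.

    Each eligible fragment end emits ``Poisson(per_end_depth / 2)`` reads per
    haplotype (the two haplotypes together give the nominal per-end depth).
    Reads carry the inline barcode, substitution errors at ``error_rate``
    and a flat quality of ``base_qual``.
    """
    enzyme = cfg.enzyme
    L = enzyme.site_len
    r = enzyme.read_start_within_site
    lam = cfg.per_end_depth / 2.0
    reads: List[ReadRecord] = []
    serial = 0
    n_retained = 0
    for hap in haplotypes:
        seqs = {rec.id: rec.seq for rec in hap}
        fragments = size_select(digest(list(hap), enzyme), *cfg.size_window)
        n_retained += len(fragments)
        for frag in fragments:
            seq = seqs[frag.contig]
            ls, rs = frag.left_site_pos, frag.right_site_pos
            mol_start = ls + r if ls is not None else frag.start
            mol_end = rs + L - r if rs is not None else frag.end
            if ls is not None:
                for _ in range(rng.poisson(lam)):
                    end = min(mol_start + cfg.read_len, mol_end)
                    genomic = _inject_errors(
                        seq[mol_start:end], cfg.error_rate, rng
                    )
                    serial += 1
                    full = barcode + genomic
                    reads.append(
                        ReadRecord(
                            f"{library}.{serial}", full,
                            bytes([cfg.base_qual]) * len(full),
                        )
                    )
            if rs is not None:
                for _ in range(rng.poisson(lam)):
                    start = max(mol_end - cfg.read_len, mol_start)
                    genomic = _inject_errors(
                        revcomp(seq[start:mol_end]), cfg.error_rate, rng
                    )
                    serial += 1
                    full = barcode + genomic
                    reads.append(
                        ReadRecord(
                            f"{library}.{serial}", full,
                            bytes([cfg.base_qual]) * len(full),
                        )
                    )
    if n_retained == 0:
        raise ValueError(
            "size window retains no fragment on any haplotype; widen "
            f"{cfg.size_window}"
        )
    return reads


def simulate_experiment(
    cfg: Optional[SimConfig] = None, seed: Optional[int] = None
) -> SimResult:
    """Full experiment: founder genome, per-library mutagenesis and reads.

    The pooled read list is shuffled, as a multiplexed lane would be, and
    still carries barcodes; run it through :func:`rescan.demux.demultiplex`
    exactly as real data.
    """
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = simulate_genome(
        cfg.genome_len, cfg.gc_frac, rng, n_contigs=cfg.n_contigs
    )
    all_muts: List[Mutation] = []
    reads: List[ReadRecord] = []
    barcodes: Dict[str, str] = {}
    for lib, (barcode, density) in cfg.libraries.items():
        barcodes[lib] = barcode
        hap1, hap2, muts = mutagenize(
            genome, density, cfg.spectrum, cfg.het_frac, rng, library=lib
        )
        all_muts.extend(muts)
        reads.extend(simulate_reads((hap1, hap2), cfg, barcode, rng, lib))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return SimResult(
        config=cfg,
        genome=genome,
        mutations=all_muts,
        reads=reads,
        barcodes=barcodes,
    )
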