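"""Shared fixtures: small simulated experiments and the large end-to-end run.

The ``e2e`` fixture is session-scoped because it is the expensive artifact
(2 Mb genome, four libraries, full de novo pipeline) shared by the
end-to-end acceptance test and the statistical property tests.  Everything
it exposes is derived from one fixed seed chosen up front.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pytest

from rescan.demux import BarcodeSpec
from rescan.insilico_digest import Enzyme, MSEI, digest, size_select
from rescan.io_formats import SeqRecord, revcomp
from rescan.pipeline import DenovoResult, prepare_libraries, run_denovo
from rescan.simulate import Mutation, SimConfig, SimResult, simulate_experiment


def make_e2e_config() -> SimConfig:
    """The end-to-end recovery scenario.

    Four libraries with homozygous densities {0, 1, 4, 2.5}/Mb; with 2/3 of
    mutations heterozygous the total densities are three times the
    homozygous ones.  MseI is used because its AT-only site cannot be
    destroyed by GC>AT changes, a wide size window maximizes the assayed
    footprint on a 2 Mb genome, and every read carries >= 70 genomic bases
    so each retained fragment end contributes a k-mer.
    """
    return SimConfig(
        genome_len=2_000_000,
        n_contigs=1,
        gc_frac=0.44,
        enzyme=MSEI,
        size_window=(70, 700),
        read_len=85,
        per_end_depth=14.0,
        error_rate=1e-3,
        het_frac=2.0 / 3.0,
        spectrum={"GC>AT": 1.0},
        libraries={
            "control": ("ATCAC", 0.0),
            "T1": ("CTCTC", 3.0),
            "T2": ("CGAAT", 12.0),
            "T3": ("GAGCA", 7.5),
        },
        seed=1,
    )


def kmer_position_map(
    genome: List[SeqRecord],
    enzyme: Enzyme,
    size_window: Tuple[int, int],
    k: int = 70,
) -> Tuple[Dict[str, Tuple[str, int, str]], Set[str]]:
    """Expected k-mer -> (contig, genome start, strand) from a digest.

    Enumerates the leading k-mer of each retained fragment end of the
    (control) genome.  K-mer sequences seen at more than one locus are
    returned in the ambiguous set and excluded from the map.
    """
    L, r = enzyme.site_len, enzyme.read_start_within_site
    mapping: Dict[str, Tuple[str, int, str]] = {}
    ambiguous: Set[str] = set()
    seqs = {rec.id: rec.seq for rec in genome}
    for frag in size_select(digest(genome, enzyme), *size_window):
        seq = seqs[frag.contig]
        ls, rs = frag.left_site_pos, frag.right_site_pos
        mol_start = ls + r if ls is not None else frag.start
        mol_end = rs + L - r if rs is not None else frag.end
        if mol_end - mol_start < k:
            continue
        ends = []
        if ls is not None:
            ends.append((seq[mol_start : mol_start + k], mol_start, "+"))
        if rs is not None:
            ends.append((revcomp(seq[mol_end - k : mol_end]), mol_end - k, "-"))
        for km, start, strand in ends:
            if km in ambiguous:
                continue
            prior = mapping.get(km)
            if prior is not None and prior != (frag.contig, start, strand):
                del mapping[km]
                ambiguous.add(km)
            else:
                mapping[km] = (frag.contig, start, strand)
    return mapping, ambiguous


@dataclass
class E2ERun:
    sim: SimResult
    denovo: DenovoResult
    duration_s: float
    libraries: List[str] = field(default_factory=list)
    # k-mer sequence -> genome placement, from the control genome's digest
    position_map: Dict[str, Tuple[str, int, str]] = field(default_factory=dict)
    ambiguous_kmers: Set[str] = field(default_factory=set)

    def genome_pos(self, target: str, pos_in_kmer: int):
        """Forward-strand genome coordinate of a k-mer position, or None."""
        km = self.denovo.kmer_seqs[target]
        placed = self.position_map.get(km)
        if placed is None:
            return None
        contig, start, strand = placed
        k = len(km)
        gpos = start + pos_in_kmer if strand == "+" else start + k - 1 - pos_in_kmer
        return contig, gpos, strand


def run_e2e(cfg: SimConfig) -> E2ERun:
    t0 = time.monotonic()
    sim = simulate_experiment(cfg)
    specs = [BarcodeSpec(library=l, barcode=b) for l, b in sim.barcodes.items()]
    libs, _ = prepare_libraries(sim.reads, specs)
    denovo = run_denovo(libs, control="control", collect_coverage=True)
    duration = time.monotonic() - t0
    pos_map, ambiguous = kmer_position_map(
        sim.genome, cfg.enzyme, cfg.size_window, k=denovo.kmer_set.k
    )
    return E2ERun(
        sim=sim,
        denovo=denovo,
        duration_s=duration,
        libraries=denovo.libraries,
        position_map=pos_map,
        ambiguous_kmers=ambiguous,
    )


@pytest.fixture(scope="session")
def e2e() -> E2ERun:
    return run_e2e(make_e2e_config())


@pytest.fixture(scope="session")
def small_sim() -> SimResult:
    """A quick NlaIII experiment for pipeline-level unit tests."""
    cfg = SimConfig(genome_len=120_000, seed=11)
    return simulate_experiment(cfg)
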