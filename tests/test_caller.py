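import math
import random

import pytest
from scipy.stats import binom

from rescan.io_formats import Basecall, PileupColumn
from rescan.mutation_caller import (
    CHANGE_CLASSES,
    CallerConfig,
    MutationCandidate,
    build_spectrum,
    call_pileup,
    change_class,
    classify_position,
    compare_mutation_sets,
    detect_candidate,
    evaluate_position,
    gate_column,
    het_detection_prob,
    mutation_density,
    spectrum_test,
)

CFG = CallerConfig()
LIBS = ["control", "T1", "T2", "T3"]


def _col(per_lib, ref="A", contig="c", pos=1, qual=40, mapq=37):
    return PileupColumn(
        contig,
        pos,
        ref,
        [[Basecall(b, qual, mapq) for b in calls] for calls in per_lib],
    )


def _gated(per_lib, **kw):
    gated, reason = gate_column(_col(per_lib, **kw), CFG)
    assert reason is None
    return gated


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def test_gate_pooled_coverage_cap_boundary():
    ok = _col([["A"] * 50] * 4)  # pooled 200: exactly at the cap
    gated, reason = gate_column(ok, CFG)
    assert reason is None and gated.pooled_cov == 200
    over = _col([["A"] * 51] + [["A"] * 50] * 3)  # pooled 201
    assert gate_column(over, CFG) == (None, "over_covered")


def test_gate_requires_every_library_covered():
    col = _col([["A"], ["A"], [], ["A"]])
    assert gate_column(col, CFG) == (None, "not_all_covered")


def test_gate_drops_low_base_and_map_quality():
    col = PileupColumn("c", 1, "A", [
        [Basecall("A", 19, 37), Basecall("A", 20, 37)],
        [Basecall("A", 40, 19), Basecall("A", 40, 20)],
        [Basecall("A", 40, None)],  # absent map quality passes the gate
        [Basecall("A", 40, 37)],
    ])
    gated, reason = gate_column(col, CFG)
    assert reason is None
    assert gated.cov_per_library == [1, 1, 1, 1]


def test_gate_stars_and_indels_cover_but_never_vote():
    col = PileupColumn("c", 1, "A", [
        [Basecall("*", 40, 37), Basecall("A", 40, 37)],
        [Basecall("A", 40, 37, indel="+AT"), Basecall("A", 40, 37)],
        [Basecall("A", 40, 37)],
        [Basecall("A", 40, 37)],
    ])
    gated, reason = gate_column(col, CFG)
    assert reason is None
    assert gated.cov_per_library == [2, 2, 1, 1]
    assert gated.bases_per_library == [["A"], ["A"], ["A"], ["A"]]


def test_gate_library_count_mismatch_raises():
    with pytest.raises(ValueError, match="libraries"):
        gate_column(_col([["A"], ["A"]]), CFG)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_single_allele_hom_ref_and_hom_snp():
    gated = _gated([["A", "A"], ["A"], ["A"], ["A"]], ref="A")
    assert classify_position(gated, "A", CFG).classification == "hom_ref"
    gated = _gated([["G", "G"], ["G"], ["G"], ["G"]], ref="A")
    assert classify_position(gated, "A", CFG).classification == "hom_snp"


def test_minor_in_multiple_libraries_het_vs_hom_rule():
    # 8 A + 2 G across two libraries: minor fraction 0.2 -> het
    gated = _gated([["A"] * 4 + ["G"], ["A"] * 4 + ["G"], ["A"], ["A"]])
    assert classify_position(gated, "A", CFG).classification == "het"
    # 97 A + 3 G across two libraries: fraction 0.03 -> hom by majority
    gated = _gated(
        [["A"] * 47 + ["G"], ["A"] * 48 + ["G", "G"], ["A"], ["A"]]
    )
    assert (
        classify_position(gated, "A", CFG).classification == "hom_by_minor_rule"
    )


def test_minor_fraction_exactly_at_threshold_is_het():
    # 18 A + 2 G = fraction exactly 0.10
    gated = _gated([["A"] * 8 + ["G"], ["A"] * 8 + ["G"], ["A"], ["A"]])
    assert classify_position(gated, "A", CFG).classification == "het"


def test_minor_private_to_one_library_routes_to_detection():
    gated = _gated([["A"], ["A"], ["G", "G"], ["A"]])
    call = classify_position(gated, "A", CFG)
    assert call.classification is None and call.routed_to_candidate


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def test_hom_candidate_pure_focal_calls():
    gated = _gated([["A", "A"], ["G", "G", "G"], ["A"], ["A"]])
    cand, reason = detect_candidate(gated, CFG, LIBS)
    assert reason is None
    assert (cand.library, cand.zygosity, cand.support) == ("T1", "hom", 3)
    assert (cand.wt_base, cand.mut_base) == ("A", "G")


def test_het_candidate_needs_five_calls_beside_wild_type():
    gated = _gated([["A"] * 2, ["G"] * 5 + ["A"] * 4, ["A"], ["A"]])
    cand, reason = detect_candidate(gated, CFG, LIBS)
    assert reason is None
    assert (cand.zygosity, cand.support) == ("het", 5)
    # four mutant calls beside wild type: below the het threshold
    gated = _gated([["A"] * 2, ["G"] * 4 + ["A"] * 4, ["A"], ["A"]])
    assert detect_candidate(gated, CFG, LIBS) == (None, "insufficient_support")


def test_single_pure_call_is_insufficient():
    gated = _gated([["A"], ["G"], ["A"], ["A"]])
    assert detect_candidate(gated, CFG, LIBS) == (None, "insufficient_support")


def test_minor_shared_between_libraries_rejected():
    gated = _gated([["A", "G"], ["G", "A"], ["A"], ["A"]])
    assert detect_candidate(gated, CFG, LIBS) == (
        None, "minor_in_multiple_libraries"
    )


def test_three_alleles_single_singleton_peeled_then_called():
    # T is a lone singleton (likely error); peel it, then call the G hom
    gated = _gated([["A", "A", "T"], ["G", "G"], ["A"], ["A"]])
    cand, reason = detect_candidate(gated, CFG, LIBS)
    assert reason is None
    assert (cand.mut_base, cand.zygosity) == ("G", "hom")


def test_three_alleles_two_singletons_ignored():
    gated = _gated([["A", "A", "T"], ["G"], ["A"], ["A"]])
    assert detect_candidate(gated, CFG, LIBS) == (None, "ignored_singletons")


def test_three_alleles_all_replicated_is_ambiguous():
    gated = _gated([["A", "A"], ["G", "G"], ["T", "T"], ["A"]])
    assert detect_candidate(gated, CFG, LIBS) == (None, "ambiguous")
    call, cand, reason = evaluate_position(gated, CFG, LIBS)
    assert cand is None and call.classification == "ambiguous"


def test_wild_type_is_majority_of_other_libraries():
    # reference says T but the other libraries vote A: wild type is A
    gated = _gated([["A", "A"], ["G", "G"], ["A"], ["A"]], ref="T")
    cand, reason = detect_candidate(gated, CFG, LIBS)
    assert reason is None and cand.wt_base == "A"


# ---------------------------------------------------------------------------
# detectability model and rates
# ---------------------------------------------------------------------------

def test_het_detection_prob_reference_values():
    assert het_detection_prob(10, 5) == 0.623046875
    assert het_detection_prob(3, 3) == 0.125
    assert het_detection_prob(4, 5) == 0.0
    assert het_detection_prob(0, 0) == 1.0
    with pytest.raises(ValueError):
        het_detection_prob(-1, 5)


def test_het_detection_prob_matches_scipy_and_monotone():
    last = 0.0
    for cov in range(5, 40):
        p = het_detection_prob(cov, 5)
        assert p == pytest.approx(binom.sf(4, cov, 0.5), abs=1e-12)
        assert p >= last
        last = p


def test_mutation_density_arithmetic():
    est = mutation_density("T1", "hom", 4, 2_000_000, 1_000_000)
    assert est.density_per_mb_raw == pytest.approx(2.0)
    assert est.density_per_mb_adjusted == pytest.approx(4.0)
    empty = mutation_density("T1", "het", 0, 0, 0.0)
    assert empty.density_per_mb_raw is None
    assert empty.density_per_mb_adjusted is None


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def test_change_class_strand_collapse():
    assert change_class("G", "A") == change_class("C", "T") == "GC>AT"
    assert change_class("A", "G") == change_class("T", "C") == "AT>GC"
    assert change_class("G", "T") == "GC>TA"
    covered = {change_class(a, b) for a in "ACGT" for b in "ACGT" if a != b}
    assert covered == set(CHANGE_CLASSES)
    with pytest.raises(ValueError):
        change_class("A", "A")


def test_build_spectrum_partitions_by_library_and_zygosity():
    cands = [
        MutationCandidate("c", 1, "G", "A", "hom", "T1", 3),
        MutationCandidate("c", 2, "C", "T", "hom", "T1", 2),
        MutationCandidate("c", 3, "A", "T", "het", "T2", 5),
    ]
    table = build_spectrum(cands)
    assert table.total() == 3
    assert table.by_class(library="T1") == {"GC>AT": 2}
    assert table.by_class(zygosity="het") == {"AT>TA": 1}
    assert table.by_class() == {"GC>AT": 2, "AT>TA": 1}


def test_spectrum_test_reference_cases():
    p, frac = spectrum_test(59, 41)
    assert frac == pytest.approx(0.59)
    assert p == pytest.approx(1.0, abs=0.1)
    p, frac = spectrum_test(100, 0)
    assert frac == 1.0 and p < 1e-6
    assert spectrum_test(0, 0) == (None, None)
    p_f, _ = spectrum_test(100, 0, method="fisher")
    assert p_f < 1e-6
    with pytest.raises(ValueError):
        spectrum_test(-1, 0)
    with pytest.raises(ValueError):
        spectrum_test(1, 1, method="bogus")


# ---------------------------------------------------------------------------
# streaming driver
# ---------------------------------------------------------------------------

def test_call_pileup_tallies_and_assayed_accounting():
    cols = [
        _col([["A"] * 3, ["A"] * 3, ["A"] * 3, ["A"] * 3], pos=1),  # hom_ref
        _col([["A"] * 3, ["G"] * 3, ["A"] * 3, ["A"] * 3], pos=2),  # hom cand
        _col([["A"] * 3, ["A"] * 3, [], ["A"] * 3], pos=3),  # gate discard
        _col([["A"] * 40, ["A"] * 40, ["A"] * 40, ["A"] * 40], pos=4),
        _col([["A"] * 51, ["A"] * 50, ["A"] * 50, ["A"] * 50], pos=5),  # over
    ]
    res = call_pileup(cols, CFG, LIBS)
    assert res.n_columns == 5 and res.n_gated == 3
    assert res.discard_tally == {"not_all_covered": 1, "over_covered": 1}
    assert res.classification_tally["hom_ref"] == 2
    (cand,) = res.candidates
    assert (cand.library, cand.pos, cand.zygosity) == ("T1", 2, "hom")
    # assayed bases: three gated columns, every library covered >= 2
    for lib in LIBS:
        assert res.assayed_hom[lib] == 3
        assert res.assayed_het_raw[lib] == 3
        # coverage 3 twice (weight P[Bin(3,.5) >= 5] = 0) and 60 once (1.0)
        assert res.assayed_het_adjusted[lib] == pytest.approx(1.0)
    rates = res.rates()
    t1_hom = next(r for r in rates if (r.library, r.zygosity) == ("T1", "hom"))
    assert t1_hom.n_mutations == 1
    assert t1_hom.density_per_mb_raw == pytest.approx(1 / 3e-6)


def test_call_pileup_collect_coverage_arrays():
    cols = [
        _col([["A"], ["A", "A"], ["A"], ["A"]], contig="k1", pos=2),
        _col([["A"], ["A"], ["A"], ["A"]], contig="k1", pos=5),
    ]
    res = call_pileup(
        cols, CFG, LIBS, collect_coverage=True, target_lengths={"k1": 6}
    )
    arr = res.coverage_by_target["k1"]
    assert arr.shape == (4, 6)
    assert arr[1, 1] == 2 and arr[0, 4] == 1
    assert arr[:, 0].sum() == 0  # uncovered positions stay zero


# ---------------------------------------------------------------------------
# referenced vs de novo comparison
# ---------------------------------------------------------------------------

def test_compare_mutation_sets_strand_aware_projection():
    from rescan.io_formats import SeqRecord, revcomp

    rng = random.Random(0)
    seq = "".join(rng.choice("ACGT") for _ in range(400))
    genome = [SeqRecord("c1", seq)]
    fwd_km = seq[100:170]
    rev_km = revcomp(seq[200:270])
    kmer_seqs = {"kF": fwd_km, "kR": rev_km, "kGone": "N" * 70}
    denovo = [
        # position 11 (1-based) in the forward k-mer -> genome 110
        MutationCandidate("kF", 11, fwd_km[10], "A" if fwd_km[10] != "A" else "G",
                          "hom", "T1", 3),
        # position 1 in the reverse k-mer -> genome 269, complemented bases
        MutationCandidate("kR", 1, rev_km[0], "A" if rev_km[0] != "A" else "G",
                          "hom", "T2", 2),
        MutationCandidate("kGone", 5, "A", "G", "hom", "T3", 2),
    ]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    referenced = [
        MutationCandidate("c1", 111, denovo[0].wt_base, denovo[0].mut_base,
                          "hom", "T1", 3),
        MutationCandidate("c1", 270, comp[denovo[1].wt_base],
                          comp[denovo[1].mut_base], "hom", "T2", 2),
        MutationCandidate("c1", 50, "G", "A", "hom", "T3", 2),
    ]
    report = compare_mutation_sets(denovo, kmer_seqs, genome, referenced)
    assert report.n_unmappable_kmers == 1
    assert report.totals() == {
        "shared": 2, "referenced_only": 1, "denovo_only": 0,
    }


def test_compare_mutation_sets_empty_inputs():
    report = compare_mutation_sets([], {}, [], [])
    assert report.totals() == {
        "shared": 0, "referenced_only": 0, "denovo_only": 0,
    }
    assert report.n_unmappable_kmers == 0
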