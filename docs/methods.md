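# Methods

## Phased-read geometry

A type II restriction enzyme with palindromic site `S` (length `L`) and cut
offset `c` produces fragments whose ends, after overhang fill-in and adapter
ligation, are sequenced starting at a fixed offset inside the recognition
site: `r = min(c, L - c)` bases in (`Enzyme.read_start_within_site`). For a
5'-overhang cutter such as MseI (T^TAA, `r = 1`) reads begin `TAA...`; for a
3'-overhang cutter such as NlaIII (CATG^, `r = 0`) the fill-in regenerates
the full site and reads begin `CATG...`. A fragment bounded by cuts at site
positions `ls` and `rs` therefore yields a double-stranded molecule spanning
`[ls + r, rs + L - r)`; forward reads run from its left end, reverse reads
(reverse-complemented) from its right end, truncating at the far end.
Contig-terminal fragment ends have no cut, no adapter and no reads. Both the
simulator and the read-start typer use this one geometry.

## K-mer pseudo-reference

Mutation discovery does not require a genome. The leading 70-mer of every
control-library read is collected; because reads are phased, genuine k-mers
recur at their locus coverage while sequencing-error k-mers are mostly
singletons. Curation:

1. **Repeat filter.** Control counts are modeled as a mixture of an error
   spike at 1, a single-copy Poisson bulk and a repeat tail. A robust
   Poisson mean is estimated from the histogram between its first valley and
   an upper guard, and k-mers above the `1 - 1e-4` Poisson quantile are
   flagged as repeat shadows (their pileups would superimpose paralogs).
2. **Hamming-1 pruning.** K-mer pairs at Hamming distance 1 (error echoes
   of each other, or alleles of one site) are found by the pigeonhole
   principle — two exact half-k-mer indexes — and the minority member of
   each pair (fewer pooled counts across all libraries; lexicographic
   tie-break) is flagged. Flags are computed against frozen counts in a
   single pass, so the result is independent of input order.

Survivors are exported as the pseudo-reference; its total length is the
assayed "complexity".

## Alignment

Reads are placed by their first 65 bases, allowing at most one substitution,
using the same pigeonhole trick: an exact hit on either 33/32-base half
yields every candidate placement, each verified by direct comparison on
both strands. A unique best placement is kept; ties are discarded as
multi-mapping; a constant mapping quality of 37 marks confidently placed
reads. Pileup columns carry per-library basecall lists with base and
mapping qualities.

## Mutation calling

One control and `n-1` treated individuals are compared per position. The
discriminating signal for an *induced* mutation is privacy: natural
polymorphism segregates in several individuals, an induced change is
private to one treated individual.

**Gating.** Basecalls below quality 20 (base or mapping) are dropped.
Positions are discarded when pooled post-gating coverage exceeds 200
(repeat shadow) or when any library has zero coverage (no cross-individual
comparison possible). Deleted-base and indel-anchored calls count toward
coverage but never vote as substitution alleles.

**Classification.** A single pooled allele gives `hom_ref`/`hom_snp`. With
two or more alleles, the least frequent allele (ties broken by fewest
libraries, then lexicographic) decides: seen in more than one library the
position is shared polymorphism — `het` when the minor fraction is at
least 10%, otherwise `hom_by_minor_rule` (the minority treated as noise);
seen in exactly one library the position becomes a mutation candidate.

**Candidate detection.** With more than two alleles, a lone least-frequent
singleton is peeled (sequencing error) and the rules re-applied; two or
more singletons make the position `ignored_singletons`; three alleles all
seen twice or more make it `ambiguous` and it is removed from analysis.
The wild-type base is the majority allele across the *other* libraries
(count then lexicographic tie-break) — not the reference base, which is the
only coherent definition for a reference-free run and is applied uniformly.
A homozygous candidate needs at least 2 mutant calls and *no* other call in
the focal library; a heterozygous candidate needs at least 5 mutant calls
beside other calls.

**Density estimation.** Rates are candidates per megabase of assayed
sequence. A position is hom-assayed for a library when gated and covered at
least twice there. Every gated position is het-assayed, but low coverage
can hide a heterozygote: with coverage `c`, the mutant allele reaches the
5-call threshold with probability `P(X >= 5), X ~ Binomial(c, 1/2)`
(`het_detection_prob`; 0.62 at coverage 10). Below coverage 15 the het
denominator accrues this probability instead of 1, correcting the density
upward honestly rather than inflating the numerator.

**Spectrum test.** Candidates are tallied into six strand-collapsed
substitution classes. The GC>AT fraction is tested (exact binomial,
optionally Fisher) against 0.59 — the fraction expected from sequencing
error alone — so rejection upward indicates a mutagen-shaped spectrum.

## Read-start (Type I) typing

Against a reference genome, the *position* of a read start is itself
evidence. Reconstructing the expected recognition window `r` bases before
each placed read start and comparing it to the reference classifies starts
as `full_site`, `proto_site` (Hamming distance 1 — a near-site) or
`off_site`. A proto-site start means either relaxed-specificity "star"
cutting or a sample SNP completing the site. When the divergent position
falls inside the read, the read's own base arbitrates (site base:
confirming; reference proto base: star). When it falls *before* the read
start — e.g. a GTAA proto under MseI, whose divergence is at window index
0 while reads begin at index 1 — no read base can speak to it, and the
start position alone is taken as evidence; star cutting is rare enough
(measured here as the star rate among determinate reads) that such starts
are treated as site-consistent.

SNP inference from a proto site is only unequivocal when a single
substitution explains the cut. Because alternative site-creating
substitutions in windows overlapping the proto window shift the cut by
less than one site length — below the positional resolution of 1-2-read
evidence — *every* site-creating substitution whose window overlaps the
proto window is a candidate: one candidate gives an `inferred` call
(GTAA: T>G on the reference orientation, reported reference→sample), more
than one gives `ambiguous` (TTTAG: T3>A and G5>A both create TTAA).

## Simulator

`rescan.simulate` generates an i.i.d. genome at a chosen GC content,
applies per-individual Poisson mutagenesis (sites drawn uniformly over
bases eligible for the drawn spectrum class; heterozygous changes land on
one random haplotype), digests each haplotype, size-selects, and emits
Poisson-depth phased reads with per-base substitution errors, inline
barcodes and flat qualities, pooled and shuffled as a multiplexed lane.
The truth list enables end-to-end audits: the validation suite compares
recovered homozygous-mutation counts per library against the truth
*realized in the assayed footprint* (gated positions, k-mers mapped back
to the founder digest, multi-locus k-mers excluded), since on desk-scale
genomes absolute mutation counts are single digits and comparison against
the implanted rate would measure Poisson placement noise, not pipeline
error. MseI is used for that audit because its AT-only site cannot be
destroyed by the GC>AT spectrum, so mutations never silently erase their
own footprint (site *creation* remains possible and is absorbed by using
realized coverage).

## Limitations

* Substitutions only: the aligner allows no gaps, and indel pileup marks
  gate coverage but are never called.
* The pseudo-reference assays only the first 65 bases behind each phased
  fragment end that survives curation; densities are per assayed megabase,
  not per genome megabase.
* With very few libraries the privacy rule loses its anchor (the wild type
  is defined by the other libraries' majority); the intended design is one
  control plus several treated individuals.
* The repeat filter assumes a unimodal single-copy coverage bulk; highly
  skewed coverage distributions would need the fixed-cutoff mode.
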