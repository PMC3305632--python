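# rescan

Reference-free discovery of rare induced point mutations from
restriction-enzyme-phased reduced-representation sequencing.

A genome digested with a frequent 4-base cutter (MseI, NlaIII) and
size-selected yields libraries whose reads all start at restriction sites
("phased" reads). This package implements the complete analysis for such
libraries:

* **in silico digestion** and fragment-size accounting (`rescan digest`);
* **demultiplexing** of inline-barcoded pooled lanes (`rescan demux`);
* a **k-mer pseudo-reference** built from the control individual's read
  starts — repeat- and near-duplicate-curated — so mutation discovery needs
  no genome at all (`rescan build-ref`);
* a phased-read **aligner** producing multi-library pileups
  (`rescan align`);
* a multi-individual **mutation caller** that separates induced mutations
  (private to one treated individual) from shared natural polymorphism,
  with binomially-corrected per-megabase density estimates and a mutation
  spectrum test (`rescan call`);
* **read-start (Type I) typing**: SNPs that *create* a restriction site are
  inferred from where reads begin, even at 1-2 read coverage
  (`rescan type1`);
* a full generative **simulator** of the experiment for validation
  (`rescan simulate`).

## Worked example

Simulate a four-individual experiment (one untreated control, three
escalating mutagen doses, GC>AT mutation spectrum) on a 300 kb genome,
then recover the mutations without ever showing the pipeline that genome.

```
$ cat sim.json
{
  "genome_len": 300000,
  "enzyme": "MseI",
  "size_window": [70, 700],
  "per_end_depth": 14.0,
  "seed": 42,
  "libraries": {
    "control": ["ATCAC", 0.0],
    "T1": ["CTCTC", 30.0],
    "T2": ["CGAAT", 60.0],
    "T3": ["GAGCA", 90.0]
  }
}

$ rescan simulate --config sim.json --out-dir sim
131598 reads, 44 mutations, 300000 genome bases -> sim
```

Demultiplex the pooled lane by its 5-base inline barcodes:

```
$ printf 'library\tbarcode\ncontrol\tATCAC\nT1\tCTCTC\nT2\tCGAAT\nT3\tGAGCA\n' > barcodes.tsv
$ rescan demux --fastq sim/pooled.fastq --barcodes barcodes.tsv --out-dir demuxed
control 32894
T1      32840
T2      32684
T3      33180
unassigned      0
```

Build the pseudo-reference from the control library and align everyone:

```
$ rescan build-ref --control demuxed/control.fastq \
    --samples demuxed/T1.fastq --samples demuxed/T2.fastq --samples demuxed/T3.fastq \
    --out ref.fasta --stats stats.tsv
2436 k-mers exported (170520 bases)

$ rescan align --ref ref.fasta \
    --fastq demuxed/control.fastq --fastq demuxed/T1.fastq \
    --fastq demuxed/T2.fastq --fastq demuxed/T3.fastq --out all.pileup
control 32893 placed
...
```

Call mutations:

```
$ rescan call --pileup all.pileup --libraries control,T1,T2,T3 \
    --control control --mode denovo \
    --out candidates.tsv --spectrum spectrum.tsv --rates rates.tsv
denovo: 152945/158340 positions gated in, 16 candidates

$ head -5 candidates.tsv
contig  pos  wt  mut  zygosity  library  support  class
kmer_000018|count=15  44  C  T  het  T2  5   GC>AT
kmer_000707|count=14  27  C  T  het  T3  13  GC>AT
kmer_000714|count=19  9   C  T  het  T2  12  GC>AT
kmer_000821|count=17  6   G  A  het  T3  8   GC>AT
```

Every candidate is a GC>AT transition, none is attributed to the control,
and the per-megabase rate table reflects the dose escalation (`rates.tsv`:
the `per_mb_adjusted` column divides by *assayed* bases, with heterozygous
denominators corrected for binomial allele sampling at low coverage):

```
library  zygosity  n  assayed_raw  assayed_adjusted  per_mb_raw  per_mb_adjusted
control  hom       0  152945.0     152945.0          0.0000      0.0000
control  het       0  152945.0     127871.8          0.0000      0.0000
T1       het       1  152945.0     127664.0          6.5383      7.8331
T2       het       8  152945.0     127603.2          52.3064     62.6943
T3       het       2  152945.0     129169.0          13.0766     15.4836
...
```

When a reference genome *is* available, `rescan type1` additionally infers
SNPs that create restriction sites from read start positions alone, and
`rescan digest` reports the fragment landscape an enzyme/size-window choice
would sample.

## Library use

Every CLI stage is a thin wrapper over an importable module
(`rescan.insilico_digest`, `rescan.demux`, `rescan.kmer_reference`,
`rescan.align_lite`, `rescan.type1_typing`, `rescan.mutation_caller`,
`rescan.simulate`, with orchestration in `rescan.pipeline`). See
`docs/methods.md` for the underlying model and calling rules.
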