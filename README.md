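# asmpipe

Tools for the computational backbone of a long-read fish genome project:
k-mer-spectrum profiling of genome size and heterozygosity, assembly QC
statistics, reference-guided scaffolding from whole-genome alignment
tables, contig end-overlap gap closure, tandem-repeat/telomere array
scanning, and pseudo-scaffold chaining for supernumerary (B) chromosome
reads.  A first-class synthetic-data generator produces diploid genomes,
reads, fragmented assemblies, markers and rearranged reference genomes
with full ground truth, so the entire pipeline is testable without any
external data.

The intended users are genome-assembly practitioners who have run the
heavy external steps (read mapping, whole-genome alignment, BLAST) and
need the downstream analysis: fitting the spectrum model, filtering and
anchoring, ordering contigs, closing gaps, and summarizing.

## The k-mer spectrum model

Counting canonical k-mers (k = 21) of a shotgun read set from a diploid
individual gives a multiplicity spectrum K(x).  Heterozygous k-mers occur
on a single haplotype and peak at half the coverage of homozygous
k-mers, so the spectrum above the error-noise cutoff is modelled as a
two-component negative-binomial mixture

    K(x) = s1 · NB(x; μ, size1) + s2 · NB(x; 2μ, size2)

with component means μ and exactly 2μ, dispersions size1/size2
(Var = m + m²/size) and non-negative scale factors s1, s2.  The fitted
component densities, summed over the fitted range, give the numbers of
heterozygous (H) and homozygous (D) non-repetitive k-mers, from which

    heterozygosity rate = (H / 2k) / (H/2 + D)

(H is halved for haploid content and divided by k because one
heterozygous base yields k heterozygous k-mers).  H/2 + D is the
non-repetitive haploid genome size; dividing all k-mer observations
above the cutoff by 2μ estimates the total size, repeats included.

The scaffolding layer chains 1:1-filtered alignments into collinear
synteny blocks (two passes, discarding spurious blocks shorter than
6 kb between passes), orders and orients contigs by their dominant block
placement, reconciles the implied contig links against independent
partial orders (optical-map style) and linkage-group assignments, and
emits scaffolds as FASTA + AGP.  Gap closure then finds +/+
end-of-contig to start-of-contig overlaps (≥95% identity) and merges
neighbours by trimming the left copy and concatenating the right.

## Worked example

```python
from asmpipe import simdata, kmer_model

genome = simdata.simulate_diploid(1, 1_000_000, het_rate=0.004, seed=1)
reads = simdata.simulate_reads(genome, coverage=36, read_length=100,
                               error_rate=0.005, seed=2)
hist = kmer_model.count_kmers(reads, k=21)
fit = kmer_model.fit_mixture(hist)
H, D = kmer_model.component_sums(fit, hist)
est = kmer_model.heterozygosity(H, D, k=21)
nonrep, total = kmer_model.genome_size(fit, hist)
print(f"mu={fit.mu:.2f}  H={H:,.0f}  D={D:,.0f}")
print(f"heterozygosity={est.rate:.5f}  genome size={total:,.0f} bp")
```

prints

```
mu=12.97  H=161,649  D=919,472
heterozygosity=0.00385  genome size=999,904 bp
```

The heterozygous peak lands at μ ≈ 13× — half the 26× effective
homozygous k-mer coverage (36× base coverage shrunk by the read-edge
factor 80/100 and by the 0.5% error rate per 21-mer) — and the planted
0.4% heterozygosity and 1 Mb haploid size are both recovered within a
few percent.  On the published component sums of the sequenced seabass
individual (H = 96,126,339 and D = 491,559,122 at k = 21) the same
formula gives 0.0042 (0.42%), inside the published 0.4–0.5% band, with a
non-repetitive genome size of 539.6 Mb.

The full synthetic pipeline (simulate → profile → stats → anchor →
synteny → scaffold → gapclose → repeatscan → chain) runs as

```sh
asmpipe pipeline --seed 1 --outdir out/
```

writing every stage product plus a JSON-lines manifest; identical seeds
reproduce byte-identical bundles.  Each stage is also available as its
own subcommand (`asmpipe profile --hist spectrum.tsv`, `asmpipe gapclose
layout.agp contigs.fasta`, ...) over the standard formats (FASTA/FASTQ,
PAF or 12-column tabular alignments, AGP v2.1, BED, TSV).

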