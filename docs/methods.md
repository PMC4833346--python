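# Methods

## Spectrum mixture model

Canonical k-mer counting collapses each k-mer with its reverse
complement (k odd, 3–31, 2-bit encoded in 64-bit words; windows
containing N are skipped).  The multiplicity spectrum of a diploid read
set is modelled above an error cutoff as

    K(x) = s1·NB(x; mean=μ, size=size1) + s2·NB(x; mean=2μ, size=size2)

The component means are tied at μ and exactly 2μ: a k-mer overlapping a
heterozygous site exists on one haplotype and is sequenced at half the
depth of a homozygous k-mer.  The negative binomial generalizes the
Poisson sampling of read starts with an overdispersion parameter
(Var = m + m²/size).  s1 and s2 are free non-negative scale factors;
their component sums over the fitted range are the heterozygous (H) and
homozygous (D) non-repetitive k-mer counts, and

    rate = (H/2k) / (H/2 + D),   non-repetitive size = H/2 + D,
    total size = Σ_{x≥cutoff} x·K_obs(x) / 2μ.

The rate divides by k because one heterozygous base creates k distinct
heterozygous k-mers; variants closer than k bases are undercounted, so
the estimate is a mild lower bound and is reported as a range in
practice.

### Fitting

* **Fit range.**  The lower cutoff defaults to the first local minimum
  of the window-3 smoothed spectrum *before* its main peak (floor 3),
  i.e. the trough between sequencing-error noise and the signal; it is
  user-overridable.  The upper bound defaults to 4× the initial peak
  guess, excluding repetitive k-mers that the two-component model does
  not describe (their mass still enters the total-size estimator).
* **Initialization.**  The spectrum argmax is either the heterozygous or
  the homozygous peak.  At moderate coverage the heterozygous bump can
  be a mere shoulder on the homozygous flank (no detectable local
  maximum), so both hypotheses (μ₀ = argmax and μ₀ = argmax/2) are
  always started deterministically; up to five additional jittered
  restarts run only if neither leaves a near-zero residual.  Given shape
  parameters, the optimal scales are obtained by non-negative least
  squares (the model is linear in s1, s2), which makes starts cheap and
  stable.
* **Optimization.**  Trust-region least squares on
  (μ, log size1, log size2, s1, s2) with bounds μ ∈ (cutoff, max_x),
  sizes ∈ [10⁻², 10⁴], s ≥ 0; tolerances 10⁻⁸, ≤2500 function
  evaluations per start.  The best residual across starts wins and is
  never worse than its own starting point.  Non-convergence raises an
  explicit error naming the last residual.
* **Degenerate spectra.**  If the converged fit places >95% of its mass
  in component 1, the implied heterozygosity would approach 1/k —
  impossible for a diploid — so the single peak is reinterpreted as the
  homozygous component (μ ← μ/2, masses swapped, s1 = 0) and the fit is
  flagged degenerate.  This is the expected pathway for fully
  homozygous input.

## Synthetic data generator

The generator emulates the data of a heterozygous fish genome project:

* **Diploid genome** — i.i.d. ACGT chromosomes; haplotype B differs by
  SNPs placed uniformly at a Binomial(L, het) count (default het 0.004,
  matching the 0.4–0.5% regime of wild-caught broodstock); optional
  minimum SNP spacing; optional planted exact tandem arrays (e.g.
  telomeric (TTAGGG)n).  No indels: the spectrum model interprets
  heterozygosity as SNPs, and indel support is an extension.
* **Reads** — fixed-length substitution-error reads drawn uniformly
  from both haplotypes and strands; total bases equal coverage × haploid
  length to within one read.  Defaults: 100 bp, 0.5% error, 30× (the
  short-read regime of 30–90× projects).  No indel or quality-score
  realism; k-mer analyses are insensitive to both.
* **Fragmented assembly** — each chromosome is cut at jittered
  evenly-spaced breakpoints (contig sizes within ~±20% of nominal, like
  the megabase-contig assemblies this emulates — no sliver contigs),
  with a planted end-overlap (default 200–500 bp) duplicated across
  every junction and optional orientation flips.  Trimming overlaps and
  concatenating in layout order reconstructs the source byte-for-byte.
* **Related reference** — per-chromosome inversions (reverse-complement
  of a ≥10 kb segment) and balanced translocations (segment swaps
  between chromosomes), then uniform point divergence.  The true
  collinear-block map is emitted alongside.
* **Alignment tables** — contig-vs-reference local alignments are
  derived from the truth by composing contig placements with the block
  map and chopping into ~8 kb pieces; identity is set by the planted
  divergence.  This reproduces what an external whole-genome aligner
  would emit, minus alignment noise — running the aligners themselves
  is out of scope, so passing tests demonstrate correct *block and
  ordering logic*, not robustness to aligner artefacts.
* **Markers** — exact substrings of contig interiors labelled with
  their source chromosome as linkage group; negative controls carry 15%
  substitutions, placing them below the 90% identity filter.

Synthetic sequences are i.i.d. uniform ACGT; real genomes have GC
structure, repeats and indel polymorphism that these tests deliberately
do not cover.

## Scaffolding layer

* **1:1 filtering** keeps alignments greedily by descending score and
  drops any alignment overlapping a retained one on either genome
  (drop, not trim: this guarantees coverage depth ≤1 exactly and is
  verified against a brute-force oracle).
* **Block chaining** groups alignments by (query, target, orientation),
  chains runs monotone in both genomes with gaps ≤ max_gap (default
  50 kb; configurable — alignment tables are dense enough that results
  are insensitive within 10–100 kb), discards blocks spanning <6000 bp
  on the query (exactly 6000 is retained), and re-chains so flanking
  runs merge across removed spurious blocks.
* **Rearrangement census**: per query chromosome, the dominant target
  and orientation are the span majority; blocks inverted relative to the
  dominant orientation or outside a longest-in-order subsequence of
  target midpoints count as intrachromosomal rearrangements when they
  span more than the threshold (default 200 kb).
* **Contig ordering**: a contig is placed on the chromosome holding the
  largest summed block span if that strictly exceeds 60% of its total
  span (an exact 60/40 split across two chromosomes is reported as
  ambiguous, not placed); position is the span-weighted mean target
  midpoint, orientation the span majority.
* **Link reconciliation** rejects links joining contigs that an
  independent partial order (e.g. an optical-map contig sequence) holds
  non-adjacent, links joining different linkage groups, and second uses
  of a contig end; a link that would close a cycle is an error.
  Two-reference operation is supported by reconciling one ordering
  against the other's as a constraint.
* **Scaffold emission** joins oriented contigs with N-runs (default
  100 N) and writes AGP v2.1 (1-based inclusive on disk; all internal
  coordinates are 0-based half-open).

## Gap closure

Neighbouring contigs are orientation-normalized; only suffix(left) →
prefix(right) (+/+) overlaps qualify.  Candidate overlap lengths come
from exact 24-mer seeds along the right contig's prefix located in the
left contig's terminal window (default 10 kb); each candidate is
verified position-wise and the longest with ≥95% identity and ≥100 bp
(both configurable; only the identity bar is externally prescribed)
wins.  Closure trims the overlap from the left contig and concatenates
the right, so mismatched overlap bases resolve to the right contig's
copy; merges propagate transitively along a scaffold, and the report
carries gaps-closed fraction and N50 before/after.  Externally computed
overlap tables in the common alignment dialects may be substituted for
the built-in detector.

## Repeat scanning and read chaining

Monomer scanning is exact (mismatch-tolerant scanning is out of scope);
self-overlapping monomers match at every offset and are de-overlapped
leftmost-greedily during array chaining.  Runs spaced exactly one
monomer apart are perfect arrays; spacings up to max_spacer form
interrupted "trains" (default max_spacer 0, min_copies 2 — both
exposed, as observed satellite organizations vary).  Density profiles
count occurrences in non-overlapping windows.

B-chromosome-style read placements are merged per target across gaps
strictly smaller than 10 kb (sort-then-merge, order independent), and
pseudo-scaffold *spans* — not summed read bases — are totalled per
linkage group, with an explicit unassigned bucket.

## QC statistics

Nx/Lx by descending cumulative length; GC windows are non-overlapping
20 kb tiles (stride configurable) discarding windows with >25% N and
computing GC over non-N bases; clone-end pairs classify as proper when
both ends hit one scaffold, convergently oriented, with outermost-
coordinate separation within the insert range (default 50–250 kb) —
mutually exclusive and exhaustive categories otherwise improper, split
or orphan.

## Problem sizes in the test suite

Parameter-recovery runs use twenty 1 Mb single-chromosome diploids at
36× (0.5% error); scaffolding recovery uses ten 500 kb chromosomes at
twenty contigs each with a 2%-diverged reference, and the inversion
census plants three 250 kb inversions; gap closure uses four 120 kb
chromosomes at eight contigs each.  These sizes make every property
sharp (binomial spreads of a few percent) while keeping the whole suite
a desk-scale run.

## Known limitations

The total-genome-size estimator assumes the spectrum above the cutoff is
dominated by the two diploid components plus repeats at multiples of μ;
heavily contaminated or polyploid spectra need more components.  The
mixture carries no explicit repeat component — repetitive mass is
excluded from the fit range rather than modelled.  Marker anchoring
counts the single best local alignment per hit as its coverage (summed
HSP coverage is not implemented).  The gap-closure seed scheme requires
one exact 24-mer inside the true overlap; overlaps with dense (>~4%)
uniformly spread mismatches can escape detection even above the identity
bar.
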