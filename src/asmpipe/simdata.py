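"""Synthetic diploid genomes, reads, fragmented assemblies and related
ground truth.

The generator emulates the data types a heterozygous fish genome project
produces: a diploid individual with SNP heterozygosity around 0.4-0.5%,
shotgun reads at tens-fold coverage, an assembly fragmented into contigs
whose neighbouring ends share planted overlaps, linkage-map markers drawn
from known chromosomes, and a rearranged related reference genome with a
known collinear-block map.  Every operation is deterministic for a fixed
seed and records the ground truth needed to score downstream inference.

Coordinates are 0-based half-open throughout.  Only SNPs (no indels)
separate the two haplotypes, matching the SNP-centric interpretation of
k-mer heterozygosity; simulated sequences use the ACGT alphabet only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AlignmentRecord
from .seq import decode, encode, revcomp, random_sequence

__all__ = [
    "DiploidGenome", "TruthLayout", "BlockTruth", "MarkerTruth",
    "simulate_diploid", "simulate_reads", "fragment_assembly",
    "mutate_reference", "simulate_markers", "simulate_alignments",
    "simulate_marker_hits",
]


@dataclass
class DiploidGenome:
    """Two haplotypes per chromosome plus the planted-variant truth."""

    haplotype_a: dict[str, str]
    haplotype_b: dict[str, str]
    truth_snps: list[tuple[str, int, str, str]]
    het_rate: float
    repeat_tracks: list[tuple[str, int, str, int]] = field(default_factory=list)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.haplotype_a)

    @property
    def haploid_length(self) -> int:
        return sum(len(s) for s in self.haplotype_a.values())


@dataclass
class TruthLayout:
    """Ground truth of a fragmented assembly.

    ``contig_order`` maps each source chromosome to its ordered list of
    (contig_id, orientation, start, end) placements; consecutive contigs
    overlap by the planted amounts in ``planted_overlaps``.
    """

    contig_order: dict[str, list[tuple[str, str, int, int]]]
    planted_overlaps: list[tuple[str, str, int]]
    marker_truth: list["MarkerTruth"] = field(default_factory=list)

    def adjacencies(self) -> list[tuple[str, str, str, str]]:
        """True neighbouring pairs as (left_id, left_orient, right_id, right_orient)."""
        out = []
        for placements in self.contig_order.values():
            for (a, oa, *_), (b, ob, *_) in zip(placements, placements[1:]):
                out.append((a, oa, b, ob))
        return out

    def contig_chrom(self) -> dict[str, str]:
        return {cid: chrom for chrom, pl in self.contig_order.items()
                for cid, *_ in pl}


@dataclass
class BlockTruth:
    """A maximal collinear segment between a genome and its mutated reference."""

    query_id: str
    qstart: int
    qend: int
    ref_id: str
    rstart: int
    rend: int
    orientation: str


@dataclass
class MarkerTruth:
    marker_id: str
    linkage_group: str
    contig_id: str
    offset: int       # position within the (oriented) contig sequence
    length: int
    mutated: bool = False


def simulate_diploid(n_chrom: int, chrom_length: int, het_rate: float = 0.004,
                     repeat_spec=None, seed: int = 0,
                     min_snp_spacing: int | None = None) -> DiploidGenome:
    """Simulate a diploid genome with uniformly placed SNPs.

    ``repeat_spec`` plants exact tandem arrays as (chrom, start, monomer,
    copies) tuples into both haplotypes.  ``min_snp_spacing`` optionally
    keeps SNPs at least that many bases apart.
    """
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1 kb")
    if not 0 <= het_rate <= 0.05:
        raise ValueError("het_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    hap_a: dict[str, str] = {}
    hap_b: dict[str, str] = {}
    snps: list[tuple[str, int, str, str]] = []
    tracks: list[tuple[str, int, str, int]] = []
    repeat_spec = list(repeat_spec or [])

    names = [f"chr{i + 1}" for i in range(n_chrom)]
    for name in names:
        arr = rng.integers(0, 4, size=chrom_length, dtype=np.uint8)
        for chrom, start, monomer, copies in repeat_spec:
            if chrom != name:
                continue
            unit = encode(monomer)
            if (unit >= 4).any():
                raise ValueError("repeat monomer must be over ACGT")
            total = len(unit) * copies
            if start < 0 or start + total > chrom_length:
                raise ValueError(
                    f"repeat array ({chrom}, start={start}, {len(unit)}bp x {copies}) "
                    f"exceeds chromosome length {chrom_length}")
            arr[start:start + total] = np.tile(unit, copies)
            tracks.append((chrom, start, monomer, copies))

        n_snps = rng.binomial(chrom_length, het_rate)
        pos = np.sort(rng.choice(chrom_length, size=n_snps, replace=False))
        if min_snp_spacing:
            keep = np.ones(len(pos), dtype=bool)
            last = -min_snp_spacing
            for i, p in enumerate(pos):
                if p - last < min_snp_spacing:
                    keep[i] = False
                else:
                    last = p
            pos = pos[keep]
        alt = (arr[pos] + rng.integers(1, 4, size=len(pos), dtype=np.uint8)) % 4
        brr = arr.copy()
        brr[pos] = alt
        hap_a[name] = decode(arr)
        hap_b[name] = decode(brr)
        snps.extend((name, int(p), decode(arr[p:p + 1]), decode(brr[p:p + 1]))
                    for p in pos)
    return DiploidGenome(hap_a, hap_b, snps, het_rate, tracks)


def simulate_reads(genome: DiploidGenome, coverage: float, read_length: int = 100,
                   error_rate: float = 0.0, seed: int = 0) -> list[tuple[str, str]]:
    """Sample error-prone substitution reads from both haplotypes.

    Total read bases equal ``coverage x haploid length`` (to within one
    read); haplotypes and strands are drawn uniformly.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    shortest = min((len(s) for s in genome.haplotype_a.values()), default=0)
    if coverage > 0 and read_length > shortest:
        raise ValueError("read_length exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    total_reads = int(round(coverage * genome.haploid_length / read_length))
    if total_reads == 0:
        return []

    chroms = genome.chromosomes
    lengths = np.array([len(genome.haplotype_a[c]) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=total_reads, p=lengths / lengths.sum())
    hap_idx = rng.integers(0, 2, size=total_reads)
    strand = rng.integers(0, 2, size=total_reads)

    reads: list[tuple[str, str]] = []
    serial = 0
    offsets = np.arange(read_length)
    for ci, chrom in enumerate(chroms):
        for hi, hap in enumerate((genome.haplotype_a, genome.haplotype_b)):
            sel = (chrom_idx == ci) & (hap_idx == hi)
            n = int(sel.sum())
            if n == 0:
                continue
            arr = encode(hap[chrom])
            starts = rng.integers(0, len(arr) - read_length + 1, size=n)
            mat = arr[starts[:, None] + offsets]
            if error_rate > 0:
                err = rng.random(mat.shape) < error_rate
                shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                mat[err] = (mat[err] + shift) % 4
            rc = strand[sel] == 1
            if rc.any():
                mat[rc] = 3 - mat[rc][:, ::-1]
            flat = decode(mat.reshape(-1))
            for j in range(n):
                reads.append((f"read_{serial}", flat[j * read_length:(j + 1) * read_length]))
                serial += 1
    return reads


def fragment_assembly(genome: DiploidGenome, n_breaks: int,
                      overlap_length_range: tuple[int, int] = (200, 500),
                      seed: int = 0, flip_fraction: float = 0.0
                      ) -> tuple[dict[str, str], TruthLayout]:
    """Break each chromosome (haplotype A) into contigs with planted
    end-to-start overlaps.

    Each break duplicates ``overlap`` bases: the left contig is extended
    past the breakpoint by the overlap so that trimming it and
    concatenating reconstructs the chromosome exactly.
    """
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    lo, hi = overlap_length_range
    if lo < 0 or hi < lo:
        raise ValueError("bad overlap_length_range")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    order: dict[str, list[tuple[str, str, int, int]]] = {}
    overlaps: list[tuple[str, str, int]] = []
    serial = 0
    for chrom, seq in genome.haplotype_a.items():
        L = len(seq)
        min_ctg = hi + 1
        if n_breaks > 0 and L < (n_breaks + 1) * (min_ctg + hi):
            raise ValueError(
                f"cannot place {n_breaks} breaks with overlaps up to {hi} bp "
                f"on a {L} bp chromosome")
        # jittered even spacing: contig sizes stay within ~±20% of the
        # nominal L/(n_breaks+1), as befits the large-contig assemblies
        # this emulates (no sliver contigs)
        spacing = L / (n_breaks + 1)
        jitter = rng.uniform(-0.2, 0.2, size=n_breaks) * spacing
        breaks = (spacing * np.arange(1, n_breaks + 1) + jitter).astype(np.int64)
        breaks = np.clip(breaks, min_ctg, L - min_ctg)
        if n_breaks and (np.any(np.diff(breaks) < min_ctg + hi)
                         or spacing < 2 * (min_ctg + hi)):
            raise ValueError("overlaps too long for the requested fragmentation")
        ovs = rng.integers(lo, hi + 1, size=n_breaks)
        bounds = [0, *breaks.tolist(), L]
        placements = []
        ids = []
        for i in range(n_breaks + 1):
            start = bounds[i]
            end = bounds[i + 1] + (int(ovs[i]) if i < n_breaks else 0)
            cid = f"ctg{serial:05d}"
            serial += 1
            orient = "+"
            piece = seq[start:end]
            if flip_fraction > 0 and rng.random() < flip_fraction:
                orient = "-"
                piece = revcomp(piece)
            contigs[cid] = piece
            placements.append((cid, orient, start, end))
            ids.append(cid)
        order[chrom] = placements
        overlaps.extend((ids[i], ids[i + 1], int(ovs[i])) for i in range(n_breaks))
    return contigs, TruthLayout(order, overlaps)


def mutate_reference(genome: DiploidGenome, n_inversions: int = 0,
                     n_translocations: int = 0, divergence: float = 0.0,
                     seed: int = 0, segment_length: int = 250_000
                     ) -> tuple[dict[str, str], list[BlockTruth]]:
    """Derive a rearranged, point-diverged related reference genome.

    Inversions reverse-complement disjoint ``segment_length`` segments
    (one per chromosome, >= 10 kb); translocations swap equal-length
    segments between chromosome pairs.  Returns the reference and the
    true collinear-block map (query = haplotype A coordinates).
    """
    if segment_length < 10_000 and (n_inversions or n_translocations):
        raise ValueError("rearranged segments must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    n_events = n_inversions + n_translocations
    eligible = [c for c in chroms if len(genome.haplotype_a[c]) >= segment_length + 20_000]
    if n_inversions > len(eligible) or n_translocations * 2 > len(eligible) - n_inversions:
        raise ValueError("requested rearrangements cannot be placed disjointly")

    ref = {c: encode(genome.haplotype_a[c]).copy() for c in chroms}
    # breakpoints per chromosome: list of (start, end, orientation, src_chrom, src_start)
    segments: dict[str, list[tuple[int, int, str, str, int]]] = {c: [] for c in chroms}

    picked = list(rng.permutation(eligible))
    for _ in range(n_inversions):
        c = picked.pop()
        L = len(ref[c])
        s = int(rng.integers(10_000, L - segment_length - 10_000 + 1))
        ref[c][s:s + segment_length] = (3 - ref[c][s:s + segment_length])[::-1]
        segments[c].append((s, s + segment_length, "-", c, s))
    for _ in range(n_translocations):
        c1, c2 = picked.pop(), picked.pop()
        s1 = int(rng.integers(10_000, len(ref[c1]) - segment_length - 10_000 + 1))
        s2 = int(rng.integers(10_000, len(ref[c2]) - segment_length - 10_000 + 1))
        a = ref[c1][s1:s1 + segment_length].copy()
        ref[c1][s1:s1 + segment_length] = ref[c2][s2:s2 + segment_length]
        ref[c2][s2:s2 + segment_length] = a
        segments[c1].append((s1, s1 + segment_length, "+", c2, s2))
        segments[c2].append((s2, s2 + segment_length, "+", c1, s1))

    blocks: list[BlockTruth] = []
    for c in chroms:
        L = len(ref[c])
        cuts = sorted(segments[c], key=lambda t: t[0])
        pos = 0
        for s, e, orient, src, src_s in cuts:
            if s > pos:
                blocks.append(BlockTruth(c, pos, s, c, pos, s, "+"))
            blocks.append(BlockTruth(src, src_s, src_s + (e - s), c, s, e, orient))
            pos = e
        if pos < L:
            blocks.append(BlockTruth(c, pos, L, c, pos, L, "+"))

    if divergence > 0:
        for c in chroms:
            arr = ref[c]
            mask = rng.random(len(arr)) < divergence
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            arr[mask] = (arr[mask] + shift) % 4
    return {c: decode(a) for c, a in ref.items()}, blocks


def simulate_alignments(layout: TruthLayout, blocks: list[BlockTruth],
                        divergence: float = 0.0, piece_length: int = 8000,
                        piece_gap: int = 200, seed: int = 0
                        ) -> list[AlignmentRecord]:
    """Emit contig-vs-reference local alignment records implied by the truth.

    Each true collinear block is intersected with each contig placement,
    the intersection chopped into ``piece_length`` pieces separated by
    ``piece_gap``, and coordinates composed through contig orientation and
    block orientation.  Identity is ``100*(1 - divergence)`` with mild
    per-piece jitter — the table a whole-genome aligner would produce,
    minus alignment noise.
    """
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    base_identity = 100.0 * (1.0 - divergence)
    for chrom, placements in layout.contig_order.items():
        for cid, orient, cstart, cend in placements:
            clen = cend - cstart
            for blk in blocks:
                if blk.query_id != chrom:
                    continue
                lo = max(cstart, blk.qstart)
                hi = min(cend, blk.qend)
                if hi - lo < 500:
                    continue
                pos = lo
                while pos < hi:
                    pe = min(pos + piece_length, hi)
                    if pe - pos >= 500:
                        # genome -> contig coordinates
                        if orient == "+":
                            q0, q1 = pos - cstart, pe - cstart
                        else:
                            q0, q1 = cend - pe, cend - pos
                        # genome -> reference coordinates
                        if blk.orientation == "+":
                            t0 = blk.rstart + (pos - blk.qstart)
                            t1 = blk.rstart + (pe - blk.qstart)
                        else:
                            t0 = blk.rstart + (blk.qend - pe)
                            t1 = blk.rstart + (blk.qend - pos)
                        strand = "+" if (orient == blk.orientation) else "-"
                        ident = min(100.0, base_identity + float(rng.normal(0, 0.2)))
                        records.append(AlignmentRecord(
                            query_id=cid, qstart=q0, qend=q1,
                            target_id=blk.ref_id, tstart=t0, tend=t1,
                            strand=strand, identity=ident, length=pe - pos,
                            score=(pe - pos) * ident / 100.0))
                    pos = pe + piece_gap
    return records


def simulate_markers(layout: TruthLayout, contigs: dict[str, str],
                     n_markers: int, marker_length: int = 500, seed: int = 0,
                     n_mutated: int = 0, mutate_fraction: float = 0.15
                     ) -> tuple[dict[str, str], list[MarkerTruth]]:
    """Draw linkage-map marker sequences from contig interiors.

    The linkage group of a marker is the chromosome its contig derives
    from.  The first ``n_mutated`` markers are negative controls with
    ``mutate_fraction`` of their bases substituted, designed to fall
    below a 90% identity filter.
    """
    rng = np.random.default_rng(seed)
    chrom_of = layout.contig_chrom()
    usable = [(cid, len(contigs[cid])) for cid in chrom_of
              if len(contigs[cid]) >= marker_length + 20]
    if not usable:
        raise ValueError("no contig long enough to host a marker")
    total_positions = sum(l - marker_length - 19 for _, l in usable)
    if n_markers > total_positions:
        raise ValueError("n_markers exceeds placeable positions")
    weights = np.array([l for _, l in usable], dtype=float)
    idx = rng.choice(len(usable), size=n_markers, p=weights / weights.sum())
    markers: dict[str, str] = {}
    truth: list[MarkerTruth] = []
    for i, ui in enumerate(idx):
        cid, clen = usable[ui]
        off = int(rng.integers(10, clen - marker_length - 10 + 1))
        seq = contigs[cid][off:off + marker_length]
        mutated = i < n_mutated
        if mutated:
            arr = encode(seq)
            n_mut = max(1, int(round(mutate_fraction * marker_length)))
            pos = rng.choice(marker_length, size=n_mut, replace=False)
            arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
            seq = decode(arr)
        mid = f"marker_{i:04d}"
        markers[mid] = seq
        truth.append(MarkerTruth(mid, chrom_of[cid], cid, off, marker_length, mutated))
    return markers, truth


def simulate_marker_hits(markers: dict[str, str], truth: list[MarkerTruth],
                         contigs: dict[str, str], n_decoys: int = 0,
                         seed: int = 0):
    """Build the alignment-hit table a marker BLAST search would yield.

    The true hit aligns each marker to its source position (identity by
    positional comparison, full coverage); optional decoys add weaker
    hits on random other contigs.
    """
    from .anchoring import MarkerHit  # local import to avoid a cycle
    from .seq import hamming_identity

    rng = np.random.default_rng(seed)
    ids = list(contigs)
    hits: list[MarkerHit] = []
    chrom_of = {t.marker_id: t for t in truth}
    for t in truth:
        mseq = markers[t.marker_id]
        ref = contigs[t.contig_id][t.offset:t.offset + t.length]
        ident = hamming_identity(mseq, ref)
        hits.append(MarkerHit(
            marker_id=t.marker_id, linkage_group=t.linkage_group,
            target_id=t.contig_id, identity=ident, coverage=100.0,
            score=t.length * ident / 100.0,
            tstart=t.offset, tend=t.offset + t.length))
        for _ in range(n_decoys):
            other = ids[int(rng.integers(0, len(ids)))]
            if other == t.contig_id:
                continue
            ident_d = float(rng.uniform(70, 88))
            cov_d = float(rng.uniform(40, 75))
            alen = int(t.length * cov_d / 100)
            start = int(rng.integers(0, max(1, len(contigs[other]) - alen)))
            hits.append(MarkerHit(
                marker_id=t.marker_id, linkage_group=t.linkage_group,
                target_id=other, identity=ident_d, coverage=cov_d,
                score=alen * ident_d / 100.0,
                tstart=start, tend=start + alen))
    return hits
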