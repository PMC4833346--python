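"""Collinear synteny blocks and reference-guided contig ordering.

Whole-genome alignment tables are reduced to 1:1 coverage, chained into
collinear blocks (two passes: short spurious blocks removed after the
first pass so flanking runs can merge in the second), summarized into
coverage / block-N50 / rearrangement statistics, and used to order and
orient contigs along reference chromosomes.  Contig links can then be
reconciled against independent partial orders (e.g. optical-map contig
sequences) and linkage-group assignments before scaffold sequences are
emitted with N gaps.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io import AgpRow, AlignmentRecord
from .seq import revcomp

__all__ = [
    "SyntenyBlock", "ContigLink", "BlockStats",
    "filter_one_to_one", "build_blocks", "block_stats",
    "order_contigs", "links_from_order", "reconcile_links", "emit_scaffolds",
]


@dataclass
class SyntenyBlock:
    query_id: str
    qstart: int
    qend: int
    target_id: str
    tstart: int
    tend: int
    orientation: str
    members: list[AlignmentRecord] = field(default_factory=list, repr=False)

    @property
    def span_length(self) -> int:
        return self.qend - self.qstart

    @property
    def target_span(self) -> int:
        return self.tend - self.tstart


@dataclass
class ContigLink:
    left: tuple[str, str]    # (contig_id, orientation)
    right: tuple[str, str]
    source: str = "synteny"  # synteny | map | linkage
    ref_chrom: str | None = None


@dataclass
class BlockStats:
    coverage: float
    block_n50: int
    n_rearrangements: int


def filter_one_to_one(alignments: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Greedy 1:1 filtering: keep alignments in descending score order,
    dropping any that overlaps a retained alignment on either genome.

    After filtering, every query and every target position is covered by
    at most one retained alignment.
    """
    q_cov: dict[str, IntervalTree] = defaultdict(IntervalTree)
    t_cov: dict[str, IntervalTree] = defaultdict(IntervalTree)
    kept: list[AlignmentRecord] = []
    for a in sorted(alignments, key=lambda r: (-r.score, r.query_id, r.qstart)):
        if q_cov[a.query_id].overlaps(a.qstart, a.qend):
            continue
        if t_cov[a.target_id].overlaps(a.tstart, a.tend):
            continue
        q_cov[a.query_id].addi(a.qstart, a.qend)
        t_cov[a.target_id].addi(a.tstart, a.tend)
        kept.append(a)
    kept.sort(key=lambda r: (r.query_id, r.qstart))
    return kept


def _chain(alignments: list[AlignmentRecord], max_gap: int) -> list[SyntenyBlock]:
    groups: dict[tuple, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        groups[(a.query_id, a.target_id, a.strand)].append(a)
    blocks: list[SyntenyBlock] = []
    for (q, t, strand), mem in groups.items():
        mem.sort(key=lambda r: r.qstart)
        run: list[AlignmentRecord] = []
        for a in mem:
            if run and _extends(run[-1], a, strand, max_gap):
                run.append(a)
            else:
                if run:
                    blocks.append(_close_block(q, t, strand, run))
                run = [a]
        if run:
            blocks.append(_close_block(q, t, strand, run))
    return blocks


def _extends(prev: AlignmentRecord, nxt: AlignmentRecord, strand: str,
             max_gap: int) -> bool:
    if not 0 <= nxt.qstart - prev.qend <= max_gap:
        return False
    if strand == "+":
        return 0 <= nxt.tstart - prev.tend <= max_gap
    return 0 <= prev.tstart - nxt.tend <= max_gap


def _close_block(q, t, strand, members) -> SyntenyBlock:
    return SyntenyBlock(
        query_id=q,
        qstart=min(m.qstart for m in members), qend=max(m.qend for m in members),
        target_id=t,
        tstart=min(m.tstart for m in members), tend=max(m.tend for m in members),
        orientation=strand, members=list(members))


def build_blocks(alignments: list[AlignmentRecord], min_block: int = 6000,
                 max_gap: int = 50_000) -> list[SyntenyBlock]:
    """Two-pass collinear chaining.

    Pass 1 chains same-(query, target, orientation) alignments that are
    monotone in both genomes within ``max_gap``.  Blocks spanning less
    than ``min_block`` on the query are spurious interruptions: their
    members are discarded and the remainder re-chained, letting the
    flanking runs merge across the removed block.  Exactly ``min_block``
    is retained (strictly-shorter removal).
    """
    pass1 = _chain(alignments, max_gap)
    survivors: list[AlignmentRecord] = []
    for b in pass1:
        if b.span_length >= min_block:
            survivors.extend(b.members)
    blocks = _chain(survivors, max_gap)
    blocks.sort(key=lambda b: (b.query_id, b.qstart))
    return blocks


def block_stats(blocks: list[SyntenyBlock], assembly_lengths: dict[str, int],
                rearrangement_min: int = 200_000) -> BlockStats:
    """Coverage fraction, block N50 and intrachromosomal rearrangement count.

    A block is a rearrangement when, relative to the dominant collinear
    order of its query chromosome on that chromosome's dominant target,
    it is inverted or out of order, and spans more than
    ``rearrangement_min`` on the query.
    """
    from .asm_stats import nx_stats

    total = sum(assembly_lengths.values())
    covered = sum(b.span_length for b in blocks)
    coverage = covered / total if total else 0.0
    n50 = nx_stats([b.span_length for b in blocks], 50)[0] if blocks else 0
    n_rearr = sum(len(v) for v in rearranged_blocks(blocks, rearrangement_min).values())
    return BlockStats(coverage=coverage, block_n50=n50, n_rearrangements=n_rearr)


def rearranged_blocks(blocks: list[SyntenyBlock], rearrangement_min: int = 200_000
                      ) -> dict[str, list[SyntenyBlock]]:
    """Blocks breaking the dominant order/orientation of their chromosome."""
    by_query: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        by_query[b.query_id].append(b)
    out: dict[str, list[SyntenyBlock]] = {}
    for q, bs in by_query.items():
        span_by_target: dict[str, int] = defaultdict(int)
        for b in bs:
            span_by_target[b.target_id] += b.span_length
        dom_target = max(span_by_target, key=span_by_target.get)
        bs = [b for b in bs if b.target_id == dom_target]
        plus = sum(b.span_length for b in bs if b.orientation == "+")
        minus = sum(b.span_length for b in bs if b.orientation == "-")
        dom_orient = "+" if plus >= minus else "-"
        bs.sort(key=lambda b: (b.qstart + b.qend) / 2)
        mids = [(b.tstart + b.tend) / 2 for b in bs]
        if dom_orient == "-":
            mids = [-m for m in mids]
        in_order = _lis_mask(mids)
        bad = [b for i, b in enumerate(bs)
               if (b.orientation != dom_orient or not in_order[i])
               and b.span_length > rearrangement_min]
        if bad:
            out[q] = bad
    return out


def _lis_mask(values) -> list[bool]:
    """Mark members of one longest non-decreasing subsequence."""
    n = len(values)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] <= values[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    mask = [False] * n
    while end != -1:
        mask[end] = True
        end = prev[end]
    return mask


def order_contigs(blocks: list[SyntenyBlock], min_dominance: float = 0.6
                  ) -> tuple[dict[str, list[tuple[str, str]]], list[str]]:
    """Order and orient contigs along reference chromosomes.

    Each contig goes to the chromosome holding the largest summed block
    span, provided that strictly exceeds ``min_dominance`` (default 0.6)
    of its total span — an exact 60/40 split across two chromosomes is
    ambiguous; otherwise the contig is left unplaced and reported.  Within a
    chromosome, contigs sort by span-weighted mean target midpoint, and
    take the orientation of the dominant span.
    """
    per_contig: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        per_contig[b.query_id].append(b)
    placements: dict[str, list[tuple[float, str, str]]] = defaultdict(list)
    unplaced: list[str] = []
    for contig, bs in per_contig.items():
        span_by_target: dict[str, int] = defaultdict(int)
        for b in bs:
            span_by_target[b.target_id] += b.span_length
        total = sum(span_by_target.values())
        dom = max(span_by_target, key=span_by_target.get)
        if span_by_target[dom] <= min_dominance * total:
            unplaced.append(contig)
            continue
        dbs = [b for b in bs if b.target_id == dom]
        plus = sum(b.span_length for b in dbs if b.orientation == "+")
        minus = sum(b.span_length for b in dbs if b.orientation == "-")
        orient = "+" if plus >= minus else "-"
        wsum = sum(((b.tstart + b.tend) / 2) * b.span_length for b in dbs)
        pos = wsum / sum(b.span_length for b in dbs)
        placements[dom].append((pos, contig, orient))
    ordered = {chrom: [(cid, o) for _, cid, o in sorted(pl)]
               for chrom, pl in placements.items()}
    return ordered, sorted(unplaced)


def links_from_order(ordered: dict[str, list[tuple[str, str]]],
                     source: str = "synteny") -> list[ContigLink]:
    links = []
    for chrom, contigs in ordered.items():
        for a, b in zip(contigs, contigs[1:]):
            links.append(ContigLink(left=a, right=b, source=source, ref_chrom=chrom))
    return links


def reconcile_links(links: list[ContigLink],
                    constraint_orders: list[list[str]] = (),
                    lg_assignments: dict[str, str] | None = None
                    ) -> tuple[list[ContigLink], list[tuple[ContigLink, str]]]:
    """Filter contig links against independent ordering evidence.

    A link is rejected when a constraint order places its two contigs
    non-adjacently, or when the contigs carry different linkage-group
    assignments.  Accepted links must form simple paths: a contig end
    may participate in at most one link, and a link closing a cycle is
    an error.  Returns (accepted, rejected-with-reason).
    """
    indexes = [{cid: i for i, cid in enumerate(order)} for order in constraint_orders]
    accepted: list[ContigLink] = []
    rejected: list[tuple[ContigLink, str]] = []
    right_used: set[str] = set()
    left_used: set[str] = set()
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for link in links:
        a, b = link.left[0], link.right[0]
        reason = None
        for idx in indexes:
            if a in idx and b in idx and abs(idx[a] - idx[b]) != 1:
                reason = "constraint order places contigs non-adjacently"
                break
        if reason is None and lg_assignments:
            la, lb = lg_assignments.get(a), lg_assignments.get(b)
            if la is not None and lb is not None and la != lb:
                reason = f"linkage-group conflict ({la} vs {lb})"
        if reason is None and (a in right_used or b in left_used):
            reason = "contig end already linked"
        if reason is not None:
            rejected.append((link, reason))
            continue
        if find(a) == find(b):
            raise ValueError(f"accepted links would form a cycle at {a}–{b}")
        parent[find(a)] = find(b)
        right_used.add(a)
        left_used.add(b)
        accepted.append(link)
    return accepted, rejected


def emit_scaffolds(ordered: dict[str, list[tuple[str, str]]],
                   contig_seqs: dict[str, str], gap_length: int = 100
                   ) -> tuple[dict[str, str], list[AgpRow]]:
    """Join oriented contigs into scaffold sequences with N gaps.

    Returns the scaffold FASTA dict and AGP v2.1 rows (1-based on disk).
    Total non-N output length equals the summed contig lengths; a contig
    placed twice is an error.
    """
    placed: set[str] = set()
    scaffolds: dict[str, str] = {}
    rows: list[AgpRow] = []
    for name, contigs in ordered.items():
        if not contigs:
            continue
        parts: list[str] = []
        pos = 0
        part_no = 0
        for i, (cid, orient) in enumerate(contigs):
            if cid in placed:
                raise ValueError(f"contig {cid} placed more than once")
            placed.add(cid)
            if i > 0 and gap_length > 0:
                part_no += 1
                rows.append(AgpRow(name, pos + 1, pos + gap_length, part_no, "N",
                                   gap_length=gap_length))
                parts.append("N" * gap_length)
                pos += gap_length
            seq = contig_seqs[cid]
            if orient == "-":
                seq = revcomp(seq)
            part_no += 1
            rows.append(AgpRow(name, pos + 1, pos + len(seq), part_no, "W",
                               component_id=cid, component_beg=1,
                               component_end=len(seq), orientation=orient))
            parts.append(seq)
            pos += len(seq)
        scaffolds[name] = "".join(parts)
    return scaffolds, rows
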