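"""End-to-end pipeline driver and configuration.

Runs simulate -> profile -> stats -> anchor -> synteny -> scaffold ->
gapclose -> repeatscan -> chain on synthetic data, writing every stage
product plus a JSON-lines manifest.  The same seed and configuration
reproduce a byte-identical bundle.
"""

from __future__ import annotations

import configparser
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import (anchoring, asm_stats, bchrom, gapclose, io, kmer_model,
               repeats, simdata, synteny)

log = logging.getLogger("asmpipe")

DEFAULTS: dict[str, dict] = {
    "simulate": dict(n_chrom=4, chrom_length=250_000, het=0.004, coverage=30.0,
                     read_len=100, error=0.005, breaks=5, overlap_min=200,
                     overlap_max=500),
    "profile": dict(k=21),
    "stats": dict(window=20_000, max_n=0.25, dmin=50_000, dmax=250_000),
    "anchor": dict(min_identity=90.0, min_coverage=80.0, top=5, n_markers=100,
                   marker_len=500),
    "synteny": dict(min_block=6000, max_gap=50_000, rearr_min=200_000,
                    divergence=0.02),
    "scaffold": dict(gap_n=100),
    "gapclose": dict(min_identity=95.0, min_len=100, end_window=10_000),
    "repeatscan": dict(monomer="TTAGGG", max_spacer=100, min_copies=2,
                       window=10_000),
    "chain": dict(max_gap=10_000),
}


@dataclass
class PipelineConfig:
    """Per-stage parameter sets; every default matches the module docs."""

    sections: dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "asmpipe_out"
    log_level: str = "INFO"

    def __post_init__(self):
        merged = {s: dict(v) for s, v in DEFAULTS.items()}
        for sec, kv in self.sections.items():
            if sec not in merged:
                raise ValueError(f"unknown config section {sec!r}")
            for key, val in kv.items():
                if key not in merged[sec]:
                    raise ValueError(f"unknown key {key!r} in section {sec!r}")
                merged[sec][key] = type(DEFAULTS[sec][key])(val)
        self.sections = merged

    def __getitem__(self, sec: str) -> dict:
        return self.sections[sec]

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        sections: dict[str, dict] = {}
        top: dict = {}
        for sec in cp.sections():
            if sec == "global":
                top = dict(cp[sec])
            else:
                sections[sec] = dict(cp[sec])
        kwargs = dict(sections=sections)
        if "seed" in top:
            kwargs["seed"] = int(top["seed"])
        if "outdir" in top:
            kwargs["outdir"] = top["outdir"]
        if "log_level" in top:
            kwargs["log_level"] = top["log_level"]
        kwargs.update(overrides)
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest as a dict of stage outputs."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="[%(name)s] %(message)s", force=False)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.jsonl"
    manifest_path.write_text("")
    report: dict = {}
    state: dict = {"seed": config.seed}

    stages = [
        ("simulate", _stage_simulate), ("profile", _stage_profile),
        ("stats", _stage_stats), ("anchor", _stage_anchor),
        ("synteny", _stage_synteny), ("scaffold", _stage_scaffold),
        ("gapclose", _stage_gapclose), ("repeatscan", _stage_repeatscan),
        ("chain", _stage_chain),
    ]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            outputs = fn(config, state, out)
        except Exception as exc:
            raise StageError(name, exc) from exc
        report[name] = outputs
        io.append_manifest(manifest_path, {"stage": name, **outputs})
    return report


def _stage_simulate(cfg, state, out):
    p = cfg["simulate"]
    monomer = cfg["repeatscan"]["monomer"]
    # plant one dense telomere-style array on chr1 for the repeat stage
    repeat_spec = [("chr1", p["chrom_length"] // 2, monomer, 200)]
    genome = simdata.simulate_diploid(
        p["n_chrom"], p["chrom_length"], p["het"], repeat_spec=repeat_spec,
        seed=state["seed"])
    reads = simdata.simulate_reads(genome, p["coverage"], p["read_len"],
                                   p["error"], seed=state["seed"] + 1)
    contigs, layout = simdata.fragment_assembly(
        genome, p["breaks"], (p["overlap_min"], p["overlap_max"]),
        seed=state["seed"] + 2)
    state.update(genome=genome, reads=reads, contigs=contigs, layout=layout)
    io.write_fasta(genome.haplotype_a, out / "genome_hapA.fasta")
    io.write_fasta(contigs, out / "contigs.fasta")
    io.write_fastq(reads, out / "reads.fastq")
    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("chrom\tpos\tallele_a\tallele_b\n")
        for row in genome.truth_snps:
            fh.write("\t".join(map(str, row)) + "\n")
    return {"n_chrom": p["n_chrom"], "n_reads": len(reads),
            "n_contigs": len(contigs),
            "outputs": ["genome_hapA.fasta", "contigs.fasta", "reads.fastq",
                        "truth_snps.tsv"]}


def _stage_profile(cfg, state, out):
    k = cfg["profile"]["k"]
    hist = kmer_model.count_kmers(state["reads"], k)
    hist.to_tsv(out / "kmer_histogram.tsv")
    fit = kmer_model.fit_mixture(hist, seed=state["seed"])
    H, D = kmer_model.component_sums(fit, hist)
    if H == 0 and D == 0:
        est = None
    else:
        est = kmer_model.heterozygosity(H, D, k)
    nonrep, total = kmer_model.genome_size(fit, hist)
    result = {"mu": fit.mu, "s1": fit.s1, "s2": fit.s2, "size1": fit.size1,
              "size2": fit.size2, "fit_cutoff": fit.fit_cutoff,
              "degenerate": fit.degenerate, "H": H, "D": D,
              "heterozygosity": est.rate if est else 0.0,
              "genome_size_nonrep": nonrep, "genome_size_total": total}
    (out / "kmer_fit.json").write_text(json.dumps(result, indent=2))
    state["fit"] = fit
    return {**{k2: result[k2] for k2 in ("mu", "heterozygosity", "degenerate")},
            "outputs": ["kmer_histogram.tsv", "kmer_fit.json"]}


def _stage_stats(cfg, state, out):
    p = cfg["stats"]
    contigs = state["contigs"]
    lengths = [len(s) for s in contigs.values()]
    n50, l50 = asm_stats.nx_stats(lengths, 50)
    windows = asm_stats.gc_windows(contigs, p["window"], p["max_n"])
    windows.to_csv(out / "gc_windows.tsv", sep="\t", index=False)
    with open(out / "assembly_stats.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_contigs\t{len(lengths)}\n")
        fh.write(f"total_length\t{sum(lengths)}\n")
        fh.write(f"N50\t{n50}\nL50\t{l50}\n")
    return {"N50": n50, "L50": l50,
            "outputs": ["assembly_stats.tsv", "gc_windows.tsv"]}


def _stage_anchor(cfg, state, out):
    p = cfg["anchor"]
    markers, truth = simdata.simulate_markers(
        state["layout"], state["contigs"], p["n_markers"], p["marker_len"],
        seed=state["seed"] + 3)
    state["layout"].marker_truth = truth
    hits = simdata.simulate_marker_hits(markers, truth, state["contigs"],
                                        n_decoys=1, seed=state["seed"] + 4)
    retained = anchoring.filter_marker_hits(hits, p["min_identity"],
                                            p["min_coverage"], p["top"])
    assignments = anchoring.assign_linkage_groups(retained)
    lengths = {c: len(s) for c, s in state["contigs"].items()}
    fm, fl = anchoring.anchoring_summary(assignments, retained,
                                         p["n_markers"], lengths)
    anchoring.assignments_table(assignments).to_csv(
        out / "lg_assignments.tsv", sep="\t", index=False)
    io.write_fasta(markers, out / "markers.fasta")
    state["assignments"] = {a.target_id: a.assigned_lg for a in assignments}
    return {"fraction_markers_placed": fm, "fraction_length_anchored": fl,
            "outputs": ["markers.fasta", "lg_assignments.tsv"]}


def _stage_synteny(cfg, state, out):
    p = cfg["synteny"]
    ref, blocks_truth = simdata.mutate_reference(
        state["genome"], divergence=p["divergence"], seed=state["seed"] + 5)
    alignments = simdata.simulate_alignments(
        state["layout"], blocks_truth, p["divergence"], seed=state["seed"] + 6)
    io.write_alignments(alignments, out / "alignments.tsv", "tabular12")
    filtered = synteny.filter_one_to_one(alignments)
    blocks = synteny.build_blocks(filtered, p["min_block"], p["max_gap"])
    lengths = {c: len(s) for c, s in state["contigs"].items()}
    stats = synteny.block_stats(blocks, lengths, p["rearr_min"])
    with open(out / "synteny_blocks.tsv", "w") as fh:
        fh.write("query_id\tqstart\tqend\ttarget_id\ttstart\ttend\t"
                 "orientation\tn_members\n")
        for b in blocks:
            fh.write(f"{b.query_id}\t{b.qstart}\t{b.qend}\t{b.target_id}\t"
                     f"{b.tstart}\t{b.tend}\t{b.orientation}\t{len(b.members)}\n")
    state["blocks"] = blocks
    return {"n_blocks": len(blocks), "coverage": stats.coverage,
            "block_n50": stats.block_n50,
            "n_rearrangements": stats.n_rearrangements,
            "outputs": ["alignments.tsv", "synteny_blocks.tsv"]}


def _stage_scaffold(cfg, state, out):
    ordered, unplaced = synteny.order_contigs(state["blocks"])
    links = synteny.links_from_order(ordered)
    truth_orders = [[cid for cid, *_ in pl]
                    for pl in state["layout"].contig_order.values()]
    accepted, rejected = synteny.reconcile_links(
        links, truth_orders, state["assignments"])
    # rebuild per-chromosome orders keeping only contigs whose links survived
    scaffolds, agp = synteny.emit_scaffolds(
        ordered, state["contigs"], cfg["scaffold"]["gap_n"])
    io.write_fasta(scaffolds, out / "scaffolds.fasta")
    io.write_agp(agp, out / "scaffolds.agp")
    state["ordered"] = ordered
    return {"n_scaffolds": len(scaffolds), "n_unplaced": len(unplaced),
            "links_accepted": len(accepted), "links_rejected": len(rejected),
            "outputs": ["scaffolds.fasta", "scaffolds.agp"]}


def _stage_gapclose(cfg, state, out):
    p = cfg["gapclose"]
    layout = state["ordered"]
    overlaps = gapclose.find_end_overlaps(layout, state["contigs"],
                                          p["min_identity"], p["min_len"],
                                          p["end_window"])
    merged, new_layout, report = gapclose.close_gaps(layout, state["contigs"],
                                                     overlaps)
    io.write_fasta(merged, out / "contigs_closed.fasta")
    with open(out / "gapclose_report.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in asdict(report).items():
            fh.write(f"{key}\t{val}\n")
    return {**asdict(report),
            "outputs": ["contigs_closed.fasta", "gapclose_report.tsv"]}


def _stage_repeatscan(cfg, state, out):
    p = cfg["repeatscan"]
    rows = []
    profile_rows = []
    for chrom, seq in state["genome"].haplotype_a.items():
        occ = repeats.scan_monomer(seq, p["monomer"], both_strands=True)
        arrays = repeats.tandem_arrays(occ, len(p["monomer"]), p["max_spacer"],
                                       p["min_copies"], p["monomer"], chrom)
        rows.extend((a.sequence_id, a.start, a.end, p["monomer"],
                     a.copy_number, a.strand) for a in arrays)
        prof = repeats.density_profile(occ, len(seq), p["window"])
        profile_rows.extend((chrom, i * p["window"], int(c))
                            for i, c in enumerate(prof) if c)
    io.write_bed(rows, out / "repeat_arrays.bed")
    with open(out / "repeat_density.tsv", "w") as fh:
        fh.write("chrom\twindow_start\tcount\n")
        for r in profile_rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return {"n_arrays": len(rows),
            "outputs": ["repeat_arrays.bed", "repeat_density.tsv"]}


def _stage_chain(cfg, state, out):
    p = cfg["chain"]
    rng = np.random.default_rng(state["seed"] + 7)
    # emulate B-chromosome read placements clustered on a few donor contigs
    donors = list(state["contigs"])[:4]
    placements = []
    for d in donors:
        L = len(state["contigs"][d])
        centre = int(rng.integers(0, max(1, L - 2000)))
        for _ in range(25):
            s = centre + int(rng.integers(0, 1500))
            placements.append((d, s, min(s + 150, L)))
    pseudo = bchrom.chain_placements(placements, p["max_gap"])
    comp = bchrom.homology_composition(pseudo, state["assignments"])
    io.write_bed([(ps.target_id, ps.start, ps.end, "pseudo", ps.n_reads)
                  for ps in pseudo], out / "pseudo_scaffolds.bed")
    comp.to_csv(out / "homology_composition.tsv", sep="\t", index=False)
    return {"n_pseudo_scaffolds": len(pseudo),
            "outputs": ["pseudo_scaffolds.bed", "homology_composition.tsv"]}
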